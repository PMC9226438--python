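"""Dilated-convolution arithmetic, SCAM, residual blocks, assembly and
parameter accounting."""

import numpy as np
import pytest

import mpcstanet as m
from mpcstanet._engine import Adam, Tensor, conv2d, softmax_cross_entropy
from conftest import mini_variant


class TestDilationArithmetic:
    @pytest.mark.parametrize("k,r,expected", [(3, 2, 5), (3, 1, 3), (7, 1, 7),
                                              (7, 2, 13), (1, 5, 1)])
    def test_effective_kernel(self, k, r, expected):
        assert m.effective_kernel(k, r) == expected

    def test_effective_kernel_rejects_non_positive(self):
        with pytest.raises(m.ArchitectureError):
            m.effective_kernel(0, 1)

    @pytest.mark.parametrize("w1,k,r,s,p,expected", [
        (128, 7, 2, 2, 6, 64),   # dilated stem geometry
        (128, 7, 1, 2, 3, 64),   # plain stem geometry
        (5, 3, 1, 1, 1, 5),      # same-padding identity
        (9, 3, 2, 1, 2, 9),
    ])
    def test_conv_output_size_examples(self, w1, k, r, s, p, expected):
        spec = m.DilatedConvSpec(k=k, r=r, s=s, p=p)
        assert m.conv_output_size(w1, spec) == expected

    def test_kernel_larger_than_padded_input_raises(self):
        with pytest.raises(m.ArchitectureError, match="kernel larger"):
            m.conv_output_size(3, m.DilatedConvSpec(k=7, r=2, s=1, p=0))

    def test_formula_matches_sliding_window_count_and_real_convolutions(self):
        """Across 200 randomized geometries the closed form must agree
        with (a) a naive count of valid kernel placements and (b) the
        observed output shape of an actual convolution."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            w1 = int(rng.integers(3, 24))
            k = int(rng.integers(1, 6))
            r = int(rng.integers(1, 4))
            s = int(rng.integers(1, 4))
            p = int(rng.integers(0, 5))
            span = r * (k - 1) + 1
            if w1 + 2 * p < span:
                continue
            spec = m.DilatedConvSpec(k=k, r=r, s=s, p=p)
            predicted = m.conv_output_size(w1, spec)
            # (a) naive placement count: slide the dilated kernel
            naive = len(range(0, w1 + 2 * p - span + 1, s))
            assert predicted == naive
            # (b) empirical shape of a real convolution
            x = Tensor(rng.normal(size=(1, 1, w1, w1)).astype(np.float32))
            w = Tensor(rng.normal(size=(1, 1, k, k)).astype(np.float32))
            out = conv2d(x, w, stride=s, padding=p, dilation=r)
            assert out.shape[2] == out.shape[3] == predicted
            checked += 1


class TestStem:
    def test_output_spatial_size_is_quarter_input(self):
        x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 128, 128)).astype(np.float32))
        for use_dc in (False, True):
            stem = m.build_stem(use_dc).eval()
            assert stem(x).shape == (1, 64, 32, 32)

    def test_dilation_does_not_change_parameter_count(self):
        plain = m.build_stem(False)
        dilated = m.build_stem(True)
        assert m.count_parameters(plain).exact_count == \
            m.count_parameters(dilated).exact_count

    def test_constant_input_interior_equality_after_weight_copy(self):
        """On a constant image the plain and dilated stems agree wherever
        every kernel tap lands inside the image (zero padding makes the
        border rows/columns differ)."""
        plain = m.build_stem(False).eval()
        dilated = m.build_stem(True).eval()
        dilated.load_state_dict(plain.state_dict())
        x = Tensor(np.full((1, 3, 64, 64), 0.7, dtype=np.float32))
        a = plain(x).data
        b = dilated(x).data
        # stem conv stride 2 then pool stride 2: 4 output px per margin cover it
        interior = (slice(None), slice(None), slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(a[interior], b[interior], atol=1e-5)
        assert a.shape == b.shape


class TestScam:
    @pytest.mark.parametrize("shape", [(2, 3, 3), (3, 4, 2), (1, 5, 5)])
    def test_vectorized_matches_naive_loop_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        scam = m.SCAM(shape[0], rng=rng)
        x = rng.normal(size=shape)
        vec = m.scam_forward(scam, x)
        ref, _ = m.scam_forward_reference(x, scam.fh.weight.data, scam.fh.bias.data)
        np.testing.assert_allclose(vec, ref, atol=1e-5)

    def test_constant_input_gives_uniform_attention(self):
        rng = np.random.default_rng(1)
        scam = m.SCAM(2, rng=rng)
        x = np.full((2, 3, 3), 1.3)
        ref, info = m.scam_forward_reference(x, scam.fh.weight.data, scam.fh.bias.data)
        np.testing.assert_allclose(info["attn_vertical"], 1 / 3, atol=1e-12)
        np.testing.assert_allclose(info["c_i"], np.full_like(info["c_i"], 1.3),
                                   atol=1e-12)
        vec = m.scam_forward(scam, x)
        np.testing.assert_allclose(vec, ref, atol=1e-5)

    def test_shape_contract_and_gate_range(self):
        rng = np.random.default_rng(2)
        scam = m.SCAM(4, rng=rng)
        x = rng.normal(size=(4, 6, 5))
        out = m.scam_forward(scam, x)
        assert out.shape == x.shape
        _, info = m.scam_forward_reference(x, scam.fh.weight.data, scam.fh.bias.data)
        assert (info["gate"] > 0).all() and (info["gate"] < 1).all()
        np.testing.assert_allclose(info["attn_vertical"].sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_allclose(info["attn_horizontal"].sum(axis=1), 1.0, atol=1e-5)
        # max strategy dominates both contexts
        c_i_b = np.repeat(info["c_i"][:, :, None], x.shape[2], axis=2)
        c_ii_b = np.repeat(info["c_ii"][:, None, :], x.shape[1], axis=1)
        assert (info["max"] >= c_i_b - 1e-12).all()
        assert (info["max"] >= c_ii_b - 1e-12).all()

    def test_gating_shrinks_nonnegative_inputs(self):
        rng = np.random.default_rng(3)
        scam = m.SCAM(2, rng=rng)
        x = rng.uniform(0.0, 2.0, size=(2, 4, 4))
        out = m.scam_forward(scam, x)
        assert np.abs(out).max() <= np.abs(x).max()

    def test_rank_mismatch_raises(self):
        scam = m.SCAM(2)
        with pytest.raises(m.ArchitectureError, match="rank-3"):
            m.scam_forward(scam, np.zeros((2, 2)))


class TestBlocks:
    def test_identity_kind_preserves_shape(self):
        rng = np.random.default_rng(4)
        block = m.build_multi_phantom_block(
            m.BlockSpec("multi_identity", 256, 256, 64), rng=rng).eval()
        x = Tensor(rng.normal(size=(2, 256, 8, 8)).astype(np.float32))
        assert block(x).shape == (2, 256, 8, 8)

    def test_conv_kind_downsamples_and_projects(self):
        rng = np.random.default_rng(5)
        block = m.build_multi_phantom_block(
            m.BlockSpec("multi_conv", 256, 512, 128, spatial_stride=2), rng=rng).eval()
        x = Tensor(rng.normal(size=(2, 256, 8, 8)).astype(np.float32))
        assert block(x).shape == (2, 512, 4, 4)

    def test_four_way_split_widths(self):
        block = m.build_multi_phantom_block(m.BlockSpec("multi_identity", 256, 256, 64))
        assert block.group == 16
        for branch in (block.branch1, block.branch2a, block.branch3a, block.branch4):
            assert branch.in_channels == 16 and branch.out_channels == 16

    def test_invalid_specs_raise(self):
        with pytest.raises(m.ArchitectureError, match="four ways"):
            m.BlockSpec("multi_identity", 256, 256, 66)
        with pytest.raises(m.ArchitectureError, match="multi_identity"):
            m.BlockSpec("multi_identity", 128, 256, 64)
        with pytest.raises(m.ArchitectureError, match="kind"):
            m.BlockSpec("bottleneck", 128, 256, 64)


class TestAssembly:
    def test_forward_pass_shape_contract(self):
        model = mini_variant(False, False, False, seed=6).eval()
        x = Tensor(np.random.default_rng(6).normal(size=(2, 3, 32, 32)).astype(np.float32))
        assert model(x).shape == (2, 4)

    def test_all_flag_combinations_run_forward(self):
        x = Tensor(np.random.default_rng(7).normal(size=(1, 3, 32, 32)).astype(np.float32))
        for spec in m.ALL_VARIANTS:
            model = m.assemble_variant(
                m.VariantSpec(spec.use_dc, spec.use_mprb, spec.use_scam, head_classes=4),
                stage_blocks=(1, 1, 1, 1), width=8).eval()
            assert model(x).shape == (1, 4)

    def test_dilation_never_changes_budget(self):
        for use_mprb in (False, True):
            for use_scam in (False, True):
                a = m.assemble_variant(m.VariantSpec(False, use_mprb, use_scam),
                                       stage_blocks=(1, 1, 1, 1), width=8)
                b = m.assemble_variant(m.VariantSpec(True, use_mprb, use_scam),
                                       stage_blocks=(1, 1, 1, 1), width=8)
                assert m.count_parameters(a).exact_count == \
                    m.count_parameters(b).exact_count

    def test_gradient_reaches_every_stage(self):
        """One optimisation step must move parameters in stem, every
        residual stage and the head (no dead branches)."""
        model = mini_variant(seed=8)
        parts = {"stem": model.stem, "stage2": model.stage2, "stage3": model.stage3,
                 "stage4": model.stage4, "stage5": model.stage5, "fc": model.fc}
        before = {name: [p.data.copy() for p in part.parameters()]
                  for name, part in parts.items()}
        x = Tensor(np.random.default_rng(8).normal(size=(4, 3, 32, 32)).astype(np.float32))
        y = np.array([0, 1, 2, 3])
        opt = Adam(list(model.parameters()), lr=1e-2)
        loss = softmax_cross_entropy(model(x), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        for name, part in parts.items():
            changed = any(not np.array_equal(old, p.data)
                          for old, p in zip(before[name], part.parameters()))
            assert changed, f"no parameter changed in {name}"


class TestParamBudget:
    def test_lone_linear_layer(self):
        from mpcstanet._engine import Linear
        layer = Linear(2048, 1000)
        assert m.count_parameters(layer).exact_count == 2048 * 1000 + 1000

    def test_count_matches_independent_enumeration(self):
        model = mini_variant(seed=9)
        # independent walk: state_dict minus the (untrainable) running stats
        total = sum(
            arr.size for name, arr in model.state_dict().items()
            if not name.endswith(("running_mean", "running_var"))
        )
        assert m.count_parameters(model).exact_count == total

    def test_millions_rounds_half_up(self):
        assert m.ParamBudget(25_557_032).millions == 25.56
        assert m.ParamBudget(25_555_000).millions == 25.56  # .5 rounds up
        assert m.ParamBudget(21_104_999).millions == 21.10

    def test_variant_names(self):
        assert m.variant_name(m.VariantSpec(False, False, False)) == "ResNet50"
        assert m.variant_name(m.VariantSpec(True, False, True)) == "ResNet50-DC-SCAM"
        assert m.variant_name(m.VariantSpec(True, True, True)) == "MPC-STANet"
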