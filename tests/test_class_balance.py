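"""Augmentation ops, SMOTE, balancing planner and stratified split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mpcstanet as m
from mpcstanet.class_balance import _allocate


def make_record(pixels, label="ND"):
    return m.ImageRecord(np.asarray(pixels, dtype=np.uint8), label,
                         "original", f"{label}_original_00000")


class TestAugmentationOps:
    def test_flip_is_an_involution(self):
        rec = make_record(np.arange(16).reshape(4, 4))
        twice = m.flip_image(m.flip_image(rec, "horizontal"), "horizontal")
        np.testing.assert_array_equal(twice.pixels, rec.pixels)

    def test_flip_changes_an_asymmetric_pattern_but_not_its_histogram(self):
        rec = make_record(np.arange(16).reshape(4, 4))
        flipped = m.flip_image(rec, "horizontal")
        assert flipped.provenance == "augmented"
        assert (flipped.pixels != rec.pixels).any()
        np.testing.assert_array_equal(np.sort(flipped.pixels.ravel()),
                                      np.sort(rec.pixels.ravel()))

    def test_zero_sigma_noise_is_identity(self):
        rec = make_record(np.full((8, 8), 77))
        out = m.add_gaussian_noise(rec, 0.0, seed=1)
        np.testing.assert_array_equal(out.pixels, rec.pixels)

    def test_noise_sigma_is_calibrated(self):
        # mid-gray image so clipping cannot bias the empirical sd
        rec = make_record(np.full((128, 128), 128))
        out = m.add_gaussian_noise(rec, 10.0, seed=2)
        delta = out.pixels.astype(float) - rec.pixels.astype(float)
        assert 9.0 <= delta.std() <= 11.0

    def test_noise_is_deterministic_per_seed(self):
        rec = make_record(np.full((8, 8), 100))
        a = m.add_gaussian_noise(rec, 10.0, seed=3)
        b = m.add_gaussian_noise(rec, 10.0, seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_negative_sigma_raises(self):
        with pytest.raises(m.BalanceError):
            m.add_gaussian_noise(make_record(np.zeros((4, 4))), -1.0)

    def test_contrast_identity_and_collapse(self):
        rec = make_record([[100, 150], [100, 150]])
        np.testing.assert_array_equal(m.adjust_contrast(rec, 1.0).pixels, rec.pixels)
        assert (m.adjust_contrast(rec, 0.0).pixels == 125).all()

    def test_contrast_factor_two_spreads_levels(self):
        rec = make_record([[100, 150], [100, 150]])
        out = m.adjust_contrast(rec, 2.0)
        assert set(out.pixels.ravel()) == {75, 175}  # mean 125: 125±2*25

    def test_negative_contrast_raises(self):
        with pytest.raises(m.BalanceError):
            m.adjust_contrast(make_record(np.zeros((4, 4))), -0.5)


class TestSmotePrimitives:
    def test_euclidean_distance_3_4_5(self):
        assert m.euclidean_distance([0, 0], [3, 4]) == 5.0
        assert m.euclidean_distance([1, 2], [1, 2]) == 0.0

    def test_euclidean_distance_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        naive = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) ** 0.5
        assert m.euclidean_distance(a, b) == pytest.approx(naive)

    def test_euclidean_length_mismatch_raises(self):
        with pytest.raises(m.BalanceError, match="length mismatch"):
            m.euclidean_distance([1, 2], [1, 2, 3])

    def test_synthesize_endpoints(self):
        np.testing.assert_array_equal(m.smote_synthesize([4.0, 2.0], [9.0, 1.0], 0.0),
                                      [4.0, 2.0])
        np.testing.assert_array_equal(m.smote_synthesize([0.0], [2.0], 1.0), [2.0])

    def test_synthesize_uses_absolute_difference(self):
        # 5 + 0.5*|5-1| = 7: the literal form overshoots both endpoints
        np.testing.assert_array_equal(m.smote_synthesize([5.0], [1.0], 0.5), [7.0])

    def test_synthesize_canonical_stays_on_segment(self):
        np.testing.assert_array_equal(
            m.smote_synthesize([5.0], [1.0], 0.5, canonical=True), [3.0])

    def test_synthesize_u_out_of_range_raises(self):
        with pytest.raises(m.BalanceError, match="u must lie"):
            m.smote_synthesize([0.0], [1.0], 1.5)


class TestSmoteOversample:
    def test_count_law_5_3_2(self):
        rng = np.random.default_rng(1)
        samples = [rng.normal(size=4) for _ in range(5)]
        out = m.smote_oversample(samples, m.SmoteParams(K=2, N=3, seed=42))
        assert len(out) == 15

    def test_identical_inputs_give_identical_synthetics(self):
        v = np.array([3.0, 1.0, 4.0])
        out = m.smote_oversample([v, v, v], m.SmoteParams(K=2, N=2, seed=0))
        for s in out:
            np.testing.assert_array_equal(s, v)

    def test_too_few_samples_raises(self):
        with pytest.raises(m.BalanceError, match="cannot find neighbors"):
            m.smote_oversample([np.zeros(3)], m.SmoteParams(K=1, N=1))

    def test_k_not_below_t_raises(self):
        with pytest.raises(m.BalanceError, match="K must be"):
            m.smote_oversample([np.zeros(2), np.ones(2)], m.SmoteParams(K=2, N=1))

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(2)
        samples = [rng.normal(size=6) for _ in range(6)]
        a = m.smote_oversample(samples, m.SmoteParams(K=3, N=2, seed=9))
        b = m.smote_oversample(samples, m.SmoteParams(K=3, N=2, seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_single_neighbour_matches_exhaustive_oracle(self):
        """With K=1 every synthetic must use its base's true nearest
        neighbour, re-derived here by brute force."""
        pts = [np.array(p, dtype=float) for p in
               [(0.0, 0.0), (1.0, 0.2), (5.0, 5.0), (5.5, 4.4)]]
        out, trace = m.smote_oversample(pts, m.SmoteParams(K=1, N=2, seed=5),
                                        return_trace=True)
        for synth, (i, j, u) in zip(out, trace):
            dists = [m.euclidean_distance(pts[i], p) if k != i else np.inf
                     for k, p in enumerate(pts)]
            assert j == int(np.argmin(dists))
            np.testing.assert_allclose(synth, pts[i] + u * np.abs(pts[i] - pts[j]))
            assert 0.0 <= u <= 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(t=st.integers(2, 12), n=st.integers(1, 4), data=st.data())
    def test_count_law_and_componentwise_bounds_property(self, t, n, data):
        k = data.draw(st.integers(1, t - 1))
        rng = np.random.default_rng(t * 100 + n * 10 + k)
        samples = [rng.normal(size=3) for _ in range(t)]
        out, trace = m.smote_oversample(samples, m.SmoteParams(K=k, N=n, seed=7),
                                        return_trace=True)
        assert len(out) == n * t
        for synth, (i, j, u) in zip(out, trace):
            a, b = samples[i], samples[j]
            lo, hi = a, a + np.abs(a - b)
            assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()


class TestPlanBalance:
    def test_reference_distribution_quotas(self):
        plan = m.plan_balance(m.ClassDistribution(dict(m.REFERENCE_SCALE_COUNTS)))
        assert plan.target_count == 3200
        q = plan.quotas
        assert (q["VMD"].n_augmented, q["VMD"].n_smote) == (960, 0)
        assert (q["MD"].n_augmented, q["MD"].n_smote) == (2304, 0)
        assert (q["MOD"].n_augmented, q["MOD"].n_smote) == (192, 2944)
        assert all(q[label].total == 3200 for label in m.CLASS_LABELS)

    def test_balanced_distribution_needs_nothing(self):
        plan = m.plan_balance(m.ClassDistribution({l: 7 for l in m.CLASS_LABELS}))
        for quota in plan.quotas.values():
            assert (quota.n_augmented, quota.n_smote) == (0, 0)

    def test_small_deficit_is_pure_augmentation(self):
        plan = m.plan_balance(
            m.ClassDistribution({"ND": 10, "VMD": 4, "MD": 10, "MOD": 10}))
        assert (plan.quotas["VMD"].n_augmented, plan.quotas["VMD"].n_smote) == (6, 0)

    def test_empty_class_with_deficit_raises(self):
        with pytest.raises(m.BalanceError, match="no originals"):
            m.plan_balance(m.ClassDistribution({"ND": 5, "VMD": 2, "MD": 1, "MOD": 0}))


class TestBalanceDataset:
    def test_desk_scale_reaches_uniform_200(self, desk_dataset, balanced_desk_dataset):
        assert balanced_desk_dataset.distribution().counts == {
            label: 200 for label in m.CLASS_LABELS}
        assert len(balanced_desk_dataset) == 800

    def test_originals_survive_untouched(self, desk_dataset, balanced_desk_dataset):
        originals = [r for r in balanced_desk_dataset.records
                     if r.provenance == "original"]
        assert len(originals) == len(desk_dataset)
        for orig, kept in zip(desk_dataset.records, originals):
            assert kept.source_id == orig.source_id
            np.testing.assert_array_equal(kept.pixels, orig.pixels)

    def test_balanced_input_is_returned_unchanged(self, small_spec):
        ds = m.generate_dataset(
            m.ClassDistribution({l: 4 for l in m.CLASS_LABELS}), small_spec)
        out = m.balance_dataset(ds, m.plan_balance(ds.distribution()))
        assert [r.source_id for r in out.records] == [r.source_id for r in ds.records]

    def test_identical_seeds_give_byte_identical_manifests(self, tmp_path, small_spec):
        dist = m.ClassDistribution({"ND": 8, "VMD": 5, "MD": 3, "MOD": 2})
        paths = []
        for name in ("a", "b"):
            ds = m.generate_dataset(dist, small_spec)
            bal = m.balance_dataset(ds, m.plan_balance(dist),
                                    m.SmoteParams(seed=42), m.AugmentationConfig(seed=42))
            paths.append(bal.write_manifest(tmp_path / f"{name}.csv"))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_plan_dataset_mismatch_raises(self, small_spec):
        ds = m.generate_dataset(
            m.ClassDistribution({"ND": 4, "VMD": 2, "MD": 2, "MOD": 2}), small_spec)
        wrong = m.plan_balance(m.ClassDistribution({"ND": 5, "VMD": 2, "MD": 2, "MOD": 2}))
        with pytest.raises(m.BalanceError, match="plan mismatch"):
            m.balance_dataset(ds, wrong)

    def test_smote_records_are_valid_images(self, balanced_desk_dataset, small_spec):
        smote = [r for r in balanced_desk_dataset.records if r.provenance == "smote"]
        assert smote, "MOD deficit must trigger SMOTE"
        for rec in smote[:5]:
            assert rec.pixels.shape == (32, 32)
            assert rec.pixels.dtype == np.uint8


class TestSplitDataset:
    def test_ten_records_split_7_2_1(self, small_spec):
        ds = m.generate_dataset(
            m.ClassDistribution({"ND": 10, "VMD": 0, "MD": 0, "MOD": 0}), small_spec)
        split = m.split_dataset(ds, m.SplitSpec(seed=1))
        assert (len(split.train), len(split.test), len(split.validation)) == (7, 2, 1)

    def test_partitions_conserve_the_dataset(self, balanced_desk_dataset):
        split = m.split_dataset(balanced_desk_dataset, m.SplitSpec(seed=5))
        rejoined = sorted(
            [r.source_id for part in split for r in part.records])
        assert rejoined == sorted(r.source_id for r in balanced_desk_dataset.records)
        ids = [set(r.source_id for r in part.records) for part in split]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_partition_sizes_near_exact_ratios(self, balanced_desk_dataset):
        split = m.split_dataset(balanced_desk_dataset, m.SplitSpec(seed=5))
        n = len(balanced_desk_dataset)
        for part, ratio in zip(split, (0.7, 0.2, 0.1)):
            assert abs(len(part) - n * ratio) <= len(m.CLASS_LABELS)

    def test_largest_remainder_allocation(self):
        assert _allocate(10, (7.0, 2.0, 1.0)) == [7, 2, 1]
        assert sum(_allocate(11, (7.0, 2.0, 1.0))) == 11
        # 3 items: floors (2,0,0), largest fractional part 0.6 -> test
        assert _allocate(3, (7.0, 2.0, 1.0)) == [2, 1, 0]

    def test_tiny_class_warns(self, small_spec):
        ds = m.generate_dataset(
            m.ClassDistribution({"ND": 4, "VMD": 4, "MD": 4, "MOD": 2}), small_spec)
        with pytest.warns(UserWarning, match="partitions stay empty"):
            m.split_dataset(ds, m.SplitSpec(seed=2))

    def test_empty_dataset_raises(self):
        with pytest.raises(m.BalanceError, match="empty"):
            m.split_dataset(m.LabeledImageSet([]), m.SplitSpec())
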