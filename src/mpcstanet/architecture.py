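"""MPC-STANet architecture: dilated stem, Multi-Phantom Residual Blocks,
Space Conversion Attention, variant assembly and parameter accounting.

The network is a ResNet50 backbone (stages of 3/4/6/3 bottleneck blocks,
global average pool, fully connected head) with three orthogonal
modifications, each switchable through :class:`VariantSpec`:

* ``use_dc`` — the 7×7 stem convolution becomes a dilated convolution
  (dilation 2, padding 6), enlarging the receptive field at identical
  parameter count and output size;
* ``use_mprb`` — every bottleneck is replaced by a Multi-Phantom
  Residual Block: a four-way channel split with 1×1 / 3×3 / 5×5 /
  pooled-1×1 branches concatenated back together, and an average-pool
  projection shortcut on downsampling blocks;
* ``use_scam`` — Space Conversion Attention: axis-wise (row and column)
  attention contexts fused by sum, max and concatenation, projected by a
  1×1 convolution and applied as a logistic gate.

Parameter budgets are reported with the canonical 1000-way head so they
are comparable with published ResNet50 figures; training uses a 4-way
head for the four dementia stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from ._engine import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    concatenate,
    conv2d,
    max_pool2d,
    softmax,
    maximum,
)

__all__ = [
    "ArchitectureError",
    "DilatedConvSpec",
    "BlockSpec",
    "VariantSpec",
    "ParamBudget",
    "effective_kernel",
    "conv_output_size",
    "build_stem",
    "SCAM",
    "scam_forward",
    "scam_forward_reference",
    "build_multi_phantom_block",
    "MultiPhantomBlock",
    "Bottleneck",
    "MPCSTANet",
    "assemble_variant",
    "count_parameters",
    "ALL_VARIANTS",
    "variant_name",
]


class ArchitectureError(ValueError):
    """Invalid architecture configuration or input."""


# ---------------------------------------------------------------------------
# dilated-convolution arithmetic
# ---------------------------------------------------------------------------


def effective_kernel(k: int, r: int) -> int:
    """Effective kernel size of a k×k convolution at dilation rate r.

    K = k + (k-1)(r-1); with r=1 this reduces to k, and the worked
    example (k=3, r=2) gives a receptive field of 5.
    """
    if k < 1 or r < 1:
        raise ArchitectureError(f"kernel size and dilation rate must be >= 1, got k={k}, r={r}")
    return k + (k - 1) * (r - 1)


@dataclass
class DilatedConvSpec:
    """Geometry of one (possibly dilated) convolution."""

    k: int
    r: int = 1
    s: int = 1
    p: int = 0
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.k < 1 or self.r < 1 or self.s < 1 or self.p < 0:
            raise ArchitectureError(f"invalid convolution spec: {self}")

    @property
    def effective_kernel(self) -> int:
        return effective_kernel(self.k, self.r)

    def output_size(self, w1: int) -> int:
        return conv_output_size(w1, self)


def conv_output_size(w1: int, spec: DilatedConvSpec) -> int:
    """Output size of a dilated convolution: floor((W1+2p-r(k-1)-1)/s)+1."""
    w2 = (w1 + 2 * spec.p - spec.r * (spec.k - 1) - 1) // spec.s + 1
    if w2 < 1:
        raise ArchitectureError(
            f"kernel larger than padded input: W1={w1}, spec={spec} gives W2={w2}"
        )
    return w2


# ---------------------------------------------------------------------------
# stem (STAGE 1)
# ---------------------------------------------------------------------------


def build_stem(use_dc: bool, in_channels: int = 3, width: int = 64,
               rng: np.random.Generator | None = None) -> Sequential:
    """STAGE-1 stem: 7×7 convolution (dilated if ``use_dc``), BN, ReLU,
    3×3 max-pool stride 2.

    The dilated form (r=2, p=6) keeps both the output spatial size and
    the parameter count of the plain form (r=1, p=3).
    """
    rng = rng or np.random.default_rng(0)
    dilation = 2 if use_dc else 1
    padding = 6 if use_dc else 3
    return Sequential(
        Conv2d(in_channels, width, 7, stride=2, padding=padding, dilation=dilation,
               bias=False, rng=rng),
        BatchNorm2d(width),
        ReLU(),
        MaxPool2d(3, stride=2, padding=1),
    )


# ---------------------------------------------------------------------------
# Space Conversion Attention Mechanism
# ---------------------------------------------------------------------------


class SCAM(Module):
    """Space Conversion Attention: two-axis context attention gate.

    For input X (C×H×W): row descriptors h_i (mean over width, one
    C-vector per row) attend over each other with parameter-free scaled
    dot-product scores e_ij = h_i·h_j/√C, giving a vertical context c_I
    (C×H); columns symmetrically give the horizontal context c_II (C×W).
    The two contexts, their broadcast sum and broadcast elementwise max
    are concatenated channelwise (4C×H×W), projected back to C channels
    by a 1×1 convolution F_h and squashed by a logistic σ into a gate
    Weight ∈ (0,1); the output is X ⊙ Weight.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.fh = Conv2d(4 * channels, channels, 1, bias=True, rng=rng)

    def _axis_context(self, h: Tensor) -> Tensor:
        # h: (N, L, C) descriptors along one axis -> (N, L, C) contexts
        c = h.shape[-1]
        scores = (h @ h.transpose(0, 2, 1)) * (1.0 / math.sqrt(c))
        attn = softmax(scores, axis=-1)
        return attn @ h

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ArchitectureError(f"SCAM expects NCHW input, got shape {x.shape}")
        n, c, h, w = x.shape
        hv = x.mean(axis=3).transpose(0, 2, 1)          # (N, H, C) row descriptors
        hh = x.mean(axis=2).transpose(0, 2, 1)          # (N, W, C) column descriptors
        c_i = self._axis_context(hv).transpose(0, 2, 1).reshape(n, c, h, 1)
        c_ii = self._axis_context(hh).transpose(0, 2, 1).reshape(n, c, 1, w)
        c_i_b = c_i.broadcast_to((n, c, h, w))
        c_ii_b = c_ii.broadcast_to((n, c, h, w))
        add = c_i_b + c_ii_b
        mx = maximum(c_i_b, c_ii_b)
        spa = concatenate([c_i_b, c_ii_b, add, mx], axis=1)
        weight = self.fh(spa).sigmoid()
        return x * weight


def scam_forward(module: SCAM, x) -> np.ndarray:
    """Apply a SCAM module to a single C×H×W feature map (numpy in/out)."""
    arr = np.asarray(x, dtype=np.float32) if not isinstance(x, Tensor) else x.data
    if arr.ndim != 3:
        raise ArchitectureError(f"scam_forward expects a rank-3 C×H×W map, got rank {arr.ndim}")
    out = module(Tensor(arr[None]))
    return out.data[0]


def scam_forward_reference(x: np.ndarray, fh_weight: np.ndarray, fh_bias: np.ndarray):
    """Naive loop implementation of SCAM for a single C×H×W map.

    Independent of the vectorized path; used as an oracle.  Returns
    ``(output, info)`` where ``info`` carries the attention matrices and
    the gate for invariant checks.
    """
    x = np.asarray(x, dtype=np.float64)
    c, h, w = x.shape
    hv = np.zeros((c, h))
    for ch in range(c):
        for i in range(h):
            hv[ch, i] = x[ch, i, :].mean()
    hh = np.zeros((c, w))
    for ch in range(c):
        for j in range(w):
            hh[ch, j] = x[ch, :, j].mean()

    def contexts(desc: np.ndarray):
        _, n = desc.shape
        e = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                e[i, j] = float(desc[:, i] @ desc[:, j]) / math.sqrt(c)
        attn = np.zeros_like(e)
        for i in range(n):
            row = np.exp(e[i] - e[i].max())
            attn[i] = row / row.sum()
        ctx = np.zeros_like(desc)
        for i in range(n):
            for ch in range(c):
                ctx[ch, i] = sum(attn[i, j] * desc[ch, j] for j in range(n))
        return ctx, attn

    c_i, attn_v = contexts(hv)    # (C, H)
    c_ii, attn_h = contexts(hh)   # (C, W)
    c_i_b = np.repeat(c_i[:, :, None], w, axis=2)
    c_ii_b = np.repeat(c_ii[:, None, :], h, axis=1)
    add = c_i_b + c_ii_b
    mx = np.maximum(c_i_b, c_ii_b)
    spa = np.concatenate([c_i_b, c_ii_b, add, mx], axis=0)  # (4C, H, W)
    wmat = fh_weight.reshape(c, 4 * c).astype(np.float64)
    pre = np.einsum("of,fhw->ohw", wmat, spa) + fh_bias.astype(np.float64)[:, None, None]
    gate = 1.0 / (1.0 + np.exp(-pre))
    out = x * gate
    info = {"attn_vertical": attn_v, "attn_horizontal": attn_h,
            "c_i": c_i, "c_ii": c_ii, "gate": gate, "add": add, "max": mx}
    return out, info


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------


@dataclass
class BlockSpec:
    """Configuration of one residual block."""

    kind: str                      # "multi_conv" | "multi_identity"
    in_channels: int
    out_channels: int
    mid_channels: int
    spatial_stride: int = 1
    scam_enabled: bool = False

    def __post_init__(self):
        if self.kind not in ("multi_conv", "multi_identity"):
            raise ArchitectureError(f"unknown block kind {self.kind!r}")
        if self.mid_channels % 4 != 0:
            raise ArchitectureError(
                f"mid_channels must split four ways, got {self.mid_channels}"
            )
        if self.kind == "multi_identity":
            if self.in_channels != self.out_channels or self.spatial_stride != 1:
                raise ArchitectureError(
                    "multi_identity blocks require in_channels == out_channels and stride 1"
                )
        if self.spatial_stride not in (1, 2):
            raise ArchitectureError(f"spatial_stride must be 1 or 2, got {self.spatial_stride}")


class Bottleneck(Module):
    """Stock ResNet50 bottleneck (1×1 → 3×3 → 1×1), optional SCAM gate
    after the 3×3 convolution."""

    def __init__(self, in_channels: int, mid_channels: int, out_channels: int,
                 stride: int = 1, scam_enabled: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_channels, mid_channels, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid_channels)
        self.conv2 = Conv2d(mid_channels, mid_channels, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid_channels)
        self.conv3 = Conv2d(mid_channels, out_channels, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_channels)
        self.scam = SCAM(mid_channels, rng=rng) if scam_enabled else None
        if stride != 1 or in_channels != out_channels:
            self.downsample = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        if self.scam is not None:
            out = self.scam(out)
        out = self.bn3(self.conv3(out))
        shortcut = x if self.downsample is None else self.downsample(x)
        return (out + shortcut).relu()


class MultiPhantomBlock(Module):
    """Multi-Phantom Residual Block.

    Linear branch: 1×1 conv → BN → ReLU → four-way channel split with
    1×1 / (1×1,3×3) / (1×1,5×5) / (max-pool,1×1) branches → channel
    concat → BN → ReLU (Y) → optional Y + SCAM(Y) → 1×1 conv → BN.
    Shortcut: identity for the identity kind; 1×1 conv + BN for the conv
    kind, preceded by a 2×2 average pool (stride 2) when the block
    downsamples.  Output = ReLU(linear + shortcut).
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        mid, g = spec.mid_channels, spec.mid_channels // 4
        if 4 * g != mid:
            raise ArchitectureError("branch widths do not re-concatenate to mid_channels")
        self.group = g
        self.conv1 = Conv2d(spec.in_channels, mid, 1, stride=spec.spatial_stride,
                            bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.branch1 = Conv2d(g, g, 1, bias=False, rng=rng)
        self.branch2a = Conv2d(g, g, 1, bias=False, rng=rng)
        self.branch2b = Conv2d(g, g, 3, padding=1, bias=False, rng=rng)
        self.branch3a = Conv2d(g, g, 1, bias=False, rng=rng)
        self.branch3b = Conv2d(g, g, 5, padding=2, bias=False, rng=rng)
        self.branch4 = Conv2d(g, g, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.scam = SCAM(mid, rng=rng) if spec.scam_enabled else None
        self.conv3 = Conv2d(mid, spec.out_channels, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(spec.out_channels)
        if spec.kind == "multi_conv":
            layers: list[Module] = []
            if spec.spatial_stride == 2:
                layers.append(AvgPool2d(2, stride=2))
            layers += [Conv2d(spec.in_channels, spec.out_channels, 1, bias=False, rng=rng),
                       BatchNorm2d(spec.out_channels)]
            self.shortcut = Sequential(*layers)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        g = self.group
        out = self.bn1(self.conv1(x)).relu()
        parts = [out[:, i * g:(i + 1) * g] for i in range(4)]
        b1 = self.branch1(parts[0])
        b2 = self.branch2b(self.branch2a(parts[1]))
        b3 = self.branch3b(self.branch3a(parts[2]))
        b4 = self.branch4(max_pool2d(parts[3], 3, stride=1, padding=1))
        y = self.bn2(concatenate([b1, b2, b3, b4], axis=1)).relu()
        if self.scam is not None:
            y = y + self.scam(y)
        out = self.bn3(self.conv3(y))
        shortcut = x if self.shortcut is None else self.shortcut(x)
        return (out + shortcut).relu()


def build_multi_phantom_block(spec: BlockSpec,
                              rng: np.random.Generator | None = None) -> MultiPhantomBlock:
    """Construct a Multi-Phantom Residual Block from its spec."""
    return MultiPhantomBlock(spec, rng=rng)


# ---------------------------------------------------------------------------
# variant assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """Ablation switches.  (False, False, False) is plain ResNet50;
    (True, True, True) is the full MPC-STANet."""

    use_dc: bool = False
    use_mprb: bool = False
    use_scam: bool = False
    head_classes: int = 1000
    input_channels: int = 3


ALL_VARIANTS: tuple[VariantSpec, ...] = (
    VariantSpec(False, False, False),
    VariantSpec(True, False, False),
    VariantSpec(False, True, False),
    VariantSpec(False, False, True),
    VariantSpec(True, True, False),
    VariantSpec(True, False, True),
    VariantSpec(False, True, True),
    VariantSpec(True, True, True),
)


def variant_name(spec: VariantSpec) -> str:
    if spec.use_dc and spec.use_mprb and spec.use_scam:
        return "MPC-STANet"
    tags = [tag for flag, tag in
            ((spec.use_dc, "DC"), (spec.use_mprb, "MPRB"), (spec.use_scam, "SCAM")) if flag]
    return "-".join(["ResNet50"] + tags)


class MPCSTANet(Module):
    """ResNet50-topology classifier with switchable DC / MPRB / SCAM."""

    def __init__(self, spec: VariantSpec, seed: int = 0,
                 stage_blocks: tuple[int, int, int, int] = (3, 4, 6, 3),
                 width: int = 64):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stage_blocks = tuple(stage_blocks)
        self.width = width
        self.stem = build_stem(spec.use_dc, in_channels=spec.input_channels,
                               width=width, rng=rng)
        mids = (width, 2 * width, 4 * width, 8 * width)
        strides = (1, 2, 2, 2)
        in_ch = width
        stages: list[Sequential] = []
        for mid, stride, n_blocks in zip(mids, strides, stage_blocks):
            out_ch = 4 * mid
            blocks: list[Module] = []
            for b in range(n_blocks):
                if b == 0:
                    if spec.use_mprb:
                        blocks.append(MultiPhantomBlock(BlockSpec(
                            "multi_conv", in_ch, out_ch, mid,
                            spatial_stride=stride, scam_enabled=spec.use_scam), rng=rng))
                    else:
                        blocks.append(Bottleneck(in_ch, mid, out_ch, stride=stride,
                                                 scam_enabled=spec.use_scam, rng=rng))
                else:
                    if spec.use_mprb:
                        blocks.append(MultiPhantomBlock(BlockSpec(
                            "multi_identity", out_ch, out_ch, mid,
                            scam_enabled=spec.use_scam), rng=rng))
                    else:
                        blocks.append(Bottleneck(out_ch, mid, out_ch,
                                                 scam_enabled=spec.use_scam, rng=rng))
                in_ch = out_ch
            stages.append(Sequential(*blocks))
        self.stage2 = stages[0]
        self.stage3 = stages[1]
        self.stage4 = stages[2]
        self.stage5 = stages[3]
        self.fc = Linear(in_ch, spec.head_classes, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        x = self.stage2(x)
        x = self.stage3(x)
        x = self.stage4(x)
        x = self.stage5(x)
        x = x.mean(axis=(2, 3))  # global average pool (STAGE 6)
        return self.fc(x)


def assemble_variant(spec: VariantSpec, seed: int = 0,
                     stage_blocks: tuple[int, int, int, int] = (3, 4, 6, 3),
                     width: int = 64) -> MPCSTANet:
    """Build a network variant.  ``stage_blocks``/``width`` default to the
    canonical ResNet50 profile; smaller values give depth-reduced models
    for desk-scale experiments."""
    return MPCSTANet(spec, seed=seed, stage_blocks=stage_blocks, width=width)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamBudget:
    """Exact trainable-parameter count and its 2-decimal 'millions' rendering."""

    exact_count: int

    @property
    def millions(self) -> float:
        return float(
            (Decimal(self.exact_count) / Decimal(1_000_000)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )

    def __str__(self) -> str:
        return f"{self.millions:.2f}M ({self.exact_count:,})"


def count_parameters(model: Module) -> ParamBudget:
    """Exact count of trainable array elements in a model."""
    return ParamBudget(int(sum(p.data.size for p in model.parameters())))
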