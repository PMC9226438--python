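"""Class-balancing preprocessing: augmentation, SMOTE, planner, split.

The staging dataset is heavily skewed (50/35/14/1 % across the four
stages), which biases training toward the majority class.  Balancing
proceeds in two layers, per minority class, up to the majority count:

1. *Data expansion* — horizontal/vertical flips, additive Gaussian
   noise, and contrast adjustment about the image's own mean, applied by
   cycling the three operations over the class's originals in manifest
   order, at most three augmented variants per original.
2. *SMOTE* — the remaining deficit is synthesised in the flattened
   raw-pixel feature space.  A base sample ``a`` picks one of its K
   Euclidean nearest neighbours ``b`` and a fresh uniform ``u``, and the
   new sample is, componentwise,

       x_new = a + u * |a - b|

   This absolute-difference form is kept as the default because it is
   what the method prescribes; note it can overshoot the segment between
   ``a`` and ``b`` (a=5, b=1, u=0.5 gives 7).  The textbook form
   ``a + u*(b - a)`` is available via ``canonical=True``.

Finally a stratified 7:2:1 train/test/validation split with
deterministic largest-remainder allocation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .synthetic_fixtures import (
    CLASS_INDEX,
    CLASS_LABELS,
    ClassDistribution,
    ImageRecord,
    LabeledImageSet,
)

__all__ = [
    "BalanceError",
    "AugmentationConfig",
    "SmoteParams",
    "ClassQuota",
    "BalancePlan",
    "SplitSpec",
    "Split",
    "flip_image",
    "add_gaussian_noise",
    "adjust_contrast",
    "euclidean_distance",
    "smote_synthesize",
    "smote_oversample",
    "plan_balance",
    "balance_dataset",
    "split_dataset",
]

logger = logging.getLogger(__name__)

FLIP_AXES = ("horizontal", "vertical")


class BalanceError(ValueError):
    """Invalid balancing configuration or request."""


@dataclass(frozen=True)
class AugmentationConfig:
    """Data-expansion settings.

    The three operations are the ones the method names; the numeric
    defaults (noise sigma 10 intensity units, contrast factors cycling
    0.8/1.2, horizontal flip only) are this package's choices — the
    method states no values.
    """

    flip_axes: tuple[str, ...] = ("horizontal",)
    noise_sigma: float = 10.0
    contrast_factors: tuple[float, ...] = (0.8, 1.2)
    seed: int = 42

    def __post_init__(self):
        for axis in self.flip_axes:
            if axis not in FLIP_AXES:
                raise BalanceError(f"unknown flip axis {axis!r}")
        if not (math.isfinite(self.noise_sigma) and self.noise_sigma >= 0):
            raise BalanceError(f"noise_sigma must be finite and >= 0, got {self.noise_sigma}")
        if not self.contrast_factors or any(
            not math.isfinite(f) or f <= 0 for f in self.contrast_factors
        ):
            raise BalanceError(f"contrast factors must be finite and > 0, got {self.contrast_factors}")
        if not (self.flip_axes or self.noise_sigma > 0 or self.contrast_factors):
            raise BalanceError("at least one augmentation op must be enabled")


@dataclass(frozen=True)
class SmoteParams:
    """SMOTE settings: K neighbours, amplification N, RNG seed.

    ``T`` (the minority sample count) is normally inferred from the
    sample list; when given it is validated against it.  The default
    seed of 42 follows the method's stated random-generator seeding.
    """

    K: int = 5
    N: int = 1
    T: int | None = None
    seed: int = 42

    def __post_init__(self):
        if self.K < 1:
            raise BalanceError(f"K must be >= 1, got {self.K}")
        if self.N < 1:
            raise BalanceError(f"N must be >= 1, got {self.N}")
        if self.T is not None:
            if self.T < 2:
                raise BalanceError(f"T must be >= 2, got {self.T}")
            if self.K > self.T - 1:
                raise BalanceError(f"need 1 <= K <= T-1, got K={self.K}, T={self.T}")


# ---------------------------------------------------------------------------
# augmentation operations
# ---------------------------------------------------------------------------


def _derived(record: ImageRecord, pixels: np.ndarray, tag: str) -> ImageRecord:
    return ImageRecord(pixels.astype(np.uint8), record.label, "augmented",
                       f"{record.source_id}_{tag}")


def flip_image(img: ImageRecord, axis: str = "horizontal") -> ImageRecord:
    """Mirror the image along ``axis``; label preserved, provenance 'augmented'."""
    if axis == "horizontal":
        flipped = np.fliplr(img.pixels)
    elif axis == "vertical":
        flipped = np.flipud(img.pixels)
    else:
        raise BalanceError(f"unknown flip axis {axis!r}")
    return _derived(img, np.ascontiguousarray(flipped), f"flip{axis[0]}")


def add_gaussian_noise(img: ImageRecord, sigma: float,
                       seed: int | np.random.Generator = 0) -> ImageRecord:
    """Additive Gaussian pixel noise, clipped and rounded back to [0, 255]."""
    if sigma < 0:
        raise BalanceError(f"noise sigma must be >= 0, got {sigma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = img.pixels.astype(np.float64) + rng.normal(0.0, sigma, size=img.pixels.shape)
    return _derived(img, np.clip(np.rint(noisy), 0, 255), "noise")


def adjust_contrast(img: ImageRecord, factor: float) -> ImageRecord:
    """Scale contrast about the image's own mean intensity.

    ``factor=0`` degenerates to a flat image at the rounded mean; negative
    factors are rejected.
    """
    if factor < 0:
        raise BalanceError(f"contrast factor must be >= 0, got {factor}")
    mean = img.pixels.astype(np.float64).mean()
    adjusted = mean + factor * (img.pixels.astype(np.float64) - mean)
    return _derived(img, np.clip(np.rint(adjusted), 0, 255), f"contrast{factor:g}")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean norm of (a - b)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise BalanceError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def smote_synthesize(a: Sequence[float], b: Sequence[float], u: float,
                     canonical: bool = False) -> np.ndarray:
    """One synthetic sample from base ``a`` and neighbour ``b`` at step ``u``.

    Default (method-literal) form: ``a + u*|a - b|`` componentwise.
    ``canonical=True`` gives the textbook ``a + u*(b - a)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise BalanceError(f"length mismatch: {a.shape} vs {b.shape}")
    if not 0.0 <= u <= 1.0:
        raise BalanceError(f"u must lie in [0, 1], got {u}")
    if canonical:
        return a + u * (b - a)
    return a + u * np.abs(a - b)


def smote_oversample(samples: Sequence[Sequence[float]], params: SmoteParams,
                     canonical: bool = False, return_trace: bool = False):
    """Oversample: exactly N×T synthetic vectors from T base samples.

    For each base sample its K Euclidean nearest neighbours (self
    excluded) are computed once; each of its N syntheses draws a
    uniformly random neighbour and a fresh u.  Fully reproducible from
    ``params.seed`` (independent substreams for neighbour choice and u).

    With ``return_trace`` also returns a list of ``(base_index,
    neighbour_index, u)`` per synthetic, for auditing.
    """
    X = np.asarray([np.asarray(s, dtype=np.float64).ravel() for s in samples])
    T = len(X)
    if T < 2:
        raise BalanceError(f"cannot find neighbors: need at least 2 samples, got {T}")
    if params.T is not None and params.T != T:
        raise BalanceError(f"params.T={params.T} does not match {T} samples")
    if params.K >= T:
        raise BalanceError(f"K must be <= T-1, got K={params.K}, T={T}")

    nn = NearestNeighbors(n_neighbors=params.K + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbours = np.empty((T, params.K), dtype=np.intp)
    for i in range(T):
        row = [j for j in idx[i] if j != i]
        neighbours[i] = row[:params.K]

    ss = np.random.SeedSequence(params.seed)
    rng_pick, rng_u = (np.random.default_rng(child) for child in ss.spawn(2))
    out: list[np.ndarray] = []
    trace: list[tuple[int, int, float]] = []
    for i in range(T):
        for _ in range(params.N):
            j = int(neighbours[i][rng_pick.integers(params.K)])
            u = float(rng_u.random())
            out.append(smote_synthesize(X[i], X[j], u, canonical=canonical))
            trace.append((i, j, u))
    if return_trace:
        return out, trace
    return out


# ---------------------------------------------------------------------------
# balancing planner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassQuota:
    n_keep_original: int
    n_augmented: int
    n_smote: int

    @property
    def total(self) -> int:
        return self.n_keep_original + self.n_augmented + self.n_smote


@dataclass(frozen=True)
class BalancePlan:
    """Per-class additions lifting every class to ``target_count``."""

    quotas: dict[str, ClassQuota]
    target_count: int


def plan_balance(distribution: ClassDistribution,
                 aug_config: AugmentationConfig | None = None) -> BalancePlan:
    """Plan how each class reaches the majority count.

    Each minority class's deficit is first filled by augmentation (at
    most three augmented variants per original — one per operation), and
    any remainder by SMOTE.  No originals are ever discarded.
    """
    if isinstance(distribution, dict):
        distribution = ClassDistribution(distribution)
    if distribution.total == 0:
        raise BalanceError("cannot plan balance for an empty distribution")
    target = max(distribution.counts.values())
    quotas = {}
    for label in CLASS_LABELS:
        n = distribution[label]
        deficit = target - n
        if deficit > 0 and n == 0:
            raise BalanceError(
                f"class {label} has no originals: nothing to augment or synthesize from"
            )
        n_aug = min(deficit, 3 * n)
        quotas[label] = ClassQuota(n, n_aug, deficit - n_aug)
    return BalancePlan(quotas, target)


def _augment_class(originals: list[ImageRecord], n_aug: int,
                   aug: AugmentationConfig) -> list[ImageRecord]:
    """Cycle (flip, noise, contrast) passes over originals in manifest order."""
    n = len(originals)
    flip_axis = aug.flip_axes[0] if aug.flip_axes else "horizontal"
    out = []
    for i in range(n_aug):
        orig = originals[i % n]
        op = i // n  # pass number: 0 flip, 1 noise, 2 contrast
        if op == 0:
            rec = flip_image(orig, flip_axis)
        elif op == 1:
            rng = np.random.default_rng(
                np.random.SeedSequence([aug.seed, CLASS_INDEX[orig.label], i])
            )
            rec = add_gaussian_noise(orig, aug.noise_sigma, rng)
        else:
            factor = aug.contrast_factors[i % len(aug.contrast_factors)]
            rec = adjust_contrast(orig, factor)
        out.append(rec)
    return out


def balance_dataset(dataset: LabeledImageSet, plan: BalancePlan,
                    smote_params: SmoteParams | None = None,
                    aug_config: AugmentationConfig | None = None,
                    canonical_smote: bool = False) -> LabeledImageSet:
    """Execute a balance plan: originals kept untouched, augmented and
    SMOTE records appended until every class holds ``target_count``.

    SMOTE operates per class on the flattened pixel vectors of that
    class's originals + augmented pool; synthetic vectors are rounded
    and clipped back to [0, 255] images with provenance ``smote``.
    """
    aug = aug_config or AugmentationConfig()
    smote = smote_params or SmoteParams()
    dist = dataset.distribution()
    new_records: list[ImageRecord] = list(dataset.records)
    shape = None if not dataset.records else dataset.records[0].pixels.shape
    for label in CLASS_LABELS:
        quota = plan.quotas[label]
        originals = dataset.by_class(label)
        if len(originals) != quota.n_keep_original or dist[label] != quota.n_keep_original:
            raise BalanceError(
                f"plan mismatch for class {label}: plan keeps {quota.n_keep_original} "
                f"originals but dataset holds {len(originals)}"
            )
        augmented = _augment_class(originals, quota.n_augmented, aug)
        new_records.extend(augmented)
        if quota.n_smote > 0:
            pool = originals + augmented
            vectors = [r.flat_vector() for r in pool]
            T = len(vectors)
            if T < 2:
                raise BalanceError(f"class {label}: cannot find neighbors with T={T}")
            n_times = math.ceil(quota.n_smote / T)
            k = min(smote.K, T - 1)
            if k != smote.K:
                logger.warning("class %s: reducing K from %d to %d (pool of %d)",
                               label, smote.K, k, T)
            params = replace(smote, K=k, N=n_times, T=None)
            synth = smote_oversample(vectors, params, canonical=canonical_smote)
            # excess synthetics are truncated deterministically from the end
            for i, vec in enumerate(synth[:quota.n_smote]):
                pixels = np.clip(np.rint(vec), 0, 255).astype(np.uint8).reshape(shape)
                new_records.append(ImageRecord(pixels, label, "smote",
                                               f"{label}_smote_{i:05d}"))
    return LabeledImageSet(new_records)


# ---------------------------------------------------------------------------
# stratified 7:2:1 split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation ratios (7:2:1 by default), stratified."""

    ratios: tuple[float, float, float] = (7.0, 2.0, 1.0)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise BalanceError(f"ratios must be three positive numbers, got {self.ratios}")


class Split(NamedTuple):
    train: LabeledImageSet
    test: LabeledImageSet
    validation: LabeledImageSet


def _allocate(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items to the ratios, ties broken
    by partition order (train, test, validation)."""
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    counts = [int(math.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(3), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(dataset: LabeledImageSet, spec: SplitSpec | None = None) -> Split:
    """Stratified split into (train, test, validation).

    Per class the records are shuffled with a seed-derived substream and
    allocated by floor + largest fractional remainder; the partitions
    are disjoint and their union is the dataset.
    """
    spec = spec or SplitSpec()
    if len(dataset) == 0:
        raise BalanceError("cannot split an empty dataset")
    parts: tuple[list[ImageRecord], ...] = ([], [], [])
    groups = ([dataset.by_class(label) for label in CLASS_LABELS]
              if spec.stratified else [list(dataset.records)])
    for gi, group in enumerate(groups):
        n = len(group)
        if n == 0:
            continue
        if n < 3:
            warnings.warn(
                f"class group {gi} has only {n} record(s); some partitions stay empty",
                stacklevel=2,
            )
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, gi]))
        order = rng.permutation(n)
        counts = _allocate(n, tuple(spec.ratios))
        start = 0
        for p, c in enumerate(counts):
            for k in order[start:start + c]:
                parts[p].append(group[int(k)])
            start += c
    return Split(*(LabeledImageSet(p) for p in parts))
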