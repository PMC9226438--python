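"""Synthetic phantom "brain slice" datasets for the four dementia stages.

Real staging datasets are single-channel 2-D MRI slices, 128×128 px,
organised one-directory-per-class with a heavy class skew (the reference
collection holds 3200/2240/896/64 images for Non-Demented, Very Mild,
Mild and Moderate Demented).  This module fabricates desk-scale datasets
with that organisation and statistics from parametric phantoms: a bright
ellipse ("brain") with a cortical rim, dark radial sulcal gaps, and
central dark "ventricles" whose size grows monotonically across the
stages — a crude but *learnable* atrophy signal — plus additive Gaussian
texture noise.  No anatomical realism is attempted.

Every image is reproducible from ``(spec.seed, label, index)``: per-image
substreams are derived through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_LABELS",
    "CLASS_DIRNAMES",
    "CLASS_INDEX",
    "FixtureError",
    "ClassGeometry",
    "PhantomSpec",
    "ClassDistribution",
    "ImageRecord",
    "LabeledImageSet",
    "default_class_geometry",
    "phantom_template",
    "generate_phantom",
    "generate_dataset",
    "DESK_SCALE_COUNTS",
    "REFERENCE_SCALE_COUNTS",
]

CLASS_LABELS: tuple[str, ...] = ("ND", "VMD", "MD", "MOD")
CLASS_DIRNAMES: dict[str, str] = {
    "ND": "NonDemented",
    "VMD": "VeryMildDemented",
    "MD": "MildDemented",
    "MOD": "ModerateDemented",
}
CLASS_INDEX: dict[str, int] = {label: i for i, label in enumerate(CLASS_LABELS)}

#: per-class counts of the reference MRI collection
REFERENCE_SCALE_COUNTS: dict[str, int] = {"ND": 3200, "VMD": 2240, "MD": 896, "MOD": 64}
#: 1/16 scaling of the reference counts, preserving the skew
DESK_SCALE_COUNTS: dict[str, int] = {"ND": 200, "VMD": 140, "MD": 56, "MOD": 4}

MANIFEST_COLUMNS = ("path", "label", "provenance", "source_id")
PROVENANCES = ("original", "augmented", "smote")

_BACKGROUND = 15.0
_BRAIN = 170.0
_CORTEX = 200.0
_SULCUS = 80.0
_VENTRICLE = 25.0


class FixtureError(ValueError):
    """Invalid phantom configuration or request."""


@dataclass(frozen=True)
class ClassGeometry:
    """Geometric parameters of one stage's phantom.

    ellipse_axes
        brain semi-axes in pixels (horizontal, vertical).
    ventricle_scale
        ventricle semi-axis as a fraction of the brain semi-axis;
        strictly increasing across stages (the "atrophy" signal).
    sulcal_gap_width
        width in pixels of the dark radial gaps in the cortical rim.
    texture_sigma
        standard deviation of the additive Gaussian texture, in
        intensity units.
    """

    ellipse_axes: tuple[float, float]
    ventricle_scale: float
    sulcal_gap_width: float
    texture_sigma: float


def default_class_geometry(image_size: int) -> dict[str, ClassGeometry]:
    s = image_size
    axes = (0.40 * s, 0.33 * s)
    scales = {"ND": 0.10, "VMD": 0.17, "MD": 0.25, "MOD": 0.35}
    gaps = {"ND": 1.0, "VMD": 1.5, "MD": 2.0, "MOD": 2.5}
    return {
        label: ClassGeometry(
            ellipse_axes=axes,
            ventricle_scale=scales[label],
            sulcal_gap_width=max(1.0, gaps[label] * s / 128.0),
            texture_sigma=6.0,
        )
        for label in CLASS_LABELS
    }


@dataclass
class PhantomSpec:
    """Configuration of the phantom generator."""

    image_size: int = 128
    class_geometry: dict[str, ClassGeometry] | None = None
    intensity_range: tuple[int, int] = (0, 255)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise FixtureError(f"image_size must be >= 32, got {self.image_size}")
        if self.class_geometry is None:
            self.class_geometry = default_class_geometry(self.image_size)
        if set(self.class_geometry) != set(CLASS_LABELS):
            raise FixtureError(
                f"class_geometry must have exactly the classes {CLASS_LABELS}"
            )
        scales = [self.class_geometry[label].ventricle_scale for label in CLASS_LABELS]
        if not all(a < b for a, b in zip(scales, scales[1:])):
            raise FixtureError(
                "ventricle_scale must strictly increase across ND -> VMD -> MD -> MOD"
            )


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class image counts."""

    counts: dict[str, int]

    def __post_init__(self):
        if set(self.counts) != set(CLASS_LABELS):
            raise FixtureError(f"distribution must cover exactly the classes {CLASS_LABELS}")
        if any(v < 0 for v in self.counts.values()):
            raise FixtureError("class counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, label: str) -> int:
        return self.counts[label]


@dataclass
class ImageRecord:
    """One grayscale slice with label and provenance."""

    pixels: np.ndarray           # uint8, image_size × image_size
    label: str
    provenance: str = "original"
    source_id: str = ""

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise FixtureError(f"unknown class label {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise FixtureError(f"unknown provenance {self.provenance!r}")
        self.pixels = np.asarray(self.pixels)

    def flat_vector(self) -> np.ndarray:
        """Flattened float64 pixel vector (the SMOTE feature space)."""
        return self.pixels.astype(np.float64).ravel()


class LabeledImageSet:
    """An ordered, manifest-backed collection of :class:`ImageRecord`."""

    def __init__(self, records: list[ImageRecord], manifest_path: Path | None = None):
        self.records = list(records)
        self.manifest_path = Path(manifest_path) if manifest_path else None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_class(self, label: str) -> list[ImageRecord]:
        return [r for r in self.records if r.label == label]

    def distribution(self) -> ClassDistribution:
        counts = {label: 0 for label in CLASS_LABELS}
        for r in self.records:
            counts[r.label] += 1
        return ClassDistribution(counts)

    # -- persistence ------------------------------------------------------

    def _relpath(self, record: ImageRecord, ext: str) -> str:
        return f"{CLASS_DIRNAMES[record.label]}/{record.source_id}.{ext}"

    def save(self, out_dir: str | Path, image_format: str = "png") -> Path:
        """Write one subdirectory per class plus ``manifest.csv``.

        PNG (lossless) is the default so pixel-level invariants survive a
        round trip; ``image_format='jpg'`` matches the lossy on-disk
        format of the reference collection.
        """
        ext = image_format.lower()
        if ext not in ("png", "jpg"):
            raise FixtureError(f"unsupported image format {image_format!r}")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for record in self.records:
            path = out / self._relpath(record, ext)
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(record.pixels.astype(np.uint8), mode="L").save(path)
        manifest = out / "manifest.csv"
        self.write_manifest(manifest, ext=ext)
        return manifest

    def write_manifest(self, path: str | Path, ext: str = "png") -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_COLUMNS)
            for record in self.records:
                writer.writerow([self._relpath(record, ext), record.label,
                                 record.provenance, record.source_id])
        self.manifest_path = path
        return path

    @classmethod
    def load(cls, root: str | Path) -> "LabeledImageSet":
        root = Path(root)
        manifest = root / "manifest.csv"
        records = []
        with open(manifest, newline="") as fh:
            reader = csv.DictReader(fh)
            if tuple(reader.fieldnames or ()) != MANIFEST_COLUMNS:
                raise FixtureError(f"unexpected manifest header in {manifest}")
            for row in reader:
                pixels = np.asarray(Image.open(root / row["path"]).convert("L"))
                records.append(ImageRecord(pixels, row["label"], row["provenance"],
                                           row["source_id"]))
        return cls(records, manifest_path=manifest)


# ---------------------------------------------------------------------------
# phantom rendering
# ---------------------------------------------------------------------------


def _streams(spec: PhantomSpec, label: str, index: int, n: int = 2):
    ss = np.random.SeedSequence([spec.seed, CLASS_INDEX[label], index])
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def phantom_template(label: str, spec: PhantomSpec, index: int) -> np.ndarray:
    """Noise-free geometric template of one phantom (float array).

    Geometry jitter (centre offset, axis scale, spoke rotation) is drawn
    deterministically from ``(spec.seed, label, index)`` so the template
    itself is reproducible; ``generate_phantom`` adds texture noise on an
    independent substream.
    """
    if label not in CLASS_LABELS:
        raise FixtureError(f"unknown class label {label!r}")
    if index < 0:
        raise FixtureError("index must be >= 0")
    geom = spec.class_geometry[label]
    s = spec.image_size
    rng, _ = _streams(spec, label, index)

    cy = s / 2.0 + rng.uniform(-0.02, 0.02) * s
    cx = s / 2.0 + rng.uniform(-0.02, 0.02) * s
    ax = geom.ellipse_axes[0] * (1.0 + rng.uniform(-0.04, 0.04))
    ay = geom.ellipse_axes[1] * (1.0 + rng.uniform(-0.04, 0.04))
    spoke_rot = rng.uniform(0.0, np.pi / 6.0)

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    rnorm = np.sqrt((dx / ax) ** 2 + (dy / ay) ** 2)

    img = np.full((s, s), _BACKGROUND)
    img[rnorm <= 1.0] = _BRAIN
    img[(rnorm > 0.82) & (rnorm <= 1.0)] = _CORTEX

    # radial sulcal gaps in the cortical rim
    n_spokes = 8
    theta = np.arctan2(dy, dx)
    radius = np.sqrt(dx**2 + dy**2) + 1e-9
    for k in range(n_spokes):
        ang = spoke_rot + k * (2.0 * np.pi / n_spokes)
        # perpendicular distance to the spoke direction
        dist = np.abs(radius * np.sin(theta - ang))
        along = radius * np.cos(theta - ang)
        gap = (dist <= geom.sulcal_gap_width / 2.0) & (along > 0) & \
              (rnorm > 0.60) & (rnorm <= 1.0)
        img[gap] = _SULCUS

    # two lateral ventricles; their area carries the stage signal
    av = geom.ventricle_scale * ax
    bv = 1.5 * geom.ventricle_scale * ay
    for side in (-1.0, 1.0):
        vx = cx + side * 0.45 * av
        mask = ((xx - vx) / max(av, 1e-9)) ** 2 + ((yy - cy) / max(bv, 1e-9)) ** 2 <= 1.0
        img[mask] = _VENTRICLE

    lo, hi = spec.intensity_range
    return np.clip(img, lo, hi)


def generate_phantom(label: str, spec: PhantomSpec, index: int) -> ImageRecord:
    """Render one phantom slice: template + Gaussian texture noise."""
    template = phantom_template(label, spec, index)
    geom = spec.class_geometry[label]
    _, noise_rng = _streams(spec, label, index)
    img = template
    if geom.texture_sigma > 0:
        img = img + noise_rng.normal(0.0, geom.texture_sigma, size=template.shape)
    lo, hi = spec.intensity_range
    pixels = np.clip(np.rint(img), lo, hi).astype(np.uint8)
    return ImageRecord(pixels, label, "original", f"{label}_original_{index:05d}")


def generate_dataset(distribution: ClassDistribution, spec: PhantomSpec,
                     out_dir: str | Path | None = None,
                     image_format: str = "png") -> LabeledImageSet:
    """Generate a phantom dataset with the requested per-class counts.

    With ``out_dir`` set, writes the class-per-directory layout plus a
    ``manifest.csv`` (columns ``path,label,provenance,source_id``); an
    all-zero distribution yields an empty set with a header-only
    manifest.  Without ``out_dir`` the set is kept in memory.
    """
    if isinstance(distribution, dict):
        distribution = ClassDistribution(distribution)
    records = [
        generate_phantom(label, spec, i)
        for label in CLASS_LABELS
        for i in range(distribution[label])
    ]
    dataset = LabeledImageSet(records)
    if out_dir is not None:
        dataset.save(out_dir, image_format=image_format)
    return dataset
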