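"""Synthetic brain-tumor phantom images, dataset splitting, and classic augmentation.

Real contrast-enhanced MRI slices of the three tumor classes (glioma,
meningioma, pituitary) are not redistributable, so the package ships a
phantom generator that emulates the gross structure a slice classifier
relies on: a bright elliptical skull rim, a textured interior, and a
class-dependent lesion.  Lesion geometry mirrors the clinical picture at
cartoon level — pituitary tumors sit near the base midline, meningiomas
grow attached to the outer covering (the inner rim here), gliomas are
larger, irregular, heterogeneous masses in one hemisphere.

The split arithmetic reproduces a 60/20/20 per-class division with
floor-train / floor-val / remainder-to-test rounding.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure
from skimage.transform import rescale, rotate

CLASS_NAMES = ("glioma", "meningioma", "pituitary")
PLANES = ("axial", "coronal", "sagittal")

__all__ = [
    "CLASS_NAMES",
    "ImageSample",
    "LabeledDataset",
    "generate_phantom",
    "generate_dataset",
    "lesion_features",
    "SplitSpec",
    "split_counts",
    "split_dataset",
    "classic_augment",
    "save_dataset",
    "load_dataset",
]


@dataclass
class ImageSample:
    """One labeled 2-D grayscale image.

    ``meta`` carries the generator's lesion-placement bookkeeping
    (skull center/axes, lesion centroid and mask) so tests can verify
    placement without re-segmenting the image.
    """

    pixels: np.ndarray
    label: str
    plane: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        validate_image(self.pixels)
        if self.label not in CLASS_NAMES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASS_NAMES}")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def validate_image(pixels: np.ndarray) -> None:
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"image must be square 2-D, got shape {pixels.shape}")
    side = pixels.shape[0]
    if side < 32 or (side & (side - 1)) != 0:
        raise ValueError(f"side must be a power of two >= 32, got {side}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("pixel intensities must lie in [0, 1]")


@dataclass
class LabeledDataset:
    """Ordered collection of :class:`ImageSample` with deterministic provenance."""

    samples: list
    class_names: tuple = CLASS_NAMES
    rng_seed: Optional[int] = None

    def __post_init__(self):
        for s in self.samples:
            if s.label not in self.class_names:
                raise ValueError(f"sample label {s.label!r} not in {self.class_names}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def images(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.samples])

    def label_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[s.label] for s in self.samples], dtype=np.int64)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in idx], self.class_names, self.rng_seed)

    def by_class(self, label: str) -> "LabeledDataset":
        return LabeledDataset([s for s in self.samples if s.label == label],
                              self.class_names, self.rng_seed)


# ---------------------------------------------------------------------------
# phantom generation


def _ellipse_field(side: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2


def _smooth_noise(rng: np.random.Generator, side: int, coarse: int = 8,
                  amplitude: float = 0.05) -> np.ndarray:
    base = rng.normal(0.0, 1.0, size=(coarse, coarse))
    up = ndimage.zoom(base, side / coarse, order=3)[:side, :side]
    up = up / (np.abs(up).max() + 1e-12)
    return amplitude * up

def generate_phantom(label: str, side: int = 64, rng=None) -> ImageSample:
    """Draw one phantom slice of the requested tumor class.

    The image contains a bright elliptical skull rim with jittered
    center/axes, smooth low-amplitude interior texture, and one lesion
    whose placement, shape, and intensity depend on the class:

    * ``pituitary`` — small compact bright blob near the base midline;
    * ``meningioma`` — lens-shaped blob attached to the inner rim;
    * ``glioma`` — larger, irregular, multi-lobed heterogeneous mass in
      one hemisphere.

    ``rng`` may be a seed or a ``numpy.random.Generator``.  The lesion
    mask and centroid are exposed in ``sample.meta``.
    """
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASS_NAMES}")
    if side < 32:
        raise ValueError(f"side must be >= 32 (stride-2 stacks need room), got {side}")
    rng = np.random.default_rng(rng)

    cy = side / 2 + rng.uniform(-0.03, 0.03) * side
    cx = side / 2 + rng.uniform(-0.03, 0.03) * side
    ay = side * 0.42 * (1 + rng.uniform(-0.05, 0.05))
    ax = side * 0.36 * (1 + rng.uniform(-0.05, 0.05))

    r2 = _ellipse_field(side, cy, cx, ay, ax)
    img = np.zeros((side, side), dtype=np.float64)
    interior = r2 < 0.82
    rim = (r2 >= 0.82) & (r2 < 1.0)
    img[interior] = 0.25
    img[rim] = 0.85
    img[interior] += _smooth_noise(rng, side, amplitude=0.05)[interior]

    lesion = np.zeros_like(img)
    yy, xx = np.mgrid[0:side, 0:side]

    if label == "pituitary":
        # compact bright blob near the base midline of the skull ellipse
        ly = cy + 0.55 * ay * (1 + rng.uniform(-0.08, 0.08))
        lx = cx + rng.uniform(-0.08, 0.08) * ax
        r = side * rng.uniform(0.055, 0.075)
        d2 = ((yy - ly) ** 2 + (xx - lx) ** 2) / r**2
        lesion = 0.95 * np.exp(-1.2 * d2) * (d2 < 4)
    elif label == "meningioma":
        # lens-shaped blob pressed against the inner rim; restricted to the
        # superior arc (convexity/parasagittal location), which also keeps
        # the class identifiable at coarse resolution
        theta = rng.uniform(math.pi + 0.6, 2 * math.pi - 0.6)
        ly = cy + 0.72 * ay * math.sin(theta)
        lx = cx + 0.72 * ax * math.cos(theta)
        # anisotropic: long axis tangent to the rim, short axis radial
        t_len = side * rng.uniform(0.14, 0.18)
        r_len = side * rng.uniform(0.045, 0.06)
        dy, dx = yy - ly, xx - lx
        tang = -dy * math.cos(theta) + dx * math.sin(theta)
        radial = dy * math.sin(theta) + dx * math.cos(theta)
        d2 = (tang / t_len) ** 2 + (radial / r_len) ** 2
        lesion = 0.75 * np.exp(-1.5 * d2) * (d2 < 4)
    else:  # glioma
        hemi = 1 if rng.random() < 0.5 else -1
        ly0 = cy + rng.uniform(-0.25, 0.1) * ay
        lx0 = cx + hemi * 0.42 * ax * (1 + rng.uniform(-0.15, 0.15))
        n_lobes = rng.integers(3, 6)
        for _ in range(n_lobes):
            ly = ly0 + rng.uniform(-0.12, 0.12) * side
            lx = lx0 + rng.uniform(-0.09, 0.09) * side
            ry = side * rng.uniform(0.06, 0.11)
            rx = side * rng.uniform(0.06, 0.11)
            amp = rng.uniform(0.45, 0.85)
            d2 = ((yy - ly) / ry) ** 2 + ((xx - lx) / rx) ** 2
            lesion = np.maximum(lesion, amp * np.exp(-1.3 * d2) * (d2 < 4))

    lesion *= interior
    mask = lesion > 0.25
    img = np.clip(np.maximum(img, lesion), 0.0, 1.0)

    if mask.any():
        centroid = tuple(np.mean(np.argwhere(mask), axis=0))
    else:  # degenerate draw: lesion clipped away entirely (not seen in practice)
        centroid = (float(cy), float(cx))
    plane = PLANES[int(rng.integers(0, 3))]
    meta = {
        "skull_center": (float(cy), float(cx)),
        "skull_axes": (float(ay), float(ax)),
        "lesion_mask": mask,
        "lesion_centroid": (float(centroid[0]), float(centroid[1])),
    }
    return ImageSample(img, label, plane=plane, meta=meta)


def generate_dataset(n_per_class: int, side: int = 64, seed: int = 0,
                     class_names: Sequence[str] = CLASS_NAMES) -> LabeledDataset:
    """``n_per_class`` phantoms for each class, deterministically from ``seed``."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.SeedSequence(seed)
    samples = []
    for label, ss in zip(class_names, master.spawn(len(class_names))):
        child = np.random.default_rng(ss)
        for _ in range(n_per_class):
            samples.append(generate_phantom(label, side, child))
    return LabeledDataset(samples, tuple(class_names), rng_seed=seed)


def lesion_features(sample: ImageSample) -> np.ndarray:
    """9-feature lesion summary used by separability checks.

    area fraction, normalized centroid offsets (y, x) w.r.t. the skull
    center in units of the skull semi-axes, eccentricity, major/minor
    axis lengths relative to the side, solidity, and lesion intensity
    mean/std.  Requires generator bookkeeping in ``sample.meta``.
    """
    mask = sample.meta["lesion_mask"]
    cy, cx = sample.meta["skull_center"]
    ay, ax = sample.meta["skull_axes"]
    side = sample.side
    if not mask.any():
        return np.zeros(9)
    props = measure.regionprops(mask.astype(np.uint8))[0]
    my, mx = props.centroid
    vals = sample.pixels[mask]
    return np.array([
        mask.sum() / side**2,
        (my - cy) / ay,
        (mx - cx) / ax,
        props.eccentricity,
        props.axis_major_length / side,
        props.axis_minor_length / side,
        props.solidity,
        float(vals.mean()),
        float(vals.std()),
    ])


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitSpec:
    """Per-class train/validation/test accounting."""

    n_total: int
    n_train: int
    n_val: int
    n_test: int
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if min(self.n_total, self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("split counts must be non-negative")
        if self.n_train + self.n_val + self.n_test != self.n_total:
            raise ValueError("split counts must sum to n_total")

    @classmethod
    def from_total(cls, n_total: int,
                   fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)) -> "SplitSpec":
        return cls(n_total, *split_counts(n_total, fractions), fractions)


def split_counts(n_total: int, fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)):
    """Per-class (train, val, test) counts.

    ``n_train = floor(f_train * n)``; the remainder is divided between
    validation and test in proportion ``f_val : f_test``, flooring the
    validation share so any odd unit goes to test.
    """
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    n_train = int(math.floor(f_train * n_total + 1e-9))
    r = n_total - n_train
    if f_val + f_test <= 0:
        n_val = 0
    else:
        n_val = int(math.floor(r * f_val / (f_val + f_test) + 1e-9))
    n_test = r - n_val
    return n_train, n_val, n_test


def split_dataset(ds: LabeledDataset, fractions=(0.6, 0.2, 0.2), rng=None):
    """Stratified shuffle-and-partition into (train, val, test).

    Shuffling is per class; counts follow :func:`split_counts`.  The
    union of the three outputs is the input, with no duplicates.
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(rng)
    parts = {k: [] for k in ("train", "val", "test")}
    for label in ds.class_names:
        idx = [i for i, s in enumerate(ds.samples) if s.label == label]
        order = rng.permutation(len(idx))
        idx = [idx[int(j)] for j in order]
        n_tr, n_va, n_te = split_counts(len(idx), fractions)
        parts["train"] += idx[:n_tr]
        parts["val"] += idx[n_tr:n_tr + n_va]
        parts["test"] += idx[n_tr + n_va:]
    return tuple(ds.subset(sorted(parts[k])) for k in ("train", "val", "test"))


# ---------------------------------------------------------------------------
# classic augmentation


def augment_pixels(pixels: np.ndarray, rng=None, scale_range=(0.9, 1.1),
                   angle: Optional[float] = None,
                   scale: Optional[float] = None) -> np.ndarray:
    """Array-level rotation + rescale used by :func:`classic_augment`.

    Rotation is about the image center with bilinear interpolation and
    zero (background) fill; rescaling crops or zero-pads back to the
    original side; output clipped to [0, 1].
    """
    rng = np.random.default_rng(rng)
    if angle is None:
        angle = rng.uniform(0.0, 359.0)
    if scale is None:
        scale = rng.uniform(*scale_range)
    side = pixels.shape[0]
    out = rotate(pixels, angle, order=1, mode="constant", cval=0.0,
                 preserve_range=True)
    if scale != 1.0:
        out = rescale(out, scale, order=1, mode="constant", cval=0.0,
                      preserve_range=True, anti_aliasing=False)
        h = out.shape[0]
        if h >= side:
            lo = (h - side) // 2
            out = out[lo:lo + side, lo:lo + side]
        else:
            pad_lo = (side - h) // 2
            pad_hi = side - h - pad_lo
            out = np.pad(out, ((pad_lo, pad_hi), (pad_lo, pad_hi)))
    return np.clip(out, 0.0, 1.0)


def classic_augment(img: ImageSample, rng=None, scale_range=(0.9, 1.1),
                    angle: Optional[float] = None,
                    scale: Optional[float] = None) -> ImageSample:
    """Random rotation (uniform 0–359 degrees) then isotropic rescaling.

    The label (and plane tag) are unchanged.  ``angle``/``scale``
    override the random draws, which the test-suite uses to force
    identity transforms.
    """
    out = augment_pixels(img.pixels, rng, scale_range, angle, scale)
    return ImageSample(out, img.label, plane=img.plane, meta=dict(img.meta))


# ---------------------------------------------------------------------------
# on-disk format: per-class PNG directories + manifest CSV


def save_dataset(ds: LabeledDataset, root, split_tags: Optional[Sequence[str]] = None) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if split_tags is None:
        split_tags = ["unsplit"] * len(ds)
    rows = []
    counters: dict = {}
    for sample, tag in zip(ds.samples, split_tags):
        k = counters.get(sample.label, 0)
        counters[sample.label] = k + 1
        rel = Path(sample.label) / f"{sample.label}_{k:05d}.png"
        (root / sample.label).mkdir(exist_ok=True)
        arr = np.round(sample.pixels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(root / rel)
        rows.append((str(rel), sample.label, tag))
    with open(root / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "split"])
        w.writerows(rows)
    return root


def load_dataset(root, split: Optional[str] = None) -> LabeledDataset:
    root = Path(root)
    samples = []
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            if split is not None and row["split"] != split:
                continue
            arr = np.asarray(Image.open(root / row["filename"]), dtype=np.float64) / 255.0
            samples.append(ImageSample(arr, row["label"]))
    return LabeledDataset(samples)
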