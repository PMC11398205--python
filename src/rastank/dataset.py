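"""Virtual/real dataset design: mixing ratios, splits, photometric augmentation.

The mixing design pairs a virtual-image pool with a (usually much smaller)
real-image pool at a stated virtual:real percentage for the training set,
while validation and test sets contain real images only — the whole point of
the design is to measure how a detector trained mostly on simulation
performs on real tank imagery. Splits follow a train:val:test proportion
(70:20:10 by convention here) with largest-remainder rounding.

Augmentation is photometric only (brightness, exposure, saturation, blur) so
bounding boxes carry over verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InfeasibleConstraintError, InvalidArgumentError

SOURCES = ("virtual", "real")
SPLITS = ("train", "val", "test", "unassigned")

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class ImageRecord:
    path: str
    source: str
    annotation_ref: str | None = None
    split: str = "unassigned"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise InvalidArgumentError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.split not in SPLITS:
            raise InvalidArgumentError(f"split must be one of {SPLITS}, got {self.split!r}")


@dataclass(frozen=True)
class MixSpec:
    """Training-set size and virtual:real percentage split."""

    total_train: int
    virtual_pct: float
    real_pct: float

    def __post_init__(self):
        if abs(self.virtual_pct + self.real_pct - 100.0) > 1e-9:
            raise InvalidArgumentError("virtual_pct + real_pct must equal 100")
        if self.total_train < 1:
            raise InvalidArgumentError("total_train must be >= 1")
        if not (0 <= self.virtual_pct <= 100):
            raise InvalidArgumentError("virtual_pct must be in [0, 100]")


def mix_counts(spec: MixSpec, strict: bool = True) -> tuple[int, int]:
    """(n_virtual, n_real) training images for a mix; conserves the total.

    In strict mode (default) the percentage must divide the total into whole
    images — every standard 700-image mix row does — otherwise the virtual
    count is rounded and the real count absorbs the remainder.
    """
    exact = spec.total_train * spec.virtual_pct / 100.0
    n_virtual = int(round(exact))
    if strict and abs(exact - n_virtual) > 1e-9:
        raise InvalidArgumentError(
            f"{spec.virtual_pct}% of {spec.total_train} is not a whole image count "
            f"({exact}); pass strict=False to round"
        )
    return n_virtual, spec.total_train - n_virtual


def largest_remainder(total: int, percentages) -> list[int]:
    """Apportion `total` into integer parts proportional to `percentages`."""
    quotas = [total * p / 100.0 for p in percentages]
    floors = [int(np.floor(q)) for q in quotas]
    short = total - sum(floors)
    order = np.argsort([f - q for f, q in zip(floors, quotas)])  # largest remainder first
    for i in order[:short]:
        floors[i] += 1
    return floors


def build_split(
    pool: list[ImageRecord],
    proportions: tuple[float, float, float] = (70, 20, 10),
    seed: int = 0,
) -> list[ImageRecord]:
    """Assign train/val/test splits over the pool; val and test get real images only.

    A seeded shuffle orders the pool; val then test are filled from the real
    images in shuffled order, everything else trains. Sizes follow
    ``proportions`` of the pool size with largest-remainder rounding.
    """
    if abs(sum(proportions) - 100.0) > 1e-9:
        raise InvalidArgumentError("split proportions must sum to 100")
    n = len(pool)
    n_train, n_val, n_test = largest_remainder(n, proportions)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    real_order = [i for i in order if pool[i].source == "real"]
    if len(real_order) < n_val + n_test:
        raise InfeasibleConstraintError(
            f"val+test need {n_val + n_test} real images but the pool has only "
            f"{len(real_order)} (shortfall {n_val + n_test - len(real_order)})"
        )
    val_idx = set(real_order[:n_val])
    test_idx = set(real_order[n_val:n_val + n_test])

    out = []
    for i, rec in enumerate(pool):
        if i in val_idx:
            split = "val"
        elif i in test_idx:
            split = "test"
        else:
            split = "train"
        out.append(dataclasses.replace(rec, split=split))
    return out


def build_manifest(
    virtual_pool: list[ImageRecord],
    real_pool: list[ImageRecord],
    mix: MixSpec,
    proportions: tuple[float, float, float] = (70, 20, 10),
    seed: int = 0,
) -> list[ImageRecord]:
    """Compose a full manifest: mixed training set plus real-only val/test.

    ``mix.total_train`` is the training-set size; the val/test sizes scale it
    by the split proportions (700 training images at 70:20:10 imply 200
    validation and 100 test images). Virtual and real images are drawn from
    their pools in seeded-shuffle order without replacement.
    """
    train_pct = proportions[0]
    if train_pct <= 0:
        raise InvalidArgumentError("train proportion must be positive")
    pool_size = mix.total_train * 100.0 / train_pct
    if abs(pool_size - round(pool_size)) > 1e-6:
        raise InvalidArgumentError(
            f"total_train={mix.total_train} is not compatible with a {train_pct}% train share"
        )
    sizes = largest_remainder(int(round(pool_size)), proportions)
    if sizes[0] != mix.total_train:
        raise InvalidArgumentError("split rounding does not reproduce total_train")
    n_val, n_test = sizes[1], sizes[2]

    n_virtual, n_real_train = mix_counts(mix)
    if len(virtual_pool) < n_virtual:
        raise InfeasibleConstraintError(
            f"need {n_virtual} virtual images, pool has {len(virtual_pool)}"
        )
    n_real_needed = n_real_train + n_val + n_test
    if len(real_pool) < n_real_needed:
        raise InfeasibleConstraintError(
            f"need {n_real_needed} real images ({n_real_train} train + {n_val} val + "
            f"{n_test} test), pool has {len(real_pool)} "
            f"(shortfall {n_real_needed - len(real_pool)})"
        )

    rng = np.random.default_rng(seed)
    v_order = rng.permutation(len(virtual_pool))[:n_virtual]
    r_order = rng.permutation(len(real_pool))[:n_real_needed]

    out = [dataclasses.replace(virtual_pool[i], split="train") for i in v_order]
    reals = [real_pool[i] for i in r_order]
    out += [dataclasses.replace(r, split="train") for r in reals[:n_real_train]]
    out += [dataclasses.replace(r, split="val") for r in reals[n_real_train:n_real_train + n_val]]
    out += [dataclasses.replace(r, split="test") for r in reals[n_real_train + n_val:]]
    return out


def write_manifest(records: list[ImageRecord], path) -> None:
    """Tab-delimited manifest: path, source, split, annotation_ref per line."""
    with open(path, "w") as fh:
        fh.write("# path\tsource\tsplit\tannotation_ref\n")
        for r in records:
            fh.write(f"{r.path}\t{r.source}\t{r.split}\t{r.annotation_ref or '-'}\n")


def read_manifest(path) -> list[ImageRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InvalidArgumentError(f"malformed manifest line: {line!r}")
            p, source, split, ref = parts
            out.append(ImageRecord(p, source, None if ref == "-" else ref, split))
    return out


# ---------------------------------------------------------------------------
# photometric augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentSpec:
    """Photometric augmentation ranges: sampled uniformly, symmetric about identity.

    ``multiplier`` augmented variants are produced per image (2 by default;
    whether originals are retained alongside is the caller's policy via
    ``keep_original``). ``blur_range`` scales the max Gaussian sigma as a
    fraction of the larger image dimension.
    """

    multiplier: int = 2
    brightness_range: float = 0.25
    exposure_range: float = 0.25
    saturation_range: float = 0.25
    blur_range: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.multiplier < 1:
            raise InvalidArgumentError("multiplier must be >= 1")
        if min(self.brightness_range, self.exposure_range,
               self.saturation_range, self.blur_range) < 0:
            raise InvalidArgumentError("augmentation ranges must be >= 0")


def augment_image(rgb: np.ndarray, spec: AugmentSpec, seed: int | None = None) -> list[np.ndarray]:
    """`multiplier` independently perturbed copies of an RGB image in [0, 1].

    Per copy: multiplicative exposure gain in 1 +- exposure_range, additive
    brightness shift in +- brightness_range of full scale, saturation scaled
    about per-pixel luma in 1 +- saturation_range, then Gaussian blur with
    sigma uniform in [0, blur_range * max(H, W)]. Outputs are clipped to
    [0, 1]; a zero range leaves that transform an exact identity.
    Deterministic given the seed (falls back to ``spec.seed``).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise InvalidArgumentError("augment_image expects rgb in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = rgb.shape[:2]
    out = []
    for _ in range(spec.multiplier):
        img = rgb
        if spec.exposure_range > 0:
            img = img * rng.uniform(1 - spec.exposure_range, 1 + spec.exposure_range)
        if spec.brightness_range > 0:
            img = img + rng.uniform(-spec.brightness_range, spec.brightness_range)
        if spec.saturation_range > 0:
            luma = img @ _LUMA
            s = rng.uniform(1 - spec.saturation_range, 1 + spec.saturation_range)
            img = luma[..., None] + s * (img - luma[..., None])
        if spec.blur_range > 0:
            sigma = rng.uniform(0, spec.blur_range * max(h, w))
            if sigma > 0:
                img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
        out.append(np.clip(img, 0.0, 1.0))
    return out


def augment_dataset(
    images: list[np.ndarray], spec: AugmentSpec, keep_original: bool = True
) -> list[np.ndarray]:
    """Augment a list of images; annotations are unaffected by these transforms."""
    out = []
    for i, img in enumerate(images):
        if keep_original:
            out.append(img)
        # derive a distinct, reproducible stream per image
        out.extend(augment_image(img, spec, seed=spec.seed * 100003 + i))
    return out
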