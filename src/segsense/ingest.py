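"""DICOM ingest, overlap-constrained patch sampling, and augmentation.

A patient folder holds one ``image/`` series plus one binary-mask series per
foreground organ (``mask_<name>/``).  Masks are merged into a single
mutually exclusive multiclass label volume; when two binary masks claim the
same pixel, the class listed *later* in ``class_order`` wins, so small
structures can be declared after large ones and not be swallowed.

Training samples are fixed-size patches drawn uniformly from the offsets
whose window overlaps at least one foreground pixel — no minimum foreground
fraction, so a patch may contain any non-zero amount of anatomy.  The
augmentation policy applies four transforms, each independently with its own
probability: 10% downscale (resample to 0.9x linear scale and back), motion
blur, Gaussian blur, and a rotation of up to 10 degrees.  Geometric
transforms move image and labels together (labels by nearest neighbour);
blurs touch the image only.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize, rotate

from segsense.phantoms import LabeledVolume

__all__ = ["Patch", "AugmentPolicy", "load_patient", "sample_patches", "augment_patch"]

logger = logging.getLogger(__name__)

#: fixed transform order, for reproducibility of the per-patch Bernoulli draws
TRANSFORM_NAMES = ("downscale", "motion_blur", "gaussian_blur", "rotate")


@dataclasses.dataclass
class Patch:
    """One training window cut from a slice.

    ``provenance`` is ``(patient_id, slice_index, row_offset, col_offset)``
    with 0-based top-left offsets and half-open windows.
    """

    image_window: np.ndarray
    label_window: np.ndarray
    provenance: tuple[str, int, int, int]
    augmented_flags: tuple[bool, bool, bool, bool] = (False, False, False, False)


@dataclasses.dataclass(frozen=True)
class AugmentPolicy:
    """Probabilistic four-transform augmentation policy.

    Each transform in :data:`TRANSFORM_NAMES` is applied independently with
    ``per_transform_probability`` (default 0.25, i.e. one transform per patch
    in expectation); ``per_transform_probabilities`` overrides the shared
    value with one probability per transform, in fixed order.
    """

    per_transform_probability: float = 0.25
    per_transform_probabilities: tuple[float, float, float, float] | None = None
    max_rotation_deg: float = 10.0
    downscale_factor: float = 0.9
    blur_kernel_px: tuple[int, int] = (3, 7)
    rotation_fill: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.probabilities:
            if not 0.0 <= p <= 1.0:
                raise ValueError("transform probabilities must lie in [0, 1]")

    @property
    def probabilities(self) -> tuple[float, float, float, float]:
        if self.per_transform_probabilities is not None:
            return self.per_transform_probabilities
        return (self.per_transform_probability,) * 4


# ---------------------------------------------------------------------------
# DICOM loading


def _read_series(directory: Path) -> np.ndarray:
    """Read a DICOM series as a (slices, H, W) stack ordered by InstanceNumber."""
    import pydicom

    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    return np.stack([d.pixel_array for d in datasets]).astype(np.float64)


def load_patient(directory: str | Path, class_order: list[str]) -> LabeledVolume:
    """Load a patient folder into a multiclass labelled volume.

    ``class_order`` names the foreground classes in label order: the first
    name becomes class 1, the second class 2, and so on.  Any nonzero mask
    pixel counts as foreground.  A declared class whose ``mask_<name>/``
    series is missing is left absent (all zeros) with a logged warning.
    """
    directory = Path(directory)
    img_dir = directory / "image"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no image series under {directory}")
    image = _read_series(img_dir)

    labels = np.zeros(image.shape, dtype=np.int64)
    for idx, name in enumerate(class_order, start=1):
        mdir = directory / f"mask_{name}"
        if not mdir.is_dir():
            logger.warning("mask series for class %r missing under %s; class left empty",
                           name, directory)
            warnings.warn(f"mask series for class {name!r} missing; class left empty",
                          stacklevel=2)
            continue
        mask = _read_series(mdir)
        if mask.shape != image.shape:
            raise ValueError(
                f"mask series {name!r} shape {mask.shape} != image shape {image.shape}"
            )
        labels[mask != 0] = idx  # later classes win overlaps

    return LabeledVolume(
        patient_id=directory.name,
        image=image,
        labels=labels,
        n_classes=len(class_order) + 1,
        class_names=tuple(["background", *class_order]),
    )


# ---------------------------------------------------------------------------
# Patch sampling


def _feasible_offsets(fg: np.ndarray, patch_size: int) -> np.ndarray:
    """All (row, col) offsets whose window contains >= 1 foreground pixel."""
    # window-sum via 2D cumulative sums; feasible where the sum is positive
    ii = np.zeros((fg.shape[0] + 1, fg.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(fg.astype(np.int64), axis=0), axis=1)
    h = fg.shape[0] - patch_size + 1
    w = fg.shape[1] - patch_size + 1
    sums = (ii[patch_size:patch_size + h, patch_size:patch_size + w]
            - ii[patch_size:patch_size + h, :w]
            - ii[:h, patch_size:patch_size + w]
            + ii[:h, :w])
    rows, cols = np.nonzero(sums > 0)
    return np.column_stack([rows, cols])


_REJECTION_CAP = 100


def sample_patches(volume: LabeledVolume, patches_per_slice: int, patch_size: int,
                   rng: np.random.Generator) -> list[Patch]:
    """Sample overlap-constrained patches from every eligible slice.

    Each slice with at least one foreground pixel contributes exactly
    ``patches_per_slice`` patches whose windows contain >= 1 nonzero-class
    pixel; offsets are uniform over the feasible set (rejection sampling with
    a retry cap, then exact enumeration of feasible offsets).  All-background
    slices are skipped.  Offsets are drawn with replacement.
    """
    side = volume.image.shape[1]
    if patch_size > side or patch_size > volume.image.shape[2]:
        raise ValueError(f"patch_size {patch_size} exceeds slice side {side}")

    patches: list[Patch] = []
    for s in range(volume.n_slices):
        lab = volume.labels[s]
        fg = lab != 0
        if not fg.any():
            continue
        max_r = lab.shape[0] - patch_size
        max_c = lab.shape[1] - patch_size
        feasible: np.ndarray | None = None
        for _ in range(patches_per_slice):
            offset = None
            for _try in range(_REJECTION_CAP):
                r = int(rng.integers(0, max_r + 1))
                c = int(rng.integers(0, max_c + 1))
                if fg[r:r + patch_size, c:c + patch_size].any():
                    offset = (r, c)
                    break
            if offset is None:
                if feasible is None:
                    feasible = _feasible_offsets(fg, patch_size)
                r, c = feasible[int(rng.integers(0, len(feasible)))]
                offset = (int(r), int(c))
            r, c = offset
            patches.append(Patch(
                image_window=volume.image[s, r:r + patch_size, c:c + patch_size].copy(),
                label_window=lab[r:r + patch_size, c:c + patch_size].copy(),
                provenance=(volume.patient_id, s, r, c),
            ))
    return patches


# ---------------------------------------------------------------------------
# Augmentation


def _downscale(image: np.ndarray, labels: np.ndarray, factor: float):
    small = max(2, int(round(image.shape[0] * factor)))
    shape = (small, small)
    img = resize(image, shape, order=1, anti_aliasing=True, preserve_range=True)
    img = resize(img, image.shape, order=1, anti_aliasing=False, preserve_range=True)
    lab = resize(labels.astype(np.float64), shape, order=0, anti_aliasing=False,
                 preserve_range=True)
    lab = resize(lab, labels.shape, order=0, anti_aliasing=False, preserve_range=True)
    return img, lab.astype(labels.dtype)


def _motion_blur(image: np.ndarray, rng: np.random.Generator,
                 kernel_range: tuple[int, int]) -> np.ndarray:
    lo, hi = kernel_range
    length = int(rng.choice(np.arange(lo, hi + 1, 2)))
    kernel = np.zeros((length, length))
    direction = int(rng.integers(0, 4))  # 0/45/90/135 degrees
    if direction == 0:
        kernel[length // 2, :] = 1.0
    elif direction == 1:
        np.fill_diagonal(kernel, 1.0)
    elif direction == 2:
        kernel[:, length // 2] = 1.0
    else:
        np.fill_diagonal(np.fliplr(kernel), 1.0)
    kernel /= kernel.sum()
    return ndimage.convolve(image, kernel, mode="nearest")


def augment_patch(patch: Patch, policy: AugmentPolicy,
                  rng: np.random.Generator | None = None) -> Patch:
    """Apply the four-transform policy to one patch.

    Transforms are drawn independently (Bernoulli with the policy
    probability) in the fixed order downscale, motion blur, Gaussian blur,
    rotate; the draw is recorded in ``augmented_flags``.
    """
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    flags = tuple(bool(rng.random() < p) for p in policy.probabilities)
    img = patch.image_window.astype(np.float64).copy()
    lab = patch.label_window.copy()

    if flags[0]:
        img, lab = _downscale(img, lab, policy.downscale_factor)
    if flags[1]:
        img = _motion_blur(img, rng, policy.blur_kernel_px)
    if flags[2]:
        lo, hi = policy.blur_kernel_px
        sigma = float(rng.uniform(lo / 6.0, hi / 6.0))  # ~kernel span in px
        img = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")
    if flags[3]:
        angle = float(rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg))
        img = rotate(img, angle, order=1, mode="constant", cval=policy.rotation_fill,
                     preserve_range=True)
        lab = rotate(lab.astype(np.float64), angle, order=0, mode="constant",
                     cval=0.0, preserve_range=True).astype(patch.label_window.dtype)

    return Patch(image_window=img, label_window=lab, provenance=patch.provenance,
                 augmented_flags=flags)
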