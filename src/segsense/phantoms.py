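"""Synthetic CT-like phantom cohorts for end-to-end pipeline testing.

Real abdominal CT cohorts for organ segmentation share a statistical
signature: slices are dominated by background, foreground organs differ
wildly in pixel count (a large soft-tissue organ vs. thin, bright bone), and
intensity statistics drift between patients because series come from
different scanners and protocols.  The phantoms here reproduce exactly that
signature at desk scale so that every downstream stage — ingest, patch
sampling, training, metric logging, importance analysis — can be exercised
deterministically on a laptop CPU with no data download.

Geometry per slice:

* class 2 ("liver"-like): a single smooth blob formed by the union of
  jittered ellipses, medium intensity;
* class 1 ("bone"-like): a thin annulus (rib-cage analog) plus a few small
  discs (vertebra analogs), high intensity;
* class 0: background, low intensity, always the majority class.

Intensities are class-conditional Gaussians plus a per-patient global offset
(the scanner-drift analog) and additive acquisition noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "LabeledVolume",
    "PhantomGenerationError",
    "generate_phantom",
    "generate_cohort",
    "export_dicom",
]

#: canonical class names for the three-class phantom task
DEFAULT_CLASS_NAMES = ("background", "bone", "liver")


class PhantomGenerationError(ValueError):
    """Raised when a phantom cannot be generated under the requested spec."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_patients:
        Number of patients in the cohort (>= 2).
    slices_per_patient:
        Inclusive ``(low, high)`` range; the slice count of each patient is
        drawn uniformly from it, emulating heterogeneous stack lengths.
    slice_size:
        Pixels per side of the square slices (>= 32).
    class_means:
        Intensity mean per class id, in arbitrary HU-like units.  Must be
        pairwise distinct — the reference learner is intensity-based.
    class_noise_scales:
        Relative within-class noise factor per class id; the effective
        per-pixel SD of class ``c`` is ``noise_sd * class_noise_scales[c]``,
        so ``noise_sd = 0`` is an exact noiseless limit.
    patient_offset_sd:
        SD of the per-patient global intensity offset (scanner drift analog).
    noise_sd:
        Global additive acquisition-noise scale, HU-like units.
    seed:
        Cohort RNG seed; ``(seed, patient_index)`` fully determines a volume.
    """

    n_patients: int = 10
    slices_per_patient: tuple[int, int] = (4, 8)
    slice_size: int = 64
    class_means: tuple[float, ...] = (-50.0, 400.0, 80.0)
    class_noise_scales: tuple[float, ...] = (1.0, 2.0, 1.33)
    patient_offset_sd: float = 40.0
    noise_sd: float = 15.0
    seed: int = 0
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.slice_size < 32:
            raise PhantomGenerationError(
                f"slice_size={self.slice_size} is too small to place the organ shapes "
                "(minimum 32)"
            )
        lo, hi = self.slices_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("slices_per_patient must be an increasing positive range")
        if len(set(self.class_means)) != len(self.class_means):
            raise ValueError("class intensity means must be pairwise distinct")
        if len(self.class_means) != len(self.class_noise_scales):
            raise ValueError("class_means and class_noise_scales must have equal length")
        if len(self.class_names) != len(self.class_means):
            raise ValueError("class_names must name every class")

    @property
    def n_classes(self) -> int:
        return len(self.class_means)


@dataclasses.dataclass
class LabeledVolume:
    """A patient's image stack plus mutually exclusive integer labels.

    ``image`` and ``labels`` are ``(n_slices, H, W)`` arrays of identical
    shape; every pixel belongs to exactly one class in ``{0..n_classes-1}``
    with 0 reserved for background.
    """

    patient_id: str
    image: np.ndarray
    labels: np.ndarray
    n_classes: int
    pixel_spacing: tuple[float, float] | None = None
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != labels shape {self.labels.shape}"
            )
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError("labels outside {0..n_classes-1}")

    @property
    def n_slices(self) -> int:
        return self.image.shape[0]


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def _annulus_mask(size: int, cy: float, cx: float, r: float, t: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return np.abs(d - r) <= t / 2.0


def _patient_rng(spec: PhantomSpec, patient_index: int) -> np.random.Generator:
    # SeedSequence keying makes volumes independent and reproducible per patient
    return np.random.default_rng(np.random.SeedSequence((spec.seed, patient_index)))


def generate_phantom(spec: PhantomSpec, patient_index: int) -> LabeledVolume:
    """Generate one patient's phantom volume, deterministic in (seed, index).

    Every slice contains both foreground organs with jittered position and
    size, and satisfies ``count(background) > count(liver) > count(bone)`` —
    the class-imbalance ordering the metric suite is designed to expose.
    """
    if patient_index >= spec.n_patients:
        raise ValueError(f"patient_index {patient_index} >= n_patients {spec.n_patients}")
    rng = _patient_rng(spec, patient_index)
    size = spec.slice_size
    lo, hi = spec.slices_per_patient
    n_slices = int(rng.integers(lo, hi + 1))
    offset = rng.normal(0.0, spec.patient_offset_sd)

    labels = np.zeros((n_slices, size, size), dtype=np.int64)
    for s in range(n_slices):
        lab = labels[s]
        # liver-like blob: union of 2 overlapping jittered ellipses
        cy = size * (0.42 + rng.uniform(-0.06, 0.06))
        cx = size * (0.40 + rng.uniform(-0.06, 0.06))
        blob = np.zeros((size, size), dtype=bool)
        for _ in range(2):
            a = size * rng.uniform(0.18, 0.24)
            b = size * rng.uniform(0.18, 0.24)
            jy = cy + size * rng.uniform(-0.02, 0.02)
            jx = cx + size * rng.uniform(-0.02, 0.02)
            blob |= _ellipse_mask(size, jy, jx, a, b)
        lab[blob] = 2
        # bone-like: thin annulus + 2-4 small discs, drawn after so it wins overlaps
        r = size * rng.uniform(0.28, 0.33)
        ring = _annulus_mask(size, size * 0.5, size * 0.5, r, 1.6)
        lab[ring] = 1
        for _ in range(int(rng.integers(2, 5))):
            dy = size * rng.uniform(0.30, 0.70)
            dx = size * rng.uniform(0.55, 0.80)
            dr = rng.uniform(1.5, 2.5)
            lab[_ellipse_mask(size, dy, dx, dr, dr)] = 1
        counts = np.bincount(lab.ravel(), minlength=spec.n_classes)
        if not (counts[0] > counts[2] > counts[1]) or counts[0] <= lab.size // 2:
            raise PhantomGenerationError(
                "organ shapes do not fit the slice with the required class ordering; "
                "increase slice_size"
            )

    means = np.asarray(spec.class_means)[labels] + offset
    pixel_sd = spec.noise_sd * np.asarray(spec.class_noise_scales)[labels]
    image = means + pixel_sd * rng.normal(0.0, 1.0, size=labels.shape)

    return LabeledVolume(
        patient_id=f"phantom_{patient_index:03d}",
        image=image,
        labels=labels,
        n_classes=spec.n_classes,
        pixel_spacing=(1.0, 1.0),
        class_names=spec.class_names,
    )


def generate_cohort(spec: PhantomSpec) -> list[LabeledVolume]:
    """Generate the full cohort of ``spec.n_patients`` volumes."""
    return [generate_phantom(spec, i) for i in range(spec.n_patients)]


def _base_dataset(rows: int, cols: int, patient_id: str, series_desc: str,
                  instance: int, signed: bool):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.Modality = "CT"
    ds.SeriesDescription = series_desc
    ds.InstanceNumber = instance
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1 if signed else 0
    return ds


def export_dicom(volume: LabeledVolume, directory: str | Path) -> dict:
    """Write a volume as DICOM series: one image series plus one binary-mask
    series per foreground class.

    Layout is ``<directory>/image/slice_###.dcm`` and
    ``<directory>/mask_<class_name>/slice_###.dcm``; a JSON manifest is
    written next to them.  Images are stored as signed 16-bit (values clipped
    and rounded), masks as 0/1.  The layout round-trips through
    :func:`segsense.ingest.load_patient`.
    """
    import pydicom

    directory = Path(directory)
    names = volume.class_names or tuple(
        f"class{c}" for c in range(volume.n_classes)
    )
    img16 = np.clip(np.rint(volume.image), -32768, 32767).astype(np.int16)

    img_dir = directory / "image"
    img_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "patient_id": volume.patient_id,
        "n_slices": volume.n_slices,
        "n_classes": volume.n_classes,
        "class_names": list(names),
        "image_series": "image",
        "mask_series": {},
    }
    for s in range(volume.n_slices):
        ds = _base_dataset(img16.shape[1], img16.shape[2], volume.patient_id,
                           "image", s + 1, signed=True)
        ds.PixelData = img16[s].tobytes()
        ds.save_as(img_dir / f"slice_{s:03d}.dcm", enforce_file_format=True)

    for c in range(1, volume.n_classes):
        series = f"mask_{names[c]}"
        mdir = directory / series
        mdir.mkdir(parents=True, exist_ok=True)
        mask = (volume.labels == c).astype(np.uint16)
        for s in range(volume.n_slices):
            ds = _base_dataset(mask.shape[1], mask.shape[2], volume.patient_id,
                               series, s + 1, signed=False)
            ds.PixelData = mask[s].tobytes()
            ds.save_as(mdir / f"slice_{s:03d}.dcm", enforce_file_format=True)
        manifest["mask_series"][names[c]] = series

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
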