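"""Thorax localisation, cropping, clipping, and dataset-level standardisation.

The thorax is located from the CT alone by a crude lung segmentation:
threshold at -400 HU (air side inclusive), two-iteration binary closing then
seven-iteration binary opening with a face-connected structuring element,
deletion of air components within 25 voxels of the x/y image border (air
outside the patient), and selection of the largest remaining component.
Axial slices outside the z-extent of that component are discarded, slices
are symmetrically cropped (or air-padded) to 256 x 256, intensities are
clipped to [-1000, 1000] HU and [0, 8] SUV, and finally both modalities are
standardised to zero mean / unit variance using statistics pooled over the
whole training set.  Dataset-level (not per-patient) standardisation keeps
absolute intensity differences between patients meaningful.

The whole chain is deterministic and needs no manual input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, NotFittedError, SegmentationFailureError
from .regions import CONN26, FACE_STRUCT
from .volume import Modality, PatientScan, Volume3D, resample_isotropic

__all__ = [
    "PreprocessConfig",
    "NormalizationStats",
    "ThoraxCrop",
    "segment_air",
    "remove_border_components",
    "select_lungs",
    "crop_thorax",
    "clip_intensities",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "preprocess_scan",
    "ThoraxPreprocessor",
    "IntensityStandardizer",
]

CT_PAD_HU = -1000.0
PET_PAD_SUV = 0.0


@dataclass(frozen=True)
class PreprocessConfig:
    hu_air_threshold: float = -400.0
    closing_iters: int = 2
    opening_iters: int = 7
    border_margin_voxels: int = 25
    crop_xy: int = 256
    ct_clip: tuple[float, float] = (-1000.0, 1000.0)
    suv_clip: tuple[float, float] = (0.0, 8.0)
    target_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.closing_iters < 0 or self.opening_iters < 0:
            raise ValueError("morphology iteration counts must be non-negative")
        if self.border_margin_voxels < 0 or self.crop_xy < 1:
            raise ValueError("border margin and crop size must be positive")
        if not (self.ct_clip[0] <= self.hu_air_threshold <= self.ct_clip[1]):
            raise ValueError("air threshold must lie within the CT clip range")


@dataclass
class NormalizationStats:
    """Pooled per-modality mean/sd, fitted once on the training set."""

    ct_mean: float
    ct_sd: float
    pet_mean: float
    pet_sd: float
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if self.ct_sd <= 0 or self.pet_sd <= 0:
            raise DegenerateDataError("standard deviations must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NormalizationStats":
        with open(path) as fh:
            return cls(**json.load(fh))

    def fill_values(self) -> tuple[float, float]:
        """Standardised equivalents of air (-1000 HU) and zero uptake (0 SUV)."""
        return (
            (CT_PAD_HU - self.ct_mean) / self.ct_sd,
            (PET_PAD_SUV - self.pet_mean) / self.pet_sd,
        )


@dataclass
class ThoraxCrop:
    """A 256 x 256 x Nz crop of both modalities around the lungs.

    ``z_range`` holds the inclusive slice bounds of the lung component in the
    1-mm grid; ``xy_offset`` the (y, x) index of the crop window origin in
    that grid (negative when the slice was padded).  Both cropped volumes
    carry updated origins, so physical node coordinates remain valid.
    """

    ct: Volume3D
    pet: Volume3D
    z_range: tuple[int, int]
    xy_offset: tuple[int, int]
    patient_id: str = ""
    standardized: bool = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.shape

    @property
    def grid(self) -> Volume3D:
        """The CT volume, used as the crop's reference geometry."""
        return self.ct


# ---------------------------------------------------------------------------
# Lung segmentation
# ---------------------------------------------------------------------------

def segment_air(ct: Volume3D | np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Binarise air (HU <= -400, inclusive on the air side) and denoise.

    Two binary closing iterations remove small gaps, seven opening
    iterations remove small air pockets and intra-lung nodules; both use the
    3D face-connected (connectivity-one) element.
    """
    cfg = cfg or PreprocessConfig()
    values = ct.values if isinstance(ct, Volume3D) else np.asarray(ct)
    mask = values <= cfg.hu_air_threshold
    if cfg.closing_iters:
        mask = ndimage.binary_closing(mask, FACE_STRUCT, iterations=cfg.closing_iters)
    if cfg.opening_iters:
        mask = ndimage.binary_opening(mask, FACE_STRUCT, iterations=cfg.opening_iters)
    return mask


def remove_border_components(
    mask: np.ndarray, margin: int = 25
) -> np.ndarray:
    """Delete components with any voxel within ``margin`` voxels of the x/y
    border (air outside the patient).  The z axis is exempt: a whole-body
    stack necessarily reaches the first/last slice with patient tissue.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=CONN26)
    if n == 0 or margin == 0:
        return mask.copy()
    ny, nx = mask.shape[1], mask.shape[2]
    border = np.zeros_like(mask)
    border[:, :margin, :] = True
    border[:, max(ny - margin, 0):, :] = True
    border[:, :, :margin] = True
    border[:, :, max(nx - margin, 0):] = True
    bad = np.unique(labels[border & mask])
    out = mask.copy()
    if bad.size:
        out[np.isin(labels, bad[bad > 0])] = False
    return out


def _locate_lungs(mask: np.ndarray, margin: int) -> np.ndarray:
    """Single-pass equivalent of remove_border_components + select_lungs."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=CONN26)
    if n == 0:
        raise SegmentationFailureError("no air component found: cannot locate lungs")
    ny, nx = mask.shape[1], mask.shape[2]
    border = np.zeros_like(mask)
    if margin > 0:
        border[:, :margin, :] = True
        border[:, max(ny - margin, 0):, :] = True
        border[:, :, :margin] = True
        border[:, :, max(nx - margin, 0):] = True
    bad = set(np.unique(labels[border & mask]).tolist()) - {0}
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")  # scan-order tie break
    for k in order:
        if (k + 1) not in bad:
            return labels == (k + 1)
    raise SegmentationFailureError(
        "all air components touch the border: cannot locate lungs"
    )


def select_lungs(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 26-connected air component (the lungs).

    Size ties break toward the component first encountered in scan order.
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=CONN26)
    if n == 0:
        raise SegmentationFailureError("no air component found: cannot locate lungs")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax returns the first maximum
    return labels == best


# ---------------------------------------------------------------------------
# Cropping / clipping / standardisation
# ---------------------------------------------------------------------------

def _centre_window(size: int, target: int) -> tuple[int, int]:
    """Start index (may be negative = padding) and stop of a symmetric window."""
    start = (size - target) // 2
    return start, start + target


def _crop_pad_2d(arr: np.ndarray, target: int, fill: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetrically crop/pad the trailing two axes of (nz, ny, nx) to target."""
    nz, ny, nx = arr.shape
    y0, y1 = _centre_window(ny, target)
    x0, x1 = _centre_window(nx, target)
    out = np.full((nz, target, target), fill, dtype=arr.dtype)
    sy0, sy1 = max(y0, 0), min(y1, ny)
    sx0, sx1 = max(x0, 0), min(x1, nx)
    out[:, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = arr[:, sy0:sy1, sx0:sx1]
    return out, (y0, x0)


def crop_thorax(
    scan: PatientScan, lungs: np.ndarray, cfg: PreprocessConfig | None = None
) -> ThoraxCrop:
    """Keep only slices within the lung component's z-range and centre-crop
    each slice to ``crop_xy`` square (air-padding smaller slices)."""
    cfg = cfg or PreprocessConfig()
    if scan.ct.shape != scan.pet.shape:
        raise SegmentationFailureError("CT and PET must share the 1-mm grid before cropping")
    if not np.any(lungs):
        raise SegmentationFailureError("empty lung mask: cannot locate thorax")
    zs = np.where(lungs.any(axis=(1, 2)))[0]
    z0, z1 = int(zs.min()), int(zs.max())
    ct_arr, (y0, x0) = _crop_pad_2d(scan.ct.values[z0 : z1 + 1], cfg.crop_xy, CT_PAD_HU)
    pet_arr, _ = _crop_pad_2d(scan.pet.values[z0 : z1 + 1], cfg.crop_xy, PET_PAD_SUV)
    sp = scan.ct.spacing
    new_origin = (
        scan.ct.origin[0] + x0 * sp[0],
        scan.ct.origin[1] + y0 * sp[1],
        scan.ct.origin[2] + z0 * sp[2],
    )
    ct = Volume3D(ct_arr, sp, new_origin, Modality.CT_HU)
    pet = Volume3D(pet_arr, scan.pet.spacing, new_origin, Modality.PET_SUV)
    return ThoraxCrop(
        ct=ct, pet=pet, z_range=(z0, z1), xy_offset=(y0, x0), patient_id=scan.patient_id
    )


def clip_intensities(crop: ThoraxCrop, cfg: PreprocessConfig | None = None) -> ThoraxCrop:
    """Bound CT to [-1000, 1000] HU and PET to [0, 8] SUV."""
    cfg = cfg or PreprocessConfig()
    ct = replace(crop.ct, values=np.clip(crop.ct.values, *cfg.ct_clip))
    pet = replace(crop.pet, values=np.clip(crop.pet.values, *cfg.suv_clip))
    return replace(crop, ct=ct, pet=pet)


def fit_normalization(
    crops: Iterable[ThoraxCrop], fitted_on: str = "training"
) -> NormalizationStats:
    """Pool mean/sd per modality over every voxel of every training crop."""
    n = 0
    s_ct = ss_ct = s_pet = ss_pet = 0.0
    for crop in crops:
        ct = crop.ct.values.astype(np.float64)
        pet = crop.pet.values.astype(np.float64)
        n += ct.size
        s_ct += ct.sum()
        ss_ct += (ct**2).sum()
        s_pet += pet.sum()
        ss_pet += (pet**2).sum()
    if n == 0:
        raise DegenerateDataError("no training crops supplied")
    ct_mean = s_ct / n
    pet_mean = s_pet / n
    ct_var = max(ss_ct / n - ct_mean**2, 0.0)
    pet_var = max(ss_pet / n - pet_mean**2, 0.0)
    if ct_var == 0.0 or pet_var == 0.0:
        raise DegenerateDataError("zero variance in training data; cannot standardise")
    return NormalizationStats(
        ct_mean=ct_mean,
        ct_sd=float(np.sqrt(ct_var)),
        pet_mean=pet_mean,
        pet_sd=float(np.sqrt(pet_var)),
        fitted_on=fitted_on,
    )


def apply_normalization(crop: ThoraxCrop, stats: NormalizationStats) -> ThoraxCrop:
    """Affine, order-preserving standardisation per modality."""
    if stats is None:
        raise NotFittedError("normalization stats missing; fit on training data first")
    ct = replace(crop.ct, values=(crop.ct.values - stats.ct_mean) / stats.ct_sd)
    pet = replace(crop.pet, values=(crop.pet.values - stats.pet_mean) / stats.pet_sd)
    return replace(crop, ct=ct, pet=pet, standardized=True)


def invert_normalization(crop: ThoraxCrop, stats: NormalizationStats) -> ThoraxCrop:
    ct = replace(crop.ct, values=crop.ct.values * stats.ct_sd + stats.ct_mean)
    pet = replace(crop.pet, values=crop.pet.values * stats.pet_sd + stats.pet_mean)
    return replace(crop, ct=ct, pet=pet, standardized=False)


def preprocess_scan(scan: PatientScan, cfg: PreprocessConfig | None = None) -> ThoraxCrop:
    """Resample both modalities to 1 mm, locate the thorax, crop and clip.

    Standardisation is not applied here: it needs dataset-level statistics
    (see :class:`IntensityStandardizer`).
    """
    cfg = cfg or PreprocessConfig()
    ct = resample_isotropic(scan.ct, cfg.target_spacing)
    pet = resample_isotropic(scan.pet, cfg.target_spacing)
    # the two grids can differ by one voxel after rounding; align on the CT
    if pet.shape != ct.shape:
        fixed = np.full(ct.shape, PET_PAD_SUV, dtype=pet.values.dtype)
        nz = min(ct.shape[0], pet.shape[0])
        ny = min(ct.shape[1], pet.shape[1])
        nx = min(ct.shape[2], pet.shape[2])
        fixed[:nz, :ny, :nx] = pet.values[:nz, :ny, :nx]
        pet = Volume3D(fixed, ct.spacing, ct.origin, Modality.PET_SUV)
    resampled = PatientScan(
        patient_id=scan.patient_id,
        scanner_id=scan.scanner_id,
        ct=ct,
        pet=pet,
        nodes=scan.nodes,
    )
    mask = segment_air(ct, cfg)
    lungs = _locate_lungs(mask, cfg.border_margin_voxels)
    crop = crop_thorax(resampled, lungs, cfg)
    return clip_intensities(crop, cfg)


# ---------------------------------------------------------------------------
# Estimator-style wrappers
# ---------------------------------------------------------------------------

class ThoraxPreprocessor:
    """Stateless transformer: PatientScan -> clipped, unstandardised ThoraxCrop."""

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config or PreprocessConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "ThoraxPreprocessor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def transform(self, scans: Sequence[PatientScan] | PatientScan):
        if isinstance(scans, PatientScan):
            return preprocess_scan(scans, self.config)
        return [preprocess_scan(s, self.config) for s in scans]


class IntensityStandardizer:
    """Dataset-level zero-mean/unit-variance standardiser (fit on training only).

    Fitted attributes: ``stats_`` (a :class:`NormalizationStats`).
    """

    def __init__(self, fitted_on: str = "training"):
        self.fitted_on = fitted_on

    def get_params(self, deep: bool = True) -> dict:
        return {"fitted_on": self.fitted_on}

    def set_params(self, **params) -> "IntensityStandardizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, crops: Sequence[ThoraxCrop], y=None) -> "IntensityStandardizer":
        self.stats_ = fit_normalization(crops, fitted_on=self.fitted_on)
        return self

    def transform(self, crops: Sequence[ThoraxCrop] | ThoraxCrop):
        if not hasattr(self, "stats_"):
            raise NotFittedError("IntensityStandardizer must be fitted first")
        if isinstance(crops, ThoraxCrop):
            return apply_normalization(crops, self.stats_)
        return [apply_normalization(c, self.stats_) for c in crops]

    def fit_transform(self, crops: Sequence[ThoraxCrop], y=None):
        return self.fit(crops).transform(crops)

    def inverse_transform(self, crops: Sequence[ThoraxCrop] | ThoraxCrop):
        if isinstance(crops, ThoraxCrop):
            return invert_normalization(crops, self.stats_)
        return [invert_normalization(c, self.stats_) for c in crops]
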