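"""Volumetric image containers and I/O.

Arrays are indexed ``(z, y, x)`` (the natural axis order of axial image
stacks) while all physical quantities — spacing, origin, node coordinates —
are expressed in millimetres in ``(x, y, z)`` order under the voxel-centre
convention: the physical position of voxel ``(k, j, i)`` is
``origin + (i, j, k) * spacing``.  Module boundaries exchange physical
coordinates, never raw indices, because the two scanners this package
targets use different native spacings.

File I/O (NIfTI, DICOM series) and resampling are delegated to SimpleITK,
whose ``(x, y, z)`` metadata convention matches ours.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import (
    ConsistencyError,
    FormatError,
    ParseError,
    SchemaError,
    ShapeError,
)

__all__ = [
    "Modality",
    "Volume3D",
    "NodeAnnotation",
    "PatientScan",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "read_nodes",
    "write_nodes",
    "write_detections",
]


class Modality(str, enum.Enum):
    CT_HU = "CT_HU"
    PET_SUV = "PET_SUV"


@dataclass
class Volume3D:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Voxel values; HU for CT, SUV for PET.
    spacing : (sx, sy, sz) in mm, strictly positive.
    origin : (ox, oy, oz) in mm — physical position of voxel (0, 0, 0).
    modality : Modality
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT_HU

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ShapeError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ShapeError("spacing and origin must be (x, y, z) triples")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")
        self.modality = Modality(self.modality)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape (nz, ny, nx)."""
        return self.values.shape  # type: ignore[return-value]

    def index_to_physical(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) ``(z, y, x)`` indices to mm ``(x, y, z)``."""
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        sp = np.asarray(self.spacing)
        og = np.asarray(self.origin)
        xyz = og + idx[:, ::-1] * sp
        return xyz if np.asarray(idx_zyx).ndim > 1 else xyz[0]

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm ``(x, y, z)`` points to fractional ``(z, y, x)`` indices."""
        pts = np.atleast_2d(np.asarray(xyz, dtype=float))
        sp = np.asarray(self.spacing)
        og = np.asarray(self.origin)
        idx = ((pts - og) / sp)[:, ::-1]
        return idx if np.asarray(xyz).ndim > 1 else idx[0]

    def physical_to_nearest_index(self, xyz: np.ndarray) -> np.ndarray:
        return np.rint(self.physical_to_index(xyz)).astype(int)

    def contains_physical(self, xyz: np.ndarray) -> np.ndarray:
        """True where a point lies inside the volume's physical extent.

        The extent includes the half-voxel border around edge voxel centres.
        """
        idx = np.atleast_2d(self.physical_to_index(xyz))
        shp = np.asarray(self.shape)
        ok = np.all((idx >= -0.5) & (idx <= shp - 0.5), axis=1)
        return ok if np.asarray(xyz).ndim > 1 else ok[0]

    @property
    def physical_extent(self) -> tuple[tuple[float, float], ...]:
        """((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)) outer bounds in mm."""
        shp = np.asarray(self.shape)[::-1]  # nx, ny, nz
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + shp * np.asarray(self.spacing)
        return tuple((float(a), float(b)) for a, b in zip(lo, hi))

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: Modality) -> "Volume3D":
        if img.GetDimension() != 3:
            raise ShapeError(f"expected 3D image, got {img.GetDimension()}D")
        return cls(
            values=sitk.GetArrayFromImage(img),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            modality=modality,
        )


@dataclass(frozen=True)
class NodeAnnotation:
    """A point-marked lymph node: physical mm centre, no contour."""

    patient_id: str
    centre: tuple[float, float, float]  # (x, y, z) mm
    source: str = "ground_truth"  # reference_reader | second_reader | ground_truth


@dataclass
class PatientScan:
    """Co-registered CT + PET pair with ground-truth node centres."""

    patient_id: str
    scanner_id: str
    ct: Volume3D
    pet: Volume3D
    nodes: list[NodeAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ct.modality is not Modality.CT_HU:
            raise ConsistencyError("PatientScan.ct must have modality CT_HU")
        if self.pet.modality is not Modality.PET_SUV:
            raise ConsistencyError("PatientScan.pet must have modality PET_SUV")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, modality: Modality | str) -> Volume3D:
    """Read a NIfTI file or a DICOM series directory.

    DICOM slices are ordered by physical slice position regardless of file
    name order.  The caller declares the modality (HU vs SUV); no unit
    conversion is performed.
    """
    modality = Modality(modality)
    path = os.fspath(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        file_names = reader.GetGDCMSeriesFileNames(path)
        if not file_names:
            raise FormatError(f"no DICOM series found in directory {path!r}")
        reader.SetFileNames(file_names)
        img = reader.Execute()
    else:
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path!r}")
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:  # unreadable / not an image
            raise FormatError(f"cannot read image {path!r}: {exc}") from exc
    if img.GetDimension() == 4 and img.GetSize()[3] == 1:
        img = img[:, :, :, 0]
    if img.GetDimension() != 3:
        raise ShapeError(
            f"{path!r}: expected a 3D image, got {img.GetDimension()}D"
        )
    if any(s <= 0 for s in img.GetSpacing()):
        raise FormatError(f"{path!r}: invalid pixel spacing {img.GetSpacing()}")
    return Volume3D.from_sitk(img, modality)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    sitk.WriteImage(vol.to_sitk(), os.fspath(path))


def resample_isotropic(vol: Volume3D, target_spacing: float = 1.0) -> Volume3D:
    """Resample to an isotropic grid (default 1 mm) with cubic B-spline
    interpolation, preserving the physical extent to within one voxel.

    Values beyond the original grid are extended with the nearest edge value.
    """
    if min(vol.shape) < 2:
        raise ShapeError(
            f"cannot resample a degenerate axis: shape {vol.shape}"
        )
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    img = vol.to_sitk()
    old_size = np.asarray(img.GetSize(), dtype=float)  # (x, y, z)
    old_sp = np.asarray(img.GetSpacing())
    new_sp = np.full(3, float(target_spacing))
    new_size = np.maximum(1, np.rint(old_size * old_sp / new_sp)).astype(int)
    # voxel-centre convention: keep the outer physical boundary fixed
    new_origin = np.asarray(img.GetOrigin()) - 0.5 * old_sp + 0.5 * new_sp
    out = sitk.Resample(
        img,
        [int(n) for n in new_size],
        sitk.Transform(),
        sitk.sitkBSpline,
        [float(o) for o in new_origin],
        [float(s) for s in new_sp],
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
        useNearestNeighborExtrapolator=True,
    )
    return Volume3D.from_sitk(out, vol.modality)


# ---------------------------------------------------------------------------
# Node annotation tables
# ---------------------------------------------------------------------------

_NODE_COLUMNS = ("patient_id", "x_mm", "y_mm", "z_mm")


def read_nodes(path: str | os.PathLike) -> list[NodeAnnotation]:
    """Read a node annotation CSV with columns patient_id,x_mm,y_mm,z_mm[,source]."""
    df = pd.read_csv(path)
    missing = [c for c in _NODE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{os.fspath(path)!r}: missing column(s) {missing}")
    for c in ("x_mm", "y_mm", "z_mm"):
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric value in column {c!r}: {exc}") from exc
    if "source" not in df.columns:
        df["source"] = "ground_truth"
    return [
        NodeAnnotation(
            patient_id=str(r.patient_id),
            centre=(float(r.x_mm), float(r.y_mm), float(r.z_mm)),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]


def write_nodes(nodes: Iterable[NodeAnnotation], path: str | os.PathLike) -> None:
    rows = [
        {
            "patient_id": n.patient_id,
            "x_mm": n.centre[0],
            "y_mm": n.centre[1],
            "z_mm": n.centre[2],
            "source": n.source,
        }
        for n in nodes
    ]
    pd.DataFrame(rows, columns=["patient_id", "x_mm", "y_mm", "z_mm", "source"]).to_csv(
        path, index=False
    )


def write_detections(
    regions: Sequence,
    scoremap: "Volume3D | None",
    path_stem: str | os.PathLike,
    grid: Volume3D | None = None,
) -> dict[str, str]:
    """Write detections as a NIfTI label map plus a centroid/volume table.

    Region ``i`` (1-based) is painted with value ``i``; 0 is background.
    Returns the mapping of artefact kind to file path.
    """
    from .regions import regions_to_labelmap  # local import: avoid cycle

    stem = os.fspath(path_stem)
    geom = grid if grid is not None else (scoremap if scoremap is not None else None)
    if geom is None:
        raise ValueError("need a grid or scoremap to define the output geometry")
    labels = regions_to_labelmap(regions, geom.shape)
    label_vol = Volume3D(
        labels.astype(np.int32), geom.spacing, geom.origin, Modality.CT_HU
    )
    out = {}
    out["labels"] = stem + "_labels.nii.gz"
    write_volume(label_vol, out["labels"])
    rows = []
    for i, r in enumerate(regions, start=1):
        centroid_xyz = geom.index_to_physical(r.voxels.mean(axis=0))
        rows.append(
            {
                "region": i,
                "patient_id": r.patient_id,
                "volume_voxels": r.volume,
                "centroid_x_mm": centroid_xyz[0],
                "centroid_y_mm": centroid_xyz[1],
                "centroid_z_mm": centroid_xyz[2],
            }
        )
    out["table"] = stem + "_regions.csv"
    pd.DataFrame(
        rows,
        columns=[
            "region",
            "patient_id",
            "volume_voxels",
            "centroid_x_mm",
            "centroid_y_mm",
            "centroid_z_mm",
        ],
    ).to_csv(out["table"], index=False)
    if scoremap is not None:
        out["scores"] = stem + "_scores.nii.gz"
        write_volume(scoremap, out["scores"])
    return out
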