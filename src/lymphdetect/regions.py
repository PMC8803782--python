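"""Connected candidate regions.

A :class:`CandidateRegion` is a 26-connected set of voxels in a crop grid.
One global convention: connected components use 26-connectivity in 3D,
morphological structuring elements use face (connectivity-one) neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError

#: 26-connectivity structuring element for component labelling.
CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Face-connected (connectivity-one) element for morphology.
FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class CandidateRegion:
    """A connected component of candidate voxels.

    voxels : (n, 3) int array of (z, y, x) grid indices, 26-connected.
    """

    voxels: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.shape[1] != 3:
            raise ConsistencyError("region voxels must be (n, 3) (z, y, x)")

    @property
    def volume(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        """Inclusive ((z0,z1),(y0,y1),(x0,x1)) index ranges."""
        lo = self.voxels.min(axis=0)
        hi = self.voxels.max(axis=0)
        return tuple((int(a), int(b)) for a, b in zip(lo, hi))

    def contains_index(self, idx_zyx: np.ndarray) -> bool:
        idx = np.asarray(idx_zyx, dtype=int)
        return bool(np.any(np.all(self.voxels == idx, axis=1)))

    def to_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        z, y, x = self.voxels.T
        if (
            (z < 0).any() or (y < 0).any() or (x < 0).any()
            or (z >= shape[0]).any() or (y >= shape[1]).any() or (x >= shape[2]).any()
        ):
            raise ConsistencyError("region voxel outside grid")
        m[z, y, x] = True
        return m

    def equivalent_diameter_mm(self, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
        """Diameter of the sphere with the region's volume (mm)."""
        voxel_mm3 = float(np.prod(spacing))
        return float((6.0 * self.volume * voxel_mm3 / np.pi) ** (1.0 / 3.0))


def label_components(mask: np.ndarray, patient_id: str = "") -> list[CandidateRegion]:
    """Extract 26-connected components of a binary mask in scan order.

    Components are numbered by scipy's raster-scan order, which makes
    size-tie handling deterministic for callers that pick by label index.
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=CONN26)
    regions = []
    for i in range(1, n + 1):
        vox = np.argwhere(labels == i)
        regions.append(CandidateRegion(voxels=vox, patient_id=patient_id))
    return regions


def regions_to_labelmap(
    regions: Sequence[CandidateRegion], shape: tuple[int, int, int]
) -> np.ndarray:
    """Paint region ``i`` (1-based) as value ``i``; 0 is background."""
    out = np.zeros(shape, dtype=np.int32)
    for i, r in enumerate(regions, start=1):
        z, y, x = r.voxels.T
        if (
            (z < 0).any() or (y < 0).any() or (x < 0).any()
            or (z >= shape[0]).any() or (y >= shape[1]).any() or (x >= shape[2]).any()
        ):
            raise ConsistencyError(f"region {i} has voxels outside the grid")
        out[z, y, x] = i
    return out


def regions_to_mask(
    regions: Sequence[CandidateRegion], shape: tuple[int, int, int]
) -> np.ndarray:
    return regions_to_labelmap(regions, shape) > 0
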