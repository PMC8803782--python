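"""Synthetic thoracic PET/CT phantoms with known node ground truth.

The generator emulates the whole-body FDG-PET/CT acquisitions the detection
pipeline consumes: a soft-tissue body on an air background, two air-filled
lung ellipsoids joined by a tracheal air bridge (so the lungs form a single
connected air region, as in real anatomy), a mediastinal compartment between
the lungs where "positive node" hot spots are planted in the PET, diffuse
physiological background uptake, and at least one distractor hot spot
outside the mediastinum (a thyroid-nodule / inflammation analogue that the
false-positive-reduction stage must learn to reject).

Two scanner profiles differ in PET voxel size, noise, and lesion contrast,
emulating the domain shift between an older and a newer PET/CT system.
Geometry is parametric (ellipsoids and cylinders), not an anatomical atlas:
it is sufficient to exercise every algorithmic stage of the pipeline at desk
scale.  PET degradation is modelled as a Gaussian point-spread blur plus
additive Gaussian noise; it is not a reconstruction simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .volume import Modality, NodeAnnotation, PatientScan, Volume3D

__all__ = [
    "ScannerProfile",
    "PhantomParams",
    "PhantomCohort",
    "SCANNER1",
    "SCANNER2",
    "scanner_profile",
    "generate_phantom",
    "generate_cohort",
    "draw_node_counts",
]


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition knobs that differ between the two emulated scanners."""

    id: str
    pet_spacing: tuple[float, float, float]  # (x, y, z) mm
    ct_spacing: tuple[float, float, float]
    pet_noise_sd: float  # SUV, additive Gaussian
    contrast_gain: float  # multiplier on lesion SUV


#: Older TOF PET/CT: coarse 4 mm isotropic PET voxels.
SCANNER1 = ScannerProfile(
    id="scanner1",
    pet_spacing=(4.0, 4.0, 4.0),
    ct_spacing=(2.0, 2.0, 2.0),
    pet_noise_sd=0.20,
    contrast_gain=1.0,
)

#: Newer digital system: finer PET voxels, less noise, higher lesion contrast.
SCANNER2 = ScannerProfile(
    id="scanner2",
    pet_spacing=(2.5, 2.5, 2.8),
    ct_spacing=(2.0, 2.0, 2.0),
    pet_noise_sd=0.15,
    contrast_gain=1.4,
)

_PROFILES = {"scanner1": SCANNER1, "scanner2": SCANNER2}


def scanner_profile(name: str) -> ScannerProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown scanner profile {name!r}") from None


#: Patients-by-node-count distribution pooled over the first scanner's
#: cohort (125 patients): P(0,1,2,3,4+). "4+" is drawn uniformly from 4-6.
DEFAULT_NODE_COUNT_PROBS: dict[str, float] = {
    "0": 67 / 125,
    "1": 17 / 125,
    "2": 16 / 125,
    "3": 7 / 125,
    "4+": 18 / 125,
}


@dataclass
class PhantomParams:
    """Tissue values, lesion statistics, and grid geometry of the phantom.

    The native grid is 128 x 128 x 96 voxels at 2 mm (x-y-z extent
    256 x 256 x 192 mm, a slim adult thorax-and-surroundings field of view);
    the pipeline resamples to 1 mm.  Anatomy scales with the grid extent,
    so larger phantoms can be requested via ``grid_shape``.
    """

    body_hu: float = 0.0
    lung_hu: float = -800.0
    air_hu: float = -1000.0
    node_hu: float = 40.0
    node_diameter_range: tuple[float, float] = (8.0, 30.0)
    node_suv_range: tuple[float, float] = (3.0, 8.0)
    background_suv: tuple[float, float] = (1.0, 2.0)
    node_count_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NODE_COUNT_PROBS)
    )
    n_nodes: int | None = None  # force an exact count (None: draw from probs)
    ct_noise_sd: float = 10.0  # HU
    pet_psf_sigma: float = 1.5  # mm, Gaussian PSF blur
    n_distractors_range: tuple[int, int] = (1, 2)
    distractor_suv_range: tuple[float, float] = (3.0, 6.0)
    grid_shape: tuple[int, int, int] = (96, 128, 128)  # (z, y, x) at ct_spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_hu <= self.lung_hu:
            raise ValueError("nodes are soft tissue: node_hu must exceed lung_hu")
        total = sum(self.node_count_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"node_count_probs must sum to 1, got {total}")


@dataclass
class PhantomCohort:
    scans: list[PatientScan]
    profile: ScannerProfile
    params: PhantomParams

    def split(self, n_first: int) -> tuple[list[PatientScan], list[PatientScan]]:
        """Split by patient: first ``n_first`` scans vs the rest (disjoint ids)."""
        return self.scans[:n_first], self.scans[n_first:]


# ---------------------------------------------------------------------------
# Geometry (all positions in physical mm, (x, y, z))
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Anatomy:
    """Parametric body geometry derived from the phantom's physical extent.

    Shapes are fractions of the (X, Y, Z) mm field of view: an elliptic-
    cylinder body, two lung ellipsoids joined by a tracheal air bridge, a
    mediastinal box between the lungs for node placement.
    """

    extent: tuple[float, float, float]

    @property
    def body_centre(self):
        return (self.extent[0] / 2, self.extent[1] / 2)

    @property
    def body_semi(self):
        return (0.39 * self.extent[0], 0.305 * self.extent[1])

    @property
    def body_z(self):
        return (0.04 * self.extent[2], 0.96 * self.extent[2])

    @property
    def lung_centres(self):
        cx, cy = self.body_centre
        dx = 0.20 * self.extent[0]
        cz = 0.52 * self.extent[2]
        return ((cx - dx, cy, cz), (cx + dx, cy, cz))

    @property
    def lung_semi(self):
        return (0.115 * self.extent[0], 0.20 * self.extent[1], 0.25 * self.extent[2])

    @property
    def bridge(self):  # (y, z, radius)
        # radius 10 mm: wide enough that the 7-iteration binary opening of
        # the lung segmentation cannot sever the air bridge at 1 mm spacing
        return (0.335 * self.extent[1], 0.55 * self.extent[2], 10.0)

    @property
    def mediastinum(self):  # node-placement box
        return {
            "dx": 0.047 * self.extent[0],
            "dy": 0.15 * self.extent[1],
            "z": (0.33 * self.extent[2], 0.72 * self.extent[2]),
        }


def _grid_coords(shape_zyx, spacing_xyz):
    """Physical (x, y, z) coordinate arrays broadcastable over a (z,y,x) grid."""
    nz, ny, nx = shape_zyx
    sx, sy, sz = spacing_xyz
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    return (
        x[np.newaxis, np.newaxis, :],
        y[np.newaxis, :, np.newaxis],
        z[:, np.newaxis, np.newaxis],
    )


def _body_mask(anat: Anatomy, x, y, z):
    cx, cy = anat.body_centre
    ax, ay = anat.body_semi
    z0, z1 = anat.body_z
    return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0) & (z >= z0) & (z <= z1)


def _lung_value(anat: Anatomy, x, y, z, centre):
    cx, cy, cz = centre
    ax, ay, az = anat.lung_semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


def _lungs_mask(anat: Anatomy, x, y, z):
    return (_lung_value(anat, x, y, z, anat.lung_centres[0]) <= 1.0) | (
        _lung_value(anat, x, y, z, anat.lung_centres[1]) <= 1.0
    )


def _bridge_mask(anat: Anatomy, x, y, z):
    by, bz, br = anat.bridge
    in_x = (x >= anat.lung_centres[0][0]) & (x <= anat.lung_centres[1][0])
    return in_x & ((y - by) ** 2 + (z - bz) ** 2 <= br**2)


def _point_lung_clearance(anat: Anatomy, p) -> float:
    """Approximate distance (mm) from a point to the nearer lung surface."""
    best = np.inf
    for c in anat.lung_centres:
        s = np.sqrt(_lung_value(anat, p[0], p[1], p[2], c))
        best = min(best, (s - 1.0) * min(anat.lung_semi))
    return float(best)


def draw_node_counts(
    rng: np.random.Generator, n: int, probs: dict[str, float] | None = None
) -> np.ndarray:
    """Draw per-patient node counts from the cohort distribution."""
    probs = dict(DEFAULT_NODE_COUNT_PROBS) if probs is None else probs
    cats = list(probs.keys())
    p = np.array([probs[c] for c in cats])
    picks = rng.choice(len(cats), size=n, p=p)
    out = np.empty(n, dtype=int)
    for i, k in enumerate(picks):
        c = cats[k]
        out[i] = rng.integers(4, 7) if c == "4+" else int(c)
    return out


def _place_spheres(
    anat: Anatomy,
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    inside_mediastinum: bool,
    existing: list[tuple[np.ndarray, float]],
    max_tries: int = 400,
) -> list[np.ndarray]:
    """Rejection-sample sphere centres with minimum separation."""
    cx, cy = anat.body_centre
    medi = anat.mediastinum
    by, bz, br = anat.bridge
    placed: list[np.ndarray] = []
    for i in range(n):
        r = float(radii[i])
        for attempt in range(max_tries):
            if inside_mediastinum:
                p = np.array(
                    [
                        cx + rng.uniform(-medi["dx"], medi["dx"]),
                        cy + rng.uniform(-medi["dy"], medi["dy"]),
                        rng.uniform(*medi["z"]),
                    ]
                )
                # keep lesions out of the air-filled lungs and trachea
                if _point_lung_clearance(anat, p) < r + 3.0:
                    continue
                if np.hypot(p[1] - by, p[2] - bz) < r + br + 3.0:
                    continue
            else:
                p = np.array(
                    [
                        cx + rng.uniform(-0.43, 0.43) * anat.extent[0],
                        cy + rng.uniform(-0.41, 0.41) * anat.extent[1],
                        rng.uniform(*medi["z"]),
                    ]
                )
                in_medi = (
                    abs(p[0] - cx) <= 0.16 * anat.extent[0]
                    and abs(p[1] - cy) <= medi["dy"] + 10
                )
                if in_medi:
                    continue
                if ((p[0] - cx) / anat.body_semi[0]) ** 2 + (
                    (p[1] - cy) / anat.body_semi[1]
                ) ** 2 > 0.85:
                    continue
                if _point_lung_clearance(anat, p) < r + 3.0:
                    continue
            ok = all(
                np.linalg.norm(p - q) >= r + rq + 4.0
                for q, rq in existing
            )
            if ok:
                placed.append(p)
                existing.append((p, r))
                break
        else:
            raise PlacementError(
                f"could not place sphere {i + 1}/{n} (radius {r:.1f} mm) "
                "at the minimum separation"
            )
    return placed


def _paint_spheres(arr, x, y, z, centres, radii, values, mode="set"):
    for c, r, v in zip(centres, radii, values):
        m = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r**2
        if mode == "set":
            arr[m] = v
        else:  # max: lesion uptake never dims the background
            arr[m] = np.maximum(arr[m], v)


def generate_phantom(
    params: PhantomParams,
    profile: ScannerProfile,
    patient_id: str,
    rng: np.random.Generator | None = None,
    with_masks: bool = False,
):
    """Generate one paired CT/PET phantom scan.

    Returns a :class:`PatientScan`; with ``with_masks=True`` also a dict of
    ground-truth masks on the CT grid (``lungs``, ``body``, ``mediastinum``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_nodes = (
        int(params.n_nodes)
        if params.n_nodes is not None
        else int(draw_node_counts(rng, 1, params.node_count_probs)[0])
    )
    node_radii = rng.uniform(*params.node_diameter_range, size=n_nodes) / 2.0
    node_suv = rng.uniform(*params.node_suv_range, size=n_nodes) * profile.contrast_gain
    n_distr = int(rng.integers(params.n_distractors_range[0], params.n_distractors_range[1] + 1))
    distr_radii = rng.uniform(10.0, 16.0, size=n_distr) / 2.0
    distr_suv = rng.uniform(*params.distractor_suv_range, size=n_distr) * profile.contrast_gain

    ct_shape = params.grid_shape
    extent = tuple(
        float(n * s) for n, s in zip(ct_shape[::-1], profile.ct_spacing)
    )  # (X, Y, Z) mm
    anat = Anatomy(extent)
    existing: list[tuple[np.ndarray, float]] = []
    node_centres = _place_spheres(anat, rng, n_nodes, node_radii, True, existing)
    distr_centres = _place_spheres(anat, rng, n_distr, distr_radii, False, existing)

    # ---- CT on its native grid ----
    x, y, z = _grid_coords(ct_shape, profile.ct_spacing)
    body = _body_mask(anat, x, y, z)
    lungs = _lungs_mask(anat, x, y, z) & body
    bridge = _bridge_mask(anat, x, y, z) & body
    ct = np.full(ct_shape, params.air_hu, dtype=np.float32)
    ct[body] = params.body_hu
    ct[lungs] = params.lung_hu
    ct[bridge] = -950.0
    _paint_spheres(ct, x, y, z, node_centres, node_radii, [params.node_hu] * n_nodes)
    ct += rng.normal(0.0, params.ct_noise_sd, size=ct_shape).astype(np.float32)

    # ---- PET on its native grid (same physical extent) ----
    pet_shape = tuple(
        int(max(1, round(e / s)))
        for e, s in zip(extent[::-1], profile.pet_spacing[::-1])
    )  # (z, y, x)
    xp, yp, zp = _grid_coords(pet_shape, profile.pet_spacing)
    bg = rng.uniform(*params.background_suv)
    body_p = _body_mask(anat, xp, yp, zp)
    lungs_p = (_lungs_mask(anat, xp, yp, zp) | _bridge_mask(anat, xp, yp, zp)) & body_p
    pet = np.zeros(pet_shape, dtype=np.float32)
    pet[body_p] = bg
    pet[lungs_p] = 0.15 * bg
    _paint_spheres(pet, xp, yp, zp, node_centres, node_radii, node_suv, mode="max")
    _paint_spheres(pet, xp, yp, zp, distr_centres, distr_radii, distr_suv, mode="max")
    sigma_vox = [params.pet_psf_sigma / s for s in profile.pet_spacing[::-1]]
    pet = ndimage.gaussian_filter(pet, sigma=sigma_vox).astype(np.float32)
    pet += rng.normal(0.0, profile.pet_noise_sd, size=pet_shape).astype(np.float32)
    np.clip(pet, 0.0, None, out=pet)

    ct_vol = Volume3D(
        ct,
        spacing=profile.ct_spacing,
        origin=tuple(s / 2.0 for s in profile.ct_spacing),
        modality=Modality.CT_HU,
    )
    pet_vol = Volume3D(
        pet,
        spacing=profile.pet_spacing,
        origin=tuple(s / 2.0 for s in profile.pet_spacing),
        modality=Modality.PET_SUV,
    )
    nodes = [
        NodeAnnotation(patient_id=patient_id, centre=tuple(map(float, c)), source="ground_truth")
        for c in node_centres
    ]
    scan = PatientScan(
        patient_id=patient_id,
        scanner_id=profile.id,
        ct=ct_vol,
        pet=pet_vol,
        nodes=nodes,
    )
    if with_masks:
        return scan, {"body": body, "lungs": lungs | bridge, "mediastinum": ~lungs & body}
    return scan


def generate_cohort(
    n_patients: int,
    params: PhantomParams,
    profile: ScannerProfile,
    seed: int | None = None,
) -> PhantomCohort:
    """Generate a cohort with per-patient seeds derived from the cohort seed."""
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    scans = []
    for i, child in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(child)
        pid = f"{profile.id}-p{i:03d}"
        scans.append(generate_phantom(params, profile, pid, rng=rng))
    return PhantomCohort(scans=scans, profile=profile, params=params)


def cohort_manifest(cohort: PhantomCohort, seed: int | None = None) -> dict:
    """A serialisable record of how a cohort was generated."""
    return {
        "profile": asdict(cohort.profile),
        "params": asdict(cohort.params),
        "seed": seed if seed is not None else cohort.params.seed,
        "patients": [
            {"patient_id": s.patient_id, "n_nodes": len(s.nodes)} for s in cohort.scans
        ],
    }
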