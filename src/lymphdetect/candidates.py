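"""Phase one: high-sensitivity candidate generation with a 2D U-Net.

Nodes are point annotations, not contours, so training labels are surrogate
spheres of radius 15 mm centred on each node (most nodes are under 30 mm in
diameter, so the sphere covers the whole node).  The U-Net sees whole
256 x 256 two-channel (CT, PET) slices — the full physiological context of
a slice — and only slices containing at least one positive label voxel are
used for training.  At inference every slice of the volume is segmented,
the probability maps are stacked and binarised, 26-connected components are
extracted, components smaller than 300 voxels are discarded, and the
survivors are dilated three iterations with the face-connected element
(overlapping dilations merge into single regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import AnnotationError, DataError, NotFittedError
from .nn import Adam, UNet2D, dice_loss_and_grad, sigmoid, state_dict, load_state_dict, state_hash
from .preprocess import ThoraxCrop
from .regions import FACE_STRUCT, CandidateRegion, label_components, regions_to_mask
from .volume import NodeAnnotation, Volume3D

__all__ = [
    "CandidateConfig",
    "make_sphere_labels",
    "filter_and_dilate",
    "candidate_sensitivity",
    "CandidateGenerator",
]


@dataclass(frozen=True)
class CandidateConfig:
    sphere_radius: float = 15.0  # mm
    min_region_voxels: int = 300
    dilation_iters: int = 3
    epochs: int = 20
    learning_rate: float = 1e-5
    mask_threshold: float = 0.5
    batch_size: int = 8
    base_channels: int = 32
    depth: int = 4

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.min_region_voxels < 1:
            raise ValueError("min_region_voxels must be >= 1")


def make_sphere_labels(
    nodes: Sequence[NodeAnnotation],
    grid: Volume3D,
    radius: float = 15.0,
) -> np.ndarray:
    """Union of spheres of ``radius`` mm around node centres, rasterised on
    the grid under the voxel-centre convention (truncated at grid borders).
    """
    mask = np.zeros(grid.shape, dtype=bool)
    sp = np.asarray(grid.spacing)  # (x, y, z)
    for node in nodes:
        if not grid.contains_physical(np.asarray(node.centre)):
            raise AnnotationError(
                f"node {node.patient_id} at {node.centre} lies outside the grid"
            )
        c_zyx = grid.physical_to_index(np.asarray(node.centre))  # fractional
        r_vox = radius / sp[::-1]  # per (z, y, x) axis
        lo = np.maximum(np.ceil(c_zyx - r_vox).astype(int), 0)
        hi = np.minimum(np.floor(c_zyx + r_vox).astype(int), np.asarray(grid.shape) - 1)
        if np.any(lo > hi):
            continue
        zz, yy, xx = np.ogrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        d2 = (
            ((zz - c_zyx[0]) * sp[2]) ** 2
            + ((yy - c_zyx[1]) * sp[1]) ** 2
            + ((xx - c_zyx[2]) * sp[0]) ** 2
        )
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= radius**2
    return mask


def filter_and_dilate(
    regions: Sequence[CandidateRegion],
    shape: tuple[int, int, int],
    cfg: CandidateConfig | None = None,
) -> list[CandidateRegion]:
    """Drop regions under the volume floor, dilate survivors, merge overlaps.

    Dilation distributes over union, so the surviving regions are dilated as
    one mask; touching dilated regions become a single component.
    """
    cfg = cfg or CandidateConfig()
    kept = [r for r in regions if r.volume >= cfg.min_region_voxels]
    if not kept:
        return []
    pid = kept[0].patient_id
    mask = regions_to_mask(kept, shape)
    if cfg.dilation_iters:
        mask = ndimage.binary_dilation(mask, FACE_STRUCT, iterations=cfg.dilation_iters)
    return label_components(mask, patient_id=pid)


def candidate_sensitivity(
    regions: Sequence[CandidateRegion],
    nodes: Sequence[NodeAnnotation],
    grid: Volume3D,
) -> float:
    """Fraction of node centres covered by at least one candidate region."""
    if len(nodes) == 0:
        warnings.warn("candidate_sensitivity undefined for zero nodes", stacklevel=2)
        return float("nan")
    if not regions:
        return 0.0
    mask = regions_to_mask(regions, grid.shape)
    hit = 0
    for node in nodes:
        idx = grid.physical_to_nearest_index(np.asarray(node.centre))
        if np.all(idx >= 0) and np.all(idx < np.asarray(grid.shape)):
            hit += bool(mask[tuple(idx)])
    return hit / len(nodes)


class CandidateGenerator:
    """sklearn-style estimator wrapping the phase-one U-Net.

    ``fit(crops, nodes_per_crop)`` trains on positive-label slices only;
    ``predict(crop)`` returns filtered, dilated candidate regions.

    Fitted attributes: ``model_``, ``loss_trace_``, ``n_training_slices_``.
    """

    def __init__(self, config: CandidateConfig | None = None, random_state: int = 0):
        self.config = config or CandidateConfig()
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "random_state": self.random_state}

    def set_params(self, **params) -> "CandidateGenerator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- training ---------------------------------------------------------
    def _gather_slices(self, crops, nodes_per_crop):
        xs, ys = [], []
        for crop, nodes in zip(crops, nodes_per_crop):
            labels = make_sphere_labels(nodes, crop.grid, self.config.sphere_radius)
            pos = np.where(labels.any(axis=(1, 2)))[0]
            for z in pos:
                xs.append(
                    np.stack([crop.ct.values[z], crop.pet.values[z]]).astype(np.float32)
                )
                ys.append(labels[z].astype(np.float32))
        return xs, ys

    def fit(
        self,
        crops: Sequence[ThoraxCrop],
        nodes_per_crop: Sequence[Sequence[NodeAnnotation]],
    ) -> "CandidateGenerator":
        cfg = self.config
        xs, ys = self._gather_slices(crops, nodes_per_crop)
        if not xs:
            raise DataError("no slices with positive labels in the training set")
        rng = np.random.default_rng(self.random_state)
        model = UNet2D(
            in_channels=2,
            base_channels=cfg.base_channels,
            depth=cfg.depth,
            rng=rng,
        )
        opt = Adam(model.params(), lr=cfg.learning_rate)
        n = len(xs)
        trace = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = np.stack([xs[i] for i in idx])
                yb = np.stack([ys[i] for i in idx])[:, None]
                logits = model.forward(xb, train=True)
                loss, dlogits = dice_loss_and_grad(logits, yb)
                opt.zero_grad()
                model.backward(dlogits.astype(np.float32))
                opt.step()
                total += loss * len(idx)
            trace.append(total / n)
        self.model_ = model
        self.loss_trace_ = trace
        self.n_training_slices_ = n
        return self

    # -- inference --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise NotFittedError("CandidateGenerator is not trained")

    def predict_probability(self, crop: ThoraxCrop, batch_size: int = 16) -> np.ndarray:
        """Per-voxel foreground probability, every slice inferred."""
        self._check_fitted()
        vol = np.stack([crop.ct.values, crop.pet.values], axis=1).astype(np.float32)
        probs = np.empty(crop.shape, dtype=np.float32)
        for start in range(0, vol.shape[0], batch_size):
            logits = self.model_.forward(vol[start : start + batch_size], train=False)
            probs[start : start + batch_size] = sigmoid(logits)[:, 0]
        return probs

    def predict_mask(self, crop: ThoraxCrop) -> np.ndarray:
        return self.predict_probability(crop) > self.config.mask_threshold

    def predict_raw_regions(self, crop: ThoraxCrop) -> list[CandidateRegion]:
        """26-connected components of the binarised stack, unfiltered."""
        return label_components(self.predict_mask(crop), patient_id=crop.patient_id)

    def predict(self, crop: ThoraxCrop) -> list[CandidateRegion]:
        """Filtered and dilated candidate regions for one crop."""
        regions = self.predict_raw_regions(crop)
        return filter_and_dilate(regions, crop.shape, self.config)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        self._check_fitted()
        np.savez_compressed(
            path,
            __meta_base_channels=self.config.base_channels,
            __meta_depth=self.config.depth,
            **state_dict(self.model_.params()),
        )

    def load(self, path) -> "CandidateGenerator":
        data = dict(np.load(path))
        base = int(data.pop("__meta_base_channels"))
        depth = int(data.pop("__meta_depth"))
        model = UNet2D(in_channels=2, base_channels=base, depth=depth)
        load_state_dict(model.params(), data)
        self.model_ = model
        return self

    def state_hash(self) -> str:
        self._check_fitted()
        return state_hash(self.model_.params())
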