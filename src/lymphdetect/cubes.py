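"""Phase two: overlapping-cube classification and score aggregation.

Candidate regions are covered by 64 mm cubes centred on a regular 8 mm
lattice anchored at the crop origin; a cube is enumerated when its centre
voxel lies inside a candidate region.  Cubes whose centre is within 16 mm
(inclusive) of a node are positive.  Negatives are randomly undersampled by
a factor of eight before training.  A 3D residual network assigns each cube
a pathological probability; because the cubes overlap, each voxel receives
several predictions, which are summed, and voxels whose summed score
strictly exceeds the aggregation threshold (default 18) form the predicted
node regions.

Training uses on-the-fly augmentation by the 48 right-angle symmetries of
the cube (random axis permutations and flips), which need no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DataError, NotFittedError
from .nn import (
    Adam,
    ResNet3D,
    ResNetSpec,
    bn_state,
    load_bn_state,
    load_state_dict,
    softmax_cross_entropy_and_grad,
    state_dict,
    state_hash,
)
from .preprocess import ThoraxCrop
from .regions import CandidateRegion, label_components, regions_to_mask
from .volume import NodeAnnotation, Volume3D

__all__ = [
    "CubeConfig",
    "CubeSample",
    "ScoreMap",
    "enumerate_cubes",
    "label_cubes",
    "undersample_negatives",
    "extract_cube",
    "aggregate_scores",
    "positive_regions",
    "CubeClassifier",
]


@dataclass(frozen=True)
class CubeConfig:
    cube_side: float = 64.0  # mm
    grid_stride: float = 8.0  # mm
    positive_radius: float = 16.0  # mm, inclusive
    undersample_factor: int = 8
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-5
    finetune_learning_rate: float = 1e-8
    agg_threshold: float = 18.0  # summed score, strictly-greater rule
    augment: bool = True
    resnet: ResNetSpec = field(default_factory=ResNetSpec)

    def __post_init__(self) -> None:
        if self.cube_side % self.grid_stride:
            raise ValueError("cube_side must be divisible by grid_stride")
        if not self.positive_radius < self.cube_side / 2:
            raise ValueError("positive_radius must be below cube_side/2")
        if self.undersample_factor < 1:
            raise ValueError("undersample_factor must be >= 1")


@dataclass
class CubeSample:
    """A two-channel cubic patch with its physical centre and label."""

    centre: tuple[float, float, float]  # (x, y, z) mm
    patch: np.ndarray  # (2, side, side, side): CT then PET, standardised
    label: int | None = None  # 1 positive, 0 negative, None unlabeled
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.patch.ndim != 4 or self.patch.shape[0] != 2:
            raise ValueError(f"patch must be (2, s, s, s), got {self.patch.shape}")


@dataclass
class ScoreMap:
    """Per-voxel summed cube predictions aligned to a thorax crop."""

    summed_score: np.ndarray
    coverage: np.ndarray
    grid: Volume3D

    def __post_init__(self) -> None:
        if self.summed_score.shape != self.coverage.shape:
            raise ValueError("score and coverage grids must share a shape")


# ---------------------------------------------------------------------------
# Cube enumeration / labelling / sampling
# ---------------------------------------------------------------------------

def _stride_voxels(grid: Volume3D, cfg: CubeConfig) -> int:
    sp = grid.spacing
    if not np.allclose(sp, sp[0]):
        raise ValueError("cube grid requires an isotropic crop")
    step = cfg.grid_stride / sp[0]
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError("grid_stride must be a voxel multiple of the crop spacing")
    return int(round(step))


def _side_voxels(grid: Volume3D, cfg: CubeConfig) -> int:
    return int(round(cfg.cube_side / grid.spacing[0]))


def enumerate_cubes(
    regions: Sequence[CandidateRegion],
    grid: Volume3D,
    cfg: CubeConfig | None = None,
) -> np.ndarray:
    """Physical (x, y, z) mm centres of the lattice points inside any region.

    The lattice is anchored at voxel (0, 0, 0) of the crop with 8 mm pitch;
    each qualifying point is listed once even where regions overlap.
    """
    cfg = cfg or CubeConfig()
    if not regions:
        return np.empty((0, 3))
    step = _stride_voxels(grid, cfg)
    mask = regions_to_mask(regions, grid.shape)
    lattice = mask[::step, ::step, ::step]
    idx = np.argwhere(lattice) * step  # (z, y, x) voxel indices
    if idx.size == 0:
        return np.empty((0, 3))
    return np.atleast_2d(grid.index_to_physical(idx))


def label_cubes(
    centres: np.ndarray,
    nodes: Sequence[NodeAnnotation],
    cfg: CubeConfig | None = None,
) -> np.ndarray:
    """1 where a node lies within ``positive_radius`` mm (inclusive) of the centre."""
    cfg = cfg or CubeConfig()
    centres = np.atleast_2d(np.asarray(centres, dtype=float))
    labels = np.zeros(len(centres), dtype=int)
    if len(nodes) == 0 or len(centres) == 0:
        return labels
    node_xyz = np.array([n.centre for n in nodes])
    d = np.linalg.norm(centres[:, None, :] - node_xyz[None, :, :], axis=2)
    labels[(d <= cfg.positive_radius).any(axis=1)] = 1
    return labels


def undersample_negatives(
    labels: np.ndarray,
    factor: int = 8,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Indices keeping every positive and round(n_neg/factor) random negatives.

    Drawn once, without replacement, reproducibly from ``rng``.
    """
    if factor < 1:
        raise ValueError("undersample factor must be >= 1")
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels != 1)[0]
    n_keep = int(np.floor(len(neg) / factor + 0.5))
    kept_neg = rng.choice(neg, size=n_keep, replace=False) if n_keep else np.empty(0, int)
    return np.sort(np.concatenate([pos, kept_neg]).astype(int))


def extract_cube(
    crop: ThoraxCrop,
    centre: np.ndarray,
    cfg: CubeConfig | None = None,
    fill: tuple[float, float] = (0.0, 0.0),
    label: int | None = None,
) -> CubeSample:
    """Cut the two-channel cube around a lattice centre, padding voxels that
    fall outside the crop with the (standardised) air / zero-uptake values.
    """
    cfg = cfg or CubeConfig()
    grid = crop.grid
    side = _side_voxels(grid, cfg)
    half = side // 2
    c = grid.physical_to_nearest_index(np.asarray(centre, dtype=float))
    shape = np.asarray(grid.shape)
    if np.any(c < 0) or np.any(c >= shape):
        raise ValueError(f"cube centre {centre} outside the crop")
    patch = np.empty((2, side, side, side), dtype=np.float32)
    patch[0] = fill[0]
    patch[1] = fill[1]
    lo = c - half
    hi = lo + side
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    patch[(0,) + dst] = crop.ct.values[src]
    patch[(1,) + dst] = crop.pet.values[src]
    return CubeSample(
        centre=tuple(float(v) for v in np.asarray(centre, dtype=float)),
        patch=patch,
        label=label,
        patient_id=crop.patient_id,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_scores(
    centres: np.ndarray,
    probabilities: np.ndarray,
    grid: Volume3D,
    cfg: CubeConfig | None = None,
) -> ScoreMap:
    """Sum each cube's probability over every voxel its 64 mm extent covers."""
    cfg = cfg or CubeConfig()
    centres = np.atleast_2d(np.asarray(centres, dtype=float))
    probabilities = np.asarray(probabilities, dtype=float)
    if len(centres) != len(probabilities):
        raise ValueError(
            f"{len(centres)} centres but {len(probabilities)} probabilities"
        )
    side = _side_voxels(grid, cfg)
    half = side // 2
    shape = np.asarray(grid.shape)
    score = np.zeros(grid.shape, dtype=np.float64)
    cover = np.zeros(grid.shape, dtype=np.int32)
    for centre, p in zip(centres, probabilities):
        c = grid.physical_to_nearest_index(centre)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c - half + side, shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        score[sl] += p
        cover[sl] += 1
    return ScoreMap(summed_score=score, coverage=cover, grid=grid)


def positive_regions(
    scoremap: ScoreMap,
    cfg: CubeConfig | None = None,
    threshold: float | None = None,
    patient_id: str = "",
) -> list[CandidateRegion]:
    """26-connected components of voxels whose summed score strictly exceeds
    the aggregation threshold."""
    cfg = cfg or CubeConfig()
    thr = cfg.agg_threshold if threshold is None else threshold
    return label_components(scoremap.summed_score > thr, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

def _octahedral_transform(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random element of the cube's 48-symmetry group (axis permutation +
    per-axis flips) applied to a channels-first patch."""
    perm = rng.permutation(3)
    out = patch.transpose((0,) + tuple(1 + perm))
    for ax in range(3):
        if rng.random() < 0.5:
            out = np.flip(out, axis=1 + ax)
    return np.ascontiguousarray(out)


class CubeClassifier:
    """sklearn-style estimator wrapping the phase-two 3D residual network.

    ``fit(X, y)`` trains from scratch; ``fine_tune(X, y)`` continues
    training the fitted network at the (much smaller) transfer-learning
    learning rate.  ``predict_proba`` applies no augmentation.

    Fitted attributes: ``model_``, ``loss_trace_``, ``finetune_trace_``.
    """

    def __init__(self, config: CubeConfig | None = None, random_state: int = 0):
        self.config = config or CubeConfig()
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "random_state": self.random_state}

    def set_params(self, **params) -> "CubeClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _item(X, i: int) -> np.ndarray:
        """Materialise sample ``i``; X may be any indexable (including a
        lazily-extracting sequence), so memory stays bounded by the batch."""
        x = X[i]
        return x.patch if isinstance(x, CubeSample) else np.asarray(x)

    def _run_epochs(self, xs, y, lr, epochs, rng, trace):
        if lr == 0 or epochs == 0:
            return  # zero-update training is a no-op by definition
        cfg = self.config
        n = len(xs)
        opt = Adam(self.model_.params(), lr=lr)
        for _epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if cfg.augment:
                    xb = np.stack(
                        [_octahedral_transform(self._item(xs, i), rng) for i in idx]
                    )
                else:
                    xb = np.stack([self._item(xs, i) for i in idx])
                yb = y[idx]
                logits = self.model_.forward(xb.astype(np.float32), train=True)
                loss, dlogits = softmax_cross_entropy_and_grad(logits, yb)
                opt.zero_grad()
                self.model_.backward(dlogits.astype(np.float32))
                opt.step()
                total += loss * len(idx)
            trace.append(total / n)

    def fit(self, X, y) -> "CubeClassifier":
        cfg = self.config
        xs = X
        y = np.asarray(y, dtype=int)
        if len(xs) != len(y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(y)) < 2:
            raise DataError("training requires at least one positive and one negative cube")
        rng = np.random.default_rng(self.random_state)
        self.model_ = ResNet3D(in_channels=2, spec=cfg.resnet, rng=rng)
        self.loss_trace_: list[float] = []
        self.finetune_trace_: list[float] = []
        self._run_epochs(xs, y, cfg.learning_rate, cfg.epochs, rng, self.loss_trace_)
        return self

    def fine_tune(
        self,
        X,
        y,
        learning_rate: float | None = None,
        epochs: int | None = None,
        random_state: int | None = None,
    ) -> "CubeClassifier":
        self._check_fitted()
        cfg = self.config
        xs = X
        y = np.asarray(y, dtype=int)
        lr = cfg.finetune_learning_rate if learning_rate is None else learning_rate
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(seed)
        self._run_epochs(
            xs, y, lr, cfg.epochs if epochs is None else epochs, rng, self.finetune_trace_
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise NotFittedError("CubeClassifier is not trained")

    def predict_proba(self, X, batch_size: int | None = None) -> np.ndarray:
        """Pathological probability per cube, deterministic (no augmentation)."""
        self._check_fitted()
        xs = X
        if len(xs) == 0:
            return np.empty(0)
        bs = batch_size or self.config.batch_size
        out = np.empty(len(xs))
        for start in range(0, len(xs), bs):
            xb = np.stack(
                [self._item(xs, i) for i in range(start, min(start + bs, len(xs)))]
            ).astype(np.float32)
            logits = self.model_.forward(xb, train=False)
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out[start : start + len(xb)] = (ez / ez.sum(axis=1, keepdims=True))[:, 1]
        return out

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    # -- persistence ------------------------------------------------------
    def snapshot(self) -> dict[str, np.ndarray]:
        """Full model state: parameters plus normalisation running buffers."""
        self._check_fitted()
        state = state_dict(self.model_.params())
        state.update({f"__buf_{k}": v for k, v in bn_state(self.model_.all_layers()).items()})
        return state

    def restore(self, state: dict[str, np.ndarray]) -> "CubeClassifier":
        params = {k: v for k, v in state.items() if not k.startswith("__buf_")}
        bufs = {k[len("__buf_"):]: v for k, v in state.items() if k.startswith("__buf_")}
        if not hasattr(self, "model_"):
            self.model_ = ResNet3D(in_channels=2, spec=self.config.resnet)
        load_state_dict(self.model_.params(), params)
        if bufs:
            load_bn_state(self.model_.all_layers(), bufs)
        if not hasattr(self, "loss_trace_"):
            self.loss_trace_ = []
            self.finetune_trace_ = []
        return self

    def save(self, path) -> None:
        np.savez_compressed(path, **self.snapshot())

    def load(self, path) -> "CubeClassifier":
        return self.restore(dict(np.load(path)))

    def state_hash(self) -> str:
        self._check_fitted()
        return state_hash(self.model_.params())
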