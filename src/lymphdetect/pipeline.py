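"""End-to-end detection pipeline.

``NodeDetectionPipeline`` is a meta-estimator chaining every stage:
thorax preprocessing -> dataset-level standardisation -> U-Net candidate
generation -> overlapping-cube 3D CNN classification -> score aggregation
-> thresholded predicted regions.  ``fit`` trains both networks on a cohort
of scans with ground-truth nodes; ``predict`` maps a scan to predicted node
regions; ``evaluate`` produces the node-level statistics; ``fine_tune``
adapts only the cube classifier to a second scanner's data (the candidate
U-Net stays frozen); ``tune_threshold`` re-tunes the aggregation threshold
on a validation cohort by minimising FP + FN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .candidates import CandidateConfig, CandidateGenerator, candidate_sensitivity
from .cubes import (
    CubeClassifier,
    CubeConfig,
    aggregate_scores,
    enumerate_cubes,
    extract_cube,
    label_cubes,
    positive_regions,
    undersample_negatives,
)
from .errors import NotFittedError
from .metrics import EvalSummary, PatientDetections, evaluate_cohort, match_detections
from .nn import ResNetSpec
from .preprocess import (
    IntensityStandardizer,
    PreprocessConfig,
    ThoraxCrop,
    preprocess_scan,
)
from .regions import CandidateRegion
from .cubes import ScoreMap
from .volume import PatientScan

__all__ = ["NodeDetectionPipeline", "tune_threshold_sweep"]


@dataclass
class PatientPrediction:
    patient_id: str
    regions: list[CandidateRegion]
    scoremap: ScoreMap
    crop: ThoraxCrop


def tune_threshold_sweep(
    scored: Sequence[tuple[ScoreMap, Sequence]],
    sweep: Sequence[int],
    cube_config: CubeConfig | None = None,
) -> tuple[int, dict[int, int]]:
    """Argmin of FP + FN over an integer threshold sweep.

    ``scored`` pairs each validation patient's score map with its nodes.
    Ties break toward the larger threshold (fewer false positives).
    Returns the chosen threshold and the full objective per threshold.
    """
    sweep = list(sweep)
    if not sweep:
        raise ValueError("empty threshold sweep")
    cfg = cube_config or CubeConfig()
    objective: dict[int, int] = {}
    for thr in sweep:
        total = 0
        for scoremap, nodes in scored:
            regions = positive_regions(scoremap, cfg, threshold=thr)
            det = PatientDetections(
                patient_id="", regions=regions, nodes=list(nodes), grid=scoremap.grid
            )
            counts, _ = match_detections([det])
            total += counts.fp + counts.fn
        objective[thr] = total
    best = sweep[0]
    for thr in sweep:
        if objective[thr] <= objective[best]:
            best = thr if objective[thr] < objective[best] or thr > best else best
    return int(best), objective


class _LazyPatches:
    """Indexable cube-patch sequence extracting from cached crops on access."""

    def __init__(self, pipe: "NodeDetectionPipeline", scans, entries):
        self._pipe = pipe
        self._scans = scans
        self._entries = entries  # (scan index, centre)

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, i: int) -> np.ndarray:
        si, centre = self._entries[i]
        crop = self._pipe.prepare(self._scans[si])
        fill = self._pipe.standardizer_.stats_.fill_values()
        return extract_cube(crop, centre, self._pipe.cube_config, fill=fill).patch


class NodeDetectionPipeline:
    """Two-phase mediastinal node detector with sklearn-style fit/predict.

    Fitted attributes: ``standardizer_``, ``candidate_generator_``,
    ``cube_classifier_``, ``threshold_``.
    """

    def __init__(
        self,
        preprocess_config: PreprocessConfig | None = None,
        candidate_config: CandidateConfig | None = None,
        cube_config: CubeConfig | None = None,
        random_state: int = 0,
    ):
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.candidate_config = candidate_config or CandidateConfig()
        self.cube_config = cube_config or CubeConfig()
        self.random_state = random_state

    @classmethod
    def scaled_down(cls, random_state: int = 0, epochs: int = 4) -> "NodeDetectionPipeline":
        """A configuration for CPU-scale phantom experiments.

        Networks are shrunk and learning rates raised so a handful of epochs
        on a small cohort converges; pipeline semantics are unchanged.  The
        fine-tuning rate keeps the full-scale 1000x reduction relative to
        base training.
        """
        cand = CandidateConfig(
            epochs=epochs, learning_rate=1e-3, base_channels=4, depth=3, batch_size=8
        )
        cube = CubeConfig(
            epochs=epochs,
            batch_size=16,
            learning_rate=3e-3,
            finetune_learning_rate=3e-6,
            resnet=ResNetSpec.tiny(),
        )
        return cls(
            candidate_config=cand, cube_config=cube, random_state=random_state
        )

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "preprocess_config": self.preprocess_config,
            "candidate_config": self.candidate_config,
            "cube_config": self.cube_config,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "NodeDetectionPipeline":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- shared plumbing --------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "cube_classifier_"):
            raise NotFittedError("pipeline is not fitted")

    def prepare(self, scan: PatientScan, standardize: bool = True) -> ThoraxCrop:
        """Preprocess (and optionally standardise) one scan, with caching."""
        cache = getattr(self, "_crop_cache", None)
        if cache is None:
            cache = self._crop_cache = {}
        key = (scan.patient_id, standardize)
        if key not in cache:
            crop = preprocess_scan(scan, self.preprocess_config)
            if standardize:
                if not hasattr(self, "standardizer_"):
                    raise NotFittedError("standardizer not fitted")
                crop = self.standardizer_.transform(crop)
            cache[key] = crop
        return cache[key]

    def candidate_regions(self, scan: PatientScan):
        """Filtered, dilated phase-one regions for one scan (cached)."""
        cache = getattr(self, "_region_cache", None)
        if cache is None:
            cache = self._region_cache = {}
        if scan.patient_id not in cache:
            crop = self.prepare(scan)
            cache[scan.patient_id] = self.candidate_generator_.predict(crop)
        return cache[scan.patient_id]

    def _enumerate_cohort(self, scans: Sequence[PatientScan]):
        """(scan index, centre, label) for every cube over candidate regions."""
        entries = []
        for si, scan in enumerate(scans):
            crop = self.prepare(scan)
            regions = self.candidate_regions(scan)
            centres = enumerate_cubes(regions, crop.grid, self.cube_config)
            if len(centres) == 0:
                continue
            lab = label_cubes(centres, scan.nodes, self.cube_config)
            entries.extend((si, c, int(l)) for c, l in zip(centres, lab))
        return entries

    def _cube_dataset(self, scans: Sequence[PatientScan], rng: np.random.Generator):
        """Candidate regions -> labelled, undersampled cubes for a cohort.

        Negatives are undersampled once (before training, as a single draw);
        patches are extracted lazily so memory stays bounded by the training
        batch, not the cube count.
        """
        entries = self._enumerate_cohort(scans)
        labels = np.array([e[2] for e in entries], dtype=int)
        keep = undersample_negatives(
            labels, factor=self.cube_config.undersample_factor, rng=rng
        )
        patches = _LazyPatches(self, scans, [entries[i][:2] for i in keep])
        return patches, labels[keep]

    # -- training ---------------------------------------------------------
    def fit(self, scans: Sequence[PatientScan]) -> "NodeDetectionPipeline":
        self._crop_cache = {}
        raw_crops = [preprocess_scan(s, self.preprocess_config) for s in scans]
        self.standardizer_ = IntensityStandardizer().fit(raw_crops)
        crops = self.standardizer_.transform(raw_crops)
        for scan, crop in zip(scans, crops):
            self._crop_cache[(scan.patient_id, True)] = crop
        self.candidate_generator_ = CandidateGenerator(
            self.candidate_config, random_state=self.random_state
        ).fit(crops, [s.nodes for s in scans])
        self._region_cache = {}
        patches, labels = self._cube_dataset(
            scans, rng=np.random.default_rng(self.random_state)
        )
        self.cube_classifier_ = CubeClassifier(
            self.cube_config, random_state=self.random_state
        ).fit(patches, labels)
        self.threshold_ = self.cube_config.agg_threshold
        return self

    def fine_tune(
        self,
        scans: Sequence[PatientScan],
        learning_rate: float | None = None,
        epochs: int | None = None,
        random_state: int | None = None,
    ) -> "NodeDetectionPipeline":
        """Adapt the cube classifier to a new scanner's training scans.

        Candidate cubes come from the frozen phase-one U-Net; only the
        phase-two classifier is updated, with the same training loop at the
        (much smaller) transfer-learning rate.  Standardisation statistics
        remain those of the original training set.
        """
        self._check_fitted()
        unet_hash_before = self.candidate_generator_.state_hash()
        patches, labels = self._cube_dataset(
            scans,
            rng=np.random.default_rng(
                self.random_state if random_state is None else random_state
            ),
        )
        self.cube_classifier_.fine_tune(
            patches,
            labels,
            learning_rate=learning_rate,
            epochs=epochs,
            random_state=random_state,
        )
        assert self.candidate_generator_.state_hash() == unet_hash_before
        return self

    # -- inference --------------------------------------------------------
    def score_cubes(self, scan: PatientScan) -> tuple[np.ndarray, np.ndarray]:
        """Cube centres and their pathological probabilities for one scan.

        Extraction and classification stream in small batches so memory
        stays bounded regardless of the candidate-region size.
        """
        self._check_fitted()
        crop = self.prepare(scan)
        regions = self.candidate_regions(scan)
        centres = enumerate_cubes(regions, crop.grid, self.cube_config)
        fill = self.standardizer_.stats_.fill_values()
        probs = np.empty(len(centres))
        chunk = max(self.cube_config.batch_size, 16)
        for start in range(0, len(centres), chunk):
            batch = [
                extract_cube(crop, c, self.cube_config, fill=fill).patch
                for c in centres[start : start + chunk]
            ]
            probs[start : start + len(batch)] = self.cube_classifier_.predict_proba(batch)
        return centres, probs

    def predict_patient(self, scan: PatientScan) -> PatientPrediction:
        self._check_fitted()
        crop = self.prepare(scan)
        centres, probs = self.score_cubes(scan)
        scoremap = aggregate_scores(centres, probs, crop.grid, self.cube_config)
        predicted = positive_regions(
            scoremap, self.cube_config, threshold=self.threshold_,
            patient_id=scan.patient_id,
        )
        return PatientPrediction(
            patient_id=scan.patient_id, regions=predicted, scoremap=scoremap, crop=crop
        )

    def predict(self, scans: Sequence[PatientScan]) -> list[PatientPrediction]:
        return [self.predict_patient(s) for s in scans]

    def phase_one_sensitivity(self, scans: Sequence[PatientScan]) -> float:
        """Fraction of nodes covered by (post-dilation) candidate regions."""
        self._check_fitted()
        covered = total = 0
        for scan in scans:
            crop = self.prepare(scan)
            regions = self.candidate_regions(scan)
            if scan.nodes:
                frac = candidate_sensitivity(regions, scan.nodes, crop.grid)
                covered += frac * len(scan.nodes)
                total += len(scan.nodes)
        return covered / total if total else float("nan")

    def evaluate(self, scans: Sequence[PatientScan]) -> EvalSummary:
        preds = self.predict(scans)
        records = [
            PatientDetections(
                patient_id=p.patient_id,
                regions=p.regions,
                nodes=list(s.nodes),
                grid=p.crop.grid,
            )
            for p, s in zip(preds, scans)
        ]
        return evaluate_cohort(records)

    def tune_threshold(
        self, scans: Sequence[PatientScan], sweep: Sequence[int] | None = None
    ) -> int:
        """Minimise FP + FN over an integer threshold sweep on a validation
        cohort; sets and returns ``threshold_`` (ties -> larger threshold)."""
        self._check_fitted()
        sweep = list(sweep) if sweep is not None else list(range(1, 41))
        scored = []
        for scan in scans:
            pred = self.predict_patient(scan)
            scored.append((pred.scoremap, scan.nodes))
        best, _ = tune_threshold_sweep(scored, sweep, self.cube_config)
        self.threshold_ = best
        return best
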