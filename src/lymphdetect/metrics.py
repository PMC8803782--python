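"""Node-level performance assessment.

A predicted region containing at least one node centre is a true positive
counted per detected node (so TP + FN equals the number of ground-truth
nodes and sensitivity is node-based); a region containing no node centre is
a false positive counted per region (so FPs/patient is region-based).
Specificity is not defined for this task — there is no agreed number of
negative nodes per patient — so agreement with a second reader is instead
summarised by Cohen's kappa on a 2x2 table whose true-negative cell uses
the convention TN = 8.3 x n_patients - (TP + FP + FN), 8.3 being the
average nodes-per-patient of the comparison study this convention follows;
TN may be fractional and is used as-is.  Exact Clopper-Pearson intervals
accompany each rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .errors import AmbiguityError, ConsistencyError
from .regions import CandidateRegion, regions_to_mask
from .volume import NodeAnnotation, Volume3D

__all__ = [
    "NODES_PER_PATIENT_CONVENTION",
    "DetectionCounts",
    "PatientDetections",
    "EvalSummary",
    "round_half_up",
    "match_detections",
    "sensitivity",
    "fps_per_patient",
    "cohen_kappa",
    "landis_koch_band",
    "clopper_pearson",
    "recover_count",
    "evaluate_cohort",
]

#: Average pathological-plus-benign nodes per patient assumed when deriving
#: the true-negative cell of the agreement table.
NODES_PER_PATIENT_CONVENTION = 8.3


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (as printed tables round)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class DetectionCounts:
    tp: int
    fp: int
    fn: int
    n_patients: int
    nodes_per_patient_convention: float = NODES_PER_PATIENT_CONVENTION

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0 or self.n_patients < 1:
            raise ValueError("counts must be non-negative with >= 1 patient")

    @property
    def n_nodes(self) -> int:
        return self.tp + self.fn

    @property
    def tn(self) -> float:
        """Derived (possibly fractional) true negatives; used as-is."""
        return self.nodes_per_patient_convention * self.n_patients - (
            self.tp + self.fp + self.fn
        )


@dataclass
class PatientDetections:
    """One patient's predicted regions and ground-truth nodes in the crop frame."""

    patient_id: str
    regions: list[CandidateRegion]
    nodes: list[NodeAnnotation]
    grid: Volume3D


def match_detections(
    patients: Sequence[PatientDetections],
) -> tuple[DetectionCounts, dict]:
    """Apply the TP/FP/FN rules per patient and pool the counts.

    Also returns a detail dict with a per-patient table and predicted-region
    size statistics (mean/max equivalent diameter, mm) — the reportable form
    of the visual check that regions are small enough to localise nodes.
    """
    tp = fp = fn = 0
    per_patient = []
    diameters: list[float] = []
    for item in patients:
        for r in item.regions:
            if r.patient_id and item.patient_id and r.patient_id != item.patient_id:
                raise ConsistencyError(
                    f"region for patient {r.patient_id!r} in record {item.patient_id!r}"
                )
        shape = item.grid.shape
        node_hits = np.zeros(len(item.nodes), dtype=bool)
        region_hit = np.zeros(len(item.regions), dtype=bool)
        node_idx = [
            item.grid.physical_to_nearest_index(np.asarray(n.centre)) for n in item.nodes
        ]
        for ri, region in enumerate(item.regions):
            mask = region.to_mask(shape)
            for ni, idx in enumerate(node_idx):
                inside = np.all(idx >= 0) and np.all(idx < np.asarray(shape))
                if inside and mask[tuple(idx)]:
                    node_hits[ni] = True
                    region_hit[ri] = True
            diameters.append(region.equivalent_diameter_mm(item.grid.spacing))
        p_tp = int(node_hits.sum())
        p_fn = int((~node_hits).sum())
        p_fp = int((~region_hit).sum())
        tp, fn, fp = tp + p_tp, fn + p_fn, fp + p_fp
        per_patient.append(
            {
                "patient_id": item.patient_id,
                "tp": p_tp,
                "fp": p_fp,
                "fn": p_fn,
                "n_regions": len(item.regions),
            }
        )
    counts = DetectionCounts(tp=tp, fp=fp, fn=fn, n_patients=max(len(patients), 1))
    detail = {
        "per_patient": per_patient,
        "region_diameter_mean_mm": float(np.mean(diameters)) if diameters else 0.0,
        "region_diameter_max_mm": float(np.max(diameters)) if diameters else 0.0,
    }
    return counts, detail


def sensitivity(counts: DetectionCounts) -> float:
    if counts.tp + counts.fn == 0:
        warnings.warn("sensitivity undefined: no ground-truth nodes", stacklevel=2)
        return float("nan")
    return counts.tp / (counts.tp + counts.fn)


def fps_per_patient(counts: DetectionCounts) -> float:
    return counts.fp / counts.n_patients


def landis_koch_band(kappa: float) -> str:
    """Qualitative agreement benchmark for a kappa value."""
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohen_kappa(counts: DetectionCounts) -> tuple[float, str]:
    """Two-rater kappa on the 2x2 table (TP, FP / FN, TN) with the derived,
    possibly fractional TN.  Returns (kappa, Landis-Koch band)."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tn < 0:
        raise ValueError(
            f"derived TN is negative ({tn:.1f}); the {counts.nodes_per_patient_convention}"
            " nodes/patient convention cannot apply"
        )
    n = tp + fp + fn + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    if np.isclose(p_e, 1.0):
        warnings.warn("kappa degenerate: chance agreement is 1", stacklevel=2)
        return float("nan"), "undefined"
    kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), landis_koch_band(kappa)


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta-quantile inversion."""
    x, n = int(successes), int(trials)
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def recover_count(printed_rate: float, denominator: int, decimals: int = 2) -> int:
    """Invert a rounded printed rate to the unique integer numerator.

    Raises :class:`AmbiguityError` when zero or several integers round to the
    printed value — ambiguity is surfaced, never resolved silently.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    k_max = int(np.ceil((printed_rate + 10.0**-decimals) * denominator)) + 1
    matches = [
        k
        for k in range(0, k_max + 1)
        if round_half_up(k / denominator, decimals) == round_half_up(printed_rate, decimals)
    ]
    if len(matches) != 1:
        raise AmbiguityError(
            f"rate {printed_rate} over {denominator} has {len(matches)} integer "
            f"solutions: {matches}"
        )
    return matches[0]


@dataclass
class EvalSummary:
    """Machine-readable cohort evaluation."""

    counts: DetectionCounts
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    fps_per_patient: float
    fps_per_patient_ci: tuple[float, float]
    kappa: float
    kappa_band: str
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"]["tn"] = self.counts.tn
        d["fps_ci_note"] = (
            "FPs/patient CI is convention-dependent: exact Clopper-Pearson on "
            "(FP, round(8.3 x patients)) trials"
        )
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def to_text(self) -> str:
        c = self.counts
        lines = [
            f"patients: {c.n_patients}  nodes: {c.n_nodes}",
            f"TP {c.tp}  FP {c.fp}  FN {c.fn}  TN(derived) {c.tn:.1f}",
            f"sensitivity: {self.sensitivity:.2f} "
            f"[{self.sensitivity_ci[0]:.2f}, {self.sensitivity_ci[1]:.2f}]",
            f"FPs/patient: {self.fps_per_patient:.2f} "
            f"[{self.fps_per_patient_ci[0]:.2f}, {self.fps_per_patient_ci[1]:.2f}]"
            " (CI convention-dependent)",
            f"kappa: {self.kappa:.2f} ({self.kappa_band})",
        ]
        if "region_diameter_mean_mm" in self.detail:
            lines.append(
                "predicted region equivalent diameter: "
                f"mean {self.detail['region_diameter_mean_mm']:.1f} mm, "
                f"max {self.detail['region_diameter_max_mm']:.1f} mm"
            )
        return "\n".join(lines)


def evaluate_cohort(
    patients: Sequence[PatientDetections] | DetectionCounts,
    detail: dict | None = None,
) -> EvalSummary:
    """Assemble counts, rates, exact CIs, and the agreement statistic."""
    if isinstance(patients, DetectionCounts):
        counts = patients
        detail = detail or {}
    else:
        counts, detail = match_detections(patients)
    sens = sensitivity(counts)
    if counts.n_nodes > 0:
        sens_ci = clopper_pearson(counts.tp, counts.n_nodes)
    else:
        sens_ci = (float("nan"), float("nan"))
    fpp = fps_per_patient(counts)
    fp_trials = int(round(counts.nodes_per_patient_convention * counts.n_patients))
    fp_ci_counts = clopper_pearson(min(counts.fp, fp_trials), fp_trials)
    fpp_ci = (
        fp_ci_counts[0] * fp_trials / counts.n_patients,
        fp_ci_counts[1] * fp_trials / counts.n_patients,
    )
    kappa, band = cohen_kappa(counts)
    return EvalSummary(
        counts=counts,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        fps_per_patient=fpp,
        fps_per_patient_ci=fpp_ci,
        kappa=kappa,
        kappa_band=band,
        detail=detail,
    )
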