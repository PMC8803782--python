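"""Shared fixtures.

The expensive fixtures (trained pipeline, transfer-learning run) are
session-scoped so the cascade is trained once and shared between the
pipeline tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from lymphdetect.phantom import (
    SCANNER1,
    SCANNER2,
    PhantomParams,
    generate_cohort,
    generate_phantom,
)
from lymphdetect.pipeline import NodeDetectionPipeline

#: Fixed node counts for held-out phantom cohorts, scaled down from the
#: patients-by-node-count spread of the corresponding clinical test sets.
#: Evaluation cohorts use fixed counts so sensitivity always has support.
TEST_COUNTS_SCANNER1 = [0, 0, 1, 2, 4, 5]  # 12 nodes over 6 patients
TEST_COUNTS_SCANNER2 = [0, 0, 0, 1, 3, 5]  # 9 nodes over 6 patients
TUNE_COUNTS_SCANNER2 = [0, 1, 1, 2, 2, 4]  # 10 nodes over 6 patients


def fixed_count_cohort(counts, profile, seed, prefix):
    """Phantoms with per-patient forced node counts, seeded per patient."""
    root = np.random.SeedSequence(seed)
    scans = []
    for i, (n, child) in enumerate(zip(counts, root.spawn(len(counts)))):
        params = PhantomParams(seed=seed, n_nodes=int(n))
        rng = np.random.default_rng(child)
        scans.append(generate_phantom(params, profile, f"{prefix}-p{i:03d}", rng=rng))
    return scans


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom with a known number of nodes."""
    params = PhantomParams(seed=3, n_nodes=3)
    scan, masks = generate_phantom(params, SCANNER1, "p-small", with_masks=True)
    return scan, masks, params


@pytest.fixture(scope="session")
def e2e_run():
    """Scaled-down end-to-end study: 12 training + 6 test phantoms.

    Trains the full cascade with shrunken networks (3 epochs), tunes the
    aggregation threshold on a validation subset of the training cohort,
    and evaluates on the held-out phantoms.
    """
    cohort = generate_cohort(12, PhantomParams(seed=42), SCANNER1, seed=42)
    train = cohort.scans
    test = fixed_count_cohort(TEST_COUNTS_SCANNER1, SCANNER1, seed=1042, prefix="s1test")
    pipe = NodeDetectionPipeline.scaled_down(random_state=0, epochs=2)
    pipe.fit(train)

    # training-set Dice overlap of the phase-one segmentation
    from lymphdetect.candidates import make_sphere_labels

    inter = pred_sum = lab_sum = 0.0
    for scan in train:
        if not scan.nodes:
            continue
        crop = pipe.prepare(scan)
        labels = make_sphere_labels(scan.nodes, crop.grid)
        pred = pipe.candidate_generator_.predict_mask(crop)
        zs = np.where(labels.any(axis=(1, 2)))[0]
        inter += float((pred[zs] & labels[zs]).sum())
        pred_sum += float(pred[zs].sum())
        lab_sum += float(labels[zs].sum())
    train_dice = 2.0 * inter / (pred_sum + lab_sum)

    phase1_sens_test = pipe.phase_one_sensitivity(test)
    # validation patients for threshold tuning: the first three training
    # patients that contain nodes, so the sweep sees both FP and FN signal
    validation = [s for s in train if s.nodes][:3]
    validation_scored = []
    for scan in validation:
        pred = pipe.predict_patient(scan)
        validation_scored.append((pred.scoremap, scan.nodes))
    from lymphdetect.pipeline import tune_threshold_sweep

    threshold, _ = tune_threshold_sweep(
        validation_scored, range(1, 41), pipe.cube_config
    )
    pipe.threshold_ = threshold

    # score each held-out scan once; reuse for the cube-level AUC and the
    # node-level evaluation
    from sklearn.metrics import roc_auc_score

    from lymphdetect.cubes import aggregate_scores, label_cubes, positive_regions
    from lymphdetect.metrics import PatientDetections, evaluate_cohort

    probs_all, labels_all, records = [], [], []
    for scan in test:
        crop = pipe.prepare(scan)
        centres, probs = pipe.score_cubes(scan)
        if len(centres):
            probs_all.append(probs)
            labels_all.append(label_cubes(centres, scan.nodes, pipe.cube_config))
        scoremap = aggregate_scores(centres, probs, crop.grid, pipe.cube_config)
        regions = positive_regions(
            scoremap, pipe.cube_config, threshold=threshold, patient_id=scan.patient_id
        )
        records.append(
            PatientDetections(
                patient_id=scan.patient_id,
                regions=regions,
                nodes=list(scan.nodes),
                grid=crop.grid,
            )
        )
    probs_all = np.concatenate(probs_all)
    labels_all = np.concatenate(labels_all)
    cube_auc = (
        roc_auc_score(labels_all, probs_all) if len(np.unique(labels_all)) > 1 else np.nan
    )
    summary = evaluate_cohort(records)
    return {
        "pipe": pipe,
        "train": train,
        "test": test,
        "train_dice": train_dice,
        "phase1_sensitivity_test": phase1_sens_test,
        "threshold": threshold,
        "validation_scored": validation_scored,
        "cube_auc": cube_auc,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def tl_run(e2e_run):
    """Transfer-learning study: fine-tune the scanner-1 cascade on 6
    scanner-2 phantoms and re-evaluate on 6 held-out scanner-2 phantoms,
    averaged over 3 fine-tuning seeds.  The U-Net stays frozen."""
    pipe = e2e_run["pipe"]
    tune2 = fixed_count_cohort(TUNE_COUNTS_SCANNER2, SCANNER2, seed=77, prefix="s2tune")
    test2 = fixed_count_cohort(TEST_COUNTS_SCANNER2, SCANNER2, seed=1077, prefix="s2test")
    base_state = pipe.cube_classifier_.snapshot()
    unet_hash_before = pipe.candidate_generator_.state_hash()
    before = pipe.evaluate(test2)
    sens_after, fps_after = [], []
    for seed in (0, 1, 2):
        pipe.cube_classifier_.restore(base_state)
        pipe.fine_tune(tune2, epochs=3, random_state=seed)
        after = pipe.evaluate(test2)
        sens_after.append(after.sensitivity)
        fps_after.append(after.fps_per_patient)
    # leave the classifier in its pre-fine-tuning state for other tests
    pipe.cube_classifier_.restore(base_state)
    return {
        "before": before,
        "sens_after": sens_after,
        "fps_after": fps_after,
        "unet_hash_unchanged": pipe.candidate_generator_.state_hash() == unet_hash_before,
        "tune2": tune2,
        "test2": test2,
    }
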