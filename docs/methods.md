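# Methods

`lymphdetect` detects pathological mediastinal lymph nodes in co-registered
whole-body [18F]FDG-PET/CT, going from raw volumes to a list of predicted
node regions with no manual step. This note records the model, the choices
made where the design was genuinely open, and what the synthetic phantoms
do and do not demonstrate.

## Detection model

The detector is a two-stage cascade, a standard construction when positives
are rare relative to the search volume:

1. **Thorax localisation.** Both modalities are resampled to an isotropic
   1 mm grid (cubic B-spline; values beyond the grid extended with the
   nearest edge value). Air is thresholded on CT at −400 HU (the boundary
   value itself counts as air), cleaned by a 2-iteration binary closing and
   a 7-iteration binary opening with the face-connected (connectivity-one)
   3-D structuring element, components within 25 voxels of the x/y image
   border are discarded (air outside the patient; the z axis is exempt
   because a whole-body stack necessarily reaches the first and last slice
   with tissue), and the largest remaining 26-connected component — the
   lungs — defines the axial slice range kept. Slices are centre-cropped or
   air-padded (−1000 HU / 0 SUV) to 256 × 256. CT is clipped to
   [−1000, 1000] HU, PET to [0, 8] SUV, and both are standardised to zero
   mean and unit variance with statistics pooled over the *whole training
   set* (never refitted at test time). Dataset-level rather than
   per-patient standardisation preserves absolute intensity differences
   between patients, which carry diagnostic signal in SUV.

2. **Candidate generation (phase one).** Node annotations are points, not
   contours, so training labels are surrogate spheres of radius 15 mm
   centred on each node (nodes are rarely larger than 30 mm in diameter).
   A 2-D U-Net (two-channel 256 × 256 slices: CT and PET) is trained with a
   soft Dice loss and Adam at learning rate 1e−5 for 20 epochs, using only
   slices that contain at least one positive label voxel. At inference
   *every* slice is segmented; probability maps are binarised at 0.5,
   stacked into 3-D, 26-connected components below 300 voxels are removed,
   and survivors are dilated 3 iterations with the face-connected element
   (touching dilated regions merge). The stage is tuned for sensitivity;
   precision is phase two's job.

3. **False-positive reduction (phase two).** Candidate regions are covered
   by overlapping 64-mm cubes centred on a regular 8-mm lattice anchored at
   the crop origin; a lattice point is used when its voxel lies inside a
   candidate region. A cube is labelled positive when a node centre lies
   within 16 mm (inclusive) of its centre. Negative cubes are randomly
   undersampled by a factor of eight, once, before training. A 3-D residual
   network (50-layer bottleneck configuration by default) classifies each
   two-channel cube, trained with cross-entropy, batch size 32, Adam at
   1e−5, 20 epochs, with on-the-fly augmentation restricted to the 48
   right-angle symmetries of the cube (axis permutations and flips), which
   need no interpolation and are exact.

4. **Aggregation.** Each voxel receives the sum of the probabilities of
   every cube whose 64-mm extent contains it (coverage is at most
   (64/8)³ = 512 cubes in the interior). Voxels whose summed score strictly
   exceeds a threshold (default 18) form the predicted regions
   (26-connected components). The threshold is re-tunable on a validation
   cohort by minimising FP + FN over an integer sweep, ties broken toward
   the larger threshold (fewer false positives). "Summed predictions" is
   interpreted as summing positive-class probabilities, not binarised
   votes; with the default threshold far below the 512 coverage bound the
   two readings behave identically for confident classifiers, and
   probabilities retain calibration information.

5. **Transfer to a second scanner.** Domain shift (different voxel size,
   noise, lesion contrast) is handled by fine-tuning *only* the cube
   classifier on the new scanner's training scans — same loop, learning
   rate reduced by three orders of magnitude (1e−8 at full scale) — with
   the candidate U-Net frozen, and the original standardisation statistics
   retained.

## Evaluation

Detection is scored at the node level: a predicted region containing at
least one node centre yields a true positive per contained node (so TP + FN
equals the number of ground-truth nodes and sensitivity is node-based); a
region containing no node centre is one false positive (so FPs/patient is
region-based). Because "how many negative nodes does a patient have" has no
agreed answer, specificity is not reported; instead agreement between the
detector and a reader is summarised by Cohen's kappa on a 2 × 2 table whose
true-negative cell uses the convention TN = 8.3 × patients − (TP + FP + FN),
8.3 being the average nodes per patient of the comparison study this
convention follows. TN may be fractional and is used as-is — it is an
explicit synthetic denominator, not a count. Kappa magnitudes are qualified
with the Landis–Koch bands. Sensitivity carries an exact 95%
Clopper–Pearson interval (Beta-quantile inversion, checked in the tests
against an independent binomial-tail bisection). The FPs/patient interval
is computed by Clopper–Pearson on (FP, round(8.3 × patients)) trials and
labelled convention-dependent in reports: no natural exact interval exists
for a rate whose denominator is a convention. Kappa confidence intervals
are not reported (no defined method for the fractional-TN table). A size
statistic (mean/max equivalent diameter of predicted regions) is reported
so that "regions small enough to localise nodes" is quantified rather than
eyeballed.

Printed 2-dp rates are inverted to integer counts by exhaustive scan with
half-up rounding; ambiguity (zero or several solutions) raises rather than
guessing.

## Synthetic phantoms

Patient data are private, so every stage is exercised on parametric
thoracic phantoms: an elliptic-cylinder soft-tissue body (≈0 HU) on air,
two lung ellipsoids (−800 HU) joined by a tracheal air bridge so the lungs
form one connected air component as in real anatomy, a mediastinal
compartment between the lungs where spherical "positive nodes"
(8–30 mm diameter, SUV 3–8 before scanner gain) are planted, diffuse body
background uptake (1–2 SUV), and 1–2 distractor hot spots outside the
mediastinum (thyroid-nodule / inflammation analogues the second stage must
reject). PET degradation is a 1.5 mm Gaussian point-spread blur plus
additive Gaussian noise; CT gets 10 HU noise. Two scanner profiles differ
in PET voxel size (4 mm isotropic vs 2.5/2.5/2.8 mm), noise (0.20 vs
0.15 SUV) and lesion contrast gain (1.0 vs 1.4) — the published description
of the newer scanner gives no quantitative contrast figure, so the gain is
a free knob held fixed across all experiments.

Per-patient node counts are drawn from the pooled patients-by-node-count
distribution of the first scanner's cohort (P(0,1,2,3,4+) =
67/125, 17/125, 16/125, 7/125, 18/125, with "4+" drawn uniformly from
4–6). Held-out phantom cohorts used for *evaluation* in the tests instead
use fixed per-patient counts scaled down from the corresponding clinical
test-set spread, so that sensitivity always has enough support to be
measured; this is an experimental-design constraint chosen before any
detector results were inspected, not a tuning knob.

The default phantom grid is 128 × 128 × 96 voxels at 2 mm native spacing
(256 × 256 × 192 mm field of view), resampled to 1 mm by the pipeline;
anatomy scales with the grid so larger phantoms can be requested. This size
keeps a full cohort study (generation, preprocessing, training, evaluation)
in the tens of minutes on a single CPU while leaving every geometric
property of the pipeline (crop size, sphere labels, cube lattice, coverage
bound) at full scale.

What phantom results do **not** show: performance on real anatomy
(heterogeneous tissue, airways, vessels, bone), reconstruction artefacts,
respiratory motion, FDG-negative nodes, or reader variability. Phantom
experiments validate the *machinery* — that every stage is implemented
correctly, trains, and composes — and the direction of effects (e.g. that
fine-tuning recovers sensitivity after a scanner change), not clinical
accuracy.

## Scaled-down study conditions

The numpy CNN engine computes in float32 with hand-written backward passes
(verified against numerical gradients to ~1e-9 in the test suite). CPU-scale
experiments shrink the networks, not the pipeline: the U-Net drops to
4 base channels and 3 pooling levels, the residual network to two basic
blocks (8/16 channels, stride-4 stem); training runs 3 epochs with learning
rates raised to 1e−3 (U-Net) and 3e−3 (cubes) so that few-epoch training
converges, and the fine-tuning rate keeps the full-scale 1000× reduction
(3e−6). The scaled end-to-end study uses 12 training and 6 test phantoms
per scanner; threshold tuning uses the first three training patients that
contain nodes (the sweep needs both FP and FN signal), mirroring the
validation-then-fold-in protocol of the full-scale recipe.

## Numerical and degenerate-input choices

- Coordinate convention: arrays are (z, y, x); physical quantities are mm
  (x, y, z) under the voxel-centre convention; module boundaries exchange
  physical coordinates only.
- −400 HU exactly is air (inclusive threshold); 16 mm exactly is a positive
  cube; a summed score of exactly the threshold is *not* positive
  ("above").
- Component size ties in lung selection break toward scan order
  (deterministic).
- Morphology runs in 3-D (not per-slice) with the face-connected element;
  connected components use 26-connectivity everywhere.
- Resampling preserves the outer physical boundary; a cohort's two grids
  may disagree by one voxel after rounding, in which case PET is aligned on
  the CT grid with zero-padding.
- Zero training variance, empty lung masks, label-free training sets,
  single-class cube sets, and zero-node sensitivity all raise or flag
  explicitly rather than returning silent defaults.
- Fine-tuning with learning rate 0 is a defined no-op (no parameter or
  normalisation-statistic updates).

## Known limitations

- The phantom is geometric; none of the learned models transfer to real
  scans without retraining.
- The U-Net and residual architectures are faithful in structure but their
  exact published layer widths were not available; widths and depths are
  configuration, with defaults at the standard values (50-layer bottleneck
  network; 4-level U-Net at 32 base channels).
- Training at the full defaults (20 epochs, full-width networks) is
  CPU-hostile; the engine is single-threaded numpy and intended for the
  scaled configurations. The pipeline semantics are identical at any scale.
- The aggregation-threshold default (18) is calibrated to full-scale
  training; scaled runs should re-tune it on validation phantoms (the
  pipeline does).
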