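"""Phase two: cube enumeration, labelling, extraction, aggregation, classifier."""

import numpy as np
import pytest

from lymphdetect.cubes import (
    CubeClassifier,
    CubeConfig,
    ScoreMap,
    aggregate_scores,
    enumerate_cubes,
    extract_cube,
    label_cubes,
    positive_regions,
    undersample_negatives,
    _octahedral_transform,
)
from lymphdetect.errors import DataError, NotFittedError
from lymphdetect.nn import ResNetSpec
from lymphdetect.preprocess import ThoraxCrop
from lymphdetect.regions import CandidateRegion, label_components
from lymphdetect.volume import Modality, NodeAnnotation, Volume3D

CFG = CubeConfig()


def _grid(shape=(48, 48, 48)):
    return Volume3D(np.zeros(shape, dtype=np.float32), (1.0, 1.0, 1.0))


def _crop(ct, pet=None):
    grid = Volume3D(np.asarray(ct, dtype=np.float32), (1.0, 1.0, 1.0), modality=Modality.CT_HU)
    pet = Volume3D(
        np.zeros_like(grid.values) if pet is None else np.asarray(pet, dtype=np.float32),
        (1.0, 1.0, 1.0),
        modality=Modality.PET_SUV,
    )
    return ThoraxCrop(ct=grid, pet=pet, z_range=(0, grid.shape[0] - 1), xy_offset=(0, 0), patient_id="p")


class TestEnumerateCubes:
    def test_empty_regions_give_no_centres(self):
        assert len(enumerate_cubes([], _grid(), CFG)) == 0

    def test_single_voxel_on_lattice_point(self):
        region = CandidateRegion(np.array([[16, 8, 24]]), "p")
        centres = enumerate_cubes([region], _grid(), CFG)
        assert centres.shape == (1, 3)
        np.testing.assert_allclose(centres[0], [24.0, 8.0, 16.0])  # (x, y, z)

    def test_off_lattice_voxel_is_not_a_centre(self):
        region = CandidateRegion(np.array([[16, 8, 25]]), "p")
        assert len(enumerate_cubes([region], _grid(), CFG)) == 0

    def test_block_region_matches_triple_loop_oracle(self):
        grid = _grid()
        mask = np.zeros(grid.shape, dtype=bool)
        mask[8:32, 8:32, 8:32] = True  # 24^3 region aligned to the lattice
        regions = label_components(mask, "p")
        centres = enumerate_cubes(regions, grid, CFG)
        expected = []
        for z in range(0, 48, 8):
            for y in range(0, 48, 8):
                for x in range(0, 48, 8):
                    if mask[z, y, x]:
                        expected.append((x, y, z))
        got = {tuple(map(float, c)) for c in centres}
        assert got == {tuple(map(float, e)) for e in expected}
        assert len(centres) == 27

    def test_overlapping_regions_list_each_centre_once(self):
        r1 = CandidateRegion(np.array([[8, 8, 8]]), "p")
        r2 = CandidateRegion(np.array([[8, 8, 8], [8, 8, 9]]), "p")
        centres = enumerate_cubes([r1, r2], _grid(), CFG)
        assert len(centres) == 1


class TestLabelCubes:
    @pytest.mark.parametrize(
        "distance,expected", [(15.9, 1), (16.0, 1), (16.1, 0)]
    )
    def test_sixteen_mm_boundary_inclusive(self, distance, expected):
        centre = np.array([[100.0, 100.0, 100.0]])
        node = NodeAnnotation("p", (100.0 + distance, 100.0, 100.0))
        assert label_cubes(centre, [node], CFG)[0] == expected

    def test_no_nodes_all_negative(self):
        centres = np.random.default_rng(0).uniform(0, 100, (10, 3))
        assert not label_cubes(centres, [], CFG).any()

    def test_matches_all_pairs_distance_oracle(self):
        rng = np.random.default_rng(1)
        centres = rng.uniform(0, 120, (60, 3))
        nodes = [NodeAnnotation("p", tuple(rng.uniform(0, 120, 3))) for _ in range(5)]
        got = label_cubes(centres, nodes, CFG)
        for c, g in zip(centres, got):
            expected = int(
                any(np.linalg.norm(c - np.asarray(n.centre)) <= 16.0 for n in nodes)
            )
            assert g == expected


class TestUndersample:
    def test_eighty_negatives_keep_ten(self):
        labels = np.array([1] * 5 + [0] * 80)
        keep = undersample_negatives(labels, 8, rng=0)
        assert (labels[keep] == 1).sum() == 5
        assert (labels[keep] == 0).sum() == 10

    def test_same_seed_same_subset(self):
        labels = (np.random.default_rng(2).random(500) > 0.9).astype(int)
        a = undersample_negatives(labels, 8, rng=7)
        b = undersample_negatives(labels, 8, rng=7)
        np.testing.assert_array_equal(a, b)

    def test_retained_ratio_reproduces_eightfold_reduction(self):
        # class balance comparable to a candidate-cube training set
        # (~9% positive); after 8x undersampling the negative share of the
        # retained set should match the binomial expectation
        rng = np.random.default_rng(3)
        labels = (rng.random(46427) < 4235 / 46427).astype(int)
        keep = undersample_negatives(labels, 8, rng=4)
        n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
        kept_neg = (labels[keep] == 0).sum()
        assert kept_neg == int(np.floor(n_neg / 8 + 0.5))
        ratio = (labels[keep] == 1).sum() / kept_neg
        assert ratio == pytest.approx(8 * n_pos / n_neg, rel=0.01)

    def test_invalid_factor_raises(self):
        with pytest.raises(ValueError):
            undersample_negatives(np.array([0, 1]), 0)


class TestExtractCube:
    def test_constant_volume_gives_constant_patch(self):
        crop = _crop(np.full((96, 96, 96), 3.0), np.full((96, 96, 96), 1.5))
        sample = extract_cube(crop, (48.0, 48.0, 48.0), CFG, fill=(-9.0, -9.0))
        assert sample.patch.shape == (2, 64, 64, 64)
        np.testing.assert_array_equal(sample.patch[0], 3.0)
        np.testing.assert_array_equal(sample.patch[1], 1.5)

    def test_near_face_padding_thickness(self):
        ct = np.full((96, 96, 96), 7.0)
        crop = _crop(ct)
        # centre 10 voxels from the x=0 face: pad slab of 64/2 - 10 = 22
        sample = extract_cube(crop, (10.0, 48.0, 48.0), CFG, fill=(-5.0, 0.0))
        assert (sample.patch[0, :, :, :22] == -5.0).all()
        assert (sample.patch[0, :, :, 22:] == 7.0).all()

    def test_channel_order_ct_then_pet(self):
        ct = np.zeros((80, 80, 80))
        pet = np.ones((80, 80, 80))
        sample = extract_cube(_crop(ct, pet), (40.0, 40.0, 40.0), CFG)
        assert sample.patch[0].max() == 0.0
        assert sample.patch[1].min() == 1.0

    def test_centre_outside_crop_raises(self):
        with pytest.raises(ValueError):
            extract_cube(_crop(np.zeros((40, 40, 40))), (100.0, 10.0, 10.0), CFG)


class TestAggregation:
    def test_zero_probabilities_give_zero_map(self):
        grid = _grid((64, 64, 64))
        centres = np.array([[8.0, 8.0, 8.0], [16.0, 16.0, 16.0]])
        sm = aggregate_scores(centres, np.zeros(2), grid, CFG)
        assert sm.summed_score.max() == 0.0
        assert sm.coverage.max() == 2

    def test_single_cube_scores_p_inside_extent(self):
        grid = _grid((96, 96, 96))
        sm = aggregate_scores(np.array([[48.0, 48.0, 48.0]]), np.array([0.3]), grid, CFG)
        assert sm.summed_score[48, 48, 48] == pytest.approx(0.3)
        assert sm.summed_score[48 - 32, 48, 48] == pytest.approx(0.3)  # start face inside
        assert sm.summed_score[48 + 32, 48, 48] == 0.0  # one past the far face
        assert sm.summed_score[48, 48, 48 - 33] == 0.0

    def test_full_lattice_interior_sum_is_512(self):
        grid = _grid((112, 112, 112))
        mask = np.ones(grid.shape, dtype=bool)
        centres = enumerate_cubes(label_components(mask, "p"), grid, CFG)
        sm = aggregate_scores(centres, np.ones(len(centres)), grid, CFG)
        v = (64, 64, 64)
        # oracle: count lattice points whose 64 mm extent contains the voxel
        count = 0
        for c in centres:
            idx = grid.physical_to_nearest_index(c)
            lo = idx - 32
            if np.all(lo <= v) and np.all(np.asarray(v) < lo + 64):
                count += 1
        assert count == 512
        assert sm.summed_score[v] == pytest.approx(512.0)
        assert sm.coverage[v] == 512
        assert sm.coverage.max() <= 512

    def test_linearity_over_disjoint_cube_sets(self):
        grid = _grid((80, 80, 80))
        rng = np.random.default_rng(5)
        c1 = np.array([[8.0, 8.0, 8.0], [40.0, 40.0, 40.0]])
        c2 = np.array([[72.0, 72.0, 72.0]])
        p1, p2 = rng.random(2), rng.random(1)
        both = aggregate_scores(np.vstack([c1, c2]), np.concatenate([p1, p2]), grid, CFG)
        a = aggregate_scores(c1, p1, grid, CFG)
        b = aggregate_scores(c2, p2, grid, CFG)
        np.testing.assert_allclose(both.summed_score, a.summed_score + b.summed_score)
        np.testing.assert_array_equal(both.coverage, a.coverage + b.coverage)

    def test_score_bounded_by_coverage_for_probabilities(self):
        grid = _grid((64, 64, 64))
        rng = np.random.default_rng(6)
        centres = rng.integers(0, 8, (30, 3)) * 8.0
        probs = rng.random(30)
        sm = aggregate_scores(centres, probs, grid, CFG)
        assert (sm.summed_score <= sm.coverage + 1e-12).all()
        assert (sm.summed_score >= 0).all()

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            aggregate_scores(np.zeros((2, 3)), np.zeros(3), _grid(), CFG)


class TestPositiveRegions:
    def test_threshold_is_strictly_greater(self):
        grid = _grid((20, 20, 20))
        score = np.full(grid.shape, 17.9)
        sm = ScoreMap(score, np.full(grid.shape, 512, dtype=np.int32), grid)
        assert positive_regions(sm, CFG) == []
        sm.summed_score[:] = 18.0  # exactly the threshold: still not positive
        assert positive_regions(sm, CFG) == []
        sm.summed_score[5, 5, 5] = 18.01
        out = positive_regions(sm, CFG)
        assert len(out) == 1 and out[0].volume == 1

    def test_single_blob_above_threshold(self):
        grid = _grid((30, 30, 30))
        score = np.zeros(grid.shape)
        score[10:15, 10:15, 10:15] = 25.0
        sm = ScoreMap(score, np.full(grid.shape, 512, dtype=np.int32), grid)
        out = positive_regions(sm, CFG)
        assert len(out) == 1
        assert out[0].contains_index((12, 12, 12))


TINY = CubeConfig(
    epochs=2,
    batch_size=8,
    learning_rate=3e-3,
    finetune_learning_rate=3e-6,
    resnet=ResNetSpec(
        block="basic", stage_blocks=(1,), base_width=4, stem_width=4, stem_kernel=3, stem_stride=2
    ),
)


def _cube_set(n=12, side=16, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i in range(n):
        c = rng.normal(0, 0.1, size=(2, side, side, side)).astype(np.float32)
        if i % 2:
            zz, yy, xx = np.mgrid[:side, :side, :side]
            m = (zz - side // 2) ** 2 + (yy - side // 2) ** 2 + (xx - side // 2) ** 2 <= 9
            c[1][m] += 3.0
        xs.append(c)
        ys.append(i % 2)
    return xs, np.array(ys)


class TestCubeClassifier:
    def test_deterministic_training_trace(self):
        xs, ys = _cube_set()
        a = CubeClassifier(TINY, random_state=3).fit(xs, ys)
        b = CubeClassifier(TINY, random_state=3).fit(xs, ys)
        assert a.loss_trace_ == b.loss_trace_
        assert a.state_hash() == b.state_hash()

    def test_single_class_raises(self):
        xs, _ = _cube_set(6)
        with pytest.raises(DataError):
            CubeClassifier(TINY).fit(xs, np.zeros(6, dtype=int))

    def test_probabilities_bounded_and_deterministic(self):
        xs, ys = _cube_set()
        clf = CubeClassifier(TINY, random_state=0).fit(xs, ys)
        p1 = clf.predict_proba(xs)
        p2 = clf.predict_proba(xs)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        np.testing.assert_array_equal(p1, p2)

    def test_unfitted_raises(self):
        with pytest.raises(NotFittedError):
            CubeClassifier(TINY).predict_proba([np.zeros((2, 16, 16, 16))])

    def test_fine_tune_with_zero_learning_rate_is_identity(self):
        xs, ys = _cube_set()
        clf = CubeClassifier(TINY, random_state=0).fit(xs, ys)
        before = clf.predict_proba(xs)
        h = clf.state_hash()
        clf.fine_tune(xs, ys, learning_rate=0.0, epochs=2)
        np.testing.assert_array_equal(clf.predict_proba(xs), before)
        assert clf.state_hash() == h

    def test_training_loss_decreases(self):
        xs, ys = _cube_set(16)
        clf = CubeClassifier(TINY, random_state=1).fit(xs, ys)
        assert clf.loss_trace_[-1] < clf.loss_trace_[0]

    def test_augmentation_invariant_predictions_on_symmetric_lesions(self):
        # a centred spherical lesion is invariant under the cube symmetries,
        # so flips of the input should leave the prediction nearly unchanged
        xs, ys = _cube_set(16)
        clf = CubeClassifier(TINY, random_state=1).fit(xs, ys)
        cube = xs[1]
        flips = [cube]
        for ax in range(3):
            flips.append(np.ascontiguousarray(np.flip(cube, axis=1 + ax)))
        probs = clf.predict_proba(flips)
        assert np.abs(probs - probs[0]).mean() < 0.2

    def test_save_load_round_trip(self, tmp_path):
        xs, ys = _cube_set()
        clf = CubeClassifier(TINY, random_state=0).fit(xs, ys)
        clf.save(tmp_path / "resnet.npz")
        clf2 = CubeClassifier(TINY).load(tmp_path / "resnet.npz")
        np.testing.assert_allclose(clf2.predict_proba(xs), clf.predict_proba(xs), atol=1e-6)


class TestOctahedralTransform:
    def test_generates_the_48_cube_symmetries(self):
        base = np.arange(2 * 4 * 4 * 4).reshape(2, 4, 4, 4).astype(float)
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(3000):
            t = _octahedral_transform(base, rng)
            seen.add(t.tobytes())
        assert len(seen) == 48

    def test_preserves_channel_axis_and_values(self):
        base = np.random.default_rng(1).normal(size=(2, 6, 6, 6))
        t = _octahedral_transform(base, np.random.default_rng(2))
        assert t.shape == base.shape
        np.testing.assert_allclose(np.sort(t[0].ravel()), np.sort(base[0].ravel()))
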