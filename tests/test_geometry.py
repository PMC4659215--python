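"""Transform mapping, nearest-label resampling, and the score function."""

import math

import numpy as np
import pytest

from specreg.geometry import (
    SimilarityTransform,
    TransformBounds,
    TransformScorer,
    map_coordinates,
    rotation_unit,
    sample_moving,
    score,
)
from specreg.metric import joint_histogram, standard_mi
from specreg.segmentation import IndexImage


def random_index(rng, shape, k):
    return IndexImage(rng.integers(0, k + 1, size=shape).astype(np.int32), k=k)


class TestMapping:
    def test_identity_maps_to_self(self):
        pixels = np.array([[0, 0], [3, 7], [9, 9]])
        out = map_coordinates(SimilarityTransform(), (10, 10), (10, 10), pixels)
        np.testing.assert_allclose(out, pixels)

    def test_pure_translation_shifts_columns(self):
        pixels = np.array([[2, 3]])
        out = map_coordinates(SimilarityTransform(tx=5), (10, 10), (10, 10), pixels)
        np.testing.assert_allclose(out, [[2, 8]])

    def test_rotation_90_matches_matrix(self):
        t = SimilarityTransform(theta=90.0)
        shape = (3, 3)
        out = map_coordinates(t, shape, shape, np.array([[0, 0]]))
        # explicit matrix arithmetic: rel (-1,-1) -> rotated (1,-1) about (1,1)
        np.testing.assert_allclose(out, [[0.0, 2.0]], atol=1e-12)
        m = t.matrix(shape, shape)
        hom = m @ np.array([0.0, 0.0, 1.0])  # (x, y) = (col, row)
        np.testing.assert_allclose(out[0], hom[[1, 0]], atol=1e-12)

    def test_scale_about_center(self):
        out = map_coordinates(SimilarityTransform(s=2.0), (5, 5), (5, 5), np.array([[2, 3]]))
        np.testing.assert_allclose(out, [[2.0, 4.0]])


class TestSampling:
    def test_identity_is_identity(self, rng):
        moving = random_index(rng, (12, 14), 4)
        out = sample_moving(moving, SimilarityTransform(), (12, 14))
        np.testing.assert_array_equal(out.labels, moving.labels)

    def test_far_shift_is_all_background(self, rng):
        moving = random_index(rng, (10, 10), 3)
        out = sample_moving(moving, SimilarityTransform(tx=100), (10, 10))
        assert (out.labels == 0).all()

    def test_translation_matches_bruteforce(self, rng):
        moving = random_index(rng, (10, 10), 5)
        t = SimilarityTransform(tx=2, ty=-1)
        out = sample_moving(moving, t, (10, 10))
        expected = np.zeros((10, 10), np.int32)
        for r in range(10):
            for c in range(10):
                rr, cc = r - 1, c + 2
                if 0 <= rr < 10 and 0 <= cc < 10:
                    expected[r, c] = moving.labels[rr, cc]
        np.testing.assert_array_equal(out.labels, expected)

    def test_half_up_rounding(self):
        # template 1x1 on a 1x2 moving image: center maps to column 0.5 + tx
        moving = IndexImage(np.array([[1, 2]]), k=2)
        out = sample_moving(moving, SimilarityTransform(), (1, 1))
        assert out.labels[0, 0] == 2  # 0.5 rounds toward +inf

    def test_rotation_matches_bruteforce(self, rng):
        moving = random_index(rng, (15, 15), 4)
        t = SimilarityTransform(tx=1, ty=-2, theta=30.0)
        out = sample_moving(moving, t, (9, 9))
        coords = map_coordinates(
            t, (9, 9), (15, 15), np.stack(np.meshgrid(range(9), range(9), indexing="ij"), -1)
        )
        for r in range(9):
            for c in range(9):
                rr = math.floor(coords[r, c, 0] + 0.5)
                cc = math.floor(coords[r, c, 1] + 0.5)
                exp = moving.labels[rr, cc] if 0 <= rr < 15 and 0 <= cc < 15 else 0
                assert out.labels[r, c] == exp


class TestScore:
    def test_self_score_is_entropy(self, rng):
        img = random_index(rng, (20, 20), 5)
        jd = joint_histogram(img, img)
        assert score(img, img, SimilarityTransform(), alpha=0.0) == pytest.approx(
            jd.entropy_x, abs=1e-12
        )

    @pytest.mark.parametrize("use_numba", [True, False])
    def test_scorer_matches_composed_path(self, rng, use_numba):
        fixed = random_index(rng, (20, 24), 6)
        moving = random_index(rng, (40, 50), 8)
        scorer = TransformScorer(fixed, moving, alpha=0.25, use_numba=use_numba)
        for t in (
            SimilarityTransform(),
            SimilarityTransform(tx=4, ty=-3),
            SimilarityTransform(tx=-2, ty=5, theta=17.0),
            SimilarityTransform(tx=1, ty=1, theta=-8.0, s=1.1),
            SimilarityTransform(tx=100, ty=0),
        ):
            reference = score(fixed, moving, t, alpha=0.25)
            assert scorer(t) == pytest.approx(reference, abs=1e-9) or (
                reference == -math.inf and scorer(t) == -math.inf
            )

    def test_numba_and_numpy_tables_identical(self, rng):
        fixed = random_index(rng, (20, 24), 6)
        moving = random_index(rng, (40, 50), 8)
        fast = TransformScorer(fixed, moving, use_numba=True)
        slow = TransformScorer(fixed, moving, use_numba=False)
        for t in (
            SimilarityTransform(tx=3.0, ty=-7.0, theta=12.5, s=0.9),
            SimilarityTransform(tx=-30.5, ty=14.25, theta=-29.0),
        ):
            np.testing.assert_array_equal(fast.counts(t), slow.counts(t))

    def test_translation_composition(self, rng):
        """Pre-shifting the moving labels equals shifting the transform."""
        moving = random_index(rng, (30, 30), 4)
        shifted = IndexImage(np.roll(moving.labels, (2, 3), axis=(0, 1)), k=4)
        t1 = sample_moving(moving, SimilarityTransform(tx=-4, ty=-5), (10, 10))
        t2 = sample_moving(shifted, SimilarityTransform(tx=-4 + 3, ty=-5 + 2), (10, 10))
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_label_permutation_invariance(self, rng):
        fixed = random_index(rng, (15, 15), 4)
        moving = random_index(rng, (25, 25), 5)
        perm = np.array([0, 3, 1, 5, 2, 4])  # permutes foreground labels only
        moving_perm = IndexImage(perm[moving.labels], k=5)
        t = SimilarityTransform(tx=2, ty=-1, theta=10.0)
        assert score(fixed, moving, t) == pytest.approx(
            score(fixed, moving_perm, t), abs=1e-12
        )

    def test_counts_cache_shared_across_alphas(self, rng):
        fixed = random_index(rng, (10, 10), 3)
        moving = random_index(rng, (20, 20), 3)
        cache: dict = {}
        a = TransformScorer(fixed, moving, alpha=0.2, counts_cache=cache)
        b = TransformScorer(fixed, moving, alpha=0.4, counts_cache=cache)
        t = SimilarityTransform(tx=1)
        a(t)
        assert len(cache) == 1
        b(t)
        assert len(cache) == 1  # reused, not recomputed


class TestBoundsAndUnits:
    def test_rotation_unit_displaces_one_pixel(self):
        shape = (121, 161)
        u = rotation_unit(shape)
        assert math.hypot(60, 80) * math.radians(u) == pytest.approx(1.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            TransformBounds(tx=(5, -5), ty=(0, 0))
        with pytest.raises(ValueError):
            TransformBounds(tx=(0, 0), ty=(0, 0), scale=(-0.5, 1.0))

    def test_transform_json_roundtrip(self):
        t = SimilarityTransform(tx=3, ty=-2, theta=12.0, s=1.05)
        import json

        data = json.loads(t.to_json((10, 10), (30, 30)))
        assert data["tx"] == 3 and data["theta_deg"] == 12.0
        assert np.asarray(data["matrix"]).shape == (3, 3)
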