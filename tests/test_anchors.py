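"""Row maxima, local extrema, morphological cleanup and the slope sieve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scoliometry.anchors import (
    AnchorSet,
    EmptyAnchorsError,
    SieveConfig,
    candidate_anchors,
    erode_square,
    remove_small_objects,
    row_global_maxima,
    row_local_extrema,
    sieve_fine_anchors,
)


def brute_force_sieve(points, min_ratio=1.0):
    """Independent re-implementation of the sieve scan for cross-checking."""
    pts = sorted(points)
    kept = [pts[0]]
    for p in pts[1:]:
        r1, c1 = kept[-1]
        r2, c2 = p
        dcol = abs(c2 - c1)
        if dcol == 0:
            kept.append(p)
        elif abs(r2 - r1) / dcol > min_ratio:
            kept.append(p)
    return kept


class TestRowGlobalMaxima:
    def test_unique_argmax(self):
        img = np.array([[0.1, 0.9, 0.3], [0.2, 0.1, 0.8]])
        assert row_global_maxima(img).points == ((0, 1), (1, 2))

    def test_tie_breaks_leftmost(self):
        img = np.array([[0.5, 0.5, 0.1], [0.1, 0.5, 0.5]])
        assert row_global_maxima(img).points == ((0, 0), (1, 1))

    def test_constant_row_emits_no_point(self):
        img = np.array([[0.5, 0.5], [0.1, 0.5]])
        assert row_global_maxima(img).points == ((1, 1),)

    def test_constant_image_emits_nothing(self):
        assert row_global_maxima(np.full((3, 4), 0.7)).points == ()

    def test_mask_gates_the_search(self):
        img = np.array([[0.1, 0.9, 0.3], [0.2, 0.1, 0.8]])
        mask = np.array([[1, 0, 1], [0, 0, 0]], dtype=np.uint8)
        # row 0: max among gated pixels {0.1, 0.3}; row 1 fully masked out
        assert row_global_maxima(img, mask).points == ((0, 2),)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            row_global_maxima(np.zeros((2, 3)), np.zeros((3, 2), dtype=np.uint8))


class TestRowLocalExtrema:
    def test_isolated_peak(self):
        img = np.array([[0, 0, 0, 1, 0, 0, 0]], dtype=float)
        assert row_local_extrema(img, radius=3).points == ((0, 3),)

    def test_constant_row_empty(self):
        assert row_local_extrema(np.full((2, 8), 0.5), radius=3).points == ()

    def test_plateau_excluded(self):
        img = np.array([[0, 0, 0, 1, 1, 0, 0]], dtype=float)
        assert row_local_extrema(img, radius=3).points == ()

    def test_boundary_compares_in_range_only(self):
        img = np.array([[1.0, 0.5, 0.2, 0.1, 0.0, 0.0, 0.0]])
        assert (0, 0) in row_local_extrema(img, radius=3).points

    @pytest.mark.parametrize("radius", [0, 2, 6])
    def test_radius_restricted(self, radius):
        with pytest.raises(ValueError):
            row_local_extrema(np.zeros((2, 8)), radius=radius)


class TestMorphology:
    def test_single_pixel_removed(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        assert remove_small_objects(mask, min_area=3).sum() == 0

    def test_diagonal_chain_kept_with_8_connectivity(self):
        mask = np.eye(3, dtype=np.uint8)
        np.testing.assert_array_equal(remove_small_objects(mask, 3, connectivity=8), mask)

    def test_diagonal_chain_removed_with_4_connectivity(self):
        mask = np.eye(3, dtype=np.uint8)
        assert remove_small_objects(mask, 3, connectivity=4).sum() == 0

    def test_remove_small_objects_idempotent(self, rng):
        mask = (rng.random((20, 20)) > 0.7).astype(np.uint8)
        once = remove_small_objects(mask, 3)
        np.testing.assert_array_equal(remove_small_objects(once, 3), once)

    def test_erode_size_one_is_identity(self, rng):
        mask = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(erode_square(mask, 1), mask)

    def test_erode_solid_block(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[1:5, 1:5] = 1
        eroded = erode_square(mask, 3)
        expected = np.zeros((6, 6), dtype=np.uint8)
        expected[2:4, 2:4] = 1
        np.testing.assert_array_equal(eroded, expected)

    def test_empty_result_guard_returns_input(self, caplog):
        # 1-pixel-wide chain: a 3x3 erosion would annihilate it
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:, 4] = 1
        with caplog.at_level("WARNING"):
            out = erode_square(mask, 3)
        np.testing.assert_array_equal(out, mask)
        assert any("empty" in r.message for r in caplog.records)


class TestCandidateAnchors:
    def test_identical_singletons(self):
        g = AnchorSet(((0, 5),), "global-max")
        l = AnchorSet(((0, 5),), "local-extremum")
        assert candidate_anchors(g, l).points == ((0, 5),)

    def test_disjoint_sets_empty(self):
        g = AnchorSet(((0, 5),), "global-max")
        l = AnchorSet(((0, 6),), "local-extremum")
        assert candidate_anchors(g, l).points == ()

    def test_plain_intersection(self):
        g = AnchorSet(((0, 5), (1, 4)), "global-max")
        l = AnchorSet(((0, 5), (1, 4), (2, 9)), "local-extremum")
        assert candidate_anchors(g, l).points == ((0, 5), (1, 4))

    def test_multi_point_row_keeps_leftmost(self):
        g = AnchorSet(((0, 5), (0, 3)), "global-max")
        l = AnchorSet(((0, 5), (0, 3)), "local-extremum")
        assert candidate_anchors(g, l).points == ((0, 3),)


class TestSieve:
    def test_vertical_line_all_accepted(self):
        cands = AnchorSet(((0, 50), (1, 50), (2, 50)), "candidate")
        assert sieve_fine_anchors(cands).points == ((0, 50), (1, 50), (2, 50))

    def test_shallow_slope_rejected(self):
        cands = AnchorSet(((0, 50), (1, 60)), "candidate")
        assert sieve_fine_anchors(cands).points == ((0, 50),)

    def test_scan_continues_from_same_anchor(self):
        cands = AnchorSet(((0, 50), (1, 60), (5, 52)), "candidate")
        assert sieve_fine_anchors(cands).points == ((0, 50), (5, 52))

    def test_empty_candidates_error(self):
        with pytest.raises(EmptyAnchorsError):
            sieve_fine_anchors(AnchorSet((), "candidate"))

    def test_boundary_slope_exactly_one_rejected(self):
        cands = AnchorSet(((0, 50), (2, 52)), "candidate")
        assert sieve_fine_anchors(cands).points == ((0, 50),)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_satisfies_slope_contract(self, data):
        n = data.draw(st.integers(1, 50))
        rows = sorted(
            data.draw(st.sets(st.integers(0, 200), min_size=n, max_size=n))
        )
        cols = [data.draw(st.integers(0, 100)) for _ in rows]
        cands = AnchorSet(tuple(zip(rows, cols)), "candidate")
        fine = sieve_fine_anchors(cands)
        assert list(fine.points) == brute_force_sieve(cands.points)
        assert fine.points[0] == cands.points[0]
        assert set(fine.points) <= set(cands.points)
        for (r1, c1), (r2, c2) in zip(fine.points, fine.points[1:]):
            assert c2 == c1 or abs(r2 - r1) / abs(c2 - c1) > 1.0


class TestSieveConfig:
    @pytest.mark.parametrize("kwargs", [
        {"local_radius": 2},
        {"max_angle_deg": 0.0},
        {"max_angle_deg": 90.0},
        {"connectivity": 6},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            SieveConfig(**kwargs)

    def test_wider_angle_admits_shallower_lines(self):
        # At 60 degrees from vertical the slope bound is tan(30) ~ 0.577.
        cands = AnchorSet(((0, 50), (2, 52), (4, 55)), "candidate")
        fine = sieve_fine_anchors(cands, SieveConfig(max_angle_deg=60.0))
        assert fine.points == ((0, 50), (2, 52), (4, 55))
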