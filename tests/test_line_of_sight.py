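"""Distance, angle and ranking-coefficient geometry of the in-line-of-sight method."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kanosight import (
    ANGLE_SCALE,
    CornerPOV,
    KanosightError,
    angle_from_corner,
    datasets,
    distance_to_corner,
    indices_from_counts,
    rank_attributes,
    ranking_coefficient,
)
from kanosight._rounding import round_half_up
from tests.conftest import PRINTED_RANKING, REFERENCE_ORDER

MUST_BE = CornerPOV("must-be")

in_square = st.tuples(st.floats(-1, 0), st.floats(0, 1))


def weighted_coordinates(group):
    counts = datasets.reference_counts(group)
    importance = datasets.reference_importance(group)
    return {attr: indices_from_counts(counts[attr], importance[attr]).weighted_coordinate
            for attr in counts}


class TestDistance:
    def test_resource_efficiency_test_group(self):
        d = distance_to_corner((-0.3726, 0.3075), MUST_BE)
        assert d == pytest.approx(0.699, abs=5e-4)

    def test_corner_itself_is_zero(self):
        assert distance_to_corner((-1.0, 0.0), MUST_BE) == 0.0

    def test_opposite_corner_is_sqrt2(self):
        assert distance_to_corner((0.0, 1.0), MUST_BE) == pytest.approx(math.sqrt(2))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(KanosightError):
            distance_to_corner((0.2, 0.5), MUST_BE)

    @given(in_square)
    def test_reflection_through_center_preserves_distances(self, point):
        """Reflecting both the point and the corner through the square's
        center (-0.5, 0.5) maps the must-be corner to the attractive one and
        leaves the distance invariant."""
        worse, better = point
        reflected = (-1 - worse, 1 - better)
        assert distance_to_corner(point, MUST_BE) == pytest.approx(
            distance_to_corner(reflected, CornerPOV("attractive")))


class TestAngle:
    def test_practicality_test_group(self):
        alpha = angle_from_corner((-0.7996, 0.2460), MUST_BE)
        assert alpha == pytest.approx(50.8, abs=0.05)

    def test_on_reference_axis_is_zero(self):
        assert angle_from_corner((-0.4, 0.0), MUST_BE) == 0.0

    def test_perpendicular_boundary_is_ninety(self):
        assert angle_from_corner((-1.0, 0.5), MUST_BE) == 90.0

    def test_corner_itself_defined_as_zero(self):
        assert angle_from_corner((-1.0, 0.0), MUST_BE) == 0.0

    def test_must_be_matches_arctan_formula(self):
        worse, better = -0.63, 0.41
        expected = math.degrees(math.atan(better / (1 + worse)))
        assert angle_from_corner((worse, better), MUST_BE) == pytest.approx(expected)

    @given(in_square)
    def test_angle_within_sector_for_all_povs(self, point):
        for name in ("must-be", "attractive", "one-dimensional", "indifferent"):
            alpha = angle_from_corner(point, CornerPOV(name))
            assert 0 <= alpha <= 90

    def test_attractive_reference_is_better_axis(self):
        # on the Better axis below the attractive corner: alpha = 0
        assert angle_from_corner((0.0, 0.3), CornerPOV("attractive")) == 0.0
        # along the top edge toward one-dimensional: alpha = 90
        assert angle_from_corner((-0.7, 1.0), CornerPOV("attractive")) == 90.0

    def test_non_adjacent_angle_reference_rejected(self):
        with pytest.raises(KanosightError):
            CornerPOV("must-be", angle_reference="attractive")


class TestRankingCoefficient:
    def test_angle_zero_equals_distance_exactly(self):
        assert ranking_coefficient(0.52, 0.0) == 0.52

    def test_zero_zero_is_zero(self):
        assert ranking_coefficient(0.0, 0.0) == 0.0

    def test_direct_evaluation(self):
        assert ranking_coefficient(0.19, 70) == pytest.approx(
            0.19 + (70 / 90) * 0.05 * math.sqrt(2))

    def test_angle_scale_is_five_percent_of_sqrt2(self):
        assert ANGLE_SCALE == pytest.approx(0.0707107, abs=1e-6)

    @pytest.mark.parametrize("d,alpha", [(-0.1, 10), (0.5, -1), (0.5, 91)])
    def test_out_of_range_inputs_rejected(self, d, alpha):
        with pytest.raises(KanosightError):
            ranking_coefficient(d, alpha)

    @given(in_square)
    def test_coefficient_bound(self, point):
        d = distance_to_corner(point, MUST_BE)
        alpha = angle_from_corner(point, MUST_BE)
        assert 0 <= ranking_coefficient(d, alpha) <= math.sqrt(2) * 1.05


class TestRankAttributes:
    @pytest.mark.parametrize("group", ["A", "B"])
    def test_reproduces_published_ranking_table(self, group):
        """Full-precision recomputation from the published counts and
        importance matches every printed d (one ULP), alpha (+-1 degree), f
        (one ULP) and rank of the published ranking tables."""
        results = {r.attribute_id: r
                   for r in rank_attributes(weighted_coordinates(group), "must-be")}
        for attr, (d, alpha, f, rank) in PRINTED_RANKING[group].items():
            got = results[attr]
            assert abs(round_half_up(got.distance) - d) <= 0.01 + 1e-12
            assert abs(got.angle - alpha) <= 1.0
            assert abs(round_half_up(got.coefficient) - f) <= 0.01 + 1e-12
            assert got.rank == rank

    def test_both_groups_rank_identically(self):
        """The headline replication: test and validation groups produce the
        same priority permutation."""
        ranks = {}
        for group in ("A", "B"):
            results = rank_attributes(weighted_coordinates(group), "must-be")
            ranks[group] = sorted(results, key=lambda r: r.rank)
        assert [r.attribute_id for r in ranks["A"]] == [r.attribute_id for r in ranks["B"]]
        assert [r.attribute_id for r in ranks["A"]] == REFERENCE_ORDER

    def test_single_attribute_gets_rank_one(self):
        [res] = rank_attributes({"only": (-0.2, 0.9)}, "must-be")
        assert res.rank == 1 and not res.tied

    def test_equal_distance_lower_angle_ranks_first(self):
        # both at distance sqrt(0.5) from (-1, 0), different angles
        res = {r.attribute_id: r for r in rank_attributes(
            {"steep": (-0.5, 0.5), "flat": (-1 + math.sqrt(0.5), 1e-6)}, "must-be")}
        assert res["flat"].angle < res["steep"].angle
        assert res["flat"].rank == 1 and res["steep"].rank == 2

    def test_exact_ties_keep_input_order_and_flag(self):
        res = rank_attributes({"b_first": (-0.5, 0.0), "a_second": (-0.5, 0.0)},
                              "must-be")
        assert [r.rank for r in res] == [1, 2]
        assert all(r.tied for r in res)

    def test_ranks_are_a_permutation(self):
        results = rank_attributes(weighted_coordinates("A"), "must-be")
        assert sorted(r.rank for r in results) == list(range(1, 10))

    def test_empty_input_rejected(self):
        with pytest.raises(KanosightError):
            rank_attributes({}, "must-be")

    def test_rank_stability_under_small_perturbation(self):
        """Perturbing every coordinate by less than half the minimal pairwise
        f gap never changes the permutation."""
        import numpy as np

        coords = weighted_coordinates("A")
        base = rank_attributes(coords, "must-be")
        f = sorted(r.coefficient for r in base)
        gap = min(b - a for a, b in zip(f, f[1:]))
        # a coordinate shift of eps moves d by <= eps and alpha-term by
        # O(eps); keep the shift well under gap/2 via the local Lipschitz
        # bound of f (~1 in d plus angle sensitivity away from the corner)
        eps = gap / 8
        rng = np.random.default_rng(0)
        for _ in range(20):
            jitter = {
                attr: (min(0.0, max(-1.0, w + rng.uniform(-eps, eps))),
                       min(1.0, max(0.0, b + rng.uniform(-eps, eps))))
                for attr, (w, b) in coords.items()
            }
            perturbed = rank_attributes(jitter, "must-be")
            assert [r.rank for r in perturbed] == [r.rank for r in base]
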