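"""Feasible-set geometry, the uniform-average mean structure, and the W policy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminogram import (
    AmineReadings,
    FeasiblePoint,
    WPolicy,
    a_bounds,
    decompose_reading,
    forward_readings,
    legacy_free_fraction,
    mean_structure,
    shares_at_point,
    solve_xy,
    w_ratio,
)
from aminogram.estimator import (
    FLAG_LONGER_PEPTIDES,
    FLAG_SUB_UNITY_W,
)

W_GRID = [1.2, 1.6, 2.0, 2.4, 2.8]

feasible_points = st.builds(
    lambda al, be, w, frac: _make_point(al, be, w, frac),
    st.floats(0, 0.3), st.floats(0, 0.3), st.floats(1.001, 2.999), st.floats(0, 1),
)


def _make_point(alpha, beta, W, frac):
    lo, hi = a_bounds(alpha, beta, W)
    if hi < lo:
        return None
    return FeasiblePoint(W=W, alpha=alpha, beta=beta, A=lo + frac * (hi - lo))


class TestWRatio:
    def test_in_range_no_flags(self):
        W, flags = w_ratio(AmineReadings(F=1, T=2))
        assert W == 2 and flags == []

    def test_above_ceiling_clamped_with_longer_peptide_flag(self):
        W, flags = w_ratio(AmineReadings(F=1, T=3.2))
        assert W == 3 and flags == [FLAG_LONGER_PEPTIDES]

    def test_sub_unity_clamped_with_warning(self):
        W, flags = w_ratio(AmineReadings(F=1, T=0.9))
        assert W == 1 and flags == [FLAG_SUB_UNITY_W]

    def test_error_policy(self):
        policy = WPolicy(above_max_action="error")
        with pytest.raises(ValueError, match="above"):
            w_ratio(AmineReadings(F=1, T=4), policy)

    @pytest.mark.parametrize("F", [0.0, -1.0])
    def test_nonpositive_F_rejected(self, F):
        with pytest.raises(ValueError):
            w_ratio(AmineReadings(F=F, T=1))


class TestABounds:
    @pytest.mark.parametrize(
        "alpha,beta,W,lo,hi",
        [
            (0.0, 0.0, 1.0, 1.0, 1.0),     # W=1 forces pure free amino acids
            (0.0, 0.0, 2.0, 0.0, 0.5),
            (0.3, 0.0, 1.5, 0.275, 0.75),
        ],
    )
    def test_examples(self, alpha, beta, W, lo, hi):
        got_lo, got_hi = a_bounds(alpha, beta, W)
        assert got_lo == pytest.approx(lo)
        assert got_hi == pytest.approx(hi)

    def test_infeasible_cell_reported_empty(self):
        lo, hi = a_bounds(0.0, 0.1, 3.0)
        assert hi < lo  # at W=3 only beta=0 admits solutions
        assert hi == pytest.approx(-0.2)

    def test_w_out_of_range_errors(self):
        with pytest.raises(ValueError, match="WPolicy"):
            a_bounds(0.0, 0.0, 3.5)

    def test_brute_force_feasibility_scan_matches_bounds(self):
        """Independent check of the A-interval: scan A on a fine grid and
        test non-negativity of (x, y) directly from the linear system."""
        for alpha, beta, W in [(0.0, 0.0, 2.0), (0.2, 0.1, 1.5), (0.3, 0.3, 1.2)]:
            lo, hi = a_bounds(alpha, beta, W)
            denom = 0.5 + 1.5 * alpha - beta
            feasible_A = []
            for A in np.linspace(0, 1, 20001):
                x = (1 - A - (1 + 2 * beta) * (W - 1) / 2) / denom
                y = (W - 1 - x) / 2
                if x >= -1e-12 and y >= -1e-12:
                    feasible_A.append(A)
            assert min(feasible_A) == pytest.approx(lo, abs=1e-4)
            assert max(feasible_A) == pytest.approx(hi, abs=1e-4)


class TestSolveXY:
    @pytest.mark.parametrize(
        "A,alpha,beta,W,x,y",
        [
            (1.0, 0.2, 0.1, 1.0, 0.0, 0.0),
            (0.0, 0.0, 0.0, 3.0, 0.0, 1.0),
            (0.25, 0.0, 0.0, 2.0, 0.5, 0.25),
        ],
    )
    def test_examples(self, A, alpha, beta, W, x, y):
        got_x, got_y = solve_xy(A, alpha, beta, W)
        assert got_x == pytest.approx(x, abs=1e-12)
        assert got_y == pytest.approx(y, abs=1e-12)

    def test_outside_feasible_set_names_violated_bound(self):
        with pytest.raises(ValueError, match="dipeptide total x"):
            solve_xy(0.9, 0.0, 0.0, 2.0)
        with pytest.raises(ValueError, match="tripeptide"):
            solve_xy(0.0, 0.0, 0.0, 1.2)

    @given(feasible_points)
    @settings(max_examples=300, deadline=None)
    def test_round_trip_through_forward_model(self, p):
        """Reconstructing the full class composition from any feasible point
        and pushing it through the forward model must return F = 1, T = W."""
        if p is None:
            return
        r = forward_readings(p.to_composition())
        assert r.F == pytest.approx(1.0, rel=1e-9)
        assert r.T == pytest.approx(p.W, rel=1e-9)
        assert p.x + 2 * p.y == pytest.approx(p.W - 1.0, rel=1e-9, abs=1e-12)


class TestSharesAtPoint:
    def test_w1_point_is_pure_free(self):
        p = FeasiblePoint(W=1.0, alpha=0.1, beta=0.2, A=1.0)
        before, after = shares_at_point(p)
        assert before == pytest.approx((1, 0, 0))
        assert after == pytest.approx((1, 0, 0))

    def test_w3_point_is_pure_tripeptide_after(self):
        p = FeasiblePoint(W=3.0, alpha=0.0, beta=0.0, A=0.0)
        _, after = shares_at_point(p)
        assert after == pytest.approx((0, 0, 1))

    def test_hand_computed_midpoint(self):
        p = FeasiblePoint(W=2.0, alpha=0.0, beta=0.0, A=0.25)
        before, after = shares_at_point(p)
        assert before == pytest.approx((0.25, 0.5, 0.25))
        assert after == pytest.approx((0.125, 0.5, 0.375))

    @given(feasible_points)
    @settings(max_examples=300, deadline=None)
    def test_both_triples_sum_to_one(self, p):
        if p is None:
            return
        before, after = shares_at_point(p)
        assert sum(before) == pytest.approx(1.0, abs=1e-9)
        assert sum(after) == pytest.approx(1.0, abs=1e-9)


class TestMeanStructure:
    def test_limit_w1(self):
        s = mean_structure(1.0)
        assert s.before == (1, 0, 0) and s.after == (1, 0, 0)

    def test_limit_w3(self):
        s = mean_structure(3.0)
        assert s.after == (0, 0, 1)

    @pytest.mark.parametrize("W", W_GRID)
    def test_shares_sum_to_one_and_balance(self, W):
        s = mean_structure(W, resolution=200)
        assert sum(s.before) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.after) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= v <= 1 for v in s.before + s.after)

    @pytest.mark.parametrize("W", [1.3, 2.0, 2.7])
    def test_mean_hydrolysis_balance(self, W):
        """E[x] + 2 E[y] = W - 1 under the uniform measure: recover the mean
        x and y from the reported shares and check the linear balance."""
        s = mean_structure(W, resolution=400)
        # x_prime = E[x (2 + 1.5 alpha)]/W and similar terms are entangled
        # with alpha, beta; use the before/after difference instead:
        # T*after - before = (0, x, 2y) componentwise in absolute units.
        mean_x = W * s.x_prime - s.x_star
        mean_2y = W * s.y_prime - s.y_star
        assert mean_x + mean_2y == pytest.approx(W - 1.0, abs=1e-9)

    @pytest.mark.parametrize("W", W_GRID)
    def test_mc_and_quadrature_agree(self, W):
        """The rejection sampler is an independent oracle for the nested
        quadrature; all six shares must agree within 0.005 at n = 1e6."""
        q = mean_structure(W, method="quadrature", resolution=400)
        m = mean_structure(W, method="mc", n_samples=1_000_000, seed=20240601)
        for a, b in zip(q.before + q.after, m.before + m.after):
            assert a == pytest.approx(b, abs=0.005)

    def test_mc_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            mean_structure(2.0, method="mc")

    def test_monotone_in_w(self):
        """Along W, the after-hydrolysis tripeptide share grows and the free
        share shrinks: more hydrolysis gain means more peptide signal."""
        grid = np.linspace(1.0, 3.0, 41)
        shares = [mean_structure(float(w), resolution=200) for w in grid]
        a_prime = [s.a_prime for s in shares]
        y_prime = [s.y_prime for s in shares]
        assert all(np.diff(a_prime) <= 1e-12)
        assert all(np.diff(y_prime) >= -1e-12)

    def test_w_out_of_range(self):
        with pytest.raises(ValueError):
            mean_structure(0.5)


class TestSupremumOfW:
    def test_ceiling_is_three_attained_only_by_single_amine_tripeptides(self):
        """Brute-force scan over a composition grid: T/F never exceeds 3,
        and the ratio approaches 3 only as the y1 class dominates."""
        best = 0.0
        grid = np.linspace(0, 1, 6)
        from itertools import product
        from aminogram import Composition

        for fields in product(grid, repeat=4):
            # scan A, one dipeptide class, and two tripeptide classes at a
            # time to keep the grid tractable; class ratios T/F are what
            # matters and every class appears in some slice
            for names in (("A", "x1", "y1", "y2"), ("x2", "x3", "y3", "y4"),
                          ("A", "x3", "y1", "y4")):
                c = Composition(**dict(zip(names, fields)))
                r = forward_readings(c)
                if r.F > 0:
                    ratio = r.T / r.F
                    assert ratio <= 3.0 + 1e-12
                    best = max(best, ratio)
        assert best == pytest.approx(3.0)
        pure_y1 = forward_readings(Composition(y1=1.0))
        assert pure_y1.T / pure_y1.F == pytest.approx(3.0)
        # every other pure class stays strictly below 3
        for name in ("A", "x1", "x2", "x3", "y2", "y3", "y4"):
            r = forward_readings(Composition(**{name: 1.0}))
            assert r.T / r.F < 3.0


class TestDecomposeReading:
    def test_pure_free(self):
        split = decompose_reading(AmineReadings(F=1, T=1))
        assert (split.free, split.dipeptide_derived, split.tripeptide_derived) == (1, 0, 0)

    def test_w3_limit_scaled_by_T(self):
        split = decompose_reading(AmineReadings(F=2, T=6))
        assert split.tripeptide_derived == pytest.approx(6.0)
        assert split.free == split.dipeptide_derived == 0.0

    def test_matches_mean_structure_scaled(self):
        split = decompose_reading(AmineReadings(F=1, T=2))
        s = mean_structure(2.0)
        assert split.free == pytest.approx(2 * s.a_prime)
        assert split.dipeptide_derived == pytest.approx(2 * s.x_prime)
        assert split.tripeptide_derived == pytest.approx(2 * s.y_prime)
        assert split.total == pytest.approx(2.0, rel=1e-9)

    def test_flags_propagate(self):
        split = decompose_reading(AmineReadings(F=1, T=3.5))
        assert FLAG_LONGER_PEPTIDES in split.flags


class TestLegacyEstimator:
    def test_f_over_w(self):
        assert legacy_free_fraction(AmineReadings(F=2.0, T=4.0)) == pytest.approx(1.0)

    def test_disagrees_with_mean_structure_in_general(self):
        r = AmineReadings(F=1.0, T=2.0)
        split = decompose_reading(r)
        assert legacy_free_fraction(r) != pytest.approx(split.free, abs=0.01)
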