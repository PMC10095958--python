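"""Stretch-and-translate registration: transforms, imputation, scoring, search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronoreg.registration import (RegistrationGrid, _GeneSeries, impute_linear,
                                    register_cohort, register_pair, results_table,
                                    score_candidate, transform_times)


class TestTransform:
    def test_arithmetic(self):
        assert transform_times(7.0, 1.0, 0.0) == pytest.approx(7.0)
        assert transform_times(7.0, 2.0, 3.0) == pytest.approx(17.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(stretch=st.floats(min_value=0.01, max_value=10.0),
           shift=st.floats(min_value=-100.0, max_value=100.0))
    def test_order_preserved(self, stretch, shift):
        t = np.array([1.0, 2.0, 5.0, 9.0])
        out = transform_times(t, stretch, shift)
        assert (np.diff(out) > 0).all()


class TestImpute:
    def test_midpoint_and_observed(self):
        assert impute_linear([0.0, 2.0], [0.0, 4.0], [1.0])[0] == pytest.approx(2.0)
        assert impute_linear([0.0, 2.0], [0.0, 4.0], [2.0])[0] == pytest.approx(4.0)

    def test_segment_slope(self):
        # segment (1,1)-(3,5): slope 2, value at 2 is 3
        assert impute_linear([0.0, 1.0, 3.0], [0.0, 1.0, 5.0], [2.0])[0] == pytest.approx(3.0)

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            impute_linear([0.0, 2.0], [0.0, 4.0], [3.0])


def _series(times, values):
    return _GeneSeries(np.asarray(times, float), np.asarray(values, float))


class TestScoreCandidate:
    def test_identical_series_scores_zero(self):
        t = np.arange(10, dtype=float)
        v = np.sin(t / 3.0) + 2.0
        s = _series(t, v)
        score, window, overlap = score_candidate(s, s, 1.0, 0.0)
        assert score == pytest.approx(0.0, abs=1e-12)
        assert len(overlap) == 10

    def test_linear_shape_stretch_candidate_exact(self):
        # B = f(t) = t on a dense grid; A = f(2t): candidate (2, 0) scores ~0
        tb = np.arange(0.0, 21.0)
        ta = np.arange(0.0, 10.5, 0.5)
        sa = _series(ta, 2.0 * ta)
        sb = _series(tb, tb)
        score, _, _ = score_candidate(sa, sb, 2.0, 0.0)
        assert score < 1e-12

    def test_empty_overlap_rejected(self):
        sa = _series([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        sb = _series([50.0, 51.0, 52.0, 53.0], [1.0, 2.0, 3.0, 4.0])
        assert score_candidate(sa, sb, 1.0, 0.0) is None

    def test_zero_variance_on_overlap_rejected(self):
        sa = _series(np.arange(8.0), np.ones(8))
        sb = _series(np.arange(8.0), np.arange(8.0))
        assert score_candidate(sa, sb, 1.0, 0.0) is None


class TestRegisterPair:
    def test_identical_series_identity_transform(self):
        t = np.arange(12, dtype=float)
        v = np.cos(t / 4.0)
        r = register_pair((t, v), (t, v))
        assert (r.stretch, r.shift) == (1.0, 0.0)
        assert r.score == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_transform(self, noise_free_cohort):
        expr_a, expr_b, pairs, truth = noise_free_cohort
        results = register_cohort(expr_a, expr_b, pairs)
        table = results_table(results).merge(truth.genes.reset_index(), on="gene_b")
        assert (table["stretch_x"] == table["stretch_y"]).all()
        assert (table["shift_x"] == table["shift_y"]).all()

    def test_boundary_candidate_stays_on_grid(self):
        from chronoreg import SyntheticConfig, simulate_expression_pair
        cfg = SyntheticConfig(n_genes=5, n_groups=1, group_params=((2.0, -4.0),),
                              noise_sd=0.0, count_dispersion=0.0,
                              contamination_fraction=0.0, seed=3)
        expr_a, expr_b, pairs, _ = simulate_expression_pair(cfg)
        grid = RegistrationGrid()
        for r in register_cohort(expr_a, expr_b, pairs, grid=grid):
            assert r.stretch in grid.stretches
            assert grid.shift_min <= r.shift <= grid.shift_max
            assert (r.stretch, r.shift) == (2.0, -4.0)

    def test_all_rejected_flags_unregistrable(self):
        t = np.arange(6, dtype=float)
        r = register_pair((t, np.ones(6)), (t, np.arange(6.0)))
        assert r.flag == "unregistrable"
        assert np.isnan(r.score)

    def test_exhaustive_search_matches_independent_enumeration(self, noisy_cohort):
        expr_a, expr_b, pairs, _ = noisy_cohort
        grid = RegistrationGrid()
        sub = pairs.pairs.head(15)
        for ga, gb in sub.itertuples(index=False):
            sa = _GeneSeries.from_expression(expr_a, ga)
            sb = _GeneSeries.from_expression(expr_b, gb)
            r = register_pair(sa, sb, grid=grid, gene_a=ga, gene_b=gb)
            # independent enumeration of every candidate on the grid
            best = np.inf
            for stretch, shift in itertools.product(grid.stretches,
                                                    np.arange(-4.0, 5.0)):
                out = score_candidate(sa, sb, stretch, shift)
                if out is not None:
                    best = min(best, out[0])
            if r.flag == "ok":
                assert r.score == pytest.approx(best, rel=1e-12)

    def test_chosen_score_never_worse_than_identity(self, noisy_cohort):
        expr_a, expr_b, pairs, _ = noisy_cohort
        for ga, gb in pairs.pairs.head(20).itertuples(index=False):
            sa = _GeneSeries.from_expression(expr_a, ga)
            sb = _GeneSeries.from_expression(expr_b, gb)
            identity = score_candidate(sa, sb, 1.0, 0.0)
            r = register_pair(sa, sb)
            if identity is not None and r.flag == "ok":
                assert r.score <= identity[0] + 1e-12


class TestInvariances:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(c=st.floats(min_value=0.05, max_value=20.0),
           d=st.floats(min_value=-100.0, max_value=100.0))
    def test_affine_invariance_of_registration(self, c, d, noise_free_cohort):
        expr_a, expr_b, pairs, _ = noise_free_cohort
        ga, gb = pairs.pairs.iloc[0]
        ta, va = expr_a.gene_series(ga)
        tb, vb = expr_b.gene_series(gb)
        r0 = register_pair((ta, va), (tb, vb))
        r1 = register_pair((ta, c * va + d), (tb, vb))
        assert (r0.stretch, r0.shift) == (r1.stretch, r1.shift)
        assert r0.score == pytest.approx(r1.score, rel=1e-6, abs=1e-9)

    def test_shift_equivariance(self, noise_free_cohort):
        # moving every query timestamp by delta moves the optimal shift by
        # -stretch * delta, leaving the score unchanged
        expr_a, expr_b, pairs, truth = noise_free_cohort
        target = truth.genes[(truth.genes["stretch"] == 1.0)].index
        gb = target[0]
        ga = pairs.pairs.set_index("gene_b").loc[gb, "gene_a"]
        ta, va = expr_a.gene_series(ga)
        tb, vb = expr_b.gene_series(gb)
        r0 = register_pair((ta, va), (tb, vb))
        delta = 2.0
        r1 = register_pair((ta + delta, va), (tb, vb))
        assert r1.stretch == r0.stretch
        assert r1.shift == pytest.approx(r0.shift - r0.stretch * delta)
        assert r1.score == pytest.approx(r0.score, abs=1e-10)


class TestGrid:
    def test_shifts_inclusive_of_bounds(self):
        g = RegistrationGrid(shift_min=-4, shift_max=4, shift_step=1)
        assert g.shifts.tolist() == list(range(-4, 5))
        assert len(g.candidates()) == 27

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            RegistrationGrid(stretches=())
        with pytest.raises(ValueError):
            RegistrationGrid(shift_min=3, shift_max=-3)
        with pytest.raises(ValueError):
            RegistrationGrid(shift_step=0)
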