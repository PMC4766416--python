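"""Box-Behnken generation, factor coding, OLS fitting and canonical analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import degratrace as dt
from degratrace.doe_rsm import (
    DEFAULT_FACTORS,
    FULL_TERMS,
    SingularDesignError,
    UnsupportedDesignError,
    _model_columns,
)

from conftest import grid_argmax_2d


class TestDesignGeneration:
    @pytest.mark.parametrize("n_center,expected_runs", [(3, 15), (1, 13), (5, 17)])
    def test_run_counts(self, n_center, expected_runs):
        dm = dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=n_center)
        assert dm.n_runs == expected_runs
        n_zero = int(np.sum(np.all(dm.runs == 0, axis=1)))
        assert n_zero == n_center

    def test_edge_runs_enumerate_all_pair_combinations(self):
        """The 12 non-center runs are exactly the +-1 pairs over the 3 factor
        pairs, each with the remaining factor at 0 (brute-force enumeration)."""
        dm = dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=1)
        edges = {tuple(r) for r in dm.runs if any(r)}
        expected = set()
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            for a in (-1.0, 1.0):
                for b in (-1.0, 1.0):
                    row = [0.0, 0.0, 0.0]
                    row[i], row[j] = a, b
                    expected.add(tuple(row))
        assert edges == expected and len(edges) == 12
        for r in dm.runs:
            if any(r):
                assert sum(1 for v in r if v == 0.0) == 1

    def test_rejects_bad_arguments(self):
        with pytest.raises(UnsupportedDesignError):
            dt.generate_box_behnken(list(DEFAULT_FACTORS[:2]), n_center=3)
        with pytest.raises(ValueError):
            dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=0)


class TestCoding:
    @pytest.mark.parametrize(
        "factor,physical,coded",
        [
            (DEFAULT_FACTORS[0], 30.0, 0.0),
            (DEFAULT_FACTORS[0], 20.0, -1.0),
            (DEFAULT_FACTORS[0], 40.0, 1.0),
            (DEFAULT_FACTORS[1], 7.0, 0.0),
            (DEFAULT_FACTORS[2], 0.25, 0.5),
        ],
    )
    def test_code_decode_anchor_points(self, factor, physical, coded):
        assert dt.code_value(factor, physical) == pytest.approx(coded, abs=1e-12)
        assert dt.decode_value(factor, coded) == pytest.approx(physical, abs=1e-12)

    @pytest.mark.parametrize("factor", DEFAULT_FACTORS, ids=lambda f: f.name)
    @pytest.mark.parametrize("x", [-1.0, -0.5, 0.0, 0.5, 1.0])
    def test_round_trip(self, factor, x):
        assert dt.code_value(factor, dt.decode_value(factor, x)) == pytest.approx(
            x, abs=1e-12
        )

    def test_invalid_factor_ordering_rejected(self):
        with pytest.raises(ValueError):
            dt.FactorDef("bad", 9.0, 7.0, 5.0)

    def test_off_midpoint_center_warns_and_is_piecewise(self):
        with pytest.warns(UserWarning, match="piecewise"):
            f = dt.FactorDef("skew", 0.0, 1.0, 4.0)
        assert dt.decode_value(f, -0.5) == pytest.approx(0.5)
        assert dt.decode_value(f, 0.5) == pytest.approx(2.5)
        assert dt.code_value(f, dt.decode_value(f, 0.7)) == pytest.approx(0.7)


class TestFitQuadratic:
    def test_exact_recovery_of_noise_free_surface(self):
        """A response generated from a known 10-term quadratic is recovered
        to machine precision (the design supports the full model)."""
        dm = dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=3)
        truth = np.array([4.2, 1.5, -0.8, 0.3, -1.1, -0.9, 0.2, 0.6, -0.4, 0.15])
        y = _model_columns(dm.runs, FULL_TERMS) @ truth
        model = dt.fit_quadratic(dt.ResponseTable(design=dm, response=y))
        np.testing.assert_allclose(model.coef, truth, atol=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_residual_orthogonality(self, bbd_table, full_model):
        X = _model_columns(bbd_table.design.runs, full_model.terms)
        resid = bbd_table.response - X @ full_model.coef
        assert np.max(np.abs(X.T @ resid)) <= 1e-8

    def test_singular_design_raises_naming_terms(self):
        dm = dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=3)
        # duplicate a run set too small for 10 terms by restricting to 9 rows
        small = dt.DesignMatrix(factors=dm.factors, runs=dm.runs[:9])
        table = dt.ResponseTable(design=small, response=np.ones(9))
        with pytest.raises(SingularDesignError):
            dt.fit_quadratic(table)

    def test_center_only_design_is_collinear(self):
        runs = np.zeros((12, 3))
        table = dt.ResponseTable(
            design=dt.DesignMatrix(factors=DEFAULT_FACTORS, runs=runs),
            response=np.ones(12),
        )
        with pytest.raises(SingularDesignError, match="collinear"):
            dt.fit_quadratic(table)


class TestPruneInteractions:
    def test_table_prunes_weak_interactions_only(self, bbd_table, full_model):
        """On the triclosan experiment the temperature-biomass and
        pH-biomass interactions are negligible and removed; the
        temperature-pH interaction is significant and retained."""
        pruned = dt.prune_interactions(full_model, bbd_table, alpha=0.05)
        assert set(pruned.interaction_terms) == {"x1*x2"}
        # main effects and quadratics always survive
        for t in ("x1", "x2", "x3", "x1^2", "x2^2", "x3^2"):
            assert t in pruned.terms

    def test_noop_when_all_interactions_significant(self):
        dm = dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=3)
        truth = np.array([4.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, 2.0, 2.0, 2.0])
        y = _model_columns(dm.runs, FULL_TERMS) @ truth
        rng = np.random.default_rng(7)
        table = dt.ResponseTable(design=dm, response=y + rng.normal(0, 0.01, len(y)))
        full = dt.fit_quadratic(table)
        pruned = dt.prune_interactions(full, table, alpha=0.05)
        assert pruned.terms == full.terms
        np.testing.assert_array_equal(pruned.coef, full.coef)

    def test_r_squared_never_increases(self, bbd_table, full_model):
        for alpha in (0.01, 0.05, 0.5, 0.99):
            pruned = dt.prune_interactions(full_model, bbd_table, alpha=alpha)
            assert pruned.r_squared <= full_model.r_squared + 1e-12


class TestStationaryPoint:
    def test_simple_maximum(self):
        model = _toy_model([5.0, 0.0, 0.0, -1.0, -1.0, 0.0])
        sp = dt.stationary_point(model)
        assert sp.nature == "maximum"
        np.testing.assert_allclose(sp.coded, [0.0, 0.0], atol=1e-12)
        assert sp.predicted == pytest.approx(5.0)

    def test_positive_definite_minimum(self):
        model = _toy_model([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        sp = dt.stationary_point(model)
        assert sp.nature == "minimum"
        np.testing.assert_allclose(sp.coded, [0.0, 0.0], atol=1e-12)

    def test_saddle(self):
        model = _toy_model([0.0, 0.0, 0.0, 1.0, -1.0, 0.0])
        assert dt.stationary_point(model).nature == "saddle"

    def test_degenerate_surface_reports_ridge(self):
        model = _toy_model([1.0, 0.5, 0.0, -1.0, 0.0, 0.0])
        sp = dt.stationary_point(model)
        assert sp.nature == "degenerate"
        assert sp.coded is None and sp.predicted is None
        assert "ridge" in sp.message

    def test_matches_grid_argmax_on_fitted_surface(self, bbd_table, full_model):
        """Canonical analysis of the triclosan fit (biomass fixed at its
        center) agrees with brute-force grid search over the coded square."""
        sp = dt.stationary_point(full_model, fixed={"x3": 0.0})
        assert sp.nature == "maximum"
        m = full_model

        def surface(x, y):
            return (
                m["const"] + m["x1"] * x + m["x2"] * y
                + m["x1^2"] * x**2 + m["x2^2"] * y**2 + m["x1*x2"] * x * y
            )

        best, _ = grid_argmax_2d(surface)
        np.testing.assert_allclose(sp.coded, best, atol=2e-3)

    def test_fixed_factor_substitution_shifts_gradient(self):
        # with x2 fixed at 1 the x1 optimum moves by -b12/(2*b11) relative terms
        model = _toy_model([0.0, 2.0, 0.0, -1.0, -1.0, 1.0])
        sp = dt.stationary_point(model, fixed={"x2": 1.0})
        # dY/dx1 = 2 - 2 x1 + x2 = 0 at x1 = 1.5 when x2 = 1
        np.testing.assert_allclose(sp.coded, [1.5], atol=1e-12)
        assert sp.fixed == {"f2": 1.0}


class TestPredict:
    def test_intercept_only_behaviour(self, full_model, bbd_table):
        assert dt.predict(full_model, [0.0, 0.0, 0.0]) == pytest.approx(
            full_model["const"]
        )

    def test_clamping(self, full_model):
        raw = dt.predict(full_model, [1.0, 1.0, 0.0])
        clamped = dt.predict(full_model, [1.0, 1.0, 0.0], clamp=(0.0, 5.0))
        assert clamped == min(max(raw, 0.0), 5.0)

    def test_dimension_mismatch_rejected(self, full_model):
        with pytest.raises(ValueError):
            dt.predict(full_model, [0.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(
    coef=st.lists(st.floats(-3, 3), min_size=10, max_size=10),
    x=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
)
def test_predict_matches_direct_polynomial(coef, x):
    """predict() equals explicit term-by-term evaluation of the polynomial."""
    dm = dt.generate_box_behnken(list(DEFAULT_FACTORS), n_center=3)
    y = _model_columns(dm.runs, FULL_TERMS) @ np.asarray(coef)
    model = dt.fit_quadratic(dt.ResponseTable(design=dm, response=y))
    x1, x2, x3 = x
    direct = (
        coef[0] + coef[1] * x1 + coef[2] * x2 + coef[3] * x3
        + coef[4] * x1**2 + coef[5] * x2**2 + coef[6] * x3**2
        + coef[7] * x1 * x2 + coef[8] * x1 * x3 + coef[9] * x2 * x3
    )
    assert dt.predict(model, x) == pytest.approx(direct, abs=1e-6)


def _toy_model(coef6, names=("f1", "f2")):
    """Two-factor quadratic model with given (b0, b1, b2, b11, b22, b12)."""
    factors = tuple(dt.FactorDef(n, -1.0, 0.0, 1.0) for n in names)
    terms = ("const", "x1", "x2", "x1^2", "x2^2", "x1*x2")
    z = np.zeros(6)
    return dt.QuadraticModel(
        factors=factors,
        terms=terms,
        coef=np.asarray(coef6, dtype=float),
        stderr=z,
        tvalues=z,
        pvalues=z,
        r_squared=1.0,
        df_resid=0,
        n_runs=6,
    )
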