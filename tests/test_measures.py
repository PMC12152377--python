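import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import combisens as cs
from combisens import measures as ms


class TestViabilityConversion:
    @pytest.mark.parametrize(
        "inhibition,expected",
        [(0.0, 1.0), (100.0, 0.0), (-200.0, 1.0), (200.0, 0.0), (50.0, 0.5)],
    )
    def test_conversion_and_clamping(self, inhibition, expected):
        assert cs.inhibition_to_viability(inhibition) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cs.inhibition_to_viability(float("nan"))


class TestFit3PL:
    def test_noiseless_recovery(self):
        b, c, e = 1.2, 0.1, 0.5
        x = np.array([0.05, 0.15, 0.5, 1.5, 5.0, 15.0])
        v = c + (1 - c) / (1 + np.exp(b * (np.log(x) - np.log(e))))
        fit = cs.fit_3pl(x, v)
        assert abs(fit.b - b) < 1e-6
        assert abs(fit.c - c) < 1e-6
        assert abs(fit.e - e) < 1e-6
        assert fit.rmse < 1e-8

    def test_minimum_points_enforced(self):
        out = cs.fit_3pl([0.1, 1, 10, 100], [0.9, 0.7, 0.4, 0.2])
        assert isinstance(out, cs.RejectedFit)
        assert out.reason == "min_points"

    def test_flat_data_flagged_degenerate(self):
        x = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        fit = cs.fit_3pl(x, np.ones(5))
        assert isinstance(fit, cs.CurveFit3PL)
        assert fit.degenerate_flat
        assert fit.c == pytest.approx(1.0, abs=1e-6)
        assert fit.rmse < 1e-8

    def test_high_rmse_rejected(self):
        rng = np.random.default_rng(0)
        x = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        v = rng.uniform(0, 1, 6)  # incoherent data
        out = cs.fit_3pl(x, v, rmse_max=0.05)
        assert isinstance(out, cs.RejectedFit) and out.reason == "rmse"

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cs.fit_3pl([0.0, 1, 2, 3, 4], [1, 0.9, 0.8, 0.7, 0.6])


class TestCurveEval:
    def test_inflection_midpoint(self):
        fit = ms.CurveFit3PL(b=2.0, c=0.2, e=1.5, rmse=0, n_points=6)
        assert cs.curve_eval(fit, 1.5) == pytest.approx(0.2 + 0.8 / 2)

    def test_zero_limit_is_one(self):
        fit = ms.CurveFit3PL(b=1.0, c=0.0, e=1.0, rmse=0, n_points=6)
        assert cs.curve_eval(fit, 0.0) == 1.0
        assert cs.curve_eval(fit, 1.0) == pytest.approx(0.5)

    @given(
        b=st.floats(0.3, 5.0),
        c=st.floats(0.0, 0.9),
        e=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_strictly_decreasing(self, b, c, e):
        fit = ms.CurveFit3PL(b=b, c=c, e=e, rmse=0, n_points=6)
        x = np.logspace(-3, 3, 50)
        v = cs.curve_eval(fit, x)
        # monotone non-increasing everywhere (flat stretches only where the
        # curve has saturated to 1 or c in float precision), strictly
        # decreasing around the inflection
        assert np.all(np.diff(v) <= 0)
        assert cs.curve_eval(fit, e * 0.9) > cs.curve_eval(fit, e * 1.1)


class TestICLevel:
    def test_ic50_at_inflection_when_c_zero(self):
        fit = ms.CurveFit3PL(b=1.0, c=0.0, e=2.0, rmse=0, n_points=6)
        assert cs.ic_level(fit, 50.0) == pytest.approx(2.0)

    def test_undefined_when_asymptote_above_line(self):
        fit = ms.CurveFit3PL(b=1.0, c=0.6, e=2.0, rmse=0, n_points=6)
        assert cs.ic_level(fit, 50.0) is None

    def test_closed_form_matches_root_finder(self):
        fit = ms.CurveFit3PL(b=2.0, c=0.25, e=1.0, rmse=0, n_points=6)
        x = cs.ic_level(fit, 50.0)
        xb = brentq(lambda t: cs.curve_eval(fit, t) - 0.5, 1e-9, 1e9, xtol=1e-15)
        assert abs(x - xb) < 1e-9

    @pytest.mark.parametrize("level", [50.0, 25.0, 10.0])
    def test_inversion_identity(self, level):
        fit = ms.CurveFit3PL(b=1.7, c=0.05, e=0.8, rmse=0, n_points=6)
        x = cs.ic_level(fit, level)
        assert cs.curve_eval(fit, x) == pytest.approx((100 - level) / 100, abs=1e-9)


class TestCMaxViability:
    def test_half_viability_at_inflection_cmax(self):
        fit = ms.CurveFit3PL(b=1.0, c=0.0, e=3.0, rmse=0, n_points=6)
        v, extrap = cs.cmax_viability(fit, 3.0, max_screened_conc=10.0)
        assert v == pytest.approx(0.5)
        assert not extrap

    def test_extrapolation_flagged(self):
        fit = ms.CurveFit3PL(b=1.0, c=0.0, e=3.0, rmse=0, n_points=6)
        _, extrap = cs.cmax_viability(fit, 20.0, max_screened_conc=10.0)
        assert extrap

    def test_inert_drug_stays_near_one(self):
        x = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        fit = cs.fit_3pl(x, np.ones(5))
        v, _ = cs.cmax_viability(fit, 100.0)
        assert v == pytest.approx(1.0, abs=1e-6)


def combo_entries(cell="C1"):
    """3x3 combination design plus both monotherapy series."""
    rows = []
    for ca in (1.0, 2.0, 4.0):
        rows.append((cell, "A", None, ca, 0.0, 100 * (1 - 0.9 ** ca)))
    for cb in (0.5, 1.0, 2.0):
        rows.append((cell, "B", None, cb, 0.0, 100 * (1 - 0.8 ** cb)))
    for ca in (1.0, 2.0, 4.0):
        for cb in (0.5, 1.0, 2.0):
            v = 0.9 ** ca * 0.8 ** cb
            rows.append((cell, "A", "B", ca, cb, 100 * (1 - v)))
    return pd.DataFrame(
        rows,
        columns=["cell_line", "drug_row", "drug_col", "conc_row", "conc_col", "inhibition"],
    )


class TestAssembleMatrix:
    def test_full_design_gives_4x4_with_margins(self):
        m = cs.assemble_matrix(combo_entries(), "C1", "A", "B")
        assert m.viability.shape == (4, 4)
        assert m.row_concs[0] == 0 and m.col_concs[0] == 0
        assert m.viability[0, 0] == 1.0
        assert m.complete

    def test_missing_margin_flagged(self):
        df = combo_entries()
        df = df[~((df["drug_row"] == "B") & df["drug_col"].isna())]
        m = cs.assemble_matrix(df, "C1", "A", "B")
        assert not m.complete
        assert m.missing[0, 1:].all()  # zero-row margin for drug B absent
        assert m.viability[0, 0] == 1.0

    def test_margin_values_come_from_monotherapies(self):
        m = cs.assemble_matrix(combo_entries(), "C1", "A", "B")
        assert m.viability[1, 0] == pytest.approx(0.9 ** 1.0)
        assert m.viability[0, 1] == pytest.approx(0.8 ** 0.5)


class TestCombinationCMaxViability:
    def test_constant_surface(self):
        concs = np.array([0.0, 1.0, 2.0])
        V = np.full((3, 3), 0.4)
        m = ms.DoseResponseMatrix("C", "A", "B", concs, concs, V, np.zeros((3, 3), bool))
        v, clamped = cs.combination_cmax_viability(m, 2.0, 2.0)
        assert v == pytest.approx(0.4)
        assert not clamped

    def test_separable_monotone_minimum_at_corner(self):
        ra = np.array([0.0, 1.0, 2.0, 4.0])
        cb = np.array([0.0, 0.5, 1.0, 2.0])
        vA = 0.9 ** ra
        vB = 0.8 ** cb
        V = np.outer(vA, vB)
        m = ms.DoseResponseMatrix("C", "A", "B", ra, cb, V, np.zeros(V.shape, bool))
        v, _ = cs.combination_cmax_viability(m, 4.0, 2.0)
        assert v == pytest.approx(vA[-1] * vB[-1])

    def test_synergy_pocket_vs_dense_oracle(self):
        rng = np.random.default_rng(5)
        ra = np.concatenate([[0.0], np.sort(rng.uniform(0.2, 8, 5))])
        cb = np.concatenate([[0.0], np.sort(rng.uniform(0.2, 8, 5))])
        V = np.outer(0.95 ** ra, 0.9 ** cb)
        V[3, 3] *= 0.3  # interior pocket of extra effect
        m = ms.DoseResponseMatrix("C", "A", "B", ra, cb, V, np.zeros(V.shape, bool))
        v, _ = cs.combination_cmax_viability(m, ra[-1], cb[-1], grid_n=100)
        oracle, _ = cs.combination_cmax_viability(m, ra[-1], cb[-1], grid_n=1000)
        res = max(np.abs(np.diff(V, axis=0)).max(), np.abs(np.diff(V, axis=1)).max())
        assert v == pytest.approx(oracle, abs=res)
        # the pocket drags the minimum below the corner product
        assert v < 0.95 ** ra[-1] * 0.9 ** cb[-1]

    def test_enlarging_box_never_increases_minimum(self):
        rng = np.random.default_rng(2)
        concs = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        V = rng.uniform(0.2, 1.0, (5, 5))
        V[0, 0] = 1.0
        m = ms.DoseResponseMatrix("C", "A", "B", concs, concs, V, np.zeros((5, 5), bool))
        # monotone for the exact minimum; the lattice approximation can
        # wobble by at most its own resolution, so use a fine grid and a
        # matching tolerance
        prev = np.inf
        for box in (1.0, 2.0, 4.0, 8.0):
            v, _ = cs.combination_cmax_viability(m, box, box, grid_n=500)
            assert v <= prev + 0.01
            prev = v

    def test_cmax_beyond_range_clamps_or_raises(self):
        concs = np.array([0.0, 1.0, 2.0])
        V = np.full((3, 3), 0.5)
        m = ms.DoseResponseMatrix("C", "A", "B", concs, concs, V, np.zeros((3, 3), bool))
        v, clamped = cs.combination_cmax_viability(m, 5.0, 1.0)
        assert clamped
        with pytest.raises(ValueError, match="exceeds"):
            cs.combination_cmax_viability(m, 5.0, 1.0, clamp=False)


class TestCurveRMSEReport:
    def test_noiseless_summary(self):
        x = np.logspace(-1, 1, 6)
        fits = [
            cs.fit_3pl(x, 0.1 + 0.9 / (1 + np.exp(b * np.log(x / 1.0))))
            for b in (0.8, 1.2, 2.0)
        ]
        rep = cs.curve_rmse_report(fits)
        assert rep["mean_rmse"] == pytest.approx(0.0, abs=1e-8)
        assert rep["fraction_below_0.3"] == 1.0

    def test_empty_after_rejection(self):
        assert cs.curve_rmse_report([cs.RejectedFit("min_points")]) is None
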