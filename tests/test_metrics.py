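"""Evaluation-statistics suite checked against a published benchmark table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhoct.benchmark import benchmark_estimates
from rhoct.metrics import (
    correlation_regression,
    dose_consistency,
    evaluate,
    identity_test,
    paired_t_test,
    percent_error,
    rmse_nrmse,
)

# %Error cells of the published per-insert benchmark, printed to 0.01
# percentage points; regenerating them pins our Eq. definitions.
PRINTED_PCT_LEHMANN = [
    -1.24, -0.54, 0.16, 0.63, 0.63, 1.79, 1.62, 3.64, 1.66, 1.40, 0.86, -6.82,
    1.45, 0.73, 1.22, 1.60, 1.48, 1.52,
]
PRINTED_PCT_SAITO = [
    0.35, 0.07, -0.31, -0.18, -0.09, -0.09, -0.57, 1.92, -0.21, -0.54, 1.07,
    -3.41, -0.96, -1.61, -1.05, -0.60, -0.63, -0.35,
]


class TestPercentError:
    def test_low_density_lung_worked_example(self):
        pct, abs_err = percent_error(0.246, 0.264)
        assert pct == pytest.approx(-6.82, abs=0.005)
        assert abs_err == pytest.approx(-0.018, abs=1e-12)

    def test_water_insert_worked_example(self):
        pct, abs_err = percent_error(1.026, 0.990)
        assert pct == pytest.approx(3.64, abs=0.005)
        assert abs_err == pytest.approx(0.036, abs=1e-12)

    def test_identity_is_zero(self):
        for x in (0.3, 1.0, 1.9):
            assert percent_error(x, x) == (0.0, 0.0)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            percent_error(1.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        est=st.floats(min_value=0.0, max_value=3.0),
        nom=st.floats(min_value=0.05, max_value=3.0),
    )
    def test_sign_consistency(self, est, nom):
        pct, abs_err = percent_error(est, nom)
        assert np.sign(pct) == np.sign(abs_err)

    @pytest.mark.parametrize("method,printed", [
        ("lehmann", PRINTED_PCT_LEHMANN), ("saito", PRINTED_PCT_SAITO),
    ])
    def test_regenerates_every_printed_cell(self, method, printed):
        tab = benchmark_estimates(method)
        pct, _ = percent_error(tab["rho_est"].to_numpy(), tab["rho_nom"].to_numpy())
        assert np.allclose(np.round(pct, 2), printed, atol=1e-9)


class TestAggregates:
    @pytest.mark.parametrize("method,rmse_ref,nrmse_ref", [
        ("lehmann", 0.0166, 1.53), ("saito", 0.0095, 0.87),
    ])
    def test_benchmark_rmse_nrmse(self, method, rmse_ref, nrmse_ref):
        rmse, nrmse = rmse_nrmse(benchmark_estimates(method))
        assert round(rmse, 4) == rmse_ref
        assert round(100 * nrmse, 2) == nrmse_ref

    def test_identical_columns_zero_error(self):
        x = np.array([0.5, 1.0, 1.5])
        assert rmse_nrmse((x, x)) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.1, max_value=3.0), min_size=2, max_size=30))
    def test_nrmse_times_mean_equals_rmse(self, nom):
        nom = np.asarray(nom)
        est = nom * 1.02 + 0.01
        rmse, nrmse = rmse_nrmse((est, nom))
        assert nrmse * nom.mean() == pytest.approx(rmse, rel=1e-12)

    def test_population_denominator(self):
        # RMSE uses 1/N, not 1/(N-1)
        est = np.array([1.1, 0.9])
        nom = np.array([1.0, 1.0])
        rmse, _ = rmse_nrmse((est, nom))
        assert rmse == pytest.approx(0.1)


class TestRegression:
    def test_benchmark_regression_lehmann(self):
        r, beta, eps, r2 = correlation_regression(benchmark_estimates("lehmann"))
        assert round(r, 4) == 0.9993
        assert round(beta, 4) == 1.0028
        assert round(eps, 4) == 0.0063
        assert round(r2, 4) == 0.9986

    def test_benchmark_regression_saito(self):
        r, beta, eps, r2 = correlation_regression(benchmark_estimates("saito"))
        assert round(r, 4) == 0.9997
        assert round(beta, 4) == 0.9952
        assert round(eps, 4) == 0.0016

    def test_exact_line(self):
        nom = np.array([0.5, 1.0, 1.5, 2.0])
        r, beta, eps, r2 = correlation_regression((2 * nom + 1, nom))
        assert (r, r2) == (1.0, 1.0)
        assert beta == pytest.approx(2.0) and eps == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        nom = rng.uniform(0.3, 2.0, 25)
        est = 0.98 * nom + 0.01 + rng.normal(0, 0.01, 25)
        _, beta, eps, _ = correlation_regression((est, nom))
        A = np.column_stack([nom, np.ones_like(nom)])
        ref = np.linalg.solve(A.T @ A, A.T @ est)
        assert beta == pytest.approx(ref[0], rel=1e-10)
        assert eps == pytest.approx(ref[1], rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlation_regression((np.array([1.0, 1.1, 1.2]), np.ones(3)))


class TestPairedT:
    def test_benchmark_tissue_surrogates_not_significant(self):
        tab = benchmark_estimates("lehmann", phantom="gammex467")
        t, df, p = paired_t_test(tab)
        assert df == 11
        assert round(p, 3) == 0.212

    def test_hand_computed_t(self):
        tab = benchmark_estimates("lehmann", phantom="gammex467")
        d = tab["rho_est"].to_numpy() - tab["rho_nom"].to_numpy()
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, _, _ = paired_t_test(tab)
        assert t == pytest.approx(t_ref, rel=1e-12)

    def test_zero_differences(self):
        x = np.array([0.9, 1.1, 1.3])
        assert paired_t_test((x, x)) == (0.0, 2, 1.0)

    def test_constant_nonzero_shift_infinite_t(self):
        nom = np.array([1.0, 1.5, 2.0])
        t, df, p = paired_t_test((nom + 0.1, nom))
        assert np.isinf(t) and p == 0.0


class TestIdentityComparison:
    def test_identity_line_convention(self):
        nom = np.array([0.5, 0.9, 1.3, 1.8])
        assert identity_test((nom.copy(), nom)) == (1.0, 1.0)

    def test_detects_wrong_slope(self):
        rng = np.random.default_rng(14)
        nom = rng.uniform(0.3, 2.0, 50)
        est = 2.0 * nom + rng.normal(0, 0.02, 50)
        p_slope, _ = identity_test((est, nom))
        assert p_slope < 0.05

    def test_accepts_near_identity(self):
        rng = np.random.default_rng(15)
        nom = rng.uniform(0.3, 2.0, 18)
        est = nom + rng.normal(0, 0.02, 18)
        p_slope, p_int = identity_test((est, nom))
        assert p_slope > 0.05 and p_int > 0.05

    def test_row_order_invariance(self):
        tab = benchmark_estimates("lehmann")
        p1 = identity_test(tab)
        shuffled = tab.sample(frac=1.0, random_state=3)
        assert identity_test(shuffled) == pytest.approx(p1)


class TestDoseConsistency:
    @staticmethod
    def _pairs(shift=0.0, seed=0):
        tab = benchmark_estimates("lehmann")[["label", "rho_est", "rho_nom"]].copy()
        rng = np.random.default_rng(seed)
        tab["rho_est"] = tab["rho_est"] + shift + rng.normal(0, 1e-4, len(tab))
        return tab

    def test_identical_estimates_give_p_one(self):
        tab = self._pairs()
        table, (t, df, p) = dose_consistency({30.0: tab, 7.5: tab.copy()})
        assert (t, p) == (0.0, 1.0) and df == 17

    def test_table_rows_and_columns(self):
        by_dose = {d: self._pairs(seed=i) for i, d in enumerate([30.0, 20.0, 10.0, 7.5])}
        table, _ = dose_consistency(by_dose)
        assert list(table.index) == [
            "RMSE", "NRMSE", "Correlation", "Regression beta", "Regression eps",
        ]
        assert list(table.columns) == [7.5, 10.0, 20.0, 30.0]

    def test_label_mismatch_rejected(self):
        a = self._pairs()
        b = self._pairs().iloc[:-1]
        with pytest.raises(ValueError, match="label"):
            dose_consistency({30.0: a, 7.5: b})


class TestEvaluateReport:
    def test_full_report_excluding_known_outlier_inserts(self):
        rep = evaluate(benchmark_estimates("lehmann"))
        assert rep.max_abs_pct_error_excluded == pytest.approx(1.79, abs=0.005)
        assert rep.nrmse * np.mean(rep.per_insert["rho_nom"]) == pytest.approx(
            rep.rmse, rel=1e-12
        )
        text = rep.render()
        assert "RMSE" in text and "0.0166" in text

    def test_saito_exclusion_bound(self):
        rep = evaluate(benchmark_estimates("saito"))
        assert rep.max_abs_pct_error_excluded == pytest.approx(1.61, abs=0.005)
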