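"""Evaluation statistics for electron-density estimates against nominals.

Implements the error suite used in phantom validation studies of
electron-density estimation:

* signed percentage error, %Error = (rho_est - rho_nom)/rho_nom * 100
* RMSE with a population (1/N) denominator, and NRMSE = RMSE / mean(rho_nom)
* Pearson correlation and ordinary least squares rho_est = beta*rho_nom + eps
* identity comparison (is the regression line distinguishable from the
  perfect-measurement line beta = 1, eps = 0?) via Wald t-tests on the OLS
  coefficients
* paired t-test of estimates against nominals, and between dose levels

Report helpers produce per-insert and per-dose tables shaped like the
summary tables of phantom studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "percent_error",
    "rmse_nrmse",
    "correlation_regression",
    "paired_t_test",
    "identity_test",
    "dose_consistency",
    "evaluate",
    "EvalReport",
    "DEFAULT_EXCLUSIONS",
]

#: Inserts conventionally excluded from "excluding inserts" error summaries:
#: the inhomogeneous low-density lung surrogate and the solid-water insert,
#: both known to carry manufacturing-related discrepancies.
DEFAULT_EXCLUSIONS = ("LN-300 lung", "CT water")


def _columns(pairs):
    if isinstance(pairs, pd.DataFrame):
        est = np.asarray(pairs["rho_est"], dtype=float)
        nom = np.asarray(pairs["rho_nom"], dtype=float)
        labels = list(pairs["label"]) if "label" in pairs else list(range(len(est)))
    else:
        est, nom = (np.asarray(a, dtype=float) for a in pairs)
        labels = list(range(len(est)))
    if np.any(nom <= 0):
        raise ValueError("nominal relative electron densities must be positive")
    return labels, est, nom


def percent_error(rho_est, rho_nom):
    """Signed percentage error and absolute (signed) error.

    Returns ``(pct, abs_err)`` where pct = (est - nom)/nom * 100 and
    abs_err = est - nom; the two always share a sign (or are both zero).
    """
    rho_est = np.asarray(rho_est, dtype=float)
    rho_nom = np.asarray(rho_nom, dtype=float)
    if np.any(rho_nom <= 0):
        raise ValueError("nominal density must be positive")
    diff = rho_est - rho_nom
    pct = diff / rho_nom * 100.0
    if pct.ndim:
        return pct, diff
    return float(pct), float(diff)


def rmse_nrmse(pairs):
    """Root mean square error (1/N denominator) and its normalised form."""
    _, est, nom = _columns(pairs)
    if len(est) == 0:
        raise ValueError("need at least one (estimate, nominal) pair")
    rmse = float(np.sqrt(np.mean((est - nom) ** 2)))
    return rmse, rmse / float(np.mean(nom))


def correlation_regression(pairs):
    """Pearson R and OLS fit rho_est = beta*rho_nom + eps.

    Returns ``(pearson_r, beta, eps, r_squared)``; r_squared is the squared
    correlation of the fit.
    """
    _, est, nom = _columns(pairs)
    if len(est) < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.allclose(nom, nom[0]):
        raise ValueError("nominal values have zero variance")
    r = float(stats.pearsonr(nom, est).statistic)
    beta, eps = np.polyfit(nom, est, 1)
    return r, float(beta), float(eps), r * r


def paired_t_test(pairs):
    """Two-sided paired t-test of estimates against nominals.

    Returns ``(t, df, p)``.  Zero-variance differences: t = 0, p = 1 when
    the mean difference is zero; infinite t, p = 0 otherwise.
    """
    _, est, nom = _columns(pairs)
    if len(est) < 2:
        raise ValueError("need at least 2 pairs")
    d = est - nom
    df = len(d) - 1
    if np.allclose(d, d[0]):
        if np.isclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    res = stats.ttest_rel(est, nom)
    return float(res.statistic), df, float(res.pvalue)


def identity_test(pairs):
    """Wald t-tests of the regression line against the identity line.

    Tests H0: beta = 1 and H0: eps = 0 using OLS coefficient standard
    errors — the operational form of comparing a measurement against an
    ideal measurement whose estimates equal the nominals.  Data lying
    exactly on the identity line return (1.0, 1.0) by convention.
    """
    _, est, nom = _columns(pairs)
    if len(est) < 4:
        raise ValueError("need at least 4 pairs for the identity comparison")
    if np.allclose(nom, nom[0]):
        raise ValueError("nominal values have zero variance")
    if np.allclose(est, nom):
        return 1.0, 1.0
    X = sm.add_constant(nom)
    fit = sm.OLS(est, X).fit()
    eps_hat, beta_hat = fit.params
    se_eps, se_beta = fit.bse
    df = fit.df_resid
    p_slope = float(2 * stats.t.sf(abs((beta_hat - 1.0) / se_beta), df))
    p_intercept = float(2 * stats.t.sf(abs(eps_hat / se_eps), df))
    return p_slope, p_intercept


@dataclass
class EvalReport:
    """Per-insert errors plus aggregate statistics for one method/dose."""

    per_insert: pd.DataFrame
    rmse: float
    nrmse: float
    pearson_r: float
    beta: float
    eps: float
    r_squared: float
    t_test: tuple[float, int, float]
    identity: tuple[float, float]
    exclusions: tuple[str, ...] = ()
    max_abs_pct_error_excluded: float = float("nan")

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "RMSE": self.rmse,
                "NRMSE": self.nrmse,
                "Correlation": self.pearson_r,
                "Regression beta": self.beta,
                "Regression eps": self.eps,
                "R squared": self.r_squared,
                "paired t p": self.t_test[2],
            }
        )

    def render(self) -> str:
        """Human-readable table: rho to 3 decimals, %Error to 2, stats to 4."""
        tab = self.per_insert.copy()
        tab["rho_nom"] = tab["rho_nom"].map(lambda v: f"{v:.3f}")
        tab["rho_est"] = tab["rho_est"].map(lambda v: f"{v:.3f}")
        tab["percent_error"] = tab["percent_error"].map(lambda v: f"{v:+.2f}%")
        tab["absolute_error"] = tab["absolute_error"].map(lambda v: f"{v:+.3f}")
        lines = [tab.to_string(index=False), ""]
        lines += [
            f"RMSE            {self.rmse:.4f}",
            f"NRMSE           {self.nrmse * 100:.2f}%",
            f"Correlation R   {self.pearson_r:.4f}",
            f"Regression beta {self.beta:.4f}",
            f"Regression eps  {self.eps:.4f}",
            f"R^2             {self.r_squared:.4f}",
            f"paired t        t={self.t_test[0]:.3f}, df={self.t_test[1]}, p={self.t_test[2]:.3f}",
            f"identity test   p(beta=1)={self.identity[0]:.3f}, p(eps=0)={self.identity[1]:.3f}",
        ]
        if self.exclusions:
            lines.append(
                f"max |%Error| excluding {list(self.exclusions)}: "
                f"{self.max_abs_pct_error_excluded:.2f}%"
            )
        return "\n".join(lines)


def evaluate(pairs, exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS) -> EvalReport:
    """Full evaluation of estimates against nominals.

    ``pairs`` is a DataFrame with columns label, rho_est, rho_nom (or a
     2-tuple of arrays).  ``exclusions`` names inserts left out of the
    "excluding inserts" maximum-percentage-error summary only; all rows
    enter the aggregate statistics.
    """
    labels, est, nom = _columns(pairs)
    pct, abs_err = percent_error(est, nom)
    per_insert = pd.DataFrame(
        {
            "label": labels,
            "rho_nom": nom,
            "rho_est": est,
            "percent_error": pct,
            "absolute_error": abs_err,
        }
    )
    rmse, nrmse = rmse_nrmse((est, nom))
    r, beta, eps, r2 = correlation_regression((est, nom))
    keep = ~per_insert["label"].isin(exclusions)
    max_excl = float(np.max(np.abs(pct[np.asarray(keep)]))) if keep.any() else np.nan
    return EvalReport(
        per_insert=per_insert,
        rmse=rmse,
        nrmse=nrmse,
        pearson_r=r,
        beta=beta,
        eps=eps,
        r_squared=r2,
        t_test=paired_t_test((est, nom)),
        identity=identity_test((est, nom)),
        exclusions=tuple(exclusions),
        max_abs_pct_error_excluded=max_excl,
    )


def dose_consistency(
    pairs_by_dose: dict[float, pd.DataFrame],
    compare: tuple[float, float] | None = None,
):
    """Per-dose aggregate table plus a paired t-test between two doses.

    ``pairs_by_dose`` maps CTDIvol (mGy) to a (label, rho_est, rho_nom)
    table; every dose must carry the same label set.  ``compare`` names the
    two doses whose estimates are paired-tested against each other
    (default: highest vs lowest).

    Returns ``(table, (t, df, p))`` where ``table`` has one column per dose
    and rows RMSE, NRMSE, Correlation, Regression beta, Regression eps.
    """
    doses = sorted(pairs_by_dose)
    frames = {d: pd.DataFrame(pairs_by_dose[d]) for d in doses}
    ref_labels = sorted(frames[doses[0]]["label"])
    for d in doses:
        if sorted(frames[d]["label"]) != ref_labels:
            raise ValueError(f"label set at dose {d} differs from the others")

    rows = {}
    for d in doses:
        f = frames[d]
        rmse, nrmse = rmse_nrmse(f)
        r, beta, eps, _ = correlation_regression(f)
        rows[d] = {
            "RMSE": rmse,
            "NRMSE": nrmse,
            "Correlation": r,
            "Regression beta": beta,
            "Regression eps": eps,
        }
    table = pd.DataFrame(rows)

    if compare is None:
        compare = (max(doses), min(doses))
    a = frames[compare[0]].sort_values("label")["rho_est"].to_numpy(dtype=float)
    b = frames[compare[1]].sort_values("label")["rho_est"].to_numpy(dtype=float)
    d = a - b
    df = len(d) - 1
    if np.allclose(a, b):
        ttest = (0.0, df, 1.0)
    else:
        res = stats.ttest_rel(a, b)
        ttest = (float(res.statistic), df, float(res.pvalue))
    return table, ttest
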