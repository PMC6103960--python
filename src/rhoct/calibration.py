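"""Phantom-calibrated conversion from dual-energy HU pairs to electron density.

Saito's conversion function maps a pair of HU values measured at a low and a
high energy to relative electron density:

    rho_e = a * ((1 + alpha)*HU_H - alpha*HU_L) / 1000 + b,

with scanner-specific parameters (a, b, alpha) obtained by least squares on a
calibration phantom whose nominal densities are known.  The fit is performed
through the exact linear reparameterisation

    rho = c1*HU_H + c2*HU_L + b,   c1 = a*(1+alpha)/1000,  c2 = -a*alpha/1000,

which is an ordinary linear least-squares problem with a closed-form optimum;
(a, alpha) are recovered as a = 1000*(c1 + c2), alpha = -c2/(c1 + c2).  This
is equivalent at the optimum to a generic surface fit but deterministic and
free of starting values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SaitoCalibration",
    "SaitoParams",
    "fit_saito",
    "apply_saito",
    "DLCT_VMI_50_200_PRESET",
]


class SaitoParams(dict):
    """Mapping with attribute access holding (a, b, alpha) and diagnostics."""

    __getattr__ = dict.__getitem__

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SaitoParams(a={self['a']:.6g}, b={self['b']:.6g}, "
            f"alpha={self['alpha']:.6g})"
        )


#: Published scanner-specific fit for 50/200 keV VMIs from a dual-layer CT
#: calibrated on a 12-insert tissue-surrogate phantom at 30 mGy.  The very
#: small |alpha| reflects the large spectral separation of the VMI pair.
DLCT_VMI_50_200_PRESET = SaitoParams(a=0.9704, b=0.9874, alpha=-0.02104)


class SaitoCalibration(BaseEstimator, RegressorMixin):
    """Fit and apply the empirical HU-pair -> electron-density conversion.

    ``X`` has two columns ``(HU_H, HU_L)`` — HU at the low (photoelectric-
    dominated) and high (Compton-dominated) energy — and ``y`` the nominal
    relative electron densities from the phantom datasheet.

    Parameters
    ----------
    collinearity_rcond : float
        Relative condition-number threshold below which the design is
        reported as rank deficient (spectrally indistinguishable columns).

    Attributes
    ----------
    a_, b_, alpha_ : float
        Fitted conversion parameters.
    sse_ : float
        Residual sum of squares at the optimum.
    residuals_ : ndarray
        Per-row residuals (y - prediction).
    """

    def __init__(self, collinearity_rcond: float = 1e-8):
        self.collinearity_rcond = collinearity_rcond

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n_samples, 2), got {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 3:
            raise ValueError(
                f"need at least 3 calibration materials for 3 free parameters, got {len(X)}"
            )
        if np.any(y <= 0):
            raise ValueError("nominal relative electron densities must be positive")
        uniq = pd.DataFrame({"h": X[:, 0], "l": X[:, 1], "r": y}).groupby(["h", "l"])
        if (uniq["r"].nunique() > 1).any():
            raise ValueError(
                "duplicated (HU_H, HU_L) pairs with conflicting nominal densities"
            )

        A = np.column_stack([X, np.ones(len(X))])
        sv = np.linalg.svd(A, compute_uv=False)
        if sv[-1] <= self.collinearity_rcond * sv[0]:
            raise ValueError(
                "calibration design is rank deficient: the two HU columns are "
                "(nearly) collinear — the energy pair provides no spectral "
                "separation, so alpha is not identifiable"
            )
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        c1, c2, b = coef
        if np.isclose(c1 + c2, 0.0):
            raise ValueError(
                "degenerate fit: c1 + c2 = 0 implies gain a = 0; the "
                "calibration data carry no density information"
            )
        self.a_ = float(1000.0 * (c1 + c2))
        self.alpha_ = float(-c2 / (c1 + c2))
        self.b_ = float(b)
        self.residuals_ = y - A @ coef
        self.sse_ = float(self.residuals_ @ self.residuals_)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n_samples, 2), got {X.shape}")
        return apply_saito(X[:, 0], X[:, 1], self.params_)

    @property
    def params_(self) -> SaitoParams:
        check_is_fitted(self, "a_")
        return SaitoParams(
            a=self.a_,
            b=self.b_,
            alpha=self.alpha_,
            sse=self.sse_,
            residuals=self.residuals_.tolist(),
        )


def fit_saito(calib: pd.DataFrame) -> SaitoParams:
    """Fit the conversion on a calibration table.

    ``calib`` needs columns ``hu_50kev`` (or ``hu_h``), ``hu_200kev`` (or
    ``hu_l``) and ``rho_nominal``; extra columns (material names) are ignored.
    """
    h = calib["hu_50kev"] if "hu_50kev" in calib else calib["hu_h"]
    l = calib["hu_200kev"] if "hu_200kev" in calib else calib["hu_l"]
    est = SaitoCalibration().fit(
        np.column_stack([h, l]), np.asarray(calib["rho_nominal"], dtype=float)
    )
    return est.params_


def apply_saito(hu_h, hu_l, params) -> np.ndarray | float:
    """Evaluate the conversion function; affine in (hu_h, hu_l)."""
    hu_h = np.asarray(hu_h, dtype=float)
    hu_l = np.asarray(hu_l, dtype=float)
    a, b, alpha = params["a"], params["b"], params["alpha"]
    val = a * ((1.0 + alpha) * hu_h - alpha * hu_l) / 1000.0 + b
    return val if val.ndim else float(val)
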