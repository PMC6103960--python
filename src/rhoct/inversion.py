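"""Closed-form two-energy inversion for electron density and effective Z.

Given a pair of virtual monoenergetic images (VMIs) at two distinct energies
(50 and 200 keV by default), each HU pair is converted to mass-attenuation
values and the two-term attenuation model is solved analytically:

    u_i = mu_w(E_i)/rho_w * (HU_i/1000 + 1)           (i = 1 low, 2 high)
    R   = u_1 / u_2
    Z^m = (R*f_c(E_2) - f_c(E_1)) / (C_p*(E_1^-n - R*E_2^-n))
    rho_e = u_1 / (C_p*Z^m*E_1^-n + f_c(E_1))

The electron density cancels in the attenuation ratio R, leaving an equation
linear in Z^m; back-substitution then gives rho_e.  No iterative solver and
no tolerance parameters are involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .physics import (
    DEFAULT_CONSTANTS,
    PhysicsConstants,
    WaterReference,
    hu_to_mu_over_rho,
    klein_nishina_fc,
    validate_energy,
)

__all__ = ["LehmannInversion", "solve_rho_z", "invert_volume", "FLAG_MEANINGS"]

# Bit flags attached to each solved element.
FLAG_OK = 0
FLAG_AIR = 1          # u at the high energy ~ 0 (HU ~ -1000): rho=0, Z undefined
FLAG_NAN = 2          # non-finite input propagated
FLAG_ZM_NONPOS = 4    # Z^m <= 0: no physical solution for Z
FLAG_Z_RANGE = 8      # Z outside the configured [z_min, z_max] bracket
FLAG_SUBUNITY_HU = 16 # HU below -1000 (unphysical input, converted anyway)

FLAG_MEANINGS = {
    FLAG_AIR: "air",
    FLAG_NAN: "nan",
    FLAG_ZM_NONPOS: "zm_nonpositive",
    FLAG_Z_RANGE: "z_out_of_range",
    FLAG_SUBUNITY_HU: "hu_below_air",
}


class LehmannInversion(BaseEstimator):
    """Estimate relative electron density and effective Z from VMI HU pairs.

    A scikit-learn style predictor over two-column input ``X`` with columns
    ``(HU at the low energy, HU at the high energy)``.  The model has no free
    parameters to learn; :meth:`fit` validates the configuration and freezes
    the water reference, after which :meth:`predict` returns relative
    electron density and :meth:`predict_material` the full per-row solution.

    Parameters
    ----------
    energies : tuple of float
        The two VMI energies in keV, low < high.  Default (50, 200): at
        50 keV the photoelectric effect dominates and at 200 keV the
        Compton effect does, which maximises the spectral separation.
    constants : PhysicsConstants
        Two-term model constants.
    water : WaterReference or None
        Water mass-attenuation reference; a self-consistent model-based
        reference (exact round trips) is built when None.
    z_bounds : tuple of float
        Admissible effective-Z bracket; the power-law model degrades for
        hydrogen-like (Z = 1) and high-Z (Z > 30) materials.
    clamp_policy : {'flag', 'clamp', 'fail'}
        What to do with out-of-bracket or non-physical Z solutions:
        keep the value and set a flag bit, clamp to the bracket, or raise.

    Attributes
    ----------
    water_ : WaterReference
        The frozen water reference used by predictions.
    mu_w_ : ndarray of shape (2,)
        Water mass-attenuation coefficients at the two energies.
    fc_ : ndarray of shape (2,)
        Klein-Nishina cross-sections at the two energies.
    """

    def __init__(
        self,
        energies: tuple[float, float] = (50.0, 200.0),
        constants: PhysicsConstants = DEFAULT_CONSTANTS,
        water: WaterReference | None = None,
        z_bounds: tuple[float, float] = (1.0, 30.0),
        clamp_policy: str = "flag",
    ):
        self.energies = energies
        self.constants = constants
        self.water = water
        self.z_bounds = z_bounds
        self.clamp_policy = clamp_policy

    def fit(self, X=None, y=None):
        """Validate configuration; X and y are ignored (nothing is learned)."""
        e1, e2 = (float(e) for e in self.energies)
        if not e1 < e2:
            raise ValueError(f"energies must satisfy low < high, got {self.energies}")
        validate_energy([e1, e2], self.constants)
        z_min, z_max = self.z_bounds
        if not 0 < z_min < z_max:
            raise ValueError(f"invalid z_bounds {self.z_bounds}")
        if self.clamp_policy not in ("flag", "clamp", "fail"):
            raise ValueError(f"unknown clamp_policy {self.clamp_policy!r}")
        water = self.water
        if water is None:
            water = WaterReference(consts=self.constants)
        elif water.consts is not self.constants:
            water = water.with_consts(self.constants)
        self.water_ = water
        self.energies_ = (e1, e2)
        self.mu_w_ = np.array([water.mu_over_rho_at(e1), water.mu_over_rho_at(e2)])
        self.fc_ = np.array(
            [klein_nishina_fc(e1, self.constants), klein_nishina_fc(e2, self.constants)]
        )
        return self

    # -- core solve ----------------------------------------------------------

    def _solve(self, hu1, hu2):
        """Vectorised closed-form solve; returns (rho_abs, rho_rel, z, flags)."""
        check_is_fitted(self, "water_")
        c = self.constants
        e1, e2 = self.energies_
        hu1 = np.asarray(hu1, dtype=float)
        hu2 = np.asarray(hu2, dtype=float)
        if hu1.shape != hu2.shape:
            raise ValueError(
                f"HU arrays are not co-registered: shapes {hu1.shape} vs {hu2.shape}"
            )
        flags = np.zeros(hu1.shape, dtype=np.uint8)
        flags[(hu1 < -1000.0) | (hu2 < -1000.0)] |= FLAG_SUBUNITY_HU

        nan = ~(np.isfinite(hu1) & np.isfinite(hu2))
        flags[nan] |= FLAG_NAN

        u1 = hu_to_mu_over_rho(hu1, e1, self.water_)
        u2 = hu_to_mu_over_rho(hu2, e2, self.water_)

        air = np.isclose(u2, 0.0, atol=1e-12 * self.mu_w_[1]) & ~nan
        flags[air] |= FLAG_AIR

        with np.errstate(divide="ignore", invalid="ignore"):
            R = u1 / u2
            zm = (R * self.fc_[1] - self.fc_[0]) / (
                c.C_p * (e1**-c.n - R * e2**-c.n)
            )
            bad_zm = (zm <= 0) & ~air & ~nan
            flags[bad_zm] |= FLAG_ZM_NONPOS
            z = np.where(zm > 0, np.abs(zm) ** (1.0 / c.m), np.nan)
            rho_abs = u1 / (c.C_p * zm * e1**-c.n + self.fc_[0])

        z_min, z_max = self.z_bounds
        out_of_range = ((z < z_min) | (z > z_max)) & np.isfinite(z)
        flags[out_of_range] |= FLAG_Z_RANGE
        if self.clamp_policy == "fail" and np.any(flags & (FLAG_ZM_NONPOS | FLAG_Z_RANGE)):
            raise ValueError(
                "effective-Z solution outside the admissible bracket "
                f"[{z_min}, {z_max}] and clamp_policy='fail'"
            )
        if self.clamp_policy == "clamp":
            z = np.clip(z, z_min, z_max)

        # air: zero density, undefined Z; NaN input: propagate
        rho_abs = np.where(air, 0.0, rho_abs)
        z = np.where(air | nan, np.nan, z)
        rho_abs = np.where(nan, np.nan, rho_abs)
        return rho_abs, rho_abs / c.rho_e_water, z, flags

    # -- public API ----------------------------------------------------------

    def predict(self, X):
        """Relative electron density for each (HU_low, HU_high) row of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n_samples, 2), got {X.shape}")
        _, rho_rel, _, _ = self._solve(X[:, 0], X[:, 1])
        return rho_rel

    def predict_material(self, X) -> pd.DataFrame:
        """Full solution table: rho_rel, rho_abs (e/cm^3), z_eff, flags."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n_samples, 2), got {X.shape}")
        rho_abs, rho_rel, z, flags = self._solve(X[:, 0], X[:, 1])
        return pd.DataFrame(
            {
                "rho_rel": rho_rel,
                "rho_abs_e_per_cm3": rho_abs,
                "z_eff": z,
                "flags": flags.astype(int),
            }
        )

    def invert_volume(self, hu_low, hu_high):
        """Element-wise solve over co-registered rasters.

        Returns ``(rho_rel, z_eff, flags)`` arrays of the input shape; the
        flag mask records air, NaN, and out-of-bracket voxels.
        """
        _, rho_rel, z, flags = self._solve(hu_low, hu_high)
        return rho_rel, z, flags


def solve_rho_z(
    hu_low: float,
    hu_high: float,
    energies: tuple[float, float] = (50.0, 200.0),
    **kwargs,
):
    """Solve one HU pair; thin wrapper over :class:`LehmannInversion`.

    Returns a one-row record with rho_rel, rho_abs_e_per_cm3, z_eff, flags.
    """
    est = LehmannInversion(energies=energies, **kwargs).fit()
    return est.predict_material([[hu_low, hu_high]]).iloc[0]


def invert_volume(hu_low, hu_high, energies=(50.0, 200.0), **kwargs):
    """Vectorised wrapper over :meth:`LehmannInversion.invert_volume`."""
    est = LehmannInversion(energies=energies, **kwargs).fit()
    return est.invert_volume(hu_low, hu_high)
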