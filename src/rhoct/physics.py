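"""Energy-dependent attenuation model for dual-energy CT material decomposition.

The mass-attenuation coefficient of a body-tissue-like material at a photon
energy ``E`` below the pair-production threshold is approximated by a two-term
parameterisation: a photoelectric power law plus incoherent (Compton)
scattering described by the total Klein-Nishina cross-section per electron,

    mu(E)/rho  ~=  rho_e * ( C_p * Z**m / E**n  +  f_c(E) ),

where ``rho_e`` is the absolute electron density (e/cm^3) and ``Z`` the
effective atomic number.  Coherent (Rayleigh) scattering is neglected.  The
same model is used in both directions: forward, to synthesise virtual
monoenergetic images (VMIs) of known phantoms, and inverse, to recover
``(rho_e, Z)`` from a pair of VMIs.

Hounsfield units relate to the mass-attenuation coefficient through the water
reference at the same energy:

    mu(E)/rho = mu_w(E)/rho_w * (HU(E)/1000 + 1).

All unit conventions are isolated here: the two-term model's right-hand side
(e/cm^3 x cm^2/electron) is the quantity matched to the HU conversion's
output, so the forward/inverse chain is self-consistent regardless of the
absolute unit attached to ``mu_w/rho_w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhysicsConstants",
    "WaterReference",
    "MaterialPoint",
    "DEFAULT_CONSTANTS",
    "ELECTRON_REST_KEV",
    "RHO_E_WATER",
    "Z_EFF_WATER",
    "NIST_WATER_MU_OVER_RHO",
    "klein_nishina_fc",
    "photoelectric_term",
    "mass_attenuation",
    "hu_to_mu_over_rho",
    "mu_over_rho_to_hu",
    "effective_z",
    "validate_energy",
]

#: Electron rest energy in keV used to form gamma = E / e_rest.
ELECTRON_REST_KEV = 510.975

#: Absolute electron density of water, e/cm^3.
RHO_E_WATER = 3.343e23

# NIST/XCOM mass-attenuation coefficients of liquid water (cm^2/g),
# with coherent scattering, at the energies a user is likely to query.
NIST_WATER_MU_OVER_RHO: dict[float, float] = {
    30.0: 0.3756,
    40.0: 0.2683,
    50.0: 0.2269,
    60.0: 0.2059,
    80.0: 0.1837,
    100.0: 0.1707,
    150.0: 0.1505,
    200.0: 0.1370,
}


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the two-term attenuation model.

    Parameters
    ----------
    C_p : float
        Photoelectric proportionality constant, 9.8e-24.
    m : float
        Photoelectric effective-Z exponent (3 <= m <= 4 for numerical fits
        to experimental data; 3.8 by default).
    n : float
        Photoelectric energy exponent (3 <= n <= 3.5; 3.2 by default).
    r0 : float
        Classical electron radius in cm.
    e_rest : float
        Electron rest energy in keV.
    rho_e_water : float
        Absolute electron density of water in e/cm^3.
    """

    C_p: float = 9.8e-24
    m: float = 3.8
    n: float = 3.2
    r0: float = 2.818e-13
    e_rest: float = ELECTRON_REST_KEV
    rho_e_water: float = RHO_E_WATER

    @property
    def C0(self) -> float:
        """Klein-Nishina prefactor, 2*pi*r0**2 (cm^2)."""
        return 2.0 * np.pi * self.r0**2

    @property
    def thomson_cross_section(self) -> float:
        """Low-energy (Thomson) limit of the Klein-Nishina cross-section."""
        return 8.0 * np.pi / 3.0 * self.r0**2

    def __post_init__(self) -> None:
        for name in ("C_p", "m", "n", "r0", "e_rest", "rho_e_water"):
            if getattr(self, name) <= 0:
                raise ValueError(f"physics constant {name!r} must be positive")
        if not 3.0 <= self.m <= 4.0:
            raise ValueError(f"photoelectric exponent m={self.m} outside [3, 4]")
        if not 3.0 <= self.n <= 3.5:
            raise ValueError(f"photoelectric exponent n={self.n} outside [3, 3.5]")


DEFAULT_CONSTANTS = PhysicsConstants()


def validate_energy(E, consts: PhysicsConstants = DEFAULT_CONSTANTS):
    """Check 0 < E < 511 keV (clinical CT range, below pair production)."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0) or np.any(E >= 511.0):
        raise ValueError(
            f"photon energy must lie in (0, 511) keV, got {E!r}"
        )
    return E


# Maclaurin coefficients of f_c/C0 in gamma (exact rationals evaluated to
# float); the closed form suffers catastrophic cancellation of order
# eps/gamma^2 for small gamma, so below _KN_SERIES_GAMMA the series is used.
_KN_SERIES_COEFFS = np.array([
    4 / 3, -8 / 3, 104 / 15, -266 / 15, 4576 / 105, -2176 / 21,
    15136 / 63, -24592 / 45, 606208 / 495, -447488 / 165, 2551808 / 429,
    -3533312 / 273, 38182912 / 1365, -6311936 / 105, 32780288 / 255,
    -41879552 / 153,
])
_KN_SERIES_GAMMA = 0.05  # truncation and cancellation both < 1e-15 here


def klein_nishina_fc(E, consts: PhysicsConstants = DEFAULT_CONSTANTS):
    """Total Klein-Nishina cross-section per electron, cm^2.

    Parameters
    ----------
    E : float or array
        Photon energy in keV, 0 < E < 511.

    Returns
    -------
    float or ndarray
        f_c(gamma) with gamma = E / 510.975 keV.  Strictly positive and
        strictly decreasing in E; tends to the Thomson cross-section
        (8*pi/3)*r0**2 as E -> 0.
    """
    E = validate_energy(E, consts)
    g = np.atleast_1d(E / consts.e_rest)
    val = np.empty_like(g)
    small = g < _KN_SERIES_GAMMA
    if small.any():
        val[small] = np.polynomial.polynomial.polyval(g[small], _KN_SERIES_COEFFS)
    gl = g[~small]
    if gl.size:
        log_term = np.log1p(2.0 * gl)
        val[~small] = (
            (1.0 + gl) / gl**2
            * (2.0 * (1.0 + gl) / (1.0 + 2.0 * gl) - log_term / gl)
            + log_term / (2.0 * gl)
            - (1.0 + 3.0 * gl) / (1.0 + 2.0 * gl) ** 2
        )
    val = consts.C0 * val.reshape(np.shape(E))
    return val if val.ndim else float(val)


def photoelectric_term(z_eff, E, consts: PhysicsConstants = DEFAULT_CONSTANTS):
    """Per-electron photoelectric contribution C_p * Z**m / E**n.

    The electron-density factor is *not* included; multiply by ``rho_e``
    to obtain the attenuation contribution.
    """
    E = validate_energy(E, consts)
    z_eff = np.asarray(z_eff, dtype=float)
    if np.any(z_eff <= 0):
        raise ValueError(f"effective atomic number must be positive, got {z_eff!r}")
    val = consts.C_p * z_eff**consts.m / E**consts.n
    return val if val.ndim else float(val)


def effective_z(
    atomic_numbers,
    electron_fractions,
    m: float = DEFAULT_CONSTANTS.m,
) -> float:
    """Power-law effective atomic number of a mixture.

    Z_eff = (sum_i w_i * Z_i**m)**(1/m) with ``w_i`` the fraction of
    electrons contributed by element ``i`` (weights are renormalised).
    """
    z = np.asarray(atomic_numbers, dtype=float)
    w = np.asarray(electron_fractions, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("electron fractions must be non-negative with positive sum")
    w = w / w.sum()
    return float((w @ z**m) ** (1.0 / m))


#: Effective atomic number of water (H2O, electron fractions 0.2/0.8)
#: under the default photoelectric exponent m = 3.8.
Z_EFF_WATER = effective_z([1, 8], [0.2, 0.8])


@dataclass(frozen=True)
class MaterialPoint:
    """Electron density and effective atomic number of one voxel or ROI."""

    rho_e_abs: float
    rho_e_rel: float
    z_eff: float

    @classmethod
    def from_relative(
        cls, rho_e_rel: float, z_eff: float,
        consts: PhysicsConstants = DEFAULT_CONSTANTS,
    ) -> "MaterialPoint":
        return cls(rho_e_rel * consts.rho_e_water, rho_e_rel, z_eff)


@dataclass(frozen=True)
class WaterReference:
    """Water mass-attenuation reference used by the HU conversion.

    mode='self_consistent' (default) evaluates the two-term forward model at
    water's own electron density and effective atomic number, which makes the
    forward-simulate -> invert round trip exact by construction.  mode=
    'tabulated' looks energies up in a user-supplied table (NIST/XCOM values
    by default); energies absent from the table raise rather than being
    silently interpolated, unless they fall within ``interp_tol_kev`` of a
    tabulated energy.
    """

    mode: str = "self_consistent"
    table: dict[float, float] = field(
        default_factory=lambda: dict(NIST_WATER_MU_OVER_RHO)
    )
    z_eff_water: float = Z_EFF_WATER
    consts: PhysicsConstants = DEFAULT_CONSTANTS
    interp_tol_kev: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("self_consistent", "tabulated"):
            raise ValueError(
                f"water reference mode must be 'self_consistent' or "
                f"'tabulated', got {self.mode!r}"
            )

    def mu_over_rho_at(self, E):
        """Water mass-attenuation coefficient at energy E (keV)."""
        E = validate_energy(E, self.consts)
        if self.mode == "self_consistent":
            val = self.consts.rho_e_water * (
                photoelectric_term(self.z_eff_water, E, self.consts)
                + klein_nishina_fc(E, self.consts)
            )
            return val
        return self._lookup(E)

    def _lookup(self, E):
        scalar = np.ndim(E) == 0
        out = np.empty(np.shape(E) or (1,), dtype=float)
        keys = np.array(sorted(self.table))
        for i, e in enumerate(np.atleast_1d(E)):
            j = int(np.argmin(np.abs(keys - e)))
            if abs(keys[j] - e) > self.interp_tol_kev:
                raise KeyError(
                    f"no tabulated water coefficient at {e} keV "
                    f"(available: {list(keys)}); use self_consistent mode "
                    f"or extend the table"
                )
            out[i] = self.table[float(keys[j])]
        return float(out[0]) if scalar else out.reshape(np.shape(E))

    def with_consts(self, consts: PhysicsConstants) -> "WaterReference":
        return replace(self, consts=consts)


def mass_attenuation(
    point: MaterialPoint, E, consts: PhysicsConstants = DEFAULT_CONSTANTS
):
    """Two-term model mass-attenuation coefficient of a material point.

    Linear in the absolute electron density; the ratio between two energies
    is therefore independent of ``rho_e_abs``.
    """
    if point.rho_e_abs < 0:
        raise ValueError("absolute electron density must be non-negative")
    if point.rho_e_abs == 0:
        E = validate_energy(E, consts)
        return np.zeros_like(E) if np.ndim(E) else 0.0
    return point.rho_e_abs * (
        photoelectric_term(point.z_eff, E, consts) + klein_nishina_fc(E, consts)
    )


def hu_to_mu_over_rho(hu, E, water: WaterReference):
    """Convert an HU value at energy E to a mass-attenuation coefficient.

    HU below -1000 (unphysical) are converted anyway; callers that care
    should check ``hu >= -1000`` and flag.
    """
    hu = np.asarray(hu, dtype=float)
    val = water.mu_over_rho_at(E) * (hu / 1000.0 + 1.0)
    return val if val.ndim else float(val)


def mu_over_rho_to_hu(mu_rho, E, water: WaterReference):
    """Inverse of :func:`hu_to_mu_over_rho` (forward-simulation direction)."""
    mu_rho = np.asarray(mu_rho, dtype=float)
    val = 1000.0 * (mu_rho / water.mu_over_rho_at(E) - 1.0)
    return val if val.ndim else float(val)
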