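"""Synthetic CT-phantom VMI generator and ROI statistics.

Emulates the two calibration phantoms commonly used for electron-density
quality assurance — a 12-insert tissue-surrogate phantom (Gammex 467 type)
and a 6-material sensitometry phantom with air references (Catphan 504
type) — as voxelised virtual monoenergetic image (VMI) pairs.  Each voxel's
noiseless HU is the forward two-term attenuation model evaluated at the
material occupying the voxel; dose-dependent Gaussian noise is added
independently per image.  The ROI rule mirrors standard phantom practice:
a coaxial cylinder at half the insert's radius and height.

The generator is a stand-in for a real scanner: it reproduces geometry,
nominal densities and the assumed noise-dose scaling, not the scanner's
spectra, reconstruction filters or noise correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physics import (
    DEFAULT_CONSTANTS,
    MaterialPoint,
    PhysicsConstants,
    WaterReference,
    Z_EFF_WATER,
    effective_z,
    mass_attenuation,
    mu_over_rho_to_hu,
)

__all__ = [
    "InsertSpec",
    "PhantomSpec",
    "NoiseModel",
    "VmiPair",
    "builtin_phantom",
    "generate_vmi_pair",
    "extract_roi",
    "roi_table",
    "BUILTIN_PHANTOMS",
]


@dataclass(frozen=True)
class InsertSpec:
    """One cylindrical insert: position, size and nominal material."""

    name: str
    center: tuple[float, float]  # in-plane (x, y), mm
    radius: float                # mm
    length: float                # mm, along the scanner axis
    rho_rel_nominal: float
    z_eff: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"insert {self.name!r}: radius must be positive")
        if self.rho_rel_nominal < 0:
            raise ValueError(f"insert {self.name!r}: negative nominal density")


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom body plus inserts; drives both simulation and evaluation."""

    name: str
    body_radius: float                  # mm
    body_material: tuple[float, float]  # (rho_rel, z_eff) of the background
    inserts: tuple[InsertSpec, ...]
    fov: float = 360.0                  # mm
    slice_thickness: float = 0.8        # mm

    def __post_init__(self) -> None:
        if self.fov < 2 * self.body_radius:
            raise ValueError(
                f"{self.name}: field of view {self.fov} mm does not cover the "
                f"{2 * self.body_radius} mm body"
            )
        for ins in self.inserts:
            r = float(np.hypot(*ins.center))
            if r + ins.radius > self.body_radius:
                raise ValueError(f"{self.name}: insert {ins.name!r} outside body")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
                if d < a.radius + b.radius:
                    raise ValueError(
                        f"{self.name}: inserts {a.name!r} and {b.name!r} overlap"
                    )

    @property
    def max_insert_length(self) -> float:
        return max(ins.length for ins in self.inserts)


@dataclass(frozen=True)
class NoiseModel:
    """Dose-dependent Gaussian HU noise, sigma(D) = sigma_ref*sqrt(dose_ref/D).

    ``sigma_ref`` applies to the low-energy (50 keV) image; the high-energy
    image uses ``energy_ratio * sigma(D)`` (high-energy VMIs are less noisy).
    Noise is independent between the two images — real dual-layer VMIs have
    anticorrelated noise, which this model does not reproduce.
    """

    sigma_ref: float = 10.0   # HU, on the 50 keV image at the reference dose
    dose_ref: float = 30.0    # mGy (CTDIvol)
    energy_ratio: float = 0.5
    seed: int | None = None

    def sigma_at(self, dose: float) -> float:
        if dose <= 0:
            raise ValueError("dose must be positive")
        if self.sigma_ref < 0:
            raise ValueError("sigma_ref must be non-negative")
        return self.sigma_ref * float(np.sqrt(self.dose_ref / dose))


@dataclass
class VmiPair:
    """Two co-registered HU rasters at distinct energies (low < high)."""

    hu_low: np.ndarray
    hu_high: np.ndarray
    energies: tuple[float, float]
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm
    phantom: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if self.hu_low.shape != self.hu_high.shape:
            raise ValueError("VMI pair members must share one shape")
        if not self.energies[0] < self.energies[1]:
            raise ValueError("energies must be ordered low < high")

    @property
    def shape(self):
        return self.hu_low.shape

    def voxel_centers(self):
        """Physical voxel-center coordinate axes (x, y, z) in mm."""
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        x = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
        y = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
        z = (np.arange(nz) + 0.5) * dz - nz * dz / 2.0
        return x, y, z


# ---------------------------------------------------------------------------
# Built-in phantom fixtures
# ---------------------------------------------------------------------------

# Effective atomic numbers of the pure materials, from elemental composition
# (electron-fraction weighting under the default photoelectric exponent).
_Z_TEFLON = effective_z([6, 9], [12, 36])          # (C2F4)n
_Z_DELRIN = effective_z([6, 1, 8], [6, 2, 8])      # (CH2O)n
_Z_ACRYLIC = effective_z([6, 1, 8], [30, 8, 16])   # (C5H8O2)n
_Z_POLYSTYRENE = effective_z([6, 1], [48, 8])      # (C8H8)n
_Z_POLYETHYLENE = effective_z([6, 1], [6, 2])      # (CH2)n; PMP identical ratio
_Z_AIR = effective_z([7, 8, 18], [0.3773, 0.1160, 0.0059])

#: Relative electron density of air (~1.2 mg/cm^3 at room conditions).
RHO_REL_AIR = 0.001

# Tissue-surrogate inserts: nominal relative electron density from the
# manufacturer datasheet; z_eff representative values for the epoxy-based
# surrogate compositions.
_GAMMEX_INSERTS = [
    # (name, rho_rel_nominal, z_eff)
    ("SB3 cortical bone", 1.696, 13.64),
    ("CB2 50% CaCO3", 1.471, 12.54),
    ("CB2 30% CaCO3", 1.280, 10.90),
    ("B200 bone mineral", 1.109, 10.24),
    ("IB inner bone", 1.107, 10.42),
    ("LV1 liver", 1.062, 7.74),
    ("BRN-SR2 brain", 1.047, 6.09),
    ("CT water", 0.990, Z_EFF_WATER),
    ("BR-12 breast", 0.961, 6.93),
    ("AP6 adipose", 0.928, 6.21),
    ("LN-450 lung", 0.466, 7.63),
    ("LN-300 lung", 0.264, 7.60),
]

_CATPHAN_INSERTS = [
    # (name, clock position, rho_rel_nominal, z_eff)
    ("Teflon", 1, 1.868, _Z_TEFLON),
    ("Delrin", 3, 1.363, _Z_DELRIN),
    ("Acrylic", 5, 1.147, _Z_ACRYLIC),
    ("Polystyrene", 7, 0.998, _Z_POLYSTYRENE),
    ("LDPE", 9, 0.945, _Z_POLYETHYLENE),
    ("PMP", 11, 0.853, _Z_POLYETHYLENE),
    ("Air (top)", 12, RHO_REL_AIR, _Z_AIR),
    ("Air (bottom)", 6, RHO_REL_AIR, _Z_AIR),
]


def _gammex467() -> PhantomSpec:
    # 33 cm body; 30 mm diameter x 70 mm inserts on a ring, electron density
    # decreasing counterclockwise from the top position.
    ring = 120.0
    inserts = []
    for k, (name, rho, z) in enumerate(_GAMMEX_INSERTS):
        theta = np.deg2rad(90.0 + 30.0 * k)
        inserts.append(
            InsertSpec(
                name=name,
                center=(ring * np.cos(theta), ring * np.sin(theta)),
                radius=15.0,
                length=70.0,
                rho_rel_nominal=rho,
                z_eff=z,
            )
        )
    return PhantomSpec(
        name="gammex467",
        body_radius=165.0,
        body_material=(0.990, 7.63),  # solid-water background
        inserts=tuple(inserts),
    )


def _catphan504() -> PhantomSpec:
    # 20 cm body; sensitometry ring of 12.5 mm diameter x 25 mm cylinders.
    ring = 58.4
    inserts = []
    for name, clock, rho, z in _CATPHAN_INSERTS:
        theta = np.deg2rad(90.0 - 30.0 * clock)
        inserts.append(
            InsertSpec(
                name=name,
                center=(ring * np.cos(theta), ring * np.sin(theta)),
                radius=6.25,
                length=25.0,
                rho_rel_nominal=rho,
                z_eff=z,
            )
        )
    return PhantomSpec(
        name="catphan504",
        body_radius=100.0,
        body_material=(1.0, Z_EFF_WATER),  # water-equivalent housing
        inserts=tuple(inserts),
    )


BUILTIN_PHANTOMS = {"gammex467": _gammex467, "catphan504": _catphan504}


def builtin_phantom(name: str) -> PhantomSpec:
    """Return a built-in phantom fixture by name."""
    try:
        return BUILTIN_PHANTOMS[name]()
    except KeyError:
        raise ValueError(
            f"unknown phantom {name!r}; available: {sorted(BUILTIN_PHANTOMS)}"
        ) from None


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _material_hu(
    rho_rel: float,
    z_eff: float,
    energies,
    water: WaterReference,
    consts: PhysicsConstants,
):
    """Noiseless HU of a homogeneous material at each energy."""
    if rho_rel > 0 and z_eff <= 0:
        raise ValueError("material with positive density needs z_eff > 0")
    pt = MaterialPoint.from_relative(rho_rel, max(z_eff, 1.0), consts)
    return np.array(
        [mu_over_rho_to_hu(mass_attenuation(pt, e, consts), e, water) for e in energies]
    )


def generate_vmi_pair(
    phantom: PhantomSpec,
    energies: tuple[float, float] = (50.0, 200.0),
    dose: float = 30.0,
    noise: NoiseModel | None = None,
    n_inplane: int | None = None,
    z_extent: float | None = None,
    water: WaterReference | None = None,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> VmiPair:
    """Rasterise a phantom and synthesise a noisy VMI pair.

    Voxel membership is by voxel center (no antialiasing) for exact
    reproducibility.  The in-plane grid defaults to fov/512 voxels; the
    axial extent defaults to the longest insert plus one slice of margin.
    Given the same seed and configuration the output is bit-identical.

    Parameters
    ----------
    dose : float
        CTDIvol in mGy controlling the noise level through ``noise``.
    noise : NoiseModel or None
        None means noiseless images.
    rng : numpy Generator, optional
        Overrides ``noise.seed`` when supplied.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    for ins in phantom.inserts:
        if ins.z_eff <= 0:
            raise ValueError(f"insert {ins.name!r} has non-positive z_eff")
    if water is None:
        water = WaterReference(consts=constants)
    n_inplane = n_inplane or 512
    dx = phantom.fov / n_inplane
    dz = phantom.slice_thickness
    if z_extent is None:
        z_extent = phantom.max_insert_length + 2 * dz
    nz = max(1, int(np.ceil(z_extent / dz)))

    x = (np.arange(n_inplane) + 0.5) * dx - phantom.fov / 2.0
    xx, yy = np.meshgrid(x, x, indexing="ij")
    zc = (np.arange(nz) + 0.5) * dz - nz * dz / 2.0

    # materials: 0 air (outside body), 1 body, 2.. inserts
    materials = [(RHO_REL_AIR, _Z_AIR), phantom.body_material] + [
        (ins.rho_rel_nominal, ins.z_eff) for ins in phantom.inserts
    ]
    label2d = np.zeros((n_inplane, n_inplane), dtype=np.int16)
    label2d[xx**2 + yy**2 <= phantom.body_radius**2] = 1
    insert_disc = []
    for idx, ins in enumerate(phantom.inserts, start=2):
        disc = (xx - ins.center[0]) ** 2 + (yy - ins.center[1]) ** 2 <= ins.radius**2
        insert_disc.append(disc)

    hu_table = np.array(
        [_material_hu(r, z, energies, water, constants) for r, z in materials]
    )  # (n_materials, 2)

    label = np.repeat(label2d[:, :, None], nz, axis=2)
    for idx, (ins, disc) in enumerate(zip(phantom.inserts, insert_disc), start=2):
        in_z = np.abs(zc) <= ins.length / 2.0
        label[disc[:, :, None] & in_z[None, None, :]] = idx

    hu_low = hu_table[label, 0]
    hu_high = hu_table[label, 1]

    if noise is not None and noise.sigma_ref > 0:
        sigma = noise.sigma_at(dose)
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        hu_low = hu_low + rng.normal(0.0, sigma, hu_low.shape)
        hu_high = hu_high + rng.normal(0.0, noise.energy_ratio * sigma, hu_high.shape)

    return VmiPair(
        hu_low=hu_low,
        hu_high=hu_high,
        energies=tuple(float(e) for e in energies),
        spacing=(dx, dx, dz),
        phantom=phantom,
    )


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(
    image: np.ndarray,
    insert: InsertSpec,
    spacing: tuple[float, float, float],
    fraction: float = 0.5,
):
    """Mean and SD of an image over a scaled coaxial ROI cylinder.

    The ROI shares the insert's axis and is scaled by ``fraction`` in both
    radius and length (default 0.5: half the radius and half the height).
    A voxel belongs to the ROI when its center falls inside the cylinder.

    Returns
    -------
    (mean, sd, n_voxels)
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    nx, ny, nz = image.shape
    dx, dy, dz = spacing
    x = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
    y = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
    z = (np.arange(nz) + 0.5) * dz - nz * dz / 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")
    disc = (xx - insert.center[0]) ** 2 + (yy - insert.center[1]) ** 2 <= (
        fraction * insert.radius
    ) ** 2
    in_z = np.abs(z) <= fraction * insert.length / 2.0
    mask = disc[:, :, None] & in_z[None, None, :]
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"ROI for insert {insert.name!r} contains zero voxels at this grid"
        )
    vals = image[mask]
    return float(vals.mean()), float(vals.std(ddof=0)), n


def roi_table(pair: VmiPair, fraction: float = 0.5) -> pd.DataFrame:
    """Per-insert ROI statistics for both members of a VMI pair."""
    if pair.phantom is None:
        raise ValueError("VmiPair carries no phantom specification")
    rows = []
    for i, ins in enumerate(pair.phantom.inserts, start=1):
        m_lo, s_lo, n = extract_roi(pair.hu_low, ins, pair.spacing, fraction)
        m_hi, s_hi, _ = extract_roi(pair.hu_high, ins, pair.spacing, fraction)
        rows.append(
            {
                "roi_id": i,
                "material": ins.name,
                "rho_rel_nominal": ins.rho_rel_nominal,
                "hu_50kev_mean": m_lo,
                "hu_50kev_sd": s_lo,
                "hu_200kev_mean": m_hi,
                "hu_200kev_sd": s_hi,
                "n_voxels": n,
            }
        )
    return pd.DataFrame(rows)
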