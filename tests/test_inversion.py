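"""Closed-form two-energy inversion: round trips, oracle agreement, flags."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import rhoct
from rhoct.inversion import (
    FLAG_AIR,
    FLAG_NAN,
    FLAG_Z_RANGE,
    LehmannInversion,
    invert_volume,
    solve_rho_z,
)
from rhoct.physics import (
    DEFAULT_CONSTANTS,
    Z_EFF_WATER,
    hu_to_mu_over_rho,
    klein_nishina_fc,
    photoelectric_term,
)

from conftest import forward_hu_pair


def brute_force_solve(hu_pair, water, energies=(50.0, 200.0)):
    """Independent 2-D least-squares search over (rho_rel, Z).

    Minimises the summed squared residuals of the two forward equations on a
    coarse grid, then polishes with Nelder-Mead.  Never uses the closed form.
    """
    u = np.array(
        [hu_to_mu_over_rho(h, e, water) for h, e in zip(hu_pair, energies)]
    )
    c = DEFAULT_CONSTANTS
    fc = np.array([klein_nishina_fc(e) for e in energies])

    def resid(params):
        rho_rel, z = params
        if rho_rel <= 0 or z <= 0:
            return 1e6
        mu = rho_rel * c.rho_e_water * (
            np.array([photoelectric_term(z, e) for e in energies]) + fc
        )
        return float(np.sum((mu - u) ** 2))

    rr = np.linspace(0.05, 2.5, 120)
    zz = np.linspace(2.0, 25.0, 120)
    grid = [(r, z) for r in rr for z in zz]
    best = min(grid, key=resid)
    res = optimize.minimize(
        resid, best, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-24, "maxiter": 20000},
    )
    return res.x


class TestClosedForm:
    def test_water_pair_recovers_water(self, inversion):
        row = inversion.predict_material([[0.0, 0.0]]).iloc[0]
        assert row.rho_rel == pytest.approx(1.0, abs=1e-12)
        assert row.z_eff == pytest.approx(Z_EFF_WATER, abs=1e-9)
        assert row["flags"] == 0

    @pytest.mark.parametrize(
        "rho,z", [(1.696, 12.5), (0.264, 7.6), (1.0, Z_EFF_WATER), (0.5, 5.0)]
    )
    def test_forward_inverse_round_trip(self, inversion, water, rho, z):
        hu = forward_hu_pair(rho, z, water)
        row = inversion.predict_material([hu]).iloc[0]
        assert row.rho_rel == pytest.approx(rho, abs=1e-9)
        assert row.z_eff == pytest.approx(z, abs=1e-9)

    def test_matches_brute_force_oracle(self, inversion, water):
        rng = np.random.default_rng(42)
        # full 100-point comparison runs in the acceptance suite; a
        # representative subsample keeps the unit test quick
        for _ in range(10):
            rho = rng.uniform(0.2, 2.0)
            z = rng.uniform(5.0, 20.0)
            hu = forward_hu_pair(rho, z, water)
            row = inversion.predict_material([hu]).iloc[0]
            oracle = brute_force_solve(hu, water)
            assert row.rho_rel == pytest.approx(oracle[0], abs=1e-6)
            assert row.z_eff == pytest.approx(oracle[1], abs=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(
        hu200=st.floats(min_value=-500.0, max_value=800.0),
        hu50_a=st.floats(min_value=-400.0, max_value=2000.0),
        delta=st.floats(min_value=1.0, max_value=300.0),
    )
    def test_z_monotone_in_low_energy_hu(self, hu200, hu50_a, delta):
        """At fixed high-energy HU, more low-energy attenuation never
        lowers the recovered effective Z."""
        inv = LehmannInversion(clamp_policy="flag").fit()
        out = inv.predict_material([[hu50_a, hu200], [hu50_a + delta, hu200]])
        z1, z2 = out["z_eff"]
        if np.isfinite(z1) and np.isfinite(z2):
            assert z2 >= z1 - 1e-9


class TestFlags:
    def test_air_pair_flagged_zero_density(self, inversion):
        row = inversion.predict_material([[-1000.0, -1000.0]]).iloc[0]
        assert int(row["flags"]) & FLAG_AIR
        assert row.rho_rel == 0.0
        assert np.isnan(row.z_eff)

    def test_nan_propagates_with_flag(self, inversion):
        row = inversion.predict_material([[np.nan, 0.0]]).iloc[0]
        assert int(row["flags"]) & FLAG_NAN
        assert np.isnan(row.rho_rel)

    def test_out_of_bracket_z_flagged_but_kept(self, water):
        inv = LehmannInversion(z_bounds=(6.0, 10.0), clamp_policy="flag").fit()
        hu = forward_hu_pair(1.5, 13.0, water)
        row = inv.predict_material([hu]).iloc[0]
        assert int(row["flags"]) & FLAG_Z_RANGE
        assert row.z_eff == pytest.approx(13.0, abs=1e-9)

    def test_clamp_policy_clamps(self, water):
        inv = LehmannInversion(z_bounds=(6.0, 10.0), clamp_policy="clamp").fit()
        hu = forward_hu_pair(1.5, 13.0, water)
        assert inv.predict_material([hu]).iloc[0].z_eff == 10.0

    def test_fail_policy_raises(self, water):
        inv = LehmannInversion(z_bounds=(6.0, 10.0), clamp_policy="fail").fit()
        hu = forward_hu_pair(1.5, 13.0, water)
        with pytest.raises(ValueError, match="bracket"):
            inv.predict(np.array([hu]))


class TestVolume:
    def test_uniform_water_volume(self, inversion):
        vol = np.zeros((4, 4, 2))
        rho, z, flags = inversion.invert_volume(vol, vol)
        assert np.allclose(rho, 1.0)
        assert not flags.any()

    def test_single_air_voxel_isolated(self, inversion):
        lo = np.zeros((4, 4, 2))
        hi = np.zeros((4, 4, 2))
        lo[1, 2, 0] = hi[1, 2, 0] = -1000.0
        rho, z, flags = inversion.invert_volume(lo, hi)
        assert flags[1, 2, 0] & FLAG_AIR
        assert flags.sum() == flags[1, 2, 0]
        mask = np.ones_like(rho, dtype=bool)
        mask[1, 2, 0] = False
        assert np.allclose(rho[mask], 1.0)

    def test_shape_mismatch_rejected(self, inversion):
        with pytest.raises(ValueError, match="co-registered"):
            inversion.invert_volume(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_simulated_phantom_roi_means_recover_nominals(
        self, gammex_noiseless_pair, inversion
    ):
        tab = rhoct.roi_table(gammex_noiseless_pair)
        est = inversion.predict(
            tab[["hu_50kev_mean", "hu_200kev_mean"]].to_numpy()
        )
        assert np.max(np.abs(est - tab["rho_rel_nominal"].to_numpy())) < 1e-9


class TestWrappersAndEstimatorApi:
    def test_solve_rho_z_single_pair(self, water):
        hu = forward_hu_pair(1.2, 9.0, water)
        row = solve_rho_z(*hu)
        assert row.rho_rel == pytest.approx(1.2, abs=1e-9)

    def test_invert_volume_wrapper(self):
        rho, _, _ = invert_volume(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.allclose(rho, 1.0)

    def test_sklearn_param_round_trip(self):
        inv = LehmannInversion(z_bounds=(2.0, 25.0))
        params = inv.get_params()
        assert params["z_bounds"] == (2.0, 25.0)
        inv.set_params(clamp_policy="clamp").fit()
        assert inv.clamp_policy == "clamp"

    def test_bad_energy_order_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            LehmannInversion(energies=(200.0, 50.0)).fit()
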