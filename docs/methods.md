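# Methods

## Attenuation model

For a narrow monoenergetic beam below the pair-production threshold
(E < 511 keV) the mass-attenuation coefficient of body-tissue-like
materials is modelled with two interaction terms:

    mu(E)/rho ≅ a_p f_p(E) + a_c f_c(E)
    a_p f_p ≅ rho_e · C_p Z^m / E^n          (photoelectric)
    a_c = rho_e,  f_c = total Klein-Nishina  (incoherent scattering)

Coherent (Rayleigh) scattering is neglected, the standard simplification
for soft tissue at clinical CT energies. Constants: C_p = 9.8e-24,
m = 3.8, n = 3.2 (numerical fits to experimental data place m in [3, 4]
and n in [3, 3.5]; the bounds are enforced on user overrides),
r0 = 2.818e-13 cm, electron rest energy 510.975 keV, water electron
density 3.343e23 e/cm^3.

The Klein-Nishina closed form suffers catastrophic cancellation of order
eps/gamma^2 for small gamma = E/510.975. Below gamma = 0.05 (~25.5 keV) the
implementation switches to the exact Maclaurin series (16 terms, rational
coefficients); truncation and cancellation are both below 1e-15 at the
switch point, and the whole range 1–510 keV agrees with a 50-digit
independent evaluation to better than 1e-12 (verified in the test suite
and the acceptance script). The gamma -> 0 limit is the Thomson
cross-section (8*pi/3) r0^2 = (4/3) C0.

### Units and the water reference

The HU conversion mu(E)/rho = mu_w(E)/rho_w (HU/1000 + 1) yields cm^2/g
while the two-term model's right side (e/cm^3 x cm^2/electron) is
dimensionally cm^-1. The source literature for this model equates the two
without comment; we adopt the same convention and isolate it entirely
inside `rhoct.physics`: the inversion divides one model expression by
another, so any fixed unit attached to mu_w/rho_w cancels and the
forward/inverse chain is self-consistent regardless.

The default water reference is *self-consistent*: mu_w/rho_w(E) is the
two-term model evaluated at water's own point (rho_e = 3.343e23,
Z_eff,water = 7.544, computed from H2O's electron fractions 0.2/0.8 with
the power-law effective-Z formula at exponent m). This makes HU = 0 map
exactly to (rho_rel = 1, Z_eff,water) and forward->inverse round trips
exact by construction. A *tabulated* mode with NIST/XCOM water
coefficients is available for users comparing against standard tables;
because the two-term model omits coherent scattering, the two modes agree
only to ~6% at 50 keV and ~0.6% at 200 keV — a documented model error, not
a bug, and the reason the tabulated mode refuses to interpolate silently.

## Cross-sectional inversion

With u_i = mu_w(E_i)/rho_w (HU_i/1000 + 1) at the two energies,
R = u_1/u_2 is independent of rho_e and linear in Z^m:

    Z^m  = (R f_c(E_2) − f_c(E_1)) / (C_p (E_1^−n − R E_2^−n))
    rho_e = u_1 / (C_p Z^m E_1^−n + f_c(E_1))

This closed form replaces the unspecified "analytic solution" of generic
descriptions: no iteration, no starting values, no tolerance knobs. The
default energy pair is (50, 200) keV — photoelectric-dominated vs
Compton-dominated, maximising spectral separation — but any ordered pair
inside (0, 511) keV is accepted.

Degenerate inputs are flagged per element rather than aborting a volume:
u_2 ≈ 0 (air, HU ≈ −1000 at the high energy) gives rho_rel = 0 with Z
undefined; NaN propagates with its own flag; Z^m ≤ 0 or Z outside the
configured bracket (default [1, 30], where the power-law model is
meaningful) is flagged, clamped, or raised per `clamp_policy` (default
flag-and-keep). HU below −1000 is converted but flagged.

The evaluation path is *average-then-solve*: ROI-mean HU pairs are
inverted, matching how phantom studies tabulate results. Because the
inversion is nonlinear, solving per voxel and then averaging differs under
noise; voxel-wise maps (`invert_volume`) are provided as a secondary
output and the two paths agree exactly in the noiseless limit. Effective Z
is reported as a free diagnostic of the same solve even though density is
the validated quantity.

## Calibrated conversion

Saito's function rho_e = a((1+alpha)HU_H − alpha HU_L)/1000 + b is affine
in the HU pair, so the least-squares fit is solved exactly through
rho = c1 HU_H + c2 HU_L + b with a = 1000(c1+c2), alpha = −c2/(c1+c2).
This is equivalent at the optimum to a generic surface-fitting routine but
deterministic and platform-reproducible; the SSE optimality is checked
against a dense grid oracle in the tests. The fit is unweighted. A
near-collinear design (HU_H ≈ HU_L for all rows — no spectral separation)
is reported as an error rather than returning an unstable alpha; the
magnitude of alpha shrinks as spectral separation grows, and the bundled
preset for 50/200 keV dual-layer VMIs (a = 0.9704, b = 0.9874,
alpha = −0.02104) shows the extreme of that trend. All calibration inserts
are used by default, including the inhomogeneous lung surrogates; an
exclusion list supports the stricter protocol that drops them.

## Synthetic phantoms and noise

`rhoct.phantom` emulates the study conditions, not a scanner:

* Tissue-surrogate phantom: 33 cm body (solid-water background), twelve
  30 mm x 70 mm cylindrical inserts on a ring, nominal rho_rel 0.264–1.696
  decreasing counterclockwise. Sensitometry phantom: 20 cm body, six
  12.5 mm x 25 mm material inserts (Teflon 1.868 … PMP 0.853) at the odd
  clock positions plus two air regions. FOV 360 mm, slice thickness
  0.8 mm, in-plane voxel fov/512 by default.
* Insert effective-Z defaults: pure plastics, water and air are computed
  from elemental composition with the power-law formula; the epoxy-based
  tissue surrogates use representative literature-style values. No test or
  acceptance quantity depends on matching a real scanner's HU — the
  generator's role is self-consistency with the forward model.
* Noise: zero-mean Gaussian HU noise with sigma(D) = sigma_ref
  sqrt(dose_ref/D), sigma_ref = 10 HU at 30 mGy on the 50 keV image and
  half that on the 200 keV image, independent per image. The 1/sqrt(dose)
  law and independence are stand-ins: real dose-noise curves and the
  anticorrelated noise of dual-layer VMIs are not reported for this
  protocol and are not modelled. Tests therefore assert only the scaling
  law and noiseless limits, never an absolute sigma.
* Rasterisation is voxel-center membership without antialiasing, so a
  given seed and configuration is bit-reproducible. With the default ROI
  fraction 0.5 the ROI cylinder is strictly interior to its insert, so ROI
  statistics are free of partial-volume boundary voxels.

Consequently, passing tests demonstrate algorithmic correctness
(round-trip exactness, oracle agreement, statistical definitions) and the
workflow's shape across the four dose levels (30/20/10/7.5 mGy); they do
not demonstrate accuracy on real scanner data, which is what the bundled
measured benchmark table is for.

## Evaluation statistics

%Error = (rho_est − rho_nom)/rho_nom x 100; RMSE uses the population 1/N
denominator as defined; NRMSE = RMSE / mean(rho_nom). Regression is OLS of
estimate on nominal; the identity comparison is operationalised as Wald
t-tests of beta = 1 and eps = 0 using OLS coefficient standard errors —
a covariance-analysis against an ideal measurement can be constructed in
several ways and the exact construction behind published p-values of that
kind is underspecified, so those specific p-values are out of scope. Data
exactly on the identity line return p = 1 by convention (zero residual
variance); constant nonzero paired differences return infinite t with
p = 0. The "excluding inserts" summary takes an explicit label list
(default: the LN-300 lung and solid-water inserts, the two known outlier
materials).

The bundled benchmark table (`rhoct.benchmark`) carries the published
per-insert estimates of both methods at 20 mGy with their nominals.
Regenerating its summary statistics — Lehmann RMSE 0.0166 / NRMSE 1.53% /
R 0.9993 / beta 1.0028, Saito 0.0095 / 0.87% / 0.9997 / 0.9952, and every
per-insert %Error cell at printed rounding — pins this module's
definitions to the field's. Two printed-prose inconsistencies in the
source material are resolved in favour of its table: the LN-300 absolute
error is −0.018 (= 0.246 − 0.264), not the −0.020 quoted in prose, and the
cortical-bone estimate 1.675 is below its nominal 1.696, contradicting the
prose claim of a maximum increase there.

## Problem sizes and reproducibility

Tests and the acceptance script simulate at reduced grids (96–256
in-plane voxels; 128 for the tissue-surrogate phantom and 192 for the
sensitometry phantom in the dose series) with the axial extent covering
the ROI; these sizes give thousands of ROI voxels, ample for the scaling
checks, while keeping runs to seconds. The dose-stability check reports a
true p-value (uniform under the null), so individual seeds can land
anywhere; the suite uses a fixed seed and the acceptance script derives
all randomness from `--seed`.

## Known limitations

* The two-term model excludes coherent scattering and is calibrated for
  5 ≲ Z ≲ 30; hydrogen-rich or high-Z materials invert with bias (flagged
  via the Z bracket).
* The synthetic noise model is independent between energies and purely
  Gaussian; real dual-layer VMI noise is anticorrelated and textured by
  reconstruction.
* Beam hardening, scatter, detector response and iterative-reconstruction
  effects are outside the VMI abstraction: the VMIs are taken as given.
* Exact reproduction of a scanner-specific calibration triple (a, b,
  alpha) is impossible without the raw calibration HU values, which are
  never published; the preset is provided for application, and parameter
  recovery is validated on synthetic data instead.
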