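# Methods

`irdosim` reconstructs the complete TG-43 dosimetric characterization of the
GammaMed Plus HDR ¹⁹²Ir source with two independent pipelines — a photon
Monte Carlo simulation and an emulated 0.1-cc ionization-chamber experiment —
and compares them. This note records the models, the numerical choices, and
what the package does and does not claim.

## Source model

The source is a nested-cylinder model in (r, z): an Ir70/Pt30 active core
(radius 0.03 cm, length 0.35 cm, effective density 21.76 g/cm³), an air-filled
gap on the lateral and distal sides of the core (capsule inner radius
0.035 cm), an AISI 316L steel capsule (outer radius 0.045 cm, 8.06 g/cm³), a
tapered distal tip approximated by three stacked cylindrical slices
(thicknesses 0.006/0.005/0.005 cm with radii 0.035/0.030/0.012 cm, widest
slice nearest the core), and a proximal drive cable (radius 0.045 cm,
compacted-steel density 5.6 g/cm³, default modeled length 6 cm — beyond which
its contribution to any tally point is negligible). θ = 0° points through the
distal tip; the cable side is θ near 180°, which is why F(r, θ) is lower at
175° than at 0°.

Open choices made here: the gap filler is dry air (configurable to vacuum;
the difference is far below every stated tolerance), and the axial gap
between the core top and the capsule interior is 0.005 cm, equal to the
lateral gap, since no separate value is available. Activity is uniform in
the core volume — the standard TG-43 assumption. The geometry is exactly
cylindrically symmetric; nothing in the code depends on azimuth.

## Physical data

Photon interaction tables are packaged as CSV (regenerated by
`scripts/build_material_tables.py`):

- **Water and dry air**: standard reference grids (Hubbell/Seltzer-style) of
  the total mass attenuation coefficient and the mass energy-absorption
  coefficient on the usual 1 keV–1.5 MeV grid. The channel split
  (photoelectric / incoherent / coherent) is reconstructed so that the
  incoherent channel is exactly Klein–Nishina × Z/A and the three channels
  sum exactly to the anchored total; the split only steers interaction-type
  sampling, while attenuation always uses the anchored totals.
- **Metals (Ir, Pt, 316L constituents)**: Klein–Nishina incoherent plus a
  photoelectric+coherent term obtained by power-law scaling in Z between two
  anchor elements (Fe and Pb) whose reference totals are embedded, honoring
  the target element's K-edge by branch selection. Estimated accuracy is a
  few percent in 0.1–1 MeV; since capsule/core filtration is largely common
  to the air and water runs, the residual effect on Λ and g_L is well below
  1%, and on F(5°–30°) of order 1%.
- **Dry-air density** is 1.205 × 10⁻³ g/cm³ (20 °C, 101.325 kPa). A config
  override exists for nonstandard densities.
- **Spectrum**: a bare ¹⁹²Ir emission-line set (25 lines, 61 keV–1.06 MeV,
  ≈2.29 photons per decay, mean ≈0.355 MeV) packaged as versioned data;
  user-supplied two-column spectra are accepted. Discrete lines are used
  rather than energy bins; the spectrum identity affects results at the
  sub-percent level.

Interpolation is log-log, exact at nodes, with a hard error outside the
grid. Mixtures combine linearly in mass fraction on the merged grid (the
Ir70/Pt30 core alloy and 316L steel are built this way).

## Monte Carlo engine

Analog photon transport with no electron transport: collision kerma, scored
with a track-length estimator (path length × E × μ_en/ρ / cell volume) in
annular ring cells, stands in for absorbed dose under charged-particle
equilibrium. This kerma approximation is the main model approximation; it is
excellent at the scoring distances used (≥0.8 cm in water) and consistent
with disabling electron transport in the reference air-kerma methodology.
Interactions: photoelectric absorption terminates the history with local
deposition (fluorescence from Ir/Pt/steel is not re-emitted — a known,
second-order bias source for small-angle anisotropy); incoherent scattering
samples the Klein–Nishina distribution by Kahn's rejection method (free
electrons, no binding/Doppler); coherent scattering deflects without energy
loss using a Thomson × screened-form-factor angular model tabulated as a
per-material inverse CDF (and can be switched off for closed-form oracle
tests). The photon cutoff is 1 keV.

Phantoms: water runs use the bounded 60 cm × 60 cm cylinder — the scatter
deficit near the boundary is physical and required for g_L(20 cm); air runs
use a 10 m × 10 m air cylinder with scoring rings at 1–100 cm on the
transverse axis.

A collision-density estimator runs in parallel with the track-length
estimator as an internal cross-check; a brute-force pure-Python transport
loop (independent geometry and sampling code) serves as the external oracle
on a one-cell toy problem in the tests.

Statistical errors are batch-mean standard errors over ≥10 batches with
seeds derived from one master seed via `numpy.random.SeedSequence`; every
random stream in the package descends from the manifest's master seed, and
fixed seeds reproduce results bit-for-bit. The engine is a single
Numba-compiled kernel; a desk-scale water run of 10⁷ histories takes about
half a minute on one core.

### Scoring grids (desk scale)

Published grids for this problem used ~10⁹ histories with sub-millimeter
cells. This package targets desk-scale runs (10⁶–10⁷ histories), so cells
are enlarged to keep track-length variance low while bounding
volume-averaging bias: transverse cells are ΔZ = 0.1 cm with ΔR = 2% of r
(inverse-square curvature bias ≲10⁻⁴), anisotropy cells are cubes of side
min(0.07 r, 0.35) cm (polar averaging ±≈2°, bias ≲0.1% where F is curved),
and air cells grow from 0.1 cm to 2 cm between 1 and 100 cm. One
non-overlapping grid replaces the three-batch scoring split of the original
workflow; non-overlap is validated at construction. Statistical accuracy at
10⁷ water histories: ≈0.2% at r = 1 cm, ≈0.3% at 20 cm and on F(5, θ) —
the reduced-scale analogue of the published 0.7–1.4%.

## TG-43 extraction

- **Geometry factor**: line-source G_L(r, θ) = β/(L r sin θ) with β computed
  as a difference of two `arctan2` projections onto the line ends (stable
  near θ → 0/180°), and the on-axis limit 1/(r² − L²/4). Verified against an
  independent numeric line integral to 10⁻⁶ relative over r ∈ [0.25, 20] cm,
  θ ∈ [1°, 179°].
- **Air kerma strength**: in-air kerma at 10–100 cm is corrected for air
  attenuation and scatter of the primary (multiplication by exp(+μ̄d) with
  the spectrum-averaged air attenuation coefficient); corrected K·d² is fit
  linearly in d and extrapolated to d = 0. The intercept is S_K, the slope
  absorbs residual scatter build-up, and the fit covariance gives the
  uncertainty.
- **Λ, g_L, F**: Λ = Ḋ(1 cm, 90°)/S_K with quadrature-combined uncertainty;
  g_L and F are the standard dual ratios with the line-source geometry
  factor, exactly 1 at their normalization points by construction. Angles
  are degrees at every interface, radians internally; θ₀ = 90°.
- Per-history tallies (MeV/g) are used throughout; because every TG-43
  deliverable is a ratio, no absolute activity normalization enters.

## Chamber pipeline

Dose from a reading is the exact multiplicative chain
D = N_DW·M_u·P_d·N_n(r)·N_Q with P_d = 0.991 and N_n anchors
1.107/1.033/1.006/1.0044 at 1/2/5/8 cm. N_n is interpolated log-linearly in
r between anchors, is 1.0 beyond 8 cm, and raises below 1 cm (no
extrapolation toward the source). The exposure-to-dose f-factor is 0.960 at
r ≤ 1 cm, linear to 0.930 across (1, 5] cm, then constant — the published
anchors show exactly this plateau structure. N_Q is never printed in the
source literature; it defaults to 1.0 and is recorded in outputs. Room
scatter on air readings is a configurable multiplicative factor (default
1.0). Repeats are combined as plain means with standard errors, no outlier
rejection.

Three radial-dose-function routes are implemented: tissue attenuation factor
(g_L = f·α normalized at 1 cm), and depth dose normalized at 1 cm or 5 cm.
The 5-cm normalization exists because chamber positioning error propagates
as ≈2Δ/r and is an order of magnitude smaller at 5 cm; the dual
normalizations satisfy the exact algebraic identity
g_L^{(5)}(r)/g_L^{(5)}(1) = g_L^{(1)}(r), which the tests enforce to 10⁻¹².
Method agreement is reported as pairwise max |A/B − 1| or as half-range
(max−min)/(2·mean), in percent.

## Virtual experiments

The generator inverts the correction chain: signal = true dose at the
jittered source position ÷ correction product at the *nominal* distance ×
lognormal noise. Jitter is uniform on ±half-width per axis (default
±0.052 cm, the documented jig tolerance stack; configurable Gaussian),
applied to the source position. Reading noise defaults to 0.5% lognormal —
the experiment's distance-dependent reproducibility (≈3%/1%/0.1% at
1/5/10 cm) emerges from jitter through inverse-square propagation (≈2Δ/r
half-range: ≈10%, 5%, 2% at 1, 2, 5 cm), not from intrinsic electrometer
noise; the split between the two is a modeling decision flagged here. The
published per-distance uncertainty statements are themselves mutually
inconsistent at 5 cm (a stated 1% versus ≈2% from the ±0.052 cm stack); the
generator reports both and asserts neither.

What the virtual experiment does *not* emulate: transit dose, leakage,
timer error (not needed for a source stable during collection), room-scatter
drift, chamber-volume averaging beyond the N_n correction, or any
energy-response change of the chamber with depth. Passing recovery tests
therefore demonstrates that the analysis pipeline is unbiased under the
modeled error structure, not that a physical experiment would achieve the
same accuracy.

## Known limitations

- Kerma approximation (no secondary-electron transport) biases dose within
  ~1 mm of the capsule and is irrelevant at the tally radii used.
- Local deposition of fluorescence after photoelectric absorption in the
  metals slightly hardens the small-angle filtered spectrum; the effect is
  second order for ¹⁹²Ir energies.
- Metal cross sections are anchored constructions, not measured tables;
  their few-percent uncertainty enters F(r, θ) at small and large polar
  angles at the ~1% level.
- The anisotropy function near 0°/180° (inside ~10°) is not tallied: cells
  there would intersect the source axis and the published values at those
  angles carry the largest disagreements between codes anyway.
- Published anisotropy values for this source family differ between codes by
  up to ~4% at intermediate angles; this package's F(5, 30°) sits ~2%
  above the packaged reference table, within the stated tolerance but
  closer to independently published datasets.
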