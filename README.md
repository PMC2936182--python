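# irdosim

TG-43 dosimetry of the **GammaMed Plus** high-dose-rate ¹⁹²Ir brachytherapy
source, for medical physicists who need to regenerate or verify the
dosimetric dataset of this source family: a desk-scale photon Monte Carlo of
the encapsulated source in air and water, extraction of the AAPM TG-43
parameters, and the ionization-chamber measurement pipeline used for
experimental cross-checks.

## The formalism

TG-43 factorizes the water dose rate around a cylindrically symmetric source
of active length L as

    D(r, θ) = S_K · Λ · [G_L(r, θ) / G_L(1 cm, 90°)] · g_L(r) · F(r, θ)

where S_K is the air kerma strength (U = cGy·cm²·h⁻¹), Λ the dose rate
constant (cGy·h⁻¹·U⁻¹), G_L the line-source geometry factor β/(L·r·sin θ),
g_L the radial dose function and F the anisotropy function. The package
computes every factor from first principles:

- **S_K** — analog photon transport of the modeled source in a 10 m air
  cylinder; kerma at 10–100 cm is corrected for air attenuation/scatter and
  K·d² extrapolated linearly to d = 0.
- **Λ, g_L, F** — the same source at the center of the bounded
  60 cm × 60 cm water cylinder, collision kerma scored by track-length
  estimation in ring cells on the transverse axis (0.8–20 cm) and on polar
  fans; TG-43 ratios with the line-source geometry factor.
- **Chamber side** — corrected doses D = N_DW·M_u·P_d·N_n(r)·N_Q from
  0.1-cc chamber readings, the tissue attenuation factor α(r) =
  D_water/D_air, radial dose functions by three routes (TAF and depth dose
  normalized at 1 or 5 cm), anisotropy from jig-coordinate readings, and
  inter-method agreement statistics. A virtual-experiment generator emulates
  the positioning-jitter and reading-noise structure of the physical
  measurement so the whole analysis chain is testable end-to-end.

## Worked example

```python
from irdosim.interface import SimulationConfig, run_simulation_workflow

cfg = SimulationConfig(air_histories=2_000_000, water_histories=2_000_000,
                       seed=42)
dataset, manifest = run_simulation_workflow(cfg)

print(f"Lambda = {dataset.dose_rate_constant:.4f} "
      f"+- {dataset.dose_rate_constant_unc:.4f} cGy/h/U")
for r in (2.0, 5.0, 10.0, 20.0):
    print(f"g_L({r:4.1f} cm) = {dataset.gl[r]:.3f}")
for th in (30.0, 90.0, 150.0):
    print(f"F(5 cm, {th:5.1f} deg) = {dataset.f[(5.0, th)]:.3f}")
```

prints (about 10 s on one core):

```
Lambda = 1.1135 +- 0.0030 cGy/h/U
g_L( 2.0 cm) = 0.997
g_L( 5.0 cm) = 1.001
g_L(10.0 cm) = 0.934
g_L(20.0 cm) = 0.655
F(5 cm,  30.0 deg) = 0.920
F(5 cm,  90.0 deg) = 1.000
F(5 cm, 150.0 deg) = 0.912
```

Λ ≈ 1.11 cGy·h⁻¹·U⁻¹ is the water dose rate at 1 cm per unit air kerma
strength — the absolute calibration point of the dataset. g_L falls to
≈0.93 at 10 cm and ≈0.66 at 20 cm as attenuation overtakes scatter build-up
in the bounded phantom, and F ≈ 0.92 at 30°/150° reflects oblique filtration
through the capsule and cable. At 2 × 10⁶ histories the statistical
uncertainty is roughly 0.5% on the transverse axis (batch standard errors
are carried per point in `dataset.gl_err` / `dataset.f_err`).

The same pipeline is scriptable from the shell:

    irdosim extract-tg43 --seed 42 --histories 2000000 --out out/
    irdosim make-synthetic --seed 4 --out readings.csv
    irdosim chamber-analyze --readings readings.csv --out chamber/
    irdosim compare-reference --gl chamber/gl_norm1.csv --column this_mc

`compare-reference` joins any computed radial-dose-function table against
the packaged published tables for this source family and reports per-radius
deviations in percent.

## Layout

    src/irdosim/physics_data.py            spectrum + cross-section tables
    src/irdosim/source_model.py            nested-cylinder source geometry
    src/irdosim/mc_engine.py, _kernels.py  analog transport + ring tallies
    src/irdosim/tg43.py                    G_L, S_K, Lambda, g_L, F
    src/irdosim/chamber_pipeline.py        correction chain, TAF, agreement
    src/irdosim/synthetic_measurements.py  virtual chamber experiments
    src/irdosim/interface.py, cli.py       workflows, manifests, CLI
    src/irdosim/data/                      packaged tables + reference fixtures
    docs/methods.md                        models, assumptions, limitations
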