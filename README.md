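# photherm

Benchmarking plasmonic nanoparticles as photothermal heaters, and
predicting how fast they can heat tissue at depth.

Photothermal therapy drives local hyperthermia in tumors by illuminating
light-absorbing nanoparticles with near-infrared light.  Choosing a
nanoparticle requires two numbers that are usually reported separately:
the **photothermal conversion efficiency** η (what fraction of the
extinguished light becomes heat) and how strongly a microgram of particles
extinguishes light in the first place (the mass extinction coefficient
ε_m, cm²/mg).  `photherm` implements both classic estimators and their
combination, the **photothermal mass conversion efficiency**

    η_m = η (1 − 10^−ε) / m_NPs        [μg⁻¹]

— heat generated per unit laser power per microgram of nanoparticles in
the beam path — and couples it to a voxel Monte Carlo simulation of 808 nm
light penetrating breast tissue (μ_a = 0.035 cm⁻¹, μ_s′ = 11.7 cm⁻¹) to
predict idealized heating rates

    Ṫ = η_m · P(z) · m_NPs / (m C)      [K/s]

and minimum ramp times from body temperature (37 °C) to the hyperthermia
threshold (43 °C) for voxels 0–30 mm deep, across nanoparticle
concentration (0.005–0.020 mg/g) and surface power density (1–5 W/cm²).

The package is aimed at nanomedicine and biophotonics researchers who
want to benchmark candidate nanoheaters from cuvette calorimetry traces
and get order-of-magnitude feasibility estimates for heating at depth.
Everything runs on synthetic data generated from the same physical models
the estimators assume, so the full pipeline is testable end to end.

## Worked example

```python
import photherm as pt

# 1. simulate a gold-nanorod calorimetry experiment (eta = 0.66, ext 0.1)
trace = pt.simulate_trace(pt.TraceGenConfig(eta_true=0.66, noise_sd_C=0.0))

# 2. recover eta from the trace with the equilibrium energy balance
eta = pt.estimate_eta(trace, blank=None, laser_power_W=1.0, extinction=0.1)

# 3. mass-normalize: eta_m for the nanorod suspension
susp = pt.preset_suspension("AuNR")
m_np = pt.mass_in_beam(susp.mass_concentration_mg_per_mL, pt.BeamGeometry(), 1.0)
eta_m = pt.estimate_eta_m(trace, None, 1.0, m_np)

print(f"eta = {eta:.3f}, m_NPs = {m_np:.3f} ug, eta_m = {eta_m:.3f} /ug")

# 4. light penetration into breast tissue and ramp times at depth
fmap = pt.run_mc(pt.TissueModel(), pt.BeamModel(), n_packets=1_000_000, seed=1)
table = pt.ramp_time_table(fmap, eta_m)
print(table.pivot(0.010).round(1))
```

prints (Monte Carlo numbers vary by ~a few % with the seed):

```
eta = 0.660, m_NPs = 0.176 ug, eta_m = 0.772 /ug
          1 W/cm2  3 W/cm2  5 W/cm2
depth_mm
0.0           3.8      1.3      0.8
10.0         35.3     11.8      7.1
20.0        249.2     83.1     49.8
30.0       1260.5    420.2    252.1
```

Reading: with 0.01 mg of nanorods per gram of tissue, a surface voxel
reaches 43 °C within seconds, while a voxel 30 mm deep needs ~20 minutes
at 1 W/cm² — the light that deep is a fraction of a percent of the
surface dose.  These are *minimum* times: the model deliberately ignores
conduction, perfusion and beam attenuation by the particles themselves.

A `photherm` console script exposes the same pipeline as four
subcommands (`simulate-traces`, `fit-efficiency`, `mc-fluence`,
`ramp-times`), each taking `--config`, `--seed`, `--out`, `--log-level`;
outputs are CSV/HDF5 with JSON provenance sidecars.

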