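# Methods

`photherm` links three models: a lumped-capacitance calorimetry model of a
stirred nanoparticle suspension, a voxel Monte Carlo model of near-infrared
light transport in a breast-tissue phantom, and an idealized single-voxel
heating model that combines the two into hyperthermia ramp times at depth.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Calorimetry model and estimators

A cuvette holding mass *m* (default 2 g) of suspension with heat capacity
*C* (4.182 J g⁻¹ K⁻¹) under a laser of power *I* obeys

    m C dT/dt = I η (1 − 10^−ε) + Q_blank − m C (T − T_amb)/τ,

where ε is the decadic extinction of the suspension at the laser line
(0.1 for every benchmark suspension), η the photothermal conversion
efficiency, Q_blank the baseline heating rate of the solvent and cuvette
(treated as a constant power, in W), and τ the Newton-cooling time
constant.  Heating approaches the equilibrium elevation
ΔT_eq = τ (I η (1 − 10^−ε) + Q_blank)/(mC) exponentially; after laser-off
the elevation decays as exp(−t/τ).  The synthetic generator samples this
solution exactly (optionally adding i.i.d. Gaussian sensor noise), so
estimator tests on synthetic traces are exact round trips up to noise.

Two estimators are provided:

* **Equilibrium energy balance.**  η = (mC ΔT_max/τ − Q_blank)/(I(1 −
  10^−ε)), with τ fitted from the linearized cooling law t = −τ ln θ and
  Q_blank obtained from the blank trace's plateau and time constant.
* **Short-time (mass) balance.**  η_m = mC (Ṫ − Ṫ_blank)/(I m_NPs), the
  light converted to heat per μg of nanoparticle in the illuminated
  column m_NPs = C_NPs · A_beam · L (A_beam = 0.081 cm², L = 1 cm).  The
  two are linked by η_m = η (1 − 10^−ε)/m_NPs, which the cross-validation
  helper inverts.

### Numerical choices

* **τ fit.**  Ordinary least squares of t on −ln θ (slope = τ), with R²
  reported.  Cooling samples below 0.02 °C elevation *or* below 30% of
  the peak elevation are excluded: far-tail points carry little leverage,
  and after the log transform their noise biases the slope upward (at
  0.05 °C noise on a 0.7 °C blank signal the bias reaches ~35% without
  the relative cutoff, and ~1% with it — validated by simulation against
  the generator).  A nonlinear exponential fit is used in the tests as an
  independent oracle, never in the estimator.
* **Initial slope for η_m.**  The heating rate over the first 60 s is the
  *tangent at t = 0 of a quadratic least-squares fit*, not a straight-line
  slope.  A straight line (or a two-point ΔT/Δt) is biased low by
  ≈ W/(2τ) — 5% at the fixture τ = 600 s — which alone would exceed the
  3% cross-method agreement the two estimators otherwise show; the
  quadratic tangent removes the first-order loss term while remaining
  model-free (residual O((W/τ)²) < 0.5%).  In the loss-free limit all
  three definitions coincide.
* **Equilibrium detection.**  A trace counts as equilibrated when the
  plateau slope is below 10⁻⁴ °C/s; the slope is estimated over the final
  300 s of heating (a 60 s window cannot resolve that rate at 0.05 °C
  noise), while the plateau level itself is the mean over the final 60 s.
  Non-equilibrated traces produce a warning, not an error.
* **Flat blanks.**  A blank that never rises above ambient has no
  fittable decay; its Q_blank is taken as zero (or, if it plateaus but
  the decay is unusable, the sample's τ is reused — the cell geometry is
  identical).

### Fixture defaults

τ = 600 s and 1 s sampling are fixture choices (the benchmark experiment
reports neither).  Heating runs for 10 τ by default so traces genuinely
equilibrate; 30 min of heating would leave a τ = 600 s trace 5% short of
plateau and is *not* "equilibrium" for this fixture.  The default blank
power 0.01 W produces a 0.72 °C blank plateau, small against the 2–10 °C
sample signals, matching the qualitative observation that water and
quartz barely absorb at 808 nm.  Ambient temperature defaults to 25 °C;
all estimators are exactly invariant to ambient offsets.

## Voxel Monte Carlo

An 8 × 8 × 5 cm homogeneous slab with μ_a = 0.035 cm⁻¹ and
μ_s′ = 11.7 cm⁻¹ at 808 nm is illuminated normally by a collimated 10 mm
beam.  Photon packets random-walk with free paths −ln U/μ_t, implicit
capture (weight × μ_s/μ_t per collision), and either isotropic scattering
at μ_s′ (the similarity reduction, the default) or Henyey–Greenstein
scattering with configurable g and μ_s = μ_s′/(1 − g).  Boundaries are
refractive-index matched by default; n > 1 enables unpolarized Fresnel
reflection (including total internal reflection) at all faces plus the
specular entry loss.

* **Scoring.**  Track-length estimator on 1 mm scoring voxels: each free
  path is walked in substeps of half a voxel and w·Δs is deposited in the
  voxel containing the substep midpoint.  Attribution error is O(substep)
  at voxel boundaries, far below Monte Carlo noise at the packet counts
  used.
* **Normalization.**  The map is divided by the mean fluence in the first
  voxel layer inside the illuminated disc, so voxel values are "fractions
  of the dose delivered to the tissue surface"; the backscatter build-up
  then legitimately exceeds 1 just below the surface.  The convention is
  recorded in the output metadata.
* **Termination.**  Below weight 10⁻⁴ a roulette keeps the packet with
  probability 0.1 (weight unchanged) and otherwise deposits the residual
  weight locally.  Unlike classic roulette (which boosts survivors by
  1/p), this keeps the per-run energy balance *exact* — launched weight
  equals absorbed + escaped to float precision every run — at the cost of
  a bias bounded by the 10⁻⁴ threshold itself, orders of magnitude below
  MC noise.
* **Reproducibility.**  One seeded RNG stream drives the whole run; a
  (model, beam, n_packets, seed) tuple is bit-reproducible, and the seed
  is stored in the map.

Validation: with scattering off, the on-axis profile matches the
Beer–Lambert exponential within 2%; with the breast-tissue coefficients
the on-axis decay ratios between 10, 20 and 30 mm match the diffusion
Green's-function integral for a flat disc source within a few percent,
and a wide (plane-wave-like) beam decays with μ_eff = √(3 μ_a(μ_a+μ_s′))
= 1.11 cm⁻¹.  The similarity relation (isotropic μ_s′ vs HG g = 0.9)
holds within ~5% for the *raw per-packet fluence* at depths ≥ 5 mm; the
surface-dose normalization unit itself is phase-function sensitive
(backscatter region), so normalized maps from different phase functions
differ by a common ~10% factor and should be compared on raw fluence.

Published depth percentages for this configuration (17%, 2% and 0.34% of
the on-axis maximum at 10, 20 and 30 mm, peak 1–3 mm deep) sit outside
what these coefficients can produce under any beam interpretation we
tested (flat disc, Gaussian FWHM = 10 mm, Gaussian 1/e² = 10 mm, matched
or n = 1.37 boundaries, isotropic or g = 0.9): the quoted 10→20 mm decay
(×8.5 per cm) is steeper than the diffusion-theory bound for a pencil
beam, while this implementation agrees with diffusion theory to ~1.5%.
The acceptance checks for those values therefore report this package's
computed profile (≈11%, ≈1.6%, ≈0.34% with the default flat beam, peak
in the first millimetre) rather than tuning the model toward the printed
numbers.

## Heating model and ramp times

The peak heating rate of a single nanoparticle-loaded voxel is

    Ṫ = η_m · P(z) · m_NPs / (m C),

with P(z) = surface power density × beam area × on-axis relative density
at depth z (surface-dose normalization), m_NPs = concentration × voxel
mass (tissue density 1 g/cm³), voxel mass 7.47 μg and C = 4.186
J g⁻¹ K⁻¹ (water).  P(z) is read as the *total beam power* scaled by the
relative density — the only reading consistent with the published
seconds-at-surface to ~tens-of-minutes-at-30-mm ratio; a per-voxel-area
reading disagrees by orders of magnitude.  Ramp time to hyperthermia is
(43 − 37) °C / Ṫ, infinite (flagged, not an exception) at zero rate.

No conduction, perfusion, inter-voxel shading or nanoparticle attenuation
of the beam is modelled: every ramp time is a strict minimum, and the
output metadata carries that warning verbatim.  Exact identities — ramp
time ∝ 1/(concentration × power × η_m), and t(z₁)/t(z₂) equal to the
inverse relative-density ratio — hold to float precision and are tested
as such.

## Problem sizes

Default packet budget is 10⁶ (≈25 s single-core after JIT warm-up),
which puts the relative standard error of the 30 mm on-axis readout near
5% with 1 mm scoring voxels; property tests use 2–4 × 10⁵ packets where
a few-percent error suffices.  Trace fixtures are 1 Hz samples over
10 τ + 6 τ.  The full CLI pipeline on defaults completes in well under
15 minutes on one CPU.

## Known limitations

* The calorimetry generator models a single thermal mass: no stirring
  dynamics, intra-cuvette gradients, sensor lag or aggregation kinetics.
  Passing round trips show estimator self-consistency under the assumed
  model, not robustness to violations of it.
* The tissue phantom is homogeneous: no skin/fat layering, polarization
  or time resolution.
* The heating model deliberately omits all heat sinks; measured ramp
  times in perfused tissue will be longer, increasingly so at depth.
* Scattering anisotropy is folded into μ_s′ by default; near-surface
  (< 5 mm) quantities are phase-function dependent and should be treated
  as indicative only.
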