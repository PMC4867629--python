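# Methods

`neonirs` implements the analysis chain behind combined frequency-domain
near-infrared spectroscopy and diffuse correlation spectroscopy
(FDNIRS-DCS) monitoring of preterm neonates: inversion of raw optical
signals to cerebral hemoglobin oxygenation (SO2) and a blood-flow index
(CBFi), computation of a cerebral oxygen-metabolism index (CMRO2i), and
longitudinal mixed-model comparison of a germinal-matrix-hemorrhage
(GM-IVH) arm against controls across postmenstrual age (PMA). Because no
bedside recordings of this kind are publicly deposited, the package ships
a first-class synthetic-cohort generator so that every stage is testable
end to end.

## Frequency-domain photon-density waves

Intensity-modulated light in a highly scattering medium obeys the
diffusion approximation; the complex wavenumber of the damped
photon-density wave satisfies

    k^2 = (v*mua - i*omega) / D,    D = v / (3*(mua + musp)),

with `v` the speed of light in tissue (refractive index 1.4 by default),
`omega` the angular modulation frequency (default 110 MHz, typical of
frequency-domain tissue oximeters), `mua` the absorption and `musp` the
reduced scattering coefficient (1/cm). In an infinite medium the AC
amplitude decays as `exp(-Re k * r)/r` and the phase grows linearly in
distance. With the principal square root, `Im k < 0`; the measured phase
delay is `-Im k * r`, which increases with distance — the sign convention
under which the slope inversion below is self-consistent.

The semi-infinite reflectance geometry uses the extrapolated-boundary
image-source solution: an isotropic source at depth `z0 = 1/(mua+musp)`
and a negative image across the extrapolated boundary at
`zb = (2/3(mua+musp)) * (1+Reff)/(1-Reff)`, with `Reff` the effective
internal reflection coefficient of the tissue-air interface
(`Reff ≈ 0.493` at n = 1.4).

### Multi-distance inversion

Per wavelength, ordinary least squares gives the slope `S_ac` of
`ln(r^p * AC)` versus `r` (p = 1 infinite, p = 2 semi-infinite) and the
slope `S_ph` of phase versus `r`; these invert algebraically:

    mua  = (omega / 2v) * (S_ph/S_ac - S_ac/S_ph)
    musp = (S_ac^2 - S_ph^2) / (3*mua) - mua.

The method uses only relative amplitudes and phases across distances, so
it is invariant to source power and detector gain (the multi-distance
method's premise); per-wavelength R² of both regressions is kept as a
quality diagnostic.

In the infinite geometry the inversion is exact. In the semi-infinite
geometry the `exp(-kr)/r^2` asymptote only holds for separations much
larger than `z0 + 2zb` (~0.5 cm at musp = 10/cm), and at the probe's
1–2.5 cm separations the plain slope inversion is biased by up to tens of
percent at the low-scattering end of the physiological range. The package
therefore refines the algebraic estimate with a 2-D root solve that
matches the slopes the forward model itself produces at the measurement
distances to the measured slopes. This keeps the estimator a pure
function of the two measured slopes (hence still calibration-free) while
removing the finite-distance bias; on noiseless data the round trip is
exact to machine precision, and the plain algebraic estimate remains
available via `MultiDistanceModel(..., refine=False)`.

### Spectral unmixing

Absorption spectra are decomposed over tabulated oxy/deoxyhemoglobin
extinction spectra (base-10 convention, 650–850 nm grid, linear
interpolation) by non-negative least squares, optionally after
subtracting a water contribution `water_fraction * mua_water(lambda)`
(default water_fraction = 0). SO2 = HbO/(HbO+HbR); the relative residual
norm of the fit is a spectral-quality diagnostic. The default wavelength
grid is {660, 690, 705, 730, 760, 785, 808, 830} nm — eight lasers
spanning 660–830 nm.

## Diffuse correlation spectroscopy

For Brownian dynamics of the moving scatterers (the field-standard model
behind a "blood flow index"), the correlation-diffusion equation gives a
decay wavenumber

    K(tau)^2 = 3*mua*musp + 6*musp^2*k0^2*BFi*tau,    k0 = 2*pi*n/lambda,

and the normalized field autocorrelation `g1` follows the same spatial
Green's functions as the DC photon-density wave with `K(tau)` in place of
`K(0)` (single-exponential in the infinite medium; the two-term image
source form in semi-infinite reflectance). The measured intensity
autocorrelation is `g2 = 1 + beta*|g1|^2` (Siegert relation), with `beta`
set by the detection optics.

Fitting minimizes the unweighted sum of squares over `(log10 BFi, beta)`
with bounds BFi ∈ [1e-10, 1e-6] cm²/s and beta ∈ (0, 0.6]; beta is
initialised from the mean of the three earliest lags minus one and BFi
from a 33-point log-grid search, making the trust-region refinement
robust over the full physiological decade. Defaults: DCS wavelength
785 nm, source-detector distance 2.0 cm, log-spaced lag grid
1e-7–1e-2 s with 64 points (mirroring multi-tau hardware correlators).
Curves with total decay below 1e-4 are rejected as flat rather than
fitted.

## Session pipeline

Quality screening is deliberately conservative and fully configurable:
median slope-regression R² ≥ 0.98 for AC and phase, spectral residual
≤ 0.10, beta within (0.1, 0.6), fit convergence required. Failed
measurements are excluded with a logged reason; tightening any threshold
can only shrink the passing set.

Aggregation: repeats are averaged within each probe location first, then
CMRO2i = CBFi × HGB × (SaO2 − SO2) is computed per location using the
session's pulse-oximeter SaO2 and blood hemoglobin HGB, and SO2, CBFi and
CMRO2i are averaged arithmetically across passing locations (three
frontal locations by default). A location with SO2 > SaO2 yields a
negative CMRO2i, which is flagged but never clamped. Sessions with no
passing location are excluded downstream.

## Longitudinal cohort statistics

Each parameter (SO2, CBFi, CMRO2i) is modelled inside a PMA window
(default 27–40 weeks) as

    y_ij = b0 + b1*(PMA_ij - ref) + b2*group_i + b3*(PMA_ij - ref)*group_i
           + u_i + e_ij,

with a per-subject random intercept `u_i` and PMA centred at the window
midpoint. Conventions:

- Fixed effects and standard errors come from the REML fit; BIC
  (−2 logLik + k ln n, k counting fixed effects plus the two variance
  components) from an ML refit, lme4-style.
- The headline group test is the joint Wald F-test of both group terms on
  the REML fit with a between-within denominator df (n_subjects − 2),
  because group varies between subjects. At the design size of ~20
  subjects this keeps the test's measured size at ~0.05 where the
  asymptotic 2-df chi-square likelihood-ratio test ran visibly
  anticonservative (~0.07 over 400 null cohorts); the ML LRT statistic
  and p-value are still reported as diagnostics.
- The response is standardised internally before optimisation (CBFi's
  ~1e-8 cm²/s magnitude otherwise produces singular Hessians) and all
  estimates, variances and log-likelihoods are transformed back to the
  original units.
- Degenerate inputs with zero within-subject variance (noise-free
  synthetic cohorts) fall back to OLS point estimates flagged
  `converged=False`.
- Candidate trajectory forms (intercept-only, PMA, PMA+group, PMA×group)
  are ranked by BIC on ML fits of identical data; non-converging
  candidates are excluded with a warning.
- No multiplicity correction is applied across the three parameters; this
  is stated in the output metadata.

The joint multivariate model (one random effect vector across all
parameters with unstructured covariance) is not implemented: with ~20
subjects it is weakly identified, and the univariate fits answer the same
per-parameter questions reproducibly.

## Synthetic cohorts

The generator emulates a two-arm NICU longitudinal design: 13 control and
7 GM-IVH subjects by default, measured on a weekly grid with random entry,
discharge and attendance so per-subject session counts are unequal
(target mean 6; ~120 sessions per cohort). Each parameter follows
group line + subject random intercept + per-session residual. Defaults
(all configurable; chosen to reproduce the qualitative structure of
published neonatal FDNIRS-DCS cohorts, not any specific dataset):

| parameter | control at 34 wk | slope /wk | subject SD | session SD |
|---|---|---|---|---|
| CBFi (cm²/s) | 1.3e-8 | +5e-10 | 1.5e-9 | 1.0e-9 |
| SO2 (fraction) | 0.70 | 0 | 0.03 | 0.02 |
| HbT (µM) | 40 | 0 | 3.0 | 2.0 |

The GM-IVH arm carries an additive deficit, default −2.6e-9 cm²/s on CBFi
(−20% of the control mean) and zero on SO2/HbT, so CMRO2i inherits the
deficit through the flow term. SaO2 is drawn U(0.90, 1.00) per session and
HGB U(10, 17) g/dL; reduced scattering per subject follows
`musp_ref*(lambda/785)^-b` with musp_ref ~ N(8, 0.5) /cm and b ~ N(1, 0.1).

The raw-signal layer forward-models three probe locations per session as
exchangeable replicates whose latent physiology carries a small
log-normal jitter (2% by default), then applies multiplicative AC noise
(1%), additive phase noise (5 mrad) and additive per-lag g2 noise (0.005).
All noise levels are part of `NoiseModel`; with every SD at zero the
simulated signals equal the forward models exactly, which is the basis of
the round-trip tests. All randomness flows through a single
`numpy.random.default_rng` seed: identical configurations are
byte-identical.

What the generator does **not** emulate: scalp/skull layering and partial
volume effects, probe-coupling and motion artifacts, instrument drift,
correlated (physiological) noise across wavelengths or lags, pulsatile
variation within a session, and any dependence of SaO2/HGB on illness
severity. Passing tests therefore demonstrate correctness of the
estimators under the stated forward models and noise structure, not
robustness to every artifact of real NICU data.

## Problem sizes and numerics

The validation harness uses 50 random parameter pairs for each optical
round trip, 50 noisy replicates for the Monte-Carlo recovery studies, 400
null cohorts for test-size calibration, 200 cohorts each for power and
confidence-interval coverage, and one full raw-signal cohort (~115
sessions, three locations each) for the end-to-end run; the whole
suite completes in a few minutes on one core. Nonlinear solves use
scipy's trust-region reflective least squares (tolerances 1e-14) and
Powell's hybrid root finder (tolerance 1e-12); slope regressions are
unweighted OLS throughout, with no distance weighting.

## Known limitations

- Analytic diffusion solutions only; no Monte-Carlo photon transport, no
  layered or heterogeneous head models, no scalp-contamination correction.
- Brownian (linear-in-tau) flow dynamics only; no random-flow (tau²) term.
- No self-calibration of detector coupling or instrument phase drift; raw
  frames are assumed relative-calibrated across distances.
- The embedded extinction table is a compact 10 nm-grid transcription of
  the standard compilation; it is internally consistent (the same table
  synthesises and unmixes in all tests) but not a metrological reference.
- Hemispheric contrasts, outcome prediction, and demographic hypothesis
  testing are out of scope.
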