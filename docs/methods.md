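# Methods

## The kinetic model

A phytochrome sample is described by occupancy fractions over the
photostates Pr, Pfr and (optionally) a lumped Bleached photoproduct.
Transitions are first order; under actinic light of fluence rate
I (μmol·m⁻²·s⁻¹) the photochemical rates are σ·I with per-state
coefficients σ (min⁻¹ per μmol·m⁻²·s⁻¹), i.e. low-intensity linear
photochemistry. Thermal (dark) reversion Pfr → Pr proceeds at k_therm;
the Bleached state is reached photochemically from Pr and decays
thermally back to Pr. The generator matrix Q uses the column convention
(Q[j,i] = rate i→j, columns sum to zero), so d**p**/dt = Q**p** conserves
occupancy exactly. Occupancies are propagated by eigendecomposition of Q
(with an `expm` fallback for near-defective generators), never by
fixed-step integration; the photostationary state is the Pfr component
of Q's stationary null vector, which for two states reduces to
σ_f·I / (σ_f·I + σ_r·I + k_therm).

Canonical units are minutes and min⁻¹ throughout. Published
thermal-reversion constants printed as ×1000 min⁻¹ are converted on I/O
(the bundled replay file keeps both representations and the loader
cross-checks them).

### Cooperative dimer reversion

Phytochromes are head-to-head dimers; dimerization through the
C-terminal output module couples the two subunits so that reversion of
one changes the rate of the other. The sequential chain

    PfrPfr --k_fast--> PfrPr --k_slow--> PrPr

starting from pure PfrPfr gives a bulk Pfr fraction
f(t) = [2·PfrPfr + PfrPr]/2 that is exactly biexponential with
amplitudes fixed by the rate ratio: amp_slow = k_fast / (2(k_fast −
k_slow)), amp_fast = 1 − amp_slow. When |k_fast − k_slow| <
1e-6·k_fast the expression is catastrophically cancelling and the code
switches to the analytic limit f(t) = (1 + k·t/2)·e^(−k·t) with
k the mean rate (amplitudes are reported as NaN there, since the signal
is no longer a sum of two pure exponentials).

Note a structural point the package makes explicit: for the published
1–908 pair (0.320/0.034 min⁻¹) the pure chain pins the fast amplitude at
≈0.44, whereas the observed share is 0.90. The chain alone therefore
cannot carry the observed amplitude split, and the generator additionally
provides a phenomenological biexponential scheme in which rates *and*
amplitude fractions are imposed directly. The bundled replay uses that
scheme with the stated splits (0.90 fast for 1–908, 0.30 fast for
full-length reversion; 50/50 where no split is printed). Whether the
observed splits arise from dimer-chain kinetics plus heterogeneity or
from another mechanism is left open; both knobs are exposed.

### Replay of published constants

Replayed photoconversion uses the phenomenological rise
Pfr(t) = 1 − Σ aᵢ·e^(−kᵢ·t): printed photoconversion constants are
observed relaxation rates toward the photostationary state, and the
per-state photochemical cross-sections needed to decompose them into a
mechanistic scheme are not available. Decays (thermal reversion,
far-red-driven Pfr → Pr) start from pure Pfr; rises start from
dark-adapted Pr at the calibrated 12 μmol·m⁻²·s⁻¹ fluence.

## Spectra

Each photostate's visible spectrum is a sum of Gaussian bands in
wavelength (centers/widths in nm, peak heights in AU). This is a
modelling convention — only band maxima are known — chosen as the
simplest smooth unimodal closed form; no vibronic/excitonic structure is
intended. Absorbance is treated as path-normalized: samples are
conventionally diluted so the dark-adapted Pr Q-band peaks at 0.4 AU.
Mixtures are Beer–Lambert occupancy-weighted sums; difference spectra
are fixed-sign (dark-adapted minus irradiated), so the Pfr absorption
maximum appears as the far-red *minimum* of the difference spectrum.
Extrema are located by strict three-point comparison with parabolic
refinement through the bracketing samples, which recovers nm-scale peak
positions from the 10-nm measurement grid; isosbestic points are sign
changes of a difference spectrum located by linear interpolation, with
identical spectra returning an empty list plus a degeneracy flag rather
than "every wavelength".

## Global exponential fitting

The fit model shares the rate constant(s) across all fitted wavelengths
while giving each wavelength its own amplitude(s) and offset. The
least-squares problem is separable: for fixed rates the design matrix
[e^(−k₁t), (e^(−k₂t)), 1] is common to all wavelengths, so amplitudes
and offsets are one exact `lstsq` solve. The nonlinear search therefore
runs only over log-rates: a log-spaced multi-start grid (8 starts per
rate spanning 1e-4…1e2 min⁻¹; ordered pairs for the double fit), with
the best starts polished by bounded scalar minimization (single) or
Levenberg–Marquardt on the variable-projection residuals (double).
k₁ ≥ k₂ is enforced by post-fit ordering. Least squares are unweighted
(homoscedastic noise). The default wavelength set is the nine
red/far-red analysis wavelengths 640, 650, 660, 670, 700, 710, 720,
730, 740 nm when present in the data.

Identifiability guard: after fitting, if the total fitted amplitude at
*every* wavelength is below 3× the residual noise estimate, the fit
raises an identifiability error (carrying the well-determined offsets)
rather than reporting a meaningless rate.

Model selection between one and two exponentials uses AICc (residual
variance counted as a parameter), accepting the double model only when
it improves AICc by more than 10 — decisive evidence, chosen because a
reproducible criterion is needed where practice says only that two
exponentials were "required". The RSS entering AICc is floored at
(1e-10 × data RMS)² per point: residuals below that are optimizer
round-off, not information, which keeps the comparison sane on noiseless
data (where both models would otherwise be compared at machine noise).

### Attainable precision

Fit precision was checked against the Cramér–Rao bound. At noise SD
0.002 AU on the 0.4-AU scale, nine wavelengths and ~50 time points
covering four relaxation times of each phase, a single rate is recovered
to well under 2%, and both rates of an even-amplitude biexponential pair
with k₁/k₂ ≈ 9 to under 3% (p95). When the slow phase holds only 10% of
the amplitude its rate is information-limited to ≈7% SD at that noise
level (≈4% at 0.001 AU) — the fitter sits at this bound, and tests
assert accordingly rather than pretending tighter recovery.

## SEC sizing

K_AV = (V_e − V₀)/(V_t − V₀); out-of-range analytes get a warning, not
an error. Calibration is ordinary least squares of log10(mass/kDa) on
K_AV (slope must be negative — larger species elute earlier).
The monomer–dimer model converts mg/mL to molar via the monomer mass,
solves the conservation quadratic in closed form
([Mono] = (−K_d + √(K_d² + 8·K_d·C))/4) and reports the weight-average
mass M_w = M·([Mono] + 4[Di])/([Mono] + 2[Di]), which rises strictly
from M to 2M with concentration. K_d is fit by bounded scalar
minimization over log10 K_d; series flat at M or 2M are flagged
unidentifiable (only a bound on K_d exists) instead of fitted. Higher
oligomers and non-spherical hydrodynamic bias are deliberately not
modelled: neither is identifiable from apparent-mass-vs-concentration
data alone.

## Synthetic data

The generator reproduces the measurement structure of the motivating
experiments: wavelengths 630–850 nm in 10-nm steps, times in minutes,
Pr Q band at 0.4 AU, and additive i.i.d. Gaussian noise per (t, λ) point
with a mandatory seed (default SD 0.002 AU — chosen so that three-
replicate SDs of fitted constants land in the few-percent range typical
of the published values). Default state spectra are 28-nm-wide Gaussian
Q bands at the construct's printed Pr/Pfr maxima with a 0.24-AU Pfr peak
(a typical phytochrome Pfr/Pr peak ratio) and a reduced-amplitude
(0.14 AU) Pr-position band for the Bleached state — synthetic
conventions, not measured values. Default sampling covers four
relaxation times of each kinetic phase with 25 points per phase (fast
and slow grids are merged for biexponential kinetics), comparable to how
a benchtop kinetics run would be scheduled.

What the generator does *not* emulate: instrument scan dynamics, actinic
leakage of the measuring beam during reversion (noted in the source as a
nominal 0.465 μmol·m⁻²·s⁻¹ and uncorrected there too), wavelength-
correlated noise, and baseline drift. Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to instrument systematics.

## Problem sizes and numerical choices

Simulations use small (2–3 state) generators, eigendecomposition
propagation, and datasets of ~50 × 23 points; Monte-Carlo checks use
100–200 seeded replicates. Tolerances: occupancy conservation 1e-9;
closed-form vs simulated dimer decay 1e-9/1e-10; simulation vs adaptive
ODE integration 1e-8; noiseless refit closure of every bundled constant
1e-4 relative (achieved: ~1e-8). Ties and degenerate inputs: flat
spectra have no extrema; identical spectra are a degenerate isosbestic
case; equal-rate chains switch to the t·e^(−kt) series; all-zero rate
matrices have no unique steady state and are rejected.

## Known limitations

Absolute SEC masses cannot be reproduced (the standard set and elution
volumes behind the published calibrations are not available), only the
model's qualitative behaviour; spectral shapes are conventions fitted to
nothing; the Bleached state is a single lumped species with no
photocycle intermediates; no temperature dependence is modelled (all
constants refer to 25 °C); and photostationary conversions at specific
fluences cannot be predicted without photochemical cross-sections,
which are not published.
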