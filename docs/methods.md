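# Methods

This note documents the models implemented in `slowmodes`, the choices
made where the underlying theory leaves the design open, and what the
synthetic cohort does and does not establish about real data.

## 1. Neural-field forward model of the EEG spectrum

A cortical region is described by a mean depolarization field
η(**r**, t).  Pre-synaptic input μ arrives through a dispersive propagator

  G(r, t) = G₀/(4π σ²) · t⁻¹ · exp(−(r² + ν̄²t²)/(2σν̄t)) · H(t),

(Gaussian falloff of connection density with dispersion σ, conduction
velocity ν̄), and is converted to depolarization by a critically damped
synaptic kernel with time constant τ and gain γ.  The ensemble firing
rate is the logistic S(η) = 1/(1+exp(−ρ(η−χ))) with threshold χ and
slope ρ.  Defaults (γ = 8 mV, τ = 4 ms, G₀ = 2000, σ = 3 mm,
ρ = 0.54 mV⁻¹, χ = 30 mV, ν̄ = 3 m/s) are standard biophysical values;
internal units are mV/mm/s, so ν̄/(2σ) = 500 s⁻¹ is the fundamental
temporal rate.

Projecting the field equations onto Laplacian eigenmodes (eigenvalues
λ_k ≤ λ₀ = 0) gives per-mode third-order linear systems whose flow
matrix is

  J_k = [[0, 0, 1],
         [c(z₁⁰), (ν̄/2σ)(σ²λ_k − 1), 0],
         [−1/τ², γ/τ, −2/τ]],

coupled only through the gain c(z₁⁰) = ρG₀(ν̄/2σ)S(1−S) evaluated at the
*fundamental-mode* amplitude z₁⁰.  The fundamental mode is slow (zero
eigenvalue), the others fast: the slow amplitude parameterizes the fast
dynamics ("slaving").  The EEG power spectrum conditional on z₁⁰ is the
coherent sum over fast modes of the transfer functions from a shared
white pre-synaptic noise input to depolarization,

  P(ω; z₁⁰) = | Σ_{k=1..k_c} (γ/τ) / det(iωI − J_k) |²,

with k_c = 16 (skull low-pass cut-off).  The numerator follows from the
state-space structure (input on the z₂ component, output z₁); the
denominator is det(iωI − J_k) expanded in closed form.  The band-limited
normalized spectrum P̄(ω) on 1–60 Hz (0.25 Hz grid) is a probability
density over frequency; its first moment ω̄ is the **center frequency**.

**Eigenvalue spacing.**  The slaving argument does not fix the domain
geometry.  We use a 1-D Neumann interval, λ_k = −(kπ/L)².  The default
L = 3 mm is deliberate: mode k is linearly stable at the worst case
z₁⁰ = χ iff 1 + σ²(kπ/L)² > γτc(χ)/(ν̄/2σ) ≈ 8.64, which requires
L < 3.41 mm for k = 1.  In this regime (a) every fast mode is stable over
the whole sweep z₁⁰ ∈ [0, 2χ], so the spectrum is the stationary density
of a well-defined stochastic process and can be checked against
simulation; (b) ω̄(z₁⁰) decreases strictly monotonically on [0, χ] with
its minimum exactly at threshold, and the sweep spans ≈ 9.4 Hz.  For
larger domains low-order modes destabilize *inside* the sweep
(pole through the origin near z₁⁰ ≈ 23.5 mV at the defaults), the curve
loses monotonicity, and no stationary spectrum exists near threshold.
The fundamental mode itself is excluded from the EEG sum — it is the
conditioning variable, and its near-marginal linearization near χ *is*
the separation of time scales.

**Simulation oracle.**  `simulate_mode_sde` integrates the fast modes
driven by one shared noise sequence.  Because small domains make the
high-order modes stiff (decay rates up to ~10⁶ s⁻¹), the default scheme
is an exponential integrator (matrix exponential of J_k·dt with
zero-order hold on the input) executed through SciPy's `lfilter`; a
plain explicit Euler scheme is available where it is stable.  At
dt = 0.2 ms the Welch spectrum of a 200 s run matches the analytic P̄(ω)
to ≈ 5 % relative L2.

## 2. Stochastic DCM generative model

Regional slow states x (one per region; interpreted as the
fundamental-mode amplitudes) follow the Langevin dynamics
ẋ = A x + u(t) + v with effective-connectivity matrix A (Hz), optional
deterministic drive u (used only by the cohort generator; the inversion
never sees it) and white state noise v.  Each state drives a balloon
model in log space (vasodilatory signal, log flow, log volume, log
deoxyhemoglobin) with rate constants κ_s = 0.65 Hz, κ_f = 0.41 Hz,
τ₀ = 2 s, α = 0.32, E₀ = 0.34, and BOLD percent signal change

  y = V₀ [k₁(1−q) + k₂(1−q/v) + (1−ε₀)(1−v)],  k₁ = 4.3·ν₀·E₀·TE ≈ 2.36,
  k₂ = ε₀·r₀·E₀·TE, with V₀ = 4, ν₀ = 40.3 Hz, TE = 40 ms, r₀ = 25 Hz,
  ε₀ = 1 (1.5 T constants).

Rest (all states zero) is an exact fixed point.  Integration is
Euler–Maruyama for the neural stage (dt = 10 ms) and RK4 for the
hemodynamic stage.  A known structural limitation of the log-state
balloon model: sustained drive below −κ_f has no fixed point (flow
collapses to zero); the integrator treats log states beyond ±20 as
divergence.  This is why the synthetic cohort uses positive block
responses (Section 5).

## 3. Variational inversion

`SdcmModel.fit()` maximizes a variational Laplace free energy with two
Gaussian factors:

* **States.**  Conditional on parameters, an extended Kalman filter over
  scans (TR/8 locally linearized sub-steps; covariance propagated with
  scaling-and-squaring matrix exponentials of the frozen Jacobian, which
  stays stable for stiff balloon states) plus Rauch–Tung–Striebel
  smoothing give the Gaussian state posterior.  The filter's innovations
  decomposition is simultaneously the log-likelihood of the data with
  states integrated out, i.e. the accuracy term of the free energy under
  the Laplace approximation.  Missing (scan-nulled) volumes skip the
  measurement update, inflating the state posterior variance there.
  Filter means are clamped to a physiological box (|x| ≤ 10, log
  hemodynamic states within ±3) so that sub-step integration cannot
  overflow far from the fit.
* **Parameters.**  The connectivity A (fully reciprocal — every entry
  free) and the two log noise precisions are updated by damped
  Gauss–Newton: exact finite-difference gradients of the penalized
  log-likelihood, curvature from Fisher scoring on the innovation
  Jacobians patched on the diagonal with finite-difference curvatures
  (which carry the |S| terms the scoring form drops), Levenberg damping,
  a trust region of one unit per proposal, and step halving until the
  objective does not decrease.  A step is accepted only if the free
  energy does not decrease; rejection restores the previous iterate
  exactly, so the reported free-energy trace is non-decreasing by
  construction.  The precisions are estimated on the log scale under the
  same lognormal priors that define them, rather than by a conjugate
  Gamma refresh — the priors on the log precisions are lognormal, so no conjugate
  update exists, and folding the precisions into the same
  acceptance-controlled step keeps the monotonicity guarantee exact.
* **Priors.**  Off-diagonal couplings N(0, 1/16) Hz², self-connections
  N(−1, 1/16); hemodynamic log-scalings N(0, 0.015) per region (zero
  scaling reproduces the table values exactly); log precisions N(0, 1).
  The hemodynamic scalings are held at their tight prior means during
  optimization; their prior block is carried into the reported posterior.
  Precisions are *initialized* from the data (half the observed variance
  to measurement noise) — initialization only, the priors are unchanged;
  starting at the prior mean (unit variances) intermittently strands the
  optimizer in a basin where all innovations are attributed to state
  noise.

Convergence: total accepted free-energy gain per iteration < 0.01 nats
(default), max 64 iterations.  The posterior covariance (and the
posterior correlation matrix, reported for identifiability diagnostics)
comes from the scoring/FD curvature at the optimum.

**What the state estimate can and cannot recover.**  For continuous-time
latent dynamics the scan-resolution state carries a within-TR white
component that no estimator can see: with 1 Hz self-decay and TR = 3 s
the conditional mean given *noiseless* BOLD plateaus near corr ≈ 0.7.
Recovery to corr ≥ 0.9 requires either slow intrinsic dynamics or
slow structured input (the epileptic-discharge blocks of the cohort);
both are exercised in the tests.

## 4. Center frequency, validation GLM, group statistics

The empirical ω̄ uses non-overlapping Hann-tapered windows of one TR
aligned to scan onsets (frequency resolution 1/TR = 0.33 Hz), the same
band limits and the same first-moment quadrature as the analytic side.
Per channel, H1 regresses ω̄ on the z-scored sDCM state means plus
confounds and H0 on the confounds alone.  Classical inference is the
partial F-test (Bonferroni over channels); Bayesian evidence is the
closed-form marginal likelihood of a Zellner g-prior linear model with
unit information (g = n) on centered regressors, reference priors on
intercept and noise variance — deterministic and invariant to the scale
of ω̄ and of the regressors.  Two confound sets: *drifts* (Fourier basis,
16 harmonics, 33 columns) and *full* (drifts + 24 motion columns + 18
cardiac/respiratory phase columns + 4 eye channels + one indicator per
scan-nulled volume, ≈ 85 columns).  Scans with any missing value are
dropped listwise; spike indicators emptied by that deletion are removed.
Evidence is pooled within subject by summing log evidences over channels
(fixed effect).

Group level: variational Dirichlet–multinomial random-effects BMS over
the four models {H1, H0} × {drifts, full}; family inference allocates
the prior uniformly over the two families (split equally within) and
sums member frequencies; exceedance probabilities are exact Beta tails
after Dirichlet aggregation in all two-way cases and seeded Monte Carlo
(10⁶ draws) otherwise.  The Bayesian omnibus test compares the free
energy of the RFX model against the null of fixed equal frequencies,
p = 1/(1+exp(F_rfx − F_null)).

Note on the omnibus under a null cohort: with ~12 channels pooled per
subject, even the pure complexity penalty of three unused regressors
(≈ −8 nats per channel under unit-information evidence) produces
subject-level preferences of order 100 nats, and the drifts-vs-full
contest adds differences of the same order; "all four models equally
frequent" is therefore essentially always rejectable in this design, for
coupled and uncoupled cohorts alike.

## 5. Synthetic cohort: what it emulates, and what it does not

Defaults: 9 subjects, 3 regions (thalamus, prefrontal cortex,
precuneus), 700 scans at TR = 3 s, 10 EEG channels + EOG + ECG at
250 Hz.  Per subject: a stable random A (off-diagonals N(0, 0.1²) Hz —
the weak-coupling regime reported for such networks; self-connections
−1 Hz), state noise sd 0.05, and ten epileptic-discharge blocks
(18–36 s) driving all three regions with gains (1.0, 0.7, 0.5).  The
regions of interest in such studies are *selected* for discharge-related
BOLD responses, hence direct drive everywhere; the third region's
response is positive because the log-balloon model cannot express
sustained deactivation (Section 2) — mild negative gains remain
available in the configuration.  Measurement noise is a shared floor
(mean regional signal sd divided by the target SNR = 1), matching both
fMRI physics (thermal noise is region-unspecific) and the model's single
measurement precision.  One percent of volumes are motion-corrupted and
scan-nulled.

EEG synthesis realizes, per scan and channel, the target spectrum
Q_c(ω) = Σ_j M_cj P(ω; z₁ = z₀ + s·x_j) by frequency-domain shaping of
white noise over 50 %-overlap Hann windows (overlap-add), plus a
random-walk drift and a frequency-wandering ~1.1 Hz cardiac component
(dominant on the EOG/ECG channels, whose neural mixing is exactly zero).
The operating point z₀ = 22 mV with the maximum state excursion mapped
to 0.95χ places resting activity near threshold — the critical-slowing
regime in which the center frequency is sensitive to slow fluctuations.
This is a modelling necessity as much as a choice: the coupling gain
c(z₁) is exponentially small below threshold, so an operating point far
from χ yields ω̄ modulations of ~0.02 Hz, unmeasurable through 3-s
windows whose estimation noise is ~1.5 Hz.

The cohort does **not** emulate: MR gradient or ballistocardiogram
artifacts (removed upstream in real pipelines), volumetric fMRI (regions
are summary time series), lead-field mixing geometry (mixing weights are
random positive numbers), inter-subject variability in hemodynamics, or
oscillatory EEG structure beyond the single-field spectrum (no alpha
peak).  Passing tests therefore demonstrate internal consistency of the
chain — states that truly modulate EEG spectra are detected, states that
do not are not — and say nothing about whether real BOLD fluctuations
have electrophysiological correlates.

## 6. Numerical choices and degenerate inputs

* Band and grids: 1–60 Hz, 0.25 Hz for analytic spectra; rfft grids for
  synthesis; trapezoidal quadrature throughout; normalized spectra must
  integrate to 1 within 1e-9.
* Spectra that are zero on the whole band raise; all-zero EEG windows
  yield NaN center frequencies that propagate as missing scans.
* Confound matrices must contain an intercept and be full rank; linearly
  dependent columns are dropped left-to-right by incremental
  Gram–Schmidt with a 1e-8 relative tolerance.
* State-regressor/confound collinearity beyond condition number 1e8
  raises.
* RFX-BMS iterates to Δα < 1e-6 (error after 10⁴ iterations); responsibilities
  are computed with log-sum-exp stabilization.
* All randomness flows through explicit seeds; per-subject seeds are
  spawned from the master seed via `SeedSequence`, and Monte-Carlo
  exceedance probabilities are seeded.

## 7. Problem sizes used in the test suite

Unit tests run the machinery at reduced scale (2–3 regions, 150–300
scans, 20-network sign-recovery study at 200 scans); the end-to-end
checks run the full default cohort (9 subjects, 700 scans, both coupled
and null variants, sharing the BOLD fits that the two variants have in
common).  These sizes keep the suite deterministic and fast while
exercising every stage at the study's native dimensions at least once.
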