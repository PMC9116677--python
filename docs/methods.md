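# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Deterministic model

Two genes in cascade.  The regulator (eBFP2-MS2CP) is transcribed from
an IPTG-inducible promoter repressed by LacI; its mean follows an
activating Hill-Langmuir curve in IPTG with leak fraction ρx, half
saturation θi [μM] and cooperativity ni.  The target (sfGFP) is
constitutively transcribed; the regulator binds an RNA hairpin on its
mRNA and blocks translation, so the target mean follows a repressing
Hill curve in the regulator level with floor fraction ρy, half
saturation θx [AU] and cooperativity nx.  Fluorescence (arbitrary
units, AU) is taken proportional to protein amount per cell.

Tetracycline sets the growth rate through Michaelis-Menten inhibition
μ(TC) = μ0/(1+TC/θc) (μ0 = 1.2 h⁻¹, θc = 526 ng/mL in the bundled
set).  Growth feeds back on expression three ways:

1. Transcription scales with μ; in amounts per cell this cancels
   against dilution, so it leaves the means unchanged but enters the
   simulator's mRNA pools.
2. The translation rate of gene *i* scales as λi(μ) ∝ (ε1i−μ)/(ε2i−μ),
   the reciprocal form that arises when ribosome content rises as an
   antibiotic slows growth.  Both factors are negative on the valid
   domain μ > ε2, so the scale is positive and grows as μ falls.  The
   maximal expressions αx, αy carry this factor relative to μ0.
   The form has a pole at μ = ε2; all evaluators restrict to
   μ > ε2 + 0.01 h⁻¹ and reject anything below, since the rational
   form has no physical meaning at or past the pole.
3. Cells swell as growth slows (volume ∝ e^{δ(μ0−μ)}, δ = 0.85 h,
   measured through the cubed forward-scatter median).  Since the
   model tracks amounts, not concentrations, the regulator-motif
   constant is corrected to θx(μ) = e^{δ(μ0−μ)}θx.  Transcriptional
   regulation is growth-independent (LacI is abundant and sensed
   through inducer concentration), so θi and ni are untouched.

Synthesis rates are SR = mean × μ (stable proteins).  Relative to the
TC = 0 state, the regulator's SR curve is λx(μ)/λx(μ0) · μ/μ0 for
every IPTG level — regulation and growth decouple under
transcriptional control — with an interior minimum at the closed-form
stationary point μ* = ε2x + √(ε2x(ε2x−ε1x)) ≈ 0.475 h⁻¹.  The
target's curve depends on IPTG; at 100 μM it peaks near 0.65 h⁻¹.
`locate_extremum` scans a 2000-point uniform grid and refines with a
bounded scalar minimizer to better than 0.005 h⁻¹ (the curves are
smooth and flat near their extrema; the grid guards against the
refiner latching onto the wrong lobe, and a boundary extremum raises
instead of returning a spurious interior point).

## Noise model

Total noise is the squared coefficient of variation, decomposed
additively assuming independent sources:

* extrinsic: a constant CV² plateau η² per gene (shared-machinery
  variability);
* intrinsic: β/⟨p⟩, with β an effective Fano factor in fluorescence
  units;
* regulation: ½ · (transfer-function slope)² × upstream variance /
  mean².  For the regulator the upstream variance is the LacI-activity
  constant η²lac [μM²] on the IPTG axis; for the target it is
  γy·⟨eBFP2⟩²·CV²eBFP2, with γy converting fluorescence variance to
  the molecular variance that actually propagates.  The ½ prefactor
  comes from time-averaging of colored upstream noise by dilution and
  is taken as given, not re-derived.

Growth scalings: βx and η²x follow λx(μ)/λx(μ0), η²y follows the
target's translation scale, η²lac follows (μ/μ0)²; βy and γy are
constant (the target mRNA is abundant, so its transcriptional noise is
negligible — the mechanism behind translational noise buffering).
Slopes are evaluated in closed form; finite differences appear only as
test oracles.

Single-cell fluorescence is Gamma distributed in the mesoscopic
parameterization: shape a = 1/CV², scale b = mean·CV² (an effective
Fano factor).  Consequently b tracks the translation rate for the
transcriptionally controlled regulator but is nearly independent of it
for the translationally controlled target.

## Langevin simulator

The exact stochastic system behind the analytic moments is
reconstructed as the minimal four-variable birth-death system (mRNA
and protein per gene, dilution at μ) whose stationary moments
reproduce the decomposition term by term; agreement with the analytic
CV² — not fidelity to any particular derivation — is the design
target.

* **Intrinsic noise**: white, with propensity-style state-dependent
  amplitudes √(2·rate·state) (square-root diffusion).  This keeps
  states non-negative and yields the skewed Gamma-like marginals that
  a constant-amplitude (Gaussian) scheme cannot produce at CV² ≈ 0.3–
  0.5.  mRNA pools default to 10 (regulator, at full induction and
  μ0) and 1000 (target — abundant constitutive transcript) in model
  units, with turnover d_m = 6 h⁻¹ (few-minute half-life); the
  mRNA-borne share of the protein Fano factor, λ/(d_m+μ), is
  accounted for and the protein-level white amplitude covers the
  remainder (β − λ/(d_m+μ), which must be non-negative or the
  requested mRNA scale is rejected as inconsistent).
* **Extrinsic noise**: one mean-one lognormal of an
  Ornstein-Uhlenbeck process per gene, injected additively as a
  perturbation of the stationary synthesis flux.  Additive injection
  keeps the three sources statistically independent, exactly as the
  analytic decomposition assumes; multiplying the translation flux
  instead would cross-couple the extrinsic factor into the mRNA-borne
  and regulation variances (by E[X²] = e^{σ²}) and overshoot the
  total by tens of percent.
* **LacI/regulation noise**: a mean-one lognormal OU multiplying the
  regulator's transcription rate.  Its log-variance is solved by
  quadrature so that, after low-pass filtering by the mRNA and
  dilution stages, the stationary contribution equals the analytic
  regulation term (the filter-overlap kernels are closed-form; the
  lognormal autocovariance e^{σ²ρ(t)}−1 is integrated numerically and
  the variance root-found with Brent's method).
* **Target regulation**: the regulator protein drives the target's
  translation rate through the linearized slope of the repression
  Hill factor, with the sensed deviation attenuated by √γy.  This
  channel is *not* calibrated — the ½ prefactor and the resulting
  regulation noise emerge from the dynamics — and serves as the
  internal consistency check between simulator and analytic model.
  Linearization matches the analytic treatment (slope-squared
  propagation); the full Hill nonlinearity would rectify the large
  LacI fluctuations (sd ≈ 80 μM against θi = 116 μM) and bias the
  mean upward by tens of percent relative to the mean-field model.

Colored processes default to correlation time τ = 1/μ (a generation;
extrinsic fluctuations persist over the cell cycle), which is also
what produces the analytic ½ time-averaging factor.  Integration is
piecewise-deterministic with fluctuations frozen over each 0.01 h
update interval — within an interval the system is then linear and is
advanced by its closed-form exponential update, which is exact, so no
adaptive stepper is needed; the target translation rate is evaluated
from the regulator level at the interval start, giving a first-order-
in-dt error only in that one coupling (halving the interval changes
stationary CV² by less than Monte-Carlo error; the suite checks
this).  White terms are redrawn per interval with variance 1/Δt
scaling; OU states advance by their exact update.  Negative states
are clamped to zero and counted; a clamp rate above 0.1% of updates
raises a warning (at the bundled parameters clamping is essentially
absent except mild mRNA clamping near the regulation-noise peak).
Each trajectory consumes an independent child of the master seed, so
enlarging an ensemble never alters existing trajectories.

Known deviations: simulated stationary CV² sits within ~5% of the
analytic totals (slight deficit from clamping and the zero-order hold
of colored noise), and the simulated regulator distribution differs
from the predicted Gamma by a Kolmogorov-Smirnov distance of 0.02–
0.035, largest at the regulation-noise peak where the propagated
lognormal component is not Gamma.

## Synthetic data generator

Emulates the characterization measurements so the inference chain is
testable end to end:

* **Cytometry events**: per condition and channel, n draws from the
  predicted Gamma law, plus Gaussian autofluorescence (default
  100 ± 30 AU — a documented convention, removed on average by the
  subtraction stage), plus an outlier fraction (default 1% in the
  pipeline; uniform on [0, 10×P99] of the clean channel, stressing
  the outlier-removal stage without modeling cytometer physics).
  Channels are independent by default since the analytic model
  constrains only the marginals; an optional mode maps each cell's
  regulator quantile through the repression transfer function for a
  negatively correlated joint readout.
* **Growth curves**: OD(t) = OD0·e^{μ(TC)t}(1+ε) with multiplicative
  noise (default sd 0.02) and a stationary ceiling (default OD 1.0);
  OD0 = 0.01 mirrors a 1:50 dilution of an exponential culture, read
  hourly for 10 h.
* **Volume proxy**: forward scatter with median fsc³ =
  e^{δ(μ0−μ)}, lognormal event scatter (sd 0.2 in log, median-
  preserving).

What the generator does *not* emulate: correlated extrinsic noise
across channels (the model's known independence inaccuracy),
scatter-gating artifacts, instrument saturation, and heterogeneous
per-cell growth.  Passing tests therefore show the chain is
self-consistent under the model's own assumptions, not that those
assumptions hold in any particular experiment.

## Inference chain

Mirrors the characterization workflow: subtract the blank mean per
channel (negative values are kept for unbiased moments but excluded
from Gamma fitting, which needs positivity); remove outliers outside
median ± 5 MAD (Gaussian-scaled; parameter-free and robust, while
preserving most of the genuine Gamma tail — though on the
heaviest-tailed channel, shape ≈ 2, the fence still trims ~0.4% of
real mass and deflates CV² by ~6%, a documented bias of any robust
rule on heavy tails); compute mean, variance, CV² per condition;
estimate growth rates as the log-OD slope over the longest contiguous
window of ≥ 4 points with R² ≥ 0.99 (stationary points fail the
linearity screen; a single ceiling-crossing point can still slip in,
shifting the slope by a few percent — a manual window override
exists); then sequential least squares with lmfit:

* growth Michaelis-Menten (μ0, θc), θc multistarted log-spaced;
* the two Hill fits, means weighted by 1/mean (multiplicative error
  structure), with deterministic multistart grids — half-saturation
  log-spaced over the data range × cooperativities {1,2,3,5,8} —
  because Hill objectives are multimodal;
* the six noise constants against both CV² profiles jointly,
  unweighted, non-negativity by bounds, deterministic parameters held
  fixed (the sequential scheme of the characterization);
* Gamma by method of moments (exactly the mesoscopic
  parameterization), optional ML refinement;
* translation-scaling constants from relative-SR curves with an
  ordered parameterization (ε2 = ε1 + gap, gap > 0), and δ by linear
  regression of log median fsc³ on μ0 − μ.

Identifiability is reported, not hidden: boundary-stuck and wide-
uncertainty estimates are flagged, a flat growth profile flags θc as
unidentified, a regulator range that misses θx flags nx.  One limit
worth knowing: from 9-point CV² profiles with 10% noise, βx is weakly
identified (estimator sd ≈ 35% — the intrinsic term spans only ~0.08
of CV² against ~0.03 per-point noise), so recovery to a few percent
requires event-level data (10⁴ events per condition give ~3%-precise
CV² and ~8% βx precision).

## Problem sizes

Defaults chosen as a realistic study scale: 9-level IPTG gradient
(0–1000 μM) and 9-level TC gradient (0–1000 ng/mL), ~10⁴ events per
condition, 3 growth replicates; Langevin ensembles of 200 trajectories
× 50 h with 10 h burn-in (≈ 60 correlation times of stationary data
per trajectory).

## Known limitations

* Independence of noise sources is assumed throughout; shared
  extrinsic fluctuations between the two channels are not modeled.
* Population-average growth rate; no per-cell growth heterogeneity or
  division lineages.
* The Langevin scheme is diffusion-level; no exact jump-process
  (Gillespie) engine is provided.
* The TC action on translation is phenomenological (the rational
  λ(μ) form and Michaelis-Menten growth inhibition), not a mechanistic
  ribosome model, and the λ(μ) form is meaningless below its pole.
* The spreadsheet reader is a best-effort dialect for one deposited
  layout and is exercised only against synthetic workbooks.
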