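# Methods

## Measuring transcription-factor activity by repression

The central measurement idea is to read a transcription factor's in-vivo
activity as *repression* of a constitutive promoter rather than activation of
a native one, which sidesteps promoter-specific, non-linear
factor–polymerase interactions. The reporter model is single-operator
repression,

    S(A*) = α_rep / (1 + A*) + T,

strictly decreasing from `α_rep + T` (unrepressed) to the basal plateau `T`.
Its inverse,

    A* = α_rep / (S − T) − 1,

is the activity estimator. Three numerical guards make it total:

* readings above the unrepressed level invert negative and are clamped to 0;
* readings at or below `T` (where the inverse diverges) map to a finite
  activity cap, default 50, with a warning — this keeps downstream fits
  well-posed;
* missing values (NaN) propagate as NaN.

The round trip `infer(forward(a)) = a` holds to 1e-9 relative error on
`[0, 0.99·cap]` and is enforced by property test.

Calibration takes `T` as the robust minimum of a reporter's own expression
across conditions (its fully-repressed plateau) and `α_rep` as robust
maximum minus `T` — the activation span is by definition the difference
between fully-unrepressed and fully-repressed expression. An alternative
reading of the calibration — differencing against the σ70 channel per time
point — exists in the field; we default to the reporter's own plateau
because it makes `T` a property of the reporter rather than of a second
measurement, and expose the choice through the calibration parameters of
`RepressionReporter` (any `(α_rep, T)` pair can be supplied directly).
Raw luminescence is normalised to OD600 first; OD readings at or below a
floor of 0.01 are treated as missing rather than divided by, reflecting the
unreliability of early time points.

## Steady-state input integration

Promoter expression is modelled over bound states — AraC–arabinose alone
(rate α), CRP–cAMP alone (β), both (γ) — scaled by the measured polymerase
signal σ and offset by basal transcription `T_B`:

    B = σ (α A* + β C* + γ A* C*) + T_B        (additive, default)
    B = σ (α A* + β C* + γ A* C*) / (1 + A* + C* + A* C*) + T_B   (occupancy)

The additive form is the default; the occupancy-weighted variant is kept
behind a `form` flag for users who prefer a partition-function reading of
the bound states, and is never selected automatically. σ enters in raw
expression units, so the coefficients are dimensionless and of order 1–10.
They are *relative* quantities: they absorb the ratio of factor binding at
the synthetic reporters to binding at the native promoters, so they rank
inputs within and across promoters but are not absolute activation rates.

Fitting is honest nonlinear least squares (`scipy.optimize.least_squares`,
Levenberg–Marquardt) with the convergence flag reported, asymptotic standard
errors from the Jacobian, and two-sided t-tests of each coefficient against
zero at level 0.05 (configurable). Because the additive form is linear in
(α, β, γ, T_B), the fit must coincide with ordinary least squares; the test
suite checks this against an independent OLS implementation to 1e-8. A
rank-deficient design (e.g. constant activities) raises a singular-fit
error rather than returning arbitrary coefficients. No non-negativity
constraint is imposed; a significant negative coefficient is reported with
a warning.

Model reduction drops every activity term insignificant at the chosen level
(never the basal), refits, and compares by residual standard error and AIC.
The AIC convention is Gaussian-likelihood with the error variance counted as
a parameter, `AIC = n ln(RSS/n) + 2(k + 1)`; conventions differ by an
additive constant that cancels in comparisons. `T_B` is fitted as a free
intercept by default, with a config option to pin it to a measured
uninduced mean.

## Dynamics during diauxic shift

Expression integrates production minus first-order loss,

    dB/dt = σ(t)(α A*(t) + β C*(t) + γ A*(t) C*(t)) + T_B − μ B.

Loss is dilution by growth, μ = ln 2/τ with τ the cell-cycle time (estimated
by log-linear OD regression over an exponential window), for long-lived
catabolic enzymes; for AraC, whose turnover is fast, a degradation constant
is added: μ = ln 2/τ + k_deg with k_deg = 0.0833 min⁻¹ by default. Note a
documented inconsistency: that constant is conventionally derived from a
60-minute half-life, which would give ln 2/60 ≈ 0.0116 min⁻¹; we use the
constant as printed in the source literature and flag the tension rather
than resolving it silently.

The integrator is fixed-step classic RK4 on the 4-minute measurement grid,
each interval sub-stepped ×4, with the driving signals A*, C*, σ linearly
interpolated between measurements. The drivers are piecewise-linear
measured series and μ ≤ ~0.13 min⁻¹, so the problem is non-stiff and RK4's
quartic convergence (checked: ≥ 4× error reduction on sub-step halving
against the constant-input closed form, agreement to 1e-6) is ample. The
initial condition defaults to the steady state implied by the initial
production (callers typically pass the first observed value); trajectories
are clipped at zero.

Replicate shift experiments differ in when glucose runs out, so series are
aligned before averaging: the rise of CRP–cAMP activity is detected as the
first time C\* exceeds its baseline mean + 3 SD (baseline = first 5 points)
for 2 consecutive points, each replicate is shifted so time zero falls 20
minutes before that rise, series are linearly interpolated onto a common
grid and averaged pointwise with the per-point replicate count reported.
Activities are computed per replicate and then averaged (not the reverse):
the activity inverse is nonlinear, so the order matters, and per-replicate
inversion keeps each replicate's own calibration regime. Prediction quality
is scored by RMSE, peak-time error, and the observed/predicted peak ratio —
the statistic behind "observed expression was about two-fold higher than
predicted".

## The synthetic-data generator

No plate-reader datasets are published for this system, so a seeded
generator stands in, emulating the two experiment classes with known ground
truth.

*Gradient plates.* Up to 96 arabinose (0–0.2 % w/v) × cAMP (0–1 mM)
combinations, default 12 × 8, read every 4 minutes over 90 minutes with the
44-minute read taken as steady state. True activities come from a
dose–response map: step-like for AraC (Hill coefficient 4 on
`ara/(K_a + ara)`, K_a = 0.05 %, max 3) — matching the observed switch-like
arabinose response — and graded for CRP (Michaelis form, K_c = 0.2 mM,
max 3), with σ constant. The promoter channel is the forward integration
model of those activities; reporter channels are the repression model.
Generating coefficient sets default to the published per-promoter fits with
the CRP-alone term structurally zero.

*Diauxic shifts.* Seven replicates by default. Each replicate draws a
glucose-exhaustion time uniformly within ±12 min of 60 min; CRP–cAMP
activity follows a piecewise-exponential pulse anchored at exhaustion
(baseline + amplitude·(1 − e^(−Δt/rise))·e^(−max(0, Δt−rise)/decay), rise
6 min, decay 10 min) and AraC–arabinose activity rises afterwards as a
saturating exponential toward a ceiling (onset 10 min after exhaustion,
rate 0.04 min⁻¹, ceiling 3). The pulse and rise shapes are phenomenological
stand-ins — only their qualitative character (sharp transient pulse;
subsequent monotone bounded rise) is constrained by observation — and the
saturating form was chosen over unbounded exponential growth so the signal
respects its ceiling and a zero rate degenerates exactly to baseline.
OD grows logistically/biphasically with a 20-minute lag at exhaustion,
independent of expression (no growth–expression feedback).

Noise is multiplicative lognormal on luminescence (default σ = 0.05) and
additive Gaussian on OD (default SD 0.002, floored at a small positive
value); zero noise reproduces the forward models exactly and the same seed
reproduces the dataset byte-for-byte after serialisation. What passing
tests show is therefore that the *machinery* — inversion, fitting,
reduction, integration, alignment — is correct under the assumed noise
structure; real plate data add features the generator does not emulate
(background luminescence drift, growth–expression coupling, reporter
cross-talk such as arabinose catabolism feeding back on cAMP, well-position
effects), so recovery performance here bounds, but does not guarantee,
performance on real data.

## Operator design

Consensus operators are computed per alignment column as the minimal IUPAC
code covering every base whose frequency (among non-gap characters) exceeds
`purity_threshold`; the default 0 covers all observed bases, and e.g. 0.5
gives a majority consensus (the threshold semantics were genuinely open and
this reading is the one under which the default reproduces "cover
everything observed"). Gaps are ignored for code selection; an all-gap
column is an error. Degenerate-variant counts multiply per-position code
sizes; reporter constructs concatenate the 47-nt constitutive σ70 promoter
with the operator immediately downstream and record the 1-based junction
coordinate. The shipped primer fixture preserves the printed sequences
verbatim, including one design primer with three rather than the nominal
four degenerate positions. No binding-energy or PWM scoring is attempted —
which library member represses most strongly was an experimental screening
question, out of scope here.

## Problem sizes and defaults

Default analyses are sized to their experiments: 96-well gradients, 7 shift
replicates on a 4-minute grid over 3 hours, 50-replicate noisy-recovery
studies and 200-replicate model-selection studies. The full four-promoter
pipeline (`aralogic run-all`) completes in about a second on one CPU; the
whole test suite runs in well under a minute.

## Known limitations

* The repression model is the single-operator form; cooperative (Hill n>1)
  repression is a one-line swap behind `repression_forward`/`infer_activity`
  but is not implemented as an option.
* AraC's repressor role at P_araC (its O1 site) and any CRP cooperativity at
  P_araFGH are not modelled; these are exactly the promoters where predicted
  dynamics are expected to deviate.
* Exogenous cAMP toxicity, inducer exclusion, and the mechanism generating
  the cAMP pulse (PTS/adenylate-cyclase signalling) are outside the model;
  the pulse is an input, not an output.
* Fitted coefficients are relative to the synthetic reporters' binding
  context and cannot be compared across studies as absolute rates.
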