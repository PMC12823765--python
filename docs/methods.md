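# Methods

This note documents the model, the numerical choices and the synthetic
study design behind the package, in the spirit of a model-description
vignette. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The bloom model

A dormancy season (1 September of the year before harvest through 30 June
of the harvest year, configurable) is simulated on hourly temperatures.

**Chill (Dynamic Model).** Winter chill follows two-step kinetics. A
precursor of the dormancy-breaking factor (PDBF, level `x`) is formed and
destroyed with Arrhenius rates `a0 = A0·exp(−E0/T)` and
`a1 = A1·exp(−E1/T)` (T in Kelvin, with the ecosystem convention
K = °C + 273 so that the fixed optimum θ* = 279 K is 6 °C). Over one hour
at constant T the precursor relaxes toward its steady state
`xs = (A0/A1)·exp((E1−E0)/T)` as `x' = xs − (xs − x)·exp(−k1)` with
`k1 = a1`. Whenever `x'` reaches 1, a sigmoidal fraction
`ξ(T) = s/(1+s)`, `s = exp(slope·Tf_K·(T−Tf_K)/T)` converts irreversibly
into accumulated chill: `y += ξ·x'`, `x ← x'(1−ξ)`. `y` is measured in
Chill Portions and is nondecreasing by construction. Conversion is checked
at most once per hourly step, after the kinetic update.

**Heat (Growing Degree Hours).** The hourly forcing response is the
piecewise cosine between base (Tb), optimal (Tu) and critical (Tc)
temperatures: zero at or below Tb and at or above Tc, rising to `Tu − Tb`
at Tu, decreasing along a half cosine back to zero at Tc. The stress
factor of the original formulation is fixed at 1. Tc is held at 36 °C
throughout.

**Coupling.** The hourly heat contribution is gated by a logistic function
of accumulated chill, `w(y) = 1/(1 + exp(−s1·(y − yc)))`: 0.5 when chill
equals the cultivar's requirement yc, saturating beyond it. Large s1 gives
strictly sequential chill-then-heat accumulation; small s1 allows parallel
accumulation. Gated heat is counted in **normalized GDH units** — the
hourly response divided by its maximum `Tu − Tb`, i.e. "effective optimal
hours". This is the unit in which the heat requirement zc (search range
100–700) is expressed; with the raw response the same range would be
exhausted within days and the bounds would be meaningless. Bloom is the
calendar day of the first hour at which gated heat reaches zc; a season
that ends earlier records a failure to bloom.

## Intermediate chill parameters

The canonical kinetic constants (E0, E1, A0, A1) are poorly constrained
and span orders of magnitude, so calibration searches over four
interpretable intermediate parameters instead: θ* (optimal constant
chilling temperature, fixed at 279 K), θc (critical constant temperature
at and above which no chill accumulates, 286–287 K), τ (hours to the first
chill portion at constant θ*, 16–48 h) and πc (critical period of a
combined cool/warm cycle at which chill negation sets in, 24–50 h).

The package inverts these defining conditions numerically rather than
transcribing a closed form:

1. **θc:** `xs(θc) = 1` exactly. After solving, A0 is nudged downward by
   at most a few ulps so the identity also holds in floating point —
   otherwise a steady state a few ulps above 1 lets 1200 h at θc deliver a
   spurious portion.
2. **τ:** at constant θ*, starting from x = 0, the precursor first reaches
   1 after exactly τ hours in continuous time (the discrete hourly
   recursion coincides with the continuous solution at integer hours, so
   the first simulated portion arrives at hour ⌈τ⌉).
3. **θ\* optimality:** the time-to-first-portion as a function of constant
   temperature is stationary (minimal) at θ*. Together with (1) and (2)
   this fixes E1, A1 and A0 in closed form *given* the energy gap
   Δ = E1 − E0.
4. **πc:** Δ is pinned by root-finding on a chill-negation threshold: a
   square-wave cycle spending 25 % of each period at θ* and 75 % at 292 K
   (19 °C, within the range of the classic negation experiments) run at
   period πc sits exactly at the boundary where the asymptotic per-cycle
   precursor maximum equals 1 (no portion is ever delivered for longer
   warm phases). The literature defines the concept but not the cycle;
   both the warm temperature and the duty fraction are configuration
   (`NegationCycle`). The defaults were chosen so that a single cool phase
   can never exceed τ anywhere in the calibration box (with a 50 % duty a
   16-h τ makes negation impossible and the defining equation has no
   root), and so that the root in Δ exists and is unique across the whole
   box — verified on a 5×5×5 grid before freezing.

The mapping is deterministic, continuous in its inputs, and verified in
the test suite by direct simulation of conditions (1) and (2).

## Calibration

Three schemes, all minimizing pooled bloom-date RMSE (days):

| scheme | free parameters | count (K cultivars) |
|---|---|---|
| baseline | yc, zc, s1 per cultivar; submodels at defaults | 3K |
| cultivar-fit | yc, zc, s1, θc, τ, πc, Tf, slope, Tb, Tu per cultivar | 10K |
| combined-fit | 7 shared submodel parameters + yc, zc, s1 per cultivar | 3K + 7 |

Default submodel parameters are E0 = 3372.8, E1 = 9900.3, A0 = 6319.5,
A1 = 5.939917×10¹³, Tf = 4 °C, slope = 1.6, Tb = 4 °C, Tu = 26 °C.

**Objective smoothness.** Reported predictions are calendar days, but an
integer-day objective is piecewise constant in the parameters and defeats
derivative-free local search. The fitted objective therefore uses
continuous bloom times (linear interpolation of the zc crossing within the
hour) and treats an observed day d as the interval [d, d+1), entering as
its midpoint d + 0.5. Without the midpoint convention the continuous
prediction is biased about +0.5 d against day-floor observations, and the
optimizer measurably exploits that bias by distorting parameters. Failure
to bloom contributes the penalty residual
`(season-end DOY − observed DOY + 30) + 100·(zc − z_final)/zc`, finite,
dominating ordinary residuals and decreasing as the model approaches
blooming. Candidates whose intermediate parameters admit no canonical
solution receive a large finite penalty (10⁶) rather than raising.

**Optimizer.** A seeded differential-evolution global stage (Sobol
initialization, immediate updating, dithered mutation 0.3–1.0,
recombination 0.9, population = popsize × dimension) runs within bounds,
followed by a bounded Powell polish. Baseline and cultivar-fit objectives
are separable by cultivar and are solved as independent per-cultivar
searches (3- and 10-dimensional respectively), with per-cultivar seeds
spawned deterministically from the problem seed. Degenerate bounds
(lower = upper everywhere) short-circuit to that point.

The combined-fit landscape needs more than that: it contains many
separated basins that differ in the shared submodel shape while the
requirement parameters compensate — yc trades against the chill-portion
rate 1/τ, zc against the heat-response scale set by Tu and Tb — and the
kink-dense residual surface makes axis-wise local descent unreliable, so
a single population search routinely converges into a basin a few tenths
of a day above the best one. The combined-fit pipeline therefore adds,
after the global stage and a cyclic block-coordinate refinement
(alternating each cultivar's requirement block, which re-simulates only
that cultivar's seasons, with the shared 7-parameter block):

1. a **profile-likelihood multistart** over the shared block —
   Sobol-sample the 7 shared parameters; score each sample cheaply by
   rescaling yc with τ (preserving gate timing) and *profiling* zc to the
   mean gated heat accumulated by the observed bloom hours; then re-score
   the best two dozen samples by actually optimizing every cultivar's
   (yc, zc, s1) block with a small seeded search, which turns the score
   into an honest profile likelihood of the shared parameters;
2. a **small-box zoom** — a short differential-evolution run on a box
   shrunk around each finalist (narrower for shared than for requirement
   coordinates), which restores the population diversity needed to
   descend along curved couplings that Powell cannot follow — followed by
   block refinement; the basin with the lowest refined objective wins.

Everything is deterministic given the problem seed; a single pipeline run
is used throughout — no independent restarts. The default desk budget
(popsize 12, 400 generations, plus the rescue stages above) calibrates
the default three-cultivar combined-fit problem in about four minutes on
one CPU; the acceptance script and the recovery test use this budget.

## Validation protocol

Per-cultivar random splits (seeded, disjoint, exhaustive): *full* mode
assigns round(0.75·n) observations to calibration (round-half-to-even);
*scarce* mode exactly 10, requiring ≥ 11 so at least one validation point
remains; under-sampled cultivars are excluded with a warning. A
chronological split is available behind a flag; random is the default
because the observation years are exchangeable in the synthetic setting.
Metrics: RMSE; RPIQ = IQR(observed)/RMSE with quartiles by linear
interpolation between order statistics (the convention matters and is
fixed); mean bias (predicted − observed); share of |residual| > 7 days.
RMSE = 0 makes RPIQ an infinite-ratio flag (`None`), not a number.
Validation predictions that fail to bloom are excluded from metrics and
counted separately.

**Response curves.** For diagnosis, each submodel is driven with 1200 h of
constant temperature over −5…50 °C at 0.1 °C (551 points). The chill curve
reports Chill Portions; the heat curve is normalized to a maximum of 1.0,
so only its shape (onset, optimum, critical point) is comparable across
fits.

## Synthetic study design

`generate_weather` draws daily means from a sinusoidal annual cycle
(coldest day = 15 January by default) plus AR(1) noise, with tmin/tmax a
half diurnal range below/above. Defaults — 40° latitude, annual mean
14 °C, amplitude 9 °C, diurnal range 10 °C, AR(1) 0.7, innovation sd
2 °C, 26 years — emulate a mid-latitude Mediterranean-temperate orchard
site (Ebro-valley-like) whose winters deliver roughly 100–130 Chill
Portions. Hourly temperatures use the idealized diurnal curve standard in
horticultural chill modelling: a sine rise from sunrise to the afternoon
peak (the hour nearest sunrise + (daylength+4)/2, anchored exactly at
tmax so sampled series preserve the daily maximum), a sine decline to
sunset, and a logarithmic decline overnight toward the next day's minimum,
with sunrise/sunset from the standard solar declination and hour-angle
equations. When the next day is much warmer, the overnight segment rises
instead of falling — the curve follows the data rather than clamping to
the current day's extremes.

The default ground truth (`TruthSpec`) is one species with shared
submodels (θc = 286.5 K, τ = 30 h, πc = 38 h, Tf = 4 °C, slope = 1.6,
Tb = 4 °C, Tu = 25 °C) and three cultivars spanning early to late bloom:
(yc, zc, s1) = (24, 190, 0.4), (32, 260, 0.6), (40, 340, 0.9). Observation
noise is Gaussian (sd 1 day) rounded to whole days, since bloom records
are calendar dates. The default recovery scenario — 3 cultivars × 25
seasons — mirrors the data volume of a typical long-term multi-cultivar
phenology dataset.

**What the generator does not emulate:** spatial structure, humidity and
radiation effects, observation-protocol drift, cultivar plasticity,
asymmetric diurnal cycles, and weather extremes beyond AR(1) noise.
Passing recovery tests therefore demonstrates internal consistency and
optimizer adequacy under the model's own assumptions, not predictive
skill on real orchards.

## Numerical choices and edge cases

- Kelvin offset 273 (not 273.15), a framework-ecosystem convention.
- Empty temperature series → empty chill trajectory (final chill 0).
- Seasons shorter than 30 days are rejected as degenerate.
- No clamp is applied to heat accumulated before any chill: the logistic
  gate is small but nonzero at y = 0, which is the parallel-accumulation
  limit of the model.
- The reparameterization root-find brackets Δ ∈ [50, 2×10⁵] and fails
  loudly (naming the negation condition) if no sign change exists.
- Gap filling: tmin and tmax are filled independently, each with its own
  window bias; a gap with zero shared days is left missing and flagged;
  |bias| or sd above 3 °C is flagged but still used. With several
  auxiliary stations the one with most shared days wins, ties broken by
  smaller |bias|. Filling is idempotent.
- Auxiliary-station distance screening (≤ 70 km) is metadata-level and not
  enforced numerically.
- Hourly inner loops are JIT-compiled (numba); the test suite checks them
  against straight-line pure-Python reference loops to 1e−9.

## Known limitations

- The negation-cycle construction behind πc is one concrete realization of
  a concept the literature leaves underspecified; alternative cycles give
  different (θc, τ, πc) ↔ (E0, E1, A0, A1) mappings that agree on
  conditions (1)–(3).
- Combined-fit recovery inherits the equifinality of process-based
  phenology models: submodel shape parameters (Tf, slope, s1) are weakly
  identified from bloom dates alone, and requirement estimates trade off
  against submodel shifts. The recovery tests quantify this under the
  default scenario rather than hiding it. At the default data volume
  (75 observations, 1-day noise) the profile likelihood of the shared
  block can separate the true basin from its compensating competitors by
  only a few hundredths of a day of RMSE on some noise realizations; on
  such draws the selected basin — and hence the requirement estimates —
  can differ from the truth even when the calibration RMSE is at the
  noise floor. This is a sampling property of the estimator, not an
  optimizer bug; more observations or informative priors on the submodel
  shape are the remedies.
- Bloom is reported at day granularity only; sub-daily timing is outside
  scope, as are photoperiod effects and stages other than full bloom.
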