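# Methods

## The power–duration model

`critpower` is built around the two-parameter critical-power (CP) model of
maximal performance: the highest mean power `P` sustainable for a duration
`t` follows a hyperbola

    P = W'/t + CP            (power form)
    t = W'/(P − CP)          (time-to-exhaustion form)
    Work = CP·t + W'         (work form)

CP (W) is the asymptote — physiologically, the boundary between the heavy
and severe exercise-intensity domains, the highest power at which muscle
metabolic homeostasis is sustainable. W′ (J) is the finite work capacity
expendable above CP before task failure. For velocity sports the same
algebra holds with critical velocity CV (m/s) and D′ (m); the code reuses
one path.

The three algebraic forms are equivalent on exact data (and the test suite
asserts recovery to ≤1e−8 relative error for all three) but are *not*
equivalent under noise, because each places the error on a different
response variable. `critpower` assigns the form by protocol:

| data source                      | measured outcome | fitting form            |
|----------------------------------|------------------|-------------------------|
| TTE (constant work rate)         | duration         | hyperbolic, nonlinear LS on `t` |
| constant-duration / MMP / field  | power            | OLS of `P` on `1/t`     |
| time trial (fixed work/distance) | work vs time     | OLS of `Work` on `t`    |
| 3-min all-out test               | trace            | end-test power reduction |

All regressions are ordinary least squares; errors-in-variables estimation
is deliberately out of scope. The regressor is treated as error-free, which
is the universal (if imperfect) practice with this model; the caveat is
surfaced here rather than silently absorbed.

Numerical choices:

* The hyperbolic fit is a bounded nonlinear least squares (trust-region
  reflective) initialised at the linearised OLS estimates, with
  CP ∈ (0, 0.999·min(P)], tolerances 1e−10, at most 500 function
  evaluations. On exact data it terminates at the global optimum to
  machine precision; the initial guess is exposed
  (`hyperbolic_initial_guess`) so the contract is testable.
* With exactly two distinct trials every form returns the identical exact
  solution and all variance quantities are NaN (zero residual degrees of
  freedom); goodness-of-fit is explicitly marked unavailable.
* 3-min all-out reduction: CP = mean power over the final 30 s
  (samples 150–180 s inclusive); W′ = trapezoidal integral of
  max(P − CP, 0) over 0–180 s. On a step trace the trapezoid attributes
  half a sample to the transition (the 500→300 W step fixture yields
  11,900 J rather than the rectangle sum's 12,000 J); this convention is
  frozen and tested. Non-uniform or >1 s sampling is rejected rather than
  re-weighted. Because the supra-CP transient need not have fully decayed
  by 150 s, the end-test power is biased upward; the generator's default
  decay constant (solved so the supra-CP integral equals W′) keeps the
  bias under 1 %, but slower decays give several percent.
* Every fit records its data's duration range. The hyperbola is a good
  approximation only between roughly 3 and 40 minutes; fits extending
  outside 180–2400 s carry an `extrapolation_risk` annotation, and every
  prediction reports whether it interpolates or extrapolates. Outside the
  fitted range the model systematically *overpredicts* (a property test
  constructs a three-parameter generator and verifies the direction).
* Residual diagnostics are descriptive only: a Wald–Wolfowitz runs test on
  residual signs ordered by the regressor (lack of fit shows up as too few
  runs) plus a Shapiro–Wilk normality p-value. All-zero residual fits are
  flagged degenerate instead of producing meaningless statistics.

Prediction intervals use the standard OLS new-observation formula at
x\* = 1/t with a t-distribution on n−2 degrees of freedom; parameter
confidence intervals are t-based marginals. Both are cross-checked in the
tests against `statsmodels` as an independent implementation, and a
Monte-Carlo test confirms 99 % empirical coverage within [0.985, 0.995]
over 5,000 held-out points.

A known artefact of the hyperbolic form is the anti-correlation of CP and
W′ changes: improving only the longest-duration trial rotates the fitted
curve, raising CP while *lowering* W′. The suite verifies the direction in
100/100 constructed cases. Flagging logic downstream must not interpret a
W′ drop alongside a CP rise as two independent signals.

## W′ balance

During intermittent exercise the remaining capacity is modelled as

    W'_bal(t) = W'_0 − Σ_{u≤t} max(P(u) − CP, 0)·Δt · e^(−(t−u)/τ_w'),

i.e. supra-CP expenditure convolved with an exponential recovery kernel.
The published statement of the integral has garbled limits; the
convolution above is the standard reading and is what we implement. The
recovery time constant is

    τ_w' = 564·e^(−0.01·D_CP) + 316   [s],

with D_CP (W) the gap between CP and the recovery power: 880 s when
recovering exactly at CP, falling towards 316 s for very easy recovery.
τ is the decay constant of the *deficit*, so small τ means fast
reconstitution; the doping-oriented plausibility screen therefore flags
implausibly **short** fitted τ (faster-than-human recovery), together with
balances that repeatedly dive well below zero at task failure (work done
that the model says was impossible). The depth that counts as "well below
zero" has no established physiological value and is a required user
parameter.

Implementation notes:

* Discrete convolution is evaluated by a one-pass IIR recursion
  (`scipy.signal.lfilter`), mathematically identical to the O(n²) direct
  sum; the tests compare against the naive double loop to ≤1e−9 relative
  error on 100 random protocols up to n = 2000.
* Expenditure within a step is attributed at the step start, so
  `wbal[0] = W'_0` exactly and constant supra-CP work with no recovery
  samples depletes exactly linearly at P − CP.
* `tau="auto"` derives one global τ from the mean power of all sub-CP
  samples. With no sub-CP samples τ → ∞, and depletion reduces exactly to
  the continuous-exercise CP model.
* Depletion times are linearly interpolated within the crossing step.
* `fit_tau_from_exhaustion` inverts the forward model: predicted depletion
  time is strictly decreasing in τ, so one protocol is solved by Brent
  root-finding on [1, 10 000] s and several protocols by least squares
  over log τ. Consequently a longer observed exhaustion time yields a
  *smaller* fitted τ. Sensitivities of τ to bout durations and environment
  are real but have no published functional form; they are left as
  configuration hooks, not modelled.

## The performance passport

The passport treats the CP model as a longitudinal biomarker in the style
of the Athlete Biological Passport: individualized expected ranges
conditioned on the athlete's own baseline, rather than population norms
(which do not exist for CP/W′ — `population_comparison` exists but
requires user-supplied reference parameters).

Per athlete and season:

1. **Detrending.** Athletes in development show a log-linear performance
   trend. Per panel duration, log(power) is regressed on year and every
   cell rescaled to the reference year. By default the trend is estimated
   once over the athlete's **full observed career** and the conditioning
   windows then expand inside the detrended table. The alternative of
   re-estimating the trend from each baseline window alone is available
   (`trend_window="baseline"`) but costs specificity: a slope estimated
   from four seasons and extrapolated one season ahead multiplies the
   held-out season by exp(−(b̂−b)·Δy), inflating the test point's variance
   ~2.5× relative to what the prediction interval accounts for
   (Var ≈ σ²(1 + 1/4) + Δy²·σ²/Sxx at four baseline years), and measured
   per-point specificity drops from ≥99.9 % to ≈93 %. Full-career
   detrending keeps the held-out season inside the trend estimation, makes
   the interval conservative, and is how the original six-season
   illustration proceeded. The cost is some self-masking: a doped test
   season inflates its own trend estimate and partially absorbs the
   doping signal. Detrending is per-duration by default (the hyperbola
   means CP-driven growth is proportionally stronger at long durations);
   a pooled-slope option exists.
2. **Conditioning.** All baseline cells — at least 12 points, i.e. three
   seasons of the four-duration panel — pool into one power-vs-1/t OLS
   fit. Fewer than 12 points is refused outright.
3. **Flagging.** Each test-season duration is compared with the two-sided
   99 % new-observation prediction interval; only exceedance of the
   *upper* bound flags (doping makes athletes faster, and one-sided upper
   flagging is what keeps specificity interpretable). The test season's
   own four-point fit gives CP and W′ point estimates compared against the
   baseline parameters' 99 % confidence intervals, also upper-one-sided by
   default — so a doping-induced W′ *decrease* via the anti-correlation
   artefact is invisible unless `two_sided_parameter_flags` is enabled.
   Exceedance must clear a 1e−9 relative margin so zero-variance
   degenerate baselines do not flag ties at machine precision.
4. **Absorption.** The tested season then joins the next baseline
   regardless of flags. This deliberately reproduces the masking weakness
   of passport-style monitoring: an undetected doped season biases the
   baseline mean upward and inflates its variance, suppressing flags in
   the following season (the Monte-Carlo masking experiment shows mean
   flag counts dropping from ≈2 to ≈0.2 between two consecutive doped
   seasons). `quarantine_flagged=True` excludes flagged seasons from later
   baselines — the obvious remedy, clearly an extension, not the default.

Independent evidence lines (a biomarker and a performance marker) combine
by Bayes' rule assuming conditional independence given the doping state —
the simplest faithful reading of the joint formulation; correlated markers
would need a joint likelihood the model does not supply.

The ROC machinery scores each athlete by the largest standardized upper
exceedance across the test season's durations ((observed − predicted)/SE
of prediction); thresholding at t-quantiles reproduces the flag decision
at any PI level, so sweeping levels traces sensitivity/specificity with
Wilson binomial intervals.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not cycling physiology:

* true performances lie exactly on each athlete's hyperbola, with CP
  following a log-linear career trend (default +2 %/yr, as for a
  developing rider) and W′ constant (no established career trend —
  configurable);
* measurement noise is multiplicative lognormal with mean 1. Defaults:
  CV 1.5 % on MMP/constant-duration powers (the low end of the published
  1.5–3.5 % typical errors, also matching within-season race-time
  variability of <2.5 %), CV 10 % on TTE durations (published range
  10–19 %), consistent with CV-based error reporting throughout this
  literature. A normal-noise option is not provided; at these CVs the
  lognormal is indistinguishable from normal, and multiplicative errors
  are the field's convention;
* doping is a multiplicative shift (+5 % default) applied to doped years
  AFTER the noise draw, so a doped career and its clean counterfactual
  from the same seed are exact scalings of each other — effects are
  isolated from noise by construction. CP-only or W′-only shifts for ROC
  experiments are the caller's choice of parameters, not asserted values;
* the default panel is {300, 600, 1200, 1800} s over six seasons
  (2003–2008), the structure of the published grand-tour illustration;
* cohorts draw athlete-level CP0 and W′ from truncated normals
  (SD 25 W and 3 kJ) with deterministic label assignment and per-athlete
  child seeds below 2³¹.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: day-to-day correlated form, training
periodisation, pacing and tactics in field MMPs (field data record what an
athlete *did*, not what they could do), environmental effects, protocol
switches between seasons, and any real doping pharmacodynamics. Passing
the specificity bound here means the statistical machinery is calibrated
under its own assumptions, not that a deployed passport would achieve 99 %
specificity on real careers.

## Problem sizes

The Monte-Carlo experiments are sized to estimate each property with
binomial error an order of magnitude smaller than the margin being
asserted: 1,250 athletes (5,000 test performances) for specificity, 5,000
replicates for interval coverage, 500 seeds for the masking comparison,
400 seeds for the parameter-shift detection rates, 100 random protocols
(n ≤ 2000) for the convolution-oracle equivalence. All randomness flows
from a single seed per experiment.

## Known limitations

* OLS throughout; when the nominally error-free regressor is itself noisy
  (ergometer calibration, course measurement), estimates are biased and no
  correction is applied.
* The passport's parameter comparison presents the baseline CI and the
  (noisy, 2-df) test-season point estimate side by side without a formal
  combined test; how to weight them is an open design question.
* Upper-one-sided defaults make artefactual W′ decreases invisible.
* The τ_w′ equation is a single published calibration; its dependence on
  bout structure and environment is acknowledged but not modelled.
* Full-career detrending trades a little sensitivity (self-masking of
  doped seasons) for calibrated specificity; with baseline-only
  detrending the 99 % specificity requirement is not attainable at four
  baseline seasons under this noise model.
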