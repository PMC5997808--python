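import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from critpower import (
    AOTTrace,
    FitForm,
    InsufficientDataError,
    PerformanceTrial,
    SingularDesignError,
    ValidationError,
    fit_3aot,
    fit_hyperbolic,
    fit_linear_power_invtime,
    fit_linear_work_time,
    hyperbolic_initial_guess,
    parameter_ci,
    predict_power,
    predict_tte,
    prediction_interval,
    residual_diagnostics,
)
from critpower.simulate import generate_trial_set

from conftest import hyperbola_trials

ALL_FORMS = [fit_linear_power_invtime, fit_linear_work_time, fit_hyperbolic]


# ---------------------------------------------------------------- exact fits

@pytest.mark.parametrize("fitter", ALL_FORMS)
def test_noiseless_hyperbola_recovered_exactly(fitter, exact_trials):
    fit = fitter(exact_trials)
    assert fit.cp == pytest.approx(250.0, rel=1e-8)
    assert fit.w_prime == pytest.approx(20_000.0, rel=1e-8)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    cp=st.floats(100.0, 450.0),
    w_prime=st.floats(5_000.0, 40_000.0),
    extra=st.lists(st.floats(200.0, 2400.0), min_size=0, max_size=5, unique=True),
)
def test_exact_recovery_property(cp, w_prime, extra):
    """Any trials generated exactly from the hyperbola are recovered by all forms."""
    durations = sorted({300.0, 1200.0, *extra})
    trials = hyperbola_trials(cp, w_prime, durations)
    for fitter in ALL_FORMS:
        fit = fitter(trials)
        assert fit.cp == pytest.approx(cp, rel=1e-8)
        assert fit.w_prime == pytest.approx(w_prime, rel=1e-8)


def test_two_point_power_invtime_solved_exactly():
    trials = [PerformanceTrial(180.0, 350.0), PerformanceTrial(720.0, 275.0)]
    fit = fit_linear_power_invtime(trials)
    # slope/intercept through two points: w' = (350-275)/(1/180-1/720) = 18 kJ
    assert fit.cp == pytest.approx(250.0, abs=1e-9)
    assert fit.w_prime == pytest.approx(18_000.0, rel=1e-12)
    assert not fit.gof_available
    assert math.isnan(fit.residual_sd) and math.isnan(fit.r_squared)


def test_two_point_work_time_solved_exactly():
    trials = [
        PerformanceTrial(180.0, 65_000.0 / 180.0, work_j=65_000.0),
        PerformanceTrial(720.0, 216_000.0 / 720.0, work_j=216_000.0),
    ]
    fit = fit_linear_work_time(trials)
    assert fit.cp == pytest.approx(151_000.0 / 540.0, rel=1e-12)
    assert fit.w_prime == pytest.approx(65_000.0 - (151_000.0 / 540.0) * 180.0, rel=1e-9)


def test_two_point_fits_agree_across_forms():
    trials = [PerformanceTrial(180.0, 350.0), PerformanceTrial(720.0, 275.0)]
    fits = [fitter(trials) for fitter in ALL_FORMS]
    for fit in fits[1:]:
        assert fit.cp == pytest.approx(fits[0].cp, rel=1e-8)
        assert fit.w_prime == pytest.approx(fits[0].w_prime, rel=1e-8)


def test_insufficient_and_singular_designs_rejected():
    with pytest.raises(InsufficientDataError):
        fit_linear_power_invtime([PerformanceTrial(300.0, 320.0)])
    same_duration = [PerformanceTrial(300.0, 320.0), PerformanceTrial(300.0, 330.0)]
    for fitter in ALL_FORMS:
        with pytest.raises(SingularDesignError):
            fitter(same_duration)


def test_trial_validation():
    with pytest.raises(ValidationError):
        PerformanceTrial(-10.0, 300.0)
    with pytest.raises(ValidationError):
        PerformanceTrial(300.0, 0.0)
    with pytest.raises(ValidationError):
        PerformanceTrial(300.0, 300.0, work_j=50_000.0)  # inconsistent with P*t


# ---------------------------------------------------------------- noisy fits

def _grid_search_linear(trials, cp_grid, wp_grid):
    """Brute-force least squares of power on 1/t over a parameter grid."""
    t = np.array([tr.duration_s for tr in trials])
    p = np.array([tr.power_w for tr in trials])
    cps, wps = np.meshgrid(cp_grid, wp_grid, indexing="ij")
    pred = wps[..., None] / t + cps[..., None]
    sse = ((p - pred) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return cp_grid[i], wp_grid[j]


def test_noisy_linear_fit_matches_grid_search_oracle():
    trials = generate_trial_set(
        280.0, 15_000.0, "constant_duration",
        np.linspace(180, 1800, 20), noise_cv=0.02, seed=42,
    )
    fit = fit_linear_power_invtime(trials)
    assert abs(fit.cp - 280.0) < 3 * fit.se_cp
    cp_grid = np.arange(fit.cp - 5, fit.cp + 5, 0.05)
    wp_grid = np.arange(fit.w_prime - 500, fit.w_prime + 500, 5.0)
    cp_star, wp_star = _grid_search_linear(trials, cp_grid, wp_grid)
    assert abs(cp_star - fit.cp) <= 0.05
    assert abs(wp_star - fit.w_prime) <= 5.0


def test_power_and_work_forms_disagree_under_noise():
    """The two linearisations weight errors differently, so noisy estimates differ."""
    trials = generate_trial_set(
        280.0, 15_000.0, "constant_duration",
        np.linspace(180, 1800, 12), noise_cv=0.02, seed=7,
    )
    a = fit_linear_power_invtime(trials)
    b = fit_linear_work_time(trials)
    assert abs(a.cp - b.cp) > 1e-9
    assert abs(a.w_prime - b.w_prime) > 1e-9


def test_hyperbolic_initialised_from_linearised_fit(exact_trials):
    assert hyperbolic_initial_guess(exact_trials) == pytest.approx(
        (250.0, 20_000.0), rel=1e-8
    )


def test_hyperbolic_fit_matches_2d_grid_search():
    trials = generate_trial_set(
        280.0, 15_000.0, "tte", [430.0, 400.0, 370.0, 340.0, 320.0, 305.0, 295.0],
        noise_cv=0.10, seed=5,
    )
    fit = fit_hyperbolic(trials)
    cp_grid = np.arange(fit.cp - 10, fit.cp + 10, 0.1)
    wp_grid = np.arange(fit.w_prime - 1000, fit.w_prime + 1000, 10.0)
    t = np.array([tr.duration_s for tr in trials])
    p = np.array([tr.power_w for tr in trials])
    cps, wps = np.meshgrid(cp_grid, wp_grid, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        pred_t = wps[..., None] / (p - cps[..., None])
    pred_t = np.where(p - cps[..., None] > 0, pred_t, np.inf)
    sse = ((t - pred_t) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    assert abs(cp_grid[i] - fit.cp) <= 0.1
    assert abs(wp_grid[j] - fit.w_prime) <= 10.0


# ------------------------------------------------------------- 3-min all-out

def test_3aot_constant_trace_gives_zero_w_prime():
    t = np.arange(0.0, 181.0)
    fit = fit_3aot(AOTTrace(t, np.full(t.size, 300.0)))
    assert fit.cp == pytest.approx(300.0)
    assert fit.w_prime == 0.0
    assert fit.form is FitForm.AOT3
    assert math.isnan(fit.se_cp)


def test_3aot_piecewise_trace_trapezoid_convention():
    """500 W for 0-60 s then 300 W: trapezoid loses half the transition step."""
    t = np.arange(0.0, 181.0)
    p = np.where(t < 60.0, 500.0, 300.0)
    fit = fit_3aot(AOTTrace(t, p))
    assert fit.cp == pytest.approx(300.0)
    # discrete trapezoid oracle on the same samples
    excess = np.maximum(p - 300.0, 0.0)
    oracle = np.sum((excess[:-1] + excess[1:]) / 2.0)
    assert oracle == pytest.approx(11_900.0)
    assert fit.w_prime == pytest.approx(oracle, rel=1e-12)


def test_3aot_exponential_trace_matches_closed_form_with_positive_bias():
    """End-test power equals the analytic window mean; undecayed tail biases CP up."""
    cp_true, peak, tau = 280.0, 800.0, 45.0
    t = np.arange(0.0, 181.0)
    trace = AOTTrace(t, cp_true + (peak - cp_true) * np.exp(-t / tau))
    fit = fit_3aot(trace)
    # discrete mean over the 31 samples in [150, 180]; geometric series closed form
    window = np.arange(150.0, 181.0)
    closed = cp_true + (peak - cp_true) * np.exp(-window / tau).mean()
    assert fit.cp == pytest.approx(closed, rel=1e-12)
    assert fit.cp > cp_true  # bias direction: always an overestimate


def test_3aot_short_trace_rejected():
    t = np.arange(0.0, 120.0)
    with pytest.raises(InsufficientDataError):
        fit_3aot(AOTTrace(t, np.full(t.size, 300.0)))


def test_aot_trace_validation():
    with pytest.raises(ValidationError):
        AOTTrace(np.array([0.0, 1.0, 3.0]), np.array([1.0, 1.0, 1.0]))  # non-uniform
    t = np.arange(0.0, 200.0, 2.0)
    with pytest.raises(ValidationError):
        AOTTrace(t, np.full(t.size, 300.0))  # step > 1 s


# ------------------------------------------------------------ prediction api

def test_predict_power_formula_and_domain_flag(exact_trials):
    fit = fit_linear_power_invtime(exact_trials)
    pred = predict_power(fit, 600.0)
    assert pred.power_w == pytest.approx(20_000.0 / 600.0 + 250.0, rel=1e-9)
    assert pred.in_domain
    outside = predict_power(fit, 60.0)
    assert outside.power_w > pred.power_w
    assert not outside.in_domain
    with pytest.raises(ValidationError):
        predict_power(fit, 0.0)


def test_predict_power_approaches_cp_from_above(exact_trials):
    fit = fit_linear_power_invtime(exact_trials)
    powers = [predict_power(fit, t).power_w for t in (1e3, 1e5, 1e8)]
    assert all(p > fit.cp for p in powers)
    assert powers[-1] == pytest.approx(fit.cp, rel=1e-6)


def test_predict_tte_and_unbounded_signal(exact_trials):
    fit = fit_linear_power_invtime(exact_trials)
    assert predict_tte(fit, 350.0) == pytest.approx(200.0, rel=1e-9)
    assert predict_tte(fit, fit.cp) is None
    assert predict_tte(fit, fit.cp - 20.0) is None


@settings(derandomize=True, max_examples=50, deadline=None)
@given(duration=st.floats(1.0, 1e5))
def test_predict_tte_inverts_predict_power(duration):
    fit = fit_linear_power_invtime(hyperbola_trials(250.0, 20_000.0, [180, 600, 900]))
    power = predict_power(fit, duration).power_w
    assert predict_tte(fit, power) == pytest.approx(duration, rel=1e-6)


# -------------------------------------------------------- intervals (vs OLS)

def test_prediction_interval_zero_width_on_noiseless_fit():
    fit = fit_linear_power_invtime(hyperbola_trials(250.0, 20_000.0, [180, 400, 600, 900]))
    lo, hi = prediction_interval(fit, 700.0, 0.99)
    assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_prediction_interval_requires_residual_df():
    trials = [PerformanceTrial(180.0, 350.0), PerformanceTrial(720.0, 275.0)]
    fit = fit_linear_power_invtime(trials)
    with pytest.raises(InsufficientDataError):
        prediction_interval(fit, 600.0)


def test_prediction_interval_matches_statsmodels():
    """Independent route: statsmodels OLS new-observation interval."""
    trials = generate_trial_set(
        280.0, 18_000.0, "constant_duration",
        [200.0, 350.0, 500.0, 800.0, 1200.0, 1800.0], noise_cv=0.02, seed=9,
    )
    fit = fit_linear_power_invtime(trials)
    x = np.array([1.0 / tr.duration_s for tr in trials])
    y = np.array([tr.power_w for tr in trials])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    for dur, level in [(300.0, 0.99), (900.0, 0.95), (2500.0, 0.99)]:
        frame = model.get_prediction(
            np.array([[1.0, 1.0 / dur]])
        ).summary_frame(alpha=1 - level)
        lo, hi = prediction_interval(fit, dur, level)
        assert lo == pytest.approx(float(frame["obs_ci_lower"].iloc[0]), rel=1e-9)
        assert hi == pytest.approx(float(frame["obs_ci_upper"].iloc[0]), rel=1e-9)
    # and parameter CIs against statsmodels conf_int
    ci = model.conf_int(alpha=0.01)
    (cp_lo, cp_hi), (wp_lo, wp_hi) = parameter_ci(fit, 0.99)
    assert (cp_lo, cp_hi) == pytest.approx(tuple(ci[0]), rel=1e-9)
    assert (wp_lo, wp_hi) == pytest.approx(tuple(ci[1]), rel=1e-9)


def test_prediction_interval_width_grows_away_from_design_mean():
    trials = generate_trial_set(
        280.0, 18_000.0, "constant_duration",
        [240.0, 360.0, 600.0, 900.0, 1500.0], noise_cv=0.02, seed=3,
    )
    fit = fit_linear_power_invtime(trials)
    xbar = fit.x.mean()
    durations = np.array([1.0 / (xbar + d) for d in (0.0, 5e-4, 1e-3, 2e-3)])
    widths = [np.diff(prediction_interval(fit, d, 0.99))[0] for d in durations]
    assert all(np.diff(widths) > 0)


def test_parameter_ci_narrows_with_more_trials():
    """Same noise level: 8 trials give tighter 99% CIs than their first 4."""
    wider, tighter = [], []
    for seed in range(25):
        trials = generate_trial_set(
            280.0, 18_000.0, "constant_duration",
            [200, 300, 450, 600, 800, 1000, 1400, 1800], noise_cv=0.02, seed=seed,
        )
        f8 = fit_linear_power_invtime(trials)
        f4 = fit_linear_power_invtime(trials[:4])
        (lo8, hi8), _ = parameter_ci(f8, 0.99)
        (lo4, hi4), _ = parameter_ci(f4, 0.99)
        wider.append(hi4 - lo4)
        tighter.append(hi8 - lo8)
    assert np.mean(wider) > np.mean(tighter)


def test_parameter_ci_coverage_near_nominal():
    """99% CP confidence interval covers the generating CP ~99% of the time."""
    hits = 0
    n = 800
    for seed in range(n):
        trials = generate_trial_set(
            280.0, 18_000.0, "constant_duration",
            [200, 300, 450, 600, 900, 1200, 1800], noise_cv=0.015, seed=10_000 + seed,
        )
        (lo, hi), _ = parameter_ci(fit_linear_power_invtime(trials), 0.99)
        hits += lo <= 280.0 <= hi
    assert 0.975 <= hits / n <= 1.0


# ----------------------------------------------------------- model artefacts

def test_anticorrelation_artifact_direction(exact_trials):
    """Raising only the longest trial's power raises CP and lowers W'."""
    base = fit_linear_power_invtime(exact_trials)
    bumped = list(exact_trials)
    longest = max(range(len(bumped)), key=lambda i: bumped[i].duration_s)
    tr = bumped[longest]
    bumped[longest] = PerformanceTrial(tr.duration_s, tr.power_w * 1.03)
    refit = fit_linear_power_invtime(bumped)
    assert refit.cp > base.cp
    assert refit.w_prime < base.w_prime


def test_overprediction_beyond_fitted_range():
    """Data from a curve below the hyperbola at long durations are overpredicted."""
    cp, wp, shift = 250.0, 22_000.0, 120.0
    durations = np.linspace(180, 1800, 8)
    trials = [
        PerformanceTrial(t, wp / (t + shift) + cp) for t in durations
    ]  # three-parameter generator, strictly below the fitted hyperbola's tail
    fit = fit_linear_power_invtime(trials)
    for t_out in (2400.0, 3600.0, 7200.0):
        truth = wp / (t_out + shift) + cp
        pred = predict_power(fit, t_out)
        assert not pred.in_domain
        assert pred.power_w > truth


def test_extrapolation_risk_annotation():
    inside = fit_linear_power_invtime(hyperbola_trials(250, 2e4, [200, 600, 1800]))
    outside = fit_linear_power_invtime(hyperbola_trials(250, 2e4, [60, 600, 1800]))
    assert not inside.extrapolation_risk
    assert outside.extrapolation_risk


# ------------------------------------------------------------------ residual

def test_diagnostics_degenerate_on_noiseless_fit(exact_trials):
    fit = fit_linear_power_invtime(
        hyperbola_trials(250.0, 20_000.0, [180, 300, 600, 900, 1200])
    )
    report = residual_diagnostics(fit)
    assert report.degenerate
    assert np.allclose(report.residuals, 0.0, atol=1e-8)
    assert math.isnan(report.runs_pvalue)


def _exact_runs_cdf(r_obs, n_pos, n_neg):
    """P(runs <= r_obs) under the exact Wald-Wolfowitz null."""
    from math import comb

    total = comb(n_pos + n_neg, n_pos)
    cdf = 0.0
    for r in range(2, r_obs + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n_pos - 1, k - 1) * comb(n_neg - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = comb(n_pos - 1, k - 1) * comb(n_neg - 1, k) + comb(
                n_pos - 1, k
            ) * comb(n_neg - 1, k - 1)
        cdf += ways / total
    return cdf


def test_diagnostics_detect_systematic_misspecification():
    """A 3-parameter curve forced through the 2-parameter model leaves a sign pattern."""
    durations = np.linspace(180, 1800, 20)
    trials = [PerformanceTrial(t, 22_000.0 / (t + 150.0) + 250.0) for t in durations]
    fit = fit_linear_power_invtime(trials)
    report = residual_diagnostics(fit)
    assert not report.degenerate
    assert report.runs_pvalue < 0.05
    # exact-null oracle: the observed runs count sits in the lower 2.5% tail
    signs = np.sign(report.residuals)
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n_pos = int(np.sum(signs > 0))
    n_neg = signs.size - n_pos
    assert _exact_runs_cdf(runs, n_pos, n_neg) < 0.025


def test_diagnostics_calibrated_under_iid_noise():
    """Sign-pattern statistic stays inside its null 95% band for most iid fits."""
    inside = 0
    n_seeds = 1000
    durations = np.linspace(180, 1800, 20)
    for seed in range(n_seeds):
        trials = generate_trial_set(
            280.0, 18_000.0, "constant_duration", durations, noise_cv=0.02,
            seed=50_000 + seed,
        )
        report = residual_diagnostics(fit_linear_power_invtime(trials))
        inside += abs(report.runs_z) <= 1.96
    assert inside / n_seeds >= 0.90
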