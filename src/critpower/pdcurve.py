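"""Two-parameter critical-power model of the power-duration relationship.

The model states that the maximal mean power :math:`P` sustainable for a
duration :math:`t` follows a hyperbola

.. math:: P = W'/t + \\mathrm{CP},

where CP (critical power, W) is the asymptote — the highest power at which
muscle metabolic homeostasis is sustainable — and W′ (joules) is the finite
work capacity expendable above CP before task failure.  Equivalent algebraic
forms are the time-to-exhaustion hyperbola :math:`t = W'/(P-\\mathrm{CP})`
and the work-time line :math:`\\mathrm{Work} = \\mathrm{CP}\\,t + W'`.

Which form to fit depends on which variable carries the measurement error:
time-to-exhaustion (TTE) protocols measure duration, so the hyperbolic form
with duration as the response is appropriate; constant-duration, time-trial
and mean-maximal-power (MMP) data measure power, so the linearised
power-vs-1/t regression applies; time-trial work data fit the work-time
line.  All regressions are ordinary least squares: the regressor is assumed
error-free, a simplification that is standard practice in this literature
but worth keeping in mind when the "independent" variable is itself noisy.

Velocity sports use the same algebra with critical velocity (CV, m/s) and
D′ (m) in place of CP and W′; no separate code path exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "Protocol",
    "FitForm",
    "PerformanceTrial",
    "AOTTrace",
    "CPFit",
    "PowerPrediction",
    "DiagnosticsReport",
    "fit_linear_power_invtime",
    "fit_linear_work_time",
    "fit_hyperbolic",
    "hyperbolic_initial_guess",
    "fit_3aot",
    "predict_power",
    "predict_tte",
    "prediction_interval",
    "parameter_ci",
    "residual_diagnostics",
    "VALID_DOMAIN_S",
]

#: Duration window (s) over which the hyperbola is a good approximation
#: (roughly 3-40 min); fits whose data extend outside it are annotated
#: with an extrapolation-risk flag.
VALID_DOMAIN_S = (180.0, 2400.0)


class Protocol(str, Enum):
    """How a maximal-effort trial was conducted."""

    TTE = "tte"                    # constant work rate, duration measured
    CONSTANT_DURATION = "constant_duration"
    TIME_TRIAL = "time_trial"
    MMP = "mmp"                    # mean-maximal power extracted from field data
    AOT3 = "3aot"                  # 3-min all-out test


class FitForm(str, Enum):
    HYPERBOLIC = "hyperbolic"
    LINEAR_POWER_INVTIME = "linear_power_invtime"
    LINEAR_WORK_TIME = "linear_work_time"
    AOT3 = "aot3"


@dataclass(frozen=True)
class PerformanceTrial:
    """One maximal effort: mean power (W) sustained for a duration (s).

    For velocity sports, ``power_w`` holds velocity in m/s and ``work_j``
    distance in m; the algebra is identical.
    """

    duration_s: float
    power_w: float
    work_j: Optional[float] = None
    protocol: Protocol = Protocol.CONSTANT_DURATION
    year: Optional[int] = None

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValidationError(f"duration must be positive, got {self.duration_s}")
        if not self.power_w > 0:
            raise ValidationError(f"power must be positive, got {self.power_w}")
        if self.work_j is not None:
            expected = self.power_w * self.duration_s
            if abs(self.work_j - expected) >= 1e-6 * self.work_j:
                raise ValidationError(
                    f"work {self.work_j} J inconsistent with power*duration {expected} J"
                )

    @property
    def work(self) -> float:
        """Total mechanical work (J), computed if not supplied."""
        return self.work_j if self.work_j is not None else self.power_w * self.duration_s


@dataclass(frozen=True)
class AOTTrace:
    """Second-by-second power from a 3-min all-out test.

    Requires a uniform sampling step of at most 1 s; non-uniform traces are
    rejected rather than re-weighted.
    """

    time_s: np.ndarray
    power_w: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.power_w, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "power_w", p)
        if t.ndim != 1 or t.size < 2 or p.shape != t.shape:
            raise ValidationError("trace needs matched 1-D time and power arrays")
        steps = np.diff(t)
        if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValidationError("trace sampling must be uniform and increasing")
        if steps[0] > 1.0 + 1e-12:
            raise ValidationError("trace sampling step must be <= 1 s")
        if np.any(p < 0):
            raise ValidationError("trace power must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def span(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class CPFit:
    """A fitted two-parameter critical-power model.

    ``cov`` is the 2x2 asymptotic covariance of (cp, w_prime).  ``residuals``
    are in the fitted response's units (W for the power form, J for the work
    form, s for the hyperbolic form).  ``duration_range_s`` records the span
    of the fitting data: predictions outside it are extrapolations and the
    model is known to overpredict there.
    """

    cp: float
    w_prime: float
    se_cp: float
    se_w_prime: float
    cov: np.ndarray
    residual_sd: float
    n: int
    form: FitForm
    r_squared: float
    residuals: np.ndarray
    duration_range_s: tuple[float, float]
    # regression internals needed for new-observation prediction intervals
    x: np.ndarray = field(default=None, repr=False)
    fitted: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        # a flat all-out trace legitimately yields W' = 0; regression fits
        # with non-positive parameters are rejected as invalid
        wp_ok = self.w_prime > 0 or (self.form is FitForm.AOT3 and self.w_prime >= 0)
        if not (self.cp > 0 and wp_ok):
            raise ValidationError(
                f"invalid fit: cp={self.cp}, w_prime={self.w_prime} must be positive"
            )
        if self.n < 2:
            raise ValidationError("a two-parameter fit needs n >= 2")

    @property
    def gof_available(self) -> bool:
        """Goodness-of-fit metrics need at least one residual degree of freedom."""
        return self.n >= 3 and self.form is not FitForm.AOT3

    @property
    def extrapolation_risk(self) -> bool:
        """True when the fitting data extend outside the ~3-40 min valid domain."""
        lo, hi = self.duration_range_s
        return lo < VALID_DOMAIN_S[0] or hi > VALID_DOMAIN_S[1]


class PowerPrediction(NamedTuple):
    power_w: float
    in_domain: bool


def _as_trials(trials: Sequence[PerformanceTrial]):
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientDataError(
            f"need at least 2 trials to fit a two-parameter model, got {len(trials)}"
        )
    t = np.array([tr.duration_s for tr in trials], dtype=float)
    p = np.array([tr.power_w for tr in trials], dtype=float)
    w = np.array([tr.work for tr in trials], dtype=float)
    if np.unique(t).size < 2:
        raise SingularDesignError("all trials share one duration; design is singular")
    return t, p, w


def _ols(x: np.ndarray, y: np.ndarray):
    """Simple-regression OLS: returns intercept, slope, cov, residuals, s, R^2.

    With n == 2 the line is exact and variance quantities are NaN (zero
    residual degrees of freedom).
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    xtx = X.T @ X
    if abs(np.linalg.det(xtx)) < 1e-12 * max(1.0, float(np.sum(x * x))):
        raise SingularDesignError("regressor values are not distinct")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    df = n - 2
    if df > 0:
        s2 = float(resid @ resid) / df
        cov = s2 * xtx_inv
        s = math.sqrt(s2)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    else:
        cov = np.full((2, 2), np.nan)
        s = float("nan")
        r2 = float("nan")
    return beta, cov, resid, fitted, s, r2


def fit_linear_power_invtime(trials: Sequence[PerformanceTrial]) -> CPFit:
    """OLS of power on inverse duration: P = W'.(1/t) + CP.

    The intercept estimates CP and the slope W′.  Appropriate when power is
    the measured outcome (constant-duration, time-trial and MMP data).
    """
    t, p, _ = _as_trials(trials)
    x = 1.0 / t
    beta, cov_b, resid, fitted, s, r2 = _ols(x, p)
    cp, w_prime = float(beta[0]), float(beta[1])
    # parameter order in `cov` is (cp, w_prime) == (intercept, slope)
    return CPFit(
        cp=cp,
        w_prime=w_prime,
        se_cp=float(np.sqrt(cov_b[0, 0])),
        se_w_prime=float(np.sqrt(cov_b[1, 1])),
        cov=cov_b,
        residual_sd=s,
        n=t.size,
        form=FitForm.LINEAR_POWER_INVTIME,
        r_squared=r2,
        residuals=resid,
        duration_range_s=(float(t.min()), float(t.max())),
        x=x,
        fitted=fitted,
    )


def fit_linear_work_time(trials: Sequence[PerformanceTrial]) -> CPFit:
    """OLS of total work on duration: Work = CP.t + W'.

    The slope estimates CP and the intercept W′.  Appropriate for time-trial
    data where total work (or distance) is controlled.
    """
    t, _, w = _as_trials(trials)
    beta, cov_b, resid, fitted, s, r2 = _ols(t, w)
    w_prime, cp = float(beta[0]), float(beta[1])
    # reorder covariance from (intercept=w', slope=cp) to (cp, w')
    cov = np.array([[cov_b[1, 1], cov_b[0, 1]], [cov_b[1, 0], cov_b[0, 0]]])
    return CPFit(
        cp=cp,
        w_prime=w_prime,
        se_cp=float(np.sqrt(cov[0, 0])),
        se_w_prime=float(np.sqrt(cov[1, 1])),
        cov=cov,
        residual_sd=s,
        n=t.size,
        form=FitForm.LINEAR_WORK_TIME,
        r_squared=r2,
        residuals=resid,
        duration_range_s=(float(t.min()), float(t.max())),
        x=t,
        fitted=fitted,
    )


def hyperbolic_initial_guess(trials: Sequence[PerformanceTrial]) -> tuple[float, float]:
    """Starting point for the hyperbolic fit: the linearised OLS estimates."""
    lin = fit_linear_power_invtime(trials)
    return lin.cp, lin.w_prime


def fit_hyperbolic(
    trials: Sequence[PerformanceTrial],
    *,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> CPFit:
    """Nonlinear least squares of duration on power: t = W'/(P - CP).

    Duration is the response, which matches TTE protocols where the work
    rate is imposed and time to exhaustion is measured.  Initialised from
    the linearised fit; CP is constrained below min(P) so the hyperbola
    stays finite at every observed power.
    """
    t, p, _ = _as_trials(trials)
    cp_hi = float(p.min()) * 0.999
    cp0, wp0 = hyperbolic_initial_guess(trials)
    cp0 = min(max(cp0, 1e-6), cp_hi)
    wp0 = max(wp0, 1e-6)

    def resid_fn(theta):
        cp, wp = theta
        return t - wp / (p - cp)

    result = optimize.least_squares(
        resid_fn,
        x0=[cp0, wp0],
        bounds=([1e-9, 1e-9], [cp_hi, np.inf]),
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    if not result.success:
        raise ConvergenceError(
            f"hyperbolic fit did not converge: {result.message}",
            best_params=tuple(result.x),
        )
    cp, w_prime = map(float, result.x)
    resid = -result.fun  # observed - fitted
    n = t.size
    df = n - 2
    if df > 0:
        s2 = float(resid @ resid) / df
        J = result.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        s = math.sqrt(s2)
        sst = float(np.sum((t - t.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    else:
        cov = np.full((2, 2), np.nan)
        s = float("nan")
        r2 = float("nan")
    fitted = w_prime / (p - cp)
    return CPFit(
        cp=cp,
        w_prime=w_prime,
        se_cp=float(np.sqrt(cov[0, 0])),
        se_w_prime=float(np.sqrt(cov[1, 1])),
        cov=cov,
        residual_sd=s,
        n=n,
        form=FitForm.HYPERBOLIC,
        r_squared=r2,
        residuals=resid,
        duration_range_s=(float(t.min()), float(t.max())),
        x=p,
        fitted=fitted,
    )


def fit_3aot(trace: AOTTrace) -> CPFit:
    """Reduce a 3-min all-out test to (CP, W′).

    CP is the end-test power: the mean power over the final 30 s of the
    nominal 180 s test (samples with 150 <= t <= 180).  W′ is the
    trapezoidal integral of power above CP over [0, 180] s.  Because the
    supra-CP transient may not have fully decayed by 150 s, the end-test
    power carries a positive bias relative to true CP; the slower the decay,
    the larger the overestimate.  No standard errors are available from a
    single trace.
    """
    if trace.span < 180.0 - 1e-9:
        raise InsufficientDataError(
            f"3-min all-out trace must span >= 180 s, got {trace.span:.1f} s"
        )
    t = trace.time_s - trace.time_s[0]
    p = trace.power_w
    window = (t >= 150.0 - 1e-9) & (t <= 180.0 + 1e-9)
    cp = float(p[window].mean())
    body = t <= 180.0 + 1e-9
    excess = np.maximum(p[body] - cp, 0.0)
    w_prime = float(np.trapezoid(excess, t[body]))
    nan2 = np.full((2, 2), np.nan)
    return CPFit(
        cp=cp,
        w_prime=w_prime,
        se_cp=float("nan"),
        se_w_prime=float("nan"),
        cov=nan2,
        residual_sd=float("nan"),
        n=int(body.sum()),
        form=FitForm.AOT3,
        r_squared=float("nan"),
        residuals=np.array([]),
        duration_range_s=(0.0, 180.0),
    )


def predict_power(fit: CPFit, duration_s: float) -> PowerPrediction:
    """Predicted maximal mean power for a duration: W'/t + CP.

    ``in_domain`` is False when the duration falls outside the fitting
    data's duration range, where the hyperbola is known to overpredict.
    """
    if not duration_s > 0:
        raise ValidationError(f"duration must be positive, got {duration_s}")
    lo, hi = fit.duration_range_s
    return PowerPrediction(
        power_w=fit.w_prime / duration_s + fit.cp,
        in_domain=bool(lo <= duration_s <= hi),
    )


def predict_tte(fit: CPFit, power_w: float) -> Optional[float]:
    """Predicted time to exhaustion at a power: W'/(P - CP).

    Returns None for power at or below CP — the model regards such work
    rates as sustainable indefinitely, so no finite time exists.
    """
    if not power_w > 0:
        raise ValidationError(f"power must be positive, got {power_w}")
    if power_w <= fit.cp:
        return None
    return fit.w_prime / (power_w - fit.cp)


def _check_pi_fit(fit: CPFit):
    if fit.form is not FitForm.LINEAR_POWER_INVTIME:
        raise ValidationError(
            "prediction intervals are defined for the linear power-vs-1/t fit"
        )
    if fit.n < 3:
        raise InsufficientDataError(
            "residual variance needs n >= 3; a 2-trial fit has no residual df"
        )


def prediction_interval(
    fit: CPFit, duration_s: float, level: float = 0.99
) -> tuple[float, float]:
    """Two-sided new-observation prediction interval for power at a duration.

    Standard OLS formula at x* = 1/duration with a t-distribution on n-2
    degrees of freedom:

    .. math:: \\hat y \\pm t_{1-\\alpha/2,\\,n-2}\\; s
              \\sqrt{1 + 1/n + (x^*-\\bar x)^2 / S_{xx}}.

    A zero-residual (noiseless) fit gives a zero-width interval.
    """
    _check_pi_fit(fit)
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0,1), got {level}")
    xstar = 1.0 / duration_s
    yhat = fit.cp + fit.w_prime * xstar
    x = fit.x
    n = fit.n
    sxx = float(np.sum((x - x.mean()) ** 2))
    spread = fit.residual_sd * math.sqrt(1.0 + 1.0 / n + (xstar - x.mean()) ** 2 / sxx)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 2)
    return (yhat - tcrit * spread, yhat + tcrit * spread)


def parameter_ci(
    fit: CPFit, level: float = 0.99
) -> tuple[tuple[float, float], tuple[float, float]]:
    """t-based marginal confidence intervals for (CP, W′) at ``level``."""
    if fit.n < 3 or not np.isfinite(fit.se_cp):
        raise InsufficientDataError("parameter CIs need n >= 3 and finite SEs")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0,1), got {level}")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=fit.n - 2)
    return (
        (fit.cp - tcrit * fit.se_cp, fit.cp + tcrit * fit.se_cp),
        (fit.w_prime - tcrit * fit.se_w_prime, fit.w_prime + tcrit * fit.se_w_prime),
    )


@dataclass
class DiagnosticsReport:
    """Descriptive residual diagnostics; no flagging threshold is applied.

    ``runs_z``/``runs_pvalue`` come from a Wald-Wolfowitz runs test on the
    signs of residuals ordered by the regressor — systematic sign patterns
    (too few runs) indicate lack of fit, which is expected when a curve with
    more structure is forced through the two-parameter hyperbola.
    ``shapiro_pvalue`` tests residual normality.  ``degenerate`` marks fits
    whose residuals are all (numerically) zero, where both tests are
    meaningless.
    """

    residuals: np.ndarray
    fitted: np.ndarray
    runs_z: float
    runs_pvalue: float
    shapiro_pvalue: float
    degenerate: bool


def residual_diagnostics(fit: CPFit) -> DiagnosticsReport:
    """Runs-test sign-pattern statistic and Shapiro normality p for a fit."""
    if fit.residuals is None or fit.residuals.size < 3 or fit.x is None:
        raise InsufficientDataError("diagnostics need a fit with >= 3 residuals")
    order = np.argsort(fit.x)
    resid = fit.residuals[order]
    fitted = fit.fitted[order]
    scale = max(float(np.max(np.abs(fitted))), 1.0)
    if np.all(np.abs(resid) < 1e-9 * scale):
        return DiagnosticsReport(
            residuals=resid,
            fitted=fitted,
            runs_z=float("nan"),
            runs_pvalue=float("nan"),
            shapiro_pvalue=float("nan"),
            degenerate=True,
        )
    from statsmodels.sandbox.stats.runs import runstest_1samp

    runs_z, runs_p = runstest_1samp(resid, cutoff=0, correction=True)
    shapiro_p = float(stats.shapiro(resid).pvalue)
    return DiagnosticsReport(
        residuals=resid,
        fitted=fitted,
        runs_z=float(runs_z),
        runs_pvalue=float(runs_p),
        shapiro_pvalue=shapiro_p,
        degenerate=False,
    )
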