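"""W' balance during intermittent exercise.

During work above critical power, the finite capacity W′ is spent at the
rate P - CP; during recovery below CP the accumulated deficit decays
exponentially with time constant τ_w′, so the remaining balance is

.. math:: W'_{bal}(t) = W'_0 - \\sum_{u \\le t} \\max(P(u)-CP, 0)\\,
          \\Delta t\\; e^{-(t-u)/\\tau_{w'}},

a discrete convolution of the supra-CP expenditure with an exponential
recovery kernel.  The time constant shortens as the recovery intensity
drops further below CP:

.. math:: \\tau_{w'} = 564\\, e^{-0.01\\, D_{CP}} + 316,

where :math:`D_{CP}` (W) is the gap between CP and the recovery power.
τ_w′ therefore falls from 880 s at recovery exactly at CP towards an
asymptote of 316 s for very easy recovery.  A SMALL τ means fast
reconstitution; implausibly small fitted values, or a balance that
repeatedly dives far below zero at task failure, are the model's two
doping-suspicion signals.

Exhaustion is predicted where the balance first reaches zero.  When a
series contains no sub-CP samples there is nothing to recover from, the
kernel degenerates (τ → ∞) and depletion reduces exactly to the cumulative
work above CP — the continuous-exercise critical-power model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, signal

from .errors import NoSolutionError, ValidationError

__all__ = [
    "PowerTimeSeries",
    "WbalTrace",
    "WbalFlags",
    "recovery_time_constant",
    "simulate_wbal",
    "time_to_depletion",
    "wbal_suspicion_flags",
    "fit_tau_from_exhaustion",
]

TAU_ASYMPTOTE_S = 316.0  # large-deficit limit of the recovery time constant
TAU_SPAN_S = 564.0       # additional span at zero deficit


@dataclass(frozen=True)
class PowerTimeSeries:
    """Uniformly sampled power output (W) on a time grid (s)."""

    time_s: np.ndarray
    power_w: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.power_w, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "power_w", p)
        if t.size == 0:
            raise ValidationError("empty power series")
        if t.ndim != 1 or p.shape != t.shape:
            raise ValidationError("time and power must be matched 1-D arrays")
        if t.size >= 2:
            steps = np.diff(t)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValidationError("sampling step must be uniform and positive")
        if np.any(p < 0):
            raise ValidationError("power must be non-negative")

    @property
    def dt(self) -> float:
        if self.time_s.size < 2:
            return 1.0
        return float(self.time_s[1] - self.time_s[0])


def recovery_time_constant(d_cp: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Recovery time constant τ_w′ (s) as a function of the deficit D_CP (W).

    ``d_cp`` is CP minus the recovery power.  The function is strictly
    decreasing, equals 880 s at zero deficit and approaches 316 s as the
    deficit grows.  Negative values (recovery above CP) are outside the
    calibration regime and raise a warning, but the formula is still
    evaluated.
    """
    d = np.asarray(d_cp, dtype=float)
    if np.any(d < 0):
        warnings.warn(
            "recovery power above CP (D_CP < 0) is outside the tau calibration regime",
            RuntimeWarning,
            stacklevel=2,
        )
    tau = TAU_SPAN_S * np.exp(-0.01 * d) + TAU_ASYMPTOTE_S
    return float(tau) if np.isscalar(d_cp) else tau


@dataclass
class WbalTrace:
    """Simulated W' balance along a power time series.

    ``depletion_times_s`` lists every downward zero crossing, linearly
    interpolated within the crossing step.
    """

    time_s: np.ndarray
    power_w: np.ndarray
    cp: float
    w0: float
    tau: float
    wbal_j: np.ndarray
    depletion_times_s: list

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if self.time_s.size > 1 else 1.0


def _crossing_times(time_s: np.ndarray, wbal: np.ndarray) -> list:
    """Downward zero crossings of wbal, interpolated within the step."""
    out = []
    above = wbal > 0
    for k in range(1, wbal.size):
        if above[k - 1] and not above[k]:
            w_prev, w_now = wbal[k - 1], wbal[k]
            frac = w_prev / (w_prev - w_now)
            out.append(float(time_s[k - 1] + frac * (time_s[k] - time_s[k - 1])))
    return out


def simulate_wbal(
    series: PowerTimeSeries,
    cp: float,
    w0: float,
    tau: Union[float, str] = "auto",
) -> WbalTrace:
    """Evolve W' balance along a power series.

    Expenditure within each step is attributed at the step start: the
    balance at sample k reflects every completed step j < k, each decayed
    by exp(-(t_k - t_j)/τ).  Consequently ``wbal[0] == w0`` and, under
    constant supra-CP power with no recovery, the balance falls exactly
    linearly at rate P - CP.

    ``tau="auto"`` derives a single global τ from the mean power of all
    sub-CP samples via :func:`recovery_time_constant`; with no sub-CP
    samples τ is infinite and depletion is purely cumulative.
    """
    if not (cp > 0 and w0 > 0):
        raise ValidationError("cp and w0 must be positive")
    p = series.power_w
    dt = series.dt
    if tau == "auto":
        sub = p[p < cp]
        tau_val = recovery_time_constant(cp - float(sub.mean())) if sub.size else math.inf
    else:
        tau_val = float(tau)
        if tau_val <= 0:
            raise ValidationError("tau must be positive")

    expenditure = np.maximum(p - cp, 0.0) * dt
    decay = 1.0 if math.isinf(tau_val) else math.exp(-dt / tau_val)
    # deficit recursion D_k = decay * (D_{k-1} + e_{k-1}), D_0 = 0, as an IIR filter
    deficit = signal.lfilter([0.0, decay], [1.0, -decay], expenditure)
    wbal = w0 - deficit
    return WbalTrace(
        time_s=series.time_s,
        power_w=p,
        cp=float(cp),
        w0=float(w0),
        tau=tau_val,
        wbal_j=wbal,
        depletion_times_s=_crossing_times(series.time_s, wbal),
    )


def time_to_depletion(trace: WbalTrace) -> Optional[float]:
    """First time (s) the balance reaches zero; None if never depleted."""
    return trace.depletion_times_s[0] if trace.depletion_times_s else None


@dataclass
class WbalFlags:
    """Physiological-plausibility screens on a simulated balance.

    A balance repeatedly diving well below zero means the athlete did work
    the model says they could not have — consistent with an underestimated
    W′ or CP, possibly from doping after the parameters were established.
    An implausibly SHORT fitted τ means implausibly fast recovery.
    """

    n_deep_excursions: int
    excursion_depths_j: list          # most-negative balance per excursion
    tau_implausible: Optional[bool]   # None when no fitted tau supplied


def wbal_suspicion_flags(
    trace: WbalTrace,
    depth_threshold_j: float,
    tau_fitted_s: Optional[float] = None,
    tau_floor_s: Optional[float] = None,
) -> WbalFlags:
    """Count sub-zero excursions deeper than a threshold and screen τ.

    ``depth_threshold_j`` has no asserted physiological default; the caller
    must choose what "well below zero" means for their data quality.
    """
    if depth_threshold_j < 0:
        raise ValidationError("depth threshold must be non-negative")
    wbal = trace.wbal_j
    below = wbal < 0
    depths = []
    k = 0
    n = wbal.size
    while k < n:
        if below[k]:
            j = k
            while j < n and below[j]:
                j += 1
            depth = float(wbal[k:j].min())
            if depth < -depth_threshold_j:
                depths.append(depth)
            k = j
        else:
            k += 1
    tau_flag = None
    if tau_fitted_s is not None and tau_floor_s is not None:
        tau_flag = bool(tau_fitted_s < tau_floor_s)
    return WbalFlags(
        n_deep_excursions=len(depths),
        excursion_depths_j=depths,
        tau_implausible=tau_flag,
    )


def fit_tau_from_exhaustion(
    protocols: Sequence[tuple[PowerTimeSeries, float]],
    cp: float,
    w0: float,
    tau_bounds: tuple[float, float] = (1.0, 10_000.0),
) -> float:
    """Fit τ so the simulated balance hits zero at the observed exhaustion.

    Predicted depletion time is a decreasing function of τ (slower recovery
    ⇒ earlier exhaustion), so a single protocol is solved by bracketed
    root-finding; several protocols are combined by least squares on the
    depletion-time residuals over log τ.
    """
    protocols = list(protocols)
    if not protocols:
        raise ValidationError("need at least one protocol with an observed exhaustion")
    for series, t_obs in protocols:
        if not 0 < t_obs <= series.time_s[-1]:
            raise ValidationError(
                "observed exhaustion time must lie within the protocol series"
            )

    def depletion_at(tau, series):
        t = time_to_depletion(simulate_wbal(series, cp, w0, tau=tau))
        return t if t is not None else math.inf

    lo, hi = tau_bounds
    if len(protocols) == 1:
        series, t_obs = protocols[0]

        def f(tau):
            d = depletion_at(tau, series)
            return (d if math.isfinite(d) else series.time_s[-1] * 10.0) - t_obs

        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            raise NoSolutionError(
                f"no tau in ({lo}, {hi}) s reproduces exhaustion at {t_obs} s"
            )
        return float(optimize.brentq(f, lo, hi, xtol=1e-3))

    def sse(log_tau):
        tau = math.exp(log_tau)
        total = 0.0
        for series, t_obs in protocols:
            d = depletion_at(tau, series)
            if not math.isfinite(d):
                d = series.time_s[-1] * 10.0
            total += (d - t_obs) ** 2
        return total

    res = optimize.minimize_scalar(
        sse, bounds=(math.log(lo), math.log(hi)), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise NoSolutionError("no tau in bounds fits the observed exhaustion times")
    tau_hat = float(math.exp(res.x))
    if all(not math.isfinite(depletion_at(tau_hat, s)) for s, _ in protocols):
        raise NoSolutionError(
            f"no tau in ({lo}, {hi}) s achieves depletion on any protocol"
        )
    return tau_hat
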