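"""Seeded synthetic athletes: careers, trial sets, all-out traces, cohorts.

Everything downstream of the fitting code can be exercised without real
power-meter data by generating athletes whose performances obey the
hyperbolic power-duration model exactly, then perturbing them with the
noise structure real testing shows:

* mean-maximal-power (MMP) careers follow a log-linear development trend in
  CP (typical of a cyclist maturing through their early twenties), with
  multiplicative lognormal measurement noise at a 1.5 % coefficient of
  variation by default — the low end of reported typical errors for
  constant-duration power (CV 1.5-3.5 %);
* time-to-exhaustion protocols put the noise on duration (CV ~10 %, per the
  reported 10-19 % range), constant-duration protocols on power (CV ~2 %);
* doping is modelled as a multiplicative shift applied to the doped years'
  MMP cells (+5 % by default), applied AFTER the noise draw so a doped
  career and its clean counterfactual generated from the same seed share
  noise exactly — the doping effect is isolated to the last multiplication.

All generators are pure functions of their arguments: the same spec and
seed reproduce the same data bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import ValidationError
from .pdcurve import AOTTrace, PerformanceTrial, Protocol
from .passport import MMPTable

__all__ = [
    "AthleteSpec",
    "CohortMember",
    "generate_career",
    "generate_trial_set",
    "generate_3aot_trace",
    "generate_cohort",
    "lognormal_sigma",
]

DEFAULT_PANEL_S = (300.0, 600.0, 1200.0, 1800.0)


def lognormal_sigma(cv: float) -> float:
    """Log-scale sigma giving a lognormal with the requested CV."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class AthleteSpec:
    """Parameters of one synthetic athlete career.

    ``cp0`` is CP (W) in the reference (first) year; ``cp_growth`` the
    fractional year-on-year CP growth (log-linear career trend).  W′ is
    constant across years by default (``w_prime_growth=0``) since no career
    trend for it is established.  ``noise_cv`` is the measurement CV on each
    MMP cell.  Doped years have every cell multiplied by (1 + doping_pct).
    """

    cp0: float = 280.0
    cp_growth: float = 0.02
    w_prime: float = 20_000.0
    w_prime_growth: float = 0.0
    noise_cv: float = 0.015
    duration_panel_s: tuple = DEFAULT_PANEL_S
    years: tuple = tuple(range(2003, 2009))
    doped_years: tuple = ()
    doping_pct: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if not (self.cp0 > 0 and self.w_prime > 0):
            raise ValidationError("cp0 and w_prime must be positive")
        if not 0 <= self.noise_cv < 0.2:
            raise ValidationError("noise_cv must be in [0, 0.2)")
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")
        if len(self.years) == 0 or len(self.duration_panel_s) == 0:
            raise ValidationError("years and duration panel must be non-empty")
        if any(y not in self.years for y in self.doped_years):
            raise ValidationError("doped_years must be a subset of years")


def true_power(spec: AthleteSpec, year: int, duration_s: float) -> float:
    """Noise-free MMP at (year, duration) under the athlete's hyperbola."""
    dy = year - spec.years[0]
    cp = spec.cp0 * (1.0 + spec.cp_growth) ** dy
    wp = spec.w_prime * (1.0 + spec.w_prime_growth) ** dy
    return wp / duration_s + cp


def generate_career(spec: AthleteSpec) -> MMPTable:
    """Season-by-duration MMP table for one athlete.

    Noise draws occur in a fixed (year-major, duration-minor) order
    regardless of which years are doped, so clean/doped counterfactuals
    from the same seed are exact scalings of each other.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    doped = set(spec.doped_years)
    for year in spec.years:
        factors = _noise_factors(rng, spec.noise_cv, len(spec.duration_panel_s))
        for dur, f in zip(spec.duration_panel_s, factors):
            power = true_power(spec, year, dur) * f
            provenance = "observed"
            if year in doped:
                power *= 1.0 + spec.doping_pct
                provenance = "doped-simulated"
            records.append((int(year), float(dur), float(power), provenance))
    return MMPTable.from_records(records)


def generate_trial_set(
    cp: float,
    w_prime: float,
    protocol: Protocol,
    durations_or_powers: Sequence[float],
    noise_cv: Optional[float] = None,
    seed: Optional[int] = None,
) -> list[PerformanceTrial]:
    """Trials on a known hyperbola with protocol-appropriate error structure.

    TTE protocols take target powers and return noisy DURATIONS (default
    CV 10 %); constant-duration (and MMP/time-trial) protocols take
    durations and return noisy POWERS (default CV 2 %).
    """
    rng = np.random.default_rng(seed)
    protocol = Protocol(protocol)
    vals = np.asarray(durations_or_powers, dtype=float)
    if protocol is Protocol.TTE:
        cv = 0.10 if noise_cv is None else noise_cv
        if np.any(vals <= cp):
            raise ValidationError("TTE trial powers must exceed CP")
        t_true = w_prime / (vals - cp)
        t_obs = t_true * _noise_factors(rng, cv, vals.size)
        return [
            PerformanceTrial(duration_s=float(t), power_w=float(p), protocol=protocol)
            for t, p in zip(t_obs, vals)
        ]
    cv = 0.02 if noise_cv is None else noise_cv
    p_true = w_prime / vals + cp
    p_obs = p_true * _noise_factors(rng, cv, vals.size)
    return [
        PerformanceTrial(duration_s=float(t), power_w=float(p), protocol=protocol)
        for t, p in zip(vals, p_obs)
    ]


def solve_decay_tau(cp: float, w_prime: float, peak_power: float) -> float:
    """Decay constant making the supra-CP integral of the all-out trace equal W′.

    Solves (peak - cp) * tau * (1 - exp(-180/tau)) = w_prime.
    """
    if peak_power <= cp:
        raise ValidationError("peak power must exceed CP")
    target = w_prime / (peak_power - cp)
    if target >= 180.0:
        raise ValidationError("W' too large to deplete within 180 s at this peak power")

    def f(tau):
        return tau * (1.0 - math.exp(-180.0 / tau)) - target

    return float(optimize.brentq(f, 1e-6, 1e6))


def generate_3aot_trace(
    cp: float,
    w_prime: float,
    peak_power: float,
    decay_tau: Optional[float] = None,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> AOTTrace:
    """Exponentially decaying all-out effort: P(t) = cp + (peak-cp) e^(-t/tau).

    With ``decay_tau=None`` the decay constant is solved so the work above
    CP over the full 180 s equals W′ — an idealised test that fully spends
    the capacity.  Optional additive Gaussian noise (W).
    """
    if w_prime > 0:
        tau = solve_decay_tau(cp, w_prime, peak_power) if decay_tau is None else decay_tau
    else:
        tau = decay_tau if decay_tau is not None else 1.0
    t = np.arange(0.0, 180.0 + dt / 2, dt)
    amp = (peak_power - cp) if w_prime > 0 else 0.0
    p = cp + amp * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = np.maximum(p + rng.normal(0.0, noise_sd, t.size), 0.0)
    return AOTTrace(time_s=t, power_w=p)


@dataclass(frozen=True)
class CohortMember:
    spec: AthleteSpec
    table: MMPTable
    doped: bool


def generate_cohort(
    n: int,
    base_spec: AthleteSpec,
    doped_fraction: float,
    seed: int,
    cp0_sd: float = 25.0,
    w_prime_sd: float = 3000.0,
) -> list[CohortMember]:
    """A labelled cohort of athletes with heterogeneous (CP, W′).

    Exactly ``round(n * doped_fraction)`` members (deterministically the
    first that many, before shuffling athlete parameters would matter) have
    their spec's ``doped_years`` activated; ground-truth labels are kept.
    Individual CP0 and W′ are truncated-normal draws around the base spec.
    """
    if not 0 <= doped_fraction <= 1:
        raise ValidationError("doped_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_doped = round(n * doped_fraction)
    doped_years = base_spec.doped_years or (base_spec.years[-1],)
    members = []
    for i in range(n):
        cp0 = max(float(rng.normal(base_spec.cp0, cp0_sd)), 50.0)
        wp = max(float(rng.normal(base_spec.w_prime, w_prime_sd)), 1000.0)
        child_seed = int(rng.integers(0, 2**31 - 1))
        doped = i < n_doped
        spec = replace(
            base_spec,
            cp0=cp0,
            w_prime=wp,
            seed=child_seed,
            doped_years=doped_years if doped else (),
        )
        members.append(CohortMember(spec=spec, table=generate_career(spec), doped=doped))
    return members
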