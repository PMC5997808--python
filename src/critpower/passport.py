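"""Longitudinal performance passport built on the critical-power model.

The idea mirrors the Athlete Biological Passport: instead of comparing an
athlete to population norms, condition a model on the athlete's own
baseline seasons and flag new performances that exceed individualized
expected ranges.  The raw material is a mean-maximal-power (MMP) table —
for each season, the best mean power over each duration of a fixed panel
(300, 600, 1200 and 1800 s by default, durations inside the hyperbola's
valid domain).

Pipeline per tested season:

1. remove the career development trend by per-duration log-linear
   regression of log(power) on year, so seasons become comparable;
2. pool all detrended baseline cells (three or more seasons, hence twelve
   or more points) into one power-vs-1/t regression;
3. compare the test season's observed power at each panel duration against
   the upper bound of the two-sided 99 % new-observation prediction
   interval (flags are upper-one-sided: only suspiciously HIGH performance
   matters), and the test season's own fitted CP and W′ against the
   baseline parameters' 99 % confidence intervals;
4. absorb the tested season into the baseline and move on.  Deliberately,
   flagged seasons are absorbed too: an undetected doped season then
   inflates the baseline mean and variance and can mask doping in the
   following season.  ``quarantine_flagged`` excludes flagged seasons from
   later baselines — the obvious remedy, provided as an extension.

Evidence from independent markers (e.g. a hematological score and a
performance flag) can be combined into a posterior probability of doping by
Bayes' rule under conditional independence given the doping state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientBaselineError, InsufficientDataError, ValidationError
from .pdcurve import (
    CPFit,
    PerformanceTrial,
    Protocol,
    fit_linear_power_invtime,
    parameter_ci,
    predict_power,
    prediction_interval,
)

__all__ = [
    "MMPTable",
    "TrendParams",
    "DurationAssessment",
    "ParameterAssessment",
    "PassportYearReport",
    "PopulationNorms",
    "PopulationFlags",
    "DopingEvidence",
    "ROCPoint",
    "detrend_log_linear",
    "apply_doping_effect",
    "evaluate_year",
    "sequential_passport",
    "population_comparison",
    "combine_evidence_bayes",
    "classifier_roc",
    "athlete_suspicion_score",
]

MIN_BASELINE_POINTS = 12  # three seasons x four panel durations

# an exceedance must be beyond this relative margin to flag, so degenerate
# zero-variance baselines do not flag ties at machine precision
_FLAG_RTOL = 1e-9


def _exceeds(value: float, bound: float) -> bool:
    return bool(value > bound + _FLAG_RTOL * abs(bound))


class MMPTable:
    """Season-year x duration grid of best mean powers.

    Thin wrapper over a DataFrame with columns ``year`` (int),
    ``duration_s`` (float), ``power_w`` (float) and ``provenance``
    (observed | detrended | doped-simulated).  At most one cell per
    (year, duration); powers strictly positive.
    """

    COLUMNS = ("year", "duration_s", "power_w", "provenance")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "provenance" not in df.columns:
            df["provenance"] = "observed"
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"MMP table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)]
        df["year"] = df["year"].astype(int)
        df["duration_s"] = df["duration_s"].astype(float)
        df["power_w"] = df["power_w"].astype(float)
        if (df["power_w"] <= 0).any():
            raise ValidationError("MMP powers must be positive")
        if df.duplicated(subset=["year", "duration_s"]).any():
            raise ValidationError("at most one MMP cell per (year, duration)")
        self._df = df.sort_values(["year", "duration_s"]).reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "MMPTable":
        """Records of (year, duration_s, power_w[, provenance])."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 3:
                rec = rec + ("observed",)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def years(self) -> list:
        return sorted(self._df["year"].unique().tolist())

    @property
    def durations(self) -> list:
        return sorted(self._df["duration_s"].unique().tolist())

    def cells(self, years: Sequence[int]) -> pd.DataFrame:
        return self._df[self._df["year"].isin(list(years))].copy()

    def trials(self, years: Sequence[int]) -> list:
        """Cells as performance trials for the fitting machinery."""
        sub = self.cells(years)
        return [
            PerformanceTrial(
                duration_s=row.duration_s,
                power_w=row.power_w,
                protocol=Protocol.MMP,
                year=int(row.year),
            )
            for row in sub.itertuples()
        ]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, MMPTable) and self._df.equals(other._df)


@dataclass(frozen=True)
class TrendParams:
    """Per-duration log-linear career trend: log(power) = intercept + slope*(year - ref)."""

    slope_per_year: float
    intercept_log_w: float
    reference_year: int


def _loglinear(years: np.ndarray, log_p: np.ndarray, ref_year: int) -> TrendParams:
    x = years - ref_year
    slope, intercept = np.polyfit(x, log_p, 1)
    return TrendParams(float(slope), float(intercept), int(ref_year))


def detrend_log_linear(
    table: MMPTable,
    estimation_years: Sequence[int],
    *,
    per_duration: bool = True,
) -> tuple[MMPTable, dict]:
    """Remove the career development trend from an MMP table.

    Per duration, log(power) is regressed on year over ``estimation_years``
    (at least three), and every cell of EVERY year is rescaled by
    exp(-slope * (year - reference_year)), reference being the earliest
    estimation year.  A table with no trend is returned unchanged (up to
    floating point); detrending an already-detrended table is idempotent.

    ``per_duration=False`` pools a single slope across durations (with
    per-duration intercepts), trading flexibility for stability.

    Returns the detrended table and ``{duration: TrendParams}``.
    """
    est_years = sorted(set(int(y) for y in estimation_years))
    if len(est_years) < 3:
        raise InsufficientBaselineError(
            f"trend estimation needs >= 3 years, got {len(est_years)}"
        )
    ref_year = est_years[0]
    df = table.df
    est = df[df["year"].isin(est_years)]
    if est.empty:
        raise InsufficientBaselineError("no MMP cells in the estimation years")

    trends: dict = {}
    if per_duration:
        for dur, grp in est.groupby("duration_s"):
            if grp["year"].nunique() < 3:
                raise InsufficientBaselineError(
                    f"duration {dur:g}s has fewer than 3 estimation years"
                )
            trends[float(dur)] = _loglinear(
                grp["year"].to_numpy(float), np.log(grp["power_w"].to_numpy()), ref_year
            )
    else:
        # common slope, per-duration intercepts: demean log power within duration
        logp = np.log(est["power_w"].to_numpy())
        x = est["year"].to_numpy(float) - ref_year
        d = est["duration_s"].to_numpy()
        logp_c = logp.copy()
        x_c = x.copy()
        for dur in np.unique(d):
            m = d == dur
            logp_c[m] -= logp[m].mean()
            x_c[m] -= x[m].mean()
        slope = float(np.sum(x_c * logp_c) / np.sum(x_c * x_c))
        for dur, grp in est.groupby("duration_s"):
            icept = float(np.log(grp["power_w"]).mean() - slope * (grp["year"].mean() - ref_year))
            trends[float(dur)] = TrendParams(slope, icept, ref_year)

    out = df.copy()
    for dur, tp in trends.items():
        m = out["duration_s"] == dur
        shift = np.exp(-tp.slope_per_year * (out.loc[m, "year"] - tp.reference_year))
        out.loc[m, "power_w"] = out.loc[m, "power_w"] * shift
        out.loc[m, "provenance"] = np.where(
            out.loc[m, "provenance"] == "doped-simulated", "doped-simulated", "detrended"
        )
    unknown = set(out["duration_s"]) - set(trends)
    if unknown:
        raise ValidationError(
            f"durations {sorted(unknown)} absent from the estimation years; cannot detrend"
        )
    return MMPTable(out), trends


def apply_doping_effect(table: MMPTable, years: Sequence[int], pct: float) -> MMPTable:
    """Multiply all MMP cells of the given years by (1 + pct).

    Simulates an across-the-board performance shift (a +5 % shift is the
    conventional illustration); affected cells are tagged doped-simulated.
    """
    years = set(int(y) for y in years)
    df = table.df
    m = df["year"].isin(years)
    df.loc[m, "power_w"] *= 1.0 + pct
    if pct != 0:
        df.loc[m, "provenance"] = "doped-simulated"
    return MMPTable(df)


@dataclass
class DurationAssessment:
    duration_s: float
    observed_w: float
    predicted_w: float
    pi_low_w: float
    pi_high_w: float
    flagged: bool  # observed above the upper prediction bound


@dataclass
class ParameterAssessment:
    name: str
    baseline_estimate: float
    ci_low: float
    ci_high: float
    test_estimate: Optional[float]
    flagged: Optional[bool]  # test estimate above the upper confidence bound


@dataclass
class PassportYearReport:
    """Outcome of comparing one season against its baseline."""

    test_year: int
    baseline_years: list
    n_baseline_points: int
    level: float
    performances: list  # DurationAssessment per panel duration
    cp: ParameterAssessment
    w_prime: ParameterAssessment
    baseline_fit: CPFit = field(repr=False, default=None)
    test_fit: Optional[CPFit] = field(repr=False, default=None)

    @property
    def n_performance_flags(self) -> int:
        return sum(a.flagged for a in self.performances)

    @property
    def any_flag(self) -> bool:
        return (
            self.n_performance_flags > 0
            or bool(self.cp.flagged)
            or bool(self.w_prime.flagged)
        )


def evaluate_year(
    table_detrended: MMPTable,
    test_year: int,
    level: float = 0.99,
    *,
    baseline_years: Optional[Sequence[int]] = None,
    min_baseline_points: int = MIN_BASELINE_POINTS,
    two_sided_parameter_flags: bool = False,
) -> PassportYearReport:
    """Compare one season's MMPs and parameters against its baseline.

    The baseline is every year strictly before ``test_year`` (or an
    explicit subset, for quarantine policies).  All baseline cells pool
    into ONE power-vs-1/t regression; each test-year duration is compared
    to the two-sided ``level`` prediction interval, flagged only when the
    observation EXCEEDS the upper bound.  The test year's own 2-parameter
    fit provides CP and W′ point estimates compared against the baseline
    parameters' ``level`` confidence intervals, again upper-one-sided by
    default (a doping-induced W′ DECREASE is invisible unless
    ``two_sided_parameter_flags`` is set).
    """
    test_year = int(test_year)
    if baseline_years is None:
        baseline_years = [y for y in table_detrended.years if y < test_year]
    else:
        baseline_years = sorted(int(y) for y in baseline_years if y < test_year)
    baseline_trials = table_detrended.trials(baseline_years)
    if len(baseline_trials) < min_baseline_points:
        raise InsufficientBaselineError(
            f"baseline has {len(baseline_trials)} MMP points; conditioning requires "
            f">= {min_baseline_points} (three or more seasons). Without population "
            "norms for CP and W', no individualized expected range can be formed."
        )
    fit = fit_linear_power_invtime(baseline_trials)
    (cp_lo, cp_hi), (wp_lo, wp_hi) = parameter_ci(fit, level)

    test_cells = table_detrended.cells([test_year])
    if test_cells.empty:
        raise InsufficientDataError(f"no MMP cells for test year {test_year}")
    performances = []
    for row in test_cells.itertuples():
        lo, hi = prediction_interval(fit, row.duration_s, level)
        pred = predict_power(fit, row.duration_s).power_w
        performances.append(
            DurationAssessment(
                duration_s=row.duration_s,
                observed_w=row.power_w,
                predicted_w=pred,
                pi_low_w=lo,
                pi_high_w=hi,
                flagged=_exceeds(row.power_w, hi),
            )
        )

    test_fit = None
    cp_test = wp_test = None
    if len(test_cells) >= 2 and test_cells["duration_s"].nunique() >= 2:
        test_fit = fit_linear_power_invtime(table_detrended.trials([test_year]))
        cp_test, wp_test = test_fit.cp, test_fit.w_prime

    def _param_flag(test_val, lo, hi):
        if test_val is None:
            return None
        if two_sided_parameter_flags:
            return _exceeds(test_val, hi) or _exceeds(lo, test_val)
        return _exceeds(test_val, hi)

    cp_assess = ParameterAssessment(
        name="cp",
        baseline_estimate=fit.cp,
        ci_low=cp_lo,
        ci_high=cp_hi,
        test_estimate=cp_test,
        flagged=_param_flag(cp_test, cp_lo, cp_hi),
    )
    wp_assess = ParameterAssessment(
        name="w_prime",
        baseline_estimate=fit.w_prime,
        ci_low=wp_lo,
        ci_high=wp_hi,
        test_estimate=wp_test,
        flagged=_param_flag(wp_test, wp_lo, wp_hi),
    )
    return PassportYearReport(
        test_year=test_year,
        baseline_years=list(baseline_years),
        n_baseline_points=len(baseline_trials),
        level=level,
        performances=performances,
        cp=cp_assess,
        w_prime=wp_assess,
        baseline_fit=fit,
        test_fit=test_fit,
    )


def sequential_passport(
    table: MMPTable,
    first_test_year: int,
    level: float = 0.99,
    *,
    trend_window: str = "career",
    quarantine_flagged: bool = False,
    per_duration_trend: bool = True,
    min_baseline_points: int = MIN_BASELINE_POINTS,
) -> list:
    """Expanding-window passport over successive seasons.

    Seasons from ``first_test_year`` on are evaluated in order; each tested
    season is then absorbed into the next baseline REGARDLESS of flags
    (reproducing the masking weakness) unless ``quarantine_flagged`` is
    set, in which case seasons with any flag are excluded from later
    baselines.

    ``trend_window`` controls detrending:

    * ``"career"`` (default): per-duration log-linear trends estimated once
      over the athlete's full observed career, then every season rescaled —
      the procedure of the original six-season illustration, and the one
      that keeps the held-out season's variance compatible with the
      prediction interval;
    * ``"baseline"``: trends re-estimated from each evaluation's baseline
      years only (the test season then carries extra trend-extrapolation
      variance, costing specificity);
    * ``"none"``: the table is used as supplied (already detrended or
      trend-free).
    """
    if trend_window not in ("career", "baseline", "none"):
        raise ValidationError(f"unknown trend_window {trend_window!r}")
    years = table.years
    test_years = [y for y in years if y >= first_test_year]
    if not test_years:
        raise ValidationError("no test years at or after first_test_year")

    if trend_window == "career":
        detrended, _ = detrend_log_linear(table, years, per_duration=per_duration_trend)
    elif trend_window == "none":
        detrended = table

    reports = []
    excluded: set = set()
    for ty in test_years:
        base_years = [y for y in years if y < ty and y not in excluded]
        if trend_window == "baseline":
            detrended, _ = detrend_log_linear(
                table, base_years, per_duration=per_duration_trend
            )
        report = evaluate_year(
            detrended,
            ty,
            level,
            baseline_years=base_years,
            min_baseline_points=min_baseline_points,
        )
        reports.append(report)
        if quarantine_flagged and report.any_flag:
            excluded.add(ty)
    return reports


@dataclass(frozen=True)
class PopulationNorms:
    """Normal cross-sectional reference for CP (W) and W′ (J).

    No published norms exist; these must be supplied by the user from
    their own reference cohort.
    """

    cp_mean: float
    cp_sd: float
    w_prime_mean: float
    w_prime_sd: float


@dataclass
class PopulationFlags:
    z_cp: float
    z_w_prime: float
    cp_flagged: bool
    w_prime_flagged: bool


def population_comparison(
    fit: CPFit, norms: PopulationNorms, quantile: float = 0.99
) -> PopulationFlags:
    """Flag unrealistically high CP or W′ against population norms.

    z-scores above the normal ``quantile`` (upper-one-sided) are flagged.
    """
    if not 0 < quantile < 1:
        raise ValidationError("quantile must be in (0,1)")
    z_cp = (fit.cp - norms.cp_mean) / norms.cp_sd
    z_wp = (fit.w_prime - norms.w_prime_mean) / norms.w_prime_sd
    zcrit = stats.norm.ppf(quantile)
    return PopulationFlags(
        z_cp=float(z_cp),
        z_w_prime=float(z_wp),
        cp_flagged=bool(z_cp > zcrit),
        w_prime_flagged=bool(z_wp > zcrit),
    )


@dataclass
class DopingEvidence:
    """Inputs to the Bayesian combination of evidence.

    Each likelihood pair is (density under doped, density under clean) for
    the observed marker value.  ``likelihood_performance`` may be None for
    the single-marker version.
    """

    prior_p_doped: float
    likelihood_biomarker: tuple[float, float]
    likelihood_performance: Optional[tuple[float, float]] = None
    posterior_p_doped: Optional[float] = None


def combine_evidence_bayes(evidence: DopingEvidence) -> float:
    """Posterior probability of doping from independent lines of evidence.

    Bayes' rule with the biomarker and the performance marker assumed
    conditionally independent given the doping state D:

    .. math:: P(D \\mid M_B, M_P) = \\frac{\\pi\\, f_B(m_B|D)\\, f_P(m_P|D)}
              {\\pi\\, f_B(m_B|D)\\, f_P(m_P|D)
               + (1-\\pi)\\, f_B(m_B|\\bar D)\\, f_P(m_P|\\bar D)}.

    Degenerate priors 0 and 1 pass through; uninformative likelihood ratios
    leave the prior unchanged.
    """
    prior = evidence.prior_p_doped
    if not 0 <= prior <= 1:
        raise ValidationError("prior must be a probability")
    pairs = [evidence.likelihood_biomarker]
    if evidence.likelihood_performance is not None:
        pairs.append(evidence.likelihood_performance)
    num = prior
    alt = 1.0 - prior
    for doped_density, clean_density in pairs:
        if doped_density < 0 or clean_density < 0:
            raise ValidationError("likelihood densities must be non-negative")
        num *= doped_density
        alt *= clean_density
    total = num + alt
    if total == 0:
        raise ValidationError("total probability is zero; evidence is inconsistent")
    posterior = num / total
    evidence.posterior_p_doped = posterior
    return posterior


def athlete_suspicion_score(table_detrended: MMPTable, test_year: int) -> float:
    """Continuous passport score: the largest standardized upper exceedance.

    For each test-year panel duration, (observed - predicted) / SE_pred
    from the baseline regression; the maximum over durations is the
    athlete's score.  Thresholding this score at the t-quantile
    corresponding to a PI level reproduces the passport's flag decision, so
    sweeping the threshold traces the classifier's ROC curve.
    """
    test_year = int(test_year)
    baseline_years = [y for y in table_detrended.years if y < test_year]
    baseline_trials = table_detrended.trials(baseline_years)
    fit = fit_linear_power_invtime(baseline_trials)
    x = fit.x
    n = fit.n
    sxx = float(np.sum((x - x.mean()) ** 2))
    best = -math.inf
    for row in table_detrended.cells([test_year]).itertuples():
        xstar = 1.0 / row.duration_s
        yhat = fit.cp + fit.w_prime * xstar
        se = fit.residual_sd * math.sqrt(1 + 1 / n + (xstar - x.mean()) ** 2 / sxx)
        best = max(best, (row.power_w - yhat) / se)
    return best


@dataclass
class ROCPoint:
    level: float              # two-sided PI level defining the operating point
    threshold: float          # t quantile applied to the suspicion score
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple
    specificity_ci: tuple


def classifier_roc(
    clean_scores: Sequence[float],
    doped_scores: Sequence[float],
    levels: Sequence[float],
    df: int,
) -> list:
    """Empirical ROC of the passport score over a grid of PI levels.

    ``df`` is the residual degrees of freedom of the baseline fits (n-2).
    Sensitivity = fraction of doped athletes flagged, specificity =
    fraction of clean athletes not flagged; 95 % binomial (Wilson) CIs on
    both.
    """
    from statsmodels.stats.proportion import proportion_confint

    clean = np.asarray(clean_scores, dtype=float)
    doped = np.asarray(doped_scores, dtype=float)
    points = []
    for level in levels:
        if not 0 < level < 1:
            raise ValidationError("PI levels must be in (0,1)")
        thr = float(stats.t.ppf(0.5 + level / 2.0, df=df))
        tp = int(np.sum(doped > thr))
        tn = int(np.sum(clean <= thr))
        sens = tp / doped.size if doped.size else float("nan")
        spec = tn / clean.size if clean.size else float("nan")
        sens_ci = proportion_confint(tp, doped.size, method="wilson") if doped.size else (np.nan, np.nan)
        spec_ci = proportion_confint(tn, clean.size, method="wilson") if clean.size else (np.nan, np.nan)
        points.append(
            ROCPoint(
                level=float(level),
                threshold=thr,
                sensitivity=float(sens),
                specificity=float(spec),
                sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
                specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
            )
        )
    return points
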