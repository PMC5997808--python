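# critpower

Critical-power modelling and a longitudinal **performance passport** for
doping screening, in Python.

Endurance performance over durations of roughly 3–40 minutes is well
described by the two-parameter critical-power (CP) model,

```
P = W′/t + CP        ⇔        t_lim = W′ / (P − CP)
```

where **CP** (W) is the highest power sustainable in metabolic
steady state and **W′** (J) is the finite work capacity expendable above
CP. Because both parameters respond predictably to ergogenic
interventions — oxygen-transport doping moves CP, strength/anaerobic aids
move W′ — an athlete's own power–duration history can serve as a
performance biomarker, monitored longitudinally the way the Athlete
Biological Passport monitors blood markers.

`critpower` provides, for sport scientists and anti-doping researchers:

* **`critpower.pdcurve`** — CP model fitting in all three algebraic forms
  (hyperbolic nonlinear LS on duration for TTE data; OLS of power on 1/t
  for constant-duration/MMP data; the work–time line for time trials) plus
  the 3-min all-out test reduction; predictions with validity flags,
  new-observation prediction intervals, parameter CIs, and residual
  diagnostics.
* **`critpower.wbal`** — the W′ balance model for intermittent exercise
  (exponential reconstitution with τ_w′ = 564·e^(−0.01·D_CP) + 316 s),
  time-to-depletion prediction, τ fitting from observed exhaustion, and
  physiological-plausibility screens.
* **`critpower.passport`** — the longitudinal pipeline: per-duration
  log-linear detrending of mean-maximal-power (MMP) careers,
  expanding-window conditioning on ≥12 baseline points, upper-one-sided
  flagging against 99 % prediction/confidence intervals, Bayesian
  combination of evidence lines, and ROC evaluation on simulated cohorts.
* **`critpower.simulate`** — seeded synthetic athletes: hyperbolic careers
  with log-linear development trends, lognormal measurement noise at
  published typical-error magnitudes, exact clean/doped counterfactual
  pairs, trial sets, all-out traces and labelled cohorts.
* **`critpower` CLI** — `fit`, `wbal`, `passport`, `simulate` over plain
  CSV files, with an audit log of every fitted parameter and flag.

## Worked example: a doped career

Simulate a six-season career (CP 280 W growing 2 %/yr, W′ 20 kJ, noise
CV 1.5 %) with a +5 % doping effect injected into the last two seasons,
then run the passport with seasons 2003–2005 as the first baseline:

```bash
critpower simulate career --seed 28 --dope-years 2007 --dope-years 2008 --out career.csv
critpower passport --mmp career.csv --first-test-year 2006 --out report.json
```

```
tested_years=[2006, 2007, 2008] flagged_years=[2007]
```

Inspecting `report.json`:

```
2006: cp_test=268.6 W  cp_ci=(269.5, 281.9)  cp_flag=False  perf_flags=0
2007: cp_test=285.7 W  cp_ci=(267.9, 280.0)  cp_flag=True   perf_flags=1
    600 s: observed 324.1 W > PI high 321.5 W
2008: cp_test=274.1 W  cp_ci=(269.4, 283.1)  cp_flag=False  perf_flags=0
```

The clean 2006 season sits inside all intervals. In the first doped
season the 600 s performance exceeds the upper 99 % prediction bound and
the season's fitted CP (285.7 W) exceeds the baseline CP confidence
interval — while W′ is not flagged, because W′'s typical error is an
order of magnitude larger than CP's. In 2008 nothing is flagged even
though the doping continued: the undetected 2007 season was absorbed into
the baseline, biasing its mean upward and widening its intervals. This
**masking** effect is a structural weakness of passport-style monitoring
that the package deliberately reproduces (and optionally removes with
`--quarantine-flagged`).

The same pipeline is available as a library:

```python
from critpower import AthleteSpec, generate_career, sequential_passport

table = generate_career(AthleteSpec(seed=28, doped_years=(2007, 2008)))
reports = sequential_passport(table, first_test_year=2006, level=0.99)
```

## Data formats

Plain UTF-8 CSV with headers: trials (`duration_s,power_w[,work_j,protocol,year]`),
power/all-out series (`time_s,power_w`), MMP tables
(`year,duration_s,power_w[,provenance]`). Fit reports and passport reports
are JSON. See `docs/methods.md` for model assumptions, conventions and
limitations.
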