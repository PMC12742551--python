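"""Cohort-level analysis of verification records.

Mirrors how a large institutional QA dataset is analyzed: filter out
human-error sessions, aggregate per category (room, ion, TPS, range shifter,
indication, year), test the mean deviation for systematic shifts and for
group differences, correlate against stack position and target volume, study
the sensitivity of the pass rate to the gradient-deactivation threshold, and
account for the total time spent.

Statistical conventions: sample SD (n-1) everywhere; significance level
alpha = 0.01; Shapiro-Wilk normality is reported but never blocks the t-test
(large-sample robustness); Levene's test gates pooled vs Welch two-sample
t-tests; ANOVA is followed by Tukey HSD only when significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .verify import (NoEvaluableChambersError, ToleranceConfig,
                     VerificationRecord, classify, compute_deviation_summary,
                     select_active_chambers)

__all__ = [
    "FieldRecord",
    "TestResult",
    "PerStepTimes",
    "ALPHA",
    "records_to_frame",
    "exclude_flagged",
    "aggregate",
    "test_mean_shift",
    "test_median_shift",
    "compare_groups",
    "compare_multi",
    "correlate",
    "threshold_sensitivity",
    "time_accounting",
    "deviation_in_mgy",
    "rounded_pass_rate",
]

ALPHA = 0.01

CATEGORY_AXES = ("room", "ion", "tps", "rashi", "indication", "year")


@dataclass(frozen=True)
class FieldRecord:
    """One verified treatment field with its category labels and summary."""

    field_id: str
    room: str                  # Hx | Ga
    ion: str                   # p | He | C
    tps: str                   # Syngo | RayStation
    rashi: bool
    indication: str
    year: int
    pos_a: float               # stack placement, mm
    pos_b: float
    pos_c: float
    volume_cm3: float
    mean_dev: float            # % of D_max, over active chambers
    sd_dev: float
    min_dev: float
    max_dev: float
    n_active: int
    time_s: float
    passed: bool
    repeat_index: int = 0
    human_error: bool = False

    def __post_init__(self):
        if not (self.min_dev <= self.mean_dev <= self.max_dev):
            raise ValueError("need min_dev <= mean_dev <= max_dev")
        if not (1 <= self.n_active <= 24):
            raise ValueError("n_active must lie in [1, 24]")


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    effect: float = 0.0
    detail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def records_to_frame(records) -> pd.DataFrame:
    """List of FieldRecords (or dicts) -> tidy DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [asdict(r) if isinstance(r, FieldRecord) else dict(r)
            for r in records]
    return pd.DataFrame(rows)


def exclude_flagged(records) -> tuple[pd.DataFrame, int]:
    """Drop records flagged as human operating errors.

    Returns the retained frame and the number of dropped records.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        return df, 0
    keep = df[~df["human_error"].astype(bool)].reset_index(drop=True)
    return keep, int(len(df) - len(keep))


def _summarize(group: pd.DataFrame) -> dict:
    n = len(group)
    mean = float(group["mean_dev"].mean())
    sd = float(group["mean_dev"].std(ddof=1)) if n > 1 else 0.0
    passed = int(group["passed"].sum())
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "single_record": n == 1,
        "min": float(group["min_dev"].min()),
        "max": float(group["max_dev"].max()),
        "time_mean_s": float(group["time_s"].mean()),
        "time_sd_s": float(group["time_s"].std(ddof=1)) if n > 1 else 0.0,
        "passed": passed,
        "failed": n - passed,
        "pass_rate_pct": 100.0 * passed / n,
        "n_active_mean": float(group["n_active"].mean()),
        "n_active_sd": float(group["n_active"].std(ddof=1)) if n > 1 else 0.0,
    }


def aggregate(records, by: str | None = None) -> pd.DataFrame:
    """Per-group cohort summary.

    Per group: mean and sample SD of the field means, global min of field
    minima and max of field maxima, pass/fail counts and rate, mean +/- SD of
    irradiation time and of the number of active chambers.  ``by=None``
    yields the single "all" row.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("cannot aggregate an empty cohort")
    if by is None:
        return pd.DataFrame([_summarize(df)], index=pd.Index(["all"],
                                                             name="group"))
    rows = {}
    for level, group in df.groupby(by, sort=True):
        rows[level] = _summarize(group)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = by
    return out


def test_mean_shift(values) -> TestResult:
    """One-sample t-test of the mean deviation against zero.

    Shapiro-Wilk normality is computed and carried along (capped at 5000
    samples for the statistic) but does not gate the test.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    t, p = stats.ttest_1samp(x, 0.0)
    sw = stats.shapiro(x if len(x) <= 5000 else x[:5000])
    return TestResult(test="one-sample t", statistic=float(t),
                      p_value=float(p), effect=float(x.mean()),
                      detail={"shapiro_p": float(sw.pvalue)})


def test_median_shift(values) -> TestResult:
    """One-sample Wilcoxon signed-rank test against zero (for the strongly
    asymmetric minimum/maximum deviations)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.all(x == x[0]):
        raise ValueError("Wilcoxon signed-rank test undefined for "
                         "all-identical values")
    res = stats.wilcoxon(x)
    return TestResult(test="wilcoxon signed-rank",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      effect=float(np.median(x)))


def compare_groups(a, b, labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-group comparison: Levene's test picks pooled vs Welch t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate zero-variance groups")
    lev_stat, lev_p = stats.levene(a, b)
    equal_var = lev_p >= ALPHA
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    name = "two-sample t (pooled)" if equal_var else "Welch t"
    return TestResult(test=name, statistic=float(t), p_value=float(p),
                      groups=labels, effect=float(a.mean() - b.mean()),
                      detail={"levene_p": float(lev_p)})


def compare_multi(groups: dict) -> tuple[TestResult, pd.DataFrame | None]:
    """One-way ANOVA over named groups; Tukey HSD pairwise when significant."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} needs at least 3 values")
        if v.std(ddof=1) == 0:
            raise ValueError(f"group {k!r} has zero variance")
    f, p = stats.f_oneway(*arrays.values())
    result = TestResult(test="one-way ANOVA", statistic=float(f),
                        p_value=float(p), groups=tuple(arrays))
    if p >= ALPHA:
        return result, None
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    table = pd.DataFrame(tukey.summary().data[1:],
                         columns=tukey.summary().data[0])
    return result, table


def correlate(values, covariate,
              labels: tuple[str, str] = ("deviation", "covariate")) -> TestResult:
    """Pearson correlation of the mean deviation against a covariate."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with at least 3 values")
    if y.std() == 0:
        raise ValueError("zero-variance covariate")
    r, p = stats.pearsonr(x, y)
    return TestResult(test="pearson r", statistic=float(r),
                      p_value=float(p), groups=labels, effect=float(r))


def threshold_sensitivity(chamber_tables: list[VerificationRecord],
                          thresholds,
                          tol: ToleranceConfig = ToleranceConfig()) -> pd.DataFrame:
    """Re-run activation + classification at several gradient thresholds.

    ``chamber_tables`` keep the per-chamber planned/measured doses and
    gradients of each field, so the whole activation decision can be
    replayed.  Returns pass rate and mean active-chamber count per threshold;
    n_active is checked to be non-increasing as the threshold tightens.
    """
    rows = []
    for frac in thresholds:
        t = ToleranceConfig(mean_tol=tol.mean_tol, min_tol=tol.min_tol,
                            max_tol=tol.max_tol,
                            gradient_threshold_fraction=frac,
                            gradient_scalar=tol.gradient_scalar)
        n_active, passed, evaluable = [], 0, 0
        for rec in chamber_tables:
            select_active_chambers(rec, t)
            try:
                summary = compute_deviation_summary(rec)
            except NoEvaluableChambersError:
                n_active.append(0)
                continue
            evaluable += 1
            n_active.append(summary.n_active)
            if classify(summary, t).passed:
                passed += 1
        rows.append({
            "threshold_fraction": frac,
            "pass_rate_pct": 100.0 * passed / max(evaluable, 1),
            "n_evaluable": evaluable,
            "mean_n_active": float(np.mean(n_active)),
            "n_active": tuple(n_active),
        })
    out = pd.DataFrame(rows).sort_values("threshold_fraction",
                                         ascending=False).reset_index(drop=True)
    # tightening the threshold can only deactivate more chambers
    for i in range(1, len(out)):
        prev, cur = out.loc[i - 1, "n_active"], out.loc[i, "n_active"]
        if any(c > p for p, c in zip(prev, cur)):
            raise AssertionError("n_active increased under a stricter "
                                 "gradient threshold")
    return out


@dataclass(frozen=True)
class PerStepTimes:
    """Fixed per-step QA workflow times, minutes."""

    tps_preparation_min: float = 15.0     # per verification
    analysis_min: float = 10.0            # per verification
    wp_setup_min: float = 30.0            # per irradiation session
    preirradiation_min: float = 5.0       # per irradiation session


def time_accounting(beam_seconds, per_step: PerStepTimes = PerStepTimes(),
                    n_verifications: int | None = None,
                    n_sessions: int | None = None) -> dict:
    """Total PSQA time: measured beam time plus fixed workflow overheads.

    overhead = verifications * (preparation + analysis)
             + sessions * (setup + pre-irradiation);
    grand total = beam time + overhead.  Returns hours.
    """
    beam = np.asarray(beam_seconds, dtype=float)
    n_ver = len(beam) if n_verifications is None else n_verifications
    n_ses = n_ver if n_sessions is None else n_sessions
    beam_h = float(beam.sum()) / 3600.0
    overhead_min = n_ver * (per_step.tps_preparation_min + per_step.analysis_min) \
        + n_ses * (per_step.wp_setup_min + per_step.preirradiation_min)
    overhead_h = overhead_min / 60.0
    return {
        "beam_time_h": beam_h,
        "overhead_h": overhead_h,
        "total_h": beam_h + overhead_h,
        "n_verifications": n_ver,
        "n_sessions": n_ses,
    }


def deviation_in_mgy(deviation_pct: float, fraction_dose_gy: float) -> float:
    """Absolute dose difference (mGy) of a percentage deviation of a fraction
    dose — e.g. 0.3% of 2 Gy = 6 mGy."""
    return deviation_pct / 100.0 * fraction_dose_gy * 1000.0


def rounded_pass_rate(passed: int, total: int) -> int:
    """Pass rate in percent, rounded to the integer as printed in reports."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * passed / total))
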