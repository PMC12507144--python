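"""The longitudinal cohort statistical battery and table-style reports.

Continuous baseline/follow-up comparisons use the classical Student
paired t-test; group comparisons the pooled-variance independent-samples
t-test (both with 95% CIs).  Nominal group differences use Fisher's
exact test; baseline/follow-up changes in abnormality incidence use
McNemar's exact (binomial) test, reported "NA" when there are no
discordant pairs.  Inter-observer agreement is ICC(2,1): two-way random
effects, single measurement, absolute agreement, with the F-based CI.
No multiple-testing correction is applied anywhere.

Conventions that matter for reproducing printed tables:
* percentages round half away from zero to integers ("12 (46%)");
* p-values print to 3 decimals, "<0.001" below that;
* the two-sided Fisher p sums hypergeometric probabilities no larger
  than the observed table's;
* a paired test on zero-variance differences is reported undefined
  rather than given a conventional p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "ICCResult",
    "map_bp",
    "paired_t",
    "unpaired_t",
    "fisher_exact",
    "mcnemar_exact",
    "pearson_r",
    "icc_absolute_agreement",
    "fmt_count_pct",
    "fmt_mean_sd",
    "fmt_p",
    "build_reports",
]


@dataclass
class TestResult:
    """Point estimate with 95% CI and p-value; ``defined`` is False when
    the statistic does not exist (e.g. zero-variance differences)."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    df: float
    defined: bool = True


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int


def map_bp(sbp: float, dbp: float) -> float:
    """Mean arterial pressure (2 * diastolic + systolic) / 3, mmHg."""
    if not (sbp > dbp > 0):
        raise ValueError(f"need systolic > diastolic > 0, got {sbp}/{dbp}")
    return (2.0 * dbp + sbp) / 3.0


def paired_t(before: np.ndarray, after: np.ndarray) -> TestResult:
    """Paired Student t on the within-subject changes (after - before)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    n = len(before)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    diff = after - before
    mean = float(diff.mean())
    if np.std(diff, ddof=1) == 0:
        return TestResult(mean, np.nan, np.nan, np.nan, n - 1, defined=False)
    res = stats.ttest_rel(after, before)
    ci = res.confidence_interval(0.95)
    return TestResult(mean, float(ci.low), float(ci.high), float(res.pvalue), n - 1)


def unpaired_t(x_a: np.ndarray, x_b: np.ndarray) -> TestResult:
    """Pooled-variance Student t; estimate is mean(b) - mean(a).

    Welch's variant is deliberately not the default (classical Student's
    test is the reference); use scipy directly if unequal variances are
    a concern.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if len(x_a) < 2 or len(x_b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if np.std(x_a, ddof=1) == 0 and np.std(x_b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x_b, x_a, equal_var=True)
    ci = res.confidence_interval(0.95)
    return TestResult(
        float(x_b.mean() - x_a.mean()), float(ci.low), float(ci.high),
        float(res.pvalue), len(x_a) + len(x_b) - 2,
    )


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Uses the standard "sum of tables no more probable than the observed"
    rule (checked in tests against full hypergeometric enumeration).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: an all-zero margin")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def mcnemar_exact(b_discordant: int, c_discordant: int) -> float | None:
    """Exact McNemar p on the discordant pairs; None ("NA") when there are none.

    Two-sided exact binomial: ``p = min(1, 2 * P(X <= min(b, c)))`` with
    ``X ~ Binomial(b + c, 1/2)``.
    """
    b, c = int(b_discordant), int(c_discordant)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return None
    k = min(b, c)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-based p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc_absolute_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n_subjects, k_raters), complete.  The CI follows the
    F-based (Satterthwaite) construction for the absolute-agreement
    coefficient.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be (n_subjects, >=2 raters)")
    n, k = r.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.isfinite(r).all():
        raise ValueError("ratings must be complete (no missing values)")
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("zero between-subject variance; ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((r - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (two-way random, absolute agreement, single measurement)
    a = k * icc / (n * (1.0 - icc))
    b_ = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b_ * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return ICCResult(float(icc), float(lower), float(upper), n, k)


# ---------------------------------------------------------------------------
# report formatting


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fmt_count_pct(count: int, total: int) -> str:
    """'12 (46%)' -- percentage rounded half away from zero to an integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{count} ({_round_half_away(100.0 * count / total)}%)"


def fmt_mean_sd(values: np.ndarray, decimals: int = 2) -> str:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return "NA"
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    return f"{values.mean():.{decimals}f} ± {sd:.{decimals}f}"


def fmt_p(p: float | None) -> str:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def _fmt_ci(res: TestResult, decimals: int = 2) -> str:
    if not res.defined:
        return "NA"
    return (
        f"{res.estimate:.{decimals}f} "
        f"[{res.ci_low:.{decimals}f}, {res.ci_high:.{decimals}f}]"
    )


# ---------------------------------------------------------------------------
# cohort table -> report CSVs

REQUIRED_COLUMNS = ("subject", "session", "group", "sbp", "dbp", "hr")
SESSIONS = ("baseline", "follow_up")


def _metric_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith(("vel_", "wss_"))]
    if "pwv" in table.columns:
        cols.append("pwv")
    return cols


def _flag_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("flag_")]


def _paired_frames(g: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    v1 = g[g.session == "baseline"].set_index("subject")
    v2 = g[g.session == "follow_up"].set_index("subject")
    common = v1.index.intersection(v2.index)
    return v1.loc[common], v2.loc[common]


def build_reports(table: pd.DataFrame, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Write table1.csv .. table4.csv style reports from a cohort table.

    The cohort table has one row per subject and session with columns
    ``subject, session (baseline/follow_up), group, sbp, dbp, hr``,
    hemodynamic metrics (``vel_*``, ``wss_*``, ``pwv``), boolean
    abnormality flags (``flag_*``) and optionally ``female``.

    * table1 -- per-group clinical characteristics at baseline
      (mean +/- SD; counts with Fisher p for ``female``);
    * table2 -- between-group (unpaired) comparisons per metric and
      session, difference with 95% CI and p;
    * table3 -- within-group baseline/follow-up (paired) comparisons per
      metric, change with 95% CI and p;
    * table4 -- abnormality incidence n (%) per session with the exact
      McNemar p ("NA" without discordant pairs).
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort table is missing required column '{col}'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = sorted(table["group"].unique())
    metrics = _metric_columns(table)
    flags = _flag_columns(table)
    base = table[table.session == "baseline"]

    # -- table 1: demographics / clinical characteristics ------------------
    rows = []
    counts = {g: len(base[base.group == g]) for g in groups}
    rows.append({"characteristic": "n", **{g: str(counts[g]) for g in groups}, "p": ""})
    clinical = [("Systolic BP (mmHg)", "sbp"), ("Diastolic BP (mmHg)", "dbp"),
                ("Heart rate (bpm)", "hr")]
    for label, col in clinical:
        row = {"characteristic": label}
        for g in groups:
            row[g] = fmt_mean_sd(base[base.group == g][col].to_numpy(), 1)
        if len(groups) == 2:
            row["p"] = fmt_p(unpaired_t(
                base[base.group == groups[0]][col].to_numpy(),
                base[base.group == groups[1]][col].to_numpy()).p)
        rows.append(row)
    row = {"characteristic": "MAP (mmHg)"}
    for g in groups:
        gb = base[base.group == g]
        maps = np.array([map_bp(s, d) for s, d in zip(gb.sbp, gb.dbp)])
        row[g] = fmt_mean_sd(maps, 1)
    rows.append(row)
    if "female" in table.columns and len(groups) == 2:
        k = [int(base[base.group == g]["female"].sum()) for g in groups]
        n = [counts[g] for g in groups]
        p = fisher_exact(k[0], n[0] - k[0], k[1], n[1] - k[1])
        rows.append({
            "characteristic": "Sex (female)",
            **{g: fmt_count_pct(k[i], n[i]) for i, g in enumerate(groups)},
            "p": fmt_p(p),
        })
    table1 = pd.DataFrame(rows).fillna("")

    # -- table 2: between-group differences per session --------------------
    rows = []
    for session in SESSIONS:
        sess = table[table.session == session]
        for metric in metrics:
            if len(groups) != 2:
                break
            x_a = sess[sess.group == groups[0]][metric].dropna().to_numpy()
            x_b = sess[sess.group == groups[1]][metric].dropna().to_numpy()
            if len(x_a) < 2 or len(x_b) < 2:
                continue
            res = unpaired_t(x_a, x_b)
            rows.append({
                "session": session, "metric": metric,
                groups[0]: fmt_mean_sd(x_a), groups[1]: fmt_mean_sd(x_b),
                "difference_ci": _fmt_ci(res), "p": fmt_p(res.p),
            })
    table2 = pd.DataFrame(rows)

    # -- table 3: paired baseline vs follow-up per group --------------------
    rows = []
    for g in groups:
        v1, v2 = _paired_frames(table[table.group == g])
        for metric in metrics:
            pair = pd.concat([v1[metric], v2[metric]], axis=1).dropna()
            if len(pair) < 2:
                continue
            res = paired_t(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            rows.append({
                "group": g, "metric": metric,
                "baseline": fmt_mean_sd(pair.iloc[:, 0].to_numpy()),
                "follow_up": fmt_mean_sd(pair.iloc[:, 1].to_numpy()),
                "change_ci": _fmt_ci(res),
                "p": fmt_p(res.p) if res.defined else "NA",
            })
    table3 = pd.DataFrame(rows)

    # -- table 4: abnormality incidence with exact McNemar ------------------
    rows = []
    for g in groups:
        v1, v2 = _paired_frames(table[table.group == g])
        for flag in flags:
            f1 = v1[flag].astype(bool)
            f2 = v2[flag].astype(bool)
            b = int((f1 & ~f2).sum())
            c = int((~f1 & f2).sum())
            rows.append({
                "group": g, "metric": flag.removeprefix("flag_"),
                "V1": fmt_count_pct(int(f1.sum()), len(f1)),
                "V2": fmt_count_pct(int(f2.sum()), len(f2)),
                "p": fmt_p(mcnemar_exact(b, c)),
            })
    table4 = pd.DataFrame(rows)

    out = {"table1": table1, "table2": table2, "table3": table3, "table4": table4}
    for name, df in out.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    return out
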