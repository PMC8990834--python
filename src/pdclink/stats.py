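"""Cohort comparison statistics for PDC analyses.

Covers the comparison layer of a single/multiple pharmacy-use adherence
study: per-group summaries (mean, SD, median, IQR), paired and unpaired
t-tests with 95% confidence intervals, Wilcoxon companions, absolute
standardized effect sizes for baseline characteristics, and the binary
(PDC >= 80%) sensitivity analysis.

No multiple-testing correction is applied (reports carry a note); the
unpaired default is the Welch unequal-variance t-test with a pooled-variance
Student option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

NO_CORRECTION_NOTE = (
    "p-values are unadjusted for multiple comparisons"
)

PAIRED = "paired"
UNPAIRED = "unpaired"


@dataclass(frozen=True)
class GroupSummary:
    """Sample summary of a collection of PDC values (percent)."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    degenerate: bool = False  # n == 1: SD reported as 0 by convention

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError("quartiles out of order")


def summarize_pdc(values: Iterable[float]) -> GroupSummary:
    """Mean/SD (sample, ddof=1) and median/IQR with linear-interpolation
    quartiles."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValidationError("summarize_pdc requires at least one value")
    degenerate = x.size == 1
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=0.0 if degenerate else float(x.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """A two-sample comparison: mean difference (percent points), 95% CI,
    parametric and rank-based p-values.

    ``estimate`` is mean(a) - mean(b) for the argument order given.
    ``degenerate`` flags zero-variance inputs where the t reference
    distribution collapses.
    """

    estimate: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value_t: float
    p_value_wrs: float
    test_kind: str
    n_a: int
    n_b: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("CI must bracket the estimate")


def compare_sources_paired(
    a: Sequence[float],
    b: Sequence[float],
    wrs: str = "signed_rank",
) -> ComparisonResult:
    """Paired comparison of two per-patient-aligned PDC vectors.

    The parametric test is the paired t-test on within-patient differences
    a - b, with a 95% t-interval on the mean difference. The rank companion
    is the Wilcoxon signed-rank test on the differences by default
    (``wrs="signed_rank"``); ``wrs="rank_sum"`` instead applies a rank-sum
    test of the differences against zero shift, for compatibility with
    reports that pair a "WRS test" with paired data.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired comparison requires equal-length vectors")
    if x.size < 2:
        raise ValidationError("paired comparison requires n >= 2")
    if wrs not in ("signed_rank", "rank_sum"):
        raise ValidationError(f"unknown wrs mode {wrs!r}")
    d = x - y
    n = d.size
    est = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all differences identical: t reference collapses
        p_t = 1.0 if est == 0.0 else 0.0
        return ComparisonResult(
            estimate=est,
            ci_low=est,
            ci_high=est,
            t_statistic=0.0 if est == 0.0 else math.inf * math.copysign(1, est),
            p_value_t=p_t,
            p_value_wrs=p_t,
            test_kind=PAIRED,
            n_a=n,
            n_b=n,
            degenerate=True,
        )
    se = sd / math.sqrt(n)
    t_stat = est / se
    p_t = float(2 * sps.t.sf(abs(t_stat), df=n - 1))
    t_crit = float(sps.t.ppf(0.975, df=n - 1))
    ci = (est - t_crit * se, est + t_crit * se)
    nz = d[d != 0]
    if wrs == "signed_rank":
        if nz.size == 0:
            p_wrs = 1.0
        else:
            p_wrs = float(sps.wilcoxon(nz).pvalue)
    else:
        p_wrs = float(sps.mannwhitneyu(d, np.zeros_like(d)).pvalue)
    return ComparisonResult(
        estimate=est,
        ci_low=ci[0],
        ci_high=ci[1],
        t_statistic=float(t_stat),
        p_value_t=p_t,
        p_value_wrs=p_wrs,
        test_kind=PAIRED,
        n_a=n,
        n_b=n,
    )


def compare_groups_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
) -> ComparisonResult:
    """Unpaired comparison of two independent groups.

    Welch's unequal-variance t-test by default (``equal_var=True`` for the
    pooled-variance Student variant), with a 95% CI on the difference of
    means and a Wilcoxon rank-sum (Mann-Whitney) companion p-value.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("unpaired comparison requires n >= 2 per group")
    est = float(x.mean() - y.mean())
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    if vx == 0.0 and vy == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        return ComparisonResult(
            estimate=est,
            ci_low=est,
            ci_high=est,
            t_statistic=0.0 if est == 0.0 else math.inf * math.copysign(1, est),
            p_value_t=p,
            p_value_wrs=p,
            test_kind=UNPAIRED,
            n_a=nx,
            n_b=ny,
            degenerate=True,
        )
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se = math.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t_stat = est / se
    p_t = float(2 * sps.t.sf(abs(t_stat), df=df))
    t_crit = float(sps.t.ppf(0.975, df=df))
    p_wrs = float(sps.mannwhitneyu(x, y).pvalue)
    return ComparisonResult(
        estimate=est,
        ci_low=est - t_crit * se,
        ci_high=est + t_crit * se,
        t_statistic=float(t_stat),
        p_value_t=p_t,
        p_value_wrs=p_wrs,
        test_kind=UNPAIRED,
        n_a=nx,
        n_b=ny,
    )


def standardized_effect_size(
    group_a: Sequence,
    group_b: Sequence,
    kind: str = "auto",
) -> float:
    """Absolute standardized effect size between two groups of one
    characteristic.

    * continuous: |mean_a - mean_b| / sqrt((s_a^2 + s_b^2)/2)
    * binary (two observed levels): standardized difference of proportions,
      |p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b))/2)
    * k-level categorical: Mahalanobis-type multivariate standardized
      difference over the k-1 indicator proportions.

    Scale-free, label-swap symmetric, and invariant to affine rescaling of
    continuous characteristics. Values can exceed 1 for extreme separations
    and are reported as computed. Zero pooled variance yields NaN with a
    warning (undefined effect size).
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if kind == "auto":
        numeric = all(isinstance(v, (int, float, np.integer, np.floating))
                      and not isinstance(v, bool) for v in a + b)
        if numeric:
            kind = "continuous"
        else:
            kind = "categorical"
    if kind == "continuous":
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        pooled = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
        if pooled == 0.0:
            if x.mean() == y.mean():
                return 0.0
            warnings.warn("zero pooled variance: effect size undefined")
            return math.nan
        return abs(float(x.mean() - y.mean())) / pooled
    if kind not in ("binary", "categorical"):
        raise ValidationError(f"unknown kind {kind!r}")
    levels = sorted({str(v) for v in a} | {str(v) for v in b})
    if len(levels) < 2:
        return 0.0
    if len(levels) == 2 or kind == "binary":
        lvl = levels[-1]
        pa = np.mean([str(v) == lvl for v in a])
        pb = np.mean([str(v) == lvl for v in b])
        denom = math.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        if denom == 0.0:
            if pa == pb:
                return 0.0
            warnings.warn("zero pooled variance: effect size undefined")
            return math.nan
        return abs(float(pa - pb)) / denom
    # k-level: Mahalanobis distance over the first k-1 level proportions
    ref = levels[:-1]
    pa = np.array([np.mean([str(v) == l for v in a]) for l in ref])
    pb = np.array([np.mean([str(v) == l for v in b]) for l in ref])
    diff = pa - pb

    # S_kl = -(p_k p_l), S_kk = p_k(1-p_k); averaged over groups
    def cov_multinomial(p):
        s = -np.outer(p, p)
        np.fill_diagonal(s, p * (1 - p))
        return s

    s = (cov_multinomial(pa) + cov_multinomial(pb)) / 2.0
    try:
        sol = np.linalg.pinv(s) @ diff
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance: effect size undefined")
        return math.nan
    val = float(diff @ sol)
    return math.sqrt(max(val, 0.0))


def binary_adherence_analysis(
    adherence: pd.DataFrame,
    threshold: float = 80.0,
) -> pd.DataFrame:
    """Proportion of adherent patients (PDC >= threshold, inclusive) per
    regime per subgroup.

    Expects columns pdc_pharmacy / pdc_claims / pdc_combined and
    pharmacy_use_class. Returns a tidy frame with one row per
    (regime, subgroup) and a ``direction_consistent`` flag marking whether
    the adherent-proportion ordering across regimes matches the ordering of
    the continuous means within that subgroup (ties tolerated).
    """
    regimes = {
        "pharmacy": "pdc_pharmacy",
        "claims": "pdc_claims",
        "combined": "pdc_combined",
    }
    groups = {"total": adherence}
    for cls, sub in adherence.groupby("pharmacy_use_class"):
        groups[str(cls)] = sub
    rows = []
    for gname, sub in groups.items():
        means = {r: sub[col].mean() for r, col in regimes.items()}
        props = {r: (sub[col] >= threshold).mean() for r, col in regimes.items()}
        order_means = sorted(means, key=means.get)
        consistent = all(
            props[order_means[i]] <= props[order_means[i + 1]] + 1e-12
            for i in range(len(order_means) - 1)
        )
        for r in regimes:
            rows.append(
                {
                    "subgroup": gname,
                    "regime": r,
                    "n": len(sub),
                    "proportion_adherent": float(props[r]),
                    "mean_pdc": float(means[r]),
                    "direction_consistent": bool(consistent),
                }
            )
    return pd.DataFrame(rows)


def _fmt_comparison(c: ComparisonResult) -> str:
    return (
        f"{c.estimate:.1f} ({c.ci_low:.1f} to {c.ci_high:.1f}) "
        f"p={c.p_value_t:.3g}"
    )


def adherence_table(
    adherence: pd.DataFrame,
    wrs: str = "signed_rank",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Regimes x subgroups adherence comparison table.

    One row per regime with mean (SD) PDC for single users, multiple users
    and the total cohort, plus the single-vs-multiple unpaired comparison;
    a final block reports the paired within-patient comparisons
    claims - pharmacy and claims - combined per subgroup.
    """
    regimes = {
        "pharmacy_dispensing": "pdc_pharmacy",
        "claims_records": "pdc_claims",
        "combined": "pdc_combined",
    }
    single = adherence[adherence.pharmacy_use_class == "single"]
    multiple = adherence[adherence.pharmacy_use_class == "multiple"]
    rows = []
    for label, col in regimes.items():
        row = {"row": label, "note": NO_CORRECTION_NOTE}
        for gname, sub in (("single", single), ("multiple", multiple),
                           ("total", adherence)):
            if len(sub):
                s = summarize_pdc(sub[col])
                row[f"{gname}_mean_sd"] = f"{s.mean:.1f} ({s.sd:.1f})"
                row[f"{gname}_n"] = s.n
            else:
                row[f"{gname}_mean_sd"] = ""
                row[f"{gname}_n"] = 0
        if len(single) >= 2 and len(multiple) >= 2:
            comp = compare_groups_unpaired(multiple[col], single[col],
                                           equal_var=equal_var)
            row["multiple_minus_single"] = _fmt_comparison(comp)
        else:
            row["multiple_minus_single"] = ""
        rows.append(row)
    for pair_label, col_a, col_b in (
        ("claims_minus_pharmacy", "pdc_claims", "pdc_pharmacy"),
        ("claims_minus_combined", "pdc_claims", "pdc_combined"),
    ):
        row = {"row": pair_label, "note": NO_CORRECTION_NOTE,
               "multiple_minus_single": ""}
        for gname, sub in (("single", single), ("multiple", multiple),
                           ("total", adherence)):
            if len(sub) >= 2:
                comp = compare_sources_paired(sub[col_a], sub[col_b], wrs=wrs)
                row[f"{gname}_mean_sd"] = _fmt_comparison(comp)
                row[f"{gname}_n"] = len(sub)
            else:
                row[f"{gname}_mean_sd"] = ""
                row[f"{gname}_n"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def characteristics_table(
    demographics: pd.DataFrame,
    class_by_patient: pd.Series,
) -> pd.DataFrame:
    """Baseline-characteristics comparison with an absolute standardized
    effect size per characteristic.

    ``demographics`` is indexed by patient_id; ``class_by_patient`` maps
    patient_id to single/multiple. Numeric columns are treated as
    continuous, everything else as categorical.
    """
    cls = class_by_patient.reindex(demographics.index)
    single = demographics[cls == "single"]
    multiple = demographics[cls == "multiple"]
    rows = []
    for col in demographics.columns:
        a = multiple[col].dropna()
        b = single[col].dropna()
        if a.empty or b.empty:
            continue
        numeric = pd.api.types.is_numeric_dtype(demographics[col])
        ses = standardized_effect_size(
            a.tolist(), b.tolist(), kind="continuous" if numeric else "categorical"
        )
        rows.append(
            {
                "characteristic": col,
                "kind": "continuous" if numeric else "categorical",
                "n_single": int(b.size),
                "n_multiple": int(a.size),
                "ses": ses,
                "ses_flag": "exceeds_1" if (not math.isnan(ses) and ses > 1)
                else ("undefined" if math.isnan(ses) else ""),
            }
        )
    return pd.DataFrame(rows)
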