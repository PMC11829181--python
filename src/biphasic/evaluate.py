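"""Scoring and statistical comparison of ovulation-detection methods.

Per-cycle errors are ``estimated - reference`` in days (positive = late
estimate); accuracy is summarised as the mean absolute error (MAE) with
its SEM, detection rate with a z-based 95% CI, and within-k-day
proportions whose denominator is *all* evaluable cycles, so undetected
cycles count as misses.  Detection rates are compared between subgroups
with the Fisher exact test (conditional-MLE odds ratio with exact CI);
error distributions with the Mann-Whitney U test plus Cliff's delta as
the effect size; families of subgroup comparisons are Bonferroni
corrected.

Subgroup stratifications follow the clinical bins: cycle length
(abnormally short <=21 / short 22-26 / medium 27-31 / long 32-35 /
abnormally long >=36 days, reference medium), cycle variability (typical
0-3 / moderately irregular 4-7 / abnormally irregular >7 days, reference
typical) and age (18-26 / 27-34 / 35-43 / >=44 years, reference 27-34).
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AgeClass,
    CycleRecord,
    LengthClass,
    Method,
    OvulationEstimate,
    ReferenceOvulation,
    SubgroupLabel,
    VariabilityClass,
    classify_age,
    classify_cycle_length,
    classify_variability,
)

__all__ = [
    "detection_rate_ci",
    "mae_sem",
    "within_k",
    "cliff_delta",
    "bonferroni",
    "fisher_detection_test",
    "mann_whitney_test",
    "fold_change",
    "ComparisonResult",
    "EvaluationReport",
    "MethodEvaluation",
    "subgroup_labels",
    "build_results_frame",
]

Z95 = 1.96  # z-score for the 95% confidence level


# ---------------------------------------------------------------------------
# elementary statistics


def detection_rate_ci(n_detected: int, n_total: int) -> tuple[float, float, float]:
    """Detection rate with z-based 95% CI, all in percent.

    CI = p +/- 1.96 * sqrt(p (1-p) / n), clipped to [0, 100].
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_detected <= n_total):
        raise ValueError("need 0 <= n_detected <= n_total")
    p = n_detected / n_total
    half = Z95 * math.sqrt(p * (1.0 - p) / n_total)
    return (100.0 * p, 100.0 * max(0.0, p - half), 100.0 * min(1.0, p + half))


def mae_sem(errors: Sequence[float]) -> tuple[float, float]:
    """Mean absolute error and its SEM (sample SD of |errors| / sqrt(n))."""
    a = np.abs(np.asarray(errors, dtype=float))
    if a.size == 0:
        raise ValueError("mae_sem requires at least one error")
    if a.size == 1:
        return float(a[0]), 0.0
    return float(a.mean()), float(a.std(ddof=1) / math.sqrt(a.size))


def within_k(errors: Sequence[float], k: float, n_total: Optional[int] = None) -> float:
    """Percent of cycles with |error| <= k days, over all evaluable cycles.

    ``errors`` holds the errors of *detected* cycles; ``n_total`` is the
    number of evaluable cycles (detected + undetected) and defaults to
    ``len(errors)``.  NaN entries (undetected placeholders) never count
    as within k.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    a = np.asarray(errors, dtype=float)
    n_total = len(a) if n_total is None else n_total
    if n_total == 0:
        return 0.0
    hits = int(np.sum(np.abs(a[~np.isnan(a)]) <= k))
    return 100.0 * hits / n_total


def cliff_delta(a: Sequence[float], b: Sequence[float]) -> float:
    """Cliff's delta between two samples.

    delta = (#{a < b} - #{a > b}) / (n_a * n_b) over all cross pairs;
    on absolute errors, positive delta means group ``a`` has the smaller
    errors.
    """
    av = np.asarray(a, dtype=float)[:, None]
    bv = np.asarray(b, dtype=float)[None, :]
    if av.size == 0 or bv.size == 0:
        raise ValueError("cliff_delta requires non-empty groups")
    less = np.sum(av < bv)
    greater = np.sum(av > bv)
    return float((less - greater) / (av.size * bv.size))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def fold_change(mae_a: float, mae_b: float) -> float:
    """Ratio of two MAEs, rounded to one decimal."""
    if mae_b <= 0:
        raise ValueError("denominator MAE must be positive")
    return round(mae_a / mae_b, 1)


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison.

    ``statistic`` is the conditional-MLE odds ratio for Fisher tests and
    the U statistic (oriented to group ``a``) for Mann-Whitney tests;
    ``ci_95`` is the exact OR confidence interval (Fisher only).
    """

    test: str                       # "fisher" | "mann_whitney"
    groups: tuple[str, str]
    statistic: float
    p_raw: float
    p_bonferroni: float
    m_comparisons: int
    ci_95: Optional[tuple[float, float]] = None
    cliff_delta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_bonferroni + 1e-12 < self.p_raw:
            raise ValueError("Bonferroni adjustment cannot lower a p-value")


def fisher_detection_test(
    detected_a: int,
    failed_a: int,
    detected_b: int,
    failed_b: int,
    m_comparisons: int = 1,
    groups: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Fisher exact test on a 2x2 detected/failed table.

    The odds ratio is the conditional maximum-likelihood estimate (the
    estimator tied to the exact test) with its exact 95% CI.  Degenerate
    tables with an all-zero column report OR 1 with p = 1.
    """
    table = np.array([[detected_a, failed_a], [detected_b, failed_b]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == table.sum(axis=0).max() == 0 or 0 in table.sum(axis=1):
        raise ValueError("empty group")
    if (table.sum(axis=0) == 0).any():
        # a zero column margin: only one outcome observed, no association
        return ComparisonResult(
            "fisher", groups, 1.0, 1.0, 1.0, m_comparisons, (0.0, math.inf)
        )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = stats.contingency.odds_ratio(table, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return ComparisonResult(
        "fisher", groups, float(orr.statistic), float(p),
        bonferroni(float(p), m_comparisons), m_comparisons,
        (float(ci.low), float(ci.high)),
    )


def mann_whitney_test(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    m_comparisons: int = 1,
    groups: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Mann-Whitney U test plus Cliff's delta on absolute errors.

    Uses exact p-value enumeration when ``n_a * n_b <= 10_000`` and no
    cross-group ties exist, otherwise the tie-corrected normal
    approximation.  The reported U is scipy's statistic for group ``a``
    (# pairs a > b plus half-ties); delta is signed so positive means
    group ``a`` has smaller absolute errors.
    """
    a = np.abs(np.asarray(errors_a, dtype=float))
    b = np.abs(np.asarray(errors_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    delta = cliff_delta(a, b)
    return ComparisonResult(
        "mann_whitney", groups, float(res.statistic), float(res.pvalue),
        bonferroni(float(res.pvalue), m_comparisons), m_comparisons,
        None, delta,
    )


# ---------------------------------------------------------------------------
# subgroup labelling and the evaluation harness


def subgroup_labels(
    cycles: Sequence[CycleRecord], history_days: int = 183
) -> dict[tuple, SubgroupLabel]:
    """Classify every complete cycle by length, variability and age.

    Variability uses the lengths of the user's earlier complete cycles
    starting within ``history_days`` before the index cycle's start;
    with fewer than two such lengths the class is unknown.
    """
    by_user: dict[str, list[CycleRecord]] = {}
    for c in cycles:
        if c.complete:
            by_user.setdefault(c.user_id, []).append(c)
    labels: dict[tuple, SubgroupLabel] = {}
    for user, ucycles in by_user.items():
        ucycles.sort(key=lambda c: c.period_start)
        for c in ucycles:
            lo = c.period_start - dt.timedelta(days=history_days)
            prior = [
                p.cycle_length for p in ucycles
                if lo <= p.period_start < c.period_start
            ]
            labels[c.cycle_id] = SubgroupLabel(
                length_class=classify_cycle_length(c.cycle_length),
                variability_class=classify_variability(prior),
                age_class=classify_age(c.age_years) if c.age_years is not None else None,
            )
    return labels


def build_results_frame(
    estimates: Sequence[OvulationEstimate],
    references: Mapping[tuple, ReferenceOvulation],
    labels: Optional[Mapping[tuple, SubgroupLabel]] = None,
) -> pd.DataFrame:
    """One row per (cycle, method) with error and subgroup columns.

    ``references`` and ``labels`` are keyed by ``CycleRecord.cycle_id``;
    estimates without a matching reference raise.
    """
    rows = []
    for est in estimates:
        cid = est.cycle.cycle_id
        if cid not in references:
            raise KeyError(f"no reference ovulation for cycle {cid}")
        ref = references[cid]
        err = (
            (est.estimated_date - ref.reference_date).days if est.detected else np.nan
        )
        lab = labels.get(cid) if labels else None
        rows.append(
            {
                "user_id": est.cycle.user_id,
                "period_start": est.cycle.period_start,
                "method": est.method.value,
                "detected": est.detected,
                "failure_reason": est.failure_reason.value,
                "error_days": err,
                "cycle_length": est.cycle.cycle_length,
                "length_class": (lab.length_class.value if lab else None),
                "variability_class": (lab.variability_class.value if lab else None),
                "age_class": (lab.age_class.value if lab and lab.age_class else None),
            }
        )
    return pd.DataFrame(rows)


_STRATA = {
    "length_class": ([c.value for c in LengthClass], LengthClass.MEDIUM.value),
    "variability_class": (
        [c.value for c in VariabilityClass if c is not VariabilityClass.UNKNOWN],
        VariabilityClass.TYPICAL.value,
    ),
    "age_class": ([c.value for c in AgeClass], AgeClass.A27_34.value),
}


def _method_stats(sub: pd.DataFrame) -> dict:
    n = len(sub)
    det = sub["detected"].sum()
    out: dict = {"n": n, "n_detected": int(det)}
    if n == 0:
        return out
    rate, lo, hi = detection_rate_ci(int(det), n)
    out.update(
        detection_rate_pct=rate, rate_ci_low=lo, rate_ci_high=hi,
        rate_sem_pct=100.0 * math.sqrt((det / n) * (1 - det / n) / n),
    )
    errs = sub.loc[sub["detected"], "error_days"].to_numpy(dtype=float)
    if errs.size:
        mae, sem = mae_sem(errs)
        out.update(mae=mae, mae_sem=sem)
    for k in (1, 2, 3):
        out[f"within_{k}_pct"] = within_k(errs, k, n_total=n)
    return out


@dataclass
class EvaluationReport:
    """Detection, accuracy and subgroup comparisons for 1+ methods.

    Attributes
    ----------
    overall : DataFrame indexed by method with n, detection rate (95% CI),
        MAE (SEM) and within-1/2/3-day percentages.
    by_length, by_variability, by_age : DataFrame
        Per-subgroup stats, one row per (class, method).
    comparisons : dict
        Named :class:`ComparisonResult` entries: reference-vs-group
        Fisher tests on detection (physiology), reference-vs-group
        Mann-Whitney tests per method, and the between-method test.
    """

    overall: pd.DataFrame
    by_length: pd.DataFrame
    by_variability: pd.DataFrame
    by_age: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    n_cycles: int

    def fold_change_between(self, method_a: str = "calendar", method_b: str = "physiology") -> float:
        """MAE ratio between two methods (e.g. calendar / physiology)."""
        return fold_change(
            self.overall.loc[method_a, "mae"], self.overall.loc[method_b, "mae"]
        )

    def summary(self) -> str:
        def fmt(df: pd.DataFrame) -> str:
            show = df.copy()
            for c in show.columns:
                if show[c].dtype.kind == "f":
                    show[c] = show[c].round(2)
            return show.to_string()

        parts = [
            f"Ovulation estimation report — {self.n_cycles} evaluable cycles",
            "=" * 60,
            "Overall:", fmt(self.overall), "",
            "By cycle length:", fmt(self.by_length), "",
            "By cycle variability:", fmt(self.by_variability), "",
            "By age:", fmt(self.by_age), "",
            "Comparisons (Bonferroni within each family):",
        ]
        for name, c in self.comparisons.items():
            extra = f", OR CI ({c.ci_95[0]:.2f}, {c.ci_95[1]:.2f})" if c.ci_95 else ""
            delta = f", delta={c.cliff_delta:+.2f}" if c.cliff_delta is not None else ""
            parts.append(
                f"  {name}: {c.test} stat={c.statistic:.2f}{extra}"
                f" p={c.p_raw:.3g} (adj {c.p_bonferroni:.3g}){delta}"
            )
        return "\n".join(parts)


class MethodEvaluation:
    """Harness comparing ovulation-estimation methods against references.

    Parameters
    ----------
    estimates : sequence of OvulationEstimate
        Output of one or more methods over the same cycles.
    references : mapping cycle_id -> ReferenceOvulation
    labels : mapping cycle_id -> SubgroupLabel, optional
        Defaults to labelling the referenced cycles directly.

    ``fit()`` returns an :class:`EvaluationReport`.
    """

    def __init__(
        self,
        estimates: Sequence[OvulationEstimate],
        references: Mapping[tuple, ReferenceOvulation],
        labels: Optional[Mapping[tuple, SubgroupLabel]] = None,
    ) -> None:
        if labels is None:
            labels = subgroup_labels([r.cycle for r in references.values()])
        self.frame = build_results_frame(estimates, references, labels)

    def fit(self) -> EvaluationReport:
        df = self.frame
        methods = list(dict.fromkeys(df["method"]))
        overall = pd.DataFrame(
            {m: _method_stats(df[df["method"] == m]) for m in methods}
        ).T.rename_axis("method")

        tables = {}
        comparisons: dict[str, ComparisonResult] = {}
        for col, (classes, ref_class) in _STRATA.items():
            rows = {}
            for cls in classes:
                for m in methods:
                    sub = df[(df["method"] == m) & (df[col] == cls)]
                    rows[(cls, m)] = _method_stats(sub)
            tables[col] = pd.DataFrame(rows).T.rename_axis([col, "method"])
            comparisons.update(
                self._stratum_comparisons(df, col, classes, ref_class, methods)
            )

        if len(methods) == 2:
            a, b = methods
            ea = df.loc[(df["method"] == a) & df["detected"], "error_days"]
            eb = df.loc[(df["method"] == b) & df["detected"], "error_days"]
            if len(ea) and len(eb):
                comparisons[f"{a}_vs_{b}"] = mann_whitney_test(
                    ea, eb, 1, groups=(a, b)
                )

        return EvaluationReport(
            overall=overall,
            by_length=tables["length_class"],
            by_variability=tables["variability_class"],
            by_age=tables["age_class"],
            comparisons=comparisons,
            n_cycles=int((df["method"] == methods[0]).sum()),
        )

    @staticmethod
    def _stratum_comparisons(
        df: pd.DataFrame,
        col: str,
        classes: list[str],
        ref_class: str,
        methods: list[str],
    ) -> dict[str, ComparisonResult]:
        out: dict[str, ComparisonResult] = {}
        # usable comparison groups: non-reference classes with >= 1 detected cycle
        usable = [
            c for c in classes
            if c != ref_class and df[(df[col] == c) & df["detected"]].shape[0] > 0
        ]
        m = max(1, len(usable))
        for meth in methods:
            sub = df[df["method"] == meth]
            ref = sub[sub[col] == ref_class]
            if ref.empty or not ref["detected"].any():
                continue
            ref_err = ref.loc[ref["detected"], "error_days"]
            for cls in usable:
                grp = sub[sub[col] == cls]
                if grp.empty:
                    continue
                key = f"{meth}:{col}:{ref_class}_vs_{cls}"
                if meth == "physiology":
                    out[key + ":detection"] = fisher_detection_test(
                        int(ref["detected"].sum()), int((~ref["detected"]).sum()),
                        int(grp["detected"].sum()), int((~grp["detected"]).sum()),
                        m, groups=(ref_class, cls),
                    )
                grp_err = grp.loc[grp["detected"], "error_days"]
                if len(grp_err):
                    out[key + ":accuracy"] = mann_whitney_test(
                        ref_err, grp_err, m, groups=(ref_class, cls)
                    )
        return out
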