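"""Grouped baseline tables ("table one") and two-group comparison tests.

Categorical variables are reported as n (percent of the per-variable
denominator), continuous ones as median (IQR).  Percentages round half-up to
one decimal so that every printed percent is exactly recomputable from its
count and denominator.  Group comparisons pick the conventional test:
chi-square when all expected cells are at least 5, otherwise Fisher's exact
test for 2×2 tables; Mann–Whitney U for continuous variables unless
normality is asserted, in which case Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import PatientRecord, classify_er_status

__all__ = [
    "CohortSummary",
    "round_half_up",
    "percent",
    "compare_groups",
    "summarize_cohort",
    "load_count_fixture",
    "percents_from_counts",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (so 54.15 → 54.2 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denominator: float, decimals: int = 1) -> float:
    """count/denominator as a half-up-rounded percentage; NaN if denom 0."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * count / denominator, decimals)


# ---------------------------------------------------------------------------
# Two-group tests
# ---------------------------------------------------------------------------

def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_groups(
    group_a,
    group_b,
    kind: str = "continuous",
    assume_normal: bool = False,
) -> tuple[str, float, float]:
    """Two-sided comparison of one variable between two groups.

    Continuous input: two 1-d samples; Mann–Whitney U by default, Welch's
    t-test when ``assume_normal``.  Categorical input: two same-length count
    vectors over shared categories; chi-square (no continuity correction)
    when every expected cell is ≥ 5, else Fisher's exact test (2×2 only).
    Returns ``(test_name, statistic, p)``.
    """
    if kind == "continuous":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be nonempty")
        if assume_normal:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            return "t-test", float(stat), float(p)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return "mann-whitney", float(stat), float(p)

    if kind != "categorical":
        raise ValueError("kind must be 'continuous' or 'categorical'")
    table = np.asarray([group_a, group_b], dtype=float)
    if table.ndim != 2 or table.shape[1] < 2 or np.any(table < 0):
        raise ValueError("categorical comparison needs ≥ 2 category counts per group")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table")
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if np.all(expected >= 5):
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return "chi-square", float(stat), float(p)
    if table.shape == (2, 2):
        a, b, c, d = (int(v) for v in table.ravel())
        odds = stats.fisher_exact(table, alternative="two-sided")[0]
        return "fisher-exact", float(odds), fisher_exact_p(a, b, c, d)
    # Small expected cells but not 2×2: chi-square is the only exact-free
    # option implemented; flagged in the test name.
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square-small-cells", float(stat), float(p)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

# (name, kind, accessor).  Binary variables summarize their True share;
# categorical ones list every observed level; continuous report median (IQR).
_SUMMARY_VARIABLES = (
    ("male", "binary", lambda r: None if r.sex is None else r.sex == "male"),
    ("age", "continuous", lambda r: r.age),
    ("bmi", "continuous", lambda r: r.bmi),
    ("asa", "categorical", lambda r: r.asa),
    ("functional", "binary", lambda r: r.functional),
    ("symptomatic", "binary", lambda r: r.symptomatic),
    ("tumor_size", "continuous", lambda r: r.tumor_size),
    ("location", "categorical", lambda r: r.location),
    ("multifocal", "binary", lambda r: r.multifocal),
    ("resection_type", "categorical", lambda r: r.resection_type),
    ("vascular_resection", "binary", lambda r: r.vascular_resection),
    ("severe_complication", "binary", lambda r: r.severe_complication),
    ("grade", "categorical", lambda r: r.grade),
    ("lvi", "binary", lambda r: r.lvi),
    ("pni", "binary", lambda r: r.pni),
    ("margin", "categorical", lambda r: r.margin),
    ("t_stage", "categorical", lambda r: r.t_stage),
    ("nodes_positive", "binary", lambda r: r.nodes_positive),
    ("nodes_examined", "continuous", lambda r: r.nodes_examined),
    ("era", "categorical", lambda r: r.era),
)


@dataclass
class CohortSummary:
    """Long-format baseline table plus per-variable comparison tests."""

    grouping: str
    groups: dict  # group label -> n
    table: pd.DataFrame  # variable, category, group, count, denominator, pct / median, iqr
    tests: pd.DataFrame  # variable, test, statistic, p (empty if < 2 groups)


def _group_records(records, grouping, cutoff_months):
    if grouping == "none":
        return {"all": list(records)}
    if grouping == "recurrence":
        out = {"no_recurrence": [], "recurrence": []}
        for r in records:
            out["recurrence" if r.recurrence else "no_recurrence"].append(r)
        return out
    if grouping == "er":
        out = {"early": [], "late": []}
        for r in records:
            status = classify_er_status(r, cutoff_months).value
            if status in out:
                out[status].append(r)
        return out
    raise ValueError("grouping must be 'none', 'recurrence' or 'er'")


def summarize_cohort(
    records: Sequence[PatientRecord],
    grouping: str = "none",
    cutoff_months: float = 18.0,
    variables: Optional[Sequence[str]] = None,
) -> CohortSummary:
    """Baseline characteristics per group with two-group tests.

    Percent denominators are the non-missing counts per variable and group
    (complete-case); empty strata report counts of 0 with undefined percents
    and no test.  With an ``er`` grouping, patients without recurrence are
    omitted (the comparison is early vs late recurrence).
    """
    wanted = set(variables) if variables is not None else None
    groups = _group_records(records, grouping, cutoff_months)
    group_labels = list(groups)

    rows, test_rows = [], []
    for name, kind, accessor in _SUMMARY_VARIABLES:
        if wanted is not None and name not in wanted:
            continue
        per_group_values = {
            g: [accessor(r) for r in recs if accessor(r) is not None]
            for g, recs in groups.items()
        }
        if kind == "continuous":
            for g in group_labels:
                vals = np.asarray(per_group_values[g], dtype=float)
                rows.append(
                    {
                        "variable": name,
                        "category": "median_iqr",
                        "group": g,
                        "count": vals.size,
                        "denominator": vals.size,
                        "median": float(np.median(vals)) if vals.size else float("nan"),
                        "q1": float(np.percentile(vals, 25)) if vals.size else float("nan"),
                        "q3": float(np.percentile(vals, 75)) if vals.size else float("nan"),
                    }
                )
            if len(group_labels) == 2 and all(
                len(per_group_values[g]) for g in group_labels
            ):
                test, stat, p = compare_groups(
                    per_group_values[group_labels[0]],
                    per_group_values[group_labels[1]],
                    kind="continuous",
                )
                test_rows.append(
                    {"variable": name, "test": test, "statistic": stat, "p": p}
                )
            continue

        if kind == "binary":
            categories = [True, False]
            display = {True: "yes", False: "no"}
        else:
            categories = sorted(
                {v for vals in per_group_values.values() for v in vals}
            )
            display = {c: c for c in categories}
        if not categories:
            continue
        counts = {
            g: [sum(v == c for v in per_group_values[g]) for c in categories]
            for g in group_labels
        }
        for g in group_labels:
            denom = sum(counts[g])
            for c, cnt in zip(categories, counts[g]):
                rows.append(
                    {
                        "variable": name,
                        "category": display[c],
                        "group": g,
                        "count": cnt,
                        "denominator": denom,
                        "pct": percent(cnt, denom) if denom else float("nan"),
                    }
                )
        if len(group_labels) == 2 and all(sum(counts[g]) for g in group_labels):
            try:
                test, stat, p = compare_groups(
                    counts[group_labels[0]], counts[group_labels[1]], kind="categorical"
                )
                test_rows.append(
                    {"variable": name, "test": test, "statistic": stat, "p": p}
                )
            except ValueError:
                pass

    return CohortSummary(
        grouping=grouping,
        groups={g: len(recs) for g, recs in groups.items()},
        table=pd.DataFrame(rows),
        tests=pd.DataFrame(test_rows, columns=["variable", "test", "statistic", "p"]),
    )


# ---------------------------------------------------------------------------
# Packaged count fixtures — aggregate counts transcribed from the published
# multi-institutional cohort tables, used for worked examples and report
# cross-checks.  Schema: variable <tab> category <tab> group <tab> count.
# ---------------------------------------------------------------------------

def load_count_fixture(name: str) -> pd.DataFrame:
    """Load a packaged count table (``table1``, ``table2`` or ``cohort``)."""
    fname = f"{name}_counts.tsv"
    with resources.files("pnetrecur.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def percents_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach per-(variable, group) denominators and half-up percents.

    The denominator of each variable within each group is the sum of its
    category counts (rows labelled ``unknown`` keep denominators aligned
    with the published totals where a table reported percentages over the
    full group).
    """
    out = counts.copy()
    denom = out.groupby(["variable", "group"])["count"].transform("sum")
    out["denominator"] = denom
    out["pct"] = [
        percent(c, d) for c, d in zip(out["count"], out["denominator"])
    ]
    return out
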