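"""Exact cohort-level statistics: Fisher's exact test, Wilcoxon tests, burden reports.

These are the tests used throughout the analysis of the MPA/DMBA mouse
mammary tumor cohort: two-sided Fisher's exact tests for cluster/feature
associations, two-tailed Wilcoxon rank-sum tests for score and burden
comparisons between tumor groups, and the one-sample signed-rank test
backing the trinucleotide-context enrichment analysis.

The rank tests delegate to scipy (``mannwhitneyu`` / ``wilcoxon``) with the
branch rules fixed here: exact enumeration for small tie-free samples,
midranks with tie and continuity correction otherwise.  Fisher's two-sided
p is computed in-package as the sum of hypergeometric probabilities of all
tables sharing the observed margins whose probability does not exceed the
observed table's (the convention under which printed cohort p-values such
as 0.009 for the squamous-histology association reproduce exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import InvalidInputError, InvalidTableError

__all__ = [
    "ContingencyTable2x2",
    "GroupComparison",
    "fisher_exact_two_sided",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "subtype_burden_report",
    "benjamini_hochberg",
]

#: combined-sample-size ceiling for the exact rank-sum branch
EXACT_RANKSUM_MAX_N = 25
#: non-zero-difference ceiling for the exact signed-rank branch
EXACT_SIGNRANK_MAX_N = 20
#: relative tolerance when comparing table probabilities to the observed one
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 contingency table; rows = group, columns = feature present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in vals):
            raise InvalidTableError(f"table entries must be non-negative integers, got {vals}")
        if sum(vals) == 0:
            raise InvalidTableError("empty contingency table (total = 0)")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group (or one-sample) comparison."""

    group_names: tuple[str, str]
    n: tuple[int, int]
    statistic: float
    p_value: float
    method: Literal["fisher_exact", "wilcoxon_rank_sum", "wilcoxon_signed_rank"]
    exact: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    p is the sum of hypergeometric probabilities of every table with the
    observed margins whose probability is <= the observed table's
    probability (within relative tolerance ``FISHER_REL_TOL``, to guard
    floating-point equality at the boundary).

    Examples of cohort associations reproduced by this convention:
    squamous histology 5/8 vs 0/9 -> p = 0.009; Trp53 4/8 vs 1/9 -> 0.13;
    Zfhx3 3/8 vs 0/9 -> 0.08.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the hypergeometric: feasible values of the (0,0) cell
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = _sps.hypergeom.pmf(support, n, row1, col1)
    p_obs = probs[a - lo]
    keep = probs <= p_obs * (1.0 + FISHER_REL_TOL)
    if keep.all():
        return 1.0
    return float(min(1.0, probs[keep].sum()))


def _all_equal(values: np.ndarray) -> bool:
    return bool(values.size) and bool(np.all(values == values[0]))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    two_tailed: bool = True,
    group_names: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-tailed (default) Wilcoxon rank-sum / Mann-Whitney test.

    Exact null enumeration when the combined sample size is <= 25 and the
    pooled values contain no ties; otherwise midranks with tie correction
    and a continuity-corrected normal approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    alternative = "two-sided" if two_tailed else "greater"
    pooled = np.concatenate([x, y])
    if _all_equal(pooled):
        # no information: degenerate, every ranking identical
        return GroupComparison(group_names, (x.size, y.size), float(x.size * y.size / 2.0),
                               1.0, "wilcoxon_rank_sum", exact=False)
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and pooled.size <= EXACT_RANKSUM_MAX_N
    res = _sps.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(group_names, (x.size, y.size), float(res.statistic),
                           float(res.pvalue), "wilcoxon_rank_sum", exact=exact)


def wilcoxon_signed_rank(
    differences: Sequence[float],
    two_tailed: bool = True,
) -> GroupComparison:
    """One-sample Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (and counted in the result); exact sign-flip
    enumeration for <= 20 non-zero differences, normal approximation beyond.
    All-zero input is degenerate and returns p = 1 with a warning.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0:
        raise InvalidInputError("differences must be non-empty")
    nonzero = d[d != 0.0]
    n_zero = int(d.size - nonzero.size)
    if nonzero.size == 0:
        warnings.warn("all differences are zero; signed-rank test is degenerate (p = 1)")
        return GroupComparison(("diff", "zero"), (0, n_zero), 0.0, 1.0,
                               "wilcoxon_signed_rank", exact=True,
                               extra={"n_zero_dropped": n_zero})
    if nonzero.size < 6:
        warnings.warn(
            f"only {nonzero.size} non-zero differences; signed-rank p has coarse resolution"
        )
    exact = nonzero.size <= EXACT_SIGNRANK_MAX_N and np.unique(np.abs(nonzero)).size == nonzero.size
    res = _sps.wilcoxon(
        nonzero,
        alternative="two-sided" if two_tailed else "greater",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return GroupComparison(("diff", "zero"), (nonzero.size, n_zero), float(res.statistic),
                           float(res.pvalue), "wilcoxon_signed_rank", exact=exact,
                           extra={"n_zero_dropped": n_zero})


def subtype_burden_report(
    per_sample_counts: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> dict:
    """Per-group burden summary with rank-sum contrasts.

    Parameters
    ----------
    per_sample_counts
        DataFrame with columns ``sample``, ``group``, ``count`` (one row per
        tumor), e.g. mutations per tumor by transcriptomic subtype.
    contrasts
        Pairs ``(group_a, group_b)`` to test; ``group_b`` may be the literal
        ``"rest"`` for a group-vs-all-others contrast (the cohort convention,
        e.g. claudin-low vs all other tumors).  Default: every group vs rest.

    Returns a dict with ``summary`` (per-group n/mean/median DataFrame) and
    ``tests`` (list of GroupComparison).
    """
    required = {"sample", "group", "count"}
    if not required.issubset(per_sample_counts.columns):
        raise InvalidInputError(f"count table must have columns {sorted(required)}")
    df = per_sample_counts
    groups = [g for g, sub in df.groupby("group", sort=True) if len(sub) > 0]
    if len(groups) < 2:
        warnings.warn("fewer than 2 non-empty groups; no tests performed")
    summary = (
        df.groupby("group")["count"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
    if contrasts is None:
        contrasts = [(g, "rest") for g in groups] if len(groups) >= 2 else []
    tests: list[GroupComparison] = []
    for ga, gb in contrasts:
        xa = df.loc[df["group"] == ga, "count"].to_numpy(dtype=float)
        if gb == "rest":
            xb = df.loc[df["group"] != ga, "count"].to_numpy(dtype=float)
            name_b = "rest"
        else:
            xb = df.loc[df["group"] == gb, "count"].to_numpy(dtype=float)
            name_b = gb
        if xa.size == 0 or xb.size == 0:
            warnings.warn(f"contrast ({ga}, {name_b}) skipped: empty group")
            continue
        tests.append(wilcoxon_rank_sum(xa, xb, group_names=(ga, name_b)))
    return {"summary": summary, "tests": tests}


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (helper; not applied by default
    anywhere in the pipeline, which reports unadjusted p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="fdr_bh")[1]
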