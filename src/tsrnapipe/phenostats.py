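"""Offspring-phenotype statistics.

Morphometric traits (cranial cartilage lengths, angles, areas) are compared
across treatment groups by one-way ANOVA followed by Tukey-Kramer pairwise
comparisons.  Both accept either raw per-embryo values or printed group
summaries (n, mean, sd): the sums of squares decompose exactly into
between-group terms computable from (n, mean) and within-group terms equal
to sum (n - 1) sd^2, so the two input modes agree to machine precision when
the summaries come from the same raw data.

Categorical phenotypes (normal / affected, or normal / mild / strong) are
tested against the control group with two-sided Fisher's exact tests using
the probability-mass definition: the p value sums the probabilities of all
tables, at fixed margins, whose probability does not exceed the observed
table's (within a small relative tolerance for floating-point ties).  2 x k
tables with k > 2 are enumerated exactly for totals up to 200.

qPCR expression is quantified by the comparative threshold-cycle method
(2^-ddCt) with the reference level taken as the arithmetic mean of the
reference-gene Ct values, equivalent to the geometric mean of their linear
quantities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.group!r}: sd must be >= 0")

    @classmethod
    def from_values(cls, group: str, values: Iterable[float]) -> "GroupSummary":
        arr = np.asarray(list(values), dtype=float)
        return cls(group, len(arr), float(arr.mean()), float(arr.std(ddof=1)))

    @classmethod
    def from_sem(cls, group: str, n: int, mean: float, sem: float) -> "GroupSummary":
        """Build from a printed mean +/- SEM value (sd = sem * sqrt(n))."""
        return cls(group, n, mean, sem * np.sqrt(n))


def _as_summaries(
    groups: Sequence[GroupSummary] | Sequence[Iterable[float]] | dict,
) -> list[GroupSummary]:
    if isinstance(groups, dict):
        return [GroupSummary.from_values(g, v) for g, v in groups.items()]
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            out.append(GroupSummary.from_values(f"group{i + 1}", g))
    return out


def anova_oneway(
    groups: Sequence[GroupSummary] | Sequence[Iterable[float]] | dict,
) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA from raw values or (n, mean, sd) summaries.

    Returns (F, (df_between, df_within), p).  Identical group means give
    F = 0 and p = 1.
    """
    summaries = _as_summaries(groups)
    if len(summaries) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_total = ns.sum()
    k = len(summaries)
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(n_total) - k
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), (df1, df2), p


def tukey_hsd(
    groups: Sequence[GroupSummary] | Sequence[Iterable[float]] | dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons (handles unequal group sizes).

    For groups i, j: q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),
    referred to the studentized-range distribution with (k, N - k)
    parameters.  Returns a table with the mean difference, q, the adjusted
    p and a (1 - alpha) simultaneous confidence interval per pair.
    """
    summaries = _as_summaries(groups)
    ns = np.array([s.n for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries])
    k = len(summaries)
    n_total = ns.sum()
    df2 = int(n_total) - k
    mse = float(((ns - 1) * sds**2).sum() / df2)
    rows = []
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df2))
    for a, b in itertools.combinations(range(k), 2):
        sa, sb = summaries[a], summaries[b]
        diff = sa.mean - sb.mean
        half = np.sqrt(mse / 2.0 * (1.0 / sa.n + 1.0 / sb.n))
        if half == 0:
            p_adj = 1.0 if diff == 0 else 0.0
            q = np.inf if diff != 0 else 0.0
            ci = (diff, diff)
        else:
            q = abs(diff) / half
            p_adj = float(stats.studentized_range.sf(q, k, df2))
            ci = (diff - q_crit * half, diff + q_crit * half)
        rows.append(
            {
                "group1": sa.group,
                "group2": sb.group,
                "mean_diff": diff,
                "q": q,
                "p_adj": p_adj,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher's exact test (probability-mass two-sided definition)

_TIE_RTOL = 1e-7


def fisher_exact_two_sided(table, method: str = "probability") -> float:
    """Two-sided Fisher's exact test on a 2x2 (or 2xk) count table.

    ``method='probability'`` (default) sums the null probabilities of all
    tables with the observed margins whose probability is <= the observed
    one (relative tolerance 1e-7 for ties); ``method='doubling'`` doubles
    the smaller one-sided tail (2x2 only), capped at 1.
    """
    t = np.asarray(table, dtype=int)
    if (np.asarray(table, dtype=float) != t).any() or (t < 0).any():
        raise ValueError("table entries must be non-negative integers")
    if t.shape[0] != 2:
        raise ValueError("table must have exactly 2 rows")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an empty margin")
    if t.shape[1] == 2:
        if method == "doubling":
            return _fisher_2x2_doubling(t)
        return _fisher_2x2_probability(t)
    if method != "probability":
        raise ValueError("2xk tables support only the probability method")
    if t.sum() > 200:
        raise ValueError(
            "2xk exact enumeration limited to total <= 200; "
            "collapse categories first"
        )
    return _fisher_2xk_probability(t)


def _fisher_2x2_probability(t: np.ndarray) -> float:
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(int(t[0, 0]))
    return float(min(1.0, pmf[pmf <= observed * (1.0 + _TIE_RTOL)].sum()))


def _fisher_2x2_doubling(t: np.ndarray) -> float:
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    rv = stats.hypergeom(n, r1, c1)
    a = int(t[0, 0])
    lower = float(rv.cdf(a))
    upper = float(rv.sf(a - 1))
    return min(1.0, 2.0 * min(lower, upper))


def _fisher_2xk_probability(t: np.ndarray) -> float:
    """Exact multivariate-hypergeometric enumeration for 2 x k tables.

    Conditional on margins, P(first row = (a_1..a_k)) =
    prod_j C(colsum_j, a_j) / C(N, rowsum_1); enumerate the whole fibre.
    """
    from math import comb

    col = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    denom = comb(n, r1)
    observed = np.prod([comb(int(c), int(a)) for c, a in zip(col, t[0])]) / denom

    k = len(col)
    total = 0.0
    # enumerate first-row vectors summing to r1 with 0 <= a_j <= col_j
    def rec(j: int, remaining: int, numer: int) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= col[j]:
                prob = numer * comb(int(col[j]), remaining) / denom
                if prob <= observed * (1.0 + _TIE_RTOL):
                    total += prob
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, numer * comb(int(col[j]), a))

    rec(0, r1, 1)
    return float(min(1.0, total))


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt quantification


def ddct_fold_change(
    records: pd.DataFrame,
    reference_condition: str = "control",
) -> pd.DataFrame:
    """Relative expression by the comparative threshold-cycle method.

    ``records`` needs columns ``sample``, ``condition``, ``ct_target`` and
    one or more ``ct_ref*`` columns (reference-gene Ct values).  The
    reference level per sample is the arithmetic mean of the reference Cts
    (the geometric mean of their linear quantities); dCt = ct_target - that
    mean; ddCt is taken against the mean dCt of ``reference_condition``;
    fold = 2^-ddCt, and folds are rescaled so the reference-condition mean
    fold is exactly 1.  Records with any missing reference Ct are excluded.
    """
    ref_cols = [c for c in records.columns if c.startswith("ct_ref")]
    if not ref_cols:
        raise ValueError("need at least one ct_ref column")
    df = records.copy()
    ok = df[ref_cols + ["ct_target"]].notna().all(axis=1)
    if not ok.all():
        import warnings

        warnings.warn(
            f"excluding {int((~ok).sum())} record(s) with missing Ct values",
            stacklevel=2,
        )
        df = df[ok]
    df["dct"] = df["ct_target"] - df[ref_cols].mean(axis=1)
    ref_mask = df["condition"] == reference_condition
    if not ref_mask.any():
        raise ValueError(f"no records in reference condition {reference_condition!r}")
    ref_dct = df.loc[ref_mask, "dct"].mean()
    df["ddct"] = df["dct"] - ref_dct
    df["fold"] = 2.0 ** (-df["ddct"])
    df["fold"] /= df.loc[ref_mask, "fold"].mean()
    return df
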