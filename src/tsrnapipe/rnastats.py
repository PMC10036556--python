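"""Differential abundance and tRNA-half ratio statistics.

Differential expression is a deliberately simplified negative-binomial
Wald test in the style of count-based RNA-seq tools:

1. per-sample size factors by the median-of-ratios method,
   s_j = median_f k_fj / (prod_j k_fj)^(1/m) over features with nonzero
   counts in every sample;
2. per-feature dispersion by method of moments on normalized counts,
   alpha_f = max((var_f - mean_f) / mean_f^2, 1e-8), with no shrinkage
   toward a fitted trend and no independent filtering;
3. per-condition NB means fitted by Fisher scoring on the log scale with
   the size factors as offsets; log2FC = log2(mu_treated / mu_control),
   its standard error from the expected information, and a two-tailed
   normal (Wald) p value.

Features are called up/down when |log2FC| >= 1 and -log10 p >= 1.3 (raw p;
a Benjamini-Hochberg column is provided for reference but does not enter
the call).

The 5'-half percentage statistic is 100 * c5 / (c5 + c3) per isoacceptor
and replicate, compared between conditions by unpaired two-tailed t tests
with Holm-Sidak step-down correction at alpha = 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_FLOOR = 1e-8
LFC_THRESHOLD = 1.0
NEGLOGP_THRESHOLD = 1.3
LN2 = np.log(2.0)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; supply a "
            "pseudo-reference (e.g. add a pseudocount) before normalizing"
        )
    sub = mat[positive]
    geo_mean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    # median taken on the linear ratio scale (matters for even feature counts)
    sf = np.median(sub / geo_mean, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame, size_factors: pd.Series
) -> pd.Series:
    """Method-of-moments NB dispersion per feature, floored at 1e-8.

    Computed on normalized counts across all samples (marginally), matching
    the population moments (maximum-likelihood variance): with only a
    handful of replicates the unbiased-variance variant is markedly noisier
    and makes the downstream Wald test conservative, while this variant
    keeps it close to its nominal level.  Features with zero mean get NaN
    and are marked untested downstream.
    """
    norm = counts.div(size_factors, axis=1).to_numpy(dtype=float)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.where(mean > 0, np.maximum(alpha, ALPHA_FLOOR), np.nan)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_nb_mean(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-feature NB mean fit with known dispersion.

    Model: K_fj ~ NB(mean = s_j * q_f, dispersion alpha_f); returns
    (beta = log q, expected information of beta).  Fisher scoring:
    U = sum_j (k - mu) / (1 + alpha mu), I = sum_j mu / (1 + alpha mu).
    """
    with np.errstate(divide="ignore"):
        beta = np.log(np.maximum((k / s).mean(axis=1), 1e-12))
    for _ in range(n_iter):
        mu = s * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((k - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = np.clip(beta + step, -50.0, 50.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = s * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def nb_wald_test(
    counts: pd.DataFrame,
    condition: pd.Series | dict,
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-condition NB Wald differential expression.

    ``condition`` maps sample -> {'control', 'treated'}; requires at least
    two replicates per condition.  Returns a per-feature table with
    base_mean, log2fc (treated vs control), se, wald_z, p_value, padj_bh
    and call ('up' / 'down' / 'ns' / 'untested').
    """
    cond = pd.Series(condition).reindex(counts.columns)
    if cond.isna().any():
        raise ValueError("every sample needs a condition label")
    groups = {c: counts.columns[cond == c] for c in ("control", "treated")}
    for c, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"need >= 2 replicates in condition {c!r}")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, size_factors)

    mat = counts.to_numpy(dtype=float)
    norm = counts.div(size_factors, axis=1).to_numpy(dtype=float)
    base_mean = norm.mean(axis=1)
    alpha = dispersion.to_numpy(dtype=float)
    testable = (mat.sum(axis=1) > 0) & np.isfinite(alpha)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.nan,
            "se": np.nan,
            "wald_z": np.nan,
            "p_value": np.nan,
            "call": "untested",
        },
        index=counts.index,
    )
    if testable.any():
        k_sub = mat[testable]
        a_sub = alpha[testable]
        betas = {}
        infos = {}
        for c, cols in groups.items():
            ix = [counts.columns.get_loc(x) for x in cols]
            s = size_factors.to_numpy(dtype=float)[ix][None, :]
            beta, info = _fit_nb_mean(k_sub[:, ix], s, a_sub)
            betas[c], infos[c] = beta, info
        log2fc = (betas["treated"] - betas["control"]) / LN2
        with np.errstate(divide="ignore"):
            se = np.sqrt(1.0 / infos["treated"] + 1.0 / infos["control"]) / LN2
        with np.errstate(invalid="ignore"):
            z = log2fc / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        idx = counts.index[testable]
        out.loc[idx, "log2fc"] = log2fc
        out.loc[idx, "se"] = se
        out.loc[idx, "wald_z"] = z
        out.loc[idx, "p_value"] = p
        singular = ~np.isfinite(z)
        if singular.any():
            out.loc[idx[singular], "call"] = "untested"
        valid = idx[~singular]
        out.loc[valid, "call"] = "pending"
    out = classify_significant(out)
    return out


def classify_significant(
    de: pd.DataFrame,
    lfc_thresh: float = LFC_THRESHOLD,
    neglogp_thresh: float = NEGLOGP_THRESHOLD,
) -> pd.DataFrame:
    """Volcano-style calls: up / down / ns at |log2FC| >= 1, -log10 p >= 1.3.

    Raw p values enter the rule; ``padj_bh`` is attached for reference only.
    """
    de = de.copy()
    p = de["p_value"].to_numpy(dtype=float)
    lfc = de["log2fc"].to_numpy(dtype=float)
    tested = np.isfinite(p) & np.isfinite(lfc) & (de["call"] != "untested")
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(np.maximum(p, 1e-300))
    call = np.where(
        tested & (lfc >= lfc_thresh) & (neglogp >= neglogp_thresh),
        "up",
        np.where(
            tested & (lfc <= -lfc_thresh) & (neglogp >= neglogp_thresh),
            "down",
            np.where(tested, "ns", "untested"),
        ),
    )
    de["call"] = call
    padj = np.full(len(de), np.nan)
    if tested.any():
        padj[tested] = _bh_adjust(p[tested])
    de["padj_bh"] = padj
    return de


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# 5'-half percentage statistics


def half_percentage(c5: float, c3: float) -> float:
    """Percentage of 5' half reads relative to the 5' + 3' total."""
    total = c5 + c3
    if total <= 0:
        raise ValueError("c5 + c3 must be > 0")
    return 100.0 * c5 / total


def holm_sidak(p_values: np.ndarray | list) -> np.ndarray:
    """Holm-Sidak step-down adjusted p values.

    Sort raw p ascending; at rank i (1-based) the Sidak bound is
    1 - (1 - p_(i))^(m - i + 1); adjusted values are the running maximum of
    the bounds, clamped to 1, and ties in raw p share the larger adjusted
    value.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    bounds = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(bounds), 1.0)
    # ties share the larger adjusted value
    ps = p[order]
    for i in range(m - 2, -1, -1):
        if ps[i] == ps[i + 1]:
            adj[i] = adj[i + 1]
    out = np.empty(m)
    out[order] = adj
    return out


def unpaired_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-tailed unpaired t test; degenerate zero-variance ties give p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def half_ratio_test(
    percents: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-isoacceptor comparison of 5'-half percentages between conditions.

    ``percents`` is a tidy table with columns isoacceptor, condition
    ('control' / 'treated'), replicate, percent5.  Returns one row per
    isoacceptor with group means, t statistic, raw and Holm-Sidak adjusted
    p, and a significance flag at ``alpha``.
    """
    rows = []
    for iso, grp in percents.groupby("isoacceptor", sort=True):
        a = grp.loc[grp["condition"] == "control", "percent5"].to_numpy()
        b = grp.loc[grp["condition"] == "treated", "percent5"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{iso}: need >= 2 replicates per condition")
        t, p = unpaired_t(b, a, equal_var=equal_var)
        rows.append(
            {
                "isoacceptor": iso,
                "mean_percent5_control": a.mean(),
                "mean_percent5_treated": b.mean(),
                "t_stat": t,
                "raw_p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("isoacceptor")
    out["adj_p"] = holm_sidak(out["raw_p"].to_numpy())
    out["significant"] = out["adj_p"] <= alpha
    return out


def half_percentages_from_counts(
    count_table: pd.DataFrame,
    feature_meta: pd.DataFrame,
    condition: pd.Series | dict,
) -> pd.DataFrame:
    """Tidy per-replicate 5'-half percentages from a half-feature table.

    ``feature_meta`` needs columns ``isoacceptor`` and ``kind`` indexed by
    feature_id.  Isoacceptor/sample cells with no 5'+3' reads at all are
    dropped (percentage undefined).
    """
    cond = pd.Series(condition)
    rows = []
    meta = feature_meta.loc[count_table.index]
    for iso, grp in meta.groupby("isoacceptor", sort=True):
        if iso is None:
            continue
        five = grp.index[grp["kind"] == "five_prime"]
        three = grp.index[grp["kind"] == "three_prime"]
        if len(five) == 0 or len(three) == 0:
            continue
        for sample in count_table.columns:
            c5 = float(count_table.loc[five, sample].sum())
            c3 = float(count_table.loc[three, sample].sum())
            if c5 + c3 <= 0:
                continue
            rows.append(
                {
                    "isoacceptor": iso,
                    "condition": cond[sample],
                    "replicate": sample,
                    "percent5": half_percentage(c5, c3),
                }
            )
    return pd.DataFrame(rows)
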