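"""Group-comparison statistics for culture-collection analyses.

Thin, validated wrappers over scipy/statsmodels covering the tests used
throughout the trait analysis: two-sample t-tests (Welch and pooled),
the Fligner-Killeen variance test for niche widths, per-taxon Fisher
exact tests of slow/fast composition with Holm multiple-testing
adjustment, and OTU richness per leaf by isolation method.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats.contingency import odds_ratio as _conditional_or
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "t_test",
    "fligner_killeen",
    "fisher_exact_2x2",
    "rowwise_fisher",
    "holm_adjust",
    "richness_per_leaf",
]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    variant: str


def t_test(a, b, variant: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test.

    ``variant="welch"`` (default) does not assume equal variances and uses
    Welch-Satterthwaite degrees of freedom; ``variant="pooled"`` is the
    classical Student test. Each sample needs n >= 2 and at least one must
    have nonzero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    if variant not in {"welch", "pooled"}:
        raise ValueError(f"unknown variant {variant!r}")
    res = scipy.stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(
        statistic=float(res.statistic), df=float(res.df),
        pvalue=float(res.pvalue), variant=variant,
    )


def fligner_killeen(groups: dict[str, list] | list) -> tuple[float, int, float]:
    """Fligner-Killeen test of equal variances across >= 2 groups.

    Rank-based (normal scores of ranks of |x - group median|), hence
    location-free and robust to non-normality; the statistic is referred
    to a chi-squared distribution with k - 1 degrees of freedom.
    Returns (chi2, df, p).
    """
    samples = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in samples]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(arrays)
    if np.all(allv == allv[0]):
        raise ValueError("all values identical across groups")
    chi2, p = scipy.stats.fligner(*arrays)
    return float(chi2), len(arrays) - 1, float(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one; the reported
    odds ratio is the conditional maximum-likelihood estimate. Both margins
    must be positive.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    oddsr = _conditional_or(t, kind="conditional").statistic
    return float(oddsr), float(p)


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, order-preserving.

    The i-th smallest p is multiplied by (m - i + 1), running maxima
    enforce monotonicity, and results are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def rowwise_fisher(table: pd.DataFrame, min_n: int = 6) -> pd.DataFrame:
    """Each taxon row vs the pooled remainder as a 2x2 Fisher exact test.

    ``table`` has taxon groups as rows and columns ``slow``/``fast``
    (counts). Rows with total <= min_n - 1 isolates are flagged NA and
    excluded from the Holm adjustment, which spans only the tested rows.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 taxon rows")
    counts = table[["slow", "fast"]].astype(int)
    totals = counts.sum(axis=1)
    colsums = counts.sum(axis=0)
    records = []
    for taxon in counts.index:
        row = counts.loc[taxon]
        rest = colsums - row
        if totals[taxon] <= min_n - 1:
            records.append({"taxon": taxon, "n_slow": row["slow"],
                            "n_fast": row["fast"], "odds_ratio": np.nan,
                            "p": np.nan, "tested": False})
            continue
        t2 = np.array([[row["slow"], row["fast"]],
                       [rest["slow"], rest["fast"]]])
        oddsr, p = fisher_exact_2x2(t2)
        records.append({"taxon": taxon, "n_slow": row["slow"],
                        "n_fast": row["fast"], "odds_ratio": oddsr,
                        "p": p, "tested": True})
    out = pd.DataFrame(records).set_index("taxon")
    out["p_adj"] = np.nan
    tested = out.index[out["tested"]]
    if len(tested):
        out.loc[tested, "p_adj"] = holm_adjust(out.loc[tested, "p"].to_numpy())
    return out


def richness_per_leaf(
    metadata: pd.DataFrame, include_empty: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, TTestResult]]:
    """Distinct-OTU counts per (leaf, isolation method) and the method contrast.

    Returns the per-cell count table, a per-method mean/sd summary, and
    the between-method t-test in both variants. Leaves with no isolates
    for one method count as richness 0 when ``include_empty`` (the
    sampling design guarantees both methods were attempted per leaf).
    """
    required = {"leaf_id", "method", "otu_id"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    counts = (
        metadata.groupby(["leaf_id", "method"])["otu_id"].nunique()
        .rename("n_otus")
    )
    if include_empty:
        leaves = metadata["leaf_id"].unique()
        methods = metadata["method"].unique()
        full = pd.MultiIndex.from_product(
            [leaves, methods], names=["leaf_id", "method"]
        )
        n_empty = len(full.difference(counts.index))
        if n_empty:
            logger.info("%d leaf x method cell(s) with no isolates count as 0",
                        n_empty)
        counts = counts.reindex(full, fill_value=0)
    cells = counts.reset_index()
    summary = cells.groupby("method")["n_otus"].agg(["mean", "std", "count"])
    tests: dict[str, TTestResult] = {}
    methods = list(summary.index)
    if len(methods) == 2:
        a = cells.loc[cells["method"] == methods[0], "n_otus"]
        b = cells.loc[cells["method"] == methods[1], "n_otus"]
        for variant in ("welch", "pooled"):
            tests[variant] = t_test(a, b, variant=variant)
    return cells, summary, tests
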