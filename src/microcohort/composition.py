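"""Two-group abundance comparisons and compositional differential abundance.

Per-taxon contrasts use the Wilcoxon rank-sum (Mann-Whitney) test on
relative abundances.  Because relative abundances sum to one per sample, a
shift in one taxon drags the rest; the compositional test (ANCOM-style)
works instead on additive log-ratios between every taxon pair and counts,
per taxon, how many of its pairwise ratio tests reject -- the W statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_tables import AbundanceTable

__all__ = [
    "wilcoxon_rank_sum",
    "per_taxon_group_test",
    "AncomResult",
    "ancom",
    "fb_ratio",
]

#: per-group size at or below which the exact Mann-Whitney null is used
#: (no ties only); above it, normal approximation with tie correction and
#: 0.5 continuity correction
EXACT_N_MAX = 10


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p).

    Exact arrangement enumeration when both groups have <= 10 observations
    and the pooled data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= EXACT_N_MAX and y.size <= EXACT_N_MAX and not has_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def per_taxon_group_test(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    adjust: str = "none",
) -> pd.DataFrame:
    """Wilcoxon rank-sum per shared taxon on relative abundances.

    Returns a frame indexed by taxon with the U statistic, two-sided p,
    the direction (which table's median is higher), and BH q-values when
    ``adjust='bh'``.
    """
    if table_a.mode != "relative" or table_b.mode != "relative":
        raise ValueError("per_taxon_group_test requires relative mode")
    ta, tb = set(table_a.taxon_ids), set(table_b.taxon_ids)
    if ta != tb:
        raise ValueError(
            "taxon sets differ between tables: "
            f"only-A={sorted(ta - tb)[:5]}, only-B={sorted(tb - ta)[:5]}"
        )
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    rows = []
    for taxon in table_a.taxon_ids:
        xa = table_a.data[taxon].to_numpy(dtype=float)
        xb = table_b.data[taxon].to_numpy(dtype=float)
        stat, p = wilcoxon_rank_sum(xa, xb)
        med_diff = float(np.median(xa) - np.median(xb))
        direction = "A" if med_diff > 0 else ("B" if med_diff < 0 else "tie")
        rows.append((taxon, stat, p, direction, med_diff))
    out = pd.DataFrame(
        rows, columns=["taxon", "statistic", "p", "direction", "median_diff"]
    ).set_index("taxon")
    if adjust == "bh":
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


@dataclass
class AncomResult:
    """Per-taxon W counts and rejection flags from the pairwise log-ratio
    screen, together with the settings that produced them."""

    table: pd.DataFrame        # index taxon; columns W, reject
    pseudocount: float
    alpha: float
    w_frac: float
    w_threshold: int


def ancom(
    table: AbundanceTable,
    group_labels,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    w_frac: float = 0.7,
) -> AncomResult:
    """Compositional differential-abundance screen on a counts table.

    For every unordered taxon pair (i, j) the per-sample additive log-ratio
    log((c_i + pc) / (c_j + pc)) is compared between the two groups with a
    Wilcoxon rank-sum test.  Each taxon's m-1 pair p-values are BH-adjusted
    at ``alpha``; W_i counts the rejections, and taxon i is flagged when
    W_i >= ceil(w_frac * (m - 1)).
    """
    if table.mode != "counts":
        raise ValueError("ancom requires counts mode")
    m = table.n_taxa
    if m < 2:
        raise ValueError("ancom requires at least two taxa")
    labels = np.asarray(group_labels)
    if labels.shape != (table.n_samples,):
        raise ValueError("group_labels length must match the table")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) != 2:
        raise ValueError("ancom compares exactly two groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")

    logc = np.log(table.values() + pseudocount)
    in_a = labels == uniq[0]
    pvals = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ratio = logc[:, i] - logc[:, j]
            _, p = wilcoxon_rank_sum(ratio[in_a], ratio[~in_a])
            pvals[i, j] = pvals[j, i] = p

    w = np.zeros(m, dtype=int)
    for i in range(m):
        others = np.delete(pvals[i], i)
        reject = multipletests(others, alpha=alpha, method="fdr_bh")[0]
        w[i] = int(reject.sum())
    w_threshold = ceil(w_frac * (m - 1))
    out = pd.DataFrame(
        {"W": w, "reject": w >= w_threshold}, index=pd.Index(table.taxon_ids, name="taxon")
    )
    return AncomResult(
        table=out,
        pseudocount=pseudocount,
        alpha=alpha,
        w_frac=w_frac,
        w_threshold=w_threshold,
    )


def fb_ratio(
    table_phylum: AbundanceTable,
    firmicutes: str = "Firmicutes",
    bacteroidetes: str = "Bacteroidetes",
) -> pd.DataFrame:
    """Per-sample Firmicutes/Bacteroidetes relative-abundance ratio.

    Samples with zero Bacteroidetes get ``ratio = NaN`` and
    ``defined = False``; exclude those rows from downstream group tests.
    """
    missing = [p for p in (firmicutes, bacteroidetes) if p not in table_phylum.taxon_ids]
    if missing:
        raise ValueError(f"phylum table lacks {missing}")
    rel = table_phylum.data.div(table_phylum.data.sum(axis=1), axis=0)
    f = rel[firmicutes].to_numpy(dtype=float)
    b = rel[bacteroidetes].to_numpy(dtype=float)
    defined = b > 0
    ratio = np.where(defined, f / np.where(defined, b, 1.0), np.nan)
    return pd.DataFrame(
        {"fb_ratio": ratio, "defined": defined},
        index=pd.Index(table_phylum.sample_ids, name="sample_id"),
    )
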