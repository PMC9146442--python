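"""Alpha diversity, Bray-Curtis dissimilarity, PCoA, and ANOSIM.

Shannon entropy is reported in nats by default (the log base is an explicit
parameter everywhere), Simpson is the Gini-Simpson form 1 - sum(p^2), and
Chao1 is the classic estimator with the doubleton-free fallback.  ANOSIM is
the rank-based two-or-more-group test on a dissimilarity matrix, with
exhaustive enumeration of label arrangements when that is cheap and
Monte-Carlo permutation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core_tables import AbundanceTable

__all__ = [
    "shannon",
    "simpson",
    "simpson_dominance",
    "chao1",
    "alpha_diversity",
    "DistanceMatrix",
    "bray_curtis_matrix",
    "OrdinationResult",
    "pcoa",
    "AnosimResult",
    "anosim",
]


def _proportions(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    return x / total


def shannon(values, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over positive proportions.

    ``base=None`` means natural log (nats); pass 2 for bits.
    """
    p = _proportions(values)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= log(base)
    return h


def simpson(values) -> float:
    """Gini-Simpson index D = 1 - sum p_i^2."""
    p = _proportions(values)
    return float(1.0 - (p ** 2).sum())


def simpson_dominance(values) -> float:
    """Simpson dominance sum p_i^2 (the complement of :func:`simpson`)."""
    return 1.0 - simpson(values)


def chao1(counts, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from integer counts.

    Classic form S_obs + F1^2 / (2 F2) when doubletons exist; otherwise the
    fallback S_obs + F1 (F1 - 1) / 2.  The bias-corrected variant replaces
    the first form with S_obs + F1 (F1 - 1) / (2 (F2 + 1)).
    """
    x = np.asarray(counts, dtype=float)
    if not np.allclose(x, np.round(x)):
        raise ValueError("chao1 requires integer counts (singletons undefined otherwise)")
    if (x < 0).any():
        raise ValueError("negative counts")
    x = np.round(x).astype(int)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: AbundanceTable, shannon_base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity: Shannon, Gini-Simpson, dominance, and
    (for counts tables) Chao1 with its S_obs / F1 / F2 ingredients."""
    rows = {}
    for sid in table.sample_ids:
        vec = table.data.loc[sid].to_numpy(dtype=float)
        row = {
            "shannon": shannon(vec, base=shannon_base),
            "simpson": simpson(vec),
            "dominance": simpson_dominance(vec),
            "s_obs": int((vec > 0).sum()),
        }
        if table.mode == "counts":
            ints = np.round(vec).astype(int)
            row["f1"] = int((ints == 1).sum())
            row["f2"] = int((ints == 2).sum())
            row["chao1"] = chao1(vec)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs:
    d(u, v) = 1 - 2 sum_i min(u_i, v_i) / (sum u + sum v)."""
    x = table.values()
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(sample_ids=table.sample_ids, values=d)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x retained axes
    eigenvalues: np.ndarray          # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained (positive) axis


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Eigendecompose B = -1/2 J D^2 J (J the centering matrix); coordinates
    are eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues.
    Negative eigenvalues are reported but excluded from the coordinates and
    from the proportion-explained denominator.
    """
    d = dist.values
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # treat tiny eigenvalues as numerical zero
    tol = max(1e-12, 1e-10 * abs(eigvals).max()) if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if n_axes is not None:
        n_pos = min(n_pos, n_axes)
    coords = eigvecs[:, :n_pos] * np.sqrt(eigvals[:n_pos])
    pos_sum = eigvals[eigvals > tol].sum()
    prop = eigvals[:n_pos] / pos_sum if pos_sum > 0 else np.zeros(n_pos)
    frame = pd.DataFrame(
        coords, index=dist.sample_ids, columns=[f"PC{i + 1}" for i in range(n_pos)]
    )
    return OrdinationResult(
        coordinates=frame, eigenvalues=eigvals, proportion_explained=prop
    )


@dataclass
class AnosimResult:
    r: float
    p_value: float
    permutations: int
    method: str          # "exhaustive" | "monte-carlo"
    seed: int | None


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return (r_between - r_within) / (m / 2.0)


def anosim(
    dist: DistanceMatrix,
    group_labels,
    permutations: int = 999,
    seed: int | None = None,
    exhaustive_limit: int = 10_000,
) -> AnosimResult:
    """ANOSIM test of group separation on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    M = n(n-1)/2 pairwise dissimilarities (average ranks on ties).  The
    one-sided p-value counts permuted R >= observed R.  With two groups and
    at most ``exhaustive_limit`` distinct label arrangements the exact
    arrangement distribution is enumerated; otherwise ``permutations``
    random relabelings are drawn and p = (1 + count) / (permutations + 1).
    """
    labels = np.asarray(group_labels)
    n = dist.n
    if labels.shape != (n,):
        raise ValueError("group_labels length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM requires at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")

    condensed = dist.condensed()
    ranks = rankdata(condensed)
    # map condensed index -> (i, j)
    iu, ju = np.triu_indices(n, k=1)

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu] == lab[ju]

    r_obs = _anosim_r(ranks, within_mask(labels))

    n_arrangements = comb(n, int(counts[0])) if len(uniq) == 2 else None
    if n_arrangements is not None and n_arrangements <= exhaustive_limit:
        g0 = uniq[0]
        k0 = int(counts[0])
        count = 0
        for subset in combinations(range(n), k0):
            lab = np.full(n, uniq[1], dtype=labels.dtype)
            lab[list(subset)] = g0
            if _anosim_r(ranks, within_mask(lab)) >= r_obs - 1e-12:
                count += 1
        return AnosimResult(
            r=float(r_obs),
            p_value=count / n_arrangements,
            permutations=n_arrangements,
            method="exhaustive",
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        lab = rng.permutation(labels)
        if _anosim_r(ranks, within_mask(lab)) >= r_obs - 1e-12:
            count += 1
    return AnosimResult(
        r=float(r_obs),
        p_value=(1 + count) / (permutations + 1),
        permutations=permutations,
        method="monte-carlo",
        seed=seed,
    )
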