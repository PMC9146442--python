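"""Presence/absence cooccurrence networks over genus tables.

For every genus pair the Jaccard index summarises how often the two genera
are detected in the same samples, and a hypergeometric model tests whether
the copresence count is larger (copresence) or smaller (mutual exclusion)
than the marginal detection frequencies predict.  Surviving edges (after
Bonferroni control over all pairs and both tails) form an undirected
network whose global clustering coefficient is compared against uniform
random graphs with matching node and edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_tables import AbundanceTable, filter_rare
from .composition import wilcoxon_rank_sum

__all__ = [
    "presence_matrix",
    "PresencePair",
    "jaccard",
    "hypergeom_test",
    "CooccurrenceNetwork",
    "build_network",
    "clustering_coefficient",
    "NullNetworkTest",
    "null_network_test",
    "intra_phylum_comparison",
]


def presence_matrix(table: AbundanceTable, detection_threshold: float = 0.0) -> pd.DataFrame:
    """Binary samples x taxa matrix: 1 where value > threshold."""
    if detection_threshold < 0:
        raise ValueError("detection_threshold must be non-negative")
    return (table.data > detection_threshold).astype(int)


@dataclass(frozen=True)
class PresencePair:
    """Presence margins for one taxon pair: N samples, a and b present
    counts, k samples with both."""

    n: int
    a: int
    b: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n and 0 <= self.b <= self.n):
            raise ValueError("presence counts must lie in [0, N]")
        if not (max(0, self.a + self.b - self.n) <= self.k <= min(self.a, self.b)):
            raise ValueError(
                f"copresence k={self.k} outside hypergeometric support for "
                f"N={self.n}, a={self.a}, b={self.b}"
            )


def jaccard(pair: PresencePair) -> float:
    """Jaccard index k / (a + b - k): samples with both over samples with
    at least one."""
    union = pair.a + pair.b - pair.k
    if union <= 0:
        raise ValueError("Jaccard undefined: neither taxon occurs")
    return pair.k / union


def hypergeom_test(pair: PresencePair) -> tuple[float, float]:
    """Inclusive hypergeometric tail probabilities for the copresence count.

    Under X ~ Hypergeometric(N, a, b): returns (P(X >= k), P(X <= k)).
    The upper tail flags copresence, the lower tail mutual exclusion.
    """
    dist = hypergeom(pair.n, pair.a, pair.b)
    p_co = float(dist.sf(pair.k - 1))
    p_ex = float(dist.cdf(pair.k))
    return min(p_co, 1.0), min(p_ex, 1.0)


@dataclass
class CooccurrenceNetwork:
    """Tested genus-pair statistics plus the retained-edge graph.

    ``pair_stats`` holds one row per tested unordered pair (retained or
    not); ``graph`` contains only genera incident to a retained edge, each
    node annotated with its phylum.
    """

    graph: nx.Graph
    pair_stats: pd.DataFrame
    clustering: float
    n_samples: int
    n_genera_tested: int
    n_tests: int
    alpha: float
    correction: str

    @property
    def edges(self) -> pd.DataFrame:
        return self.pair_stats[self.pair_stats["retained"]].reset_index(drop=True)

    def to_edge_list(self) -> pd.DataFrame:
        cols = [
            "genus_a", "genus_b", "phylum_a", "phylum_b",
            "jaccard", "sign", "p_raw", "p_adj",
        ]
        return self.edges[cols]


def build_network(
    table: AbundanceTable,
    min_mean_rel: float = 0.001,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    detection_threshold: float = 0.0,
    tails_in_family: int = 2,
) -> CooccurrenceNetwork:
    """Build the tested cooccurrence network from a genus-level table.

    Rare genera (mean relative abundance below ``min_mean_rel``) are
    excluded first; presence is value > ``detection_threshold``.  Every
    unordered pair gets a Jaccard index and both hypergeometric tails; raw
    p-values are Bonferroni-multiplied by pairs x ``tails_in_family``
    (capped at 1) and edges with adjusted p <= alpha are retained, signed
    by the winning tail.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    if tails_in_family not in (1, 2):
        raise ValueError("tails_in_family must be 1 or 2")
    filtered = filter_rare(table, min_mean_relative=min_mean_rel)
    genera = filtered.taxon_ids
    m = len(genera)
    if m < 2:
        raise ValueError(f"fewer than 2 genera remain after the rare filter ({m})")
    pres = presence_matrix(filtered, detection_threshold).to_numpy()
    n = pres.shape[0]
    margins = pres.sum(axis=0)
    co = pres.T @ pres  # copresence counts for all pairs

    iu, ju = np.triu_indices(m, k=1)
    a = margins[iu]
    b = margins[ju]
    k = co[iu, ju]
    p_co = hypergeom.sf(k - 1, n, a, b)
    p_ex = hypergeom.cdf(k, n, a, b)
    union = a + b - k
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, k / np.maximum(union, 1), np.nan)

    n_tests = len(iu) * tails_in_family
    copresence_wins = p_co <= p_ex
    p_raw = np.where(copresence_wins, p_co, p_ex)
    p_adj = np.minimum(p_raw * n_tests, 1.0)
    retained = (p_adj <= alpha) & np.isfinite(jac)

    phyla = {g: filtered.lineages[g].phylum for g in genera}
    pair_stats = pd.DataFrame(
        {
            "genus_a": [genera[i] for i in iu],
            "genus_b": [genera[j] for j in ju],
            "phylum_a": [phyla[genera[i]] for i in iu],
            "phylum_b": [phyla[genera[j]] for j in ju],
            "n": n,
            "a": a,
            "b": b,
            "k": k,
            "jaccard": jac,
            "p_copresence": p_co,
            "p_exclusion": p_ex,
            "sign": np.where(copresence_wins, "copresence", "exclusion"),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "retained": retained,
        }
    )

    graph = nx.Graph()
    for row in pair_stats[pair_stats["retained"]].itertuples():
        graph.add_node(row.genus_a, phylum=row.phylum_a)
        graph.add_node(row.genus_b, phylum=row.phylum_b)
        # display strength: Jaccard for copresence, 1 - Jaccard for exclusion
        strength = row.jaccard if row.sign == "copresence" else 1.0 - row.jaccard
        graph.add_edge(
            row.genus_a,
            row.genus_b,
            jaccard=float(row.jaccard),
            sign=row.sign,
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            strength=float(strength),
        )
    c = clustering_coefficient(graph) if graph.number_of_nodes() else 0.0
    return CooccurrenceNetwork(
        graph=graph,
        pair_stats=pair_stats,
        clustering=c,
        n_samples=n,
        n_genera_tested=m,
        n_tests=n_tests,
        alpha=alpha,
        correction=correction,
    )


def clustering_coefficient(graph: nx.Graph) -> float:
    """Global (average local) clustering coefficient; nodes with degree < 2
    contribute 0.  Edge signs are ignored."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty node set")
    return float(nx.average_clustering(graph, count_zeros=True))


@dataclass
class NullNetworkTest:
    observed_c: float
    null_c: np.ndarray
    p_value: float
    r: int
    seed: int | None
    null_model: str = "gnm"

    def summary(self) -> dict:
        return {
            "observed_clustering": self.observed_c,
            "null_mean": float(self.null_c.mean()),
            "null_sd": float(self.null_c.std(ddof=1)) if self.r > 1 else 0.0,
            "p_value": self.p_value,
            "random_networks": self.r,
            "null_model": self.null_model,
            "seed": self.seed,
        }


def null_network_test(
    network: CooccurrenceNetwork | nx.Graph,
    r: int = 10_000,
    null_model: str = "gnm",
    seed: int | None = None,
) -> NullNetworkTest:
    """Compare the observed clustering coefficient against random graphs.

    ``gnm`` draws uniform G(n, m) graphs with matching node and edge
    counts; ``rewire`` degree-preserving double-edge swaps.  One-sided
    p = (1 + #{C_null >= C_obs}) / (r + 1).
    """
    graph = network.graph if isinstance(network, CooccurrenceNetwork) else network
    if graph.number_of_nodes() < 3 or graph.number_of_edges() < 1:
        raise ValueError("need >= 3 nodes and >= 1 edge for the null test")
    if r < 100:
        raise ValueError("need at least 100 random networks")
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    c_obs = clustering_coefficient(graph)
    rng = np.random.default_rng(seed)
    null_c = np.empty(r)
    for i in range(r):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if null_model == "gnm":
            g = nx.gnm_random_graph(n, m, seed=sub_seed)
        elif null_model == "rewire":
            g = graph.copy()
            nswap = max(1, 10 * m)
            try:
                nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=sub_seed)
            except nx.NetworkXError:
                pass  # graphs too small/dense to swap keep their structure
        else:
            raise ValueError("null_model must be 'gnm' or 'rewire'")
        null_c[i] = nx.average_clustering(g, count_zeros=True)
    p = (1 + int((null_c >= c_obs - 1e-12).sum())) / (r + 1)
    return NullNetworkTest(
        observed_c=c_obs, null_c=null_c, p_value=p, r=r, seed=seed, null_model=null_model
    )


def intra_phylum_comparison(
    network_a: CooccurrenceNetwork,
    network_b: CooccurrenceNetwork,
    phylum: str,
) -> tuple[float, float]:
    """Compare two cohorts' intra-phylum cooccurrence strengths.

    Collects the Jaccard indices of all tested genus pairs where both
    genera belong to ``phylum`` in each cohort and applies a two-sided
    Wilcoxon rank-sum test.  Returns (statistic, p).
    """
    vals = []
    for net in (network_a, network_b):
        stats_ = net.pair_stats
        mask = (stats_["phylum_a"] == phylum) & (stats_["phylum_b"] == phylum)
        jac = stats_.loc[mask, "jaccard"].dropna().to_numpy()
        if jac.size < 2:
            raise ValueError(
                f"fewer than 2 intra-{phylum} genus pairs in one cohort"
            )
        vals.append(jac)
    return wilcoxon_rank_sum(vals[0], vals[1])
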