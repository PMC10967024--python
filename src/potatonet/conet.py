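"""Signed presence-absence metanetworks and per-sample local network properties.

The metanetwork tests every qualifying taxon pair for co-presence across
samples against a fixed-margin hypergeometric null: with N samples and
marginal presence counts nA, nB, the co-presence count follows
Hypergeometric(N, nA, nB) under independence. Pairs co-present significantly
more often than expected form co-occurrence ("+") edges, significantly less
often co-exclusion ("-") edges, after Benjamini-Hochberg correction over the
union of both one-sided tail families.

Per-sample local properties (modularity, transitivity, average path length)
are computed on the subgraph of the metanetwork induced by the taxa present
in that sample, separately per edge sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .diversity import rarefy
from .tables_io import CountTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pairwise hypergeometric test
# ---------------------------------------------------------------------------

class DegenerateMarginError(ValueError):
    """A taxon is present in zero or all samples; the pair is untestable."""


def pair_test(
    presence: np.ndarray, taxon_a: int, taxon_b: int
) -> tuple[int, float, float, float]:
    """Test one taxon pair for non-random co-presence.

    presence: samples x taxa binary matrix. Returns (k, expected, p_more,
    p_less) where k is the observed co-presence count, expected = nA*nB/N,
    and the tail probabilities are exact hypergeometric.
    """
    presence = np.asarray(presence, dtype=bool)
    n = presence.shape[0]
    a = presence[:, taxon_a]
    b = presence[:, taxon_b]
    na, nb = int(a.sum()), int(b.sum())
    if na in (0, n) or nb in (0, n):
        raise DegenerateMarginError(
            f"degenerate margin (nA={na}, nB={nb}, N={n}); pair skipped"
        )
    k = int(np.sum(a & b))
    expected = na * nb / n
    p_more = float(hypergeom.sf(k - 1, n, na, nb))
    p_less = float(hypergeom.cdf(k, n, na, nb))
    return k, expected, p_more, p_less


# ---------------------------------------------------------------------------
# metanetwork construction
# ---------------------------------------------------------------------------

@dataclass
class MetaNetwork:
    marker: str
    nodes: list[str]  # taxa passing the prevalence pre-filter
    edges: pd.DataFrame  # node_a, node_b, sign, k, expected, p, q
    n_samples: int = 0
    n_tests: int = 0
    rarefied: CountTable | None = None  # kept for per-sample subsetting

    def graph(self, sign: str | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        edges = self.edges if sign is None else self.edges[self.edges["sign"] == sign]
        for row in edges.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, sign=row.sign, q=row.q)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        out = self.edges.copy()
        out["weight"] = out["k"].astype(float)
        return out[["node_a", "node_b", "sign", "weight", "p", "q", "k", "expected"]]


def _swap_null_pvalues(
    presence: np.ndarray, idx: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-margin permutation null: independently shuffle each taxon's
    presence vector across samples (preserves both margins exactly)."""
    iu_a, iu_b = idx
    n_pairs = iu_a.size
    k_obs = np.zeros(n_pairs, dtype=int)
    ge = np.zeros(n_pairs)
    le = np.zeros(n_pairs)
    p = presence.astype(np.int8)
    k_obs = np.einsum("si,si->i", p[:, iu_a], p[:, iu_b])
    for _ in range(n_perm):
        perm = np.empty_like(p)
        for t in range(p.shape[1]):
            perm[:, t] = p[rng.permutation(p.shape[0]), t]
        k_p = np.einsum("si,si->i", perm[:, iu_a], perm[:, iu_b])
        ge += k_p >= k_obs
        le += k_p <= k_obs
    return (1.0 + ge) / (1.0 + n_perm), (1.0 + le) / (1.0 + n_perm)


def build_metanetwork(
    table: CountTable,
    depth: int,
    seed: int,
    q_threshold: float = 0.05,
    min_prevalence: int = 5,
    null: str = "hypergeometric",
    n_perm: int = 999,
) -> MetaNetwork:
    """Rarefy, call presence (rarefied count > 0), pre-filter taxa present in
    at least `min_prevalence` and at most N - `min_prevalence` samples, test
    all unordered pairs, BH-correct both tail families jointly, and keep
    edges with q < `q_threshold`, signed by tail."""
    rar = rarefy(table, depth, seed)
    rtab = rar.table
    presence = rtab.counts > 0
    n = presence.shape[0]
    prev = presence.sum(axis=0)
    ok = (prev >= min_prevalence) & (prev <= n - min_prevalence)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("prevalence filter removed %d taxa", skipped)
    taxa = [t for t, keep in zip(rtab.taxon_ids, ok) if keep]
    if len(taxa) < 3:
        raise ValueError("fewer than 3 taxa after prevalence filtering")
    p_sub = presence[:, ok]
    prev_sub = prev[ok]

    t = len(taxa)
    iu_a, iu_b = np.triu_indices(t, k=1)
    k = (p_sub.astype(np.int64).T @ p_sub.astype(np.int64))[iu_a, iu_b]
    na = prev_sub[iu_a]
    nb = prev_sub[iu_b]
    expected = na * nb / n

    if null == "hypergeometric":
        p_more = hypergeom.sf(k - 1, n, na, nb)
        p_less = hypergeom.cdf(k, n, na, nb)
    elif null == "permutation":
        rng = np.random.default_rng(seed + 1)
        p_more, p_less = _swap_null_pvalues(p_sub, (iu_a, iu_b), n_perm, rng)
    else:
        raise ValueError(f"unknown null model: {null}")

    all_p = np.concatenate([p_more, p_less])
    _, all_q, _, _ = multipletests(all_p, method="fdr_bh")
    q_more, q_less = all_q[: k.size], all_q[k.size:]

    rows = []
    for i in range(k.size):
        sig_more = q_more[i] < q_threshold
        sig_less = q_less[i] < q_threshold
        if not (sig_more or sig_less):
            continue
        if sig_more and (not sig_less or p_more[i] <= p_less[i]):
            sign, p, q = "+", p_more[i], q_more[i]
        else:
            sign, p, q = "-", p_less[i], q_less[i]
        rows.append(
            (taxa[iu_a[i]], taxa[iu_b[i]], sign, int(k[i]), expected[i], p, q)
        )
    edges = pd.DataFrame(
        rows, columns=["node_a", "node_b", "sign", "k", "expected", "p", "q"]
    )
    return MetaNetwork(
        marker=table.marker,
        nodes=taxa,
        edges=edges,
        n_samples=n,
        n_tests=2 * k.size,
        rarefied=rtab,
    )


# ---------------------------------------------------------------------------
# graph property primitives
# ---------------------------------------------------------------------------

def graph_transitivity(g: nx.Graph) -> float:
    """3 * triangles / connected triples; 0 when there are no triples."""
    return float(nx.transitivity(g))


def average_path_length(g: nx.Graph) -> float:
    """Mean shortest-path distance over connected node pairs (NaN if no edges)."""
    if g.number_of_edges() == 0:
        return float("nan")
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    return total / pairs  # each unordered pair counted twice in both, ratio exact


def best_louvain_q(g: nx.Graph, seed: int, restarts: int = 10) -> float:
    """Best modularity over seeded Louvain restarts on the unweighted graph."""
    if g.number_of_edges() == 0:
        return float("nan")
    best = -np.inf
    for r in range(restarts):
        parts = nx.community.louvain_communities(g, weight=None, seed=seed + r)
        q = nx.community.modularity(g, parts, weight=None)
        best = max(best, q)
    return float(best)


# ---------------------------------------------------------------------------
# per-sample local properties
# ---------------------------------------------------------------------------

SIGNS = ("+", "-")
SIGN_NAMES = {"+": "co-occurrence", "-": "co-exclusion"}


@dataclass
class LocalProps:
    sample_id: str
    marker: str
    sign: str
    modularity: float
    transitivity: float
    average_path_length: float
    n_nodes: int
    n_edges: int


def local_properties(
    metanet: MetaNetwork,
    table: CountTable,
    sample_id: str,
    sign: str,
    seed: int = 0,
    restarts: int = 10,
) -> LocalProps:
    """Local properties of the metanetwork subgraph induced by the taxa
    present (count > 0) in one sample, restricted to edges of one sign.

    `table` should be the rarefied table the metanetwork was built on (kept
    on the MetaNetwork). Properties undefined on edgeless subgraphs are NaN,
    never zero-filled.
    """
    if sample_id not in table.sample_ids:
        raise KeyError(f"unknown sample: {sample_id}")
    i = table.sample_ids.index(sample_id)
    present = {t for t, c in zip(table.taxon_ids, table.counts[i]) if c > 0}
    nodes = [t for t in metanet.nodes if t in present]
    g_full = metanet.graph(sign)
    g = g_full.subgraph(nodes).copy()
    n_edges = g.number_of_edges()
    if n_edges == 0:
        mod, trans, apl = float("nan"), float("nan"), float("nan")
    else:
        mod = best_louvain_q(g, seed=seed, restarts=restarts)
        trans = graph_transitivity(g)
        apl = average_path_length(g)
    return LocalProps(
        sample_id=sample_id,
        marker=metanet.marker,
        sign=sign,
        modularity=mod,
        transitivity=trans,
        average_path_length=apl,
        n_nodes=len(nodes),
        n_edges=n_edges,
    )


def local_properties_all(
    metanets: dict[str, MetaNetwork],
    tables: dict[str, CountTable],
    seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """One row per sample x marker x sign, covering every combination."""
    rows = []
    for marker, metanet in metanets.items():
        table = tables[marker]
        for sid in table.sample_ids:
            for sign in SIGNS:
                lp = local_properties(metanet, table, sid, sign, seed=seed, restarts=restarts)
                rows.append(
                    {
                        "sample_id": lp.sample_id,
                        "marker": lp.marker,
                        "sign": SIGN_NAMES[sign],
                        "modularity": lp.modularity,
                        "transitivity": lp.transitivity,
                        "average_path_length": lp.average_path_length,
                        "n_nodes": lp.n_nodes,
                        "n_edges": lp.n_edges,
                    }
                )
    return pd.DataFrame(rows)
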