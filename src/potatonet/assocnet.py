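"""Cross-domain Spearman association network, genus-network preprocessing,
and the prevalence-conditional degree permutation test."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import rarefy
from .tables_io import CountTable, SampleFrame, TaxonomyTable, aggregate_to_genus

logger = logging.getLogger(__name__)

#: reserved pooled-remainder category that keeps per-sample totals intact
POOLED_REMAINDER = "pooled_remainder"


@dataclass
class AssocNetwork:
    nodes: pd.DataFrame  # index variable name; columns: category, cluster
    edges: pd.DataFrame  # node_a, node_b, rho, p, q, n_used, sign

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, rho=row.rho, q=row.q, sign=row.sign)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        out = self.edges.copy()
        out["weight"] = out["rho"]
        return out[["node_a", "node_b", "sign", "weight", "p", "q", "rho", "n_used"]]


def _spearman_exact(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    rho = stats.spearmanr(x, y).statistic
    exceed = 0
    for _ in range(n_perm):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            exceed += 1
    return rho, (1.0 + exceed) / (1.0 + n_perm)


def spearman_network(
    variables: pd.DataFrame,
    categories: dict[str, str] | None = None,
    min_n: int = 8,
    threshold_mode: str = "fdr",
    threshold: float = 0.05,
    exact_below: int = 0,
    n_perm_for_ties: int = 999,
    seed: int = 0,
) -> AssocNetwork:
    """Pairwise-complete Spearman correlation network with BH correction.

    Edges pass either the BH q (threshold_mode="fdr") or the raw p
    (threshold_mode="p") cutoff. Louvain on the positive-edge subgraph
    (|rho| weights) assigns cluster labels. Constant variables are dropped
    with a warning.
    """
    if threshold_mode not in ("fdr", "p"):
        raise ValueError("threshold_mode must be 'fdr' or 'p'")
    cols = []
    for c in variables.columns:
        v = variables[c].dropna()
        if v.size and np.allclose(v, v.iloc[0]):
            warnings.warn(f"constant variable '{c}' dropped")
            continue
        cols.append(c)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(cols, 2):
        sub = variables[[a, b]].dropna()
        n = len(sub)
        if n < min_n:
            continue
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            continue
        if exact_below and n < exact_below:
            rho, p = _spearman_exact(x, y, n_perm_for_ties, rng)
        else:
            res = stats.spearmanr(x, y)
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append((a, b, rho, p, n))
    pairs = pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p", "n_used"])
    if len(pairs):
        _, q, _, _ = multipletests(pairs["p"].to_numpy(), method="fdr_bh")
        pairs["q"] = q
    else:
        pairs["q"] = []
    crit = pairs["q"] if threshold_mode == "fdr" else pairs["p"]
    edges = pairs[crit < threshold].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "+", "-")
    edges = edges[["node_a", "node_b", "rho", "p", "q", "n_used", "sign"]].reset_index(drop=True)

    # Louvain clusters on the positive-edge subgraph, |rho| weighted
    gpos = nx.Graph()
    gpos.add_nodes_from(cols)
    for row in edges[edges["sign"] == "+"].itertuples(index=False):
        gpos.add_edge(row.node_a, row.node_b, weight=abs(row.rho))
    parts = nx.community.louvain_communities(gpos, weight="weight", seed=seed)
    cluster = {}
    cid = 0
    for part in sorted(parts, key=lambda p: sorted(p)[0]):
        connected = [v for v in part if gpos.degree(v) > 0]
        if not connected:
            continue
        for v in connected:
            cluster[v] = cid
        cid += 1

    nodes = pd.DataFrame(index=pd.Index(cols, name="variable"))
    nodes["category"] = [
        (categories or {}).get(c, "unknown") for c in nodes.index
    ]
    nodes["cluster"] = [cluster.get(c, np.nan) for c in nodes.index]
    return AssocNetwork(nodes=nodes, edges=edges)


def neighborhood(network: AssocNetwork, node: str) -> AssocNetwork:
    """Induced subnetwork on a node plus its direct neighbors."""
    if node not in network.nodes.index:
        raise KeyError(f"unknown node: {node}")
    adj = set(
        network.edges.loc[network.edges["node_a"] == node, "node_b"]
    ) | set(network.edges.loc[network.edges["node_b"] == node, "node_a"])
    keep = adj | {node}
    edges = network.edges[
        network.edges["node_a"].isin(keep) & network.edges["node_b"].isin(keep)
    ].reset_index(drop=True)
    nodes = network.nodes.loc[[n for n in network.nodes.index if n in keep]]
    return AssocNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# genus-network preprocessing
# ---------------------------------------------------------------------------

def genus_network_preprocess(
    table: CountTable,
    tax: TaxonomyTable,
    frame: SampleFrame,
    depth: int,
    seed: int = 0,
    min_prevalence_frac: float = 0.20,
) -> tuple[CountTable, pd.DataFrame]:
    """Genus aggregation, rarefaction (samples below depth dropped), 20%
    prevalence filter with removed genera pooled into a remainder category
    (per-sample totals preserved), plus a metadata block with numeric
    variables z-scored and location/treatment one-hot encoded."""
    genus = aggregate_to_genus(table, tax)
    rar = rarefy(genus, depth, seed)
    gtab = rar.table
    presence = gtab.counts > 0
    prev_frac = presence.mean(axis=0)
    keep = prev_frac >= min_prevalence_frac
    kept = [t for t, k in zip(gtab.taxon_ids, keep) if k]
    pooled = gtab.counts[:, ~keep].sum(axis=1)
    counts = np.column_stack([gtab.counts[:, keep], pooled])
    out = CountTable(
        gtab.sample_ids, kept + [POOLED_REMAINDER], counts, gtab.marker
    )

    meta = frame.data.loc[gtab.sample_ids]
    blocks = []
    for col in frame.numeric_columns():
        v = meta[col].astype(float)
        sd = v.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"constant metadata column '{col}' dropped")
            continue
        blocks.append(((v - v.mean()) / sd).rename(col))
    onehot = pd.get_dummies(meta[["location", "treatment"]], prefix_sep="=").astype(float)
    encoded = pd.concat(blocks + [onehot], axis=1)
    return out, encoded


# ---------------------------------------------------------------------------
# prevalence-conditional degree permutation test
# ---------------------------------------------------------------------------

def _prevalence_bins(prevalence: pd.Series, n_bins: int) -> pd.Series:
    """Equal-frequency bins; singleton bins merged into their neighbor."""
    ranks = prevalence.rank(method="first")
    n = len(prevalence)
    n_bins = min(n_bins, n)
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    counts = bins.value_counts()
    # merge any single-member bin into the previous (or next) bin
    for b in sorted(counts.index):
        if (bins == b).sum() == 1:
            target = b - 1 if b > 0 else b + 1
            logger.info("merging singleton prevalence bin %s into %s", b, target)
            bins[bins == b] = target
    return bins


def degree_prevalence_test(
    edges: pd.DataFrame,
    prevalence: pd.Series,
    grouping: pd.Series | None = None,
    n_perm: int = 999,
    seed: int = 0,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Are units (taxa or clades) more or less connected than expected given
    their prevalence?

    Expected degree per node is the mean degree of its equal-frequency
    prevalence bin; the unit statistic sums (observed - expected) over
    member nodes; the null permutes node degrees within bins.
    """
    if (prevalence <= 0).any() or (prevalence > 1).any():
        raise ValueError("prevalence must lie in (0, 1]")
    nodes = list(prevalence.index)
    deg = pd.Series(0.0, index=nodes)
    for row in edges.itertuples(index=False):
        if row.node_a in deg.index:
            deg[row.node_a] += 1
        if row.node_b in deg.index:
            deg[row.node_b] += 1

    bins = _prevalence_bins(prevalence, n_bins)
    expected = deg.groupby(bins).transform("mean")
    diff = deg - expected

    if grouping is None:
        units = pd.Series(nodes, index=nodes)
    else:
        units = grouping.reindex(nodes)
    obs = diff.groupby(units).sum()

    rng = np.random.default_rng(seed)
    deg_arr = deg.to_numpy()
    bin_idx = [np.flatnonzero(bins.to_numpy() == b) for b in np.unique(bins)]
    unit_codes, unit_labels = pd.factorize(units)
    n_units = len(unit_labels)
    exceed = np.zeros(n_units)
    obs_arr = obs.reindex(unit_labels).to_numpy()
    diff_base = -expected.to_numpy()
    for _ in range(n_perm):
        perm_deg = deg_arr.copy()
        for bi in bin_idx:
            perm_deg[bi] = deg_arr[bi[rng.permutation(len(bi))]]
        null = np.bincount(unit_codes, weights=perm_deg + diff_base, minlength=n_units)
        exceed += np.abs(null) >= np.abs(obs_arr) - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    out = pd.DataFrame(
        {
            "observed_degree": deg.groupby(units).sum().reindex(unit_labels),
            "expected_degree": expected.groupby(units).sum().reindex(unit_labels),
            "difference": obs_arr,
            "p": pvals,
        },
        index=pd.Index(unit_labels, name="unit"),
    )
    return out


# ---------------------------------------------------------------------------
# centrality summaries
# ---------------------------------------------------------------------------

def centrality_summary(
    edges: pd.DataFrame, clade: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Per-node degree and exact (unnormalized) betweenness; optional
    per-clade total degree."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b)
    bet = nx.betweenness_centrality(g, normalized=False)
    per_node = pd.DataFrame(
        {
            "degree": [g.degree(n) for n in g.nodes],
            "betweenness": [bet[n] for n in g.nodes],
        },
        index=pd.Index(list(g.nodes), name="node"),
    ).sort_index()
    per_clade = None
    if clade is not None:
        per_clade = per_node["degree"].groupby(clade.reindex(per_node.index)).sum()
    return per_node, per_clade
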