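"""Readers/writers for count tables, taxonomy, sample metadata and signed edge lists.

All on-disk formats are plain TSV with "." decimals and "NA" for missing
values; writers and readers round-trip byte-identically. Count tables are
written with taxa as rows (the canonical orientation); the transpose is
accepted via an orientation flag.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"
#: reserved genus label that pools ASVs without a genus assignment
UNASSIGNED_GENUS = "g__unassigned"

_EDGE_COLUMNS = ["node_a", "node_b", "sign", "weight", "p", "q"]


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class CountTable:
    """Samples x taxa non-negative integer matrix with a marker label."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_taxa), integer dtype
    marker: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableFormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise TableFormatError("non-integer count")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise TableFormatError("negative count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError("duplicate sample id")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise TableFormatError("duplicate taxon id")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxon_ids), self.counts[idx], self.marker)

    def relative_abundance(self) -> np.ndarray:
        totals = self.sample_totals().astype(float)
        if np.any(totals == 0):
            raise TableFormatError("zero-total sample")
        return self.counts / totals[:, None]


@dataclass
class TaxonomyTable:
    """taxon_id -> rank assignments for one marker."""

    assignments: pd.DataFrame  # index taxon_id, columns subset of RANKS
    marker: str = ""

    def __post_init__(self) -> None:
        bad = [c for c in self.assignments.columns if c not in RANKS]
        if bad:
            raise TableFormatError(f"unknown taxonomy ranks: {bad}")
        if self.assignments.index.has_duplicates:
            raise TableFormatError("duplicate taxon id in taxonomy")
        self.assignments = self.assignments.fillna(UNASSIGNED).astype(str)
        empty = (self.assignments == "").any(axis=None)
        if empty:
            raise TableFormatError("empty rank string; use 'unassigned'")

    def genus_of(self, taxon_ids: list[str]) -> pd.Series:
        missing = [t for t in taxon_ids if t not in self.assignments.index]
        if missing:
            raise TableFormatError(f"taxon missing from taxonomy: {missing[:5]}")
        if "genus" not in self.assignments.columns:
            raise TableFormatError("taxonomy table has no genus rank")
        g = self.assignments.loc[taxon_ids, "genus"]
        return g.where(g != UNASSIGNED, UNASSIGNED_GENUS)


REQUIRED_META = ("location", "treatment", "timepoint")
TREATMENTS = ("control", "treated")
TIMEPOINTS = ("T0", "T1")


@dataclass
class SampleFrame:
    """Per-sample design (location/treatment/timepoint) plus numeric measurements."""

    data: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        for col in REQUIRED_META:
            if col not in self.data.columns:
                raise TableFormatError(f"metadata missing required column '{col}'")
            if self.data[col].isna().any():
                raise TableFormatError(f"missing values in required column '{col}'")
        if self.data.index.has_duplicates:
            raise TableFormatError("duplicate sample id in metadata")
        bad_t = set(self.data["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise TableFormatError(f"unknown treatment labels: {sorted(bad_t)}")
        bad_tp = set(self.data["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise TableFormatError(f"unknown timepoint labels: {sorted(bad_tp)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def numeric_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c not in REQUIRED_META and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def subset(self, sample_ids: list[str]) -> "SampleFrame":
        return SampleFrame(self.data.loc[sample_ids].copy())


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_counts(path, marker: str = "", orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table.

    orientation="taxa_rows" (canonical): rows are taxa, columns samples.
    orientation="samples_rows": the transpose.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError("no samples") from None
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise TableFormatError("no samples")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            raise TableFormatError(f"non-numeric count in column '{col}'")
        if not np.all(np.mod(numeric.to_numpy(), 1) == 0):
            raise TableFormatError(f"non-integer count in column '{col}'")
        values[:, j] = numeric.to_numpy().astype(np.int64)
    if orientation == "taxa_rows":
        return CountTable(list(df.columns), list(df.index), values.T, marker)
    elif orientation == "samples_rows":
        return CountTable(list(df.index), list(df.columns), values, marker)
    raise ValueError(f"unknown orientation: {orientation}")


def write_counts(table: CountTable, path) -> None:
    df = pd.DataFrame(table.counts.T, index=table.taxon_ids, columns=table.sample_ids)
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path, marker: str = "") -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df, marker)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    out = tax.assignments.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    return SampleFrame(df)


def write_metadata(frame: SampleFrame, path) -> None:
    out = frame.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# genus aggregation
# ---------------------------------------------------------------------------

def aggregate_to_genus(table: CountTable, tax: TaxonomyTable) -> CountTable:
    """Sum counts over ASVs sharing a genus; unassigned ASVs pool under a
    reserved label. Per-sample totals are preserved exactly."""
    genus = tax.genus_of(table.taxon_ids)
    df = table.to_frame()
    agg = df.T.groupby(genus.to_numpy()).sum().T
    # deterministic genus order: first appearance in the input taxon order
    seen: dict[str, None] = {}
    for g in genus:
        seen.setdefault(g, None)
    order = [g for g in seen if g in agg.columns]
    agg = agg[order]
    return CountTable(table.sample_ids, list(agg.columns), agg.to_numpy(), table.marker)


# ---------------------------------------------------------------------------
# signed edge lists
# ---------------------------------------------------------------------------

def write_edges(edges: pd.DataFrame, path) -> None:
    """Write a signed weighted edge list.

    Required columns: node_a, node_b, sign, weight, p, q. Extra columns are
    preserved after the canonical six.
    """
    missing = [c for c in _EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise TableFormatError(f"edge frame missing columns: {missing}")
    extra = [c for c in edges.columns if c not in _EDGE_COLUMNS]
    out = edges[_EDGE_COLUMNS + extra]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"edge file missing columns: {missing}")
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    if (df["node_a"] == df["node_b"]).any():
        raise TableFormatError("self-loop in edge file")
    key = df.apply(lambda r: frozenset((r["node_a"], r["node_b"])), axis=1)
    if key.duplicated().any():
        raise TableFormatError("duplicate undirected edge")
    return df


def edges_to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        attrs = {k: v for k, v in row._asdict().items() if k not in ("node_a", "node_b")}
        g.add_edge(str(row.node_a), str(row.node_b), **attrs)
    return g


def write_graphml(edges: pd.DataFrame, path) -> None:
    g = edges_to_graph(edges.fillna(""))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# flat key-value records (truth records, manifests)
# ---------------------------------------------------------------------------

def write_keyvalue(record: dict, path) -> None:
    with open(path, "w") as fh:
        for key in record:
            fh.write(f"{key}\t{record[key]}\n")


def read_keyvalue(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = value
    return out
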