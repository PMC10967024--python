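"""End-to-end orchestration: synthetic generation (optional) through
diversity, metanetworks, treatment tests, association network and core/DA
stages, with a structured manifest and byte-reproducible outputs."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assocnet, conet, coreda, diversity, synthgen, tables_io, treatstats

DEFAULT_DEPTHS = {"16S": 10_000, "ITS": 18_750}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    synthetic: bool = True
    # synthetic design (used when synthetic=True)
    n_locations: int = 8
    n_replicates_per_arm: int = 3
    n_taxa_per_marker: int = 60
    library_size_range: tuple[int, int] = (2000, 4000)
    # real-data paths (used when synthetic=False); marker -> path
    counts: dict = field(default_factory=dict)
    taxonomy: dict = field(default_factory=dict)
    metadata: str | None = None
    # thresholds and depths
    depths: dict = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    q_threshold: float = 0.05
    min_prevalence: int = 5
    genus_prevalence_frac: float = 0.20
    core_detection: float = 0.01
    core_prevalence: float = 0.25
    n_perm: int = 199
    permanova_terms: tuple[str, ...] = ("location", "treatment", "time", "treatment:time")
    rda_terms: tuple[str, ...] = ("treatment", "time")

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")
        for name, v, lo, hi in (
            ("q_threshold", self.q_threshold, 0, 1),
            ("genus_prevalence_frac", self.genus_prevalence_frac, 0, 1),
            ("core_detection", self.core_detection, 0, 1),
            ("core_prevalence", self.core_prevalence, 0, 1),
        ):
            if not lo < v < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi})")
        if not self.synthetic:
            if not self.counts or self.metadata is None:
                raise ValueError("non-synthetic runs need counts and metadata paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "library_size_range" in raw:
            raw["library_size_range"] = tuple(raw["library_size_range"])
        for key in ("permanova_terms", "rda_terms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the report directory. Deterministic under a
    fixed config (same bytes on re-run)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _config_dict(config), "stages": {}}

    # ---- stage 1: synthgen ----------------------------------------------
    stage = "synthgen"
    try:
        if config.synthetic:
            design = synthgen.TrialDesign(
                n_locations=config.n_locations,
                n_replicates_per_arm=config.n_replicates_per_arm,
                n_taxa_per_marker=config.n_taxa_per_marker,
                library_size_range=config.library_size_range,
                seed=config.seed,
            )
            effects = synthgen.PlantedEffects(
                treated_taxa={"ITS": {i: 1.5 for i in range(5)}},
                cooccur_pairs={"16S": [(10, 11), (12, 13), (14, 15)]},
                coexclude_pairs={"16S": [(16, 17)]},
                yield_model=synthgen.YieldModel(treatment_pct=10.0, proxy_coef=15.0),
            )
            tables, frame, truth = synthgen.generate_trial(design, effects)
            for marker, tab in tables.items():
                tables_io.write_counts(tab, out / f"counts_{marker}.tsv")
                tax = synthgen.synthetic_taxonomy(marker, design.n_taxa_per_marker, config.seed)
                tables_io.write_taxonomy(tax, out / f"taxonomy_{marker}.tsv")
            tables_io.write_metadata(frame, out / "metadata.tsv")
            tables_io.write_keyvalue(truth, out / "truth.tsv")
            counts_paths = {m: out / f"counts_{m}.tsv" for m in tables}
            tax_paths = {m: out / f"taxonomy_{m}.tsv" for m in tables}
            meta_path = out / "metadata.tsv"
            manifest["stages"][stage] = {
                "samples": len(frame.sample_ids),
                "taxa_per_marker": config.n_taxa_per_marker,
            }
        else:
            counts_paths = {m: Path(p) for m, p in config.counts.items()}
            tax_paths = {m: Path(p) for m, p in config.taxonomy.items()}
            meta_path = Path(config.metadata)
            manifest["stages"][stage] = {"skipped": True}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- stage 2: tables_io ---------------------------------------------
    stage = "tables_io"
    try:
        tables = {m: tables_io.read_counts(p, marker=m) for m, p in counts_paths.items()}
        taxonomies = {m: tables_io.read_taxonomy(p, marker=m) for m, p in tax_paths.items()}
        frame = tables_io.read_metadata(meta_path)
        manifest["stages"][stage] = {
            m: {"samples": t.n_samples, "taxa": t.n_taxa} for m, t in tables.items()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- stage 3: diversity ---------------------------------------------
    stage = "diversity"
    try:
        rarefied = {}
        info = {}
        for marker, tab in tables.items():
            depth = _depth_for(config, tab)
            rar = diversity.rarefy(tab, depth, config.seed)
            rarefied[marker] = rar.table
            a = diversity.alpha(rar.table)
            a.to_csv(out / f"alpha_{marker}.tsv", sep="\t", float_format="%.10g")
            dm = diversity.bray_curtis(rar.table)
            ordn = diversity.pcoa(dm)
            ordn.coordinates.iloc[:, :4].to_csv(
                out / f"pcoa_{marker}.tsv", sep="\t", float_format="%.10g"
            )
            sub = frame.subset(rar.table.sample_ids)
            perma = diversity.permanova(
                dm, sub, list(config.permanova_terms), n_perm=config.n_perm, seed=config.seed
            )
            perma.table.to_csv(out / f"permanova_{marker}.tsv", sep="\t", float_format="%.10g")
            rda = diversity.rda_location_centered(
                rar.table, sub, list(config.rda_terms), n_perm=config.n_perm, seed=config.seed
            )
            rda.to_csv(out / f"rda_{marker}.tsv", sep="\t", float_format="%.10g")
            info[marker] = {"depth": depth, "dropped": len(rar.dropped)}
        manifest["stages"][stage] = info
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- stage 4: conet --------------------------------------------------
    stage = "conet"
    try:
        metanets = {}
        info = {}
        for marker, tab in tables.items():
            depth = _depth_for(config, tab)
            net = conet.build_metanetwork(
                tab,
                depth=depth,
                seed=config.seed,
                q_threshold=config.q_threshold,
                min_prevalence=config.min_prevalence,
            )
            metanets[marker] = net
            tables_io.write_edges(net.to_edge_frame(), out / f"metanetwork_{marker}.tsv")
            tables_io.write_graphml(net.to_edge_frame(), out / f"metanetwork_{marker}.graphml")
            info[marker] = {"nodes": len(net.nodes), "edges": len(net.edges)}
        localprops = conet.local_properties_all(
            metanets, {m: n.rarefied for m, n in metanets.items()}, seed=config.seed
        )
        localprops.to_csv(out / "localprops.tsv", sep="\t", index=False, float_format="%.10g", na_rep="NA")
        manifest["stages"][stage] = info
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- stage 5: treatstats --------------------------------------------
    stage = "treatstats"
    try:
        t1 = tables_io.SampleFrame(frame.data[frame.data["timepoint"] == "T1"].copy())
        rows = []
        for var in ["yield"] + [c for c in frame.numeric_columns() if c != "yield"]:
            try:
                res = treatstats.treated_vs_control(t1, var, standardize=True)
            except ValueError:
                continue
            kw_stat, kw_p = treatstats.across_locations(t1, var)
            rows.append(
                {
                    "variable": var,
                    "n_control": res.n_control,
                    "n_treated": res.n_treated,
                    "wilcoxon_stat": res.statistic,
                    "wilcoxon_p": res.p,
                    "direction": res.direction,
                    "kruskal_stat": kw_stat,
                    "kruskal_p": kw_p,
                }
            )
        pd.DataFrame(rows).to_csv(
            out / "treatment_tests.tsv", sep="\t", index=False, float_format="%.10g"
        )
        manifest["stages"][stage] = {"variables": len(rows)}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- stage 6: assocnet ----------------------------------------------
    stage = "assocnet"
    try:
        variables, categories = _variable_frame(frame, rarefied, localprops)
        net = assocnet.spearman_network(
            variables, categories=categories, threshold=config.q_threshold, seed=config.seed
        )
        tables_io.write_edges(net.to_edge_frame(), out / "assoc_network.tsv")
        net.nodes.to_csv(out / "assoc_clusters.tsv", sep="\t", na_rep="NA")
        if "yield" in net.nodes.index:
            hood = assocnet.neighborhood(net, "yield")
            tables_io.write_edges(hood.to_edge_frame(), out / "yield_neighborhood.tsv")
        deg_info = {}
        for marker, metanet in metanets.items():
            prev = pd.Series(
                (metanet.rarefied.counts > 0).mean(axis=0),
                index=metanet.rarefied.taxon_ids,
            ).loc[metanet.nodes]
            phylum = taxonomies[marker].assignments["phylum"].reindex(metanet.nodes)
            dt = assocnet.degree_prevalence_test(
                metanet.edges, prev, grouping=phylum, n_perm=config.n_perm, seed=config.seed
            )
            dt.to_csv(out / f"degree_test_{marker}.tsv", sep="\t", float_format="%.10g")
            per_node, per_clade = assocnet.centrality_summary(metanet.edges, clade=phylum)
            per_node.to_csv(out / f"centrality_{marker}.tsv", sep="\t", float_format="%.10g")
            deg_info[marker] = {"units": len(dt)}
        manifest["stages"][stage] = {"edges": len(net.edges), "degree_tests": deg_info}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- stage 7: coreda -------------------------------------------------
    stage = "coreda"
    try:
        info = {}
        for marker, tab in tables.items():
            gtab = tables_io.aggregate_to_genus(tab, taxonomies[marker])
            sub = frame.subset(gtab.sample_ids)
            profile = coreda.prevalence_profile(
                gtab,
                sub,
                detections=[0.001, config.core_detection, 0.05],
                core_detection=config.core_detection,
                core_prevalence=config.core_prevalence,
            )
            core_df = pd.DataFrame(profile.core)
            core_df.to_csv(out / f"core_{marker}.tsv", sep="\t")
            shared = coreda.shared_taxa_constrained(
                tab, frame.subset(tab.sample_ids), tax=taxonomies[marker], level="genus"
            )
            shared.to_csv(out / f"shared_{marker}.tsv", sep="\t", index=False)
            da = coreda.nb_differential_abundance(
                tab, frame.subset(tab.sample_ids), tax=taxonomies[marker], level="genus"
            )
            da.to_csv(out / f"da_{marker}.tsv", sep="\t", float_format="%.10g", na_rep="NA")
            info[marker] = {
                "core_groups": len(profile.core),
                "da_tested": int((da["status"] == "tested").sum()),
            }
        manifest["stages"][stage] = info
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _depth_for(config: RunConfig, table: tables_io.CountTable) -> int:
    depth = config.depths.get(table.marker)
    if depth is None:
        depth = int(np.median(table.sample_totals()))
    # synthetic libraries may sit below the published depths; never rarefy
    # deeper than the smallest library
    return min(int(depth), int(table.sample_totals().max()))


def _variable_frame(frame, rarefied, localprops):
    """Wide per-plot variable table: yield + covariates from the T1 row,
    alpha-diversity and local network properties at T0 and T1 per marker."""
    meta = frame.data
    t1_rows = meta[meta["timepoint"] == "T1"]
    plots = {sid[:-3]: sid for sid in t1_rows.index if sid.endswith("_T1")}
    df = t1_rows.loc[list(plots.values()), frame.numeric_columns()].copy()
    df.index = list(plots.keys())
    categories = {c: "metadata" for c in df.columns}
    categories["yield"] = "yield"

    lp = localprops.copy()
    lp["timepoint"] = lp["sample_id"].str.rsplit("_", n=1).str[-1]
    lp["plot"] = lp["sample_id"].str.rsplit("_", n=1).str[0]
    for prop in ("modularity", "transitivity", "average_path_length"):
        for (marker, sign, tp), grp in lp.groupby(["marker", "sign", "timepoint"]):
            name = f"{tp} {marker} {sign} {prop}"
            df[name] = grp.set_index("plot")[prop].reindex(df.index)
            categories[name] = "network-property"
    from .diversity import alpha as alpha_fn

    for marker, tab in rarefied.items():
        a = alpha_fn(tab)
        a_plot = a.copy()
        a_plot["plot"] = [s.rsplit("_", 1)[0] for s in a_plot.index]
        a_plot["timepoint"] = [s.rsplit("_", 1)[1] for s in a_plot.index]
        for metric in ("chao1", "shannon"):
            for tp, grp in a_plot.groupby("timepoint"):
                name = f"{tp} {marker} {metric}"
                df[name] = grp.set_index("plot")[metric].reindex(df.index)
                categories[name] = "biodiversity"
    return df, categories


def _config_dict(config: RunConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["library_size_range"] = list(d["library_size_range"])
    d["permanova_terms"] = list(d["permanova_terms"])
    d["rda_terms"] = list(d["rda_terms"])
    d["counts"] = {k: str(v) for k, v in d["counts"].items()}
    d["taxonomy"] = {k: str(v) for k, v in d["taxonomy"].items()}
    return d
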