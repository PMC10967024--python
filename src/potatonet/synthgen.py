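"""Synthetic multi-location trial generator with planted, recoverable effects.

Generates per-marker ASV count tables over a location x arm x replicate x
timepoint design, a sample metadata frame (yield at T1 only, nutrient and
environmental covariates with location-specific means) and a truth record of
everything that was planted:

* location-dominant compositional structure: per-location mean compositions
  drawn from a Dirichlet around a global log-normal taxon profile, with
  per-sample Dirichlet-multinomial noise;
* a treatment effect applied multiplicatively to a chosen taxon set in
  treated T1 cells of one marker;
* co-occurring / co-excluding taxon pairs whose presence is coupled through
  shared (or complementary) Bernoulli latent factors;
* yield linked to treatment, a designated network-structure proxy column and
  metadata covariates, plus Gaussian noise.

All randomness flows from a single seeded generator, so identical seeds give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CountTable, SampleFrame, TaxonomyTable, UNASSIGNED

MARKERS = ("16S", "ITS")

#: numeric covariates emitted in the SampleFrame, with (global mean, between-
#: location sd, within-location sd)
COVARIATES = {
    "soil_nitrate": (25.0, 8.0, 3.0),
    "soil_potassium": (180.0, 40.0, 15.0),
    "petiole_nitrogen": (4.0, 0.8, 0.3),
    "peel_zinc": (12.0, 3.0, 1.5),
    "env_temp": (18.0, 4.0, 1.0),
    "env_precip": (60.0, 20.0, 5.0),
}

#: name of the designated network-structure proxy column
NET_PROXY = "net_proxy"


@dataclass
class TrialDesign:
    n_locations: int = 21
    n_replicates_per_arm: int = 3
    timepoints: tuple[str, ...] = ("T0", "T1")
    markers: tuple[str, ...] = MARKERS
    n_taxa_per_marker: int = 80
    library_size_range: tuple[int, int] = (2000, 4000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("n_locations must be >= 2")
        if self.n_replicates_per_arm < 2:
            raise ValueError("n_replicates_per_arm must be >= 2")
        if self.n_taxa_per_marker < 1:
            raise ValueError("empty taxon set")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("library size below 1 or inverted range")


@dataclass
class YieldModel:
    base: float = 400.0
    location_sd: float = 40.0
    treatment_pct: float = 0.0  # +15 -> treated mean is 15% above control
    proxy_coef: float = 0.0
    covariate_coefs: dict[str, float] = field(default_factory=dict)


@dataclass
class PlantedEffects:
    #: Dirichlet concentration for per-location mean compositions; np.inf
    #: removes the location effect entirely
    location_concentration: float = 30.0
    #: Dirichlet concentration of per-sample compositions around the location mean
    sample_concentration: float = 200.0
    #: marker -> {taxon index -> log2 fold change} applied in treated T1 cells
    treated_taxa: dict[str, dict[int, float]] = field(default_factory=dict)
    #: marker -> list of (i, j) taxon-index pairs with coupled presence
    cooccur_pairs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    #: marker -> list of (i, j) pairs with complementary presence
    coexclude_pairs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    #: probability a pair member follows its latent factor
    latent_coupling: float = 0.9
    #: marginal presence probability of the latent factor
    latent_presence: float = 0.5
    #: uniform range of per-taxon baseline occupancy probabilities
    occupancy_range: tuple[float, float] = (0.55, 0.98)
    yield_model: YieldModel = field(default_factory=YieldModel)
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for marker in set(self.cooccur_pairs) | set(self.coexclude_pairs):
            co = self.cooccur_pairs.get(marker, [])
            ex = self.coexclude_pairs.get(marker, [])
            used: set[int] = set()
            for i, j in list(co) + list(ex):
                if i == j or i in used or j in used:
                    raise ValueError("planted pairs must be disjoint")
                used.update((i, j))
        for fcs in self.treated_taxa.values():
            for lfc in fcs.values():
                if not np.isfinite(lfc) or lfc == 0:
                    raise ValueError("fold changes must be finite and nonzero")


def taxon_ids(marker: str, n: int) -> list[str]:
    return [f"{marker}_t{i:03d}" for i in range(n)]


def _design_rows(design: TrialDesign) -> list[tuple[str, str, str, str]]:
    rows = []
    for loc in range(design.n_locations):
        lname = f"L{loc + 1:02d}"
        for arm in ("control", "treated"):
            for rep in range(design.n_replicates_per_arm):
                for tp in design.timepoints:
                    sid = f"{lname}_{arm}_r{rep + 1}_{tp}"
                    rows.append((sid, lname, arm, tp))
    return rows


def generate_trial(
    design: TrialDesign, effects: PlantedEffects
) -> tuple[dict[str, CountTable], SampleFrame, dict[str, str]]:
    """Generate one full synthetic trial.

    Returns one CountTable per marker (row sums equal the drawn library
    sizes exactly), the SampleFrame, and a flat truth record listing planted
    pairs, treated taxa and yield coefficients.
    """
    rng = np.random.default_rng(design.seed)
    rows = _design_rows(design)
    sample_ids = [r[0] for r in rows]
    locations = np.array([r[1] for r in rows])
    treatments = np.array([r[2] for r in rows])
    timepoints = np.array([r[3] for r in rows])
    n_samples = len(rows)
    loc_names = [f"L{i + 1:02d}" for i in range(design.n_locations)]
    loc_index = {l: i for i, l in enumerate(loc_names)}

    truth: dict[str, str] = {"seed": str(design.seed)}

    tables: dict[str, CountTable] = {}
    for marker in design.markers:
        T = design.n_taxa_per_marker
        tids = taxon_ids(marker, T)
        base = rng.lognormal(mean=0.0, sigma=1.3, size=T)

        planted_co = effects.cooccur_pairs.get(marker, [])
        planted_ex = effects.coexclude_pairs.get(marker, [])
        treated = effects.treated_taxa.get(marker, {})
        planted_idx = sorted(
            {i for p in planted_co + planted_ex for i in p} | set(treated)
        )
        if planted_idx:
            # keep planted taxa comfortably abundant so presence is driven by
            # the latent factors / fold changes, not by sampling depth
            base[planted_idx] = np.quantile(base, 0.9)
        base = base / base.sum()

        if np.isinf(effects.location_concentration):
            loc_comps = np.tile(base, (design.n_locations, 1))
        else:
            conc = np.maximum(base * effects.location_concentration, 1e-9)
            loc_comps = rng.dirichlet(conc, size=design.n_locations)

        occupancy = rng.uniform(*effects.occupancy_range, size=T)
        occupancy[planted_idx] = 1.0  # presence handled by latent factors / always on

        counts = np.zeros((n_samples, T), dtype=np.int64)
        lo, hi = design.library_size_range
        for s in range(n_samples):
            li = loc_index[locations[s]]
            conc = np.maximum(loc_comps[li] * effects.sample_concentration, 1e-9)
            comp = rng.dirichlet(conc)

            present = rng.random(T) < occupancy
            for pairs, complementary in ((planted_co, False), (planted_ex, True)):
                for i, j in pairs:
                    z = rng.random() < effects.latent_presence
                    fi = rng.random() < effects.latent_coupling
                    fj = rng.random() < effects.latent_coupling
                    pi = z if fi else (rng.random() < effects.latent_presence)
                    zj = (not z) if complementary else z
                    pj = zj if fj else (rng.random() < effects.latent_presence)
                    present[i], present[j] = pi, pj

            mult = np.ones(T)
            if treated and treatments[s] == "treated" and timepoints[s] == "T1":
                for i, lfc in treated.items():
                    mult[i] = 2.0 ** lfc

            comp = comp * present * mult
            tot = comp.sum()
            if tot == 0:  # pathological occupancy draw; fall back to raw composition
                comp = rng.dirichlet(conc)
            else:
                comp = comp / tot
            lib = int(rng.integers(lo, hi + 1))
            counts[s] = rng.multinomial(lib, comp)

        tables[marker] = CountTable(list(sample_ids), tids, counts, marker)

        for k, (i, j) in enumerate(planted_co):
            truth[f"cooccur_{marker}_{k}"] = f"{tids[i]},{tids[j]}"
        for k, (i, j) in enumerate(planted_ex):
            truth[f"coexclude_{marker}_{k}"] = f"{tids[i]},{tids[j]}"
        for i, lfc in sorted(treated.items()):
            truth[f"treated_{marker}_{tids[i]}"] = f"{lfc:.6g}"

    # ---------------- metadata ----------------
    meta = pd.DataFrame(
        {
            "location": locations,
            "treatment": treatments,
            "timepoint": timepoints,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    loc_of = np.array([loc_index[l] for l in locations])
    for name, (mu, between, within) in COVARIATES.items():
        loc_means = rng.normal(mu, between, size=design.n_locations)
        meta[name] = loc_means[loc_of] + rng.normal(0, within, size=n_samples)

    proxy_loc = rng.normal(0.0, 1.0, size=design.n_locations)
    meta[NET_PROXY] = proxy_loc[loc_of] + rng.normal(0.0, 1.0, size=n_samples)

    ym = effects.yield_model
    yield_loc = rng.normal(ym.base, ym.location_sd, size=design.n_locations)
    y = yield_loc[loc_of].copy()
    y = y * np.where(treatments == "treated", 1.0 + ym.treatment_pct / 100.0, 1.0)
    y = y + ym.proxy_coef * meta[NET_PROXY].to_numpy()
    for cov, coef in ym.covariate_coefs.items():
        y = y + coef * meta[cov].to_numpy()
    y = y + rng.normal(0.0, effects.noise_sd, size=n_samples)
    meta["yield"] = np.where(timepoints == "T1", y, np.nan)

    truth["yield_base"] = f"{ym.base:.6g}"
    truth["yield_treatment_pct"] = f"{ym.treatment_pct:.6g}"
    truth["yield_proxy_coef"] = f"{ym.proxy_coef:.6g}"
    for cov, coef in ym.covariate_coefs.items():
        truth[f"yield_coef_{cov}"] = f"{coef:.6g}"

    return tables, SampleFrame(meta), truth


def synthetic_taxonomy(marker: str, n_taxa: int, seed: int = 0) -> TaxonomyTable:
    """Invent a plausible taxonomy: taxa grouped into genera (2-4 ASVs each),
    genera into a handful of phyla/classes; a few ASVs left unassigned."""
    rng = np.random.default_rng(seed)
    tids = taxon_ids(marker, n_taxa)
    phyla = [f"{marker}_phylum{i}" for i in range(4)]
    classes = [f"{marker}_class{i}" for i in range(6)]
    rows = []
    g = 0
    i = 0
    while i < n_taxa:
        size = int(rng.integers(1, 4))
        genus = f"{marker}_genus{g:03d}"
        ph = phyla[int(rng.integers(len(phyla)))]
        cl = classes[int(rng.integers(len(classes)))]
        for _ in range(size):
            if i >= n_taxa:
                break
            unassigned = rng.random() < 0.05
            rows.append(
                {
                    "kingdom": "Bacteria" if marker == "16S" else "Fungi",
                    "phylum": ph,
                    "class": cl,
                    "order": UNASSIGNED,
                    "family": UNASSIGNED,
                    "genus": UNASSIGNED if unassigned else genus,
                }
            )
            i += 1
        g += 1
    df = pd.DataFrame(rows, index=pd.Index(tids, name="taxon_id"))
    return TaxonomyTable(df, marker)
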