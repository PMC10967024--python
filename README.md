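# potatonet

Analytics for multi-location, two-arm (control vs treated) microbiome field
trials sampled at two timepoints (T0/T1) with paired 16S and ITS marker
count tables. The package covers:

- **`synthgen`** — synthetic trial generator: location-dominant
  Dirichlet-multinomial compositions, a treatment effect planted in one
  marker at T1, co-occurring / co-excluding taxon pairs coupled through
  Bernoulli latent factors, and yield linked to treatment, a
  network-structure proxy and metadata covariates. Everything planted is
  written to a truth record, so every downstream method is testable without
  external data.
- **`tables_io`** — strict TSV readers/writers for count tables, taxonomy,
  sample metadata and signed edge lists (plus GraphML export); genus
  aggregation that preserves per-sample totals exactly.
- **`diversity`** — rarefaction (exact without-replacement subsampling),
  rarefaction curves, Chao1/Shannon, Bray–Curtis, PCoA, sequential
  PERMANOVA with free or within-location permutations, envfit-style vector
  fitting, and location-centered constrained RDA on log(1+count) data with
  restricted (within-location) Freedman–Lane permutation tests.
- **`conet`** — signed presence–absence metanetworks: every qualifying
  taxon pair is tested against a fixed-margin hypergeometric null
  (permutation null available behind a flag), BH-corrected over both tail
  families; per-sample local network properties (Louvain modularity with
  restarts, transitivity, average path length) on the metanetwork subgraph
  induced by the taxa present in each sample, per sign.
- **`assocnet`** — cross-domain Spearman association network with BH
  q-values and Louvain clusters on the positive-edge subgraph; yield
  neighborhood extraction; genus-network preprocessing (rarefy, 20%
  prevalence filter with total-preserving remainder pooling, z-scored
  numeric metadata + one-hot design); prevalence-conditional degree
  permutation test; exact betweenness/degree summaries.
- **`coreda`** — core-microbiome prevalence profiles across detection
  thresholds with an all-locations core rule, location-constrained
  shared-taxa counts, and negative-binomial differential abundance
  (median-of-ratios size factors, Cox–Reid adjusted profile-likelihood
  dispersion, Wald test with a t reference).
- **`treatstats`** — location-standardized (z-score by location) Wilcoxon
  treated-vs-control comparisons, Kruskal–Wallis across locations, and
  T0→T1 net-change comparisons.
- **`pipeline` / CLI** — `potatonet run --config run.yaml` orchestrates all
  stages into a report directory with a JSON manifest; reruns are
  byte-identical under a fixed config.

## CLI

```bash
# full pipeline on a bundled synthetic trial
cat > run.yaml <<EOF
out_dir: report
seed: 7
n_locations: 6
n_taxa_per_marker: 50
library_size_range: [2000, 4000]
depths: {16S: 1000, ITS: 1200}
n_perm: 199
EOF
potatonet run --config run.yaml

# individual stages
potatonet alpha --counts report/counts_16S.tsv --depth 1000 --seed 1 --out alpha.tsv
potatonet conet-build --counts report/counts_16S.tsv --depth 1000 --seed 1 \
    --q 0.05 --min-prev 5 --out edges.tsv
potatonet permanova --counts report/counts_16S.tsv --metadata report/metadata.tsv \
    --depth 1000 --terms location,treatment,time --seed 1 --out permanova.tsv
potatonet degtest --edges edges.tsv --prevalence prev.tsv --group phylum \
    --perms 999 --seed 1 --out degtest.tsv
potatonet da --counts report/counts_ITS.tsv --metadata report/metadata.tsv \
    --taxonomy report/taxonomy_ITS.tsv --level genus --out da.tsv
```

Defaults follow the published analysis: rarefaction depths 10,000 (16S) /
18,750 (ITS), 20% genus prevalence filter, BH q < 0.05 edges, core
membership at detection 0.01 with 25% prevalence in all locations.

## Acceptance

Acceptance is property-based (graph-property and hypergeometric oracles,
FDR control, planted-effect recovery, type-I calibration, conservation and
byte-identical round trips) and lives in `tests/test_acceptance.py`. The
report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes a compact self-check of the same quantities and writes the
(empty — no numeric targets are defined) acceptance JSON; a failed
self-check exits non-zero.
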