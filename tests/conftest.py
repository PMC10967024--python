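import numpy as np
import pandas as pd
import pytest

from potatonet import synthgen
from potatonet.tables_io import CountTable, SampleFrame, TaxonomyTable


@pytest.fixture
def toy_counts() -> CountTable:
    counts = np.array(
        [
            [5, 3, 0, 2],
            [0, 4, 4, 2],
            [1, 1, 2, 6],
        ]
    )
    return CountTable(["s1", "s2", "s3"], ["t1", "t2", "t3", "t4"], counts, "16S")


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    df = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 4,
            "phylum": ["P1", "P1", "P2", "P2"],
            "genus": ["GA", "GA", "GB", "unassigned"],
        },
        index=pd.Index(["t1", "t2", "t3", "t4"], name="taxon_id"),
    )
    return TaxonomyTable(df, "16S")


@pytest.fixture
def toy_frame() -> SampleFrame:
    df = pd.DataFrame(
        {
            "location": ["L1", "L1", "L2"],
            "treatment": ["control", "treated", "control"],
            "timepoint": ["T0", "T0", "T1"],
            "yield": [np.nan, np.nan, 410.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return SampleFrame(df)


@pytest.fixture(scope="session")
def small_trial():
    """A modest synthetic trial reused across tests (deterministic)."""
    design = synthgen.TrialDesign(
        n_locations=5,
        n_replicates_per_arm=3,
        n_taxa_per_marker=40,
        library_size_range=(800, 1200),
        seed=11,
    )
    effects = synthgen.PlantedEffects(
        cooccur_pairs={"16S": [(1, 2), (3, 4)]},
        coexclude_pairs={"16S": [(5, 6)]},
        treated_taxa={"ITS": {0: 1.5, 1: 1.5}},
        yield_model=synthgen.YieldModel(treatment_pct=12.0, proxy_coef=10.0),
    )
    return synthgen.generate_trial(design, effects)
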