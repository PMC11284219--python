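import numpy as np
import pandas as pd
import pytest

from seqrunqc import (
    SyntheticConfig,
    TaxonCountTable,
    TaxonomyLineage,
    SampleMetadata,
    aggregate_to_rank,
    build_taxonomy,
    simulate_study,
)
from seqrunqc.synthetic import RunSpec, AberrantBias, SiteEffect


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Compact study: 2 sites x 2 plots x 2 reps x 3 libraries x 6 runs."""
    defaults = dict(
        n_phyla=8, n_classes_per_phylum=2, n_genera_per_class=4,
        n_species_per_genus=3, n_plots=2, n_replicates=2, seed=seed,
        runs=[
            RunSpec("Lab1", depth=25_000, reference=True),
            RunSpec("Lab2a", depth=22_000, aberrant=True),
            RunSpec("Lab2b", depth=20_000),
            RunSpec("Lab4", depth=26_000, reference=True),
            RunSpec("Lab5", depth=8_000, quality_removed=0.30),
            RunSpec("Lab6", depth=40_000),
        ],
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def study():
    """One simulated small study shared across tests."""
    cfg = small_config(seed=42)
    table, metadata, funnels, truth = simulate_study(cfg)
    return dict(config=cfg, table=table, metadata=metadata,
                funnels=funnels, truth=truth,
                lineage=build_taxonomy(cfg))


@pytest.fixture(scope="session")
def genus_table(study):
    return aggregate_to_rank(study["table"], study["lineage"], "genus")


@pytest.fixture
def tiny_table():
    data = pd.DataFrame([[3, 0, 2], [1, 2, 0], [4, 4, 4]],
                        index=["s1", "s2", "s3"], columns=["t1", "t2", "t3"])
    return TaxonCountTable(data, rank="species")


@pytest.fixture
def tiny_lineage():
    df = pd.DataFrame(
        {"genus": ["g1", "g1", "g2"], "class": ["c1", "c1", "c1"],
         "phylum": ["p1", "p1", "p1"]}, index=["t1", "t2", "t3"])
    return TaxonomyLineage(df)


def random_count_table(rng: np.random.Generator, n_samples: int = 5,
                       n_taxa: int = 8, depth: int = 200) -> TaxonCountTable:
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_taxa)), size=n_samples)
    return TaxonCountTable(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)],
                     columns=[f"t{j}" for j in range(n_taxa)]))
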