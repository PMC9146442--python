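import numpy as np
import pandas as pd
import pytest

from microcohort.core_tables import AbundanceTable, TaxonLineage


def make_lineage(taxon_id, phylum="Firmicutes", genus=None):
    """Fully assigned lineage down to genus (placeholder middle ranks)."""
    return TaxonLineage(
        taxon_id=taxon_id,
        kingdom="Bacteria",
        phylum=phylum,
        class_=f"{phylum}_cls",
        order=f"{phylum}_ord",
        family=f"{phylum}_fam",
        genus=genus or taxon_id,
    )


def make_table(counts, taxon_ids=None, sample_ids=None, phyla=None, mode="counts"):
    counts = np.asarray(counts)
    n, m = counts.shape
    taxon_ids = taxon_ids or [f"g{j}" for j in range(m)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    phyla = phyla or ["Firmicutes"] * m
    lineages = {t: make_lineage(t, phylum=p) for t, p in zip(taxon_ids, phyla)}
    return AbundanceTable(
        data=pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        lineages=lineages,
        mode=mode,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220520)


@pytest.fixture
def random_counts_table(rng):
    counts = rng.integers(0, 200, size=(12, 20))
    counts[:, 0] += 1  # no all-zero samples
    return make_table(counts)
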