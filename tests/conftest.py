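import numpy as np
import pytest

import samniche as sn


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across the suite."""
    adata, truth = sn.generate_dataset(sn.SimConfig(seed=7))
    return adata, truth


@pytest.fixture(scope="session")
def qc_dataset(default_dataset):
    adata, truth = default_dataset
    adata = sn.filter_nuclei(adata, min_features=100, min_reads=1000)
    adata = sn.filter_features(adata, min_nuclei=4)
    return adata, truth


@pytest.fixture(scope="session")
def seed_panels(qc_dataset):
    """(seed ids, cycle marker ids, TE ids) present after QC."""
    adata, truth = qc_dataset
    seeds = [s for s in truth.seed_gene_ids if s in adata.var_names]
    cyc = [m for m in ("HTR13", "CDT1A", "CYCB1.1") if m in adata.var_names]
    te_ids = list(adata.var_names[adata.var["kind"] == "transposon"])
    return seeds, cyc, te_ids


@pytest.fixture(scope="session")
def adjusted_te_profiles(qc_dataset, seed_panels):
    """Adjusted correlations of all TEs against the seed+cycle panel."""
    adata, _ = qc_dataset
    seeds, cyc, te_ids = seed_panels
    adj = sn.adjusted_from_counts(adata, n_null=100, seed=7,
                                  feature_subset=seeds + cyc + te_ids)
    profiles = sn.extract_seed_profiles(
        adj, sn.SeedGeneSet(seeds + cyc, label="GESS+cellcycle"), te_ids)
    return adj, profiles


@pytest.fixture(scope="session")
def independent_dataset():
    """Depth-heterogeneous matrix with all planted programs disabled."""
    cfg = sn.SimConfig(seed=5, n_genes=200, n_tes=50,
                       marker_effect=1.0, te_program_effect=1.0)
    return sn.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
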