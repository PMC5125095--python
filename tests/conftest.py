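import numpy as np
import pytest

from multigwas import mlm, simdata


@pytest.fixture(scope="session")
def small_dataset():
    """One 300-sample, 20-block dataset with phenotype, kinship and REML fit."""
    cfg = simdata.SimConfig(n_samples=300, n_blocks=20, seed=123, missing_rate=0.0)
    G, truth = simdata.simulate_genotypes(cfg)
    pheno = simdata.simulate_phenotype(G, truth, cfg)
    y = pheno["adg"].to_numpy(dtype=float)
    K = mlm.compute_kinship(G, seed=0)
    W = mlm.design_matrix(pheno)
    vc = mlm.reml_variance_components(y, W, K)
    return {
        "cfg": cfg, "G": G, "truth": truth, "pheno": pheno,
        "y": y, "K": K, "W": W, "vc": vc,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
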