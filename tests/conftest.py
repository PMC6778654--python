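import numpy as np
import pandas as pd
import pytest

from ascna import beta_core, simulate
from ascna.ploidy_admixture import compute_dna_admixture, compute_ploidy


@pytest.fixture(scope="session")
def small_error_table():
    """A quickly built error table for tests that exercise the lookup."""
    return beta_core.build_error_table(
        nsnps_grid=(10, 50, 200), cov_grid=(20, 100, 200),
        beta_grid=(0.5, 1.0), reps=200, seed=5)


@pytest.fixture(scope="session")
def diploid_sim():
    return simulate.simulate_tumor(simulate.fixture_model("diploid-clean"),
                                   seed=7)


@pytest.fixture(scope="session")
def diploid_bt(diploid_sim):
    return beta_core.compute_beta_table(diploid_sim.seg_tb,
                                        diploid_sim.pileup_tumor,
                                        diploid_sim.pileup_normal)


@pytest.fixture(scope="session")
def diploid_estimates(diploid_bt):
    pl = compute_ploidy(diploid_bt)
    adm = compute_dna_admixture(diploid_bt, pl)
    return pl, adm


@pytest.fixture(scope="session")
def aneuploid_bt():
    sim = simulate.simulate_tumor(simulate.fixture_model("aneuploid-shifted"),
                                  seed=3)
    return beta_core.compute_beta_table(sim.seg_tb, sim.pileup_tumor,
                                        sim.pileup_normal)


@pytest.fixture(scope="session")
def subclonal_sim():
    return simulate.simulate_tumor(simulate.fixture_model("subclonal"), seed=11)


def synthetic_beta_table(logr, beta, nsnps=50, cov=100.0, n_beta=1.0,
                         length=1_000_000, err=0.04):
    """Hand-built beta table rows for estimator tests that need exact input."""
    logr = np.asarray(logr, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = logr.size
    starts = np.arange(n, dtype=np.int64) * (length + 1) + 1
    return pd.DataFrame({
        "sample": "synthetic",
        "chrom": "chr1",
        "start": starts,
        "end": starts + length - 1,
        "logR": logr,
        "beta": beta,
        "nsnps": np.full(n, nsnps),
        "cov": np.full(n, float(cov)),
        "n_beta": np.full(n, float(n_beta)),
        "beta_min": np.clip(beta - err, 0, 1),
        "beta_max": np.clip(beta + err, 0, 1),
    })
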