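import numpy as np
import pandas as pd
import pytest

from coassoc.data_io import MISSING, EnvMatrix, FreqMatrix, PopulationFrame, SnpTable


@pytest.fixture
def toy_snp_table():
    """10 diploid individuals in 3 populations, 3 SNPs with hand-set genotypes.

    SNP A: common, fully genotyped. SNP B: rare (MAF below 5%).
    SNP C: heavily missing.
    """
    geno = np.array([
        # A  B  C
        [0, 0, MISSING],
        [1, 0, MISSING],
        [2, 0, MISSING],
        [1, 0, MISSING],
        [0, 0, MISSING],
        [1, 0, MISSING],
        [2, 0, MISSING],
        [1, 1, MISSING],
        [0, 0, MISSING],
        [1, 0, 2],
    ])
    inds = [f"i{k}" for k in range(10)]
    pops = {f"i{k}": ("p1" if k < 4 else "p2" if k < 8 else "p3") for k in range(10)}
    return SnpTable(
        snp_ids=["A", "B", "C"],
        contig_ids=["g1", "g1", "g2"],
        positions=[10, 20, 30],
        derived_known=[True, True, False],
        genotypes=geno,
        individual_ids=inds,
        pop_of_individual=pops,
    )


@pytest.fixture
def toy_pops():
    return PopulationFrame(pd.DataFrame({
        "latitude": [50.0, 52.0, 54.0],
        "longitude": [-120.0, -122.0, -124.0],
        "elevation": [800.0, 900.0, 1000.0],
        "n_individuals": [4, 4, 2],
    }, index=pd.Index(["p1", "p2", "p3"], name="pop_id")))


@pytest.fixture
def random_freqs():
    """20 populations x 40 SNPs of iid allele frequencies."""
    rng = np.random.default_rng(11)
    pops = [f"p{i}" for i in range(20)]
    snps = [f"s{i}" for i in range(40)]
    f = pd.DataFrame(rng.uniform(0.05, 0.95, (20, 40)), index=pops, columns=snps)
    n = pd.DataFrame(50, index=pops, columns=snps)
    return FreqMatrix(f, n)


@pytest.fixture
def random_envs():
    rng = np.random.default_rng(12)
    pops = [f"p{i}" for i in range(20)]
    cols = [f"e{i}" for i in range(5)]
    return EnvMatrix(pd.DataFrame(rng.standard_normal((20, 5)),
                                  index=pops, columns=cols))


@pytest.fixture(scope="session")
def ibd_sim_with_selection():
    """One desk-scale IBD landscape with selected loci, reused across tests."""
    from coassoc.simulate import SimulationConfig, simulate_landscape

    cfg = SimulationConfig(width=32, height=32, capacity=25, n_neutral=200,
                           n_selected=10, demography="IBD", seed=77)
    return simulate_landscape(cfg)


@pytest.fixture(scope="session")
def ibd_study(ibd_sim_with_selection):
    """Association layers + truth for the shared IBD landscape."""
    from coassoc.evaluation import simulation_association_study

    return simulation_association_study(ibd_sim_with_selection, n_pops=250,
                                        seed=77)
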