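import numpy as np
import pandas as pd
import pytest

from rhizonet.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """30 hosts, 10+10 OTUs, 300 SNPs, two planted SNPs."""
    cfg = SimulationConfig(
        n_hosts=30,
        n_bacteria=10,
        n_fungi=10,
        n_snps=300,
        n_causal=2,
        effect_size=1.0,
        seed=42,
    )
    geno, taxonomy, abundance, truth = simulate_all(cfg)
    return cfg, geno, taxonomy, abundance, truth


@pytest.fixture(scope="session")
def toy_taxonomy():
    return pd.DataFrame(
        {
            "otu_id": [1, 2, 3, 4],
            "kingdom": ["bacteria", "bacteria", "fungi", "fungi"],
            "phylum": ["Proteobacteria", "Actinobacteria", "Ascomycota", "Ascomycota"],
            "class": [
                "Betaproteobacteria",
                "Actinobacteria",
                "Leotiomycetes",
                "Sordariomycetes",
            ],
        }
    ).set_index("otu_id")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
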