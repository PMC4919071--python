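import numpy as np
import pytest

from mampscan import synthetic_data as sd
from mampscan.datatypes import GenotypeDataset


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Desk-scale study small enough for per-module tests."""
    return sd.SimulationConfig(
        n_samples=120,
        n_snps=1500,
        chromosome_lengths={str(c): 1_000_000 for c in range(1, 4)},
        n_genes=150,
        traits=[
            sd.TraitConfig("elf18_DC", "elf18", [(sd._gene_id(100), 10.0)], 0.3, 42.0),
            sd.TraitConfig("elf18_Ps", "elf18", [(sd._gene_id(30), 6.0)], 0.3, 40.0),
            sd.TraitConfig("flg22_Pa", "flg22", [(sd._gene_id(70), 6.0)], 0.3, 40.0),
            sd.TraitConfig("flg22_Pv", "flg22", [], 0.0, 6.0),
        ],
        shared_loci={
            "elf18": [(sd._gene_id(10), 8.0)],
            "flg22": [(sd._gene_id(120), 8.0)],
        },
        lof_fraction={"elf18": 0.02, "flg22": 0.06},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> sd.SimulatedStudy:
    return sd.simulate_study(small_config)


@pytest.fixture()
def toy_genotypes() -> GenotypeDataset:
    """6 samples x 8 SNPs on two chromosomes, deterministic, no missing."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
    calls[:, 0] = [0, 0, 0, 1, 1, 1]  # guaranteed polymorphic
    return GenotypeDataset.create(
        [f"s{i}" for i in range(6)],
        [f"m{j}" for j in range(8)],
        ["1"] * 4 + ["2"] * 4,
        [100, 500, 900, 1300, 100, 500, 900, 1300],
        ["A"] * 8,
        ["T"] * 8,
        calls,
    )
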