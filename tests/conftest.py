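import numpy as np
import pandas as pd
import pytest

from clinepop.genio import LOCUS_COLUMNS, GenotypeTable
from clinepop.simdata import SimulationConfig, TraitParams, generate_dataset


def make_table(dosages, pops, scaffold=None, position=None):
    """Build a GenotypeTable from a dosage matrix and per-sample pop labels."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    samples = [f"s{i}" for i in range(n)]
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j}" for j in range(L)],
            "scaffold": scaffold if scaffold is not None else ["sc1"] * L,
            "position": position if position is not None else np.arange(1, L + 1) * 100,
            "ref": ["A"] * L,
            "alt": ["G"] * L,
        }
    )[LOCUS_COLUMNS]
    return GenotypeTable(samples, dict(zip(samples, pops)), loci, dosages)


@pytest.fixture
def two_pop_table():
    """2 pops x 5 samples, 4 loci with mixed dosage patterns."""
    dos = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [0, 0, 2, 1],
            [2, 1, 2, 0],
            [1, 0, 2, 0],
            [2, 1, 0, 2],
            [2, 2, 0, 2],
            [1, 1, 0, 1],
            [2, 2, 0, 2],
            [2, 1, 0, 2],
        ],
        dtype=float,
    )
    return make_table(dos, ["p1"] * 5 + ["p2"] * 5)


@pytest.fixture(scope="session")
def balanced_sim():
    """Medium simulation shared across tests: 9 pops x 10, F = 0.05."""
    cfg = SimulationConfig(
        n_geno=(10,) * 9,
        n_pheno=(15,) * 9,
        n_neutral=2000,
        n_clinal=20,
        F=0.05,
        missing_rate=0.02,
        seed=20260131,
        traits={
            "bill_length": TraitParams(8.0, 0.4, 0.02, 0.0),
            "wing": TraitParams(60.0, 0.0, 2.0, 0.0),
        },
    )
    return generate_dataset(cfg)
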