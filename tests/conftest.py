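import numpy as np
import pandas as pd
import pytest

from bivarped.io import PedRecord
from bivarped.pedigree import build_pedigree, kinship
from bivarped.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def nuclear_records():
    """One nuclear family: founder couple + three children."""
    return [
        PedRecord("F1", "dad", None, None, "male"),
        PedRecord("F1", "mom", None, None, "female"),
        PedRecord("F1", "kid1", "dad", "mom", "male"),
        PedRecord("F1", "kid2", "dad", "mom", "female"),
        PedRecord("F1", "kid3", "dad", "mom", "male"),
    ]


@pytest.fixture
def three_gen_records():
    """Three generations: grandparents, two children with spouses, cousins."""
    recs = [
        PedRecord("F1", "gp1", None, None, "male"),
        PedRecord("F1", "gp2", None, None, "female"),
        PedRecord("F1", "a", "gp1", "gp2", "male"),
        PedRecord("F1", "b", "gp1", "gp2", "female"),
        PedRecord("F1", "a_sp", None, None, "female"),
        PedRecord("F1", "b_sp", None, None, "male"),
        PedRecord("F1", "a_kid", "a", "a_sp", "male"),
        PedRecord("F1", "b_kid", "b_sp", "b", "female"),
    ]
    return recs


@pytest.fixture(scope="session")
def sim_small():
    """Shared small simulated cohort: 150 nuclear families of 2 sibs."""
    cfg = SimulationConfig(seed=101, n_pedigrees=150, structure=("nuclear", 2),
                           n_markers=20)
    ped, g, pheno, errors = simulate_dataset(cfg)
    return {"cfg": cfg, "ped": ped, "g": g, "pheno": pheno,
            "phi": kinship(ped), "errors": errors}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
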