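import numpy as np
import pytest
from hypothesis import settings

from syndeep.featnet import FeatureSchema
from syndeep.labels import EXCLUDED, balance_classes
from syndeep.synth import (SynthConfig, center_signal, generate_universe,
                           plant_labels, random_signal)
from syndeep.universe import RelationalUniverse

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def toy_universe():
    """Hand-built universe small enough to verify every profile by eye.

    Schema widths: DT=4, GM=2, GE=2, DM=2, CF=3 per drug, CL=3
    -> group VI pair-vector length 4+2+2+2+6+2+3 = 21.
    """
    return RelationalUniverse(
        drugs=["A", "B", "C"],
        cell_lines=["cl1", "cl2", "cl3"],
        targets=["T1", "T2", "T3", "T4"],
        proteins=["P5", "P6", "T1", "T2", "T3", "T4"],
        metabolites=["M1", "M2"],
        dt_edges={("A", "T1"), ("B", "T2"), ("B", "T3"), ("C", "T1"), ("C", "T4")},
        ppi_edges={("P5", "T1"), ("P6", "T2"), ("T2", "T3")},
        pmi_edges={("T2", "M1"), ("T4", "M2")},
        gm_assoc={("T1", "gm1"), ("T2", "gm2")},
        ge_assoc={("T3", "ge1"), ("T4", "ge2")},
        dm_assoc={("T1", "dm1"), ("T4", "dm2")},
        chem={
            "A": np.array([1.0, 0.0, 2.5]),
            "B": np.array([0.0, 3.0, -1.0]),
            "C": np.array([2.0, 1.0, 0.5]),
        },
    )


@pytest.fixture(scope="session")
def planted_universe():
    """Small synthetic universe with a strong centered planted signal."""
    cfg = SynthConfig(n_drugs=24, n_cell_lines=6, n_targets=30, n_proteins=60,
                      n_metabolites=25, n_gm=10, n_ge=10, n_dm=10, n_fp=16,
                      n_desc=7, edge_density=0.1, noise_sd=0.1,
                      additive_fraction=0.05, seed=11)
    universe = generate_universe(cfg)
    schema = FeatureSchema.from_universe(universe)
    signal = center_signal(universe, random_signal(schema, seed=11, scale=1.0), cfg)
    records = plant_labels(universe, signal, cfg)
    return universe, schema, signal, records, cfg


@pytest.fixture(scope="session")
def planted_balanced(planted_universe):
    universe, schema, signal, records, cfg = planted_universe
    labeled = [r for r in records if r.label != EXCLUDED]
    return universe, schema, signal, balance_classes(labeled, seed=5)
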