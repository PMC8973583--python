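"""Shared fixtures: small molecule sets and one cached reduced-scale
experiment reused by several end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from fmx.chemio import LabeledDataset, MoleculeRecord
from fmx.graphga import GAConfig
from fmx.pipeline import ExperimentConfig, FailureModeExperiment
from fmx.triad import MODIFIED_FOREST


def record(smiles: str, id: str | None = None) -> MoleculeRecord:
    rec = MoleculeRecord.from_smiles(smiles, id=id)
    assert rec is not None, f"fixture SMILES failed to parse: {smiles}"
    return rec


@pytest.fixture(scope="session")
def alkane_ether_dataset() -> LabeledDataset:
    """100 unique molecules, 10 'active' linear alcohols: stratification toy."""
    smiles = ["OC" + "C" * n for n in range(1, 11)]  # 10 actives
    smiles += ["C" * n for n in range(1, 31)]
    smiles += ["CC(C)" + "C" * n for n in range(1, 31)]
    smiles += ["COC" + "C" * n for n in range(1, 31)]
    records = [record(s, id=f"toy:{i}") for i, s in enumerate(smiles)]
    labels = [1] * 10 + [0] * 90
    assert len(records) == 100 and len({r.smiles for r in records}) == 100
    return LabeledDataset(records, labels, name="toy100")


@pytest.fixture(scope="session")
def separable_dataset() -> LabeledDataset:
    """Perfectly separable set: actives carry a sulfonamide, inactives do not."""
    actives = [f"NS(=O)(=O)c1ccccc1{'C' * n}" for n in range(0, 10)]
    inactives = [("c1ccccc1" + "C" * n) for n in range(1, 11)]
    records = [record(s) for s in actives + inactives]
    return LabeledDataset(records, [1] * 10 + [0] * 10, name="separable")


@pytest.fixture(scope="session")
def concordant_experiment():
    """One reduced-scale end-to-end run on the concordant regime.

    Session-scoped because it is the most expensive fixture; several
    end-to-end properties are asserted against the same results object.
    """
    config = ExperimentConfig(
        classifier=MODIFIED_FOREST,
        ga=GAConfig(population_size=50, n_generations=30),
        n_runs=3,
        seed=0,
    )
    model = FailureModeExperiment.from_synthetic("concordant", seed=0, config=config)
    return model.fit()
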