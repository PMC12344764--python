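"""Shared fixtures: synthetic universes and small trained models.

Everything is generated programmatically and deterministically; the
expensive fixtures (the full-size universe and the retention experiment)
are session-scoped so they are built exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import hetretro as hr
from hetretro.predictor import ModelConfig, SingleStepModel, build_vocab, reaction_to_pair


@pytest.fixture(scope="session")
def tiny_universe() -> hr.ToyUniverse:
    """Small universe for fast unit tests."""
    return hr.generate_universe(11, hr.UniverseSizes(60, 40, 12, 40, 8))


@pytest.fixture(scope="session")
def universe() -> hr.ToyUniverse:
    """Study-scale universe: 500 general / 200 ring reactions, 20 routes."""
    return hr.generate_universe(7, hr.UniverseSizes(500, 200, 50, 100, 20))


@pytest.fixture(scope="session")
def forgetting_table(universe):
    """The retention experiment over three seeds (the expensive fixture)."""
    return hr.forgetting_experiment(universe, seeds=(0, 1, 2))


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_universe) -> SingleStepModel:
    """A small retro model trained briefly on the tiny general corpus."""
    records = tiny_universe.corpora["general_like"]
    pairs = [reaction_to_pair(rec) for rec in records]
    vocab = build_vocab(tok for pair in pairs for tok in pair)
    model = SingleStepModel(vocab, "retro", ModelConfig(d_model=48, beam_size=5), seed=3)
    rng = np.random.default_rng(3)

    def batches():
        while True:
            idx = rng.choice(len(pairs), size=16)
            yield [pairs[i] for i in idx]

    model.train_steps(batches(), 200)
    return model


@pytest.fixture(scope="session")
def all_molecules(universe) -> list[str]:
    """Canonical SMILES of every molecule in the study-scale universe."""
    seen: set[str] = set()
    for records in universe.corpora.values():
        for rec in records:
            for mol in rec.reactants + rec.reagents + rec.products:
                seen.add(mol.smiles)
    seen.update(universe.building_blocks)
    return sorted(seen)
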