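"""Shared fixtures: a small imbalanced molecule set and cached experiment runs.

The heavy objects (conformer descriptor cache, nested-CV runs) are
session-scoped so the structural-integrity, leakage and directional
tests all audit the same runs.
"""

from __future__ import annotations

import logging

import pytest

from cover import features, pipeline, synthetic
from cover.validation import ConformerFeatureCache, folds_from_molecules

logging.disable(logging.WARNING)

# single grid point: keeps nested-CV runs small while exercising the
# full inner/outer machinery
TOY_GRID = {
    "learning_rate": [0.1],
    "hidden_units": [32],
    "dropout_input": [0.0],
    "dropout_hidden": [0.2],
    "n_layers": [2],
}

TOY_SPEC = synthetic.ToySpec(n_neg=64, n_pos=4, seed=7, label_noise=0.05)


@pytest.fixture(scope="session")
def toy_mols():
    return synthetic.make_molecule_dataset(TOY_SPEC)


@pytest.fixture(scope="session")
def toy_folds(toy_mols):
    return folds_from_molecules(toy_mols, 5, seed=1)


@pytest.fixture(scope="session")
def shared_cache(toy_mols):
    return ConformerFeatureCache(toy_mols, conformer_seed=1, config=features.DescriptorConfig())


def _run(toy_mols, toy_folds, shared_cache, mode, balance, network_seed):
    cfg = pipeline.RunConfig(
        mode=mode,
        base_factor=1,
        balance=balance,
        grid=TOY_GRID,
        conformer_seed=1,
        fold_seed=1,
        network_seed=network_seed,
        max_epochs=150,
        batch_size=32,
    )
    return pipeline.run_experiment(toy_mols, cfg, folds=toy_folds, cache=shared_cache)


@pytest.fixture(scope="session")
def cover_runs(toy_mols, toy_folds, shared_cache):
    """COVER-balanced nested-CV runs for three network seeds."""
    return {s: _run(toy_mols, toy_folds, shared_cache, "cover", True, s) for s in (11, 12, 13)}


@pytest.fixture(scope="session")
def baseline_runs(toy_mols, toy_folds, shared_cache):
    """Single-conformer (no augmentation) runs for the same seeds."""
    return {s: _run(toy_mols, toy_folds, shared_cache, "none", False, s) for s in (11, 12, 13)}
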