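"""End-to-end experiment runner.

Wires the modules into one reproducible workflow: clustered fold
construction, per-split augmentation (conformational oversampling /
SMOTE / none), nested cross-validated training, evaluation, and
descriptive statistics.  Every results dict embeds the full run
configuration, the seeds and the library versions, and serialises to
byte-identical JSON for equal inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import features, metrics, validation
from .model import HyperparameterSet, TrainConfig
from .standardize import MoleculeRecord
from .validation import AugmentSpec, FoldAssignment, NestedCvResult


@dataclass
class RunConfig:
    """Everything that determines one experiment run."""

    mode: str = "cover"              # cover | smote | none
    base_factor: int = 1
    balance: bool = True
    k_folds: int = 5
    conformer_seed: int = 1
    fold_seed: int = 1
    network_seed: int = 1
    grid: dict | None = None         # None -> full default grid (180 points)
    descriptor_sets: tuple[str, ...] = features.DESCRIPTOR_SETS
    patience: int = 20
    max_epochs: int = 500
    batch_size: int = 128
    ensemble_k: int = 1
    fold_strategy: str = "random"

    def augment_spec(self) -> AugmentSpec:
        mode = "none" if self.mode == "none" else self.mode
        return AugmentSpec(mode=mode, base_factor=self.base_factor, balance=self.balance)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            patience=self.patience,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            network_seed=self.network_seed,
        )


def _versions() -> dict:
    import rdkit
    import sklearn

    from . import __version__

    return {
        "cover": __version__,
        "numpy": np.__version__,
        "rdkit": rdkit.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_experiment(
    molecules: Sequence[MoleculeRecord],
    config: RunConfig,
    folds: FoldAssignment | None = None,
    cache: validation.ConformerFeatureCache | None = None,
) -> dict:
    """Run one full experiment and return a JSON-serialisable results dict."""
    if folds is None:
        folds = validation.folds_from_molecules(
            molecules, config.k_folds, config.fold_seed, strategy=config.fold_strategy
        )
    grid = validation.grid_points(config.grid) if config.grid is not None else validation.grid_points()
    desc_cfg = features.DescriptorConfig(sets=tuple(config.descriptor_sets))
    result = validation.nested_cv(
        molecules,
        folds,
        config.augment_spec(),
        grid,
        config.train_config(),
        conformer_seed=config.conformer_seed,
        ensemble_k=config.ensemble_k,
        descriptor_config=desc_cfg,
        cache=cache,
    )
    return build_results(molecules, config, folds, result)


def build_results(
    molecules: Sequence[MoleculeRecord],
    config: RunConfig,
    folds: FoldAssignment,
    result: NestedCvResult,
) -> dict:
    pooled = result.pooled_evaluation()
    per_fold = [
        {
            "fold": f.fold_id,
            "best_hyperparameters": f.best_hp.__dict__,
            "evaluation": f.evaluation,
            "plan_tag": f.plan_tag,
            "n_train_rows": f.n_train_rows,
            "n_eval_molecules": len(f.parent_ids),
            "parent_ids": f.parent_ids,
            "y_true": f.y_true,
            "scores": f.scores,
            "train_parent_ids": f.train_parent_ids,
        }
        for f in result.outer
    ]
    complete = [f.evaluation for f in result.outer if f.evaluation.get("balanced_accuracy") is not None]
    summary = None
    if len(complete) >= 2:
        summary = metrics.summarize_models(complete).to_dict(orient="records")
    out = {
        "config": asdict(config),
        "seeds": {
            "conformers": config.conformer_seed,
            "folds": config.fold_seed,
            "network": config.network_seed,
        },
        "versions": _versions(),
        "n_molecules": len(molecules),
        "class_counts": {
            "negative": sum(1 for m in molecules if m.label == 0),
            "positive": sum(1 for m in molecules if m.label == 1),
        },
        "folds": {m: int(f) for m, f in sorted(folds.mol_to_fold.items())},
        "clusters": {m: int(c) for m, c in sorted(folds.mol_to_cluster.items())},
        "outer_folds": per_fold,
        "inner_trials": result.inner_trials,
        "pooled": pooled.to_dict(),
        "summary": summary,
    }
    return out


def results_to_json(results: dict) -> str:
    """Canonical serialisation (sorted keys) — equal runs give equal bytes."""
    return json.dumps(results, sort_keys=True, indent=2)
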