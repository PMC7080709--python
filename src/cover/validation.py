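"""Clustered nested cross-validation and baselines.

Folds are built from whole structural clusters (affinity propagation on
a Morgan-fingerprint Tanimoto matrix) so that train and evaluation
folds are structurally dissimilar.  The 5x4 nested scheme runs a grid
search in the inner loop, retrains the winning configuration on the
full inner pool, and evaluates on the held-out outer fold.

Augmentation (conformational oversampling or SMOTE) is applied to the
training molecules of each split only, *after* the split — evaluation
molecules never contribute training rows in any mode.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.neighbors import NearestNeighbors

from . import features, metrics, oversample
from .model import HyperparameterSet, MLPClassifier, TrainConfig, predict_labels
from .oversample import OversamplingPlan, make_plan
from .standardize import MoleculeRecord

logger = logging.getLogger(__name__)

#: Default hyperparameter grid: 3 learning rates x 5 layer widths x
#: 2 input dropouts x 2 hidden dropouts x 3 depths = 180 combinations.
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [0.01, 0.1, 1],
    "hidden_units": [256, 512, 1024, 2048, 4096],
    "dropout_input": [0, 0.2],
    "dropout_hidden": [0.2, 0.5],
    "n_layers": [2, 3, 4],
}

_GRID_FIELDS = ("learning_rate", "hidden_units", "dropout_input", "dropout_hidden", "n_layers")


def _derive_seed(*parts) -> int:
    h = hashlib.blake2b("|".join(str(p) for p in parts).encode(), digest_size=8)
    return (int.from_bytes(h.digest(), "big") & 0x7FFFFFFF) or 1


@dataclass
class FoldAssignment:
    mol_to_cluster: dict[str, int]
    mol_to_fold: dict[str, int]
    k_folds: int
    rng_seed: int

    def fold_members(self, fold: int) -> list[str]:
        return [m for m, f in self.mol_to_fold.items() if f == fold]


def cluster_folds(
    similarity: np.ndarray,
    mol_ids: Sequence[str],
    k_folds: int,
    seed: int,
    damping: float = 0.9,
    max_iter: int = 1000,
    preference: float | None = None,
    strategy: str = "random",
    fallback_threshold: float = 0.4,
) -> FoldAssignment:
    """Affinity-propagation clustering + cluster-wise random fold assignment.

    The cluster count emerges from the message passing; preference
    defaults to the median off-diagonal similarity.  Every molecule of a
    cluster lands in the same fold.  ``strategy="random"`` assigns each
    cluster to a uniformly random fold (redrawing deterministically if a
    fold would be empty); ``strategy="balanced"`` greedily packs
    clusters into the currently smallest fold.
    """
    sim = np.asarray(similarity, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n) or len(mol_ids) != n:
        raise ValueError("similarity must be square and match mol_ids")
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    off = sim[~np.eye(n, dtype=bool)]
    pref = float(np.median(off)) if preference is None else preference
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        max_iter=max_iter,
        preference=pref,
        random_state=seed,
    )
    labels = ap.fit_predict(sim)
    if len(ap.cluster_centers_indices_) == 0 or (labels < 0).any():
        logger.warning(
            "affinity propagation did not converge; falling back to "
            "connected components at similarity > %.2f",
            fallback_threshold,
        )
        from scipy.sparse.csgraph import connected_components

        adj = sim > fallback_threshold
        np.fill_diagonal(adj, True)
        _, labels = connected_components(adj, directed=False)
    clusters = sorted(set(int(l) for l in labels))
    mol_to_cluster = {mid: int(lab) for mid, lab in zip(mol_ids, labels)}

    def draw(try_idx: int) -> dict[int, int]:
        rng = np.random.default_rng(_derive_seed(seed, "fold-draw", try_idx))
        return {c: int(rng.integers(k_folds)) for c in clusters}

    if strategy == "balanced":
        rng = np.random.default_rng(_derive_seed(seed, "fold-balanced"))
        order = list(clusters)
        rng.shuffle(order)
        sizes = {c: sum(1 for l in labels if l == c) for c in clusters}
        order.sort(key=lambda c: -sizes[c])
        load = [0] * k_folds
        cluster_to_fold = {}
        for c in order:
            f = int(np.argmin(load))
            cluster_to_fold[c] = f
            load[f] += sizes[c]
    elif strategy == "random":
        cluster_to_fold = draw(0)
        if len(clusters) >= k_folds:
            # FoldAssignment contract: every fold non-empty; redraw
            # deterministically until satisfied.
            for t in range(1, 200):
                if len(set(cluster_to_fold.values())) == k_folds:
                    break
                cluster_to_fold = draw(t)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    mol_to_fold = {mid: cluster_to_fold[mol_to_cluster[mid]] for mid in mol_ids}
    return FoldAssignment(mol_to_cluster=mol_to_cluster, mol_to_fold=mol_to_fold, k_folds=k_folds, rng_seed=seed)


def folds_from_molecules(
    molecules: Sequence[MoleculeRecord], k_folds: int, seed: int, **kwargs
) -> FoldAssignment:
    """Convenience wrapper: fingerprints -> Tanimoto matrix -> cluster_folds."""
    fps = [features.morgan_fingerprint(m.smiles, mol_id=m.id) for m in molecules]
    sim = features.tanimoto_matrix(fps)
    return cluster_folds(sim, [m.id for m in molecules], k_folds, seed, **kwargs)


def grid_points(grid: Mapping[str, Sequence] | None = None) -> list[HyperparameterSet]:
    """Full Cartesian product of the grid, in deterministic field order."""
    grid = dict(DEFAULT_GRID if grid is None else grid)
    unknown = set(grid) - set(_GRID_FIELDS)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    missing = [f for f in _GRID_FIELDS if f not in grid or len(grid[f]) == 0]
    if missing:
        raise ValueError(f"grid parameters missing or empty: {missing}")
    values = [grid[f] for f in _GRID_FIELDS]
    return [HyperparameterSet(**dict(zip(_GRID_FIELDS, combo))) for combo in itertools.product(*values)]


# ---- SMOTE ------------------------------------------------------------------


def smote_balance(X, y, k_neighbors: int = 5, seed: int = 0):
    """Synthetic minority oversampling in feature space.

    New minority rows are drawn on the segment between a minority point
    and one of its k nearest minority neighbours:
    ``x_new = x_i + u * (x_nn - x_i)`` with u ~ U[0, 1].  The output is
    balanced to the majority count.  Training data only — never give
    this function evaluation rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == n1:
        return X.copy(), y.copy()
    min_label = 1 if n1 < n0 else 0
    n_min = min(n0, n1)
    n_new = abs(n0 - n1)
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if k_neighbors > n_min - 1:
        logger.warning("k_neighbors reduced from %d to %d (minority size)", k_neighbors, n_min - 1)
        k_neighbors = n_min - 1
    Xmin = X[y == min_label]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)
    rng = np.random.default_rng(seed)
    new_rows = np.empty((n_new, X.shape[1]))
    for t in range(n_new):
        i = int(rng.integers(n_min))
        j = int(idx[i][1 + rng.integers(k_neighbors)])  # skip self at position 0
        u = rng.random()
        new_rows[t] = Xmin[i] + u * (Xmin[j] - Xmin[i])
    X_out = np.vstack([X, new_rows])
    y_out = np.concatenate([y, np.full(n_new, min_label, dtype=int)])
    return X_out, y_out


# ---- conformer feature cache ------------------------------------------------


class ConformerFeatureCache:
    """Descriptor rows per (molecule, conformer index), computed lazily.

    Conformer ``i`` of a molecule is deterministic in the generation
    seed alone (per-index seed derivation), so rows can be shared
    across folds and hyperparameter trials without changing results.
    """

    def __init__(
        self,
        molecules: Sequence[MoleculeRecord],
        conformer_seed: int,
        config: features.DescriptorConfig | None = None,
    ):
        self.molecules = {m.id: m for m in molecules}
        self.seed = conformer_seed
        self.config = config or features.DescriptorConfig()
        self._rows: dict[tuple[str, int], np.ndarray | None] = {}

    def _row(self, mol_id: str, conf_index: int) -> np.ndarray | None:
        key = (mol_id, conf_index)
        if key not in self._rows:
            from rdkit import Chem

            rec = self.molecules[mol_id]
            mol = Chem.MolFromSmiles(rec.smiles)
            row = None
            if mol is not None:
                s = oversample.conformer_seed(self.seed, mol_id, conf_index)
                m = oversample._embed_one(Chem.AddHs(mol), s)
                if m is not None:
                    try:
                        row = features.descriptor_row(m, self.config.sets)
                        if not np.isfinite(row).all():
                            row = None
                    except Exception:
                        row = None
            self._rows[key] = row
        return self._rows[key]

    def rows_for(self, mol_id: str, k: int) -> np.ndarray:
        """Up to k descriptor rows for one molecule (embedding failures skipped)."""
        rows = [r for r in (self._row(mol_id, i) for i in range(k)) if r is not None]
        return np.array(rows) if rows else np.empty((0, len(features.descriptor_names(self.config.sets))))


# ---- nested cross-validation ------------------------------------------------


@dataclass(frozen=True)
class AugmentSpec:
    """What to do to each training split: conformational oversampling
    ("cover"), feature-space interpolation ("smote"), or nothing."""

    mode: str = "cover"
    base_factor: int = 1
    balance: bool = True

    def __post_init__(self):
        if self.mode not in ("cover", "smote", "none"):
            raise ValueError("mode must be cover, smote or none")


@dataclass
class OuterFoldResult:
    fold_id: int
    best_hp: HyperparameterSet
    evaluation: dict
    parent_ids: list[str]
    y_true: list[int]
    scores: list[float]
    train_parent_ids: list[str]
    n_train_rows: int
    plan_tag: str | None


@dataclass
class NestedCvResult:
    outer: list[OuterFoldResult]
    inner_trials: list[dict]
    k_folds: int

    def pooled_evaluation(self) -> metrics.EvaluationResult:
        """Confusion metrics over the concatenated outer-fold predictions."""
        y = np.concatenate([f.y_true for f in self.outer])
        s = np.concatenate([f.scores for f in self.outer])
        return metrics.evaluate(y, predict_labels(s), scores=s)


def _class_counts(mols: Sequence[MoleculeRecord]) -> tuple[int, int]:
    n1 = sum(1 for m in mols if m.label == 1)
    return len(mols) - n1, n1


def _training_matrix(
    train_mols: Sequence[MoleculeRecord],
    augment: AugmentSpec,
    cache: ConformerFeatureCache,
    seed: int,
):
    """Assemble (X, y, parent_ids, plan) for one training split."""
    plan: OversamplingPlan | None = None
    rows, labels, parents = [], [], []
    if augment.mode == "cover":
        plan = make_plan([m.label for m in train_mols], augment.base_factor, augment.balance)
        per_mol = {m.id: plan.conformers_for(m.label) for m in train_mols}
    else:
        per_mol = {m.id: 1 for m in train_mols}
    for m in train_mols:
        r = cache.rows_for(m.id, per_mol[m.id])
        rows.append(r)
        labels.extend([m.label] * len(r))
        parents.extend([m.id] * len(r))
    X = np.vstack([r for r in rows if len(r)])
    y = np.asarray(labels, dtype=int)
    if augment.mode == "smote":
        n_before = len(y)
        X, y = smote_balance(X, y, seed=seed)
        parents = parents + ["synthetic"] * (len(y) - n_before)
    return X, y, parents, plan


def _eval_matrix(mols: Sequence[MoleculeRecord], cache: ConformerFeatureCache, k: int = 1):
    """One (or k, for ensemble evaluation) conformer rows per molecule."""
    X, y, pids, groups = [], [], [], {}
    for m in mols:
        r = cache.rows_for(m.id, k)
        if len(r) == 0:
            logger.warning("no conformer for evaluation molecule %s; skipped", m.id)
            continue
        groups[m.id] = r
        X.append(r[0])
        y.append(m.label)
        pids.append(m.id)
    return np.array(X), np.asarray(y, dtype=int), pids, groups


class _Scaler:
    def __init__(self, X: np.ndarray):
        self.center = X.mean(axis=0)
        self.scale = X.std(axis=0)
        self.scale[self.scale == 0] = 1.0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale


def _train_once(X, y, mX, my, hp: HyperparameterSet, cfg: TrainConfig, net_seed: int) -> MLPClassifier:
    local = TrainConfig(
        momentum=cfg.momentum,
        patience=cfg.patience,
        max_epochs=cfg.max_epochs,
        batch_size=cfg.batch_size,
        threshold=cfg.threshold,
        network_seed=net_seed,
        harmonic_monitor=cfg.harmonic_monitor,
    )
    model = MLPClassifier(hp, X.shape[1], local)
    model.fit(X, y, mX, my)
    return model


def _tie_break_key(mean_score: float, hp: HyperparameterSet):
    # prefer simpler, more regularised models on ties
    return (-mean_score, hp.hidden_units, hp.n_layers, -(hp.dropout_input + hp.dropout_hidden))


def nested_cv(
    molecules: Sequence[MoleculeRecord],
    folds: FoldAssignment,
    augment: AugmentSpec,
    grid: Sequence[HyperparameterSet] | None,
    train_config: TrainConfig,
    conformer_seed: int,
    ensemble_k: int = 1,
    descriptor_config: features.DescriptorConfig | None = None,
    cache: ConformerFeatureCache | None = None,
) -> NestedCvResult:
    """5x4 (generally kx(k-1)) nested cross-validation.

    For each outer fold the remaining folds form the inner pool; every
    grid point is scored by mean balanced accuracy over the inner
    folds, the winner is retrained on the whole inner pool (with a 10%
    class-stratified molecule-level monitor split for early stopping)
    and evaluated on the outer fold.
    """
    grid = list(grid) if grid is not None else grid_points()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    by_fold: dict[int, list[MoleculeRecord]] = {f: [] for f in range(folds.k_folds)}
    for m in molecules:
        by_fold[folds.mol_to_fold[m.id]].append(m)
    cache = cache or ConformerFeatureCache(molecules, conformer_seed, descriptor_config)
    outer_results: list[OuterFoldResult] = []
    inner_trials: list[dict] = []
    base_seed = train_config.network_seed
    for f in range(folds.k_folds):
        eval_mols = by_fold[f]
        pool = [m for g, ms in by_fold.items() if g != f for m in ms]
        if not eval_mols:
            logger.warning("outer fold %d empty; skipped", f)
            continue
        n0, n1 = _class_counts(pool)
        if n0 == 0 or n1 == 0:
            logger.warning("outer fold %d: single-class inner pool; skipped", f)
            continue
        inner_ids = [g for g in range(folds.k_folds) if g != f and by_fold[g]]
        trial_means: list[tuple[HyperparameterSet, float]] = []
        for hp_idx, hp in enumerate(grid):
            scores = []
            for g in inner_ids:
                tr = [m for h in inner_ids if h != g for m in by_fold[h]]
                va = by_fold[g]
                t0, t1 = _class_counts(tr)
                v0, v1 = _class_counts(va)
                if 0 in (t0, t1, v0, v1):
                    logger.warning("inner split (outer %d, held-out %d): single class; skipped", f, g)
                    continue
                X, y, _, _ = _training_matrix(tr, augment, cache, seed=_derive_seed(conformer_seed, f, g))
                sc = _Scaler(X)
                vX, vy, _, _ = _eval_matrix(va, cache)
                model = _train_once(
                    sc(X), y, sc(vX), vy, hp, train_config, _derive_seed(base_seed, "inner", f, g, hp_idx)
                )
                scores.append(model.best_monitor_score)
            mean_score = float(np.mean(scores)) if scores else float("nan")
            trial_means.append((hp, mean_score))
            inner_trials.append(
                {
                    "outer_fold": f,
                    "hp": hp.__dict__,
                    "inner_scores": scores,
                    "mean_balanced_accuracy": mean_score,
                }
            )
        valid = [(hp, s) for hp, s in trial_means if np.isfinite(s)]
        if valid:
            best_hp = min(valid, key=lambda t: _tie_break_key(t[1], t[0]))[0]
        else:
            # every inner split was degenerate (tiny minority class):
            # fall back to the tie-break-preferred grid point
            best_hp = min(grid, key=lambda hp: _tie_break_key(0.0, hp))
            logger.warning(
                "outer fold %d: no valid inner trial; falling back to %s", f, best_hp
            )
        # final retrain on the full inner pool with a stratified monitor split
        rng = np.random.default_rng(_derive_seed(base_seed, "monitor-split", f))
        monitor: list[MoleculeRecord] = []
        held_out_ids: set[str] = set()
        for lab in (0, 1):
            cls = [m for m in pool if m.label == lab]
            n_mon = max(1, int(round(0.1 * len(cls))))
            pick = rng.choice(len(cls), size=n_mon, replace=False)
            chosen = [cls[i] for i in pick]
            monitor.extend(chosen)
            # a class's only molecule is shared between train and monitor
            # rather than removed (early stopping must see both classes)
            if len(cls) - n_mon >= 1:
                held_out_ids.update(m.id for m in chosen)
        fit_mols = [m for m in pool if m.id not in held_out_ids]
        X, y, train_parents, plan = _training_matrix(
            fit_mols, augment, cache, seed=_derive_seed(conformer_seed, f, "final")
        )
        sc = _Scaler(X)
        mX, my, _, _ = _eval_matrix(monitor, cache)
        model = _train_once(sc(X), y, sc(mX), my, best_hp, train_config, _derive_seed(base_seed, "final", f))
        eX, ey, pids, groups = _eval_matrix(eval_mols, cache, k=ensemble_k)
        if ensemble_k > 1:
            fold_scores = np.array([float(np.mean(model.predict_scores(sc(groups[p])))) for p in pids])
        else:
            fold_scores = model.predict_scores(sc(eX))
        preds = predict_labels(fold_scores, train_config.threshold)
        tp, fp, tn, fn = metrics.confusion(ey, preds)
        evaluation: dict = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
        evaluation["sensitivity"] = metrics.sensitivity(tp, fn) if tp + fn else None
        evaluation["specificity"] = metrics.specificity(tn, fp) if tn + fp else None
        if evaluation["sensitivity"] is not None and evaluation["specificity"] is not None:
            evaluation["balanced_accuracy"] = metrics.balanced_accuracy(
                evaluation["sensitivity"], evaluation["specificity"]
            )
            evaluation["auc"] = metrics.auc(ey, fold_scores)
        else:
            evaluation["balanced_accuracy"] = None
            evaluation["auc"] = None
        outer_results.append(
            OuterFoldResult(
                fold_id=f,
                best_hp=best_hp,
                evaluation=evaluation,
                parent_ids=pids,
                y_true=[int(v) for v in ey],
                scores=[float(v) for v in fold_scores],
                train_parent_ids=sorted(set(train_parents) - {"synthetic"}),
                n_train_rows=len(y),
                plan_tag=plan.tag if plan else None,
            )
        )
    if not outer_results:
        raise RuntimeError("nested CV produced no evaluable outer fold")
    return NestedCvResult(outer=outer_results, inner_trials=inner_trials, k_folds=folds.k_folds)
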