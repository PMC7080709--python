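# cover — conformational oversampling for imbalanced molecular datasets

Training binary classifiers on toxicity endpoints usually means facing
small, heavily imbalanced datasets: a model can reach high accuracy and
AUC while predicting almost every compound into the majority (inactive)
class. `cover` implements **conformational oversampling**: instead of
inventing synthetic feature vectors, the minority class is enlarged by
generating multiple 3D conformations of each real molecule and treating
every conformation as an independent labeled training instance — the
cheminformatics analogue of crop/rotate augmentation in image learning.

Given per-class molecule counts n_maj and n_min, the integer imbalance
ratio is

    r = ⌊ n_maj / n_min ⌉        (rounded half up)

and a *balanced* "n–m" dataset generates `n` conformers per majority
molecule and `m = n·r` per minority molecule (`m = n` when only
enlarging, not balancing). Conformers are embedded with the ETKDG
distance-geometry algorithm and minimised with the UFF force field.

Around this core the package provides:

- **standardize** — fragment splitting, organic filtering, Group I/II
  metal-bond deletion, charge neutralization, functional-group
  normalization, solvent removal, InChIKey deduplication with
  label-conflict elimination.
- **features** — open 3D descriptor sets (inertial shape factors,
  radius of gyration, 3D autocorrelations, WHIM), Morgan fingerprints,
  Kabsch-aligned RMSD diversity summaries, PCA projections.
- **validation** — affinity-propagation *clustered* cross-validation
  folds, a 5×4 nested CV harness with grid search, and a SMOTE baseline
  implemented from its definition. Augmentation is always applied after
  splitting, to training molecules only.
- **model** — a feed-forward ReLU network (SGD, momentum 0.7,
  He-normal init, dropout) with early stopping on monitored balanced
  accuracy and mean-score ensemble prediction over conformers.
- **metrics** — sensitivity, specificity, balanced accuracy,
  trapezoidal ROC AUC, and descriptive statistics over model
  collections.
- **synthetic** — fixture generators whose labels are tied to a
  conformation-derived property (radius of gyration above the library
  median), so augmentation benefits are observable at toy scale.

## Worked example

Generate a 64 negative / 4 positive fixture, balance it by
conformational oversampling, and compare nested-CV training with and
without augmentation:

```bash
cover fixtures --n-neg 64 --n-pos 4 --seed 7 --out toy.csv
# wrote 68 molecules (4 positives) to toy.csv

cover oversample --in toy.csv --base-factor 1 --balance --seed 1 --out toy_1r.sdf
# plan 1-16 (r=16): wrote 128 conformers, 0 molecules with shortfalls

cat > grid.json <<'EOF'
{"learning_rate":[0.1],"hidden_units":[32],"dropout_input":[0.0],
 "dropout_hidden":[0.2],"n_layers":[2]}
EOF

cover train-nested --in toy.csv --mode cover --base-factor 1 --balance \
    --grid grid.json --seed 1 --network-seed 11 --max-epochs 150 --out results_cover.json
# pooled outer-fold metrics: sensitivity 1.000, specificity 0.797, balanced accuracy 0.898

cover train-nested --in toy.csv --mode none \
    --grid grid.json --seed 1 --network-seed 11 --max-epochs 150 --out results_none.json
# pooled outer-fold metrics: sensitivity 0.000, specificity 0.984, balanced accuracy 0.492
```

The pattern is the method's point: training on one conformer per
molecule (`--mode none`) yields a model that is specific but blind to
the minority class (sensitivity 0.0); balancing the training folds with
r conformers per positive (here r ≈ 16, recomputed per training split)
recovers the positives (sensitivity 1.0) at a modest specificity cost.
The results JSON embeds the full configuration, all seeds and library
versions, and is byte-identical across reruns with equal seeds.

Python API equivalent:

```python
from cover import ToySpec, make_molecule_dataset, RunConfig, run_experiment

mols = make_molecule_dataset(ToySpec(n_neg=64, n_pos=4, seed=7))
cfg = RunConfig(mode="cover", base_factor=1, balance=True,
                grid={"learning_rate": [0.1], "hidden_units": [32],
                      "dropout_input": [0.0], "dropout_hidden": [0.2],
                      "n_layers": [2]},
                conformer_seed=1, fold_seed=1, network_seed=11)
results = run_experiment(mols, cfg)
print(results["pooled"])
```

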