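# Methods

## The augmentation model

`cover` treats a molecule's 3D conformers as label-preserving
variations of one training example. For an imbalanced binary dataset
with n_maj majority and n_min minority molecules, the imbalance ratio
is r = round_half_up(n_maj / n_min), computed in exact integer
arithmetic (`floor((2·n_maj + n_min) / (2·n_min))`) so that e.g. 31/2 =
15.5 rounds to 16. A plan tagged "n-m" generates n conformers per
majority molecule and m per minority molecule, with m = n·r in balanced
mode and m = n otherwise. Each conformer becomes an independent row in
the descriptor matrix with the parent's label.

The conformations carry no claim of biological relevance (no energy
windows, no Boltzmann weighting, no pose selection, no RMSD-based
duplicate pruning — near-duplicate conformers of rigid molecules are
kept). They exist only to enlarge the training space while preserving
labels; balancing additionally reweights the loss toward the minority
class without duplicating identical rows.

Conformers are embedded by ETKDG distance geometry and minimised with
UFF (up to 200 iterations). Every conformer index receives its own
31-bit seed derived by hashing (generation seed, parent id, conformer
index), which makes conformer i bit-reproducible regardless of how
many conformers are requested — this is what allows descriptor rows to
be cached and shared across folds and trials without changing any
result. Embedding failures leave a molecule with fewer conformers than
planned; the shortfall is recorded and never compensated by resampling
other molecules.

## Standardization

The cleaning pipeline is: split into connected fragments → keep
fragments with ≥1 carbon → per fragment: delete covalent bonds to
Group I/II metals (charges adjusted to the ionic pair), neutralize,
apply the normalization rule table, neutralize again (the second pass
is usually a no-op, kept for symmetry with the two-pass design) →
drop solvent fragments → keep the largest surviving fragment →
InChIKey → deduplicate. Duplicate keys with identical labels collapse
to the first record; conflicting labels remove the compound entirely.
Every rejection is reported with stage and reason.

Design choices worth noting:

- The normalization rules are an explicit, enumerable SMIRKS table
  (nitro, azide, sulfoxide/sulfone and phosphate charge-separation
  forms) rather than an opaque external rule engine — reproducibility
  requires knowing exactly which transforms run. No general tautomer
  canonicalization is attempted.
- Neutralization uses the standard protonate-anion / deprotonate-cation
  pattern, skipping zwitterion partners and valence-capped atoms
  (quaternary N stays charged).
- Neutralization precedes solvent matching, so e.g. sodium acetate
  standardizes to acetic acid and is then removed as a solvent. The
  shipped solvent list (`cover/data/solvents.txt`) is editable
  InChIKeys, one per line.
- Compounds with several surviving organic fragments keep the largest
  (heavy-atom count; ties keep the first). The pipeline is idempotent
  on its own output.

## Descriptors

MOE and DRAGON 3D descriptor products are proprietary; the shipped set
is an open one computed with RDKit: 10 inertial/shape descriptors
(PMI1–3, NPR1–2, radius of gyration, inertial shape factor,
asphericity, eccentricity, spherocity), 80 3D autocorrelations and 114
WHIM descriptors (204 columns total). All are functions of geometry
alone; rigid-motion invariance is asserted per set by a parametrized
test over random rotations. Descriptor failures are imputed with the
column median and flagged (or dropped, per config). Zero-variance
columns are flagged, not removed. Feature matrices are z-scaled with
statistics of the (augmented) training split only.

RMSD diagnostics use the closed-form Kabsch superposition (centroid
removal, SVD rotation with determinant correction) on heavy atoms by
default; conformers of one molecule share atom order by construction,
so no atom-mapping search is done. PCA centres and unit-variance
scales by default, since descriptor magnitudes span orders of
magnitude.

## Clustered nested cross-validation

Folds are built from whole structural clusters so evaluation folds are
structurally dissimilar from training folds: Morgan fingerprints
(diameter 4, folded to 1024 bits) → Tanimoto similarity matrix →
affinity propagation (precomputed similarity, damping 0.9, max 1000
iterations, preference = median off-diagonal similarity; the cluster
count emerges). Non-convergence falls back, loudly, to connected
components at a similarity threshold. Each cluster is assigned to a
uniformly random fold; if that leaves a fold empty the draw is
repeated with a deterministically incremented seed (a size-balancing
greedy strategy is available behind `strategy="balanced"`).

The harness is a 5×4 nested scheme: for each outer fold, the other
four folds form the inner pool; every grid point is trained on three
inner folds and scored by balanced accuracy on the held-out inner
fold; the best mean score wins, with ties broken toward smaller hidden
layers, fewer layers, then more dropout (simpler, more regularised
models). The winner is retrained on the full inner pool and evaluated
on the outer fold. Augmentation — conformer generation or SMOTE — is
applied after splitting, to training molecules only; evaluation
molecules get exactly one conformer unless ensemble evaluation is
requested, in which case the compound score is the arithmetic mean
over its conformer scores.

Small-data guards: inner splits with a single class are skipped with a
warning; if *every* inner trial is degenerate the tie-break-preferred
grid point is used so the outer fold still produces a model; the final
retrain's early-stopping monitor is a 10% class-stratified molecule
split taken before augmentation, and a class's only molecule is shared
between training and monitor rather than removed (both sides are
training data — evaluation folds are never touched). Per-fold
confusion metrics are reported where defined, and pooled
outer-fold predictions give overall sensitivity/specificity for runs
whose individual folds lack positives.

## Network and training

A dense ReLU network (n_layers × hidden_units, input/hidden dropout,
sigmoid output) implemented directly on numpy. Fixed recipe: binary
cross-entropy, SGD with momentum 0.7, He-normal initialisation. Early
stopping monitors balanced accuracy at threshold 0.5 and stops after
20 epochs without a new maximum, restoring the best epoch's weights.
Prediction labels positive strictly above 0.5 (a score of exactly 0.5
is negative). Defaults the search does not cover: batch size 128,
epoch cap 500. Balanced accuracy is the arithmetic mean of sensitivity
and specificity (the standard definition); a harmonic-mean variant is
exposed as a flag for sensitivity analysis. Undefined metrics (empty
denominator, single-class AUC) raise rather than silently coercing.

## Synthetic fixtures

`make_molecule_dataset` samples from a generated library of ~200
valid, InChIKey-unique decorated scaffolds, half rigid (aromatic/fused
rings) and half flexible (ester/ether/amine chains); the
rigid/flexible draw follows `flexibility_mix` (default 0.5). The label
is 1, with probability 1 − label_noise (default 0.05), exactly when
the radius of gyration of the molecule's UFF-minimised structure
(embedding seed derived from the InChIKey, so the property is a fixed
attribute of the molecule) exceeds the library median. Tying labels to
a conformation-computable property near the median makes the classes
adjacent in descriptor space — which is exactly the regime where
imbalanced training collapses onto the majority class and balancing
shows its effect. Exact class counts are filled by rejection sampling.

What the fixture does *not* emulate: real assay label noise structure,
activity cliffs, the descriptor distributions of screening libraries,
or dataset sizes beyond a few hundred molecules. Passing the
directional tests shows the machinery behaves as designed, not that
any particular real endpoint will gain the same margins.

`make_feature_dataset` produces two unit-variance Gaussian blobs a
given number of SDs apart, for unit-testing SMOTE and the network.

## Problem sizes and defaults used in the shipped checks

The bundled experiment runs use the 64 negative / 4 positive fixture,
five clustered folds, a singleton grid (learning rate 0.1, 32 hidden
units in 2 layers, hidden dropout 0.2), batch size 32 and an epoch cap
of 150 — small enough that a full nested run takes seconds on one CPU
while still exercising every code path (grid scoring, retraining,
pooled evaluation). The directional claim (balanced training raises
sensitivity while specificity stays above 0.5) is asserted on the
median over three network seeds of pooled outer-fold metrics.

## Known limitations

- The standardization rule table is deliberately minimal; rule-by-rule
  equivalence with any external standardiser cannot be guaranteed.
- Affinity propagation on very uniform similarity matrices can pick
  arbitrary exemplars; fold *membership* stays deterministic per seed.
- The numpy network trains on CPU only and is not intended for
  thousand-unit layers at scale; the grid's larger widths are
  supported but slow.
- With only a handful of minority molecules, per-split imbalance
  ratios vary between folds (each split recomputes r from its own
  labels), so plan tags differ across folds at toy scale.
- Decision-threshold tuning and probability calibration are out of
  scope; the 0.5 threshold is fixed throughout.
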