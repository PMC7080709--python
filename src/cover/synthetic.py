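"""Synthetic imbalanced molecular fixtures.

Generates labeled drug-like molecule sets in which the label is tied to
a conformation-derived property — the radius of gyration of the
UFF-minimised 3D structure being above the library median — so that 3D
descriptors genuinely carry class signal.  This is what makes the
benefit of conformational augmentation observable at toy scale; it does
not emulate any real assay's biology.

Also provides plain Gaussian-blob feature datasets for unit-testing the
network and the SMOTE baseline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors3D, rdMolDescriptors

from .standardize import MoleculeRecord

# Scaffolds carry one substitution slot.  Rigid scaffolds (few rotatable
# bonds) produce near-identical conformers; flexible ones produce
# diverse ensembles — mirroring the rigid/flexible split of real
# screening collections.
_RIGID_SCAFFOLDS = [
    "c1ccc({})cc1",
    "Fc1ccc({})cc1",
    "Clc1ccc({})cc1",
    "c1ccc2cc({})ccc2c1",
    "c1ccnc({})c1",
    "c1cnc({})cn1",
    "O=C1N({})C(=O)c2ccccc21",
    "c1ccc2[nH]c({})cc2c1",
    "O=c1cc({})oc2ccccc12",
    "C1CC({})C1",
]
_FLEXIBLE_SCAFFOLDS = [
    "CCOC(=O)CC{}",
    "CCN(CC)C(=O)C{}",
    "COCCOCC{}",
    "CCCCOCC{}",
    "CCSCCC{}",
    "CCCN(C)CC{}",
    "CC(=O)NCCCC{}",
    "CCOCCN(C)CC{}",
    "CCCC(=O)OCC{}",
    "CC(C)CCOCC{}",
]
_SUBSTITUENTS = ["C", "CC", "OC", "N(C)C", "F", "Cl", "C(F)(F)F", "C(=O)OC", "CCO", "C#N"]

_FLEX_ROTATABLE_MIN = 3  # rotatable bonds at/above which a molecule counts as flexible


@dataclass(frozen=True)
class ToySpec:
    """Specification of one synthetic imbalanced dataset."""

    n_neg: int
    n_pos: int
    seed: int
    label_noise: float = 0.05
    flexibility_mix: float = 0.5

    def __post_init__(self):
        if self.n_neg < 1 or self.n_pos < 1:
            raise ValueError("n_neg and n_pos must be >= 1")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not (0.0 <= self.flexibility_mix <= 1.0):
            raise ValueError("flexibility_mix must lie in [0, 1]")


def _embed_seed(inchikey: str) -> int:
    h = hashlib.blake2b(inchikey.encode(), digest_size=8)
    return (int.from_bytes(h.digest(), "big") & 0x7FFFFFFF) or 1


@lru_cache(maxsize=1)
def candidate_library() -> tuple[tuple[str, str, bool], ...]:
    """All valid, InChIKey-unique (smiles, inchikey, is_flexible) candidates."""
    seen: set[str] = set()
    out: list[tuple[str, str, bool]] = []
    for scaffold in _RIGID_SCAFFOLDS + _FLEXIBLE_SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            smi = scaffold.format(sub)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            key = Chem.MolToInchiKey(mol)
            if key in seen:
                continue
            seen.add(key)
            flex = rdMolDescriptors.CalcNumRotatableBonds(mol) >= _FLEX_ROTATABLE_MIN
            out.append((Chem.MolToSmiles(mol), key, flex))
    return tuple(out)


_ROG_CACHE: dict[str, float | None] = {}


def conformer_property(smiles: str, inchikey: str) -> float | None:
    """Radius of gyration (Å) of the UFF-minimised ETKDG structure.

    The embedding seed derives from the InChIKey alone, so the property
    is a fixed attribute of the molecule, independent of any dataset
    seed.
    """
    if inchikey in _ROG_CACHE:
        return _ROG_CACHE[inchikey]
    mol = Chem.MolFromSmiles(smiles)
    val: float | None = None
    if mol is not None:
        m = Chem.AddHs(mol)
        params = AllChem.ETKDG()
        params.randomSeed = _embed_seed(inchikey)
        if AllChem.EmbedMolecule(m, params) == 0:
            try:
                AllChem.UFFOptimizeMolecule(m, maxIters=200)
                val = float(Descriptors3D.RadiusOfGyration(m))
            except Exception:
                val = None
    _ROG_CACHE[inchikey] = val
    return val


@lru_cache(maxsize=1)
def _library_with_properties() -> tuple[tuple[tuple[str, str, bool], ...], float]:
    lib = tuple(
        (smi, key, flex)
        for smi, key, flex in candidate_library()
        if conformer_property(smi, key) is not None
    )
    rogs = [conformer_property(smi, key) for smi, key, _ in lib]
    return lib, float(np.median(rogs))


def library_median() -> float:
    """Median radius of gyration over the candidate library (the label threshold)."""
    return _library_with_properties()[1]


def generating_label(smiles: str, inchikey: str) -> int:
    """The noise-free label: 1 iff the conformer property exceeds the library median."""
    rog = conformer_property(smiles, inchikey)
    if rog is None:
        raise ValueError(f"no embeddable structure for {smiles}")
    return int(rog > library_median())


def make_molecule_dataset(spec: ToySpec) -> list[MoleculeRecord]:
    """Sample an imbalanced labeled molecule set with exact class counts.

    Candidates are drawn rigid-vs-flexible according to
    ``flexibility_mix``; each gets label 1 with probability
    (1 - label_noise) when its radius of gyration exceeds the library
    median, else label 0; rejection sampling fills the requested class
    counts exactly.
    """
    lib, median = _library_with_properties()
    rng = np.random.default_rng(spec.seed)
    rigid = [c for c in lib if not c[2]]
    flexible = [c for c in lib if c[2]]
    rigid = [rigid[i] for i in rng.permutation(len(rigid))]
    flexible = [flexible[i] for i in rng.permutation(len(flexible))]
    need = {0: spec.n_neg, 1: spec.n_pos}
    records: list[MoleculeRecord] = []
    i = 0
    while need[0] > 0 or need[1] > 0:
        pool = flexible if (rng.random() < spec.flexibility_mix and flexible) or not rigid else rigid
        if not pool:
            raise ValueError(
                f"candidate library exhausted with {need[0]} negatives / {need[1]} positives still needed"
            )
        smi, key, _ = pool.pop()
        base = int(conformer_property(smi, key) > median)
        label = base if rng.random() >= spec.label_noise else 1 - base
        if need[label] == 0:
            continue
        need[label] -= 1
        records.append(MoleculeRecord(id=f"syn{i:03d}", smiles=smi, inchikey=key, label=label))
        i += 1
    order = rng.permutation(len(records))
    return [
        MoleculeRecord(id=f"syn{j:03d}", smiles=records[i].smiles, inchikey=records[i].inchikey, label=records[i].label)
        for j, i in enumerate(order)
    ]


def make_feature_dataset(
    n_maj: int, n_min: int, dim: int, separation: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian blobs whose means are ``separation`` SDs apart.

    Majority class is labeled 0, minority 1; exact class counts.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    offset = np.zeros(dim)
    offset[0] = separation
    X0 = rng.normal(size=(n_maj, dim))
    X1 = rng.normal(size=(n_min, dim)) + offset
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_maj, dtype=int), np.ones(n_min, dtype=int)])
    order = rng.permutation(len(y))
    return X[order], y[order]
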