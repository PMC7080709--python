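"""Conformational oversampling.

An imbalanced dataset is balanced by generating ``r`` times more 3D
conformations for minority-class molecules than for majority-class
molecules, where

    r = round_half_up(n_maj / n_min)

Each conformation is treated as an independent labeled training
instance: a dataset tagged "n-m" holds ``n`` conformers per majority
molecule and ``m`` per minority molecule (``m = n*r`` when balancing,
``m = n`` for pure oversampling).

Conformers are embedded by the ETKDG distance-geometry algorithm
(experimental-torsion knowledge terms) and energy-minimised with the
UFF force field.  The conformations are *not* meant to be biologically
relevant poses; they only enlarge the training space while preserving
labels, the way crops and flips augment image datasets.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .standardize import MoleculeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OversamplingPlan:
    """Per-class conformer counts derived from the imbalance ratio."""

    n_maj: int
    n_min: int
    r: int
    base_factor: int
    minority_factor: int
    majority_label: int
    minority_label: int

    @property
    def tag(self) -> str:
        return f"{self.base_factor}-{self.minority_factor}"

    def conformers_for(self, label: int) -> int:
        return self.minority_factor if label == self.minority_label else self.base_factor


@dataclass
class ConformerRecord:
    """One 3D embedding of a molecule, carrying its parent's label."""

    parent_id: str
    conf_index: int
    mol: Chem.Mol  # with explicit hydrogens and exactly one conformer
    label: int | None
    seed_used: int

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def heavy_coords(self) -> np.ndarray:
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() != 1]
        return self.coords[idx]


@dataclass
class ConformerDataset:
    records: list[ConformerRecord]
    plan: OversamplingPlan | None
    generation_seed: int
    failures: list[tuple[str, int, int]] = field(default_factory=list)  # (id, requested, obtained)

    def __len__(self) -> int:
        return len(self.records)

    def by_parent(self) -> dict[str, list[ConformerRecord]]:
        groups: dict[str, list[ConformerRecord]] = {}
        for r in self.records:
            groups.setdefault(r.parent_id, []).append(r)
        return groups


def imbalance_ratio(n_maj: int, n_min: int) -> int:
    """round_half_up(n_maj / n_min), never below 1.

    Exact integer arithmetic: floor((2*n_maj + n_min) / (2*n_min)),
    so 15.5 rounds up to 16 with no floating-point surprises.
    """
    if n_min < 1:
        raise ValueError("empty minority class")
    if n_maj < n_min:
        raise ValueError("classes swapped: majority count below minority count")
    return max(1, (2 * n_maj + n_min) // (2 * n_min))


def make_plan(labels: Sequence[int], base_factor: int, balance: bool) -> OversamplingPlan:
    """Derive the per-class conformer counts from the label vector."""
    if base_factor < 1:
        raise ValueError("base_factor must be >= 1")
    labels = [int(l) for l in labels]
    n1 = sum(labels)
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to build a plan")
    # ties: positives treated as minority by convention
    if n1 <= n0:
        minority_label, majority_label, n_min, n_maj = 1, 0, n1, n0
    else:
        minority_label, majority_label, n_min, n_maj = 0, 1, n0, n1
    r = imbalance_ratio(n_maj, n_min)
    minority_factor = base_factor * r if balance else base_factor
    return OversamplingPlan(
        n_maj=n_maj,
        n_min=n_min,
        r=r,
        base_factor=base_factor,
        minority_factor=minority_factor,
        majority_label=majority_label,
        minority_label=minority_label,
    )


def conformer_seed(seed: int, parent_id: str, conf_index: int) -> int:
    """Deterministic 31-bit positive seed for one conformer embedding."""
    h = hashlib.blake2b(f"{seed}|{parent_id}|{conf_index}".encode(), digest_size=8)
    return (int.from_bytes(h.digest(), "big") & 0x7FFFFFFF) or 1


def _embed_one(mol_h: Chem.Mol, rnd_seed: int) -> Chem.Mol | None:
    m = Chem.Mol(mol_h)
    params = AllChem.ETKDG()
    params.randomSeed = rnd_seed
    if AllChem.EmbedMolecule(m, params) != 0:
        return None
    try:
        AllChem.UFFOptimizeMolecule(m, maxIters=200)
    except Exception:
        return None
    return m


def generate_conformers(
    record: MoleculeRecord | Chem.Mol,
    k: int,
    seed: int,
    parent_id: str | None = None,
    label: int | None = None,
) -> tuple[list[ConformerRecord], int]:
    """Embed up to ``k`` conformers of one molecule.

    Each conformer index gets its own deterministic seed derived from
    (seed, parent_id, conf_index), so conformer ``i`` is bit-identical
    no matter how many conformers are requested.  Returns the records
    and the number requested (for failure bookkeeping).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(record, MoleculeRecord):
        mol = Chem.MolFromSmiles(record.smiles)
        parent_id = record.id
        label = record.label
    else:
        mol = record
        if parent_id is None:
            raise ValueError("parent_id required when passing a raw Mol")
    if mol is None:
        return [], k
    mol_h = Chem.AddHs(mol)
    out: list[ConformerRecord] = []
    for i in range(k):
        s = conformer_seed(seed, parent_id, i)
        m = _embed_one(mol_h, s)
        if m is None:
            logger.debug("embedding failed for %s conformer %d", parent_id, i)
            continue
        out.append(ConformerRecord(parent_id=parent_id, conf_index=i, mol=m, label=label, seed_used=s))
    return out, k


def build_dataset(
    molecules: Sequence[MoleculeRecord], plan: OversamplingPlan, seed: int
) -> ConformerDataset:
    """Generate the full oversampled conformer dataset for a molecule list.

    Embedding failures leave a molecule with fewer conformers than the
    plan requests; the shortfall is logged in ``failures`` and never
    compensated by resampling other molecules.
    """
    records: list[ConformerRecord] = []
    failures: list[tuple[str, int, int]] = []
    any_success = False
    for rec in molecules:
        if rec.label is None:
            raise ValueError(f"molecule {rec.id} has no label")
        k = plan.conformers_for(rec.label)
        confs, requested = generate_conformers(rec, k, seed)
        if len(confs) < requested:
            failures.append((rec.id, requested, len(confs)))
        if confs:
            any_success = True
        records.extend(confs)
    if molecules and not any_success:
        raise RuntimeError("conformer embedding failed for every molecule")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return ConformerDataset(records=records, plan=plan, generation_seed=seed, failures=failures)


# ---- SDF I/O ----------------------------------------------------------------


def write_sdf(dataset: ConformerDataset, path) -> None:
    """Write all conformers to a V2000 SDF with provenance properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for rec in dataset.records:
        m = Chem.Mol(rec.mol)
        m.SetProp("parent_id", rec.parent_id)
        m.SetProp("conf_index", str(rec.conf_index))
        m.SetProp("label", "" if rec.label is None else str(rec.label))
        m.SetProp("seed_used", str(rec.seed_used))
        m.SetProp("_Name", f"{rec.parent_id}_{rec.conf_index}")
        writer.write(m)
    writer.close()


def read_sdf(path) -> ConformerDataset:
    """Read a conformer dataset written by :func:`write_sdf`."""
    records = []
    for m in Chem.SDMolSupplier(str(path), removeHs=False):
        if m is None:
            continue
        label_s = m.GetProp("label") if m.HasProp("label") else ""
        records.append(
            ConformerRecord(
                parent_id=m.GetProp("parent_id") if m.HasProp("parent_id") else m.GetProp("_Name"),
                conf_index=int(m.GetProp("conf_index")) if m.HasProp("conf_index") else 0,
                mol=m,
                label=int(label_s) if label_s != "" else None,
                seed_used=int(m.GetProp("seed_used")) if m.HasProp("seed_used") else -1,
            )
        )
    return ConformerDataset(records=records, plan=None, generation_seed=-1)
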