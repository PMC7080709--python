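"""Compound standardization and deduplication.

Turns raw (id, SMILES, label) rows into a clean modeling table:

1. split into disconnected fragments
2. discard non-organic fragments (no carbon)
3. per organic fragment: delete bonds to Group I/II metals,
   neutralize charges, apply structure-normalization rules,
   neutralize again
4. drop solvent fragments (InChIKey list); reject the compound if
   nothing remains
5. keep the largest surviving fragment, generate its InChIKey
6. deduplicate on InChIKey: identical labels collapse to the first
   record, conflicting labels remove the compound entirely

Every rejected record is reported with the stage and reason — nothing
is dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")


@dataclass(frozen=True)
class RawRecord:
    id: str
    structure: str
    label: int | None = None


@dataclass(frozen=True)
class MoleculeRecord:
    id: str
    smiles: str
    inchikey: str
    label: int | None


@dataclass(frozen=True)
class Rejection:
    id: str
    stage: str
    reason: str


# Alkali and alkaline-earth metals (Groups I and II)
_GROUP12 = {3, 11, 19, 37, 55, 87, 4, 12, 20, 38, 56, 88}

# Explicit normalization rule table (SMIRKS).  Deliberately enumerable:
# functional groups with several valid depictions are mapped to one
# canonical form.  No general tautomer canonicalization.
NORMALIZATION_RULES = """//\tName\tSMIRKS
Nitro to N+(=O)[O-]\t[N;X3:1](=[O:2])=[O:3]>>[N+1:1](=[O:2])[O-:3]
Azide to N=N+=N-\t[N;X2:2]=[N;X2:3]#[N;X1:4]>>[N:2]=[N+1:3]=[N-1:4]
Broken azide to N=N+=N-\t[N;X2-:2][N;X2+0:3]#[N;X1:4]>>[N+0:2]=[N+1:3]=[N-1:4]
Charge-separated sulfoxide to S=O\t[S+1;X3:1][O-;X1:2]>>[S+0:1]=[O+0:2]
Sulfone S+2 to S(=O)(=O)\t[S+2:1]([O-:2])([O-:3])>>[S+0:1](=[O+0:2])=[O+0:3]
Phosphate P+O- to P=O\t[P+1;X4:1][O-;X1:2]>>[P+0:1]=[O+0:2]
"""

_normalizer = rdMolStandardize.NormalizerFromData(
    NORMALIZATION_RULES, rdMolStandardize.CleanupParameters()
)

# Protonatable anions / deprotonatable cations, excluding zwitterion
# partners (a charge adjacent to the opposite charge is left alone).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def parse_structure(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def split_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    """Connected components of the molecular graph, as separate Mols."""
    return list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))


def is_organic(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def filter_organic(fragments: Sequence[Chem.Mol]) -> list[Chem.Mol]:
    """Keep only fragments containing at least one carbon, order preserved."""
    return [f for f in fragments if is_organic(f)]


def strip_group12_metal_bonds(fragment: Chem.Mol) -> list[Chem.Mol]:
    """Delete covalent bonds to Group I/II metals; may split the fragment."""
    metal_idx = {a.GetIdx() for a in fragment.GetAtoms() if a.GetAtomicNum() in _GROUP12}
    if not metal_idx:
        return [fragment]
    rw = Chem.RWMol(fragment)
    to_remove = []
    for bond in rw.GetBonds():
        b, e = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if b in metal_idx or e in metal_idx:
            to_remove.append((b, e))
    for b, e in to_remove:
        rw.RemoveBond(b, e)
        # broken covalent bond becomes an ionic pair
        ab, ae = rw.GetAtomWithIdx(b), rw.GetAtomWithIdx(e)
        metal, other = (ab, ae) if ab.GetAtomicNum() in _GROUP12 else (ae, ab)
        metal.SetFormalCharge(metal.GetFormalCharge() + 1)
        other.SetFormalCharge(other.GetFormalCharge() - 1)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return split_fragments(mol)


def neutralize(fragment: Chem.Mol) -> Chem.Mol:
    """Adjust protonation toward net charge 0 where chemically possible.

    Charged heteroatoms gain/lose hydrogens; charges that cannot be
    removed without a valence violation (quaternary N) or that belong to
    an internal zwitterion pair are kept.
    """
    mol = Chem.Mol(fragment)
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        chg = atom.GetFormalCharge()
        hcount = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(hcount - chg)
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol


def apply_structure_rules(fragment: Chem.Mol) -> Chem.Mol:
    """Map functional-group depictions to one canonical form (idempotent)."""
    out = _normalizer.normalize(fragment)
    Chem.SanitizeMol(out)
    return out


def _load_solvent_keys() -> frozenset[str]:
    text = resources.files("cover.data").joinpath("solvents.txt").read_text()
    keys = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        keys.add(line.split()[0])
    return frozenset(keys)


_SOLVENT_KEYS: frozenset[str] | None = None


def solvent_keys() -> frozenset[str]:
    global _SOLVENT_KEYS
    if _SOLVENT_KEYS is None:
        _SOLVENT_KEYS = _load_solvent_keys()
    return _SOLVENT_KEYS


def is_solvent(fragment: Chem.Mol, solvents: frozenset[str] | None = None) -> bool:
    """True iff the fragment's InChIKey is in the solvent list."""
    keys = solvents if solvents is not None else solvent_keys()
    return Chem.MolToInchiKey(fragment) in keys


def standardize_structure(
    smiles: str, solvents: frozenset[str] | None = None
) -> tuple[Chem.Mol | None, str | None]:
    """Run the full per-compound pipeline; return (mol, rejection_reason)."""
    mol = parse_structure(smiles)
    if mol is None:
        return None, "unparseable structure"
    organic = filter_organic(split_fragments(mol))
    if not organic:
        return None, "no organic fragment"
    processed: list[Chem.Mol] = []
    for frag in organic:
        for piece in filter_organic(strip_group12_metal_bonds(frag)):
            try:
                piece = neutralize(piece)
                piece = apply_structure_rules(piece)
                piece = neutralize(piece)  # second pass, usually a no-op
            except Exception as exc:  # pragma: no cover - rdkit edge cases
                return None, f"standardization failure: {exc}"
            processed.append(piece)
    survivors = [p for p in processed if not is_solvent(p, solvents)]
    if not survivors:
        return None, "solvent"
    # keep the largest organic fragment (heavy atoms; ties -> first)
    best = max(survivors, key=lambda m: m.GetNumHeavyAtoms())
    return best, None


def deduplicate(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Collapse InChIKey duplicates; remove label-conflicting groups entirely."""
    by_key: dict[str, list[MoleculeRecord]] = {}
    for r in records:
        by_key.setdefault(r.inchikey, []).append(r)
    kept: list[MoleculeRecord] = []
    rejected: list[Rejection] = []
    seen: set[str] = set()
    for r in records:
        if r.inchikey in seen:
            continue
        seen.add(r.inchikey)
        group = by_key[r.inchikey]
        labels = {g.label for g in group}
        if len(labels) > 1:
            for g in group:
                rejected.append(Rejection(g.id, "deduplicate", "conflicting labels for identical structure"))
        else:
            kept.append(group[0])
            for g in group[1:]:
                rejected.append(Rejection(g.id, "deduplicate", f"duplicate of {group[0].id}"))
    return kept, rejected


def remove_overlap(
    train: Sequence[MoleculeRecord], test: Sequence[MoleculeRecord]
) -> list[MoleculeRecord]:
    """Drop test records whose InChIKey occurs in the training set."""
    train_keys = {r.inchikey for r in train}
    filtered = [r for r in test if r.inchikey not in train_keys]
    if not filtered and test:
        logger.warning("all %d test records overlap the training set", len(test))
    return filtered


def standardize_dataset(
    raw: Iterable[RawRecord], solvents: frozenset[str] | None = None
) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Full pipeline over a record list; returns (clean records, rejections)."""
    staged: list[MoleculeRecord] = []
    rejections: list[Rejection] = []
    for rec in raw:
        if rec.label is not None and rec.label not in (0, 1):
            rejections.append(Rejection(rec.id, "input", "ambiguous label"))
            continue
        mol, reason = standardize_structure(rec.structure, solvents)
        if mol is None:
            stage = "parse" if reason == "unparseable structure" else "standardize"
            rejections.append(Rejection(rec.id, stage, reason))
            continue
        staged.append(
            MoleculeRecord(
                id=rec.id,
                smiles=Chem.MolToSmiles(mol),
                inchikey=Chem.MolToInchiKey(mol),
                label=rec.label,
            )
        )
    kept, dedup_rej = deduplicate(staged)
    rejections.extend(dedup_rej)
    return kept, rejections


# ---- tabular I/O ------------------------------------------------------------


def read_raw_csv(path) -> list[RawRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols or "id" not in cols:
        raise ValueError("input CSV needs 'id' and 'smiles' columns")
    out = []
    for _, row in df.iterrows():
        label = None
        if "label" in cols and pd.notna(row[cols["label"]]):
            label = int(row[cols["label"]])
        out.append(RawRecord(id=str(row[cols["id"]]), structure=str(row[cols["smiles"]]), label=label))
    return out


def write_clean_csv(records: Sequence[MoleculeRecord], path) -> None:
    pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles, "inchikey": r.inchikey, "label": r.label} for r in records]
    ).to_csv(path, index=False)


def read_clean_csv(path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    return [
        MoleculeRecord(
            id=str(r["id"]),
            smiles=str(r["smiles"]),
            inchikey=str(r["inchikey"]),
            label=None if pd.isna(r.get("label")) else int(r["label"]),
        )
        for _, r in df.iterrows()
    ]


def write_rejections_csv(rejections: Sequence[Rejection], path) -> None:
    pd.DataFrame(
        [{"id": r.id, "stage": r.stage, "reason": r.reason} for r in rejections]
    ).to_csv(path, index=False)
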