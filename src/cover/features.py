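"""Conformer featurization and diagnostics.

3D descriptor vectors feed the classifier; Morgan fingerprints feed the
structural clustering; Kabsch-aligned RMSD matrices and PCA projections
diagnose how diverse the generated conformer ensembles are.

The 3D descriptor set is an open one built from RDKit: principal
moments of inertia and derived shape factors, radius of gyration,
asphericity/eccentricity/spherocity, 3D autocorrelations and WHIM
descriptors.  All are functions of geometry alone and invariant under
rigid-body motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors3D, rdFingerprintGenerator, rdMolDescriptors

from .oversample import ConformerDataset, ConformerRecord

logger = logging.getLogger(__name__)

_SHAPE_DESCRIPTORS = {
    "PMI1": Descriptors3D.PMI1,
    "PMI2": Descriptors3D.PMI2,
    "PMI3": Descriptors3D.PMI3,
    "NPR1": Descriptors3D.NPR1,
    "NPR2": Descriptors3D.NPR2,
    "RadiusOfGyration": Descriptors3D.RadiusOfGyration,
    "InertialShapeFactor": Descriptors3D.InertialShapeFactor,
    "Asphericity": Descriptors3D.Asphericity,
    "Eccentricity": Descriptors3D.Eccentricity,
    "SpherocityIndex": Descriptors3D.SpherocityIndex,
}

DESCRIPTOR_SETS = ("shape", "autocorr3d", "whim")


@dataclass
class DescriptorConfig:
    sets: tuple[str, ...] = DESCRIPTOR_SETS
    scale: bool = False          # z-scale columns (recorded in scaling_meta)
    on_failure: str = "impute"   # "impute" (column median) or "drop"


@dataclass
class DescriptorMatrix:
    row_ids: list[tuple[str, int]]          # (parent_id, conf_index)
    columns: list[str]
    values: np.ndarray
    scaling_meta: dict | None = None
    zero_variance: list[str] = field(default_factory=list)
    flagged_rows: list[tuple[str, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "conf_index", [c for _, c in self.row_ids])
        df.insert(0, "parent_id", [p for p, _ in self.row_ids])
        return df


def descriptor_names(sets: Sequence[str] = DESCRIPTOR_SETS) -> list[str]:
    names: list[str] = []
    for s in sets:
        if s == "shape":
            names.extend(_SHAPE_DESCRIPTORS)
        elif s == "autocorr3d":
            names.extend(f"AUTOCORR3D_{i}" for i in range(80))
        elif s == "whim":
            names.extend(f"WHIM_{i}" for i in range(114))
        else:
            raise ValueError(f"unknown descriptor set {s!r}")
    return names


def descriptor_row(mol: Chem.Mol, sets: Sequence[str] = DESCRIPTOR_SETS) -> np.ndarray:
    """Descriptor vector for a single conformer-bearing molecule."""
    parts: list[np.ndarray] = []
    for s in sets:
        if s == "shape":
            parts.append(np.array([f(mol) for f in _SHAPE_DESCRIPTORS.values()], dtype=float))
        elif s == "autocorr3d":
            parts.append(np.asarray(rdMolDescriptors.CalcAUTOCORR3D(mol), dtype=float))
        elif s == "whim":
            parts.append(np.asarray(rdMolDescriptors.CalcWHIM(mol), dtype=float))
        else:
            raise ValueError(f"unknown descriptor set {s!r}")
    return np.concatenate(parts)


def compute_3d_descriptors(
    dataset: ConformerDataset, config: DescriptorConfig | None = None
) -> DescriptorMatrix:
    """One descriptor row per conformer record, in dataset order."""
    config = config or DescriptorConfig()
    cols = descriptor_names(config.sets)
    rows: list[np.ndarray | None] = []
    ids: list[tuple[str, int]] = []
    flagged: list[tuple[str, int]] = []
    for rec in dataset.records:
        try:
            row = descriptor_row(rec.mol, config.sets)
            if not np.isfinite(row).all():
                raise ValueError("non-finite descriptor values")
        except Exception as exc:
            logger.warning("descriptor failure for %s/%d: %s", rec.parent_id, rec.conf_index, exc)
            row = None
            flagged.append((rec.parent_id, rec.conf_index))
        rows.append(row)
        ids.append((rec.parent_id, rec.conf_index))
    good = np.array([r for r in rows if r is not None])
    if good.size == 0:
        raise ValueError("no conformer produced a valid descriptor row")
    medians = np.median(good, axis=0)
    if config.on_failure == "drop":
        keep = [i for i, r in enumerate(rows) if r is not None]
        values = good
        ids = [ids[i] for i in keep]
    else:
        values = np.array([r if r is not None else medians for r in rows])
    zero_var = [cols[j] for j in range(values.shape[1]) if np.ptp(values[:, j]) == 0]
    scaling_meta = None
    if config.scale:
        center = values.mean(axis=0)
        scale = values.std(axis=0)
        scale[scale == 0] = 1.0
        values = (values - center) / scale
        scaling_meta = {"center": center.tolist(), "scale": scale.tolist()}
    return DescriptorMatrix(
        row_ids=ids,
        columns=cols,
        values=values,
        scaling_meta=scaling_meta,
        zero_variance=zero_var,
        flagged_rows=flagged,
    )


# ---- fingerprints -----------------------------------------------------------


@dataclass(frozen=True)
class Fingerprint:
    mol_id: str
    bits: object  # rdkit ExplicitBitVect

    def __len__(self) -> int:
        return self.bits.GetNumBits()


def morgan_fingerprint(mol: Chem.Mol | str, mol_id: str = "", diameter: int = 4, nbits: int = 1024) -> Fingerprint:
    """Circular substructure fingerprint of radius diameter/2, folded to nbits."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        mol = parsed
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=diameter // 2, fpSize=nbits)
    return Fingerprint(mol_id=mol_id, bits=gen.GetFingerprint(mol))


def tanimoto_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Symmetric Tanimoto similarity matrix with unit diagonal."""
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    n = len(fps)
    sim = np.eye(n)
    vects = [f.bits for f in fps]
    for i in range(1, n):
        row = DataStructs.BulkTanimotoSimilarity(vects[i], vects[:i])
        sim[i, :i] = row
        sim[:i, i] = row
    return sim


# ---- Kabsch RMSD ------------------------------------------------------------


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD over all rigid superpositions of two ordered point sets.

    Centroids are removed, the optimal rotation comes from the SVD of
    the cross-covariance with the determinant sign corrected so only
    proper rotations (no reflections) are allowed.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A @ R.T - B
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


@dataclass
class RmsdSummary:
    parent_id: str
    pairwise: np.ndarray      # strictly lower-triangular (zeros elsewhere)
    median_rmsd: float
    n_conformers: int


def rmsd_summary(dataset: ConformerDataset, include_h: bool = False) -> list[RmsdSummary]:
    """Per-molecule all-vs-all conformer RMSD and its median.

    Conformers of one molecule share atom order by construction, so no
    atom-mapping search is needed.  Heavy atoms only by default.
    Molecules with a single conformer are omitted.
    """
    out: list[RmsdSummary] = []
    for pid, recs in dataset.by_parent().items():
        if len(recs) < 2:
            logger.info("molecule %s has a single conformer; omitted from RMSD summary", pid)
            continue
        coords = [r.coords if include_h else r.heavy_coords() for r in recs]
        n = len(coords)
        mat = np.zeros((n, n))
        vals = []
        for i in range(n):
            for j in range(i):
                v = kabsch_rmsd(coords[i], coords[j])
                mat[i, j] = v
                vals.append(v)
        out.append(RmsdSummary(parent_id=pid, pairwise=mat, median_rmsd=float(np.median(vals)), n_conformers=n))
    return out


# ---- PCA --------------------------------------------------------------------


def pca_scores(matrix: DescriptorMatrix, n_components: int, scale: bool = True):
    """PCA of the descriptor matrix: (scores, explained-variance fractions).

    Columns are centred (and unit-variance scaled by default, since the
    descriptor magnitudes differ by orders of magnitude) before the
    decomposition.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix.values, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(X)
    return scores, p.explained_variance_ratio_


# ---- plots ------------------------------------------------------------------


def plot_rmsd_histogram(summaries: Sequence[RmsdSummary], path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = [s.median_rmsd for s in summaries]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(vals, bins=30)
    ax.set_xlabel("median conformer RMSD per molecule (Å)")
    ax.set_ylabel("molecules")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(scores: np.ndarray, labels, path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, color in ((0, "tab:green"), (1, "tab:red")):
        m = labels == lab
        ax.scatter(scores[m, 0], scores[m, 1], s=8, c=color, label=f"label {lab}", alpha=0.6)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
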