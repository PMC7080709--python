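import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, rdMolTransforms
from scipy.spatial.transform import Rotation

from cover import features as ft
from cover import oversample as ov
from cover.standardize import MoleculeRecord


def _embedded(smiles, seed=11):
    m = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDG()
    params.randomSeed = seed
    AllChem.EmbedMolecule(m, params)
    AllChem.UFFOptimizeMolecule(m)
    return m


def _apply_rigid_motion(mol, rotation, translation):
    out = Chem.Mol(mol)
    conf = out.GetConformer()
    coords = conf.GetPositions() @ rotation.T + translation
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz.tolist())
    return out


class TestDescriptors:
    @pytest.mark.parametrize("dset", ft.DESCRIPTOR_SETS)
    def test_rigid_motion_invariance(self, dset):
        mol = _embedded("CCOC(=O)c1ccccc1N")
        base = ft.descriptor_row(mol, (dset,))
        rng = np.random.default_rng(5)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(scale=10, size=3)
            moved = _apply_rigid_motion(mol, R, t)
            row = ft.descriptor_row(moved, (dset,))
            assert np.allclose(base, row, atol=1e-6)

    def test_butane_rotamers_differ(self):
        mol = _embedded("CCCC")
        heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
        anti = Chem.Mol(mol)
        rdMolTransforms.SetDihedralDeg(anti.GetConformer(), *heavy, 180.0)
        gauche = Chem.Mol(mol)
        rdMolTransforms.SetDihedralDeg(gauche.GetConformer(), *heavy, 60.0)
        a = ft.descriptor_row(anti, ("shape",))
        g = ft.descriptor_row(gauche, ("shape",))
        assert not np.allclose(a, g, atol=1e-3)

    def test_matrix_shape_and_order(self):
        mols = [MoleculeRecord(f"m{i}", s, f"K{i}", 0) for i, s in enumerate(["CCCCCCO", "c1ccccc1N"])]
        plan = ov.make_plan([0, 0, 1], 1, False)  # dummy labels just for a plan
        recs = []
        for m in mols:
            confs, _ = ov.generate_conformers(m, 2, seed=1)
            recs.extend(confs)
        ds = ov.ConformerDataset(records=recs, plan=None, generation_seed=1)
        mat = ft.compute_3d_descriptors(ds)
        assert mat.values.shape == (4, len(ft.descriptor_names()))
        assert mat.row_ids == [(r.parent_id, r.conf_index) for r in recs]
        assert np.isfinite(mat.values).all()


class TestFingerprints:
    def test_length_1024(self):
        fp = ft.morgan_fingerprint("CCOC(=O)c1ccccc1")
        assert len(fp) == 1024

    def test_smiles_spelling_invariant(self):
        a = ft.morgan_fingerprint("c1ccccc1CCO")
        b = ft.morgan_fingerprint("OCCc1ccccc1")
        assert DataStructs.TanimotoSimilarity(a.bits, b.bits) == 1.0

    def test_distinct_structures_differ(self):
        a = ft.morgan_fingerprint("C")
        b = ft.morgan_fingerprint("c1ccccc1")
        assert DataStructs.TanimotoSimilarity(a.bits, b.bits) < 1.0

    def test_tanimoto_matrix_properties(self):
        fps = [ft.morgan_fingerprint(s) for s in ("CCO", "CCO", "c1ccccc1", "CCCCN")]
        sim = ft.tanimoto_matrix(fps)
        assert np.allclose(sim, sim.T) and np.allclose(np.diag(sim), 1.0)
        assert sim[0, 1] == 1.0 and ((0 <= sim) & (sim <= 1)).all()

    def test_tanimoto_hand_case(self):
        # |a n b| = 2, |a u b| = 4 -> 0.5, via hand-built bit vectors
        a = DataStructs.ExplicitBitVect(8)
        b = DataStructs.ExplicitBitVect(8)
        for bit in (0, 1, 2):
            a.SetBit(bit)
        for bit in (1, 2, 3):
            b.SetBit(bit)
        fps = [ft.Fingerprint("a", a), ft.Fingerprint("b", b)]
        assert ft.tanimoto_matrix(fps)[0, 1] == pytest.approx(0.5)


def _grid_search_rmsd(A, B):
    """SO(3) search oracle: coarse random rotations + local refinement.

    Independent of the closed-form SVD route being tested.
    """
    from scipy.optimize import minimize

    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = A @ R.T - B
        return np.sqrt(np.mean(np.sum(d**2, axis=1)))

    rots = Rotation.random(2000, random_state=np.random.default_rng(0))
    vecs = rots.as_rotvec()
    best_vec = min(vecs, key=cost)
    res = minimize(cost, best_vec, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return res.fun


class TestKabsch:
    def test_identity(self):
        A = np.random.default_rng(1).normal(size=(6, 3))
        assert ft.kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_quotient(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        B = A @ R.T + rng.normal(scale=5, size=3)
        assert ft.kabsch_rmsd(A, B) < 1e-8

    def test_single_displacement_bound_and_grid_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 3))
        B = A.copy()
        d = 0.5
        B[0] += [d, 0, 0]
        v = ft.kabsch_rmsd(A, B)
        assert v <= d / np.sqrt(4) + 1e-12
        assert v == pytest.approx(_grid_search_rmsd(A, B), abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        assert ft.kabsch_rmsd(A, B) == pytest.approx(ft.kabsch_rmsd(B, A), abs=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ft.kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRmsdSummary:
    def _dataset(self, smiles, k, seed=1):
        rec = MoleculeRecord("m", smiles, "K", 0)
        confs, _ = ov.generate_conformers(rec, k, seed=seed)
        return ov.ConformerDataset(records=confs, plan=None, generation_seed=seed)

    def test_rigid_molecule_small_median(self):
        out = ft.rmsd_summary(self._dataset("c1ccccc1", 5))
        assert len(out) == 1 and out[0].median_rmsd < 0.2

    def test_identical_conformers_zero(self):
        ds = self._dataset("CCCCCCO", 1)
        ds.records = ds.records * 3  # same conformer three times
        out = ft.rmsd_summary(ds)
        assert out[0].median_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_three_conformers_median_is_middle(self):
        ds = self._dataset("CCOCCOCC", 3)
        out = ft.rmsd_summary(ds)
        tri = out[0].pairwise
        vals = sorted(tri[np.tril_indices(3, k=-1)])
        assert len(vals) == 3 and out[0].median_rmsd == pytest.approx(vals[1])

    def test_single_conformer_omitted(self):
        out = ft.rmsd_summary(self._dataset("CCCCCCO", 1))
        assert out == []


class TestPca:
    def _matrix(self, values):
        return ft.DescriptorMatrix(
            row_ids=[("m", i) for i in range(len(values))],
            columns=[f"d{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_explained_variance_sorted_and_bounded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        _, evr = ft.pca_scores(self._matrix(X), 4)
        assert all(evr[i] >= evr[i + 1] for i in range(3)) and evr.sum() <= 1 + 1e-12

    def test_rank_one_matrix(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.normal(size=20), rng.normal(size=4))
        _, evr = ft.pca_scores(self._matrix(X), 2, scale=False)
        assert evr[0] >= 0.999

    def test_score_orthogonality(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 6))
        scores, _ = ft.pca_scores(self._matrix(X), 3)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_raises(self):
        with pytest.raises(ValueError):
            ft.pca_scores(self._matrix(np.zeros((3, 2))), 5)
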