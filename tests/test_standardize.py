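import pytest
from rdkit import Chem

from cover import standardize as std


def _frag_count_oracle(smiles):
    """Graph-traversal oracle: connected components over atoms/bonds."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    adj = {i: set() for i in range(n)}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
    seen, comps = set(), 0
    for i in range(n):
        if i in seen:
            continue
        comps += 1
        stack = [i]
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            stack.extend(adj[a] - seen)
    return comps


class TestSplitFragments:
    @pytest.mark.parametrize(
        "smiles,n", [("CCO", 1), ("CC(=O)[O-].[Na+]", 2), ("CC(=O)[O-].[Na+].O", 3)]
    )
    def test_component_counts(self, smiles, n):
        frags = std.split_fragments(Chem.MolFromSmiles(smiles))
        assert len(frags) == n == _frag_count_oracle(smiles)

    def test_atom_multiset_conserved(self):
        smiles = "CC(=O)[O-].[Na+].O"
        mol = Chem.MolFromSmiles(smiles)
        frags = std.split_fragments(mol)
        atoms_in = sorted(a.GetSymbol() for a in mol.GetAtoms())
        atoms_out = sorted(a.GetSymbol() for f in frags for a in f.GetAtoms())
        assert atoms_in == atoms_out


class TestFilterOrganic:
    @pytest.mark.parametrize(
        "smiles_list,expected",
        [
            (["CC(=O)[O-]", "[Na+]"], ["CC(=O)[O-]"]),
            (["O", "[Cl-]"], []),
            (["C", "O"], ["C"]),
        ],
    )
    def test_carbon_rule(self, smiles_list, expected):
        frags = [Chem.MolFromSmiles(s) for s in smiles_list]
        kept = std.filter_organic(frags)
        assert [Chem.MolToSmiles(m) for m in kept] == [
            Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in expected
        ]


class TestMetalBonds:
    def test_no_metal_passthrough(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        out = std.strip_group12_metal_bonds(benzene)
        assert len(out) == 1 and Chem.MolToSmiles(out[0]) == "c1ccccc1"

    def test_covalent_sodium_split(self):
        out = std.strip_group12_metal_bonds(Chem.MolFromSmiles("CO[Na]"))
        smis = sorted(Chem.MolToSmiles(m) for m in out)
        assert len(out) == 2 and "[Na+]" in smis

    def test_grignard_split(self):
        out = std.strip_group12_metal_bonds(Chem.MolFromSmiles("C[Mg]Br"))
        # both Mg bonds (C and Br) are deleted -> 3 fragments
        assert len(out) == 3


class TestNeutralize:
    def test_acetate_to_acetic_acid(self):
        out = std.neutralize(Chem.MolFromSmiles("CC(=O)[O-]"))
        assert Chem.GetFormalCharge(out) == 0
        assert Chem.MolToSmiles(out) == "CC(=O)O"

    def test_quaternary_nitrogen_kept(self):
        out = std.neutralize(Chem.MolFromSmiles("C[N+](C)(C)C"))
        assert Chem.GetFormalCharge(out) == 1

    def test_idempotent_on_neutral(self):
        aspirin = "CC(=O)Oc1ccccc1C(=O)O"
        out = std.neutralize(Chem.MolFromSmiles(aspirin))
        assert Chem.MolToSmiles(out) == Chem.MolToSmiles(Chem.MolFromSmiles(aspirin))


class TestStructureRules:
    def test_nitro_forms_converge(self):
        a = std.apply_structure_rules(Chem.MolFromSmiles("CN(=O)=O"))
        b = std.apply_structure_rules(Chem.MolFromSmiles("C[N+](=O)[O-]"))
        assert Chem.MolToSmiles(a) == Chem.MolToSmiles(b) == "C[N+](=O)[O-]"

    @pytest.mark.parametrize("smiles", ["C[N+](=O)[O-]", "CCN=[N+]=[N-]", "CS(C)=O", "c1ccccc1"])
    def test_idempotent(self, smiles):
        once = std.apply_structure_rules(Chem.MolFromSmiles(smiles))
        twice = std.apply_structure_rules(once)
        assert Chem.MolToSmiles(once) == Chem.MolToSmiles(twice)

    def test_azide_normalized(self):
        out = std.apply_structure_rules(Chem.MolFromSmiles("CCN=N#N"))
        assert Chem.MolToSmiles(out) == Chem.MolToSmiles(Chem.MolFromSmiles("CCN=[N+]=[N-]"))


class TestSolvents:
    @pytest.mark.parametrize("smiles,expected", [("CCO", True), ("CS(C)=O", True), ("CC(=O)Oc1ccccc1C(=O)O", False)])
    def test_membership(self, smiles, expected):
        assert std.is_solvent(Chem.MolFromSmiles(smiles)) is expected


class TestDeduplicate:
    def _rec(self, i, key, label):
        return std.MoleculeRecord(id=i, smiles="C", inchikey=key, label=label)

    def test_same_label_collapses_to_first(self):
        kept, rej = std.deduplicate([self._rec("a", "K1", 1), self._rec("b", "K1", 1)])
        assert [r.id for r in kept] == ["a"] and len(rej) == 1

    def test_conflicting_labels_removed_entirely(self):
        kept, rej = std.deduplicate([self._rec("a", "K1", 0), self._rec("b", "K1", 1)])
        assert kept == [] and {r.id for r in rej} == {"a", "b"}

    def test_unique_keys_identity(self):
        recs = [self._rec(f"m{i}", f"K{i}", i % 2) for i in range(5)]
        kept, rej = std.deduplicate(recs)
        assert kept == recs and rej == []


class TestRemoveOverlap:
    def _rec(self, i, key):
        return std.MoleculeRecord(id=i, smiles="C", inchikey=key, label=0)

    def test_disjoint_unchanged(self):
        test = [self._rec("t1", "A"), self._rec("t2", "B")]
        assert std.remove_overlap([self._rec("x", "C")], test) == test

    def test_shared_key_dropped(self):
        test = [self._rec("t1", "A"), self._rec("t2", "B")]
        out = std.remove_overlap([self._rec("x", "A")], test)
        assert [r.id for r in out] == ["t2"]

    def test_full_subset_empties_test(self):
        test = [self._rec("t1", "A")]
        assert std.remove_overlap([self._rec("x", "A")], test) == []


class TestPipeline:
    def _raw(self):
        # 10 records: 2 exact duplicates (same label), 1 conflicting pair,
        # 1 inorganic salt -> 10 - 1 - 2 - 1 = 6 survivors
        return [
            std.RawRecord("r1", "CC(=O)Oc1ccccc1C(=O)O", 1),
            std.RawRecord("r2", "c1ccccc1C(=O)O", 0),
            std.RawRecord("r3", "c1ccccc1C(=O)O", 0),        # duplicate of r2
            std.RawRecord("r4", "CCCCN", 1),
            std.RawRecord("r5", "CCCCN", 0),                 # label conflict with r4
            std.RawRecord("r6", "[Na+].[Cl-]", 0),           # inorganic
            std.RawRecord("r7", "CCCCCCCCO", 1),
            std.RawRecord("r8", "c1ccc2ccccc2c1", 0),
            std.RawRecord("r9", "CCOC(=O)c1ccccc1", 0),
            std.RawRecord("r10", "CN1CCC(O)CC1", 1),
        ]

    def test_toy_file_bookkeeping(self):
        kept, rej = std.standardize_dataset(self._raw())
        assert len(kept) == 6
        stages = {r.id: r.stage for r in rej}
        assert stages["r3"] == "deduplicate"
        assert stages["r4"] == stages["r5"] == "deduplicate"
        assert stages["r6"] == "standardize"

    def test_empty_and_identity(self):
        assert std.standardize_dataset([]) == ([], [])
        clean = [std.RawRecord(f"m{i}", s, 1) for i, s in enumerate(["CCCCCCO", "c1ccccc1N", "CCOCC(C)C"])]
        kept, rej = std.standardize_dataset(clean)
        assert len(kept) == 3 and rej == []

    def test_idempotent(self):
        kept, _ = std.standardize_dataset(self._raw())
        again, rej2 = std.standardize_dataset(
            [std.RawRecord(r.id, r.smiles, r.label) for r in kept]
        )
        assert [(r.id, r.smiles) for r in again] == [(r.id, r.smiles) for r in kept]
        assert rej2 == []

    def test_inchikey_bijective(self):
        kept, _ = std.standardize_dataset(self._raw())
        keys = [r.inchikey for r in kept]
        assert len(keys) == len(set(keys))
        assert all(len(k) == 27 and k[14] == "-" and k[25] == "-" for k in keys)
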