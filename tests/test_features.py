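import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from sbpharm import (ExcludedVolume, PerceptionRules, detect_hbonds,
                     excluded_volumes_for, ligand_feature_points,
                     make_complex_ensemble, perceive)
from sbpharm.chem import from_rdkit, total_h_count
from sbpharm.complex_io import AtomRecord, ComplexStructure, LigandMolecule
from sbpharm.fixtures import FixtureSpec
from sbpharm.geometry import RigidTransform, random_rotation


def mol_from_smiles(smiles):
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return from_rdkit(Chem.RemoveHs(mol))


def kinds(features):
    return sorted(f.kind for f in features)


class TestLigandFeaturePoints:
    def test_benzene_is_a_single_hydrophobe(self):
        lig = mol_from_smiles("c1ccccc1")
        feats = ligand_feature_points(lig)
        assert kinds(feats) == ["HYD"]
        centroid = lig.coords.mean(axis=0)
        assert np.linalg.norm(feats[0].center - centroid) < 1e-6

    def test_methylamine_is_donor_and_positive(self):
        # rule table by hand: sp3 amine N bears H (donor) and is protonatable
        lig = mol_from_smiles("CN")
        feats = ligand_feature_points(lig)
        assert kinds(feats) == ["HBD", "POS"]
        n_idx = next(i for i, a in enumerate(lig.atoms) if a.element == "N")
        for f in feats:
            assert np.allclose(f.center, lig.atoms[n_idx].coords)

    def test_acetate_is_negative_with_two_acceptors(self):
        lig = mol_from_smiles("CC(=O)[O-]")
        feats = ligand_feature_points(lig)
        assert kinds(feats) == ["HBA", "HBA", "NEG"]
        group = [i for i, a in enumerate(lig.atoms)
                 if a.element == "O"
                 or (a.element == "C" and any(
                     lig.atoms[j].element == "O"
                     for j, _ in lig.neighbors(i)))]
        centroid = np.mean([lig.atoms[i].coords for i in group], axis=0)
        neg = next(f for f in feats if f.kind == "NEG")
        assert np.linalg.norm(neg.center - centroid) < 1e-6

    def test_implicit_hydrogen_accounting(self):
        lig = mol_from_smiles("CN")  # explicit H stripped on conversion
        n_idx = next(i for i, a in enumerate(lig.atoms) if a.element == "N")
        assert total_h_count(lig, n_idx) == 2

    def test_bondless_multiatom_ligand_rejected(self):
        atoms = [AtomRecord(1, "C1", "C", [0, 0, 0], "LIG", 1, "A", True),
                 AtomRecord(2, "C2", "C", [9, 0, 0], "LIG", 1, "A", True)]
        with pytest.raises(ValueError, match="bond perception required"):
            ligand_feature_points(LigandMolecule(atoms, []))


def planted_hbond_complex(da_distance=2.9, angle_deg=175.0):
    """Ligand N-H donating to a backbone carbonyl O at a chosen geometry."""
    n_pos = np.zeros(3)
    theta = np.radians(180.0 - angle_deg)
    h_pos = np.array([np.cos(theta), np.sin(theta), 0.0])
    o_pos = np.array([da_distance, 0.0, 0.0])
    lig = LigandMolecule(
        [AtomRecord(1, "N1", "N", n_pos, "LIG", 1, "A", True),
         AtomRecord(2, "H1", "H", h_pos, "LIG", 1, "A", True)],
        [(0, 1, 1)], [0, 0])
    protein = [
        AtomRecord(10, "O", "O", o_pos, "GLY", 5, "A"),
        AtomRecord(11, "C", "C", o_pos + [1.23, 0, 0], "GLY", 5, "A"),
    ]
    return ComplexStructure("planted", protein, lig)


class TestDetectHbonds:
    def test_planted_bond_detected(self):
        hbs = detect_hbonds(planted_hbond_complex(2.9, 175.0))
        assert len(hbs) == 1
        hb = hbs[0]
        assert hb.donor_is_ligand
        assert hb.d_a_distance == pytest.approx(2.9)
        assert hb.dha_angle > 160.0  # near-linear planted geometry

    def test_long_contact_rejected(self):
        assert detect_hbonds(planted_hbond_complex(5.0, 175.0)) == []

    def test_bent_geometry_rejected(self):
        assert detect_hbonds(planted_hbond_complex(2.9, 100.0)) == []

    def test_matches_exhaustive_enumeration(self, ensemble):
        """Independent O(n^2) re-derivation of the distance criterion."""
        cx = ensemble[1]
        lig = cx.ligand
        found = {(hb.ligand_atom_index, hb.donor_is_ligand,
                  hb.acceptor.serial if hb.donor_is_ligand
                  else hb.donor.serial)
                 for hb in detect_hbonds(cx)}
        expected = set()
        for i, a in enumerate(lig.atoms):
            if a.element == "H":
                continue
            for p in cx.protein_atoms:
                d = np.linalg.norm(a.coords - p.coords)
                if d > 3.5:
                    continue
                # ligand donor side (N/O/S with >=1 H)
                if a.element in ("N", "O", "S") and total_h_count(lig, i) >= 1 \
                        and p.element in ("N", "O"):
                    h_atoms = [lig.atoms[j].coords for j, _ in lig.neighbors(i)
                               if lig.atoms[j].element == "H"]
                    ok = True
                    if h_atoms:
                        ok = any(_ang(a.coords, h, p.coords) >= 120.0
                                 for h in h_atoms)
                    if ok:
                        expected.add((i, True, p.serial))
                # protein donor side (no protein H in fixtures); ligand
                # acceptors need an available lone pair
                acc_ok = ((a.element == "O" and lig.formal_charges[i] <= 0)
                          or (a.element == "N"
                              and total_h_count(lig, i) == 0
                              and any(o >= 2 for _, o in lig.neighbors(i))))
                if acc_ok and p.element in ("N", "O", "S"):
                    expected.add((i, False, p.serial))
        assert found == expected


def _ang(d, h, a):
    u, v = d - h, a - h
    return np.degrees(np.arccos(np.clip(
        np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))


class TestPerceive:
    @pytest.mark.parametrize("seed", range(20))
    def test_planted_feature_recovery(self, seed):
        """One site of each kind in one complex: perception returns exactly
        the planted kinds, centred within 0.5 A."""
        sites = [("HBD", [0, 0, 0], 1), ("HBA", [12, 0, 0], 1),
                 ("HYD", [0, 12, 0], 1), ("POS", [0, 0, 12], 1),
                 ("NEG", [12, 12, 0], 1)]
        spec = FixtureSpec(seed=seed, n_complexes=1, planted_sites=sites,
                           noise_sd=0.2)
        cx = make_complex_ensemble(spec)[0]
        feats = perceive(cx)
        assert kinds(feats) == ["HBA", "HBD", "HYD", "NEG", "POS"]
        for kind, center, _ in sites:
            f = next(f for f in feats if f.kind == kind)
            assert np.linalg.norm(f.center - np.array(center, float)) < 0.5
            assert f.contacts, "retained feature must name a contact residue"

    def test_isolated_ligand_yields_nothing(self):
        cx = planted_hbond_complex(2.9, 175.0)
        far = cx.transformed(RigidTransform(np.eye(3), np.zeros(3)))
        # move the protein 50 A away instead of the ligand
        for a in far.protein_atoms:
            a.coords = a.coords + 50.0
        assert perceive(far) == []

    def test_distant_benzene_keeps_no_hydrophobe(self):
        lig = mol_from_smiles("c1ccccc1")
        protein = [AtomRecord(1, "CB", "C", [10.0, 0, 0], "ALA", 1, "A")]
        cx = ComplexStructure("far", protein, lig)
        assert perceive(cx) == []

    def test_rigid_invariance(self, ensemble):
        cx = ensemble[2]
        rng = np.random.default_rng(3)
        tf = RigidTransform(random_rotation(rng), rng.uniform(-15, 15, 3))
        f_then_t = sorted(
            (f.kind, *np.round(tf.apply(f.center), 6)) for f in perceive(cx))
        t_then_f = sorted(
            (f.kind, *np.round(f.center, 6)) for f in perceive(cx.transformed(tf)))
        for a, b in zip(f_then_t, t_then_f):
            assert a[0] == b[0]
            assert np.allclose(a[1:], b[1:], atol=1e-6)

    def test_all_retained_features_have_contacts(self, pooled_features):
        assert all(f.contacts for f in pooled_features)


class TestExcludedVolumes:
    def _single(self, protein_xyz, lig_xyz=(0.0, 0.0, 0.0)):
        lig = LigandMolecule(
            [AtomRecord(1, "C1", "C", np.array(lig_xyz), "LIG", 1, "A", True)],
            [], [0])
        protein = [AtomRecord(2, "CB", "C", np.array(protein_xyz), "ALA", 1, "A")]
        return ComplexStructure("ev", protein, lig)

    def test_single_contact_atom(self):
        evs = excluded_volumes_for([self._single([4.0, 0, 0])])
        assert len(evs) == 1
        assert evs[0].radius == pytest.approx(1.2)
        assert np.allclose(evs[0].center, [4.0, 0, 0])
        assert evs[0].source_residue == "A:ALA:1"

    def test_atom_beyond_cutoff_ignored(self):
        assert excluded_volumes_for([self._single([5.5, 0, 0])]) == []

    def test_duplicate_complexes_collapse(self, ensemble):
        one = excluded_volumes_for([ensemble[0]])
        two = excluded_volumes_for([ensemble[0], ensemble[0]])
        assert len(one) == len(two)
        assert np.allclose([e.center for e in one], [e.center for e in two])

    def test_merge_collapses_coincident_candidates(self):
        """30 candidate atoms with 4 coincident pairs merge to 26 spheres."""
        rng = np.random.default_rng(0)
        base = rng.uniform(-10, 10, size=(26, 3))
        dup = np.vstack([base, base[:4] + 1e-4])
        protein = [AtomRecord(i + 1, "CB", "C", p, "ALA", i + 1, "A")
                   for i, p in enumerate(dup)]
        lig = LigandMolecule(
            [AtomRecord(99, "C1", "C", np.zeros(3), "LIG", 900, "A", True)],
            [], [0])
        cx = ComplexStructure("m", protein, lig)
        evs = excluded_volumes_for([cx], contact_cutoff=100.0)
        assert len(evs) == 26

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no structures"):
            excluded_volumes_for([])
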