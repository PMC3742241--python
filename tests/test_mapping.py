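import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbpharm import (ConformerSet, bound_vs_mapped_rmsd, fit_value,
                     map_conformer, map_molecule, make_library,
                     read_library_sdf, screen_library)
from sbpharm.consensus import ConsensusPharmacophore, ModelFeature
from sbpharm.features import ExcludedVolume, PharmFeature
from sbpharm.fixtures import _active_ligand
from sbpharm.geometry import RigidTransform, kabsch, random_rotation


def small_model(kinds=("HBD", "HBA", "HYD", "POS"), spread=8.0, tol=1.6):
    rng = np.random.default_rng(42)
    feats = []
    for i, k in enumerate(kinds):
        center = rng.uniform(-spread, spread, 3)
        feats.append(ModelFeature(f"F{i}", k, center, tol))
    return ConsensusPharmacophore(feats, [], n_complexes=1)


def points_for(model, extra=(), jitter=0.0, rng=None):
    pts = []
    for f in model.features:
        c = f.center.copy()
        if jitter and rng is not None:
            c += rng.normal(0, jitter, 3)
        pts.append(PharmFeature(f.kind, c, 1.6))
    for kind, center in extra:
        pts.append(PharmFeature(kind, np.array(center, float), 1.6))
    return pts


class TestFitValue:
    def test_perfect_map_reaches_weight_sum(self):
        assert fit_value([0.0] * 6, [1.6] * 6) == pytest.approx(6.0)

    def test_displacement_at_tolerance_scores_zero(self):
        assert fit_value([1.6], [1.6]) == pytest.approx(0.0)

    def test_half_tolerance(self):
        assert fit_value([0.8], [1.6]) == pytest.approx(0.75)

    def test_arity_mismatch(self):
        with pytest.raises(ValueError, match="arity"):
            fit_value([0.1, 0.2], [1.6])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=8),
           st.floats(0.1, 5.0))
    def test_bounds_and_monotonicity(self, ds, tol):
        ds = np.array(ds)
        tols = np.full_like(ds, tol)
        v = fit_value(ds, tols)
        assert 0.0 <= v <= len(ds) + 1e-9
        bumped = ds.copy()
        bumped[0] += 0.5
        assert fit_value(bumped, tols) <= v + 1e-12
        perm = np.random.default_rng(0).permutation(len(ds))
        assert fit_value(ds[perm], tols[perm]) == pytest.approx(v)


class TestMapConformer:
    def test_exact_coincidence_scores_maximum(self):
        model = small_model()
        pts = points_for(model)
        conf = np.array([p.center for p in pts])
        res = map_conformer(conf, pts, model)
        assert res.valid
        assert res.fit == pytest.approx(4.0, abs=1e-9)
        assert np.abs(res.displacements).max() < 1e-9

    def test_missing_kind_invalidates(self):
        model = small_model()
        pts = [p for p in points_for(model) if p.kind != "POS"]
        res = map_conformer(np.zeros((1, 3)), pts, model)
        assert not res.valid
        assert res.fit == 0.0

    def test_matches_exhaustive_assignment_oracle(self):
        """4-feature model, 6 candidate points: brute force over all
        injective kind-compatible assignments gives the same best fit."""
        model = small_model()
        rng = np.random.default_rng(3)
        pts = points_for(model, jitter=0.8, rng=rng,
                         extra=[("HBD", rng.uniform(-8, 8, 3)),
                                ("HYD", rng.uniform(-8, 8, 3))])
        conf = np.array([p.center for p in pts])
        res = map_conformer(conf, pts, model)

        best = 0.0
        m = len(model.features)
        for perm in itertools.permutations(range(len(pts)), m):
            if any(pts[j].kind != model.features[i].kind
                   for i, j in enumerate(perm)):
                continue
            P = np.array([pts[j].center for j in perm])
            Q = np.array([f.center for f in model.features])
            tf, _ = kabsch(P, Q)
            disp = np.linalg.norm(tf.apply(P) - Q, axis=1)
            if np.any(disp > 1.6 + 1e-9):
                continue
            best = max(best, fit_value(disp, [1.6] * m))
        assert res.fit == pytest.approx(best, abs=1e-9)

    def test_excluded_volume_clash_rejected(self):
        model = small_model()
        model.excluded_volumes.append(
            ExcludedVolume(model.features[0].center + [0.5, 0, 0], 1.2))
        pts = points_for(model)
        conf = np.array([p.center for p in pts])  # heavy atom inside the EV
        res = map_conformer(conf, pts, model)
        assert not res.valid

    def test_frame_invariance_of_fit(self):
        """Rigidly transforming model and conformer together leaves the
        fit unchanged."""
        model = small_model()
        rng = np.random.default_rng(8)
        pts = points_for(model, jitter=0.7, rng=rng)
        conf = np.array([p.center for p in pts])
        base = map_conformer(conf, pts, model).fit

        tf = RigidTransform(random_rotation(rng), rng.uniform(-9, 9, 3))
        model2 = ConsensusPharmacophore(
            [ModelFeature(f.feature_id, f.kind, tf.apply(f.center),
                          f.tolerance) for f in model.features], [])
        pts2 = [PharmFeature(p.kind, tf.apply(p.center), p.tolerance)
                for p in pts]
        assert map_conformer(tf.apply(conf), pts2, model2).fit == \
            pytest.approx(base, abs=1e-6)


class TestMapMolecule:
    def _confset(self, model, good_slot):
        rng = np.random.default_rng(4)
        lig = _active_ligand(model, rng, jitter=0.0)
        good = lig.coords
        bad = good + np.arange(len(good))[:, None] * 3.0  # internally distorted
        confs = [bad.copy() for _ in range(3)]
        confs[good_slot] = good
        return ConformerSet("m", lig, confs)

    def test_best_conformer_index_recorded(self, model):
        cs = self._confset(model, good_slot=2)
        res = map_molecule(cs, model)
        assert res.valid and res.conformer_index == 2

    def test_duplicate_conformers_lowest_index_wins(self, model):
        rng = np.random.default_rng(5)
        lig = _active_ligand(model, rng, jitter=0.0)
        cs = ConformerSet("m", lig, [lig.coords, lig.coords.copy()])
        assert map_molecule(cs, model).conformer_index == 0

    def test_best_dominates_each_conformer(self, model):
        cs = self._confset(model, good_slot=1)
        best = map_molecule(cs, model)
        from sbpharm.features import ligand_feature_points
        heavy = cs.topology.heavy_indices()
        for c in cs.conformers:
            pts = ligand_feature_points(cs.topology.with_coords(c))
            single = map_conformer(c[heavy], pts, model)
            assert best.fit >= single.fit - 1e-9

    def test_empty_conformer_list_rejected(self, model):
        rng = np.random.default_rng(6)
        lig = _active_ligand(model, rng)
        with pytest.raises(ValueError, match="no conformers"):
            map_molecule(ConformerSet("m", lig, []), model)


class TestBoundVsMappedRmsd:
    def test_identical_coordinates(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        assert bound_vs_mapped_rmsd(X, X) == 0.0

    def test_single_displaced_atom_hand_value(self):
        X = np.zeros((4, 3))
        Y = X.copy()
        Y[0, 0] = 1.0
        assert bound_vs_mapped_rmsd(X, Y) == pytest.approx(0.5)

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        Y = X + rng.normal(0, 0.3, size=(6, 3))
        base = bound_vs_mapped_rmsd(X, Y)
        tf = RigidTransform(random_rotation(rng), rng.uniform(-5, 5, 3))
        assert bound_vs_mapped_rmsd(tf.apply(X), tf.apply(Y)) == \
            pytest.approx(base, abs=1e-9)

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError, match="correspondence"):
            bound_vs_mapped_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


@pytest.fixture(scope="module")
def hits_and_library(model):
    sdf = make_library(model, n_actives=10, n_decoys=90, seed=23)
    lib = read_library_sdf(sdf)
    return screen_library(lib, model, top_k=1000), lib


class TestScreenLibrary:
    def test_all_actives_outrank_all_decoys(self, hits_and_library):
        hits, _ = hits_and_library
        actives = [h for h in hits if h.molecule_id.startswith("ACT")]
        decoys = [h for h in hits if h.molecule_id.startswith("DEC")]
        assert len(actives) == 10
        assert not decoys  # structural decoys cannot cover every feature

    def test_top_k_larger_than_mappers_returns_all(self, hits_and_library):
        hits, _ = hits_and_library
        # 100 molecules, only the 10 actives map: truncation is a no-op
        assert len(hits) == 10

    def test_truncation_and_ranks(self, model, hits_and_library):
        _, lib = hits_and_library
        top3 = screen_library(lib, model, top_k=3)
        assert [h.rank for h in top3] == [1, 2, 3]

    def test_identical_fit_breaks_ties_by_id(self, model):
        rng = np.random.default_rng(9)
        lig = _active_ligand(model, rng, jitter=0.0)
        a = ConformerSet("ZMOL", lig, [lig.coords])
        b = ConformerSet("AMOL", lig, [lig.coords.copy()])
        hits = screen_library([a, b], model, top_k=10)
        assert [h.molecule_id for h in hits] == ["AMOL", "ZMOL"]
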