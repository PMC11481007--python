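"""Feature perception, model construction, and the k-of-n distance matcher."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from pharmfunnel.chemio import generate_conformers, mol_from_rdkit
from pharmfunnel.pharmacophore import (
    DegenerateModelError,
    FeatureCloud,
    FeaturePoint,
    PharmFeature,
    PharmModel,
    PharmacophoreError,
    build_model_from_reference,
    default_gpr40_model,
    match,
    match_bruteforce,
    perceive_features,
    screen,
)


def _mol(smiles, mol_id="m", seed=0):
    m = mol_from_rdkit(Chem.MolFromSmiles(smiles), mol_id)
    return generate_conformers(m, seed=seed)


def _random_rigid(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-10, 10, size=3)


class TestPerception:
    def test_benzene_single_aromatic_point_at_centroid(self):
        m = _mol("c1ccccc1", "benzene")
        pts = perceive_features(m)
        aro = [p for p in pts if p.kind == "aromatic"]
        assert len(aro) == 1
        np.testing.assert_allclose(
            aro[0].centroid, m.conformers[0].mean(axis=0), atol=1e-8
        )

    def test_acetate_two_acceptors_no_aromatic(self):
        m = _mol("CC(=O)[O-]", "acetate")
        pts = perceive_features(m)
        assert sum(p.kind == "acceptor" for p in pts) == 2
        assert sum(p.kind == "aromatic" for p in pts) == 0

    def test_toluene_one_aromatic_no_hydrophobic(self):
        # the methyl carbon alone is below the 3-carbon hydrophobic minimum
        m = _mol("Cc1ccccc1", "toluene")
        pts = perceive_features(m)
        assert sum(p.kind == "aromatic" for p in pts) == 1
        assert sum(p.kind == "hydrophobic" for p in pts) == 0

    def test_butyl_chain_is_hydrophobic(self):
        m = _mol("CCCCc1ccccc1", "butylbenzene")
        pts = perceive_features(m)
        assert sum(p.kind == "hydrophobic" for p in pts) == 1

    def test_missing_conformer_is_error(self):
        m = mol_from_rdkit(Chem.MolFromSmiles("CCO"), "flat")
        m.conformers = []
        with pytest.raises(PharmacophoreError):
            perceive_features(m)


class TestModelConstruction:
    def test_two_picks_single_constraint(self):
        m = _mol("CCO", "ethanol")
        m.conformers = [np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], dtype=float)]
        model = build_model_from_reference(
            m, [("acceptor", [0]), ("hydrophobic", [1])]
        )
        assert model.n_features == 2
        assert model.constraint(0, 1) == pytest.approx(3.0)

    def test_five_picks_give_ten_constraints(self):
        model, _ = default_gpr40_model()
        assert len(model.distances) == 10

    def test_coincident_picks_raise(self):
        m = _mol("CCO", "ethanol")
        m.conformers = [np.zeros((3, 3))]
        with pytest.raises(DegenerateModelError):
            build_model_from_reference(
                m, [("acceptor", [0]), ("hydrophobic", [1])]
            )

    def test_self_match_has_full_count_and_zero_deviation(self):
        model, ref = default_gpr40_model()
        cloud = FeatureCloud(
            "ref",
            [FeaturePoint(f.kind, ref[i]) for i, f in enumerate(model.features)],
        )
        res = match(model, cloud)
        assert res is not None
        assert res.matched_count == 5
        assert res.deviation == pytest.approx(0.0, abs=1e-12)

    def test_model_yaml_round_trip(self, tmp_path):
        model, _ = default_gpr40_model()
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = PharmModel.from_yaml(path)
        assert back.min_required == model.min_required
        assert back.distances == pytest.approx(model.distances)
        assert [f.kind for f in back.features] == [f.kind for f in model.features]

    def test_invalid_parameters_rejected(self):
        feats = [PharmFeature("A1", "acceptor"), PharmFeature("R1", "aromatic")]
        with pytest.raises(PharmacophoreError):
            PharmModel(feats, {(0, 1): 5.0}, tolerance=0.7)
        with pytest.raises(PharmacophoreError):
            PharmModel(feats, {(0, 1): 5.0}, min_required=3)
        with pytest.raises(DegenerateModelError):
            PharmModel(feats, {(0, 1): 0.0}, min_required=2)


class TestMatcher:
    def test_matcher_equals_bruteforce_on_random_instances(self, gpr40_model):
        """Backtracking search must agree with exhaustive enumeration."""
        model, ref = gpr40_model
        rng = np.random.default_rng(42)
        kinds = ["aromatic", "hydrophobic", "acceptor"]
        n_checked = 0
        for k in range(200):
            n_pts = int(rng.integers(3, 9))
            pts = [
                FeaturePoint(
                    kinds[rng.integers(3)],
                    ref[rng.integers(5)]
                    + rng.normal(scale=rng.uniform(0.05, 3.0), size=3),
                )
                for _ in range(n_pts)
            ]
            cloud = FeatureCloud(f"case_{k}", pts)
            fast = match(model, cloud)
            slow = match_bruteforce(model, cloud)
            assert (fast is None) == (slow is None)
            if fast is not None:
                assert fast.matched_count == slow.matched_count
                assert fast.score == pytest.approx(slow.score, abs=1e-10)
                assert fast.deviation == pytest.approx(slow.deviation, abs=1e-10)
            n_checked += 1
        assert n_checked == 200

    def test_rigid_motion_invariance(self, gpr40_model, small_library):
        model, _ = gpr40_model
        clouds, _ = small_library
        rng = np.random.default_rng(7)
        for cloud in clouds[:12]:
            rot, trans = _random_rigid(rng)
            moved = FeatureCloud(
                cloud.id,
                [FeaturePoint(p.kind, p.centroid @ rot.T + trans)
                 for p in cloud.points],
            )
            a, b = match(model, cloud), match(model, moved)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.matched_count == b.matched_count
                assert a.score == pytest.approx(b.score, abs=1e-8)

    def test_tolerance_monotonicity(self, gpr40_model):
        """Enlarging tau never decreases the matched count."""
        model, ref = gpr40_model
        rng = np.random.default_rng(13)
        clouds = []
        for k in range(20):
            pts = [
                FeaturePoint(f.kind, ref[i] + rng.normal(scale=0.6, size=3))
                for i, f in enumerate(model.features)
            ]
            clouds.append(FeatureCloud(f"n{k}", pts))
        taus = [0.05, 0.10, 0.125, 0.20, 0.30]
        for cloud in clouds:
            counts = []
            for tau in taus:
                m = PharmModel(
                    model.features, dict(model.distances), tau,
                    min_required=model.min_required,
                )
                res = match(m, cloud)
                counts.append(0 if res is None else res.matched_count)
            assert counts == sorted(counts)

    def test_real_scaffold_matches_model_built_on_itself(self):
        """End-to-end on real chemistry: perceive, build, re-match."""
        m = _mol("OC(=O)Cc1ccc(-c2ccccc2)cc1CCCC", "agonist_like", seed=3)
        pts = perceive_features(m)
        picks = []
        for kind in ("aromatic", "hydrophobic", "acceptor"):
            for p in pts:
                if p.kind == kind:
                    picks.append((kind, list(p.atom_indices)))
        model = build_model_from_reference(m, picks, min_required=len(picks))
        res = match(model, m)
        assert res is not None
        assert res.matched_count == len(picks)
        assert res.deviation == pytest.approx(0.0, abs=1e-9)


class TestScreen:
    def test_planted_actives_all_hit_and_sorted(self, gpr40_model, small_library):
        model, _ = gpr40_model
        clouds, labels = small_library
        df = screen(model, clouds)
        hit_ids = set(df["id"])
        assert hit_ids == {i for i, is_act in labels.items() if is_act}
        scores = df["score"].to_numpy()
        assert (np.diff(scores) <= 1e-12).all()

    def test_empty_library_raises(self, gpr40_model):
        model, _ = gpr40_model
        with pytest.raises(PharmacophoreError):
            screen(model, [])
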