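"""Pharmacophore perception, alignment and relative fit scoring."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from deepquartet.chem import parse_smiles
from deepquartet.pharmacophore import (FeatureRules, FitResult, LigandFeature,
                                       LigandFeatureSet, PharmacophoreFeature,
                                       PharmacophoreModel, align_features,
                                       etkdg_conformers, perceive_features,
                                       relative_fit_score, score_molecule)


def _embedded(smiles, seed=0):
    confs = etkdg_conformers(parse_smiles(smiles), k=1, seed=seed)
    assert confs, f"embedding failed for {smiles}"
    return confs[0]


class TestPerception:
    def test_benzene_single_aromatic_feature_at_centroid(self):
        mol = _embedded("c1ccccc1")
        feats = perceive_features(mol)
        aro = [f for f in feats.features if f.kind == "aromatic"]
        assert len(aro) == 1
        centroid = mol.GetConformer().GetPositions().mean(axis=0)
        assert np.allclose(aro[0].xyz, centroid, atol=1e-6)

    def test_methylamine_cationic_and_donor_at_nitrogen(self):
        mol = _embedded("CN")
        feats = perceive_features(mol)
        kinds = {f.kind for f in feats.features}
        assert "cationic" in kinds and "hbond_donor" in kinds
        n_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N"][0]
        npos = mol.GetConformer().GetPositions()[n_idx]
        for f in feats.features:
            if f.kind in ("cationic", "hbond_donor"):
                assert np.allclose(f.xyz, npos, atol=1e-6)

    def test_amide_not_cationic(self):
        feats = perceive_features(_embedded("CC(=O)NC"))
        assert not [f for f in feats.features if f.kind == "cationic"]

    def test_benzyl_ether_amine_feature_census(self):
        mol = _embedded("CNCc1ccc(OCc2ccccc2OCc2ccccc2)cc1")
        feats = perceive_features(mol)
        assert len([f for f in feats.features if f.kind == "aromatic"]) >= 3
        assert len([f for f in feats.features if f.kind == "cationic"]) >= 1

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError):
            perceive_features(parse_smiles("CCO"))


def _brute_min_rmsd(M, L, n_starts=40):
    """Oracle: minimize RMSD over rotations (rotation-vector parametrization,
    many restarts) after centroid removal."""
    M = M - M.mean(axis=0)
    L = L - L.mean(axis=0)

    def f(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((L @ R.T - M) ** 2).sum(axis=1).mean())

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(f, rng.normal(0, 2, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestAlignment:
    def test_identical_points_identity(self):
        pts = np.random.default_rng(0).normal(0, 3, (5, 3))
        R, t, rmsd = align_features(list(zip(pts, pts)))
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(0, 3, (6, 3))
        R0 = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = pts @ R0.T + np.array([5.0, -2.0, 1.0])
        _, _, rmsd = align_features(list(zip(pts, moved)))
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self, rng):
        for _ in range(10):
            M = rng.normal(0, 2, (4, 3))
            L = rng.normal(0, 2, (4, 3))
            R, _, _ = align_features(list(zip(M, L)))
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_rotation_search(self, rng):
        """Kabsch result equals the restarted numerical rotation-search
        oracle on random 4-point sets."""
        for _ in range(5):
            M = rng.normal(0, 2, (4, 3))
            L = rng.normal(0, 2, (4, 3))
            _, _, rmsd = align_features(list(zip(M, L)))
            oracle = _brute_min_rmsd(M, L)
            assert rmsd <= oracle + 1e-9          # Kabsch is optimal
            assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_single_pair_translation_only(self):
        R, t, rmsd = align_features([(np.array([1.0, 2.0, 3.0]),
                                      np.array([0.0, 0.0, 0.0]))])
        assert np.allclose(R, np.eye(3))
        assert np.allclose(t, [1, 2, 3])
        assert rmsd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_features([])


def _point_model(points, kinds, tol=1.5, required=None):
    feats = [PharmacophoreFeature(k, tuple(p), tol,
                                  required=bool(required and i in required))
             for i, (p, k) in enumerate(zip(points, kinds))]
    return PharmacophoreModel("test", feats)


def _point_ligand(points, kinds):
    return LigandFeatureSet([LigandFeature(k, tuple(p), (i,))
                             for i, (p, k) in enumerate(zip(points, kinds))])


def _brute_force_best_score(ligand, model, w=0.5):
    """Independent enumerator: all subsets x all injective assignments,
    no pruning; same alignment and score formula."""
    n_model = len(model.features)
    rmsd_ref = model.rmsd_ref
    best = 0.0
    idx_l = range(len(ligand.features))
    for r in range(1, n_model + 1):
        for msub in itertools.combinations(range(n_model), r):
            if any(model.features[i].required and i not in msub
                   for i in range(n_model)):
                continue
            for lsub in itertools.permutations(idx_l, r):
                if any(model.features[i].kind != ligand.features[j].kind
                       for i, j in zip(msub, lsub)):
                    continue
                pairs = [(model.features[i].xyz, ligand.features[j].xyz)
                         for i, j in zip(msub, lsub)]
                R, t, rmsd = align_features(pairs)
                ok = all(np.linalg.norm(R @ ligand.features[j].xyz + t
                                        - model.features[i].xyz)
                         <= model.features[i].tolerance + 1e-9
                         for i, j in zip(msub, lsub))
                if not ok:
                    continue
                frac = r / n_model
                score = (w * frac + (1 - w) * max(0.0, 1 - rmsd / rmsd_ref)
                         if r >= 3 else w * frac)
                best = max(best, score)
    return best


class TestRelativeFit:
    def test_self_fit_is_one(self, toy_pharm):
        fit = relative_fit_score(toy_pharm.matching_features, toy_pharm.model)
        assert fit.score == pytest.approx(1.0, abs=1e-9)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert fit.n_matched == len(toy_pharm.model.features)

    def test_rigid_motion_invariance(self, toy_pharm, rng):
        base = relative_fit_score(toy_pharm.matching_features,
                                  toy_pharm.model).score
        feats = toy_pharm.matching_features
        for _ in range(5):
            R = Rotation.from_rotvec(rng.normal(0, 2, 3)).as_matrix()
            t = rng.normal(0, 10, 3)
            moved = LigandFeatureSet([
                LigandFeature(f.kind, tuple(R @ f.xyz + t), f.atom_indices)
                for f in feats.features])
            s = relative_fit_score(moved, toy_pharm.model).score
            assert s == pytest.approx(base, abs=1e-6)

    def test_matches_brute_force_enumerator(self, rng):
        """Pruned assignment search equals the exhaustive enumerator on
        random <= 5-feature cases."""
        kinds = ["aromatic", "hydrophobic", "cationic", "hbond_donor"]
        for trial in range(8):
            nm = int(rng.integers(2, 5))
            nl = int(rng.integers(2, 6))
            mk = [kinds[i] for i in rng.integers(0, len(kinds), nm)]
            lk = [kinds[i] for i in rng.integers(0, len(kinds), nl)]
            model = _point_model(rng.normal(0, 3, (nm, 3)), mk, tol=2.0)
            ligand = _point_ligand(rng.normal(0, 3, (nl, 3)), lk)
            ours = relative_fit_score(ligand, model).score
            oracle = _brute_force_best_score(ligand, model)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_score_non_increasing_as_one_point_degrades(self):
        """Perturbing one matched point increases rmsd and can only lower
        the score, until the point falls outside tolerance."""
        base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        kinds = ["cationic", "aromatic", "aromatic", "hydrophobic"]
        model = _point_model(base, kinds, tol=1.5)
        prev = 1.0 + 1e-12
        for d in (0.0, 0.3, 0.6, 0.9, 1.2):
            pts = base.copy()
            pts[3, 2] += d
            score = relative_fit_score(_point_ligand(pts, kinds), model).score
            assert score <= prev + 1e-9
            prev = score
        assert prev < 1.0

    def test_required_feature_unmatchable_scores_zero(self):
        model = _point_model(np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], float),
                             ["cationic", "aromatic", "aromatic"],
                             required={0})
        ligand = _point_ligand(np.array([[0, 0, 0], [3, 0, 0]], float),
                               ["aromatic", "aromatic"])
        assert relative_fit_score(ligand, model).score == 0.0

    def test_score_bounds(self, rng):
        kinds = ["aromatic", "hydrophobic", "cationic"]
        for _ in range(10):
            model = _point_model(rng.normal(0, 2, (3, 3)), kinds, tol=1.0)
            ligand = _point_ligand(rng.normal(0, 2, (4, 3)),
                                   [kinds[i] for i in rng.integers(0, 3, 4)])
            s = relative_fit_score(ligand, model).score
            assert 0.0 <= s <= 1.0


class TestScoreMolecule:
    def test_self_defining_conformer_scores_one(self, toy_pharm):
        fit = score_molecule(toy_pharm.matching, toy_pharm.model,
                             conformer_provider=lambda m, k, s: [toy_pharm.matching])
        assert fit.score == pytest.approx(1.0, abs=1e-9)

    def test_none_molecule_scores_zero(self, toy_pharm):
        assert score_molecule(None, toy_pharm.model).score == 0.0

    def test_best_of_two_conformers_selected(self, toy_pharm):
        matching = toy_pharm.matching
        decoy = toy_pharm.decoy
        fit = score_molecule(matching, toy_pharm.model,
                             conformer_provider=lambda m, k, s: [decoy, matching])
        assert fit.score == pytest.approx(1.0, abs=1e-9)

    def test_embedding_failure_scores_zero(self, toy_pharm):
        fit = score_molecule(parse_smiles("CCO"), toy_pharm.model,
                             conformer_provider=lambda m, k, s: [])
        assert fit.score == 0.0
        assert fit.n_matched == 0
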