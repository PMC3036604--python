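import math

import numpy as np
import pytest
from rdkit import Chem

from _oracle import brute_force_best_mapping
from phorescreen.chemio import MoleculeRecord, generate_conformers
from phorescreen.pharmacophore import (
    DEFAULT_TOLERANCE,
    FeatureKind,
    FeaturePoint,
    PharmFeature,
    Pharmacophore,
    best_fit,
    fit_value,
    kabsch_align,
    map_conformer,
    perceive_features,
    read_pharmacophore,
    write_pharmacophore,
)
from phorescreen._smarts import HBA_SMARTS, HBD_SMARTS
from phorescreen.synthdata import make_pharmacophore, random_rigid_transform


def _conformer_points(smiles, mol_id="m", seed=1):
    cs = generate_conformers(MoleculeRecord(id=mol_id, structure=smiles),
                             max_conformers=5, seed=seed)
    return cs.mol, cs.conformers[0], perceive_features(cs.mol, coords=cs.conformers[0])


def _points_at(hypo, displace=None):
    """Feature points exactly at (or displaced from) the hypothesis centers."""
    pts = []
    for i, f in enumerate(hypo.features):
        pos = np.asarray(f.center, dtype=float)
        if displace and i in displace:
            pos = pos + displace[i]
        pts.append(FeaturePoint(kind=f.kind, position=tuple(pos)))
    return pts


class TestPerception:
    def test_methanol_donor_acceptor(self):
        _, _, pts = _conformer_points("CO")
        kinds = sorted(p.kind.value for p in pts)
        assert kinds == ["HBA", "HBD"]
        hbd = next(p for p in pts if p.kind == FeatureKind.HBD)
        assert hbd.direction is not None
        assert np.linalg.norm(hbd.direction) == pytest.approx(1.0, abs=1e-6)

    def test_benzene_ring_centroid(self):
        mol, xyz, pts = _conformer_points("c1ccccc1")
        arom = [p for p in pts if p.kind == FeatureKind.RING_AROM]
        assert len(arom) == 1
        ring_atoms = [a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()]
        centroid = xyz[ring_atoms].mean(axis=0)
        assert np.allclose(arom[0].xyz, centroid, atol=1e-9)

    def test_phenol_matches_manual_smarts_application(self):
        # oracle: apply the shipped SMARTS dictionary directly with RDKit
        mol, xyz, pts = _conformer_points("Oc1ccccc1")
        donors = set()
        for smarts in HBD_SMARTS:
            for match in mol.GetSubstructMatches(Chem.MolFromSmarts(smarts)):
                donors.add(match[0])
        acceptors = set()
        for smarts in HBA_SMARTS:
            for match in mol.GetSubstructMatches(Chem.MolFromSmarts(smarts)):
                acceptors.add(match[0])
        got = {k: sum(1 for p in pts if p.kind == k) for k in FeatureKind}
        assert got[FeatureKind.HBD] == len(donors)
        assert got[FeatureKind.HBA] == len(acceptors)
        assert got[FeatureKind.RING_AROM] == 1
        assert got[FeatureKind.HBIC] == 0  # aromatic carbons belong to RingArom

    def test_requires_coordinates(self):
        mol = Chem.MolFromSmiles("CCO")
        with pytest.raises(ValueError, match="no 3D coordinates"):
            perceive_features(mol)

    def test_every_point_cites_atoms(self):
        _, _, pts = _conformer_points("CCCCO")
        assert all(len(p.atom_indices) >= 1 for p in pts)


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(5, 3))
        R, t, rmsd = kabsch_align(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_recovers_constructed_rotation(self, rng):
        # independent construction: axis-angle rotation built from scratch
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        theta = 1.1
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R0 = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
        t0 = np.array([0.3, -4.0, 2.5])
        Q = rng.normal(size=(6, 3))
        P = Q @ R0.T + t0
        R, t, rmsd = kabsch_align(P, Q, weights=rng.uniform(0.5, 2.0, 6))
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(R, R0, atol=1e-8)
        assert np.allclose(t, t0, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_of_chiral_set_keeps_proper_rotation(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        Q = P.copy()
        Q[:, 2] *= -1  # improper reflection of a chiral 4-point set
        R, t, rmsd = kabsch_align(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_size_mismatch_errors(self):
        with pytest.raises(ValueError, match="point sets"):
            kabsch_align(np.zeros((3, 3)), np.zeros((4, 3)))


class TestMapConformer:
    def test_exact_match_scores_total_weight(self, truth5):
        res = map_conformer(_points_at(truth5), truth5, max_omitted=0)
        assert res.fit == pytest.approx(5.0, abs=1e-9)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.omitted_count == 0

    def test_fit_formula_boundary_term_contributes_zero(self):
        # a displacement exactly at tolerance adds nothing to the fit
        tol = DEFAULT_TOLERANCE
        assert fit_value([0, 0, 0, 0, tol], [tol] * 5, [1.0] * 5) == pytest.approx(4.0, abs=1e-9)
        assert fit_value([0, 0, 0, 0, 0], [tol] * 5, [1.0] * 5) == pytest.approx(5.0)

    def test_displaced_point_lowers_fit_below_total(self, truth5):
        pts = _points_at(truth5, displace={0: np.array([DEFAULT_TOLERANCE, 0.0, 0.0])})
        res = map_conformer(pts, truth5, max_omitted=0)
        assert res is not None
        assert res.fit < 5.0

    def test_missing_donor_is_no_match_at_zero_omitted(self, truth5):
        pts = [p for p in _points_at(truth5) if p.kind != FeatureKind.HBD]
        assert map_conformer(pts, truth5, max_omitted=0) is None
        partial = map_conformer(pts, truth5, max_omitted=1)
        assert partial is not None
        assert partial.omitted_count == 1

    def test_parameter_errors(self, truth5):
        with pytest.raises(ValueError, match="max_omitted"):
            map_conformer(_points_at(truth5), truth5, max_omitted=-1)
        with pytest.raises(ValueError, match="no features"):
            map_conformer(_points_at(truth5), Pharmacophore(features=[]))

    def test_rigid_invariance_of_fit(self, truth5, rng):
        pts = _points_at(truth5, displace={1: np.array([0.4, -0.2, 0.3])})
        base = map_conformer(pts, truth5, max_omitted=0).fit
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = [FeaturePoint(kind=p.kind, position=tuple(R @ p.xyz + t)) for p in pts]
            assert map_conformer(moved, truth5, max_omitted=0).fit == pytest.approx(
                base, abs=1e-6
            )

    def test_fit_bounded_by_weights_with_equality_iff_exact(self, truth5, rng):
        for trial in range(10):
            disp = {i: rng.normal(0, 0.5, 3) for i in range(5)}
            pts = _points_at(truth5, displace=disp)
            res = map_conformer(pts, truth5, max_omitted=4)
            if res is None:
                continue
            assert 0.0 <= res.fit <= truth5.total_weight + 1e-9
            if res.fit >= truth5.total_weight - 1e-9:
                assert res.rmsd == pytest.approx(0.0, abs=1e-6)


TOY_HYPO = Pharmacophore(
    features=[
        PharmFeature(kind=FeatureKind.HBD, center=(0.0, 0.0, 0.0)),
        PharmFeature(kind=FeatureKind.HBIC, center=(3.0, 0.0, 0.0)),
        PharmFeature(kind=FeatureKind.HBA, center=(0.0, 4.0, 0.0)),
    ]
)

# frozen toy point sets (kind, xyz) probing ambiguous and partial matches
TOY_POINT_SETS = [
    [("HBD", (0.1, -0.2, 0.0)), ("HBic", (3.2, 0.1, -0.1)), ("HBA", (-0.2, 3.8, 0.2))],
    [("HBD", (5.0, 5.0, 5.0)), ("HBic", (8.1, 5.2, 4.9)), ("HBA", (5.1, 9.2, 5.0)),
     ("HBic", (6.5, 7.0, 5.5))],
    [("HBA", (0.0, 0.0, 0.0)), ("HBA", (0.0, 4.5, 0.0)), ("HBD", (-0.3, 0.4, 1.0)),
     ("HBic", (2.6, -0.5, 0.4)), ("HBic", (3.3, 1.0, -0.8))],
    [("HBD", (1.0, 1.0, 1.0)), ("HBic", (1.5, 1.0, 1.2))],  # geometry too compressed
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("pts_spec", TOY_POINT_SETS)
    @pytest.mark.parametrize("max_omitted", [0, 1])
    def test_matches_bruteforce_on_toy_sets(self, pts_spec, max_omitted):
        pts = [FeaturePoint(kind=FeatureKind(k), position=xyz) for k, xyz in pts_spec]
        got = map_conformer(pts, TOY_HYPO, max_omitted=max_omitted)
        expected = brute_force_best_mapping(pts, TOY_HYPO, max_omitted=max_omitted)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got.fit == pytest.approx(expected[0], abs=1e-3)

    def test_matches_bruteforce_on_random_sets(self, rng):
        kinds = [FeatureKind.HBD, FeatureKind.HBA, FeatureKind.HBIC]
        for trial in range(6):
            k = int(rng.integers(2, 4))
            hypo = make_pharmacophore(k, kinds=kinds[:k], seed=int(rng.integers(2**31)))
            n = int(rng.integers(3, 7))
            pts = [
                FeaturePoint(
                    kind=kinds[int(rng.integers(len(kinds)))],
                    position=tuple(rng.uniform(-2, 12, 3)),
                )
                for _ in range(n)
            ]
            got = map_conformer(pts, hypo, max_omitted=1)
            expected = brute_force_best_mapping(pts, hypo, max_omitted=1)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert got.fit == pytest.approx(expected[0], abs=1e-3)


class TestBestFit:
    def test_single_conformer_equals_map_conformer(self, truth5):
        pts = _points_at(truth5, displace={2: np.array([0.3, 0.0, 0.0])})
        direct = map_conformer(pts, truth5, max_omitted=0)
        via = best_fit([pts], truth5, max_omitted=0)
        assert via.fit == pytest.approx(direct.fit, abs=1e-12)
        assert via.conformer_index == 0

    def test_picks_conformer_satisfying_tolerances(self, truth5):
        bad = [FeaturePoint(kind=p.kind, position=tuple(p.xyz * 3.0))
               for p in _points_at(truth5)]
        good = _points_at(truth5)
        res = best_fit([bad, good], truth5, max_omitted=0)
        assert res.conformer_index == 1

    def test_empty_set_and_bad_mode_error(self, truth5):
        with pytest.raises(ValueError, match="empty"):
            best_fit([], truth5)
        with pytest.raises(ValueError, match="mode"):
            best_fit([_points_at(truth5)], truth5, mode="exhaustive")

    def test_best_mode_never_below_fast_mode(self, truth5, rng):
        for trial in range(5):
            disp = {i: rng.normal(0, 0.6, 3) for i in range(5)}
            pts = _points_at(truth5, displace=disp)
            fast = best_fit([pts], truth5, mode="fast", max_omitted=2)
            best = best_fit([pts], truth5, mode="best", max_omitted=2)
            if fast is not None:
                assert best is not None
                assert best.fit >= fast.fit - 1e-9


class TestModelIO:
    def test_lossless_roundtrip(self, truth5, tmp_path):
        from phorescreen.hypogen import CostReport
        from phorescreen.pharmacophore import FitLine

        hypo = Pharmacophore(
            features=truth5.features,
            fit_line=FitLine(slope=1.3, intercept=3.5),
            train_r=0.97,
            costs=CostReport(
                error_cost=5.0, weight_cost=1.0, config_cost=2.0, total_cost=8.0,
                fixed_cost=3.0, null_cost=100.0, residual_cost=92.0,
            ),
        )
        path = tmp_path / "hypo.json"
        write_pharmacophore(hypo, path)
        back = read_pharmacophore(path)
        assert back.kind_multiset() == hypo.kind_multiset()
        assert np.allclose(back.centers, hypo.centers)
        assert np.allclose(back.tolerances, hypo.tolerances)
        assert back.fit_line.slope == hypo.fit_line.slope
        assert back.fit_line.intercept == hypo.fit_line.intercept
        assert back.train_r == hypo.train_r
        assert back.costs.residual_cost == pytest.approx(92.0)

    def test_six_feature_file_rejected(self, tmp_path):
        path = tmp_path / "six.json"
        feats = [{"kind": "HBic", "center": [float(i) * 4, 0.0, 0.0]} for i in range(6)]
        path.write_text('{"features": %s}' % str(feats).replace("'", '"'))
        with pytest.raises(ValueError, match="maximum is 5"):
            read_pharmacophore(path)

    def test_zero_tolerance_rejected(self, tmp_path):
        path = tmp_path / "tol.json"
        path.write_text(
            '{"features": [{"kind": "HBD", "center": [0, 0, 0], "tolerance": 0.0}]}'
        )
        with pytest.raises(ValueError, match="tolerance"):
            read_pharmacophore(path)

    def test_missing_field_named(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"features": [{"kind": "HBD"}]}')
        with pytest.raises(ValueError, match="center"):
            read_pharmacophore(path)
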