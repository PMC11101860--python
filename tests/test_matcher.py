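"""Kabsch superposition and template scanning."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hemescan.fixtures import FixtureSpec, make_toy_heme_protein, perturb_structure
from hemescan.matcher import (
    DegenerateGeometryError,
    MatcherParams,
    RigidTransform,
    brute_force_scan,
    enumerate_candidate_triplets,
    kabsch_superpose,
    scan,
)
from hemescan.structure_io import detect_heme_groups
from hemescan.template_library import MATCH_ATOMS, build_library


def random_rigid(rng) -> RigidTransform:
    r = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return RigidTransform(r, t)


def transformed_structure(s, tr: RigidTransform):
    out = s.copy()
    for res in out.residues:
        for a in res.atoms:
            a.coord = tr.apply(a.coord)
    return out


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.4, 1.2]])
        tr, rmsd = kabsch_superpose(pts, pts)
        assert rmsd <= 1e-12
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-12)

    def test_recovers_constructed_transform(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 1.5]], dtype=float)
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        moved = pts @ rot90.T + np.array([1.0, 2.0, 3.0])
        tr, rmsd = kabsch_superpose(pts, moved)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(tr.rotation, rot90, atol=1e-9)
        np.testing.assert_allclose(tr.translation, [1, 2, 3], atol=1e-9)
        tr.validate()

    @pytest.mark.parametrize("trial", range(5))
    def test_beats_random_transforms_and_never_reflects(self, trial):
        rng = np.random.default_rng(1000 + trial)
        moving = rng.normal(0, 3, size=(9, 3))
        fixed = rng.normal(0, 3, size=(9, 3))
        tr, rmsd = kabsch_superpose(moving, fixed)
        tr.validate()
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        cm, cf = moving.mean(0), fixed.mean(0)
        for _ in range(200):
            r = Rotation.random(rng=rng).as_matrix()
            cand = (moving - cm) @ r.T + cf
            cand_rmsd = np.sqrt(((cand - fixed) ** 2).sum() / len(fixed))
            assert rmsd <= cand_rmsd + 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            moving = rng.normal(0, 2, size=(9, 3))
            fixed = rng.normal(0, 2, size=(9, 3))
            tr, rmsd = kabsch_superpose(moving, fixed)
            rot, _ = Rotation.align_vectors(
                fixed - fixed.mean(0), moving - moving.mean(0)
            )
            np.testing.assert_allclose(tr.rotation, rot.as_matrix(), atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_mirror_input_still_returns_proper_rotation(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 2, size=(9, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tr, rmsd = kabsch_superpose(pts, mirrored)
        tr.validate()
        assert rmsd > 0.1  # a reflection would give 0; it must not be used


class TestEnumeration:
    def brute_force_triplets(self, query, t, params):
        """Same two rules, no pruning shortcuts: full O(n^3) enumeration."""
        eligible = []
        for res in query.standard_residues():
            names = MATCH_ATOMS.get(res.name)
            if names and all(res.get_atom(n) for n in names):
                eligible.append(res)
        tca = [tr.coords[list(tr.atom_names).index("CA")] for tr in t.residues]
        td = [
            np.linalg.norm(tca[0] - tca[1]),
            np.linalg.norm(tca[0] - tca[2]),
            np.linalg.norm(tca[1] - tca[2]),
        ]
        out = set()
        for a in eligible:
            for b in eligible:
                for c in eligible:
                    if len({a.rid, b.rid, c.rid}) != 3:
                        continue
                    if (a.name, b.name, c.name) != tuple(
                        tr.res_name for tr in t.residues
                    ):
                        continue
                    ds = [
                        np.linalg.norm(a.ca.coord - b.ca.coord),
                        np.linalg.norm(a.ca.coord - c.ca.coord),
                        np.linalg.norm(b.ca.coord - c.ca.coord),
                    ]
                    if all(abs(d - e) <= params.pair_tol for d, e in zip(ds, td)):
                        out.add((a.rid, b.rid, c.rid))
        return out

    def test_self_scan_includes_own_triplet(self, canonical, canonical_libraries):
        for (s, gt), lib in zip(canonical, canonical_libraries):
            t = lib.templates[0]
            trips = enumerate_candidate_triplets(s, t)
            assert tuple(tr.source_id for tr in t.residues) in [
                tuple(r.rid for r in trip) for trip in trips
            ]

    def test_no_matching_types_is_empty(self, canonical_libraries):
        spec = FixtureSpec(
            seed=77,
            ligating_residues=(("ASP", 3.6), ("GLU", 3.6), ("ASN", 3.6)),
            env_composition=(("GLN", 1),),
            n_scaffold_residues=0,
        )
        s, _ = make_toy_heme_protein(spec)
        t = canonical_libraries[0].templates[0]  # His/Tyr/Leu types
        assert enumerate_candidate_triplets(s, t) == []

    def test_matches_brute_force(self, canonical, canonical_libraries):
        params = MatcherParams()
        for (s, _), lib in zip(canonical, canonical_libraries):
            for t in lib.templates:
                got = {
                    tuple(r.rid for r in trip)
                    for trip in enumerate_candidate_triplets(s, t, params)
                }
                assert got == self.brute_force_triplets(s, t, params)


class TestScan:
    def test_self_scan_identity(self, canonical, canonical_libraries):
        for (s, gt), lib in zip(canonical, canonical_libraries):
            result = scan(s, lib)
            assert len(result.matches) >= 1
            best = result.matches[0]
            assert best.rmsd <= 1e-9
            assert np.linalg.norm(best.placed_fe - gt.fe_coord) <= 1e-9
            assert set(best.query_residues) == set(gt.site_rids)

    def test_placed_fe_is_transform_of_template_fe(self, toy, canonical_libraries):
        s, _ = toy
        lib = canonical_libraries[0]
        result = scan(s, lib)
        by_id = {t.template_id: t for t in lib.templates}
        for m in result.matches:
            t = by_id[m.template_id]
            expected = m.transform.apply(t.heme_coords)[t.fe_index]
            assert np.array_equal(m.placed_fe, expected)

    def test_rigid_invariance(self, toy, canonical_libraries):
        s, gt = toy
        lib = canonical_libraries[0]
        base = scan(s, lib)
        rng = np.random.default_rng(5)
        tr = random_rigid(rng)
        moved = transformed_structure(s, tr)
        result = scan(moved, lib)
        assert [m.query_residues for m in result.matches] == [
            m.query_residues for m in base.matches
        ]
        for a, b in zip(result.matches, base.matches):
            assert a.rmsd == pytest.approx(b.rmsd, abs=1e-6)
        best = result.matches[0]
        np.testing.assert_allclose(
            best.placed_fe, tr.apply(gt.fe_coord), atol=1e-6
        )

    def test_rmsd_max_monotonicity(self, toy, canonical_libraries):
        s, _ = toy
        lib = canonical_libraries[0]
        q = perturb_structure(s, 0.3, seed=11)
        keys = {}
        for rmsd_max in (0.5, 1.0, 2.0, 4.0):
            result = scan(q, lib, MatcherParams(rmsd_max=rmsd_max))
            keys[rmsd_max] = {(m.template_id, m.query_residues) for m in result.matches}
        assert keys[0.5] <= keys[1.0] <= keys[2.0] <= keys[4.0]

    def test_missing_match_atom_counted_as_skip(self, toy, canonical_libraries):
        s, gt = toy
        lib = canonical_libraries[0]
        s2 = s.copy()
        res = s2.find_residue(gt.site_rids[0])
        res.atoms = [a for a in res.atoms if a.name != "NE2"]
        result = scan(s2, lib)
        # the planted His lost its functional atom: no self-match any more
        assert all(set(m.query_residues) != set(gt.site_rids) for m in result.matches)

    def test_pruned_scan_equals_brute_force(self, canonical, canonical_libraries):
        params = MatcherParams()
        for (s, _), lib in zip(canonical, canonical_libraries):
            for seed in (0, 1):
                q = s if seed == 0 else perturb_structure(s, 0.3, seed=seed)
                fast = scan(q, lib, params)
                slow = brute_force_scan(q, lib, params)
                fkeys = [(m.template_id, m.query_residues) for m in fast.matches]
                skeys = [(m.template_id, m.query_residues) for m in slow.matches]
                assert fkeys == skeys
                for a, b in zip(fast.matches, slow.matches):
                    assert a.rmsd == pytest.approx(b.rmsd, abs=1e-9)
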