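"""Coordinate model: chain building, superposition, bundle RMSD, symmetry."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from emnmr.model import (Ensemble, InputError, ProtocolConfig, Structure,
                         SymmetryGroup, apply_symmetry, build_backbone,
                         bundle_rmsd, superpose)
from conftest import fitted_helix_axis


class TestBuildBackbone:
    def test_helical_rise(self, helix21):
        _, axis, extent = fitted_helix_axis(helix21.ca_coords())
        rise = extent / 20
        assert rise == pytest.approx(1.5, abs=0.1)

    def test_consecutive_ca_distance(self, rng):
        dih = rng.uniform(-179, 180, size=(30, 2))
        s = build_backbone("A" * 30, dih)
        d = np.linalg.norm(np.diff(s.ca_coords(), axis=0), axis=1)
        assert np.all(np.abs(d - 3.80) < 0.1)

    def test_single_residue_ideal_bonds(self):
        s = build_backbone("A", [(-60.0, 140.0)])
        assert np.linalg.norm(s.atom(1, "N") - s.atom(1, "CA")) == pytest.approx(1.458, abs=1e-6)
        assert np.linalg.norm(s.atom(1, "CA") - s.atom(1, "C")) == pytest.approx(1.525, abs=1e-6)

    def test_helix_hydrogen_bond_geometry(self, helix21):
        # i -> i+4 O···N distances of an ideal α-helix
        for i in range(1, 17):
            d = np.linalg.norm(helix21.atom(i, "O") - helix21.atom(i + 4, "N"))
            assert 2.8 <= d <= 3.2

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            build_backbone("AAA", [(-60, -40)] * 2)

    def test_out_of_range_dihedral_rejected(self):
        with pytest.raises(InputError):
            build_backbone("AA", [(-60, -40), (190.0, 0.0)])


class TestSuperpose:
    def test_identical_structures(self, helix21):
        rmsd, _ = superpose(helix21, helix21)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, helix21, rng):
        rot = Rotation.random(random_state=7).as_matrix()
        moved = helix21.transformed(rot, rng.normal(0, 10, 3))
        rmsd, _ = superpose(moved, helix21)
        assert rmsd < 1e-6

    def test_symmetric_rmsd(self, rng):
        a = rng.normal(0, 5, (10, 3))
        b = rng.normal(0, 5, (10, 3))
        assert superpose(a, b)[0] == pytest.approx(superpose(b, a)[0], abs=1e-6)

    def test_against_rotation_search_oracle(self, rng):
        """Kabsch result matches brute-force minimisation over rotations."""
        x = rng.normal(0, 3, (4, 3))
        y = rng.normal(0, 3, (4, 3))
        rmsd, _ = superpose(x, y)

        def cost(rv):
            rot = Rotation.from_rotvec(rv).as_matrix()
            xr = (x - x.mean(0)) @ rot.T
            yr = y - y.mean(0)
            return np.sqrt(np.mean(np.sum((xr - yr) ** 2, axis=1)))

        best = np.inf
        for seed_rv in rng.normal(0, 2, size=(40, 3)):
            r = minimize(cost, seed_rv, method="Nelder-Mead",
                         options=dict(maxiter=400, fatol=1e-12, xatol=1e-8))
            best = min(best, r.fun)
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_too_few_atoms(self):
        with pytest.raises(InputError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestBundleRmsd:
    def test_identical_conformers(self, helix21):
        ens = Ensemble([helix21.copy() for _ in range(4)], np.zeros(4))
        assert bundle_rmsd(ens) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, helix21, rng):
        rot = Rotation.random(random_state=3).as_matrix()
        moved = helix21.transformed(rot, rng.normal(0, 5, 3))
        ens = Ensemble([helix21.copy(), moved], np.zeros(2))
        assert bundle_rmsd(ens) < 1e-6

    def test_matches_explicit_mean_iteration(self, helix21):
        """Two conformers differing by one displaced atom: compare against a
        direct implementation of the mean-structure definition."""
        other = helix21.copy()
        other.coords[30] += np.array([0.9, 0.0, 0.0])
        ens = Ensemble([helix21.copy(), other], np.zeros(2))
        got = bundle_rmsd(ens, selection=("N", "CA", "C", "O", "CB", "SC"))

        sel = np.arange(helix21.coords.shape[0])
        coords = [helix21.coords[sel], other.coords[sel]]
        mean = coords[0].copy()
        for _ in range(200):
            aligned = []
            for x in coords:
                _, (rot, t) = superpose(x, mean)
                aligned.append(x @ rot.T + t)
            new_mean = np.mean(aligned, axis=0)
            if np.max(np.abs(new_mean - mean)) < 1e-6:
                mean = new_mean
                coords = aligned
                break
            mean = new_mean
            coords = aligned
        expect = np.mean([np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=1)))
                          for x in coords])
        assert got == pytest.approx(expect, rel=1e-3)

    def test_permutation_invariance(self, helix21, rng):
        confs = []
        for k in range(3):
            c = helix21.copy()
            c.coords = c.coords + rng.normal(0, 0.3, c.coords.shape)
            confs.append(c)
        a = bundle_rmsd(Ensemble(confs, np.zeros(3)))
        b = bundle_rmsd(Ensemble(confs[::-1], np.zeros(3)))
        assert a == pytest.approx(b, abs=1e-6)

    def test_single_conformer_warns_zero(self, helix21):
        with pytest.warns(UserWarning):
            assert bundle_rmsd(Ensemble([helix21], np.zeros(1))) == 0.0


class TestSymmetry:
    def test_identity_group(self, helix21):
        chains = apply_symmetry(helix21, SymmetryGroup.identity())
        assert len(chains) == 1
        assert np.allclose(chains[0].coords, helix21.coords)

    def test_c2_group(self, helix21):
        group = SymmetryGroup.cyclic(2)
        chains = apply_symmetry(helix21, group)
        assert len(chains) == 2
        rot, tr = group.operators[1]
        expect = helix21.coords @ rot.T + tr
        assert np.allclose(chains[1].coords, expect, atol=1e-9)

    def test_tetrahedral_order_is_twelve(self, helix21):
        group = SymmetryGroup.tetrahedral()
        assert group.order == 12
        assert len(apply_symmetry(helix21, group)) == 12

    def test_tetrahedral_group_closed(self):
        ops = [r for r, _ in SymmetryGroup.tetrahedral().operators]
        for a in ops:
            for b in ops:
                prod = a @ b
                assert any(np.allclose(prod, c, atol=1e-6) for c in ops)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(InputError):
            SymmetryGroup([(np.eye(3) * 1.5, np.zeros(3))])


class TestProtocolConfig:
    def test_defaults_hold_protocol_constants(self):
        cfg = ProtocolConfig()
        assert cfg.overlap_threshold == 0.7
        assert cfg.fix_tolerance == 0.5
        assert cfg.disambig_cutoff == 8.0
        assert cfg.resolution_schedule == (8.0, 6.0, 4.1)

    @pytest.mark.parametrize("kw", [
        dict(overlap_threshold=1.5),
        dict(fix_tolerance=-1.0),
        dict(resolution_schedule=(6.0, 8.0)),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(InputError):
            ProtocolConfig(**kw)
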