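"""Target function, annealing, ranking logic, fitting, refinement rules."""

import numpy as np
import pytest

from emnmr.calc import (TargetFunctionSpec, anneal, converged, flexible_fit,
                        target_function)
from emnmr.calc.rank import ScoreCard, _pareto_rank
from emnmr.calc.target import compute_torsions
from emnmr.density import DensityMap, simulate_map
from emnmr.model import (Ensemble, InputError, ProtocolConfig, SymmetryGroup,
                         build_backbone, superpose)
from emnmr.restraints import (DihedralRestraint, DistanceRestraint,
                              RestraintSet, disambiguate)


def _wrap(x):
    return (x + 180.0) % 360.0 - 180.0


def brute_force_tf(structure, rset, spec):
    """Independent term-by-term reference implementation."""
    tf = 0.0
    for r in rset.distance:
        ds = [np.linalg.norm(structure.atom(*a) - structure.atom(*b))
              for a, b in r.candidates]
        if len(ds) == 1:
            d = ds[0]
        else:
            d = sum(x ** -6 for x in ds) ** (-1 / 6)
        if d > r.upper:
            tf += spec.w_upper * (d - r.upper) ** 2
        elif d < r.lower:
            tf += spec.w_lower * (r.lower - d) ** 2
    phi, psi = compute_torsions(structure)
    for d in rset.dihedral:
        ang = psi[d.residue - 1] if d.angle == "psi" else phi[d.residue - 1]
        dv = abs(_wrap(ang - d.target))
        if dv > d.tolerance:
            tf += spec.w_dihedral * (dv - d.tolerance) ** 2
    # steric over CA/SC with residue separation >= 2
    atoms = [(r, n) for r in range(1, structure.n_residues + 1)
             for n in ("CA", "SC")]
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if atoms[j][0] - atoms[i][0] < 2:
                continue
            d = np.linalg.norm(structure.atom(*atoms[i]) - structure.atom(*atoms[j]))
            if d < spec.steric_radius:
                tf += spec.w_steric * (spec.steric_radius - d) ** 2
    return tf


class TestTargetFunction:
    def test_satisfied_restraints_zero(self, helix21):
        r = DistanceRestraint([((1, "CA"), (2, "CA"))], 0.0, 5.0)
        d = DihedralRestraint(5, "phi", -57.0, 20.0)
        assert target_function(helix21, RestraintSet([r], [d])) == 0.0

    def test_single_violation_quadratic(self, helix21):
        d = np.linalg.norm(helix21.atom(1, "CA") - helix21.atom(5, "CA"))
        r = DistanceRestraint([((1, "CA"), (5, "CA"))], 0.0, d - 1.0)
        spec = TargetFunctionSpec(w_steric=0.0)
        assert target_function(helix21, RestraintSet([r], []), spec) == \
            pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_on_random_instances(self, rng):
        spec = TargetFunctionSpec()
        for trial in range(20):
            n = int(rng.integers(5, 15))
            dih = rng.uniform(-170, 170, (n, 2))
            s = build_backbone("A" * n, dih)
            dist = []
            for k in range(int(rng.integers(3, 12))):
                i, j = rng.choice(np.arange(1, n + 1), 2, replace=False)
                names = rng.choice(["N", "CA", "C", "O", "CB", "SC"], 2)
                cands = [((int(i), str(names[0])), (int(j), str(names[1])))]
                if rng.random() < 0.3:
                    i2, j2 = rng.choice(np.arange(1, n + 1), 2, replace=False)
                    cands.append(((int(i2), "N"), (int(j2), "SC")))
                lo = float(rng.uniform(0, 3))
                dist.append(DistanceRestraint(cands, lo, lo + float(rng.uniform(0.5, 5))))
            dihe = [DihedralRestraint(int(rng.integers(1, n + 1)),
                                      str(rng.choice(["phi", "psi"])),
                                      float(rng.uniform(-179, 180)),
                                      float(rng.uniform(5, 30)))
                    for _ in range(int(rng.integers(0, 5)))]
            rset = RestraintSet(dist, dihe)
            got = target_function(s, rset, spec)
            expect = brute_force_tf(s, rset, spec)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_missing_atom_rejected(self, helix21):
        r = DistanceRestraint([((1, "CA"), (99, "CA"))], 0.0, 5.0)
        with pytest.raises(InputError):
            target_function(helix21, RestraintSet([r], []))

    def test_removing_restraint_never_raises_tf(self, helix21, rng):
        spec = TargetFunctionSpec(w_steric=0.0)
        dist = []
        for k in range(8):
            i, j = rng.choice(np.arange(1, 22), 2, replace=False)
            dist.append(DistanceRestraint([((int(i), "CA"), (int(j), "CA"))],
                                          0.0, float(rng.uniform(2, 6))))
        full = target_function(helix21, RestraintSet(dist, []), spec)
        for k in range(len(dist)):
            reduced = dist[:k] + dist[k + 1:]
            assert target_function(helix21, RestraintSet(reduced, []), spec) <= full + 1e-12


class TestAnneal:
    def test_no_restraints_zero_tf(self):
        cfg = ProtocolConfig.scaled(seed=3, n_conformers=4, anneal_steps=300)
        spec = TargetFunctionSpec(w_steric=0.0)
        ens = anneal("A" * 8, RestraintSet([], []), cfg, spec)
        assert np.allclose(ens.energies, 0.0)

    def test_contradictory_bounds_floor(self):
        """upper 4 and lower 10 on one pair: TF >= 2*(3)^2 = 18 >= 9."""
        r1 = DistanceRestraint([((1, "CA"), (8, "CA"))], 0.0, 4.0)
        r2 = DistanceRestraint([((1, "CA"), (8, "CA"))], 10.0, 50.0)
        cfg = ProtocolConfig.scaled(seed=1, n_conformers=6, anneal_steps=500)
        spec = TargetFunctionSpec(w_steric=0.0, w_dihedral=0.0)
        ens = anneal("A" * 8, RestraintSet([r1, r2], []), cfg, spec)
        assert np.all(ens.energies >= 9.0)

    def test_bitwise_reproducible(self, mono3_case):
        rset = mono3_case.calculation_set()
        cfg = ProtocolConfig.scaled(seed=7, n_conformers=4, anneal_steps=400)
        a = anneal(mono3_case.truth.sequence, rset, cfg)
        b = anneal(mono3_case.truth.sequence, rset, cfg)
        assert np.array_equal(a.energies, b.energies)
        for x, y in zip(a.conformers, b.conformers):
            assert np.array_equal(x.coords, y.coords)

    def test_dense_exact_restraints_recover_fold(self, mono3_case):
        """A complete +-0.5 Å CA-CA distance net (< 12 Å pairs) refolds the
        toy bundle to within 2 Å backbone RMSD."""
        truth = mono3_case.truth
        ca = truth.ca_coords()
        dist = []
        n = truth.n_residues
        for i in range(n):
            for j in range(i + 2, n):
                d = float(np.linalg.norm(ca[i] - ca[j]))
                if d < 12.0:
                    dist.append(DistanceRestraint(
                        [((i + 1, "CA"), (j + 1, "CA"))],
                        max(0.0, d - 0.5), d + 0.5))
        dihe = [DihedralRestraint(i + 1, a, float(t), 20.0)
                for i, c in enumerate(mono3_case.ss) if c == "H"
                for a, t in (("phi", truth.phi[i]), ("psi", truth.psi[i]))]
        cfg = ProtocolConfig.scaled(seed=11, n_conformers=24, anneal_steps=2500)
        ens = anneal(truth.sequence, RestraintSet(dist, dihe), cfg)
        rmsd, _ = superpose(ens.best, truth, selection=("N", "CA", "C"))
        assert rmsd <= 2.0

    def test_restraint_to_absent_residue_rejected(self):
        r = DistanceRestraint([((1, "CA"), (50, "CA"))], 0.0, 5.0)
        cfg = ProtocolConfig.scaled(seed=1, n_conformers=2, anneal_steps=100)
        with pytest.raises(InputError):
            anneal("A" * 10, RestraintSet([r], []), cfg)


class TestRankingRules:
    def test_dominated_hypothesis_ranks_lower(self):
        from emnmr.restraints import AssignmentHypothesis
        a = ScoreCard(AssignmentHypothesis(((0, 0),)), 10.0, 0.9)
        b = ScoreCard(AssignmentHypothesis(((0, 1),)), 10.0, 0.4)
        ranked = _pareto_rank([b, a])
        assert ranked[0].overlap_fraction == 0.9

    def test_pareto_front_before_dominated(self):
        from emnmr.restraints import AssignmentHypothesis
        cards = [
            ScoreCard(AssignmentHypothesis(((0, 0),)), 1.0, 0.2),   # front
            ScoreCard(AssignmentHypothesis(((0, 1),)), 5.0, 0.9),   # front
            ScoreCard(AssignmentHypothesis(((0, 2),)), 6.0, 0.1),   # dominated
        ]
        ranked = _pareto_rank(cards)
        labels = [c.hypothesis.label for c in ranked]
        assert labels.index("0>2") == 2


class TestConvergenceRule:
    def test_documented_example(self):
        assert converged([1.00, 0.95, 0.90, 0.88], 0.10, 3)

    def test_halving_series_never_converges(self):
        series = [8.0, 4.0, 2.0, 1.0, 0.5, 0.25]
        for k in range(2, len(series) + 1):
            assert not converged(series[:k], 0.10, 3)

    def test_exhaustive_small_series(self):
        """All series up to length 6 over a value grid, brute-forced."""
        import itertools
        grid = [1.0, 0.95, 0.9, 0.5, 0.05]
        for n in range(1, 7):
            for series in itertools.product(grid, repeat=n):
                expect = False
                if n >= 4:
                    changes = [abs(b - a) / a for a, b in zip(series[-4:-1],
                                                             series[-3:])]
                    expect = all(c < 0.10 for c in changes)
                assert converged(series, 0.10, 3) == expect, series


class TestDisambiguationRule:
    def test_exhaustive_candidate_configurations(self, helix21):
        """Every <8 Å membership pattern over up to 6 candidates: resolves
        iff exactly one candidate is short."""
        import itertools
        # candidate pool with known distances: consecutive CA ~3.8 (short),
        # termini pair > 8 (long)
        short_pair = ((1, "CA"), (2, "CA"))
        long_pairs = [((1, "CA"), (k, "CA")) for k in (15, 17, 19, 21)]
        assert np.linalg.norm(helix21.atom(1, "CA") - helix21.atom(15, "CA")) > 8
        ens = Ensemble([helix21.copy(), helix21.copy()], np.zeros(2))
        for n_cand in range(2, 7):
            for n_short in range(0, min(n_cand, 2) + 1):
                shorts = [short_pair, ((2, "CA"), (3, "CA"))][:n_short]
                longs = long_pairs[:n_cand - n_short]
                if len(shorts) + len(longs) < 2:
                    continue
                r = DistanceRestraint(shorts + longs, 0.0, 9.0, "NOE")
                resolved, still = disambiguate([r], ens, cutoff=8.0)
                if n_short == 1:
                    assert resolved and resolved[0].candidates[0] == short_pair
                else:
                    assert still and not resolved


class TestFlexibleFit:
    def test_at_optimum_barely_moves(self, mono3_case):
        fitted = flexible_fit(mono3_case.truth, mono3_case.dmap)
        disp = np.sqrt(np.mean(np.sum((fitted.coords - mono3_case.truth.coords) ** 2,
                                      axis=1)))
        assert disp < 0.2

    def test_constant_map_unchanged(self, helix21):
        m = DensityMap(np.ones((40, 40, 40), np.float32), 2.0,
                       helix21.coords.min(axis=0) - 20.0)
        fitted = flexible_fit(helix21, m)
        assert np.allclose(fitted.coords, helix21.coords)

    def test_recovers_rigid_displacement(self, mono3_case):
        shifted = mono3_case.truth.copy()
        shifted.coords = shifted.coords + np.array([2.0, 1.5, 1.5])
        fitted = flexible_fit(shifted, mono3_case.dmap)
        dev = np.sqrt(np.mean(np.sum((fitted.coords - mono3_case.truth.coords) ** 2,
                                     axis=1)))
        assert dev < 1.0

    def test_geometry_regularized(self, mono3_case):
        from emnmr.calc.fit import _bond_list
        shifted = mono3_case.truth.copy()
        shifted.coords = shifted.coords + 1.5
        fitted = flexible_fit(shifted, mono3_case.dmap)
        for i, j, b in _bond_list(fitted.n_residues):
            d = np.linalg.norm(fitted.coords[j] - fitted.coords[i])
            assert abs(d - b) / b < 0.02

    def test_structure_outside_map_rejected(self, helix21):
        m = DensityMap(np.ones((8, 8, 8), np.float32), 1.0,
                       np.array([500.0, 500.0, 500.0]))
        with pytest.raises(InputError):
            flexible_fit(helix21, m)


class TestRefineStep3Contracts:
    def test_strict_symmetry_exact(self, mono3_case):
        """Chains of the refined assembly are exact operator images."""
        from emnmr.calc.refine import refine_step3
        group = SymmetryGroup.cyclic(3)
        # place the protomer off-axis so images do not overlap
        prot = mono3_case.truth.copy()
        prot.coords = prot.coords - prot.coords.mean(axis=0) + np.array([30.0, 0, 0])
        from emnmr.model import apply_symmetry
        chains = apply_symmetry(prot, group)
        asm_map = simulate_map(chains, 8.0, 2.0)
        asm_map.nominal_resolution = 8.0
        cfg = ProtocolConfig.scaled(seed=2, resolution_schedule=(8.0,))
        ens = Ensemble([prot], np.zeros(1))
        out = refine_step3(ens, asm_map, group, mono3_case.calculation_set(),
                           cfg, n_structures=1)
        assembly = out.best_assembly
        assert len(assembly) == 3
        for k, (rot, tr) in enumerate(group.operators):
            expect = out.protomers.best.coords @ rot.T + tr
            assert np.array_equal(assembly[k].coords, expect)

    def test_schedule_finer_than_map_rejected(self, mono3_case):
        from emnmr.calc.refine import refine_step3
        cfg = ProtocolConfig.scaled(seed=2, resolution_schedule=(8.0, 4.0, 2.0))
        ens = Ensemble([mono3_case.truth], np.zeros(1))
        with pytest.raises(InputError):
            refine_step3(ens, mono3_case.map_fine, SymmetryGroup.identity(),
                         mono3_case.calculation_set(), cfg)
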