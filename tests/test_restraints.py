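"""Restraint model: enumeration, pruning, conversions, disambiguation, I/O."""

import itertools
import math

import numpy as np
import pytest

from emnmr.features import HelixDensity, SequenceHelix
from emnmr.model import Ensemble, InputError
from emnmr.restraints import (DihedralRestraint, DistanceRestraint,
                              ParseError, RestraintSet, classify_restraints,
                              count_assignments, disambiguate,
                              enumerate_assignments, filter_intersubunit,
                              fix_positions, hypothesis_to_restraints,
                              read_restraints, site_restraints,
                              write_restraints)


def _densities(lengths, spacing=20.0):
    return [HelixDensity(np.array([k * spacing, 0, 0]), np.array([0, 0, 1.0]),
                         float(L), 0.8) for k, L in enumerate(lengths)]


def _seq_helices(res_lengths):
    out = []
    pos = 1
    for L in res_lengths:
        out.append(SequenceHelix(pos, pos + L - 1))
        pos += L + 4
    return out


class TestEnumeration:
    def test_two_by_two_center_only(self):
        hyps = enumerate_assignments(_seq_helices([10, 10]), _densities([15, 15]),
                                     prune=False)
        assert len(hyps) == 2

    def test_oriented_count_matches_printed_scale(self):
        """8 sequence helices x 7 rods, oriented, unpruned: the ordered
        injective count with 2 orientations per rod."""
        assert count_assignments(8, 7, oriented=True) == 5_160_960
        assert count_assignments(8, 7, oriented=True) == \
            math.perm(8, 7) * 2 ** 7

    @pytest.mark.parametrize("n_seq,n_den", [(3, 2), (4, 4), (5, 3), (6, 2)])
    def test_enumeration_matches_closed_form(self, n_seq, n_den):
        seqh = _seq_helices([10] * n_seq)
        dens = _densities([15] * n_den)
        for mode, oriented in (("center-only", False), ("oriented", True)):
            hyps = enumerate_assignments(seqh, dens, mode=mode, prune=False)
            assert len(hyps) == count_assignments(n_seq, n_den, oriented)

    def test_closed_form_random_sizes_oracle(self, rng):
        for _ in range(50):
            n_seq = int(rng.integers(1, 7))
            n_den = int(rng.integers(1, n_seq + 1))
            brute = sum(1 for _ in itertools.permutations(range(n_seq), n_den))
            assert count_assignments(n_seq, n_den, False) == brute
            assert count_assignments(n_seq, n_den, True) == brute * 2 ** n_den

    def test_pruning_example(self):
        """30 Å sequence helix must take the 31 Å rod (tol 3 Å)."""
        seqh = [SequenceHelix(1, 10), SequenceHelix(15, 24), SequenceHelix(30, 49)]
        assert [h.length_A for h in seqh] == [15.0, 15.0, 30.0]
        dens = _densities([14.0, 31.0])
        hyps = enumerate_assignments(seqh, dens, length_tol_A=3.0, prune=True)
        assert len(hyps) == 2
        for h in hyps:
            mapping = dict(h.mapping)
            assert mapping[1] == 2  # the 31 Å rod takes the 30 Å helix

    def test_pruning_soundness_brute_force(self, rng):
        """Pruning never removes a mapping whose every pair fits the tol."""
        for trial in range(10):
            n_den = int(rng.integers(2, 5))
            n_seq = int(rng.integers(n_den, 6))
            seqh = _seq_helices([int(x) for x in rng.integers(6, 20, n_seq)])
            dens = _densities([float(x) for x in rng.uniform(8, 32, n_den)])
            tol = float(rng.uniform(2, 8))
            kept = {h.mapping for h in enumerate_assignments(
                seqh, dens, length_tol_A=tol, prune=True)}
            for perm in itertools.permutations(range(n_seq), n_den):
                fits = all(abs(seqh[s].length_A - dens[d].length) <= tol
                           for d, s in enumerate(perm))
                mapping = tuple((d, s) for d, s in enumerate(perm))
                assert (mapping in kept) == fits

    def test_more_densities_than_helices_rejected(self):
        with pytest.raises(InputError):
            enumerate_assignments(_seq_helices([10]), _densities([15, 15]))


class TestHypothesisToRestraints:
    def test_pair_count(self):
        seqh = _seq_helices([8] * 5)
        dens = _densities([12] * 5)
        hyps = enumerate_assignments(seqh, dens, prune=False)
        pins = hypothesis_to_restraints(hyps[0], dens, seqh)
        assert len(pins) == 10  # C(5, 2)

    def test_bounds_bracket_center_distance(self):
        seqh = _seq_helices([8, 8])
        dens = [HelixDensity(np.zeros(3), [0, 0, 1], 12.0, 0.8),
                HelixDensity(np.array([20.0, 0, 0]), [0, 0, 1], 12.0, 0.8)]
        hyps = enumerate_assignments(seqh, dens, prune=False)
        pins = hypothesis_to_restraints(hyps[0], dens, seqh, tol=0.5)
        assert len(pins) == 1
        assert pins[0].lower == pytest.approx(19.5)
        assert pins[0].upper == pytest.approx(20.5)
        assert pins[0].origin == "HELIX_CENTER"

    def test_single_helix_no_pairs(self):
        seqh = _seq_helices([8])
        dens = _densities([12])
        hyps = enumerate_assignments(seqh, dens, prune=False)
        assert hypothesis_to_restraints(hyps[0], dens, seqh) == []


class TestFixPositions:
    def test_two_atoms_single_restraint(self, helix21):
        # restrict to one residue pair -> 3+3 atoms; cap keeps all pairs small
        out = fix_positions(helix21, [1], tol=0.5)
        # 3 atoms of one residue -> C(3,2) = 3 restraints
        assert len(out) == 3
        for r in out:
            assert r.origin == "EM_FIX"
            d = np.linalg.norm(helix21.atom(*r.candidates[0][0]) -
                               helix21.atom(*r.candidates[0][1]))
            assert r.lower == pytest.approx(d - 0.5, abs=1e-9)
            assert r.upper == pytest.approx(d + 0.5, abs=1e-9)

    def test_empty_flag_set(self, helix21):
        assert fix_positions(helix21, []) == []

    def test_restores_geometry_under_annealing(self, helix21, rng):
        """A perturbed copy annealed under only the pin network recovers the
        pinned substructure's internal geometry within 2x the tolerance."""
        from emnmr.calc.anneal import anneal
        from emnmr.model import ProtocolConfig, superpose
        flagged = list(range(3, 19))
        pins = fix_positions(helix21, flagged, tol=0.5, seed=4)
        phi = helix21.phi + rng.normal(0, 12.0, helix21.n_residues)
        psi = helix21.psi + rng.normal(0, 12.0, helix21.n_residues)
        cfg = ProtocolConfig.scaled(seed=5, n_conformers=8, anneal_steps=1500)
        ens = anneal(helix21.sequence, RestraintSet(pins, []), cfg,
                     initial=(phi, psi))
        sel = ("N", "CA", "C")
        ref = helix21.coords[helix21.select(sel, residues=flagged)]
        got = ens.best.coords[ens.best.select(sel, residues=flagged)]
        rmsd, _ = superpose(got, ref)
        assert rmsd < 1.0

    def test_unknown_residue_rejected(self, helix21):
        with pytest.raises(InputError):
            fix_positions(helix21, [99])


class TestDisambiguate:
    def _ensemble(self, helix21):
        return Ensemble([helix21.copy() for _ in range(3)], np.zeros(3))

    def test_unique_short_candidate_resolves(self, helix21):
        ens = self._ensemble(helix21)
        r = DistanceRestraint([((1, "CA"), (2, "CA")), ((1, "CA"), (20, "CA"))],
                              0.0, 6.0, "NOE")
        resolved, still = disambiguate([r], ens, cutoff=8.0)
        assert len(resolved) == 1 and not still
        assert resolved[0].candidates == [((1, "CA"), (2, "CA"))]

    def test_two_short_candidates_stay_ambiguous(self, helix21):
        ens = self._ensemble(helix21)
        r = DistanceRestraint([((1, "CA"), (2, "CA")), ((2, "CA"), (3, "CA"))],
                              0.0, 6.0, "NOE")
        resolved, still = disambiguate([r], ens, cutoff=8.0)
        assert not resolved and len(still) == 1

    def test_never_drops_restraints(self, helix21, rng):
        ens = self._ensemble(helix21)
        rs = []
        for k in range(10):
            i, j = sorted(rng.choice(np.arange(1, 22), 2, replace=False))
            rs.append(DistanceRestraint(
                [((int(i), "CA"), (int(j), "CA")),
                 ((1, "CA"), (21, "CA"))], 0.0, 8.0, "NOE"))
        resolved, still = disambiguate(rs, ens, cutoff=8.0)
        assert len(resolved) + len(still) == len(rs)

    def test_accuracy_on_labelled_synthetic_truth(self, mono3_case):
        """With a near-truth ensemble, resolved candidates match the labels."""
        amb = [r for r in mono3_case.restraints.distance if r.ambiguous]
        ens = Ensemble([mono3_case.truth.copy() for _ in range(3)], np.zeros(3))
        resolved, _ = disambiguate(amb, ens, cutoff=8.0)
        assert resolved
        labels = mono3_case.labels["true_candidate"]
        by_id = {r.id: r for r in amb}
        n_match = 0
        for r in resolved:
            true_pair = by_id[r.id].candidates[labels[r.id]]
            n_match += r.candidates[0] == true_pair
        assert n_match / len(resolved) >= 0.95

    def test_missing_atom_rejected(self, helix21):
        ens = self._ensemble(helix21)
        r = DistanceRestraint([((1, "CA"), (99, "CA"))], 0.0, 6.0, "NOE")
        with pytest.raises(InputError):
            disambiguate([r], ens)


class TestFilterAndClassify:
    def _set_with_inter(self, n_total=524, n_inter=8):
        dist = []
        for k in range(n_total):
            i = 1 + (k % 40)
            j = i + 2 + (k % 7)
            scope = "inter" if k < n_inter else "intra"
            dist.append(DistanceRestraint([((i, "N"), (j, "N"))], 0.0, 8.0,
                                          "RFDR", scope, k))
        return RestraintSet(dist, [])

    def test_paper_scale_arithmetic(self):
        rset = self._set_with_inter(524, 8)
        kept, removed = filter_intersubunit(rset, range(8))
        assert removed == 8
        assert len(kept.distance) == 516

    def test_empty_labels_identity(self):
        rset = self._set_with_inter(20, 0)
        kept, removed = filter_intersubunit(rset, [])
        assert removed == 0 and len(kept.distance) == 20

    def test_all_labelled_leaves_dihedrals(self):
        rset = self._set_with_inter(10, 0)
        rset.dihedral.append(DihedralRestraint(1, "phi", -57.0, 20.0))
        kept, removed = filter_intersubunit(rset, range(10))
        assert removed == 10 and not kept.distance and len(kept.dihedral) == 1

    def test_unknown_id_rejected(self):
        with pytest.raises(InputError):
            filter_intersubunit(self._set_with_inter(5, 0), [99])

    def test_counts_conserved_under_filter(self):
        rset = self._set_with_inter(30, 6)
        kept, removed = filter_intersubunit(rset, range(6))
        assert removed + len(kept.distance) == len(rset.distance)

    def test_sequence_separation_convention(self):
        near = DistanceRestraint([((10, "N"), (12, "N"))], 0, 8)
        far = DistanceRestraint([((10, "N"), (14, "N"))], 0, 8)
        counts = classify_restraints(RestraintSet([near, far], []))
        assert counts["short_range"] == 1  # |i-j| = 2 < 4
        assert counts["long_range"] == 1   # |i-j| = 4

    def test_counts_match_generator_bookkeeping(self, mono3_case):
        counts = mono3_case.restraints.counts
        dist = mono3_case.restraints.distance
        assert counts["total_distance"] == len(dist)
        assert counts["ambiguous"] == sum(1 for r in dist if r.ambiguous)
        assert counts["ambiguous"] == len(mono3_case.labels["true_candidate"])
        assert counts["short_range"] + counts["long_range"] == len(dist)


class TestSiteRestraints:
    def test_five_residues_two_centers(self):
        out = site_restraints([68, 182, 213, 235, 323], 2, (2.0, 2.6))
        assert len(out) == 10
        for r in out:
            assert r.origin == "SITE"
            assert (r.lower, r.upper) == (2.0, 2.6)

    def test_zero_centers_empty(self):
        assert site_restraints([68], 0, (2.0, 2.6)) == []


class TestRestraintIO:
    def _sample_set(self, rng, n=50):
        dist = []
        for k in range(n):
            i, j = sorted(rng.choice(np.arange(1, 40), 2, replace=False))
            cands = [((int(i), "N"), (int(j), "SC"))]
            if k % 5 == 0:
                cands.append(((int(i) + 1, "N"), (int(j) - 1, "SC")))
            dist.append(DistanceRestraint(cands, 0.0, float(rng.uniform(4, 8)),
                                          "NOE" if k % 2 else "RFDR", "intra", k))
        dihe = [DihedralRestraint(r, a, -57.0 if a == "phi" else -47.0, 20.0)
                for r in range(1, 6) for a in ("phi", "psi")]
        return RestraintSet(dist, dihe)

    def test_json_round_trip(self, tmp_path, rng):
        rset = self._sample_set(rng)
        path = tmp_path / "r.json"
        write_restraints(rset, path, "json")
        back = read_restraints(path, "json")
        assert back.distance == rset.distance
        assert back.dihedral == rset.dihedral

    def test_upl_semantics(self, tmp_path):
        path = tmp_path / "r.upl"
        path.write_text("   3  ALA N      9  VAL SC      8.00\n")
        rset = read_restraints(path, "upl")
        r = rset.distance[0]
        assert r.upper == 8.0 and r.lower == 0.0
        assert r.candidates == [((3, "N"), (9, "SC"))]

    def test_upl_ambiguous_group_round_trip(self, tmp_path):
        amb = DistanceRestraint([((3, "N"), (9, "SC")), ((4, "N"), (11, "SC"))],
                                0.0, 7.5, "NOE", "intra", 0)
        single = DistanceRestraint([((5, "CA"), (15, "CA"))], 0.0, 6.0,
                                   "NOE", "intra", 1)
        path = tmp_path / "r.upl"
        write_restraints(RestraintSet([amb, single], []), path, "upl",
                         sequence="A" * 20)
        back = read_restraints(path, "upl")
        ambs = [r for r in back.distance if r.ambiguous]
        assert len(ambs) == 1
        assert set(ambs[0].candidates) == set(amb.candidates)
        assert ambs[0].upper == 7.5

    def test_aco_round_trip(self, tmp_path):
        dihe = [DihedralRestraint(3, "phi", -57.0, 20.0),
                DihedralRestraint(3, "psi", -47.0, 15.0)]
        path = tmp_path / "r.aco"
        write_restraints(RestraintSet([], dihe), path, "aco", sequence="A" * 5)
        back = read_restraints(path, "aco")
        assert back.dihedral == dihe

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.upl"
        path.write_text("3 ALA N 9 VAL SC 8.00\nbroken row\n")
        with pytest.raises(ParseError, match=":2"):
            read_restraints(path, "upl")
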