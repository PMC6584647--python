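"""Helix detection, subunit clustering, sequence-helix extraction."""

import numpy as np
import pytest

from emnmr.density import DensityMap, simulate_map
from emnmr.features import (HelixDensity, cluster_into_subunits, detect_helices,
                            helices_from_tsv, helices_to_tsv,
                            sequence_helices_from_ss)
from emnmr.model import InputError, build_backbone
from emnmr.synthetic import true_helix_geometry
from conftest import IDEAL_HELIX_DIHEDRALS, fitted_helix_axis


def _helix_map(n_res: int, resolution: float = 8.0, voxel: float = 2.0):
    s = build_backbone("A" * n_res, [IDEAL_HELIX_DIHEDRALS] * n_res)
    m = simulate_map(s, resolution, voxel)
    m.nominal_resolution = resolution
    return s, m


class TestDetectHelices:
    def test_single_ideal_helix(self):
        s, m = _helix_map(21)
        hits = detect_helices(m, min_length=12.0)
        assert len(hits) == 1
        center, axis, extent = fitted_helix_axis(s.ca_coords())
        ang = np.degrees(np.arccos(min(1.0, abs(hits[0].axis @ axis))))
        assert ang < 10.0
        assert hits[0].length == pytest.approx(30.0, abs=6.0)
        assert np.linalg.norm(hits[0].center - center) < 4.0

    def test_all_zero_map_empty(self):
        m = DensityMap(np.zeros((16, 16, 16), np.float32), 2.0, np.zeros(3),
                       nominal_resolution=8.0)
        assert detect_helices(m) == []

    def test_three_helix_bundle(self, mono3_case):
        hits = detect_helices(mono3_case.dmap, min_length=10.0)
        geo = true_helix_geometry(mono3_case.truth, mono3_case.ss)
        assert len(hits) == 3
        matched = set()
        for h in hits:
            dists = [np.linalg.norm(g[0] - h.center) for g in geo]
            k = int(np.argmin(dists))
            assert dists[k] < 4.0
            matched.add(k)
        assert matched == {0, 1, 2}

    def test_length_monotone_in_true_length(self):
        lengths = []
        for n_res in (10, 16, 24):
            _, m = _helix_map(n_res)
            hits = detect_helices(m, min_length=8.0)
            assert len(hits) >= 1
            lengths.append(hits[0].length)
        assert lengths[0] < lengths[1] < lengths[2]

    def test_rotation_equivariance(self):
        """Rotating the map grid by 90° rotates the detected axis with it."""
        s, m = _helix_map(18)
        hits = detect_helices(m, min_length=10.0)
        rot_grid = np.rot90(m.grid, k=1, axes=(0, 1)).copy()
        m_rot = DensityMap(rot_grid, m.voxel, m.origin, nominal_resolution=8.0)
        hits_rot = detect_helices(m_rot, min_length=10.0)
        assert hits and hits_rot
        # x -> y, y -> -x under this grid rotation (up to axis sign freedom)
        a = hits[0].axis
        expect = np.array([-a[1], a[0], a[2]])
        ang = np.degrees(np.arccos(min(1.0, abs(hits_rot[0].axis @ expect))))
        assert ang < 15.0

    def test_resolution_out_of_range_rejected(self):
        _, m = _helix_map(18)
        m.nominal_resolution = 2.0
        with pytest.raises(InputError):
            detect_helices(m)


class TestClusterIntoSubunits:
    def _fake_subunit(self, origin, rng, n=5, spread=9.0):
        out = []
        for _ in range(n):
            c = origin + rng.normal(0, spread / 3, 3)
            out.append(HelixDensity(c, rng.normal(0, 1, 3), 15.0, 0.8))
        return out

    def test_single_group(self, rng):
        helices = self._fake_subunit(np.zeros(3), rng)
        clusters, noise = cluster_into_subunits(helices)
        assert len(clusters) == 1 and len(clusters[0]) == 5 and not noise

    def test_three_separated_groups(self, rng):
        helices = []
        for origin in (np.zeros(3), np.array([60.0, 0, 0]), np.array([0, 60.0, 0])):
            helices += self._fake_subunit(origin, rng)
        clusters, noise = cluster_into_subunits(helices, expected_per_subunit=5)
        assert sorted(len(c) for c in clusters) == [5, 5, 5]
        assert not noise

    def test_far_helix_is_noise(self, rng):
        helices = self._fake_subunit(np.zeros(3), rng)
        helices.append(HelixDensity(np.array([400.0, 400.0, 400.0]),
                                    np.array([1.0, 0, 0]), 15.0, 0.8))
        clusters, noise = cluster_into_subunits(helices)
        assert len(noise) == 1
        assert np.allclose(noise[0].center, [400, 400, 400])

    def test_partition_covers_non_noise_exactly_once(self, rng):
        helices = self._fake_subunit(np.zeros(3), rng) + \
            self._fake_subunit(np.array([55.0, 5.0, 0]), rng)
        clusters, noise = cluster_into_subunits(helices)
        seen = [id(h) for cl in clusters for h in cl] + [id(h) for h in noise]
        assert sorted(seen) == sorted(id(h) for h in helices)

    def test_c3_assembly_clusters(self, c3_case):
        """Synthetic trimer: detected rods cluster 3 x 5 per subunit."""
        case = c3_case
        hits = detect_helices(case.dmap, min_length=10.0)
        assert len(hits) >= 12
        clusters, _ = cluster_into_subunits(hits, expected_per_subunit=5)
        assert len(clusters) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            cluster_into_subunits([])


class TestSequenceHelices:
    def test_simple_run(self):
        out = sequence_helices_from_ss("CCHHHHHHCC")
        assert len(out) == 1
        h = out[0]
        assert (h.start, h.end, h.central_residue) == (3, 8, 5)
        assert h.length_res == 6
        assert h.length_A == pytest.approx(9.0)

    def test_all_coil_empty(self):
        assert sequence_helices_from_ss("C" * 40) == []

    def test_eight_runs_sorted_with_tie_order(self):
        runs = [12, 9, 9, 5, 4, 4, 4, 4]
        ss = "C".join("H" * r for r in runs)
        out = sequence_helices_from_ss(ss, min_len_res=4)
        assert len(out) == 8
        assert [h.length_res for h in out] == sorted(runs, reverse=True)
        # ties ordered by start index
        for a, b in zip(out, out[1:]):
            if a.length_res == b.length_res:
                assert a.start < b.start
        # verify against direct enumeration
        starts = []
        pos = 1
        for r in runs:
            starts.append(pos)
            pos += r + 1
        expect = sorted(zip([-r for r in runs], starts))
        assert [(h.start, h.length_res) for h in out] == \
            [(s, -nr) for nr, s in expect]

    def test_min_length_filter(self):
        assert sequence_helices_from_ss("HHHHCCHHH", min_len_res=4)[0].start == 1
        assert len(sequence_helices_from_ss("HHHHCCHHH", min_len_res=4)) == 1

    def test_invalid_codes_rejected(self):
        with pytest.raises(InputError):
            sequence_helices_from_ss("HHXX")
        with pytest.raises(InputError):
            sequence_helices_from_ss("HHHH", min_len_res=3)


def test_helix_tsv_round_trip(tmp_path, rng):
    helices = [HelixDensity(rng.normal(0, 20, 3), rng.normal(0, 1, 3),
                            float(10 + 5 * k), 0.5 + 0.1 * k) for k in range(3)]
    path = tmp_path / "helices.tsv"
    helices_to_tsv(helices, path)
    back = helices_from_tsv(path)
    assert len(back) == 3
    for a, b in zip(helices, back):
        assert np.allclose(a.center, b.center, atol=1e-3)
        assert np.allclose(a.axis, b.axis, atol=1e-3)
        assert a.length == pytest.approx(b.length, abs=1e-3)
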