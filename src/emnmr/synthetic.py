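"""Synthetic benchmark generator: ground-truth helical-bundle folds, maps,
and restraint sets with the statistical structure the protocol assumes.

The generator emulates the study conditions end to end: a compact α-helical
bundle built in torsion space, a Gaussian-kernel density map simulated at
high resolution and Fourier-truncated to the working (6–10 Å) resolution,
TALOS-style backbone dihedral restraints for helical residues, and sparse
amide/methyl contact restraints (≤ 8 Å) of which a tunable fraction is
spectrally ambiguous (the true pair is always among the candidates) and,
for assemblies, a small fraction crosses subunits.

Every case regenerates bit-exactly from its manifest (all parameters plus
the seed).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import io as _io
from .density import DensityMap, fourier_truncate, simulate_map, write_map
from .model import (HELIX_RISE_PER_RES, InputError, Structure,
                    SymmetryGroup, build_backbone)
from .restraints import DihedralRestraint, DistanceRestraint, RestraintSet

__all__ = ["BenchmarkCase", "GenerationError", "make_toy_fold",
           "simulate_restraints", "make_benchmark", "CASES",
           "true_helix_geometry"]


class GenerationError(RuntimeError):
    """Rejection sampling failed; loosen the fold parameters."""


IDEAL_HELIX = (-57.0, -47.0)

# Loop conformation library: (φ, ψ) runs from allowed Ramachandran regions,
# pre-selected so that two ideal helices joined by the loop come out roughly
# antiparallel at bundle-like (~10 Å) axis spacing.  Generation jitters
# these and rejection-samples the whole fold for self-avoidance and
# compactness, so the library biases — but does not fix — the topology.
_TURNS_5 = [
    [(-47, -27), (-51, -41), (-105, 11), (27, 50), (-99, 134)],
    [(69, 55), (-118, 147), (-85, 7), (-118, -17), (-69, -24)],
    [(-76, -41), (-137, 106), (-97, 116), (81, 64), (-127, 122)],
    [(64, 48), (-82, 138), (-64, 157), (39, 44), (-119, -20)],
    [(-82, 171), (-114, 122), (-136, 179), (-112, 149), (73, 52)],
    [(81, 44), (-62, 164), (-113, 3), (-116, 109), (-83, -11)],
    [(75, 44), (-78, 152), (-63, -44), (-119, 155), (-122, 34)],
    [(64, 69), (-121, 134), (-116, 0), (-65, 144), (-44, -28)],
]
_TURNS_4 = [
    [(87.7, 69.6), (-103.1, 163.7), (-83.3, 168.2), (69.5, 35.8)],
    [(71.9, 9.9), (-91.9, -30.5), (-67.9, 121.3), (-63.2, 152.1)],
    [(40.8, 40.5), (-120.1, -23.0), (37.5, 60.3), (-99.0, 165.8)],
    [(71.6, 37.8), (-146.3, 99.9), (48.8, 64.1), (-90.4, -13.8)],
    [(80.1, 35.7), (-87.2, -56.3), (-79.0, 134.1), (-68.2, 180.0)],
    [(75.1, 37.0), (-69.2, 161.4), (-54.9, 146.3), (61.0, 46.2)],
    [(-120.5, 76.9), (-130.4, 82.9), (-100.1, -0.5), (-134.6, 114.1)],
    [(-138.7, 122.6), (-75.3, 19.4), (-97.7, 161.3), (50.1, 26.0)],
]

_HYDROPHOBIC = "AVILMF"
MIN_NONBONDED = 2.5  # Å, self-avoidance acceptance rule
RG_FACTOR = 1.2      # compactness: Rg < factor * ideal-bundle Rg


def _ideal_bundle_rg(helix_lens: Sequence[int]) -> float:
    """Rg of an idealised bundle: parallel rods on a hexagonal lattice at
    11 Å axis spacing, each with the α-helix 2.3 Å radial mass spread."""
    s = 11.0
    lattice = s * np.array([(0.0, 0.0), (1.0, 0.0), (0.5, 0.866),
                            (-0.5, 0.866), (-1.0, 0.0), (0.0, 1.732),
                            (1.5, 0.866), (-1.5, 0.866)])
    n = len(helix_lens)
    xy = lattice[:n] - lattice[:n].mean(axis=0)
    mean_r2 = float(np.mean(np.sum(xy ** 2, axis=1))) if n > 1 else 0.0
    axial = float(np.mean([(l * HELIX_RISE_PER_RES) ** 2 / 12 for l in helix_lens]))
    return float(np.sqrt(axial + mean_r2 + 2.3 ** 2))


def _loop_dihedrals(llen: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    if llen >= 5:
        motif = _TURNS_5[rng.integers(0, len(_TURNS_5))]
        pre = [( -120 + rng.normal(0, 15), 130 + rng.normal(0, 15))
               for _ in range(llen - 5)]
        base = pre + [tuple(p) for p in motif]
    elif llen == 4:
        base = [tuple(p) for p in _TURNS_4[rng.integers(0, len(_TURNS_4))]]
    else:
        base = [(-120 + rng.normal(0, 30), 130 + rng.normal(0, 30))
                for _ in range(llen)]
    out = []
    for p, s in base:
        out.append((p + rng.normal(0, 6.0), s + rng.normal(0, 6.0)))
    return out


def _self_avoiding(s: Structure) -> bool:
    res_ids = np.repeat(np.arange(s.n_residues), 6)
    pairs = cKDTree(s.coords).query_pairs(MIN_NONBONDED, output_type="ndarray")
    if len(pairs) == 0:
        return True
    gaps = np.abs(res_ids[pairs[:, 0]] - res_ids[pairs[:, 1]])
    return not bool((gaps >= 2).any())


def _pack_loops(arr: np.ndarray, lens: Sequence[int], loop_len: int,
                seed: int) -> tuple[np.ndarray, float]:
    """Anneal loop torsions only (helices frozen) against a bundle-packing
    objective: adjacent helix centers at 9–12 Å, non-adjacent ones kept
    apart, plus an all-atom soft-sphere term."""
    from . import _kernels as K
    nres = len(arr)
    phi = np.ascontiguousarray(arr[:, 0].copy())
    psi = np.ascontiguousarray(arr[:, 1].copy())
    free = np.zeros(2 * nres, dtype=np.int8)
    starts = np.cumsum([0] + [l + loop_len for l in lens[:-1]])
    centers = []
    for st, hl in zip(starts, lens):
        centers.append(st + hl // 2)
        if st + hl < nres:
            for i in range(st + hl, min(nres, st + hl + loop_len)):
                free[i] = 1
                free[nres + i] = 1
    ci, cj, lo, up = [], [], [], []
    for a in range(len(centers)):
        for b in range(a + 1, len(centers)):
            ci.append(centers[a] * 6 + 1)
            cj.append(centers[b] * 6 + 1)
            if b == a + 1:
                lo.append(8.5)
                up.append(11.5)
            elif b == a + 2:
                lo.append(9.0)
                up.append(18.0)
            else:
                lo.append(9.0)
                up.append(24.0)
    ci = np.array(ci, dtype=np.int64)
    cj = np.array(cj, dtype=np.int64)
    gp = np.arange(len(ci) + 1, dtype=np.int64)
    lo = np.array(lo)
    up = np.array(up)
    empty_i = np.zeros(0, dtype=np.int64)
    empty_b = np.zeros(0, dtype=np.int8)
    empty_f = np.zeros(0)
    steric_atoms = np.arange(nres * 6, dtype=np.int64)
    steric_res = np.repeat(np.arange(nres), 6).astype(np.int64)
    # steric floor 0.3 Å above the acceptance rule: a packed fold with
    # TF = 0 is then self-avoiding by construction
    tf = K.mc_anneal(phi, psi, free, 4000, 30.0, 0.02, seed % (2 ** 31),
                     ci, cj, gp, lo, up,
                     empty_i, empty_b, empty_f, empty_f,
                     steric_atoms, steric_res, MIN_NONBONDED + 0.3,
                     1.0, 1.0, 0.0025, 1.0, 1500)
    return np.column_stack([phi, psi]), tf


def make_toy_fold(n_helices: int, helix_len_res: int | Sequence[int],
                  loop_len_res: int, seed: int,
                  max_attempts: int = 40) -> tuple[Structure, str]:
    """Compact self-avoiding helical-bundle backbone, deterministic per seed.

    Helices are ideal (−57, −47) α-helices with ±2° jitter.  Loops start
    from the turn library with ±6° jitter and are then packed: a short
    annealing over the loop torsions alone drives adjacent helix axes to
    bundle spacing while a soft-sphere term removes clashes.  The packed
    fold is accepted only if it is self-avoiding (non-bonded atoms > 2.5 Å
    for |i−j| ≥ 2) and compact (CA radius of gyration < 1.2× that of an
    ideal bundle); otherwise a fresh attempt is drawn.
    """
    if n_helices < 1:
        raise InputError("need at least one helix")
    lens = ([int(helix_len_res)] * n_helices if np.isscalar(helix_len_res)
            else [int(x) for x in helix_len_res])
    if len(lens) != n_helices:
        raise InputError("helix_len_res list length must equal n_helices")
    rg_max = RG_FACTOR * _ideal_bundle_rg(lens)
    rng_seq = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        sub = (seed * 100003 + attempt) % (2 ** 31)
        rng = np.random.default_rng(sub)
        dihedrals: list[tuple[float, float]] = []
        ss = []
        for h, hlen in enumerate(lens):
            for _ in range(hlen):
                dihedrals.append((IDEAL_HELIX[0] + rng.normal(0, 2.0),
                                  IDEAL_HELIX[1] + rng.normal(0, 2.0)))
                ss.append("H")
            if h < n_helices - 1:
                dihedrals.extend(_loop_dihedrals(loop_len_res, rng))
                ss.extend("C" * loop_len_res)
        arr = np.clip(np.array(dihedrals), -179.9, 180.0)
        seq = "".join(_HYDROPHOBIC[rng_seq.integers(0, len(_HYDROPHOBIC))]
                      for _ in range(len(arr)))
        if n_helices == 1:
            return build_backbone(seq, arr), "".join(ss)
        arr, tf = _pack_loops(arr, lens, loop_len_res, sub)
        if tf > 5.0:  # packing grossly unsatisfied; the explicit rules below decide
            continue
        s = build_backbone(seq, arr)
        ca = s.ca_coords()
        rg = float(np.sqrt(np.mean(np.sum((ca - ca.mean(axis=0)) ** 2, axis=1))))
        if rg < rg_max and _self_avoiding(s):
            return s, "".join(ss)
    raise GenerationError(
        f"no acceptable fold in {max_attempts} attempts; loosen helix/loop "
        "lengths or the compactness factor")


# ---------------------------------------------------------------------------
# restraints


@dataclasses.dataclass
class RestraintParams:
    contact_cutoff: float = 8.0
    coverage: float = 0.6
    ambiguity_rate: float = 0.2
    decoy_count: int = 2
    inter_subunit_rate: float = 0.0
    bound_padding: float = 1.0
    dihedral_tol: float = 20.0

    def __post_init__(self) -> None:
        for r in (self.coverage, self.ambiguity_rate, self.inter_subunit_rate):
            if not 0 <= r <= 1:
                raise InputError("rates must be in [0, 1]")


def _contact_atoms(s: Structure) -> tuple[np.ndarray, list]:
    """Amide N and methyl-centroid SC atoms — the observable contact classes."""
    refs = [(r, n) for r in range(1, s.n_residues + 1) for n in ("N", "SC")]
    pos = np.array([s.atom(r, n) for r, n in refs])
    return pos, refs


def simulate_restraints(truth: Structure, params: RestraintParams | None = None,
                        seed: int = 0, ss: str | None = None,
                        assembly: list[Structure] | None = None
                        ) -> tuple[RestraintSet, dict]:
    """Draw a restraint set the way the experiments would observe it.

    Returns (restraints, labels) where labels holds the ground truth the
    benchmarks score against: the true candidate index of every ambiguous
    restraint and the ids of inter-subunit contacts.
    """
    p = params or RestraintParams()
    rng = np.random.default_rng(seed)
    pos, refs = _contact_atoms(truth)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(p.contact_cutoff, output_type="ndarray")
    contacts = []
    for i, j in pairs:
        (ri, ai), (rj, aj) = refs[i], refs[j]
        if abs(ri - rj) < 2:
            continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        contacts.append(((ri, ai), (rj, aj), d))
    if not contacts:
        raise GenerationError("no contacts under the cutoff")
    contacts.sort()
    keep = rng.random(len(contacts)) < p.coverage
    selected = [c for c, k in zip(contacts, keep) if k]

    all_pairs_by_class: dict[tuple[str, str], list] = {}
    for (ri, ai), (rj, aj), _ in contacts:
        pass  # decoys are drawn from the full same-class pair space below
    n_res = truth.n_residues

    def random_same_class_pair(ai: str, aj: str, exclude):
        for _ in range(200):
            ri = int(rng.integers(1, n_res + 1))
            rj = int(rng.integers(1, n_res + 1))
            if abs(ri - rj) < 2:
                continue
            cand = ((ri, ai), (rj, aj))
            if cand not in exclude and (cand[1], cand[0]) not in exclude:
                return cand
        raise GenerationError("cannot draw decoy pair")

    dist: list[DistanceRestraint] = []
    true_candidate: dict[int, int] = {}
    rid = 0
    for (a, b, d) in selected:
        origin = "NOE" if a[1] == "SC" and b[1] == "SC" else "RFDR"
        upper = d + p.bound_padding
        if rng.random() < p.ambiguity_rate:
            cands = [(a, b)]
            used = {(a, b)}
            for _ in range(p.decoy_count):
                c = random_same_class_pair(a[1], b[1], used)
                used.add(c)
                cands.append(c)
            order = rng.permutation(len(cands))
            cands = [cands[k] for k in order]
            ti = int(np.where(order == 0)[0][0])
            r = DistanceRestraint(cands, 0.0, upper, origin, "intra", rid)
            true_candidate[rid] = ti
        else:
            r = DistanceRestraint([(a, b)], 0.0, upper, origin, "intra", rid)
        dist.append(r)
        rid += 1

    inter_ids: list[int] = []
    if assembly is not None and len(assembly) > 1 and p.inter_subunit_rate > 0:
        inter_contacts = _inter_chain_contacts(assembly, p.contact_cutoff)
        n_inter = min(len(inter_contacts),
                      int(round(p.inter_subunit_rate * len(selected)
                                / max(1e-9, 1 - p.inter_subunit_rate))))
        if n_inter > 0:
            idx = rng.choice(len(inter_contacts), size=n_inter, replace=False)
            for k in sorted(int(i) for i in idx):
                a, b, d = inter_contacts[k]
                origin = "NOE" if a[1] == "SC" and b[1] == "SC" else "RFDR"
                dist.append(DistanceRestraint([(a, b)], 0.0,
                                              d + p.bound_padding, origin,
                                              "inter", rid))
                inter_ids.append(rid)
                rid += 1

    dihe: list[DihedralRestraint] = []
    if ss is not None and truth.phi is not None:
        for i, code in enumerate(ss):
            if code != "H":
                continue  # loops carry no dihedral information
            dihe.append(DihedralRestraint(i + 1, "phi",
                                          float(truth.phi[i]), p.dihedral_tol))
            dihe.append(DihedralRestraint(i + 1, "psi",
                                          float(truth.psi[i]), p.dihedral_tol))
    rset = RestraintSet(dist, dihe)
    labels = {"true_candidate": true_candidate, "inter_subunit": inter_ids}
    return rset, labels


def _inter_chain_contacts(assembly: list[Structure], cutoff: float):
    """Contacts between chain 0 and any other chain, expressed (deceptively,
    as in the real experiment) in single-chain residue numbering."""
    pos0, refs0 = _contact_atoms(assembly[0])
    out = []
    seen = set()
    for other in assembly[1:]:
        pos1, refs1 = _contact_atoms(other)
        t = cKDTree(pos1)
        for i, neigh in enumerate(t.query_ball_point(pos0, cutoff)):
            for j in neigh:
                a, b = refs0[i], refs1[j]
                key = (a, b)
                if key in seen:
                    continue
                seen.add(key)
                d = float(np.linalg.norm(pos0[i] - pos1[j]))
                out.append((a, b, d))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# benchmark cases


@dataclasses.dataclass
class BenchmarkCase:
    name: str
    truth: Structure
    ss: str
    dmap: DensityMap            # working-resolution (Fourier-truncated) map
    map_fine: DensityMap        # high-resolution simulated map (for schedules)
    restraints: RestraintSet    # full set, inter-subunit contacts included
    labels: dict
    manifest: dict
    assembly: list[Structure] | None = None
    symmetry: SymmetryGroup | None = None

    def calculation_set(self) -> RestraintSet:
        """Single-chain calculation set: labelled inter-subunit contacts removed."""
        from .restraints import filter_intersubunit
        kept, _ = filter_intersubunit(self.restraints, self.labels["inter_subunit"])
        return kept

    def save(self, directory) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        _io.write_structure(self.truth, d / "truth.pdb")
        if self.assembly is not None:
            _io.write_structure(self.assembly, d / "assembly.pdb")
        write_map(self.dmap, d / "map.ccp4")
        from .restraints import write_restraints
        write_restraints(self.restraints, d / "restraints.json")
        write_restraints(self.restraints, d / "restraints.upl", "upl",
                         sequence=self.truth.sequence)
        write_restraints(self.restraints, d / "restraints.aco", "aco",
                         sequence=self.truth.sequence)
        (d / "ss.txt").write_text(self.ss + "\n")
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


CASES: dict[str, dict] = {
    # 5-helix, 8 Å regime of the assignment step; mono3 is the fast smoke case
    "mono3": dict(n_helices=3, helix_len_res=[14, 12, 10], loop_len_res=5,
                  map_resolution=8.0, sim_resolution=4.1, voxel=2.0,
                  symmetry=None),
    "mono5": dict(n_helices=5, helix_len_res=[14, 12, 11, 9, 8], loop_len_res=4,
                  map_resolution=8.0, sim_resolution=4.1, voxel=2.0,
                  symmetry=None),
    "c3": dict(n_helices=5, helix_len_res=[13, 11, 10, 9, 8], loop_len_res=4,
               map_resolution=8.0, sim_resolution=4.1, voxel=2.0,
               symmetry="C3", inter_subunit_rate=0.03),
}


def _place_off_axis(protomer: Structure, group: SymmetryGroup) -> Structure:
    """Translate the protomer radially until symmetry mates no longer clash."""
    s = protomer.copy()
    s.coords = s.coords - s.coords.mean(axis=0)
    radius = float(np.max(np.linalg.norm(s.coords[:, :2], axis=1)))
    for r in np.arange(max(4.0, radius * 0.7), radius * 2 + 40, 1.0):
        cand = s.copy()
        cand.coords = cand.coords + np.array([r, 0.0, 0.0])
        chains = [cand.transformed(rot, tr) for rot, tr in group.operators]
        ok = True
        for k in range(1, len(chains)):
            t = cKDTree(chains[k].coords)
            if t.query(chains[0].coords, k=1)[0].min() < 3.5:
                ok = False
                break
        if ok:
            return cand
    raise GenerationError("cannot place protomer off-axis without clashes")


def make_benchmark(case: str | dict, seed: int = 0) -> BenchmarkCase:
    """Build a named benchmark case (or one from an explicit manifest dict)."""
    if isinstance(case, str):
        if case not in CASES:
            raise InputError(f"unknown case {case!r}; available: {sorted(CASES)}")
        spec = dict(CASES[case])
        name = case
    else:
        spec = dict(case)
        name = spec.pop("name", "custom")
        seed = spec.pop("seed", seed)
    manifest = dict(spec, name=name, seed=seed)

    truth, ss = make_toy_fold(spec["n_helices"], spec["helix_len_res"],
                              spec["loop_len_res"], seed)
    symmetry = None
    assembly = None
    if spec.get("symmetry"):
        sym = spec["symmetry"]
        if sym == "T":
            symmetry = SymmetryGroup.tetrahedral()
        elif sym.startswith("C"):
            symmetry = SymmetryGroup.cyclic(int(sym[1:]))
        else:
            raise InputError(f"unknown symmetry {sym!r}")
        truth = _place_off_axis(truth, symmetry)
        from .model import apply_symmetry
        assembly = apply_symmetry(truth, symmetry)

    rparams = RestraintParams(
        contact_cutoff=spec.get("contact_cutoff", 8.0),
        coverage=spec.get("coverage", 0.6),
        ambiguity_rate=spec.get("ambiguity_rate", 0.2),
        decoy_count=spec.get("decoy_count", 2),
        inter_subunit_rate=spec.get("inter_subunit_rate", 0.0),
        bound_padding=spec.get("bound_padding", 1.0),
        dihedral_tol=spec.get("dihedral_tol", 20.0),
    )
    rset, labels = simulate_restraints(truth, rparams, seed=seed + 1, ss=ss,
                                       assembly=assembly)

    source = assembly if assembly is not None else truth
    map_fine = simulate_map(source, spec["sim_resolution"], spec["voxel"])
    dmap = fourier_truncate(map_fine, spec["map_resolution"])
    dmap.nominal_resolution = spec["map_resolution"]

    return BenchmarkCase(name, truth, ss, dmap, map_fine, rset, labels,
                         manifest, assembly, symmetry)


def true_helix_geometry(structure: Structure, ss: str
                        ) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """(center, axis, CA-extent length) of every helix, from the truth fold."""
    from .features import sequence_helices_from_ss
    out = []
    for sh in sequence_helices_from_ss(ss):
        ca = np.array([structure.atom(r, "CA") for r in sh.residues])
        c = ca.mean(axis=0)
        _, _, vt = np.linalg.svd(ca - c)
        axis = vt[0]
        proj = (ca - c) @ axis
        out.append((c, axis, float(proj.max() - proj.min())))
    return out
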