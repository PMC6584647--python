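"""Restraint data model, combinatorial helix-to-density assignment, and the
conversions that turn real-space (EM) information into distance restraints.

Distance restraints reference atoms as ``(residue, atom_name)`` pairs with
1-based residues.  A restraint with more than one candidate atom pair is
*ambiguous*: the observed contact could stem from any of the listed pairs,
and it contributes through the r^-6-summed effective distance until it is
disambiguated against intermediate structures.

Origin tags record provenance: NOE/RFDR/DARR are spectroscopic, EM_FIX are
map-derived position fixes, HELIX_CENTER are the step-1 helix-center pins,
SITE are metal-site restraints to virtual atoms (negative residue index).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from typing import Iterable, Iterator, Sequence

import numpy as np

from .features import HelixDensity, SequenceHelix
from .model import Ensemble, InputError, Structure, aa1to3

AtomRef = tuple[int, str]

ORIGINS = ("NOE", "RFDR", "DARR", "EM_FIX", "HELIX_CENTER", "SITE")


class ParseError(ValueError):
    """Malformed restraint file row."""


@dataclasses.dataclass
class DistanceRestraint:
    candidates: list[tuple[AtomRef, AtomRef]]
    lower: float
    upper: float
    origin: str = "NOE"
    subunit_scope: str = "unknown"  # intra | inter | unknown
    id: int | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise InputError("restraint needs at least one candidate pair")
        if not 0 <= self.lower <= self.upper:
            raise InputError(f"invalid bounds [{self.lower}, {self.upper}]")
        if self.origin not in ORIGINS:
            raise InputError(f"unknown origin tag {self.origin!r}")
        self.candidates = [((int(a[0]), a[1]), (int(b[0]), b[1]))
                           for a, b in self.candidates]

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    def seq_separation(self) -> int:
        (i, _), (j, _) = self.candidates[0]
        return abs(i - j)


@dataclasses.dataclass
class DihedralRestraint:
    residue: int
    angle: str  # "phi" | "psi"
    target: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.angle not in ("phi", "psi"):
            raise InputError("angle must be 'phi' or 'psi'")
        if self.tolerance <= 0:
            raise InputError("tolerance must be positive")
        if not -180 < self.target <= 180:
            raise InputError("target must be in (-180, 180]")


@dataclasses.dataclass
class RestraintSet:
    distance: list[DistanceRestraint] = dataclasses.field(default_factory=list)
    dihedral: list[DihedralRestraint] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for n, r in enumerate(self.distance):
            if r.id is None:
                r.id = n

    @property
    def counts(self) -> dict:
        return classify_restraints(self)

    def copy(self) -> "RestraintSet":
        return RestraintSet([dataclasses.replace(r) for r in self.distance],
                            [dataclasses.replace(d) for d in self.dihedral])


@dataclasses.dataclass(frozen=True)
class AssignmentHypothesis:
    """An injective mapping density-index -> sequence-helix-index.

    `orientation` carries one flag per mapped density in oriented mode
    (which way the sequence helix runs along the rod); center-only mode —
    the default, since rod polarity is invisible — leaves it None.
    """

    mapping: tuple[tuple[int, int], ...]  # sorted ((density_idx, seq_idx), ...)
    orientation: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        seqs = [s for _, s in self.mapping]
        if len(set(seqs)) != len(seqs):
            raise InputError("mapping must be injective")

    @property
    def label(self) -> str:
        s = ",".join(f"{d}>{h}" for d, h in self.mapping)
        if self.orientation is not None:
            s += "|" + "".join(map(str, self.orientation))
        return s


def count_assignments(n_seq: int, n_densities: int, oriented: bool) -> int:
    """Closed-form count of injective density->sequence placements."""
    if n_densities > n_seq:
        raise InputError("more densities than sequence helices")
    count = math.perm(n_seq, n_densities)
    if oriented:
        count *= 2 ** n_densities
    return count


def _passes_pruning(seq_helices, densities, perm, length_tol_A: float) -> bool:
    return all(abs(seq_helices[s].length_A - densities[d].length) <= length_tol_A
               for d, s in enumerate(perm))


def iter_assignments(seq_helices: Sequence[SequenceHelix],
                     densities: Sequence[HelixDensity],
                     mode: str = "center-only",
                     length_tol_A: float = 6.0,
                     prune: bool = True) -> Iterator[AssignmentHypothesis]:
    """Lazily yield hypotheses in deterministic lexicographic order."""
    if len(densities) == 0:
        raise InputError("need at least one density")
    if len(densities) > len(seq_helices):
        raise InputError("more densities than sequence helices")
    if mode not in ("center-only", "oriented"):
        raise InputError(f"unknown mode {mode!r}")
    nd = len(densities)
    for perm in itertools.permutations(range(len(seq_helices)), nd):
        if prune and not _passes_pruning(seq_helices, densities, perm, length_tol_A):
            continue
        mapping = tuple((d, s) for d, s in enumerate(perm))
        if mode == "oriented":
            for flags in itertools.product((0, 1), repeat=nd):
                yield AssignmentHypothesis(mapping, flags)
        else:
            yield AssignmentHypothesis(mapping)


def enumerate_assignments(seq_helices: Sequence[SequenceHelix],
                          densities: Sequence[HelixDensity],
                          mode: str = "center-only",
                          length_tol_A: float = 6.0,
                          prune: bool = True) -> list[AssignmentHypothesis]:
    """All injective helix-to-density assignments, optionally length-pruned.

    Pruning discards any mapping in which some sequence helix's length (at
    1.5 Å/residue) differs from its assigned rod's length by more than
    `length_tol_A`.
    """
    return list(iter_assignments(seq_helices, densities, mode, length_tol_A, prune))


def hypothesis_to_restraints(hyp: AssignmentHypothesis,
                             densities: Sequence[HelixDensity],
                             seq_helices: Sequence[SequenceHelix],
                             tol: float = 0.5) -> list[DistanceRestraint]:
    """Encode one assignment as relative distance restraints.

    The CA of each assigned helix's central residue is pinned to its rod
    center *relatively*: every pair of pinned CAs gets a distance restraint
    bracketing the Euclidean center–center distance by ±tol.  Absolute
    placement is irrelevant; the map geometry enters purely through these
    relative distances.
    """
    pins = [(seq_helices[s].central_residue, densities[d].center)
            for d, s in hyp.mapping]
    out = []
    for (ri, ci), (rj, cj) in itertools.combinations(pins, 2):
        d = float(np.linalg.norm(np.asarray(ci) - np.asarray(cj)))
        out.append(DistanceRestraint([((ri, "CA"), (rj, "CA"))],
                                     max(0.0, d - tol), d + tol,
                                     origin="HELIX_CENTER", subunit_scope="intra"))
    return out


def fix_positions(structure: Structure, flagged_residues: Sequence[int],
                  tol: float = 0.5, max_near: int = 6, max_random: int = 2,
                  seed: int = 0) -> list[DistanceRestraint]:
    """Pin the backbone of well-fitting residues via pairwise restraints.

    All-pairs encoding is quadratic; instead each backbone atom (N, CA, C)
    of a flagged residue is tied to its `max_near` nearest flagged
    neighbours plus `max_random` random long-range partners (seeded), which
    keeps the restraint graph generically rigid at linear size.
    """
    flagged = sorted(set(int(r) for r in flagged_residues))
    for r in flagged:
        if not 1 <= r <= structure.n_residues:
            raise InputError(f"flagged residue {r} not in structure")
    atoms: list[AtomRef] = [(r, n) for r in flagged for n in ("N", "CA", "C")]
    if len(atoms) < 2:
        return []
    pos = np.array([structure.atom(r, n) for r, n in atoms])
    n = len(atoms)
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    d2 = np.sum((pos[:, None] - pos[None, :]) ** 2, axis=2)
    for i in range(n):
        order = np.argsort(d2[i])
        near = [int(j) for j in order[1:max_near + 1]]
        far = [int(j) for j in order[max_near + 1:]]
        chosen = near + (list(rng.choice(far, size=min(max_random, len(far)),
                                         replace=False)) if far else [])
        for j in chosen:
            pairs.add((min(i, j), max(i, j)))
    out = []
    for i, j in sorted(pairs):
        d = float(np.sqrt(d2[i, j]))
        out.append(DistanceRestraint([(atoms[i], atoms[j])],
                                     max(0.0, d - tol), d + tol,
                                     origin="EM_FIX", subunit_scope="intra"))
    return out


def measure_distance(structure: Structure, pair: tuple[AtomRef, AtomRef]) -> float:
    (ri, ai), (rj, aj) = pair
    return float(np.linalg.norm(structure.atom(ri, ai) - structure.atom(rj, aj)))


def disambiguate(ambiguous: Sequence[DistanceRestraint], ensemble: Ensemble,
                 cutoff: float = 8.0, n_models: int = 10
                 ) -> tuple[list[DistanceRestraint], list[DistanceRestraint]]:
    """Resolve ambiguous restraints against intermediate structures.

    Each candidate's distance is the median over the `n_models` lowest-energy
    conformers; a restraint resolves iff exactly one candidate is shorter
    than `cutoff`.  No restraint is ever dropped.
    """
    if len(ensemble) == 0:
        raise InputError("empty ensemble")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    models = ensemble.sorted_by_energy().conformers[:n_models]
    topo = models[0]
    for r in ambiguous:
        for cand in r.candidates:
            for res, name in cand:
                try:
                    topo.atom_index(res, name)
                except InputError as exc:
                    raise InputError(f"restraint {r.id}: {exc}") from exc
    resolved, still = [], []
    for r in ambiguous:
        if not r.ambiguous:
            resolved.append(r)
            continue
        medians = []
        for cand in r.candidates:
            try:
                ds = [measure_distance(m, cand) for m in models]
            except InputError as exc:
                raise InputError(
                    f"restraint {r.id}: candidate atom missing ({exc})") from exc
            medians.append(float(np.median(ds)))
        short = [k for k, d in enumerate(medians) if d < cutoff]
        if len(short) == 1:
            resolved.append(dataclasses.replace(
                r, candidates=[r.candidates[short[0]]]))
        else:
            still.append(r)
    return resolved, still


def filter_intersubunit(rset: RestraintSet, labels: Iterable[int]
                        ) -> tuple[RestraintSet, int]:
    """Remove restraints known to cross subunits from the calculation set."""
    labels = set(labels)
    known = {r.id for r in rset.distance}
    unknown = labels - known
    if unknown:
        raise InputError(f"unknown restraint ids: {sorted(unknown)}")
    kept = [dataclasses.replace(r) for r in rset.distance if r.id not in labels]
    removed = len(rset.distance) - len(kept)
    return RestraintSet(kept, [dataclasses.replace(d) for d in rset.dihedral]), removed


def classify_restraints(rset: RestraintSet) -> dict:
    """Tally restraints the way structure papers report them.

    Sequence separation uses the first candidate pair; short-range means
    |i - j| < 4, long-range |i - j| >= 4.
    """
    dist = rset.distance
    by_origin: dict[str, int] = {}
    for r in dist:
        by_origin[r.origin] = by_origin.get(r.origin, 0) + 1
    return {
        "total_distance": len(dist),
        "short_range": sum(1 for r in dist if r.seq_separation() < 4),
        "long_range": sum(1 for r in dist if r.seq_separation() >= 4),
        "unambiguous": sum(1 for r in dist if not r.ambiguous),
        "ambiguous": sum(1 for r in dist if r.ambiguous),
        "by_origin": by_origin,
        "dihedral": len(rset.dihedral),
    }


def site_restraints(site_residues: Sequence[int], n_centers: int,
                    bounds: tuple[float, float]) -> list[DistanceRestraint]:
    """Generous restraints from chelating side chains to virtual site atoms.

    Virtual metal centers are encoded as negative residue indices
    (-1 .. -n_centers) with atom name "SITE"; they are bookkeeping objects
    for the final local refinement, not part of the chain topology.
    """
    lo, hi = bounds
    if not 0 <= lo <= hi:
        raise InputError("invalid bounds")
    out = []
    for res in site_residues:
        for k in range(n_centers):
            out.append(DistanceRestraint([((int(res), "SC"), (-(k + 1), "SITE"))],
                                         lo, hi, origin="SITE"))
    return out


# ---------------------------------------------------------------------------
# file dialects


def write_restraints(rset: RestraintSet, path, dialect: str = "json",
                     sequence: str | None = None) -> None:
    if dialect == "json":
        _write_json(rset, path)
    elif dialect == "upl":
        _write_upl(rset.distance, path, sequence or "")
    elif dialect == "aco":
        _write_aco(rset.dihedral, path, sequence or "")
    else:
        raise InputError(f"unknown dialect {dialect!r}")


def read_restraints(path, dialect: str = "json") -> RestraintSet:
    if dialect == "json":
        return _read_json(path)
    if dialect == "upl":
        return RestraintSet(_read_upl(path), [])
    if dialect == "aco":
        return RestraintSet([], _read_aco(path))
    raise InputError(f"unknown dialect {dialect!r}")


def _write_json(rset: RestraintSet, path) -> None:
    doc = {
        "distance": [
            {
                "id": r.id,
                "candidates": [[list(a), list(b)] for a, b in r.candidates],
                "lower": r.lower, "upper": r.upper,
                "origin": r.origin, "subunit_scope": r.subunit_scope,
            } for r in rset.distance
        ],
        "dihedral": [
            {"residue": d.residue, "angle": d.angle,
             "target": d.target, "tolerance": d.tolerance}
            for d in rset.dihedral
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _read_json(path) -> RestraintSet:
    with open(path) as fh:
        doc = json.load(fh)
    dist = [DistanceRestraint(
        [( (a[0], a[1]), (b[0], b[1]) ) for a, b in r["candidates"]],
        r["lower"], r["upper"], r["origin"], r["subunit_scope"], r["id"])
        for r in doc["distance"]]
    dihe = [DihedralRestraint(d["residue"], d["angle"], d["target"], d["tolerance"])
            for d in doc["dihedral"]]
    return RestraintSet(dist, dihe)


def _resname(sequence: str, res: int) -> str:
    if 1 <= res <= len(sequence):
        return aa1to3(sequence[res - 1])
    return "UNK"


def _write_upl(restraints: Sequence[DistanceRestraint], path, sequence: str) -> None:
    """CYANA-style upper distance limits; ambiguous restraints are emitted as
    one row per candidate tagged with a shared `#group N` comment."""
    with open(path, "w") as fh:
        for r in restraints:
            for (ri, ai), (rj, aj) in r.candidates:
                row = (f"{ri:4d} {_resname(sequence, ri):>4s} {ai:<4s} "
                       f"{rj:4d} {_resname(sequence, rj):>4s} {aj:<4s} "
                       f"{r.upper:8.2f}")
                if r.ambiguous:
                    row += f"  #group {r.id}"
                fh.write(row + "\n")


def _read_upl(path) -> list[DistanceRestraint]:
    groups: dict[int, list] = {}
    singles: list[DistanceRestraint] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            body, _, comment = line.partition("#")
            if not body.strip():
                continue
            toks = body.split()
            if len(toks) != 7:
                raise ParseError(f"{path}:{ln}: expected 7 columns, got {len(toks)}")
            try:
                ri, rj = int(toks[0]), int(toks[3])
                upper = float(toks[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            pair = ((ri, toks[2]), (rj, toks[5]))
            gid = None
            ctoks = comment.split()
            if len(ctoks) >= 2 and ctoks[0] == "group":
                gid = int(ctoks[1])
            if gid is None:
                singles.append(DistanceRestraint([pair], 0.0, upper))
            else:
                groups.setdefault(gid, []).append((pair, upper))
    out = list(singles)
    for gid in sorted(groups):
        cands = [p for p, _ in groups[gid]]
        upper = groups[gid][0][1]
        out.append(DistanceRestraint(cands, 0.0, upper))
    for n, r in enumerate(out):
        r.id = n
    return out


_ANGLE_UP = {"phi": "PHI", "psi": "PSI"}
_ANGLE_DOWN = {v: k for k, v in _ANGLE_UP.items()}


def _write_aco(dihedrals: Sequence[DihedralRestraint], path, sequence: str) -> None:
    with open(path, "w") as fh:
        for d in dihedrals:
            lo = d.target - d.tolerance
            hi = d.target + d.tolerance
            fh.write(f"{d.residue:4d} {_resname(sequence, d.residue):>4s} "
                     f"{_ANGLE_UP[d.angle]:<4s} {lo:8.1f} {hi:8.1f}\n")


def _read_aco(path) -> list[DihedralRestraint]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            body = line.partition("#")[0]
            if not body.strip():
                continue
            toks = body.split()
            if len(toks) != 5:
                raise ParseError(f"{path}:{ln}: expected 5 columns, got {len(toks)}")
            try:
                res = int(toks[0])
                lo, hi = float(toks[3]), float(toks[4])
                angle = _ANGLE_DOWN[toks[2]]
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            target = (lo + hi) / 2
            out.append(DihedralRestraint(res, angle, target, (hi - lo) / 2))
    return out
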