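"""Coordinate model: reduced-representation structures, ensembles, symmetry.

A :class:`Structure` holds one chain at backbone resolution with six atoms
per residue (N, CA, C, O, CB and an SC side-chain-centroid pseudo-atom, in
that canonical order).  This is the representation every other module works
on: restraints address (residue, atom-name) pairs, density simulation uses
backbone atoms, and the annealing engine rebuilds coordinates from (φ, ψ)
with ideal covalent geometry.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from ._kernels import ATOM_ORDER, N_SLOTS

ATOM_INDEX = {name: i for i, name in enumerate(ATOM_ORDER)}

#: residues per turn-independent helical rise used to convert residue counts
#: to Ångström lengths of helices (1.5 Å axial rise per residue).
HELIX_RISE_PER_RES = 1.5

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = {v: k for k, v in _AA3.items()}


class InputError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclasses.dataclass
class Structure:
    """One chain, six atom slots per residue, 1-based residue indexing."""

    sequence: str
    coords: np.ndarray  # (n_res * 6, 3) float64, canonical atom order
    chain_id: str = "A"
    phi: np.ndarray | None = None  # torsions when built in torsion space
    psi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.sequence) * N_SLOTS, 3):
            raise InputError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.sequence)} residues x {N_SLOTS} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def residues(self) -> list[tuple[int, str]]:
        return [(i + 1, aa) for i, aa in enumerate(self.sequence)]

    def atom_index(self, residue: int, name: str) -> int:
        """Flat index of atom `name` of 1-based `residue`."""
        if not 1 <= residue <= self.n_residues:
            raise InputError(f"residue {residue} outside 1..{self.n_residues}")
        try:
            return (residue - 1) * N_SLOTS + ATOM_INDEX[name]
        except KeyError:
            raise InputError(f"unknown atom name {name!r}") from None

    def atom(self, residue: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(residue, name)]

    def select(self, names: Iterable[str], residues: Sequence[int] | None = None) -> np.ndarray:
        """Flat indices of the named atoms, optionally restricted to residues."""
        cols = sorted(ATOM_INDEX[n] for n in names)
        res = range(1, self.n_residues + 1) if residues is None else residues
        return np.array([(r - 1) * N_SLOTS + c for r in res for c in cols], dtype=np.int64)

    def copy(self) -> "Structure":
        return Structure(self.sequence, self.coords.copy(), self.chain_id,
                         None if self.phi is None else self.phi.copy(),
                         None if self.psi is None else self.psi.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def ca_coords(self) -> np.ndarray:
        return self.coords[ATOM_INDEX["CA"]::N_SLOTS]


@dataclasses.dataclass
class Ensemble:
    """Conformers sharing one topology plus their target-function values."""

    conformers: list[Structure]
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if len(self.conformers) != len(self.energies):
            raise InputError("energies length must equal conformer count")
        n = {c.coords.shape[0] for c in self.conformers}
        if len(n) > 1:
            raise InputError("conformers differ in atom count")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def best(self) -> Structure:
        return self.conformers[int(np.argmin(self.energies))]

    def sorted_by_energy(self) -> "Ensemble":
        order = np.argsort(self.energies, kind="stable")
        return Ensemble([self.conformers[i] for i in order], self.energies[order])


@dataclasses.dataclass
class SymmetryGroup:
    """Finite rotation group given as (rotation, translation) operators."""

    operators: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        ops = []
        for rot, tr in self.operators:
            rot = np.asarray(rot, dtype=np.float64)
            tr = np.asarray(tr, dtype=np.float64)
            if rot.shape != (3, 3) or tr.shape != (3,):
                raise InputError("operator must be (3x3 rotation, 3-vector)")
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
                raise InputError("non-orthonormal rotation in symmetry group")
            ops.append((rot, tr))
        self.operators = ops

    @property
    def order(self) -> int:
        return len(self.operators)

    @classmethod
    def identity(cls) -> "SymmetryGroup":
        return cls([(np.eye(3), np.zeros(3))])

    @classmethod
    def cyclic(cls, n: int, axis: np.ndarray | None = None) -> "SymmetryGroup":
        """C_n about `axis` (default z) through the origin."""
        axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        ops = []
        for k in range(n):
            ops.append((_axis_angle(axis, 2 * np.pi * k / n), np.zeros(3)))
        return cls(ops)

    @classmethod
    def tetrahedral(cls) -> "SymmetryGroup":
        """The order-12 rotation group of the tetrahedron (chiral T)."""
        ops = [np.eye(3)]
        # three C2 about coordinate axes
        for ax in np.eye(3):
            ops.append(_axis_angle(ax, np.pi))
        # eight C3 about the body diagonals
        for sx in (1, -1):
            for sy in (1, -1):
                d = np.array([sx, sy, 1.0]) / np.sqrt(3.0)
                ops.append(_axis_angle(d, 2 * np.pi / 3))
                ops.append(_axis_angle(d, 4 * np.pi / 3))
        return cls([(r, np.zeros(3)) for r in ops])


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


@dataclasses.dataclass
class ProtocolConfig:
    """All tunable protocol constants with their literature defaults.

    The counts (`n_conformers`, `anneal_steps`) default to the full-scale
    protocol; the pipeline and benchmarks scale them down for desk-size
    problems via `scaled`.
    """

    overlap_threshold: float = 0.7
    fix_tolerance: float = 0.5
    disambig_cutoff: float = 8.0
    convergence_rel_tol: float = 0.10
    convergence_cycles: int = 3
    resolution_schedule: tuple[float, ...] = (8.0, 6.0, 4.1)
    n_conformers: int = 1000
    n_keep: int = 10
    anneal_steps: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold < 1:
            raise InputError("overlap_threshold must be in (0, 1)")
        if self.fix_tolerance <= 0 or self.disambig_cutoff <= 0:
            raise InputError("tolerances must be positive")
        sched = tuple(self.resolution_schedule)
        if any(b >= a for a, b in zip(sched, sched[1:])):
            raise InputError("resolution schedule must be strictly decreasing (Å)")
        self.resolution_schedule = sched

    @classmethod
    def scaled(cls, **kw) -> "ProtocolConfig":
        """Desk-scale defaults: fewer conformers/moves, same science constants."""
        kw.setdefault("n_conformers", 50)
        kw.setdefault("anneal_steps", 2000)
        return cls(**kw)


# ---------------------------------------------------------------------------
# operations


def build_backbone(sequence: str, dihedrals: Sequence[tuple[float, float]],
                   chain_id: str = "A") -> Structure:
    """Build an ideal-geometry chain from per-residue (φ, ψ) in degrees."""
    if len(dihedrals) != len(sequence):
        raise InputError(
            f"{len(dihedrals)} dihedral pairs for {len(sequence)} residues")
    arr = np.asarray(dihedrals, dtype=np.float64).reshape(len(sequence), 2)
    if np.any(arr <= -180.0) or np.any(arr > 180.0):
        raise InputError("dihedrals must lie in (-180, 180]")
    phi = np.ascontiguousarray(arr[:, 0])
    psi = np.ascontiguousarray(arr[:, 1])
    coords = np.empty((len(sequence) * N_SLOTS, 3))
    _kernels.build_chain(phi, psi, coords)
    return Structure(sequence, coords, chain_id, phi, psi)


def superpose(mobile: np.ndarray | Structure, reference: np.ndarray | Structure,
              selection: Iterable[str] | None = None
              ) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Least-squares rigid superposition (Kabsch, proper rotations only).

    Returns (rmsd, (rotation, translation)) such that
    ``mobile @ R.T + t`` best matches the reference.
    """
    x = _paired(mobile, selection)
    y = _paired(reference, selection)
    if x.shape != y.shape:
        raise InputError("selections yield different atom counts")
    if x.shape[0] < 3:
        raise InputError("need at least 3 paired atoms")
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    h = (x - xm).T @ (y - ym)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ym - rot @ xm
    moved = x @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rmsd, (rot, t)


def _paired(obj: np.ndarray | Structure, selection: Iterable[str] | None) -> np.ndarray:
    if isinstance(obj, Structure):
        if selection is None:
            return obj.coords
        return obj.coords[obj.select(selection)]
    return np.asarray(obj, dtype=np.float64)


def bundle_rmsd(ensemble: Ensemble, selection: Iterable[str] = ("N", "CA", "C")) -> float:
    """Mean RMSD of conformers to their mean structure (iterated superposition).

    The ensemble spread ("precision") of an NMR-style bundle: conformers are
    superposed onto the running mean until the mean stabilises, then the mean
    of per-conformer RMSDs to that mean is returned.
    """
    if len(ensemble) < 2:
        warnings.warn("bundle_rmsd of a single conformer is 0 by definition")
        return 0.0
    sel = ensemble.conformers[0].select(selection)
    coords = [c.coords[sel] for c in ensemble.conformers]
    mean = coords[0].copy()
    for _ in range(100):
        aligned = []
        for x in coords:
            _, (rot, t) = superpose(x, mean)
            aligned.append(x @ rot.T + t)
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        coords = aligned
        if shift < 1e-4:
            break
    rmsds = [np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=1))) for x in coords]
    return float(np.mean(rmsds))


def apply_symmetry(protomer: Structure, group: SymmetryGroup) -> list[Structure]:
    """Replicate a protomer by every group operator; chain ids A, B, C, ..."""
    chains = []
    for k, (rot, tr) in enumerate(group.operators):
        c = protomer.transformed(rot, tr)
        c.chain_id = chr(ord("A") + k % 26)
        chains.append(c)
    return chains


def aa1to3(aa: str) -> str:
    return _AA3.get(aa, "UNK")


def aa3to1(aa: str) -> str:
    return _AA1.get(aa, "X")
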