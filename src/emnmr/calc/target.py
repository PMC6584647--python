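"""Restraint target function.

TF = w_up Σ max(0, d − upper)² + w_lo Σ max(0, lower − d)²
   + w_dih Σ max(0, |Δangle| − tol)² + w_steric Σ max(0, r_min − d)²

Distances in Å, angles in degrees.  Ambiguous restraints contribute through
the r⁻⁶-summed effective distance over their candidates, the standard
treatment for unassigned NOE-type contacts.  TF = 0 iff every restraint is
satisfied; the default dihedral weight (1/20°)² makes a 20°-past-tolerance
angle violation cost as much as a 1 Å distance violation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .. import _kernels
from .._kernels import N_SLOTS
from ..model import InputError, Structure
from ..restraints import DihedralRestraint, DistanceRestraint, RestraintSet


@dataclasses.dataclass
class TargetFunctionSpec:
    w_upper: float = 1.0
    w_lower: float = 1.0
    w_dihedral: float = 0.0025
    w_steric: float = 1.0
    steric_radius: float = 2.5  # uniform soft-sphere radius for CA/SC classes

    def __post_init__(self) -> None:
        ws = (self.w_upper, self.w_lower, self.w_dihedral, self.w_steric)
        if any(w < 0 for w in ws):
            raise InputError("weights must be non-negative")
        if all(w == 0 for w in ws):
            raise InputError("at least one weight must be positive")


@dataclasses.dataclass
class CompiledRestraints:
    """Flat-array form consumed by the numba kernels."""

    cand_i: np.ndarray
    cand_j: np.ndarray
    grp_ptr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    dihe_res: np.ndarray
    dihe_is_psi: np.ndarray
    dihe_target: np.ndarray
    dihe_tol: np.ndarray
    steric_atoms: np.ndarray
    steric_res: np.ndarray
    n_distance: int


def _atom_flat(n_res: int, ref) -> int:
    res, name = ref
    if not 1 <= res <= n_res:
        raise InputError(f"atom ({res}, {name}) outside topology (1..{n_res})")
    try:
        col = _kernels.ATOM_ORDER.index(name)
    except ValueError:
        raise InputError(f"unknown atom name {name!r}") from None
    return (res - 1) * N_SLOTS + col


def compile_restraints(restraints: RestraintSet | Sequence, n_res: int,
                       steric_names: Sequence[str] = ("CA", "SC")
                       ) -> CompiledRestraints:
    """Flatten a restraint set against an n-residue topology.

    SITE-origin restraints reference virtual atoms outside the chain and are
    skipped here (they are bookkeeping for the final local refinement).
    """
    if isinstance(restraints, RestraintSet):
        dist = restraints.distance
        dihe = restraints.dihedral
    else:
        dist = [r for r in restraints if isinstance(r, DistanceRestraint)]
        dihe = [r for r in restraints if isinstance(r, DihedralRestraint)]
    dist = [r for r in dist if r.origin != "SITE"]

    ci, cj, ptr, lo, up = [], [], [0], [], []
    for r in dist:
        for a, b in r.candidates:
            ci.append(_atom_flat(n_res, a))
            cj.append(_atom_flat(n_res, b))
        ptr.append(len(ci))
        lo.append(r.lower)
        up.append(r.upper)
    d_res, d_psi, d_tar, d_tol = [], [], [], []
    for d in dihe:
        if not 1 <= d.residue <= n_res:
            raise InputError(f"dihedral restraint residue {d.residue} outside topology")
        d_res.append(d.residue - 1)
        d_psi.append(1 if d.angle == "psi" else 0)
        d_tar.append(d.target)
        d_tol.append(d.tolerance)
    cols = [_kernels.ATOM_ORDER.index(n) for n in steric_names]
    satoms = np.array([r * N_SLOTS + c for r in range(n_res) for c in cols],
                      dtype=np.int64)
    sres = np.repeat(np.arange(n_res, dtype=np.int64), len(cols))
    return CompiledRestraints(
        np.array(ci, dtype=np.int64), np.array(cj, dtype=np.int64),
        np.array(ptr, dtype=np.int64), np.array(lo, float), np.array(up, float),
        np.array(d_res, dtype=np.int64), np.array(d_psi, dtype=np.int8),
        np.array(d_tar, float), np.array(d_tol, float),
        satoms, sres, len(dist))


def compute_torsions(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Measure backbone (φ, ψ) in degrees from Cartesian coordinates.

    φ[0] and ψ[-1] are conventions (ψ[-1] from the carbonyl): undefined
    boundary torsions are reported as 0 when geometry does not fix them.
    """
    if structure.phi is not None and structure.psi is not None:
        return structure.phi.copy(), structure.psi.copy()
    n = structure.n_residues
    co = structure.coords
    phi = np.zeros(n)
    psi = np.zeros(n)

    def tor(p0, p1, p2, p3):
        b0 = p1 - p0
        b1 = p2 - p1
        b2 = p3 - p2
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m = np.cross(n1, b1 / np.linalg.norm(b1))
        return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))

    for i in range(n):
        q = i * N_SLOTS
        if i > 0:
            phi[i] = tor(co[q - N_SLOTS + 2], co[q], co[q + 1], co[q + 2])
        if i < n - 1:
            psi[i] = tor(co[q], co[q + 1], co[q + 2], co[q + N_SLOTS])
        else:
            # last ψ from the carbonyl O, which was placed at ψ - 180
            o_tor = tor(co[q], co[q + 1], co[q + 2], co[q + 3])
            psi[i] = o_tor + 180.0 if o_tor <= 0 else o_tor - 180.0
    return phi, psi


def target_function(structure: Structure, restraints, spec: TargetFunctionSpec | None = None
                    ) -> float:
    """Evaluate TF for any structure (torsions measured if not stored)."""
    spec = spec or TargetFunctionSpec()
    c = compile_restraints(restraints, structure.n_residues)
    phi, psi = compute_torsions(structure)
    return float(_kernels.tf_eval(
        np.ascontiguousarray(structure.coords), phi, psi,
        c.cand_i, c.cand_j, c.grp_ptr, c.lower, c.upper,
        c.dihe_res, c.dihe_is_psi, c.dihe_target, c.dihe_tol,
        c.steric_atoms, c.steric_res, spec.steric_radius,
        spec.w_upper, spec.w_lower, spec.w_dihedral, spec.w_steric))
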