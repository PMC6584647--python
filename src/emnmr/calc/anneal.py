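"""Restrained simulated annealing in torsion space.

Each conformer starts from random (φ, ψ), anneals through a geometric
temperature schedule with Monte-Carlo torsion moves (ideal covalent
geometry is guaranteed because coordinates are always rebuilt from
torsions), and ends with a greedy local polish.  The steric weight is off
for the first 70 % of the schedule and on for the remainder — collapsing
through clashes early and cleaning them up cold, which is both faster
(the soft-sphere term dominates the cost) and better-converging.

Only the lowest-TF conformers are retained; their count and the move
budget come from the protocol configuration.
"""

from __future__ import annotations

import numpy as np

from .. import _kernels
from ..model import Ensemble, InputError, ProtocolConfig, Structure
from .target import TargetFunctionSpec, compile_restraints

#: a conformer whose TF exceeds this many units per restraint is flagged
DIVERGENCE_CEILING_PER_RESTRAINT = 1.0e6


def _seed_stream(master: int, name: str) -> np.random.SeedSequence:
    """Named substream so every stochastic stage is independently reproducible."""
    tag = sum(ord(c) * 31 ** k for k, c in enumerate(name)) % (2 ** 20)
    return np.random.SeedSequence((int(master) % (2 ** 30)) * 2 ** 20 + tag)


def anneal(sequence: str, restraints, config: ProtocolConfig | None = None,
           spec: TargetFunctionSpec | None = None,
           n_conformers: int | None = None,
           stream: str = "anneal",
           polish_sweeps: int = 8,
           initial: tuple[np.ndarray, np.ndarray] | None = None) -> Ensemble:
    """Compute an ensemble by restrained annealing; keep the n_keep best.

    With `initial` (φ, ψ) the run refines around a seed model instead of
    folding from scratch: conformer 0 starts exactly at the seed, the rest
    at perturbed copies, and the temperature schedule starts warm rather
    than hot so the seed topology survives.

    Returns the ensemble sorted by TF ascending, with ``ens.diverged``
    True when more than half of all conformers hit the divergence ceiling.
    Bitwise reproducible for a given (config.seed, inputs).
    """
    config = config or ProtocolConfig.scaled()
    spec = spec or TargetFunctionSpec()
    n_res = len(sequence)
    if n_res < 2:
        raise InputError("need at least 2 residues")
    c = compile_restraints(restraints, n_res)
    n_conf = n_conformers if n_conformers is not None else config.n_conformers
    n_steps = config.anneal_steps
    ceiling = DIVERGENCE_CEILING_PER_RESTRAINT * max(1, c.n_distance +
                                                     len(c.dihe_res))
    ss = _seed_stream(config.seed, stream)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_conf)]
    free = np.ones(2 * n_res, dtype=np.int8)
    empty_atoms = np.zeros(0, dtype=np.int64)
    empty_res = np.zeros(0, dtype=np.int64)

    # dihedral restraints (TALOS-style) define the local conformation
    # residue-by-residue; starting restrained torsions at their targets is
    # the standard head start — the search then concentrates on the
    # unrestrained (loop) torsions that set the tertiary arrangement
    tar_phi = np.zeros(n_res)
    tar_psi = np.zeros(n_res)
    has_phi = np.zeros(n_res, dtype=bool)
    has_psi = np.zeros(n_res, dtype=bool)
    for r, is_psi, t in zip(c.dihe_res, c.dihe_is_psi, c.dihe_target):
        if is_psi:
            tar_psi[r] = t
            has_psi[r] = True
        else:
            tar_phi[r] = t
            has_phi[r] = True

    results = []
    n_flagged = 0
    # seeded runs refine, they do not re-fold: short, barely-warm phase
    hot = int((0.7 if initial is None else 0.15) * n_steps)
    t_hot = 50.0 if initial is None else 0.3
    for k in range(n_conf):
        rng = np.random.default_rng(child_seeds[k])
        if initial is not None:
            phi = np.ascontiguousarray(initial[0].copy())
            psi = np.ascontiguousarray(initial[1].copy())
            if k > 0:
                phi += rng.normal(0, 6.0, n_res)
                psi += rng.normal(0, 6.0, n_res)
        else:
            phi = np.ascontiguousarray(rng.uniform(-179.9, 180.0, n_res))
            psi = np.ascontiguousarray(rng.uniform(-179.9, 180.0, n_res))
            phi[has_phi] = tar_phi[has_phi] + rng.normal(0, 5.0, int(has_phi.sum()))
            psi[has_psi] = tar_psi[has_psi] + rng.normal(0, 5.0, int(has_psi.sum()))
        np.clip(phi, -179.9, 180.0, out=phi)
        np.clip(psi, -179.9, 180.0, out=psi)
        local = 0 if initial is None else 1
        _kernels.mc_anneal(phi, psi, free, hot, t_hot, 0.5,
                           child_seeds[k],
                           c.cand_i, c.cand_j, c.grp_ptr, c.lower, c.upper,
                           c.dihe_res, c.dihe_is_psi, c.dihe_target, c.dihe_tol,
                           empty_atoms, empty_res, spec.steric_radius,
                           spec.w_upper, spec.w_lower, spec.w_dihedral, 0.0,
                           0, local)
        tf = _kernels.mc_anneal(phi, psi, free, n_steps - hot, 0.5, 0.01,
                                child_seeds[k] + 1,
                                c.cand_i, c.cand_j, c.grp_ptr, c.lower, c.upper,
                                c.dihe_res, c.dihe_is_psi, c.dihe_target,
                                c.dihe_tol,
                                c.steric_atoms, c.steric_res, spec.steric_radius,
                                spec.w_upper, spec.w_lower, spec.w_dihedral,
                                spec.w_steric, max(200, n_steps // 8), local)
        if tf > ceiling:
            n_flagged += 1
            continue
        results.append((float(tf), phi, psi))

    results.sort(key=lambda t: t[0])
    kept = results[:config.n_keep]
    if polish_sweeps > 0:
        # deep deterministic polish of the retained conformers only
        polished = []
        for tf, phi, psi in kept:
            tf = float(_kernels.coord_descent(
                phi, psi, free, c.cand_i, c.cand_j, c.grp_ptr, c.lower,
                c.upper, c.dihe_res, c.dihe_is_psi, c.dihe_target, c.dihe_tol,
                c.steric_atoms, c.steric_res, spec.steric_radius,
                spec.w_upper, spec.w_lower, spec.w_dihedral, spec.w_steric,
                polish_sweeps))
            polished.append((tf, phi, psi))
        polished.sort(key=lambda t: t[0])
        kept = polished
    conformers = []
    energies = []
    coords = np.empty((n_res * _kernels.N_SLOTS, 3))
    for tf, phi, psi in kept:
        _kernels.build_chain(phi, psi, coords)
        conformers.append(Structure(sequence, coords.copy(), "A",
                                    phi.copy(), psi.copy()))
        energies.append(tf)
    if not conformers:
        # fully diverged run: return the flagged marker with no models
        ens = Ensemble([], np.zeros(0))
        ens.diverged = True
        return ens
    ens = Ensemble(conformers, np.array(energies))
    ens.diverged = n_flagged > n_conf / 2
    return ens
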