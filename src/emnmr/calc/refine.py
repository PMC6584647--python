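"""Iterative refinement (step 2) and symmetry-replicated real-space
refinement against maps of increasing resolution (step 3).

Step 2 loop: flexible-fit the current best model into the map, flag
residues whose per-residue map correlation exceeds the threshold, pin them
with ±tolerance distance restraints, disambiguate the ambiguous NMR pool
against the intermediate ensemble (< cutoff uniqueness rule), re-anneal
with the grown restraint set.  Map-derived pins are regenerated — not
accumulated — every cycle; resolved NMR restraints persist.  The loop ends
when the ensemble bundle RMSD changes by less than the relative tolerance
for the required number of consecutive cycles.

Step 3: the protomer is rigid-body placed (symmetry-expanded correlation
search), then its torsions plus one rigid-body transform are minimised
against E = TF + w_map · Σ(−ρ) with strict symmetry — every chain is the
exact operator image of the protomer, and all images contribute to the
energy.  The schedule proceeds coarse to fine; the map weight is
recalibrated at each resolution so both terms start at equal magnitude.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .. import _kernels
from .._kernels import N_SLOTS
from ..density import (DensityMap, fourier_truncate, map_correlation,
                       overlap_fraction, per_residue_overlap, simulate_map)
from ..model import (Ensemble, InputError, ProtocolConfig, Structure,
                     SymmetryGroup, apply_symmetry, bundle_rmsd, superpose)
from ..restraints import (DistanceRestraint, RestraintSet, disambiguate,
                          fix_positions)
from .anneal import anneal
from .fit import flexible_fit
from .target import TargetFunctionSpec, compile_restraints, compute_torsions


def converged(series: Sequence[float], rel_tol: float = 0.10,
              cycles: int = 3) -> bool:
    """True once the last `cycles` consecutive relative changes of the
    bundle-RMSD series are all below `rel_tol`."""
    s = list(series)
    if len(s) < cycles + 1:
        return False
    for prev, cur in zip(s[-cycles - 1:-1], s[-cycles:]):
        if prev == 0:
            if cur != 0:
                return False
            continue
        if abs(cur - prev) / abs(prev) >= rel_tol:
            return False
    return True


@dataclasses.dataclass
class Step2Result:
    ensemble: Ensemble              # kept conformers, placed in the map frame
    restraints: RestraintSet        # final grown restraint set
    history: list[dict]             # per-cycle records
    converged: bool
    model: Structure | None = None  # carried-forward representative model


def _place_on_reference(conf: Structure, reference: Structure,
                        residues: Sequence[int] | None) -> Structure:
    sel_res = list(residues) if residues else None
    sel = conf.select(("N", "CA", "C"), residues=sel_res)
    if len(sel) < 3:
        sel = conf.select(("CA",))
    _, (rot, t) = superpose(conf.coords[sel], reference.coords[sel])
    return conf.transformed(rot, t)


def iterate_step2(seed_structure: Structure, dmap: DensityMap,
                  restraints: RestraintSet,
                  config: ProtocolConfig | None = None,
                  spec: TargetFunctionSpec | None = None,
                  max_cycles: int = 20,
                  pins: list[DistanceRestraint] | None = None) -> Step2Result:
    """Iteratively grow map-derived and disambiguated restraints.

    `restraints` is the NMR pool (unambiguous + ambiguous + dihedrals);
    `seed_structure` must already sit in the map frame (step-1 placement).
    `pins` are the helix-center restraints of the decided assignment; they
    persist through every cycle and anchor the helices' register against
    the axial sliding the map alone cannot see.
    """
    if max_cycles <= 0:
        raise InputError("cycle cap must be positive")
    config = config or ProtocolConfig.scaled()
    spec = spec or TargetFunctionSpec()
    resolution = dmap.nominal_resolution or 8.0
    pins = list(pins) if pins else []

    unambig = [r for r in restraints.distance if not r.ambiguous]
    amb_pool = [r for r in restraints.distance if r.ambiguous]
    resolved: list[DistanceRestraint] = []
    dihedrals = list(restraints.dihedral)

    current = seed_structure
    prev_ens: Ensemble | None = None
    history: list[dict] = []
    rmsd_series: list[float] = []
    is_converged = False

    for cycle in range(1, max_cycles + 1):
        fitted = flexible_fit(current, dmap)
        corrs, _ = per_residue_overlap(fitted, dmap, resolution)
        flagged = [i + 1 for i, cc in enumerate(corrs)
                   if cc > config.overlap_threshold]
        em_fix = fix_positions(fitted, flagged, tol=config.fix_tolerance,
                               seed=config.seed * 131 + cycle)
        source = prev_ens if prev_ens is not None and len(prev_ens) else \
            Ensemble([fitted], np.zeros(1))
        newly, amb_pool = disambiguate(amb_pool, source,
                                       cutoff=config.disambig_cutoff,
                                       n_models=config.n_keep)
        resolved.extend(newly)

        cycle_set = RestraintSet(
            [dataclasses.replace(r) for r in unambig + resolved + amb_pool
             + pins] + em_fix, dihedrals)
        sub = dataclasses.replace(config, seed=config.seed * 131 + cycle)
        # refine around the current model: the grown EM_FIX network encodes
        # the fitted geometry and pulls the ensemble onto it.  Seeding uses
        # the model's STORED torsions (exact torsion-space representation);
        # measuring torsions off the Cartesian fitted model would lose its
        # ω deviations and the rebuilt seed would be globally distorted.
        seed_torsions = compute_torsions(current)
        ens = anneal(current.sequence, cycle_set, sub, spec,
                     stream=f"step2-{cycle}", initial=seed_torsions,
                     polish_sweeps=2)
        if len(ens) == 0:
            history.append(dict(cycle=cycle, diverged=True))
            break
        placed = [_place_on_reference(c, fitted, flagged)
                  for c in ens.conformers]
        ens = Ensemble(placed, ens.energies)
        prev_ens = ens
        current = ens.best

        brmsd = bundle_rmsd(ens)
        rmsd_series.append(brmsd)
        history.append(dict(
            cycle=cycle, bundle_rmsd=brmsd, n_em_fix=len(em_fix),
            n_flagged=len(flagged), n_resolved=len(resolved),
            n_ambiguous=len(amb_pool),
            overlap_fraction=overlap_fraction(corrs, config.overlap_threshold)))
        if converged(rmsd_series, config.convergence_rel_tol,
                     config.convergence_cycles):
            is_converged = True
            break

    final_set = RestraintSet(
        [dataclasses.replace(r) for r in unambig + resolved + amb_pool]
        + (em_fix if history else []), dihedrals)
    if prev_ens is None:
        raise InputError("step 2 produced no ensemble (all cycles diverged)")
    return Step2Result(prev_ens, final_set, history, is_converged, current)


def nmr_only(rset: RestraintSet) -> RestraintSet:
    """Strip map-derived restraints (EM_FIX pins, helix-center pins): the
    final refinement sees the map in real space, not through pins."""
    keep = [dataclasses.replace(r) for r in rset.distance
            if r.origin not in ("EM_FIX", "HELIX_CENTER")]
    return RestraintSet(keep, [dataclasses.replace(d) for d in rset.dihedral])


# ---------------------------------------------------------------------------
# step 3


@dataclasses.dataclass
class AssemblyEnsemble:
    """Protomer conformers plus the group that replicates them; chains of
    every assembly are exact operator images of the protomer."""

    protomers: Ensemble
    symmetry: SymmetryGroup

    def assemblies(self) -> list[list[Structure]]:
        return [apply_symmetry(p, self.symmetry)
                for p in self.protomers.conformers]

    @property
    def best_assembly(self) -> list[Structure]:
        return apply_symmetry(self.protomers.best, self.symmetry)


def _assembly_correlation(protomer: Structure, group: SymmetryGroup,
                          dmap: DensityMap, resolution: float) -> float:
    chains = apply_symmetry(protomer, group)
    sim = simulate_map(chains, resolution, dmap.voxel, like=dmap)
    return map_correlation(sim, dmap)


def refine_rigid_placement(protomer: Structure, dmap: DensityMap,
                           group: SymmetryGroup,
                           resolution: float | None = None) -> Structure:
    """Rigid-body search maximising the symmetry-expanded map correlation."""
    res = resolution or dmap.nominal_resolution or 8.0

    def cost(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        cand = protomer.transformed(rot, p[3:])
        try:
            return -_assembly_correlation(cand, group, dmap, res)
        except Exception:
            return 1.0

    steps6 = np.array([0.1, 0.1, 0.1, 1.5, 1.5, 1.5])
    best = None
    for init in (np.zeros(6),):
        simplex = np.vstack([init, init + np.diag(steps6)])
        r = minimize(cost, init, method="Nelder-Mead",
                     options=dict(maxiter=400, xatol=1e-3, fatol=1e-5,
                                  initial_simplex=simplex))
        if best is None or r.fun < best.fun:
            best = r
    rot = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return protomer.transformed(rot, best.x[3:])


def refine_step3(protomer_ensemble: Ensemble, map_fine: DensityMap,
                 group: SymmetryGroup, restraints: RestraintSet,
                 config: ProtocolConfig | None = None,
                 spec: TargetFunctionSpec | None = None,
                 n_structures: int = 4, maxiter: int = 60
                 ) -> AssemblyEnsemble:
    """Strict-symmetry real-space refinement over a resolution schedule.

    All protomer degrees of freedom (torsions + one rigid-body transform)
    are minimised against TF + w_map·Σ_atoms(−ρ); each resolution runs
    `n_structures` independently perturbed seeded repeats and passes its
    lowest-energy result on.
    """
    config = config or ProtocolConfig.scaled()
    spec = spec or TargetFunctionSpec()
    finest = map_fine.nominal_resolution or 2 * map_fine.voxel
    for r in config.resolution_schedule:
        if r < finest - 1e-9:
            raise InputError(
                f"schedule entry {r} Å finer than the map's nominal "
                f"resolution {finest} Å")

    start = protomer_ensemble.best
    n_res = start.n_residues
    comp = compile_restraints(restraints, n_res)
    seq = start.sequence

    work0 = _truncate_for(map_fine, config.resolution_schedule[0])
    start = refine_rigid_placement(start, work0, group,
                                   config.resolution_schedule[0])

    ops_R = np.array([op[0] for op in group.operators])
    ops_t = np.array([op[1] for op in group.operators])
    bb_cols = [0, 1, 2, 3]  # N, CA, C, O pull into density
    bb_idx = np.array([r * N_SLOTS + c for r in range(n_res) for c in bb_cols],
                      dtype=np.int64)

    rng_master = np.random.default_rng(config.seed * 7919 + 3)
    current = start
    protomers, energies = [start], [np.inf]
    free = np.ones(2 * n_res, dtype=np.int8)

    first_resolution = True
    for res in config.resolution_schedule:
        work = _truncate_for(map_fine, res)
        g = work.grid.astype(np.float64)
        g /= max(1e-9, np.abs(g).max())
        origin = work.origin
        voxel = work.voxel
        ops_r = np.ascontiguousarray(ops_R)
        ops_tt = np.ascontiguousarray(ops_t)

        def torsions_and_frame(struct):
            p, q = compute_torsions(struct)
            p = np.ascontiguousarray(np.clip(p, -179.9, 180.0))
            q = np.ascontiguousarray(np.clip(q, -179.9, 180.0))
            built = np.empty((n_res * N_SLOTS, 3))
            _kernels.build_chain(p, q, built)
            _, (r0, tt0) = superpose(built, struct.coords)
            return p, q, r0, tt0

        phi0, psi0, rot0, t0 = torsions_and_frame(current)

        def tf_of(phi, psi):
            coords = np.empty((n_res * N_SLOTS, 3))
            _kernels.build_chain(phi, psi, coords)
            return float(_kernels.tf_eval(
                coords, phi, psi, comp.cand_i, comp.cand_j, comp.grp_ptr,
                comp.lower, comp.upper, comp.dihe_res, comp.dihe_is_psi,
                comp.dihe_target, comp.dihe_tol, comp.steric_atoms,
                comp.steric_res, spec.steric_radius, spec.w_upper,
                spec.w_lower, spec.w_dihedral, spec.w_steric))

        def map_term(phi, psi, rot, tr):
            coords = np.empty((n_res * N_SLOTS, 3))
            _kernels.build_chain(phi, psi, coords)
            return float(_kernels._map_energy(coords, bb_idx, rot, tr,
                                              ops_r, ops_tt, g, origin, voxel))

        m0 = map_term(phi0, psi0, rot0, t0)
        w_map = max(tf_of(phi0, psi0), 1.0) / max(abs(m0), 1e-9)

        def refine_one(phi, psi, rot, tr):
            """Alternate rigid 6-DOF search with torsion coordinate descent."""
            e = np.inf
            for _ in range(3):
                # rigid: NM over (rotvec delta about com, translation delta)
                coords = np.empty((n_res * N_SLOTS, 3))
                _kernels.build_chain(phi, psi, coords)
                com = coords.mean(axis=0)

                def rigid_cost(p):
                    dr = Rotation.from_rotvec(p[:3]).as_matrix()
                    rr = dr @ rot
                    tt = dr @ (tr - (rot @ com + tr)) + (rot @ com + tr) + p[3:]
                    # tt keeps the com fixed under dr, then translates
                    return (_kernels._map_energy(coords, bb_idx, rr, tt,
                                                 ops_r, ops_tt, g, origin,
                                                 voxel))

                steps6 = np.array([0.05, 0.05, 0.05, 1.0, 1.0, 1.0])
                simplex = np.vstack([np.zeros(6), np.diag(steps6)])
                r = minimize(rigid_cost, np.zeros(6), method="Nelder-Mead",
                             options=dict(maxiter=200, xatol=1e-3,
                                          fatol=1e-7,
                                          initial_simplex=simplex))
                dr = Rotation.from_rotvec(r.x[:3]).as_matrix()
                pivot = rot @ com + tr
                tr = dr @ (tr - pivot) + pivot + r.x[3:]
                rot = dr @ rot
                # torsions at fixed rigid frame
                e = float(_kernels.map_coord_descent(
                    phi, psi, free, np.ascontiguousarray(rot),
                    np.ascontiguousarray(tr), ops_r, ops_tt, g, origin,
                    voxel, bb_idx, w_map,
                    comp.cand_i, comp.cand_j, comp.grp_ptr, comp.lower,
                    comp.upper, comp.dihe_res, comp.dihe_is_psi,
                    comp.dihe_target, comp.dihe_tol, comp.steric_atoms,
                    comp.steric_res, spec.steric_radius, spec.w_upper,
                    spec.w_lower, spec.w_dihedral, spec.w_steric, 4))
            return e, phi, psi, rot, tr

        results = []
        for k in range(n_structures):
            # at the first (coarsest) resolution the repeats start from
            # distinct ensemble conformers — the bundle spread is the most
            # honest sampling of the remaining uncertainty; afterwards
            # repeats are perturbations of the running best
            if first_resolution and k < len(protomer_ensemble):
                phi, psi, rot, tr = torsions_and_frame(
                    protomer_ensemble.conformers[k])
            else:
                phi, psi, rot, tr = phi0.copy(), psi0.copy(), rot0.copy(), t0.copy()
                phi = np.ascontiguousarray(_wrap_arr(
                    phi + rng_master.normal(0, 2.0, n_res)))
                psi = np.ascontiguousarray(_wrap_arr(
                    psi + rng_master.normal(0, 2.0, n_res)))
            results.append(refine_one(phi, psi, rot, tr))
        results.sort(key=lambda t: t[0])
        first_resolution = False

        protomers, energies = [], []
        for e, phi, psi, rot, tr in results:
            coords = np.empty((n_res * N_SLOTS, 3))
            _kernels.build_chain(phi, psi, coords)
            s = Structure(seq, coords @ rot.T + tr, current.chain_id,
                          phi.copy(), psi.copy())
            protomers.append(s)
            energies.append(e)
        current = protomers[0]

    return AssemblyEnsemble(Ensemble(protomers, np.array(energies)), group)


def _wrap_arr(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


def _truncate_for(map_fine: DensityMap, res: float) -> DensityMap:
    nominal = map_fine.nominal_resolution or 0.0
    if res <= nominal + 1e-9:
        out = map_fine.copy()
    else:
        out = fourier_truncate(map_fine, res)
    out.nominal_resolution = res
    return out
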