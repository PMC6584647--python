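"""Hypothesis scoring and ranking for the helix-to-density assignment step.

Each assignment hypothesis is annealed under the NMR restraints plus its
helix-center pin restraints; hypotheses are then ranked on two criteria:

* the mean target function of the kept conformers (agreement with the
  distance/dihedral restraints), and
* the fraction of assigned-helix residues whose simulated backbone density
  correlates > threshold with the helices-only region of the experimental
  map, computed on the lowest-TF conformer after rigid placement.

Wrong assignments force bent or twisted helices — high TF and poor map
overlap — so the correct one dominates both criteria.  Runs whose target
function diverges (the tell-tale of an impossible assignment) are excluded
from the ranking but reported.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Sequence

import numpy as np

from ..density import DensityMap, overlap_fraction, per_residue_overlap
from ..features import HelixDensity, SequenceHelix
from ..model import Ensemble, InputError, ProtocolConfig, Structure, superpose
from ..restraints import (AssignmentHypothesis, RestraintSet,
                          hypothesis_to_restraints)
from .anneal import anneal
from .target import TargetFunctionSpec


@dataclasses.dataclass
class ScoreCard:
    hypothesis: AssignmentHypothesis
    target_function: float
    overlap_fraction: float
    diverged: bool = False

    def __post_init__(self) -> None:
        if not self.diverged:
            assert 0.0 <= self.overlap_fraction <= 1.0


def mask_map_to_helices(dmap: DensityMap, densities: Sequence[HelixDensity],
                        radius: float = 6.0) -> DensityMap:
    """Zero the map outside cylinders around the detected helix rods —
    the 'helix-density' reference region used by the overlap criterion."""
    idx = np.indices(dmap.shape).reshape(3, -1).T
    pts = dmap.origin + dmap.voxel * idx
    keep = np.zeros(len(pts), dtype=bool)
    for h in densities:
        v = pts - h.center
        t = v @ h.axis
        lat2 = np.einsum("ij,ij->i", v, v) - t ** 2
        keep |= (np.abs(t) <= h.length / 2 + radius / 2) & (lat2 <= radius ** 2)
    out = dmap.copy()
    out.grid = np.where(keep.reshape(dmap.shape), dmap.grid, 0.0).astype(np.float32)
    return out


def rigid_place_by_pins(structure: Structure, hyp: AssignmentHypothesis,
                        densities: Sequence[HelixDensity],
                        seq_helices: Sequence[SequenceHelix]) -> Structure:
    """Move the model into the map frame by superposing the pinned central
    CAs onto their assigned rod centers (proper rotation only)."""
    mob = np.array([structure.atom(seq_helices[s].central_residue, "CA")
                    for d, s in hyp.mapping])
    ref = np.array([densities[d].center for d, s in hyp.mapping])
    if len(mob) < 3:
        raise InputError("need >= 3 pinned helices for rigid placement")
    _, (rot, t) = superpose(mob, ref)
    return structure.transformed(rot, t)


def score_and_rank(hypotheses: Sequence[AssignmentHypothesis],
                   base_restraints: RestraintSet,
                   sequence: str,
                   dmap: DensityMap,
                   densities: Sequence[HelixDensity],
                   seq_helices: Sequence[SequenceHelix],
                   config: ProtocolConfig | None = None,
                   spec: TargetFunctionSpec | None = None,
                   pin_tol: float = 2.0,
                   n_screen: int = 4,
                   beam: int = 3,
                   ) -> tuple[list[ScoreCard], list[ScoreCard], dict[str, Ensemble]]:
    """Anneal every hypothesis and rank by (TF, map overlap).

    Screening mirrors how full-scale runs are handled: every hypothesis
    first gets a small slice of `n_screen` conformers; runs whose energies
    blow past the divergence ceiling are stopped and reported separately,
    and only the `beam` most promising assignments (by mean kept TF) are
    annealed out to the full conformer count.  Assignments outside the
    beam keep their screening scores — they compete in the same ranking,
    they just never overtake a fully sampled better hypothesis in
    practice.

    Returns (ranked, diverged, ensembles_by_label); `ranked` is sorted by
    Pareto dominance on (low TF, high overlap), ties by the normalised
    score sum, then by hypothesis label.
    """
    config = config or ProtocolConfig.scaled()
    spec = spec or TargetFunctionSpec()
    helix_map = mask_map_to_helices(dmap, densities)
    resolution = dmap.nominal_resolution or 8.0

    def hyp_seed(hyp):
        # label-derived, so the per-hypothesis substream is independent of
        # the enumeration order or any pre-filtering of the list
        return (config.seed * 997 + zlib.crc32(hyp.label.encode()) % 9973) \
            % (2 ** 30)

    rsets: dict[str, RestraintSet] = {}
    screens: list[tuple[int, "AssignmentHypothesis", Ensemble]] = []
    diverged: list[ScoreCard] = []
    for hi, hyp in enumerate(hypotheses):
        pins = hypothesis_to_restraints(hyp, densities, seq_helices, tol=pin_tol)
        rset = RestraintSet(
            [dataclasses.replace(r) for r in base_restraints.distance] +
            pins, list(base_restraints.dihedral))
        rsets[hyp.label] = rset
        sub = ProtocolConfig.scaled(
            n_conformers=min(n_screen, config.n_conformers),
            anneal_steps=config.anneal_steps,
            n_keep=config.n_keep, seed=hyp_seed(hyp))
        screen = anneal(sequence, rset, sub, spec, stream="screen",
                        polish_sweeps=0)
        if getattr(screen, "diverged", False) or len(screen) == 0:
            tf = float(screen.energies.min()) if len(screen) else np.inf
            diverged.append(ScoreCard(hyp, tf, 0.0, diverged=True))
            continue
        screens.append((hi, hyp, screen))

    screens.sort(key=lambda t: float(t[2].energies.mean()))
    ensembles: dict[str, Ensemble] = {}
    cards: list[ScoreCard] = []
    for rank_pos, (hi, hyp, screen) in enumerate(screens):
        if rank_pos < beam and config.n_conformers > n_screen:
            sub2 = ProtocolConfig.scaled(
                n_conformers=config.n_conformers - n_screen,
                anneal_steps=config.anneal_steps, n_keep=config.n_keep,
                seed=hyp_seed(hyp))
            rest = anneal(sequence, rsets[hyp.label], sub2, spec,
                          stream="screen2", polish_sweeps=4)
            ens = Ensemble(screen.conformers + rest.conformers,
                           np.concatenate([screen.energies, rest.energies])
                           ).sorted_by_energy()
            ens = Ensemble(ens.conformers[:config.n_keep],
                           ens.energies[:config.n_keep])
        else:
            ens = screen
        ensembles[hyp.label] = ens
        mean_tf = float(ens.energies.mean())
        placed = rigid_place_by_pins(ens.best, hyp, densities, seq_helices)
        helix_res = sorted({r for _, s in hyp.mapping
                            for r in seq_helices[s].residues})
        corrs, _ = per_residue_overlap(placed, helix_map, resolution,
                                       residues=helix_res)
        ov = overlap_fraction(corrs, config.overlap_threshold)
        cards.append(ScoreCard(hyp, mean_tf, ov))

    ranked = _pareto_rank(cards)
    return ranked, diverged, ensembles


def _pareto_rank(cards: list[ScoreCard]) -> list[ScoreCard]:
    if not cards:
        return []
    tfs = np.array([c.target_function for c in cards])
    ovs = np.array([c.overlap_fraction for c in cards])

    def dominates(i, j):
        return (tfs[i] <= tfs[j] and ovs[i] >= ovs[j]
                and (tfs[i] < tfs[j] or ovs[i] > ovs[j]))

    n = len(cards)
    front = np.zeros(n, dtype=int)
    remaining = set(range(n))
    level = 0
    while remaining:
        nd = [i for i in remaining
              if not any(dominates(j, i) for j in remaining if j != i)]
        for i in nd:
            front[i] = level
            remaining.discard(i)
        level += 1
    # normalised score sum for ties within a front
    tf_rng = tfs.max() - tfs.min() or 1.0
    ov_rng = ovs.max() - ovs.min() or 1.0
    norm = (tfs - tfs.min()) / tf_rng + (ovs.max() - ovs) / ov_rng
    order = sorted(range(n), key=lambda i: (front[i], norm[i],
                                            cards[i].hypothesis.label))
    return [cards[i] for i in order]
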