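"""Model-vs-reference comparison utilities.

Used to benchmark a computed (or deposited) ensemble against an independent
reference structure — e.g. an NMR/EM hybrid bundle against a crystal
structure: per-conformer backbone RMSD to the reference, and the ensemble's
internal precision (bundle RMSD about the mean).

The functions work on plain CA coordinate arrays so they apply equally to
reduced-representation models and to full-atom deposited files read with
:func:`emnmr.io.read_backbone_coords`.
"""

from __future__ import annotations

import numpy as np

from .model import InputError, superpose

__all__ = ["ensemble_vs_reference", "ensemble_precision"]


def _common_length(models: list[np.ndarray]) -> list[np.ndarray]:
    n = min(len(m) for m in models)
    if n < 3:
        raise InputError("fewer than 3 common atoms")
    return [np.asarray(m[:n], dtype=float) for m in models]


def ensemble_vs_reference(models: list[np.ndarray], reference: np.ndarray
                          ) -> dict:
    """Backbone RMSD of each conformer to a reference structure.

    Coordinates are truncated to the common atom count (deposited models
    and references often differ in modelled termini); each conformer is
    superposed onto the reference before the RMSD is taken.
    """
    if not models:
        raise InputError("empty ensemble")
    all_sets = _common_length(list(models) + [np.asarray(reference, float)])
    ref = all_sets[-1]
    rmsds = [superpose(m, ref)[0] for m in all_sets[:-1]]
    return {
        "per_model_rmsd": rmsds,
        "mean_rmsd": float(np.mean(rmsds)),
        "best_rmsd": float(np.min(rmsds)),
        "n_atoms": int(len(ref)),
    }


def ensemble_precision(models: list[np.ndarray]) -> float:
    """Bundle precision: mean RMSD of conformers to their mean coordinates
    after iterative superposition (same convention as model bundles)."""
    if len(models) < 2:
        raise InputError("need at least 2 conformers")
    coords = _common_length(list(models))
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
    return float(np.mean([np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=1)))
                          for x in coords]))
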