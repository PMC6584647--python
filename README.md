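# emnmr

Integrated cryo-EM + NMR structure determination for proteins whose data
are individually insufficient: a medium-resolution density map (≈4–10 Å)
shows *where* the α-helices are but not *which* helix is which, while NMR
gives the backbone conformation residue-by-residue (φ/ψ restraints) and
sparse ≤8 Å atom–atom contacts, but too few of them to fold the chain on
their own. `emnmr` implements the three-step protocol that joins them:

1. **Helix-to-density assignment.** Rod-like densities are detected in the
   map (masked cylinder cross-correlation over orientations) and grouped
   into subunits (DBSCAN). Every injective assignment of sequence helices
   (from the NMR secondary structure) to rods — `P(s, d)` possibilities,
   `× 2^d` with orientations; about 5×10⁶ for 8 helices and 7 rods — is
   length-pruned to a manageable set. Each surviving assignment pins the
   central CA of every assigned helix to its rod center via *relative*
   distance restraints (±0.5 Å) and is scored by restrained simulated
   annealing in torsion space. Two criteria rank the assignments: the
   restraint target function TF = Σ w·max(0, violation)², and the fraction
   of helix residues whose simulated density overlaps the map by >0.7.
   Wrong assignments bend their helices — high TF, poor overlap — so the
   correct one dominates both.
2. **Iterative restraint growth.** The best model is flexibly fitted into
   the map; residues with per-residue overlap >0.7 are pinned (±0.5 Å
   pairwise backbone restraints); ambiguous NMR contacts whose candidates
   have exactly one <8 Å distance in the intermediate ensemble are
   resolved; the model is re-annealed under the grown set. Cycles repeat
   until the ensemble bundle RMSD changes <10 % for 3 consecutive cycles.
3. **Symmetric real-space refinement.** The protomer's torsions plus one
   rigid transform are minimised against TF + w_map·Σ(−ρ) with strict
   symmetry (all chains exact operator images), against maps of
   increasing resolution (8 → 6 → 4.1 Å by Fourier truncation).

A synthetic benchmark generator (helical bundles, Gaussian-kernel maps,
TALOS-like dihedral restraints, amide/methyl contacts with tunable
ambiguity and inter-subunit contamination) makes every stage testable
without any experimental download. See `docs/methods.md` for the model,
all conventions, and known limitations.

## Worked example

```python
from emnmr import ProtocolConfig
from emnmr.pipeline import run_benchmark

cfg = ProtocolConfig.scaled(seed=0, n_conformers=50, anneal_steps=2000)
result = run_benchmark("mono5", cfg, seed=0)

print("hypotheses considered:", result.n_hypotheses)
print("rank of true assignment:", result.true_rank)
for name, st in [("step1", result.step1), ("step2", result.step2),
                 ("step3", result.step3)]:
    print(f"{name}: bundle {st.bundle_rmsd:.2f} Å, "
          f"RMSD to truth {st.rmsd_to_truth:.2f} Å, "
          f"overlap {st.overlap_fraction:.2f}")
```

Output (seed 0):

```
hypotheses considered: 36
rank of true assignment: 0
step1: bundle 3.56 Å, RMSD to truth 3.31 Å, overlap 0.79
step2: bundle 0.34 Å, RMSD to truth 3.17 Å, overlap 0.90
step3: bundle 0.87 Å, RMSD to truth 2.13 Å, overlap 0.91
```

Reading it: of the 36 assignments that survive length pruning, the true one
ranks first; the step-1 model has the right topology but low accuracy
(exactly the regime this protocol expects); growing map restraints tightens
the bundle, and the final refinement against the 4.1 Å map brings the
backbone to ~2 Å of the generator's ground truth. Outcomes vary by
replicate at this reduced scale — the true assignment wins the ranking in
roughly half the seeds and final accuracy spans ~1–5 Å; see
`docs/methods.md` for what limits it and how the full-scale settings
differ.

The same stages are scriptable from the shell:

```sh
emnmr simulate --case mono5 --seed 1 --out case/
emnmr detect --map case/map.ccp4 --resolution 8 --out helices.tsv
emnmr assign --helices helices.tsv --ss case/ss.txt
emnmr run-all --case mono5 --seed 1 --out run/
```

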