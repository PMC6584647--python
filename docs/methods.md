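# Methods

`emnmr` determines protein backbone structures by combining two
complementary data sources that are individually insufficient: a
medium-resolution (≈4–10 Å) cryo-EM density map, which shows where
α-helices are but not which helix is which, and NMR-derived restraints
(backbone φ/ψ ranges and sparse ≤8 Å atom–atom contacts), which say how the
chain is built locally but not how the pieces pack globally. The protocol
has three steps: (1) combinatorial assignment of sequence helices to
detected helical densities, decided by restrained-annealing calculations;
(2) iterative refinement with restraints grown from the map and with
ambiguous NMR contacts resolved against intermediate models; (3) real-space
refinement of the (optionally symmetric) assembly against maps of
increasing resolution.

## Model representation

Chains are reduced to six atoms per residue — N, CA, C, O, CB, and an SC
pseudo-atom at the side-chain centroid (1.2 Å beyond CB along the CA→CB
direction). Backbone amide contacts address N; methyl-type contacts address
SC. Coordinates are always generated from torsions (φ, ψ; ω fixed at 180°)
with ideal trans-peptide covalent geometry, so bond lengths and angles can
never degrade during optimisation. Residues are 1-based, matching PDB/NMR
conventions.

## Target function

TF = w_up Σ max(0, d−upper)² + w_lo Σ max(0, lower−d)²
   + w_dih Σ max(0, |Δangle|−tol)² + w_steric Σ max(0, r_min−d)²

Distances in Å; dihedral violations in degrees with default weight
(1/20°)² = 0.0025, making 20° past tolerance cost as much as 1 Å of
distance violation. Ambiguous restraints contribute through the r⁻⁶-summed
effective distance over their candidate pairs. The steric term is a
soft-sphere repulsion (radius 2.5 Å, unit weight) over CA and SC atoms of
residues separated by ≥2 in sequence. TF = 0 iff every restraint is
satisfied.

## Annealing engine

Conformers are computed by Monte-Carlo simulated annealing over torsions
with a geometric temperature schedule, followed by a deterministic cyclic
coordinate-descent polish of the retained (lowest-TF) conformers. Design
choices that matter:

* **Initialisation at dihedral targets.** Torsions carrying a dihedral
  restraint start at the restraint target (±5° noise); unrestrained (loop)
  torsions start uniformly. The dihedral restraints encode the secondary
  structure residue-by-residue, so this is information the data already
  provides — the stochastic search then concentrates on the loop torsions
  that determine the tertiary arrangement.
* **Move mixture.** Loop torsions are proposed 3× more often than
  restrained ones; restrained torsions are occasionally reset straight to
  their target; a fraction of moves are full-range jumps. The steric weight
  is off for the first 70 % of the schedule (collapse first, clean up
  cold), which is both faster and better-converging.
* **Seeded refinement mode.** When a seed model is supplied (step-2 cycles,
  see below) the run starts from the seed's torsions (conformer 0 exact,
  the rest perturbed by ±6°) with a short, barely-warm phase and *local
  moves only* — no full-range jumps or target resets. This is essential:
  distance restraints are blind to the chirality of the helix arrangement
  (a mirrored topology satisfies every distance bound, and packed bundles
  are nearly mirror-symmetric constellations, so even the map tolerates
  both hands at 8 Å); large loop-torsion jumps would let the walk hop into
  the enantiomeric arrangement and the iteration would lock it in.
* **Retention and divergence.** The n_keep lowest-TF conformers are kept,
  sorted ascending; a conformer whose TF exceeds 10⁶ per restraint is
  flagged, and a run with >50 % flagged conformers is marked diverged.
* Default desk scale is 50 conformers × 2000 moves (the full-scale protocol
  values, 1000 × 4000, remain available through the configuration). All
  randomness flows from one master seed through named substreams, so every
  stage is independently reproducible.

## Density maps

Simulated density is a sum of per-atom Gaussians with
σ = resolution·√(ln2/2)/π (the kernel's Fourier amplitude falls to ½ at
1/resolution). Maps are reduced to a target resolution by sharp Fourier
truncation (a raised-cosine edge is available to suppress ringing); the
benchmark maps are simulated at 4.1 Å and truncated to the 8 Å working
resolution, mirroring how lower-resolution data are derived from a single
experimental map. Grids are isotropic, X-fastest, stored as CCP4 mode-2.

**Global map correlation** is Pearson over a mask (default: voxels where
either map exceeds 10⁻⁶ of its maximum). **Per-residue overlap** simulates
each residue's backbone (N/CA/C/O) density on the experimental grid and
correlates it against the experimental map *about zero* (cosine overlap)
inside the residue's own density region (>0.3 of its max). The about-zero
convention — the default of the standard interactive map-correlation tools
— is what the ">0.7 = good overlap" rule expresses: a perfectly placed
residue scores 0.8–0.95, a residue in empty map ≈0, and a mean-subtracted
(Pearson) value would hover near zero even for perfect placements because
a single residue's blob never has the same shape as the full rod density
around it. The 0.3 mask level was chosen so that the 0.7 threshold
separates placed from misplaced residues with a wide margin; at much looser
masks the statistic saturates near 0.6 for everything.

## Helix detection

At 6–10 Å an α-helix is a rod ≈5 Å across. Detection cross-correlates a
point-sampled, Gaussian-smoothed solid cylinder (radius 2.5 Å, length
10 Å) with the map over ≈15°-spaced orientations, evaluating the Pearson
correlation only inside a tight cylindrical box around the template —
crucial in packed bundles, where a rectangular correlation window would
include neighbouring rods and crush the score. High-scoring local maxima
seed segments that grow along the axis while the sliding correlation stays
above 80–90 % of the seed value; collinear overlapping segments merge. The
final axis comes from density-weighted PCA of the rod's voxels, and the
final length/centre from the half-maximum extent of the axial density
profile (accurate to ≈±1 Å on isolated helices, ±5 Å in bundles). Axis
polarity is intentionally not reported — rod direction is invisible at
these resolutions. Subunit grouping uses DBSCAN on rod centres with the
neighbourhood radius chosen at the widest plateau of the cluster count
over a radius scan, falling back to k-medoids when an expected
per-subunit count is violated.

## Assignment enumeration and ranking

Assignments are injective maps from detected rods to sequence helices
(maximal H-runs of the secondary-structure string). In center-only mode
(default, polarity unknown) the count for s sequence helices and d rods is
P(s, d) = s!/(s−d)!; oriented mode multiplies by 2^d. Pruning removes
assignments in which any helix's sequence length (1.5 Å/residue) differs
from its rod's length by more than a tolerance; the library default is 6 Å,
and the pipeline uses 8 Å — the detector's measured length uncertainty in
bundles plus conversion error — falling back to the unpruned set if
pruning empties the list.

Each assignment becomes restraints that pin the CA of every assigned
helix's central residue to its rod center *relatively*: one distance
restraint per pin pair, bounds = center distance ± the detector's center
uncertainty (2 Å default — tighter pins convert detection noise into
target-function penalties against the *correct* assignment, since wrong
assignments can always deform to compensate, while the correct one is
rigidly committed to the true geometry). Absolute placement is irrelevant;
the map's geometry enters through these relative distances only. Each hypothesis is annealed under NMR restraints + pins; ranking uses
two criteria: mean TF of the kept conformers, and the fraction of
assigned-helix residues with per-residue overlap >0.7 against the
helices-only map region (computed on the lowest-TF conformer after rigid
placement of the pinned CAs onto the rod centers). Hypotheses are ordered
by Pareto dominance on (low TF, high overlap), ties broken by the
normalised score sum. For cost control every hypothesis is first screened
with a small conformer slice; only the most promising few are annealed to
the full count (runs that blow the divergence ceiling are stopped and
reported separately, as at full scale where half the assignment runs were
stopped on divergent energies).

## Step 2: iterative restraint growth

The helix-center pins of the decided assignment persist through step 2:
they anchor each helix's register against the axial sliding that the map
cannot see. Per cycle: (i) flexible-fit the current best model into the
working-resolution map; (ii) flag residues with overlap >0.7 and pin their backbone
(N, CA, C) with pairwise distance restraints at ±0.5 Å — each atom is tied
to its 8 nearest flagged neighbours plus 4 random long-range partners,
which keeps the restraint graph generically rigid at linear (not
quadratic) size; (iii) resolve ambiguous NMR restraints whose candidates
have exactly one median distance <8 Å over the 10 lowest-energy
intermediate conformers; (iv) re-anneal, seeded from the fitted model,
under the grown set. Map-derived pins are regenerated each cycle (never
accumulated); resolved NMR restraints persist. The loop ends when the
bundle RMSD changes by <10 % for 3 consecutive cycles, or at a cycle cap.

Flexible fitting is a density-gradient flow with an elastic network (springs
between all atom pairs <10 Å restoring start-conformation distances),
preceded by a *local* rigid-body alignment (6-DOF Nelder–Mead on mean
density; jumps beyond 4 Å / 20° are discarded as basin escapes) and followed
by Gauss–Seidel bond-length regularisation (within 2 % of ideal). The
model-to-map correlation is guaranteed non-decreasing: if the fit scores
worse than its input, the input is returned.

## Step 3: symmetric real-space refinement

The protomer is rigid-body placed by maximising the symmetry-expanded
model-to-map correlation, then all protomer degrees of freedom (torsions +
one rigid transform) are minimised against E = TF + w_map·Σ(−ρ) with strict
symmetry: every chain is the exact operator image of the protomer and all
images contribute to the map term. w_map is recalibrated at the start of
each resolution so both terms begin at equal magnitude. The minimiser
alternates a rigid 6-DOF Nelder–Mead stage with cyclic coordinate descent
over torsions (trial steps 8°…0.5°); each resolution runs several
independently seeded repeats — at the coarsest resolution the repeats start
from distinct ensemble conformers, afterwards from perturbations of the
running best — and passes its lowest-energy result to the next, finer map.
The schedule (default 8, 6, 4.1 Å) is validated against the map's nominal
resolution.

## Synthetic benchmarks

The generator builds ground-truth helical bundles in torsion space: ideal
(−57, −47) helices (±2° jitter) joined by loops drawn from a small library
of turn conformations (pre-selected from allowed Ramachandran regions so
consecutive helices come out roughly antiparallel at ~10 Å spacing, ±6°
jitter). Loop torsions alone are then annealed against a bundle-packing
objective (adjacent helix centers 8.5–11.5 Å, soft-sphere 2.8 Å over all
atoms), and the fold is accepted only if self-avoiding (non-bonded atoms
>2.5 Å for |i−j|≥2) and compact (CA radius of gyration <1.2× that of an
idealised rod bundle at 11 Å hexagonal spacing).

Restraints emulate the experiments: contacts are N/SC atom pairs with
|i−j|≥2 within 8 Å, observed with a coverage fraction (default 0.6), upper
bound = true distance + 1 Å padding, lower 0; a fraction (default 0.2) is
made ambiguous by adding 2 same-atom-class decoy pairs (the true pair
always included, its index recorded); amide-involving contacts are tagged
RFDR, methyl–methyl NOE. Helix residues get φ/ψ restraints at their true
values ±20° (a TALOS-like uncertainty); loops get none, mirroring
unassigned loops in the real data. For assemblies, a small fraction of
contacts crosses chains and is labelled — written, deceptively, in
single-chain numbering, exactly the trap the inter-subunit filter exists
for. Shipped cases: `mono3` (3 helices), `mono5` (5 helices, the
assignment-regime benchmark), `c3` (C3 trimer, 5 helices/chain); all with
8 Å working maps derived by Fourier truncation from 4.1 Å simulations, all
regenerable bit-exactly from their manifest.

What the generator does **not** emulate: experimental map noise, CTF
artefacts, B-factor variation, local-resolution variation, spectral noise
or misassignment in the NMR data, and real side-chain packing. Passing
benchmarks therefore demonstrate the protocol's logic (assignment
identification, restraint growth, convergence behaviour) under clean
conditions, not robustness to experimental pathology. One consequence of
the clean maps: the >0.7 overlap rule flags most residues even in
moderately wrong models, so map-derived pins are less selective than with
real (noisy) maps, and step 2 mainly consolidates rather than corrects —
accuracy gains concentrate in step 3's finest-resolution refinement.

## Numerical choices and degenerate inputs

* Superposition is Kabsch with proper rotations only (det +1); reflections
  are never applied. Bundle RMSD iterates superposition to the running mean
  until the mean moves <1e-4 Å.
* Distance-restraint bounds of ambiguous restraints are evaluated with the
  r⁻⁶ effective distance everywhere, including in the brute-force oracle.
* Empty or constant maps: detection returns an empty list; flexible fitting
  returns its input unchanged (correlation against a constant map is
  undefined).
* Detected rods in excess of the sequence-helix count are cut by length
  (longest kept), as at full scale where only the five longest detected
  helices were used.
* A single-conformer bundle RMSD is 0 by definition (with a warning).
* Degenerate Nelder–Mead starts use explicit initial simplexes (Å/radian
  scale); zero-initialised simplexes would collapse immediately.

## Scale

Desk-scale defaults (50 conformers × 2000 moves, ≤8 step-2 cycles, 3–4
step-3 repeats) complete a full mono5 replicate in roughly two minutes on
one core. These are the problem sizes used throughout the test-suite and
the acceptance script; the full-scale protocol constants remain the
configuration defaults (`ProtocolConfig()`) and everything scales up by
raising `n_conformers`/`anneal_steps`.

## Known limitations

* The MC annealer does not reach TF ≈ 0 on sparse restraint networks from
  random starts the way full-scale torsion-angle dynamics does; ranking
  relies on TF *differences* between assignments, which are preserved.
* β-sheet density features are not detected or used.
* Register along a rod is invisible at 8 Å; it is fixed only by NMR
  contacts and by rod-end/pitch signals at the finest map resolution, so
  final accuracy is sensitive to contact coverage.
* The SC pseudo-atom is a crude side-chain proxy; methyl-contact geometry
  is honoured only at centroid resolution.
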