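# Methods

This note records the exact geometric criteria, the energy model, the
statistical procedures, and the design of the synthetic-data generator.
Every parameter below is the package default; most are exposed as
function arguments or `RunConfig` fields.

## Trajectory model and equilibrium windowing

A `Trajectory` is an atom table (name, residue name, residue position,
element, optional charge/ε/σ force-field columns) plus a list of frames
(float coordinates in Å, optional orthorhombic box, optional time).
Production trajectories are read through MDAnalysis (PDB/GRO/XTC/DCD);
the atom-selection grammar supports `protein`, `water`, `backbone`,
`all`, `name`/`resname`/`element`/`resid` filters (with `a-b` ranges)
and `and`/`or`/`not`/parentheses.

Analyses operate on an **equilibrium window**: the trailing
⌈f·n_frames⌉ frames for keep-fraction f (default 0.5, so a 2500-frame
trajectory yields its last 1250 frames).

## Hydrogen bonds

A donor–hydrogen–acceptor triple is a hydrogen bond when

- donor and acceptor are O or N heavy atoms,
- donor–acceptor distance ≤ 3.5 Å (minimum image when a box is present),
- donor–H···acceptor angle ≥ 150°.

Each hydrogen is assigned to its nearest heavy atom within 1.25 Å; a
hydrogen with no heavy atom within 1.6 Å is a typing error and raises.
`count_hbonds` counts only bonds crossing the protein–water interface
(either direction), per frame, and reports the per-frame series with
its mean and standard deviation.

## Hydration-shell classification

Every water in a frame gets exactly one of five labels, evaluated in
priority order. The *contact distance* of a water is the shortest
H···acceptor distance over its hydrogen bonds to the protein — water H
to protein O/N acceptor, or protein H to the water oxygen — and the
*anchor* is the protein-side heavy atom of that bond.

1. `hydrophilic_L1` — hydrogen-bonded, contact distance ≤ 2.0 Å;
2. `hydrophilic_L2` — hydrogen-bonded, contact distance ≤ 3.2 Å;
3. `hydrophilic_beyond_L2` — hydrogen-bonded but further than 3.2 Å
   (geometrically possible with a long donor–acceptor bond; kept as its
   own label so L1 + L2 counts stay pure);
4. `hydrophobic_L3` — no protein hydrogen bond, but the water oxygen is
   within 4.0 Å of a protein carbon or sulfur (anchor = nearest such
   atom);
5. `bulk` — everything else.

`hydration_counts` averages the per-frame label counts over the window;
`scope="local"` restricts the protein side to a selection (e.g. one
residue) before classifying.

## Protein–water interaction energy

Pairwise, over all protein–water atom pairs within a 12 Å cutoff
(minimum image):

- Coulomb: `k q_i q_j / r` with k = 1389.35485 kJ·mol⁻¹·Å·e⁻²
  (equivalently 138.935485 kJ·mol⁻¹·nm·e⁻²), so two unit charges at
  10 Å contribute 138.935485 kJ/mol;
- Lennard-Jones: `4ε[(σ/r)¹² − (σ/r)⁶]` with Lorentz–Berthelot
  combining (arithmetic σ, geometric ε), minimum −ε at r = 2^(1/6)σ.

Missing (NaN) charge/ε/σ parameters on an atom inside the cutoff raise
a typing error rather than silently contributing zero.

## Radial distribution functions

`rdf` histograms reference–target minimum-image distances in bins of
0.1 Å out to r_max (default 10 Å), normalised by shell volume and the
mean target number density; r_max beyond half the smallest box edge is
rejected. For an ideal gas, g(r) → 1.

## Conformation

Dihedrals use the convention in which the quadruple
(0,0,0)/(1,0,0)/(1,1,0)/(1,1,1) measures +90°, matching common MD
toolkits. For ring residues (PRO/HYP/MOP):

- χ1 = N–Cα–Cβ–Cγ, χ2 = Cα–Cβ–Cγ–Cδ;
- **Cγ-endo** ⇔ χ1 > 0 and χ2 < 0; **Cγ-exo** ⇔ χ1 < 0 and χ2 > 0;
  anything else is `other`;
- the preceding peptide bond is **cis** when |ω| < 90°, **trans**
  otherwise.

`occupancy` converts a pucker/isomer time series into per-residue
percentages summing to 100. Ramachandran histograms use 10° bins over
[−180°, 180°]; terminal residues without both φ and ψ are counted as
skipped. Distance maps are time-averaged Cα–Cα distances.

## Flexibility and clustering

RMSF removes rigid-body motion by iterating (Kabsch fit to the running
mean → recompute mean) twice on the fit selection (default backbone),
then reports per-residue root-mean-square fluctuation of the heavy
atoms. For isotropic Gaussian positional noise of width σ the expected
RMSF is σ√3, which the tests verify to 2% at 10⁴ frames. Site-set
summaries average the profile over named residue sets; replicate
summaries pool per-replicate means.

Clustering is Jarvis–Patrick on the pairwise superposed-RMSD matrix:
each frame keeps its K = 10 nearest neighbours (distance ties broken
toward the lower frame index); two frames join when each is in the
other's list and they share at least 3 common neighbours (excluding
themselves); clusters are the connected components. The central
structure of a cluster minimises mean RMSD to the other members.

## Cross-link proximity

Lysine Nζ–Nζ distances are counted against cutoffs 16–30 Å in 2 Å
steps, per frame, then averaged per replicate. Two models are compared
per cutoff with Welch's unequal-variance t-test on the replicate means
(≥ 2 replicates per side required); significance stars are strict:
`*` p < 0.05, `**` p < 0.01, `***` p < 0.001 (p = 0.05 earns none).

## Synthetic-data generator

The generator exists to give every estimator a fixture with exactly
known ground truth; it emulates geometry, not physics.

- **Peptide building**: residues are grown by natural-extension
  (NeRF-style) placement with φ = −70°, ψ = 150° and ω = 180° (or 0°
  for cis). Proline gets a Cβ/Cγ/Cδ ring with two Cγ hydrogens and no
  amide hydrogen; the ring is stamped from χ templates — endo
  (χ1, χ2) = (30°, −35°), exo (−30°, 35°). Lysine carries a coarse
  Cγ + Nζ sidechain.
- **Pucker schedules**: requested occupancies are converted to exact
  frame counts via `int(round(pct/100 · n_frames))`, and the frame list
  is shuffled deterministically. Per-frame Gaussian coordinate noise of
  width σ is then added; for scheduled ring residues the noise is
  rejection-resampled (bounded retries) until the noisy ring still
  classifies as scheduled, so measured occupancies equal the schedule
  exactly. If σ is large enough that retries are exhausted, the
  generator raises a geometry error instead of silently corrupting the
  ground truth.
- **Hydration planting**: waters are attached to protein anchors on
  outward directions chosen from a Fibonacci sphere, with feasibility
  checks (an infeasible shell request raises). L1 waters use contact
  distances cycling through 1.8/1.7/1.9 Å, L2 through 2.4/2.25/2.5 Å,
  all with donor–acceptor ≤ 3.5 Å and near-linear geometry; L3 waters
  sit within 4 Å of a carbon without hydrogen-bonding geometry; bulk
  waters are placed far from the chain. Planted waters ride rigidly on
  their anchors under the noise, so per-frame shell counts are exact.
- **Ensembles and lysine toys**: `make_ensemble` places cluster centres
  on a line so centre-to-centre superposed RMSD is exactly
  |i − j| · separation, with isotropic intra-cluster spread;
  `make_lysine_toy` plants Nζ–Nζ pairs at requested distances with
  optional jitter, spacing the pairs far apart so pairs never
  cross-contact.

What the generator does **not** emulate: solvation thermodynamics,
force-field dynamics, water exchange kinetics, or realistic
conformational ensembles. Noise is isotropic Gaussian by design so that
closed-form expectations (σ√3 RMSF, exact occupancies and counts) exist.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` seeds;
  derived seeds are drawn below 2³¹ so results are portable.
- Distances use the minimum-image convention for orthorhombic boxes
  only; triclinic boxes are out of scope.
- Dihedral comparisons against MDAnalysis are limited by its float32
  arithmetic (~10⁻⁴ degrees).
- The interaction energy is a bare truncated sum — no Ewald/PME
  long-range correction and no switching function — so it is a local
  interaction score, not a total electrostatic energy.
- The hydrogen-bond criterion is purely geometric; no energetic or
  orbital weighting is applied.
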