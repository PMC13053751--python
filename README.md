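# hypelast

Analysis toolkit for molecular-dynamics trajectories of elastin-like
peptides and tropoelastin, focused on the structural consequences of
prolyl 4-hydroxylation.

## The scientific problem

Tropoelastin, the soluble precursor of the elastin matrix, is
post-translationally modified by prolyl 4-hydroxylase, which replaces a
hydrogen at the proline Cγ with a hydroxyl group to form
(2S,4R)-4-hydroxyproline (Hyp). Hydroxylation is only possible at
prolines inside Gly-Yaa-Pro-Gly or Gly-Yaa-Zaa-Pro-Gly motifs (Yaa, Zaa
any residue except proline). The modification changes how the peptide
interacts with water, shifts the proline ring between its Cγ-endo and
Cγ-exo pucker states, alters local chain flexibility, and moves the
lysines that form elastin's covalent cross-links closer or further apart.
All of these effects are measurable from MD trajectories, and this
package implements the measurement pipeline:

- **`sequence_and_sites`** — motif scanning, hydroxylation-site
  bookkeeping (designated sites Pro190/Pro360, the optional Pro615, the
  never-modified Pro421, and a 17-site candidate pool for random
  assignment), and the coordinate-level Pro → Hyp edit.
- **`trajectory_io`** — PDB/GRO/XTC/DCD loading (via MDAnalysis), a
  uniform `Trajectory` container, a small atom-selection grammar, and
  equilibrium windowing (keep the trailing fraction of frames).
- **`hydration`** — geometric hydrogen-bond detection, three-layer
  hydration-shell classification (hydrophilic layers ≤ 2 Å and ≤ 3.2 Å
  by H···acceptor contact distance; a hydrophobic layer ≤ 4 Å around
  C/S), short-range Coulomb + Lennard-Jones protein–water interaction
  energy, and radial distribution functions.
- **`conformation`** — χ1/χ2-based endo/exo ring-pucker classification,
  cis/trans ω isomer state, occupancy tables, Ramachandran histograms,
  and Cα distance maps.
- **`dynamics`** — Kabsch superposition, iterated-fit RMSF profiles,
  per-site-set RMSF summaries, and RMSD series.
- **`clustering`** — Jarvis–Patrick shared-nearest-neighbour clustering
  (K = 10 nearest by pairwise superposed RMSD, edge when mutual
  neighbours share ≥ 3 common neighbours) with per-cluster central
  structures.
- **`crosslink`** — lysine Nζ–Nζ distance maps, contact counts swept
  over 16–30 Å cutoffs, and replicate-level Welch comparisons with
  significance stars (*p < 0.05, **p < 0.01, ***p < 0.001).
- **`synthetic_data`** — a generator of peptide-in-water trajectories
  with *planted* ground truth (pucker occupancies, hydration-shell
  counts, fluctuation amplitudes, cluster labels, lysine distances) so
  every estimator can be validated without running MD.
- **`pipeline`** / the `hypelast` CLI — config-driven orchestration of
  the full per-model workflow and cross-model comparison.

## Worked example

Build a hydroxylation map, generate a synthetic fixture with planted
ground truth, and recover the planted values:

```python
import numpy as np
from hypelast import (
    clustering, conformation, crosslink, hydration,
    sequence_and_sites as seqs, synthetic_data as sd,
)

# a 5-site map: the designated sites plus the optional 615, plus
# two positions drawn from the 17-site candidate pool
m = seqs.build_map(5, include_615=True, seed=42)
print(seqs.format_map(m))
# 5hyp-2	designated:190,360,615	random:116,551

# a noisy GVPG peptide with 40/60 endo/exo pucker occupancy at Pro3
# and a planted hydration shell around Val2
spec = sd.SyntheticSpec(
    sequence="GVPG", box_edge=40.0, n_frames=100, seed=7, sigma=0.1,
    pucker_occupancy={3: {"endo": 40.0, "exo": 60.0}},
    hydration={2: {"L1": 3, "L2": 2, "L3": 4, "bulk": 2}},
)
traj = sd.make_trajectory(spec)          # 58 atoms, 100 frames

s = hydration.hydration_counts(traj, scope="global")
print(s.total, s.hydrophilic, s.hydrophobic, s.sd_total)
# 9.0 5.0 4.0 0.0        <- L1+L2 hydrophilic, L3 hydrophobic, exact

counts, hb_mean, hb_sd = hydration.count_hbonds(traj, "protein")
print(hb_mean)                           # 5.0 protein-water H-bonds

occ = conformation.occupancy(conformation.pucker_timeseries(traj, [3]))[3]
print(occ)                               # {'exo': 60.0, 'endo': 40.0}

# clustering recovers a planted 3-cluster ensemble exactly
ens, labels = sd.make_ensemble(3, 20, intra_spread=0.2,
                               inter_separation=10.0, seed=3)
d = clustering.pairwise_rmsd(ens, selection=None)
r = clustering.jarvis_patrick(d, k=10, min_shared=3)
print(r.n_clusters, r.sizes.tolist())    # 3 [20, 20, 20]

# a lysine pair planted at 17 A enters the sweep between 16 and 18 A
toy = sd.make_lysine_toy([17.0], jitter_sigma=0.0, n_frames=20)
sw = crosslink.contact_sweep(toy, [1, 2])
print(dict(zip(sw.cutoffs.tolist(), sw.mean_counts.tolist())))
# {16.0: 0.0, 18.0: 1.0, 20.0: 1.0, ..., 30.0: 1.0}
```

The same stages are available from the command line, e.g.
`hypelast map build --n 5 --with-615 --seed 42`,
`hypelast pucker --coords traj.pdb --residues 3`, or a full
config-driven run via `hypelast run --config model.yaml` followed by
`hypelast compare a/report.json b/report.json`.

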