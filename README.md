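# lipsite

Lipid–protein interaction analysis for membrane molecular-dynamics
trajectories, built for the kind of question asked of phosphoinositide
binding to ion channels: *which residues does a lipid class occupy, is the
class enriched around the protein, how long do individual lipids reside at
a binding site, and what does binding do to protein mobility?*

It is aimed at people analysing coarse-grained or atomistic membrane
simulations (GRO/PDB structures, XTC/TRR/DCD trajectories) who want the
standard lipid-fingerprinting toolbox as tested, composable library
functions rather than one-off scripts.

## What it computes

* **Contacts and occupancy** — per-frame lipid–residue contacts at a
  minimum-image cutoff (default 0.7 nm, inclusive); occupancy of residue
  *i* by lipid class *c* is the fraction of frames with ≥ 1 contact.
* **Depletion–enrichment index** —
  DEI(c) = [Σ_f n_c,shell / Σ_f n_shell] ÷ [N_c / N], pooled over frames
  and computed within the leaflet(s) the class occupies.  DEI = 1 means
  neither enriched nor depleted.
* **Binding-residue detection** — residues whose occupancy lies strictly
  above the upper Tukey fence Q3 + 1.5×IQR of the per-residue occupancy
  distribution (quartiles by linear interpolation).
* **Binding events** — per lipid, the interval from the first to the last
  frame with ≥ 2 site-residue contacts, bridged by ≥ 1 contact throughout;
  plus strict ≥ k-residue interaction runs, duration thresholds, and joint
  contact-count frequency matrices between two residue groups.
* **Structural metrics** — Kabsch superposition, per-residue RMSF with a
  replicate-level Student's t-test for differential mobility (p < α,
  two-sided, pooled variance), ligand RMSD without re-fitting,
  GROMOS-style neighbour-count pose clustering, headgroup-region contact
  frequencies, and motif–pocket centroid distances.
* **Synthetic membranes** — a generator that plants two-state binding
  kinetics (per-frame bind/unbind probabilities, geometric dwells) in a
  diffusing bilayer around a residue scaffold and records exact bound
  intervals, so every estimator above can be validated against ground
  truth.

## Worked example

Plant a binding site in a synthetic membrane and recover it blind, the
way the fingerprint is meant to be run — three replicates, occupancy
averaged before outlier detection:

```python
import numpy as np
import pandas as pd
from lipsite import (SynthConfig, simulate_membrane, contact_timeline,
                     residue_occupancy, depletion_enrichment,
                     tukey_site_detection, detect_binding_events,
                     site_contact_counts)
from lipsite.contacts import OccupancyTable
from lipsite.fingerprint import aggregate_dei
from lipsite.synth import site_definition

occ_tables, dei_tables, n_events = [], [], 0
for seed in (0, 1, 2):                      # three replicate simulations
    cfg = SynthConfig(rng_seed=seed)        # 20,000 frames at 1 ns spacing
    topo, traj, truth = simulate_membrane(cfg)
    tl = contact_timeline(traj, topo, cutoff=0.7, bead_scope="headgroup")
    occ_tables.append(residue_occupancy(tl, topo, group_by="class"))
    dei_tables.append(depletion_enrichment(traj, topo, shell=0.7))
    counts = site_contact_counts(tl, site_definition(cfg))
    keep = counts.lipid_species == "PIPB"   # the binding species
    counts.counts = counts.counts[keep]
    counts.lipid_ids = counts.lipid_ids[keep]
    counts.lipid_species = counts.lipid_species[keep]
    n_events += len(detect_binding_events(counts))

agg = OccupancyTable.aggregate(occ_tables)
pip = agg[agg["group"] == "PIP"]
series = pd.Series(pip["mean_occupancy"].to_numpy(),
                   index=pip["residue_id"].to_numpy())
det = tukey_site_detection(series)
print("detected binding residues:", det.detected_residues)
print("upper fence (Q3 + 1.5 IQR):", round(det.fence, 3))
print(aggregate_dei(dei_tables).round(3).to_string(index=False))
print("binding events (binding species, 3 replicates):", n_events)
```

Output:

```
detected binding residues: (1, 2, 3, 4)
upper fence (Q3 + 1.5 IQR): 0.068
lipid_class leaflet_scope  mean_dei  se_dei  n
         PA         lower     0.871   0.012  3
         PC   lower+upper     0.891   0.006  3
        PIP         lower     2.197   0.124  3
binding events (binding species, 3 replicates): 102
```

The detector flags exactly the four planted site residues (occupancies
~0.6–0.9 against a ~0.05 background, far above the 0.068 fence).  The
binding species is ~2.2× enriched in the 0.7 nm shell while the
leaflet-matched inert control and the bulk PC background are mildly
depleted — depletion is the arithmetic mirror of another class's
enrichment within the same leaflet pool.  The 102 events are dominated by
brief grazes; their duration distribution has a long tail from genuine
bound dwells (mean 500 ns by construction).

The same pipeline runs from the shell on real files:

```sh
lipsite simulate --config config.yaml --seed 0 --out-dir sim/
lipsite fingerprint --structure sim/structure.gro --trajectory sim/trajectory.xtc \
    --detect-class PIP --out-dir results/
lipsite events --structure sim/structure.gro --trajectory sim/trajectory.xtc \
    --site planted --lipids PIP --out-dir results/
```

Subcommands: `simulate`, `occupancy`, `density`, `fingerprint`, `events`,
`rmsf`, `rmsd`, `cluster`, `regions`, `motif-distance`.  Passing several
`--trajectory` files treats them as replicates and reports mean ±
standard error.  Every run writes a `manifest.json` with the config
snapshot, input checksums and seed.

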