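# Methods

`lipsite` analyses lipid–protein interactions in membrane molecular-dynamics
trajectories: which residues a lipid class occupies, whether a species is
enriched in the annular shell around the protein, how long individual lipids
reside at a designated binding site, and what binding does to protein
mobility and to the conformational ensemble of a bound headgroup.  Because
multi-microsecond membrane trajectories are rarely shipped with a paper, the
package also contains a synthetic membrane generator with planted binding
kinetics, and every statistical claim the package makes is validated
end-to-end against that generator's exact ground truth.

## Contacts and occupancy

A lipid contacts a residue in a frame when the minimum-image distance
between any selected lipid bead and any selected residue bead is **at or
below** the cutoff.  The default cutoff is 0.7 nm, the standard
coarse-grained interaction distance; the boundary is inclusive by
convention (the behaviour at exactly the cutoff must be pinned one way or
the other, and ≤ matches common practice).  Residue beads default to
side-chain beads, because headgroup–side-chain distances are the quantity
of interest for basic-residue coordination; a whole-residue option exists.
Lipid beads default to headgroup beads for headgroup-binding analyses and
can be widened to all beads for whole-lipid fingerprints (the package uses
all beads when computing the fingerprint occupancies, headgroup beads for
site kinetics).

Distances are computed with an exact orthorhombic minimum-image kernel
(coordinates wrapped once into the primary cell, then per-axis
`min(|d|, L−|d|)`); the kernel is verified against brute-force enumeration
of all 27 periodic images.  Triclinic cells are rejected at load time.
Occupancy(residue, class) is the fraction of frames in which **any** lipid
of the class contacts the residue — lipid identity is deliberately ignored,
matching how per-residue fingerprints are drawn.

## Depletion–enrichment index (DEI)

DEI(class) = [Σ_frames n_class_in_shell / Σ_frames n_total_in_shell] ÷
[N_class / N_total].  A lipid is in the shell when any headgroup bead lies
within the shell radius (default 0.7 nm, matching the contact cutoff) of
any protein bead.  Two choices deserve note:

* Counts are **pooled over frames before dividing**, not averaged as
  per-frame ratios.  Per-frame ratios are unstable whenever a frame's shell
  is nearly empty; pooling weights every observation equally.
* Each class is compared against the lipid pool of the **leaflet(s) it
  occupies**.  A species confined to the cytoplasmic leaflet (as
  phosphoinositides are) would otherwise be diluted by the opposite
  leaflet and its DEI would depend on the composition of a monolayer it
  can never visit.

DEI = 1 means neither enriched nor depleted; the index is exactly 1 for a
single-class membrane and invariant under uniform duplication of every
lipid (both properties are tested).

## Binding-residue detection (Tukey fence)

For one lipid class, the per-residue occupancy distribution is summarised
by quartiles and residues **strictly above Q3 + 1.5×IQR** are flagged as
binding residues.  Quartiles use linear interpolation of order statistics;
this convention is pinned in the configuration because the fence value
depends on it.  At least 4 residues are required.

Detection is performed on occupancy **averaged over replicates** (n = 3 in
the validation studies).  This matters: the upper Tukey fence on ~30
approximately normal background values flags a spurious residue in roughly
0.5–1 % of calls *regardless of sampling depth* (the fence is scale-free, so
longer trajectories shrink the noise and the fence together).  Averaging
replicates before detection both normalises the background distribution and
reduces the number of detection calls, which is what makes exact recovery
reproducible; per-seed detection is available but is expected to show
occasional single-residue false positives.

## Binding events and residence times

Two duration definitions coexist, both computed from the per-frame count of
site core residues contacted by each lipid:

* **Strict interaction times**: maximal runs of consecutive frames with
  ≥ k residues contacted (default k = 2).
* **Binding events (bridged)**: within each maximal run of frames with
  ≥ 1 contact, the interval from the first to the last frame with ≥ 2
  contacts.  A dip from 2 contacts to 1 does not terminate an event; a drop
  to 0 does.  This captures a lipid that stays tethered to the site while
  its coordination fluctuates.

Durations are reported as t_last − t_first, a literal reading under which a
single-frame event has duration 0 and is removed by any positive threshold.
When comparing against per-frame kinetic rates the natural estimator is
instead the run length in frames (a K-frame bound interval occupies K
frames and E[K] = 1/p_unbind for geometric dwells); `strict_run_lengths`
provides it, and the kinetic-recovery validation uses it.  The t_last −
t_first convention would converge to 1/p_unbind − 1 frames, a distinction
that matters at fast unbinding rates and is immaterial once durations are
thresholded.

Both detectors are verified exhaustively against O(n²) window-enumeration
oracles on **all** 65,536 length-8 count sequences over {0,1,2,3}.

## Structural metrics

Superposition uses the Kabsch algorithm (SVD with a reflection guard, so
the rotation is always proper); it is cross-checked against an independent
quaternion-based (QCP) fit.  RMSF is computed per alpha-carbon-equivalent
bead after superposing every frame onto the first retained frame on a
configurable alignment selection (default: all protein residues — the
appropriate alignment region is system-dependent and exposed as a
parameter).  RMSF/RMSD are reported in ångströms, the customary unit for
these quantities; all other lengths are nm.

Differential mobility between two simulation arms (e.g. ligand-bound vs
apo) is a per-residue two-sample **pooled-variance Student's t-test** on
replicate RMSF values, two-sided, flagged at α = 0.05.  Welch's correction
is available by flag; no multiple-testing correction is applied by default
(raw p-values are reported, Benjamini–Hochberg can be applied downstream).
The test's type-I error is calibrated in the validation suite: under the
null, the flagged fraction over 1,000 synthetic residues must stay inside
binomial 99 % bounds of α.

Ligand RMSD superposes each frame on the protein selection only and then
measures the ligand against the reference without re-fitting, so genuine
ligand motion survives while rigid-body drift is removed.

Pose clustering is the neighbour-count (GROMOS-style) scheme on the matrix
of pairwise post-superposition RMSDs: repeatedly take the frame with the
most neighbours within the cutoff as a centroid and remove its cluster.
Default cutoffs of 2.5–3 Å are typical for headgroup-pose clustering.  Ties
in neighbour count resolve to the lowest frame index.  The two-stage
recipe (cluster the headgroup, then cluster the coordinating residues
within the top cluster) is expressed as two chained calls rather than a
bespoke operation.

The motif–pocket metric is the per-frame distance between the unweighted
centroid of one motif residue and the joint centroid of its receptor-pocket
residues (unit masses are correct for coarse-grained beads; atomistic
masses would change centroids by little for the residues involved), with a
histogram/density summary for comparing distributions between conditions.

## The synthetic membrane generator

The generator reproduces the statistical structure the analyses assume,
with no physics:

* **Geometry.**  A static ring scaffold of n = 32 single-backbone,
  single-side-chain-bead residues spans a bilayer in a 16 × 16 × 10 nm box
  (the lateral footprint of an enriched-phosphoinositide simulation cell).
  The ring radius is chosen so consecutive side-chain beads are ~0.785 nm
  apart — just above the 0.7 nm cutoff.  Side-chain beads sit in the
  cytoplasmic headgroup plane; leaflet planes are 4 nm apart, so only
  cytoplasmic lipids can reach them.
* **Lipids.**  Lipids are leaflet-confined 2D Gaussian random walks
  (σ_d = 0.1 nm/frame at 1 ns spacing, i.e. D ≈ 5×10⁻³ nm²/ns, the right
  order for coarse-grained lipid diffusion) with periodic x–y boundaries.
  The default composition mimics an enriched-phosphoinositide membrane: a
  PC background in both leaflets plus two 5 % anionic species in the
  cytoplasmic leaflet, one binding ("PIPB") and one inert control ("PIPN")
  with identical diffusion.
* **Binding.**  A contiguous 4-residue block is the planted site.  Anchors
  sit at the midpoints between consecutive site side-chain beads, so a
  tethered lipid (jitter σ_b = 0.08 nm) is ~0.39 nm from exactly the two
  flanking residues — inside the cutoff — and > 1.1 nm from every other
  residue.  An unbound binder within 0.5 nm of a free anchor binds with
  probability p_bind = 0.5 per frame (capacity 1 per anchor, simultaneous
  candidates resolved uniformly at random); a bound lipid unbinds with
  p_unbind = 0.002 per frame, giving geometric dwells with mean 500
  frames.  A lipid released at frame f may not rebind until frame f+1;
  without this exclusion an instant re-capture silently merges ground-truth
  intervals and the realised mean dwell is roughly double the geometric
  law.  Exact bound intervals are recorded as ground truth.
* **Defaults as study conditions.**  20,000 frames at 1 ns spacing, three
  replicate seeds.  These sizes keep every validation study within minutes
  on one CPU while leaving site occupancy (~0.85 per anchor), background
  occupancy (~0.05) and event counts (tens per seed) in regimes with clear
  separations.

What the generator does **not** emulate: excluded volume, inter-lipid
interactions, membrane undulations, leaflet flip-flop, protein
conformational change, or any force field.  Passing the validation studies
therefore demonstrates that the *estimators* are correct and calibrated on
data satisfying their assumptions — not that real membranes satisfy those
assumptions.

A second, purely statistical generator emits site-contact counts from a
hidden two-state telegraph chain (bound states draw counts from {2,3,4},
unbound from {0,1}) and is used for kinetic-recovery checks where the
hidden state is known exactly.

## Numerical and degenerate-input choices

* Inclusive cutoff comparisons are done on squared distances to avoid a
  square-root rounding step at the boundary.
* Kabsch superposition rejects < 3 points and collinear point sets
  (singular-value ratio < 1e−8) rather than returning an arbitrary
  rotation.
* Quartiles of fewer than 4 occupancies, empty selections, bead-count
  mismatches, non-orthorhombic boxes, and trajectories emptied by the
  discard window are all hard errors, not warnings.
* Leaflets are assigned once at frame 0 by a median-z split of headgroup
  beads; flip-flop is out of scope (the source systems are laterally
  stable), and a lipid exactly at the median is left unassigned.
* All randomness flows from a single seed per run; the generator is
  bit-reproducible and the simulate→analyse→CSV path is verified to be
  byte-identical across repeated runs.

## Known limitations

* The DEI has no attached significance test; replicate mean ± SE is
  reported and interpretation is left to the user.
* Event attribution is single-site; competing sites must be analysed as
  separate site definitions.
* Lateral density maps assume a laterally restrained protein (no frame
  alignment by default).
* Per-seed Tukey detection on homogeneous backgrounds has an irreducible
  false-positive floor (see above); use replicate means.
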