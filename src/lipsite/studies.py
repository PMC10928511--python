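"""End-to-end validation studies on synthetic data.

The package is validated against planted ground truth rather than against
unavailable multi-microsecond trajectories.  Each study here runs one
self-contained check at desk scale and returns its metrics as a plain dict;
the test suite asserts on them and ``scripts/acceptance.py`` reports them.

Problem sizes are chosen so every study completes in minutes on one CPU:
exhaustive detector checks use all 4^8 length-8 count sequences; geometry
checks use 1,000 random few-bead systems; kinetic recovery uses 10^5-frame
telegraph chains; the membrane studies use three replicate seeds of the
default 20,000-frame generator system.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (Bead, Residue, Lipid, SystemTopology, Trajectory,
                   write_table)
from .contacts import contact_timeline, residue_occupancy, OccupancyTable
from .fingerprint import depletion_enrichment, aggregate_dei, tukey_site_detection
from .events import (site_contact_counts, detect_binding_events,
                     strict_interaction_times, strict_run_lengths,
                     event_statistics, SiteContactCounts)
from .structure_metrics import rmsf_profile, differential_mobility, cluster_poses
from .synth import (SynthConfig, simulate_membrane, simulate_contact_timeline,
                    event_oracle, strict_run_oracle, site_definition)

__all__ = [
    "event_detector_exhaustive_check",
    "contact_geometry_check",
    "kinetic_recovery_study",
    "site_recovery_study",
    "mutant_surrogate_study",
    "rmsf_calibration_study",
    "clustering_recovery_study",
    "determinism_check",
]


# --------------------------------------------------------------------------
# event detectors vs brute-force window oracles
# --------------------------------------------------------------------------

def event_detector_exhaustive_check(length: int = 8,
                                    alphabet=(0, 1, 2, 3)) -> dict:
    """Compare both event detectors against their O(n^2) window oracles on
    every count sequence of the given length (4^8 = 65,536 by default)."""
    times = np.arange(length, dtype=float)
    lipid_ids = np.array([0])
    species = np.array(["SYN"], dtype=object)
    n_event_mismatch = n_strict_mismatch = n_seq = 0
    for seq in itertools.product(alphabet, repeat=length):
        counts = SiteContactCounts(
            lipid_ids=lipid_ids, lipid_species=species, times=times,
            counts=np.array([seq], dtype=np.int16), n_core_residues=max(alphabet))
        impl = [(e.start_frame, e.end_frame)
                for e in detect_binding_events(counts)]
        orac = [(e.start_frame, e.end_frame) for e in event_oracle(counts)]
        if impl != orac:
            n_event_mismatch += 1
        if strict_interaction_times(counts) != strict_run_oracle(counts):
            n_strict_mismatch += 1
        n_seq += 1
    return {"n_sequences": n_seq,
            "event_detector_mismatches": n_event_mismatch,
            "strict_run_mismatches": n_strict_mismatch}


# --------------------------------------------------------------------------
# contact geometry vs 27-image brute force
# --------------------------------------------------------------------------

def _toy_system(rng):
    """A random <=5-bead system (1-2 residues, 1-2 lipids, 1-2 beads each)
    in a random orthorhombic box, over 1-3 frames."""
    box = rng.uniform(2.0, 12.0, 3)
    n_res = int(rng.integers(1, 3))
    n_lip = int(rng.integers(1, 3))
    res_beads = [int(rng.integers(1, 3)) for _ in range(n_res)]
    lip_beads = [int(rng.integers(1, 3)) for _ in range(n_lip)]
    while sum(res_beads) + sum(lip_beads) > 5:
        res_beads, lip_beads = [1] * n_res, [1] * n_lip
    residues, idx = [], 0
    for i in range(n_res):
        beads = tuple(Bead(idx + k, f"SC{k + 1}", "sidechain")
                      for k in range(res_beads[i]))
        residues.append(Residue(residue_id=i + 1, name="LEU", beads=beads))
        idx += res_beads[i]
    lipids = []
    for j in range(n_lip):
        b = tuple(range(idx, idx + lip_beads[j]))
        lipids.append(Lipid(lipid_id=n_res + j + 1, species="L",
                            headgroup_bead_indices=b[:1], all_bead_indices=b,
                            leaflet="lower", resname="L"))
        idx += lip_beads[j]
    topo = SystemTopology(residues=residues, lipids=lipids,
                          species_to_class={"L": "L"},
                          bead_names=tuple("B" for _ in range(idx)))
    n_frames = int(rng.integers(1, 4))
    coords = rng.uniform(0.0, 1.0, (n_frames, idx, 3)) * box
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      coordinates=coords,
                      box=np.tile(box, (n_frames, 1)))
    return topo, traj, box


def _brute_force_indicator(topo, traj, cutoff):
    """Exhaustive all-bead-pairs, all-27-images contact indicator."""
    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3)))
    n_lip, n_res = len(topo.lipids), len(topo.residues)
    ind = np.zeros((n_lip, n_res, traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        box = traj.box[f]
        for li, lip in enumerate(topo.lipids):
            for ri, res in enumerate(topo.residues):
                best = np.inf
                for lb in lip.all_bead_indices:
                    for rb in res.bead_indices:
                        delta = (traj.coordinates[f, lb]
                                 - traj.coordinates[f, rb])
                        for s in shifts:
                            d = np.linalg.norm(delta + s * box)
                            best = min(best, d)
                ind[li, ri, f] = best <= cutoff
    return ind


def contact_geometry_check(n_systems: int = 1000, seed: int = 0) -> dict:
    """Contact indicators from the production kernel vs the brute-force
    27-image enumeration, on random few-bead systems."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_systems):
        topo, traj, box = _toy_system(rng)
        cutoff = float(rng.uniform(0.3, 4.0))
        tl = contact_timeline(traj, topo, cutoff=cutoff, bead_scope="all",
                              residue_bead_scope="all")
        if not np.array_equal(tl.indicator_dense(),
                              _brute_force_indicator(topo, traj, cutoff)):
            mismatches += 1
    return {"n_systems": n_systems, "indicator_mismatches": mismatches}


# --------------------------------------------------------------------------
# kinetic parameter recovery from telegraph timelines
# --------------------------------------------------------------------------

def kinetic_recovery_study(p_unbinds=(0.2, 0.05, 0.01), p_bind: float = 0.5,
                           n_frames: int = 100000, seed: int = 0) -> list[dict]:
    """Recover per-frame unbinding rates and stationary occupancy from
    emitted contact counts.

    Residence is estimated as the strict-run length in frames (a K-frame
    bound interval occupies K frames), whose mean obeys the geometric law
    1/p_unbind; stationary occupancy is compared with p_bind/(p_bind+p_unbind)
    at 3 standard errors with the effective sample size set by the chain's
    renewal time.
    """
    out = []
    for i, p10 in enumerate(p_unbinds):
        counts, gt = simulate_contact_timeline(
            p_bind, p10, {2: 0.5, 3: 0.3, 4: 0.2}, {0: 0.7, 1: 0.3},
            n_frames=n_frames, seed=seed + i)
        runs = np.array(strict_run_lengths(counts))
        # drop the final run when censored by the end of the timeline
        if counts.counts[0, -1] >= 2 and runs.size:
            runs = runs[:-1]
        mean_dwell = float(runs.mean()) if runs.size else np.nan
        occ = float(np.mean(gt.bound_state[0] >= 0))
        expect_occ = p_bind / (p_bind + p10)
        n_eff = n_frames / (1.0 / p_bind + 1.0 / p10)
        se = float(np.sqrt(expect_occ * (1 - expect_occ) / n_eff))
        out.append({
            "p_unbind": p10,
            "n_runs": int(runs.size),
            "mean_dwell_frames": mean_dwell,
            "expected_dwell_frames": 1.0 / p10,
            "dwell_rel_error": abs(mean_dwell - 1.0 / p10) * p10,
            "occupancy": occ,
            "expected_occupancy": expect_occ,
            "occupancy_se": se,
            "occupancy_within_3se": bool(abs(occ - expect_occ) <= 3 * se),
        })
    return out


# --------------------------------------------------------------------------
# full-membrane site recovery and the mutant surrogate
# --------------------------------------------------------------------------

def _membrane_replicates(seeds, p_bind=None):
    """Run the default generator system for several seeds; returns per-seed
    (config, topology, trajectory, ground truth, timeline, occupancy, dei)."""
    reps = []
    for s in seeds:
        kwargs = {"rng_seed": int(s)}
        if p_bind is not None:
            kwargs["p_bind"] = p_bind
        cfg = SynthConfig(**kwargs)
        topo, traj, gt = simulate_membrane(cfg)
        tl = contact_timeline(traj, topo, cutoff=0.7, bead_scope="headgroup")
        occ = residue_occupancy(tl, topo, group_by="class")
        dei = depletion_enrichment(traj, topo, shell=0.7)
        reps.append((cfg, topo, traj, gt, tl, occ, dei))
    return reps


def _mean_occupancy_series(occ_tables, group):
    agg = OccupancyTable.aggregate(occ_tables)
    sub = agg[agg["group"] == group]
    return pd.Series(sub["mean_occupancy"].to_numpy(),
                     index=sub["residue_id"].to_numpy())


def site_recovery_study(seeds=(0, 1, 2)) -> dict:
    """Plant a binding site, then recover it blind.

    Occupancy is averaged over the replicate seeds before outlier detection
    (the replicate-mean convention used for occupancy fingerprints, n = 3);
    the depletion-enrichment index is aggregated as mean +/- SE over seeds.
    """
    reps = _membrane_replicates(seeds)
    cfg = reps[0][0]
    site = site_definition(cfg)
    binding_class = "PIP"
    occ_tables = [r[5] for r in reps]
    detected = {}
    for cls in sorted({cfg_sp.headgroup_class for cfg_sp in cfg.species}):
        series = _mean_occupancy_series(occ_tables, cls)
        detected[cls] = tukey_site_detection(series).detected_residues
    dei = aggregate_dei([r[6] for r in reps]).set_index("lipid_class")
    evs_per_seed = []
    for (_, topo, _, _, tl, _, _) in reps:
        counts = site_contact_counts(tl, site)
        binder = np.isin(counts.lipid_species.astype(str), ["PIPB"])
        counts.counts = counts.counts[binder]
        counts.lipid_ids = counts.lipid_ids[binder]
        counts.lipid_species = counts.lipid_species[binder]
        evs_per_seed.append(detect_binding_events(counts))
    gt_bound = [float(np.mean(np.any(r[3].bound_state >= 0, axis=0)))
                for r in reps]
    return {
        "seeds": list(seeds),
        "site_residues": tuple(site.core_residues),
        "detected": detected,
        "binding_class": binding_class,
        "dei_binding_mean": float(dei.loc["PIP", "mean_dei"]),
        "dei_binding_se": float(dei.loc["PIP", "se_dei"]),
        "dei_baseline_mean": float(dei.loc["PA", "mean_dei"]),
        "dei_baseline_se": float(dei.loc["PA", "se_dei"]),
        "events_per_seed": [len(e) for e in evs_per_seed],
        "ground_truth_site_bound_fraction": gt_bound,
        "site_occupancy_mean": float(
            _mean_occupancy_series(occ_tables, binding_class)
            .loc[list(site.core_residues)].mean()),
    }


def _analytic_baseline_occupancy(cfg: SynthConfig, species: str,
                                 cutoff: float = 0.7) -> float:
    """Expected residue occupancy by a freely diffusing species: lipids are
    uniform on the leaflet, so P(>=1 of N within the lateral cutoff disc)
    = 1 - (1 - pi c^2 / A)^N (side-chain beads sit in the headgroup plane,
    so the contact zone is a disc of radius = cutoff)."""
    area = cfg.box[0] * cfg.box[1]
    p = np.pi * cutoff ** 2 / area
    n = sum(s.n_lipids for s in cfg.species
            if s.name == species and s.leaflet == "lower")
    return float(1.0 - (1.0 - p) ** n)


def mutant_surrogate_study(seeds=(0, 1, 2),
                           thresholds=(2000.0, 10000.0)) -> dict:
    """Re-run the site-recovery system with binding disabled (p_bind = 0),
    the synthetic analogue of neutralising the binding residues: no event
    survives any positive duration threshold and site occupancy relaxes to
    the analytic free-diffusion baseline."""
    reps = _membrane_replicates(seeds, p_bind=0.0)
    cfg = reps[0][0]
    site = site_definition(cfg)
    n_above = {float(t): 0 for t in thresholds}
    max_duration = 0.0
    for (_, topo, _, _, tl, _, _) in reps:
        counts = site_contact_counts(tl, site)
        binder = np.isin(counts.lipid_species.astype(str), ["PIPB"])
        counts.counts = counts.counts[binder]
        counts.lipid_ids = counts.lipid_ids[binder]
        counts.lipid_species = counts.lipid_species[binder]
        evs = detect_binding_events(counts)
        table, _ = event_statistics(evs, thresholds=sorted(thresholds))
        sub = table[table["species"] == "all"].set_index("threshold_ns")
        for t in thresholds:
            n_above[float(t)] += int(sub.loc[float(t), "n_events"])
        if evs:
            max_duration = max(max_duration, max(e.duration for e in evs))
    per_seed_occ = [
        float(occ.for_group("PIP").loc[list(site.core_residues)].mean())
        for (_, _, _, _, _, occ, _) in reps]
    baseline = _analytic_baseline_occupancy(cfg, "PIPB")
    mean_occ = float(np.mean(per_seed_occ))
    se = float(np.std(per_seed_occ, ddof=1) / np.sqrt(len(per_seed_occ)))
    return {
        "seeds": list(seeds),
        "events_above_thresholds": n_above,
        "max_event_duration_ns": max_duration,
        "site_occupancy_per_seed": per_seed_occ,
        "site_occupancy_mean": mean_occ,
        "site_occupancy_se": se,
        "analytic_baseline_occupancy": baseline,
        "within_3se_of_baseline": bool(abs(mean_occ - baseline) <= 3 * se),
    }


# --------------------------------------------------------------------------
# RMSF differential-mobility calibration
# --------------------------------------------------------------------------

def _jitter_replicate(rng, sigmas_nm, n_frames):
    """One replicate trajectory: n mobile single-bead residues with planted
    per-residue jitter plus 4 static alignment beads."""
    n_res = sigmas_nm.size
    base = np.zeros((n_res + 4, 3))
    base[:n_res] = np.stack([np.arange(n_res) * 0.5,
                             np.zeros(n_res), np.zeros(n_res)], axis=1)
    base[n_res:] = [[0, 5, 0], [5, 5, 0], [0, 5, 5], [5, 5, 5]]
    coords = np.tile(base, (n_frames, 1, 1))
    coords[:, :n_res, :] += rng.normal(
        0.0, 1.0, (n_frames, n_res, 3)) * sigmas_nm[None, :, None]
    residues = [Residue(residue_id=i + 1, name="ALA",
                        beads=(Bead(i, "BB", "backbone"),))
                for i in range(n_res + 4)]
    topo = SystemTopology(residues=residues, lipids=[], species_to_class={},
                          bead_names=tuple("BB" for _ in range(n_res + 4)))
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      coordinates=coords,
                      box=np.tile([50.0, 50.0, 50.0], (n_frames, 1)))
    return topo, traj


def rmsf_calibration_study(n_residues: int = 1000, n_replicates: int = 5,
                           n_frames: int = 200, alpha: float = 0.05,
                           seed: int = 0) -> dict:
    """Type-I-error calibration of the per-residue mobility t-test under the
    null (both arms share each residue's planted jitter scale), plus power
    on one residue shifted by 10 pooled standard deviations."""
    rng = np.random.default_rng(seed)
    sigmas = rng.uniform(0.03, 0.15, n_residues)
    metric = list(range(1, n_residues + 1))
    align = list(range(n_residues + 1, n_residues + 5))

    def arm(tag):
        profs = []
        for r in range(n_replicates):
            topo, traj = _jitter_replicate(rng, sigmas, n_frames)
            profs.append(rmsf_profile(traj, topo, metric_residues=metric,
                                      align_residues=align,
                                      replicate_id=f"{tag}{r}"))
        return profs

    arm_a, arm_b = arm("a"), arm("b")
    null = differential_mobility(arm_a, arm_b, alpha=alpha)
    frac = float(null["significant"].mean())
    bound = 2.576 * np.sqrt(alpha * (1 - alpha) / n_residues)

    # plant a 10-pooled-SD shift on the first residue of arm A
    a0 = np.array([p.rmsf[0] for p in arm_a])
    b0 = np.array([p.rmsf[0] for p in arm_b])
    pooled_sd = np.sqrt((a0.var(ddof=1) + b0.var(ddof=1)) / 2.0)
    for p in arm_a:
        p.rmsf = p.rmsf.copy()
        p.rmsf[0] += 10.0 * pooled_sd
    shifted = differential_mobility(arm_a, arm_b, alpha=alpha)
    return {
        "n_residues": n_residues,
        "alpha": alpha,
        "null_flagged_fraction": frac,
        "binomial_99_bound": float(bound),
        "null_within_bounds": bool(abs(frac - alpha) <= bound),
        "planted_shift_p": float(shifted["p_value"].iloc[0]),
        "planted_shift_flagged": bool(shifted["significant"].iloc[0]),
    }


# --------------------------------------------------------------------------
# pose-clustering recovery
# --------------------------------------------------------------------------

def clustering_recovery_study(seed: int = 0) -> dict:
    """Recover a planted 7/3 pose partition with intra-group spread far
    below and inter-group separation far above the cutoff, plus the two
    degenerate cutoff limits."""
    rng = np.random.default_rng(seed)
    pose_a = rng.uniform(0.0, 5.0, (6, 3))
    pose_b = pose_a + rng.normal(0.0, 4.0, pose_a.shape)
    frames = np.array(
        [pose_a + rng.normal(0, 0.05, pose_a.shape) for _ in range(7)]
        + [pose_b + rng.normal(0, 0.05, pose_b.shape) for _ in range(3)])
    pc = cluster_poses(frames, cutoff=1.0)
    wide = cluster_poses(frames, cutoff=1e9)
    narrow = cluster_poses(frames, cutoff=1e-9)
    return {
        "largest_cluster_size": int(len(pc.clusters[0])),
        "largest_cluster_members": sorted(int(i) for i in pc.clusters[0]),
        "representative_in_major_group": bool(pc.representative < 7),
        "n_clusters_infinite_cutoff": len(wide.clusters),
        "n_clusters_zero_cutoff": len(narrow.clusters),
    }


# --------------------------------------------------------------------------
# determinism
# --------------------------------------------------------------------------

def determinism_check(seed: int = 0) -> dict:
    """Identical config + seed must reproduce byte-identical result tables
    (and bit-identical trajectories)."""
    outputs = []
    coords = []
    for _ in range(2):
        cfg = SynthConfig(n_frames=1500, rng_seed=seed)
        topo, traj, _ = simulate_membrane(cfg)
        tl = contact_timeline(traj, topo, cutoff=0.7)
        occ = residue_occupancy(tl, topo)
        with tempfile.TemporaryDirectory() as td:
            p = Path(td) / "occupancy.csv"
            write_table(occ.data, p)
            outputs.append(p.read_bytes())
        coords.append(traj.coordinates)
    return {
        "tables_identical": outputs[0] == outputs[1],
        "trajectories_identical": bool(np.array_equal(coords[0], coords[1])),
    }
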