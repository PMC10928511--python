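"""Superposition-based structural metrics.

RMSF/RMSD values are reported in angstroms, the customary unit for
atomistic mobility measures; trajectory coordinates (nm) are converted
internally.  Superposition uses the Kabsch algorithm (proper rotation via
SVD with a reflection guard).  Pose clustering follows the neighbour-count
(GROMOS-style) scheme: repeatedly take the frame with most neighbours
within the pairwise-RMSD cutoff as a cluster centroid and remove the
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SystemTopology, Trajectory, ConfigError

__all__ = [
    "kabsch_superpose",
    "rmsf_profile",
    "differential_mobility",
    "ligand_rmsd_series",
    "cluster_poses",
    "region_contact_frequency",
    "motif_pocket_distance",
    "RMSFProfile",
    "PoseClustering",
    "DegenerateGeometryError",
]

NM_TO_ANGSTROM = 10.0


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate for a unique superposition."""


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t, post-fit RMSD) such that
    ``mobile @ R.T + t`` best matches ``reference``.  R is a proper rotation
    (det +1).  RMSD is in the input units.  Requires >= 3 non-collinear
    points in each set.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ConfigError("point sets must share a shape (n, 3)")
    if X.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite coordinates")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - cx, Y - cy
    for pts, label in ((X0, "mobile"), (Y0, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                f"{label} points are collinear; rotation is not unique")
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    fitted = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Y) ** 2, axis=1))))
    return R, t, rmsd


def _metric_bead(residue) -> int:
    """The alpha-carbon-equivalent bead of a residue: its first backbone
    bead, or its first bead when no backbone bead exists."""
    for b in residue.beads:
        if b.role == "backbone":
            return b.index
    return residue.beads[0].index


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (angstrom) for one replicate."""

    residue_ids: np.ndarray
    rmsf: np.ndarray  # angstrom
    replicate_id: str = ""
    metric_selection: str = "backbone beads"
    align_selection: str = "backbone beads"

    def validate(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.rmsf, index=self.residue_ids,
                         name=self.replicate_id or "rmsf")


def rmsf_profile(traj: Trajectory, topo: SystemTopology,
                 metric_residues: Sequence[int] | None = None,
                 align_residues: Sequence[int] | None = None,
                 discard: float = 0.0,
                 replicate_id: str = "") -> RMSFProfile:
    """Per-residue RMSF of alpha-carbon-equivalent beads after rigid
    superposition of each frame onto the first retained frame.

    ``align_residues`` defaults to all protein residues; ``discard`` drops
    frames with time < discard (ns) before the calculation.
    """
    res_all = {int(r.residue_id): r for r in topo.residues}
    metric_ids = ([int(i) for i in metric_residues] if metric_residues is not None
                  else sorted(res_all))
    align_ids = ([int(i) for i in align_residues] if align_residues is not None
                 else sorted(res_all))
    if not metric_ids or not align_ids:
        raise ConfigError("metric and alignment selections may not be empty")
    for i in metric_ids + align_ids:
        if i not in res_all:
            raise ConfigError(f"residue {i} absent from topology")
    metric_beads = np.array([_metric_bead(res_all[i]) for i in metric_ids])
    align_beads = np.array([_metric_bead(res_all[i]) for i in align_ids])

    keep = np.nonzero(traj.times >= discard)[0]
    if keep.size < 2:
        raise ConfigError("need at least 2 frames after the discard window")
    ref_align = traj.coordinates[keep[0]][align_beads].astype(float)
    aligned = np.empty((keep.size, metric_beads.size, 3))
    for k, f in enumerate(keep):
        R, t, _ = kabsch_superpose(
            traj.coordinates[f][align_beads].astype(float), ref_align)
        aligned[k] = traj.coordinates[f][metric_beads].astype(float) @ R.T + t
    mean_pos = aligned.mean(axis=0)
    rmsf_nm = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    prof = RMSFProfile(
        residue_ids=np.array(metric_ids, dtype=int),
        rmsf=rmsf_nm * NM_TO_ANGSTROM,
        replicate_id=replicate_id,
        metric_selection=f"{len(metric_ids)} residues, backbone beads",
        align_selection=f"{len(align_ids)} residues, backbone beads")
    prof.validate()
    return prof


def differential_mobility(profiles_with: Sequence[RMSFProfile],
                          profiles_without: Sequence[RMSFProfile],
                          alpha: float = 0.05,
                          welch: bool = False) -> pd.DataFrame:
    """Per-residue two-sample t-test of replicate RMSF values between two
    simulation arms (e.g. with and without a bound lipid).

    Uses the classic pooled-variance (Student's) two-sided test by default;
    ``welch=True`` drops the equal-variance assumption.  No multiple-testing
    correction is applied (raw p-values are reported); apply
    Benjamini-Hochberg downstream if desired.

    Returns columns residue_id, mean_with, mean_without, t_stat, p_value,
    significant.
    """
    if len(profiles_with) < 2 or len(profiles_without) < 2:
        raise ConfigError("need >= 2 replicates in each arm")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must lie strictly between 0 and 1")
    ref_ids = profiles_with[0].residue_ids
    for p in list(profiles_with) + list(profiles_without):
        if not np.array_equal(p.residue_ids, ref_ids):
            raise ConfigError("replicate RMSF profiles cover different residues")
    A = np.stack([p.rmsf for p in profiles_with])
    B = np.stack([p.rmsf for p in profiles_without])
    t_stat, p_val = stats.ttest_ind(A, B, axis=0, equal_var=not welch)
    return pd.DataFrame({
        "residue_id": ref_ids,
        "mean_with": A.mean(axis=0),
        "mean_without": B.mean(axis=0),
        "t_stat": t_stat,
        "p_value": p_val,
        "significant": p_val < alpha,
    })


def ligand_rmsd_series(traj: Trajectory,
                       ligand_beads: Sequence[int],
                       align_beads: Sequence[int],
                       reference_frame: int = 0) -> np.ndarray:
    """Per-frame ligand RMSD (angstrom) after superposing each frame onto a
    reference frame using ``align_beads`` (typically the protein); the
    ligand is *not* re-fit, so genuine ligand motion is retained while
    global rigid-body motion is removed."""
    ligand_beads = np.asarray(ligand_beads, dtype=np.intp)
    align_beads = np.asarray(align_beads, dtype=np.intp)
    if ligand_beads.size == 0 or align_beads.size == 0:
        raise ConfigError("ligand and alignment selections may not be empty")
    if ligand_beads.max() >= traj.n_beads or align_beads.max() >= traj.n_beads:
        raise ConfigError("selection indices exceed the trajectory bead count")
    ref_align = traj.coordinates[reference_frame][align_beads].astype(float)
    ref_lig = traj.coordinates[reference_frame][ligand_beads].astype(float)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(
            traj.coordinates[f][align_beads].astype(float), ref_align)
        lig = traj.coordinates[f][ligand_beads].astype(float) @ R.T + t
        out[f] = np.sqrt(np.mean(np.sum((lig - ref_lig) ** 2, axis=1)))
    return out * NM_TO_ANGSTROM


@dataclass
class PoseClustering:
    """Neighbour-count clustering of frames by pairwise RMSD.

    Clusters partition the frame set; the representative is the centroid
    frame of the largest cluster.
    """

    cutoff: float  # angstrom
    clusters: list[np.ndarray]  # member frame indices, first = centroid's cluster order
    centroids: list[int]
    representative: int

    def validate(self) -> None:
        members = np.concatenate(self.clusters) if self.clusters else np.empty(0)
        if len(np.unique(members)) != len(members):
            raise ValueError("clusters must not overlap")
        for c, members_ in zip(self.centroids, self.clusters):
            if c not in members_:
                raise ValueError("centroid must belong to its cluster")


def _pose_coordinates(traj_or_coords, selection=None) -> np.ndarray:
    """Coordinates (n_frames, n_points, 3) in angstrom from a Trajectory plus
    bead selection, or from a raw array already in angstrom."""
    if isinstance(traj_or_coords, Trajectory):
        if selection is None:
            raise ConfigError("a bead selection is required with a Trajectory")
        beads = np.asarray(selection, dtype=np.intp)
        return traj_or_coords.coordinates[:, beads, :].astype(float) * NM_TO_ANGSTROM
    return np.asarray(traj_or_coords, dtype=float)


def pairwise_pose_rmsd(coords: np.ndarray, superpose: bool = True) -> np.ndarray:
    """Symmetric matrix of pairwise RMSDs between frames, after optimal
    superposition when possible (>= 3 points), else direct RMSD."""
    n = coords.shape[0]
    mat = np.zeros((n, n))
    fit = superpose and coords.shape[1] >= 3
    for i in range(n):
        for j in range(i + 1, n):
            if fit:
                try:
                    _, _, r = kabsch_superpose(coords[j], coords[i])
                except DegenerateGeometryError:
                    r = float(np.sqrt(np.mean(
                        np.sum((coords[j] - coords[i]) ** 2, axis=1))))
            else:
                r = float(np.sqrt(np.mean(
                    np.sum((coords[j] - coords[i]) ** 2, axis=1))))
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_poses(traj_or_coords, selection=None, cutoff: float = 3.0,
                  superpose: bool = True) -> PoseClustering:
    """GROMOS-style neighbour-count clustering at a pairwise-RMSD cutoff
    (angstrom).

    Accepts a :class:`Trajectory` plus bead selection (coordinates converted
    from nm) or a raw (n_frames, n_points, 3) array already in angstrom.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    coords = _pose_coordinates(traj_or_coords, selection)
    n = coords.shape[0]
    if n < 1:
        raise ConfigError("need at least one frame to cluster")
    rmsd = pairwise_pose_rmsd(coords, superpose=superpose)
    neighbour = rmsd <= cutoff
    np.fill_diagonal(neighbour, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[np.ndarray] = []
    centroids: list[int] = []
    while remaining.any():
        counts = (neighbour & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        c = int(np.argmax(counts))  # ties: lowest frame index
        members = np.nonzero(neighbour[c] & remaining)[0]
        clusters.append(members)
        centroids.append(c)
        remaining[members] = False
    order = np.argsort([-len(m) for m in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    centroids = [centroids[i] for i in order]
    out = PoseClustering(cutoff=float(cutoff), clusters=clusters,
                         centroids=centroids, representative=centroids[0])
    out.validate()
    return out


def region_contact_frequency(traj: Trajectory, topo: SystemTopology,
                             regions: Mapping[str, Sequence[int]],
                             residues: Sequence[int],
                             cutoff: float = 0.45) -> pd.DataFrame:
    """Fraction of frames in which each residue's side-chain beads lie within
    ``cutoff`` nm (minimum image) of each named headgroup region (e.g. the
    4'-phosphate, 5'-phosphate and linking phosphate bead sets).

    Returns columns residue_id, region, fraction.
    """
    if not regions:
        raise ConfigError("regions mapping may not be empty")
    if not len(residues):
        raise ConfigError("residue selection may not be empty")
    for name, beads in regions.items():
        if not len(beads):
            raise ConfigError(f"region {name!r} has no beads")
    res_objs = [topo.residue_by_id(int(i)) for i in residues]
    cut2 = float(cutoff) ** 2
    rows = []
    for name, beads in regions.items():
        beads = np.asarray(beads, dtype=np.intp)
        for r in res_objs:
            rb = np.asarray(r.sidechain_bead_indices(), dtype=np.intp)
            P = traj.coordinates[:, beads, :].astype(float)
            Q = traj.coordinates[:, rb, :].astype(float)
            box = traj.box[:, None, None, :]
            delta = P[:, :, None, :] - Q[:, None, :, :]
            delta -= box * np.round(delta / box)
            d2 = np.einsum("fijk,fijk->fij", delta, delta).min(axis=(1, 2))
            rows.append((r.residue_id, name, float(np.mean(d2 <= cut2))))
    return pd.DataFrame(rows, columns=["residue_id", "region", "fraction"])


def aggregate_region_frequency(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- standard error of region contact fractions over replicates."""
    if not tables:
        raise ValueError("no tables to aggregate")
    stacked = pd.concat(tables, ignore_index=True)
    g = stacked.groupby(["residue_id", "region"])["fraction"]
    out = g.mean().rename("mean_fraction").reset_index()
    n = len(tables)
    if n > 1:
        out["se_fraction"] = g.agg(lambda v: v.std(ddof=1) / np.sqrt(len(v))).to_numpy()
    else:
        out["se_fraction"] = 0.0
    out["n"] = n
    return out


def motif_pocket_distance(traj: Trajectory, topo: SystemTopology,
                          motif_residue: int,
                          pocket_residues: Sequence[int],
                          bins: int | Sequence[float] = 50
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Distance (nm) between the centroid of a motif residue and the joint
    centroid of its receptor-pocket residues, per frame, with a histogram
    summary.

    Beads carry unit mass (appropriate for coarse-grained beads).  Returns
    (per-frame distances, histogram table with bin_lo/bin_hi/density).
    """
    motif = topo.residue_by_id(int(motif_residue))
    if not len(pocket_residues):
        raise ConfigError("pocket selection may not be empty")
    pocket = [topo.residue_by_id(int(i)) for i in pocket_residues]
    m_beads = np.asarray(motif.bead_indices, dtype=np.intp)
    p_beads = np.concatenate([np.asarray(r.bead_indices, dtype=np.intp)
                              for r in pocket])
    m_cent = traj.coordinates[:, m_beads, :].astype(float).mean(axis=1)
    p_cent = traj.coordinates[:, p_beads, :].astype(float).mean(axis=1)
    dist = np.sqrt(np.sum((m_cent - p_cent) ** 2, axis=1))
    hist, edges = np.histogram(dist, bins=bins, density=True)
    table = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                          "density": hist})
    return dist, table
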