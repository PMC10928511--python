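"""Distance geometry and contact detection.

A lipid is "in contact" with a residue in a frame when the minimum-image
distance between any selected lipid bead and any selected residue bead is
at or below the cutoff (inclusive; default 0.7 nm).  Residue beads default
to side-chain beads, matching the convention of measuring lipid headgroup
to side-chain bead distances in coarse-grained models.

The contact timeline is stored sparsely as (lipid, residue, frame) triples;
minimum distances can optionally be stored densely for small selections
(e.g. to reproduce per-event minimum-distance traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SystemTopology, Trajectory, ConfigError

__all__ = [
    "min_image_distance",
    "contact_timeline",
    "residue_occupancy",
    "lateral_density_map",
    "ContactTimeline",
    "OccupancyTable",
    "DensityMap",
]


def min_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Reduce displacement vectors to their minimum periodic image
    (orthorhombic box)."""
    return delta - box * np.round(delta / box)


def min_image_distance(a, b, box) -> float:
    """Minimum-image Euclidean distance between two points in an orthorhombic
    box (all in nm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b)) and
            np.all(np.isfinite(box))):
        raise ValueError("non-finite input to min_image_distance")
    if not np.all(box > 0):
        raise ValueError("box edge lengths must be positive")
    d = min_image_displacement(a - b, box)
    return float(np.sqrt(np.sum(d * d)))


def _min_image_d2(P: np.ndarray, Q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Squared minimum-image distances between two bead sets over a frame
    chunk: P (c, n, 3), Q (c, m, 3), box (c, 3) -> (c, n, m).

    Coordinates are wrapped into the primary cell once, after which the
    per-axis minimum image is min(|d|, L - |d|); cheaper than the
    divide-and-round form on large arrays and exact for orthorhombic cells.
    """
    box = box.astype(P.dtype, copy=False)
    d2 = None
    for k in range(3):
        L = box[:, k]
        p = np.mod(P[:, :, k], L[:, None])
        q = np.mod(Q[:, :, k], L[:, None])
        delta = np.abs(p[:, :, None] - q[:, None, :])
        np.minimum(delta, L[:, None, None] - delta, out=delta)
        delta *= delta
        if d2 is None:
            d2 = delta
        else:
            d2 += delta
    return d2


def _grouped_bead_arrays(groups: Sequence[Sequence[int]]):
    """Concatenate per-group bead index lists; return (flat indices, group
    start offsets) for use with ``np.minimum.reduceat``."""
    starts = np.zeros(len(groups), dtype=np.intp)
    flat: list[int] = []
    for gi, g in enumerate(groups):
        starts[gi] = len(flat)
        flat.extend(g)
    return np.asarray(flat, dtype=np.intp), starts


@dataclass
class ContactTimeline:
    """Sparse lipid x residue x frame contact indicators.

    ``frame_idx``/``lipid_idx``/``res_idx`` are parallel arrays listing every
    contact triple.  ``min_distance`` (optional) is dense with shape
    (n_lipids, n_residues, n_frames), in nm.
    """

    lipid_ids: np.ndarray
    lipid_species: np.ndarray
    residue_ids: np.ndarray
    times: np.ndarray
    cutoff: float
    frame_idx: np.ndarray
    lipid_idx: np.ndarray
    res_idx: np.ndarray
    species_to_class: dict[str, str] = field(default_factory=dict)
    min_distance: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def indicator_dense(self) -> np.ndarray:
        """Dense boolean (n_lipids, n_residues, n_frames) indicator array."""
        ind = np.zeros((self.n_lipids, self.n_residues, self.n_frames), dtype=bool)
        ind[self.lipid_idx, self.res_idx, self.frame_idx] = True
        return ind

    def validate(self) -> None:
        if self.min_distance is not None:
            expect = self.min_distance <= self.cutoff
            mismatch = expect != self.indicator_dense()
            # forgive float rounding exactly at the cutoff boundary
            boundary = np.abs(self.min_distance - self.cutoff) < 1e-9
            if np.any(mismatch & ~boundary):
                raise ValueError(
                    "contact indicators inconsistent with stored min distances")


def contact_timeline(traj: Trajectory, topo: SystemTopology,
                     lipid_selection: Iterable[str] | None = None,
                     residue_selection: Iterable[int] | None = None,
                     cutoff: float = 0.7,
                     bead_scope: str = "headgroup",
                     residue_bead_scope: str = "sidechain",
                     store_distances: bool = False) -> ContactTimeline:
    """Detect per-frame lipid-residue contacts at ``cutoff`` (nm, inclusive).

    ``lipid_selection`` filters by species code or headgroup class (None =
    all lipids).  ``bead_scope`` chooses headgroup beads (default, suited to
    headgroup-binding analyses) or all lipid beads (suited to whole-lipid
    fingerprints).  ``residue_bead_scope`` is ``"sidechain"`` (default) or
    ``"all"``.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    if bead_scope not in ("headgroup", "all"):
        raise ConfigError(f"bad bead_scope {bead_scope!r}")
    if residue_bead_scope not in ("sidechain", "all"):
        raise ConfigError(f"bad residue_bead_scope {residue_bead_scope!r}")

    lipids = topo.lipids_matching(lipid_selection)
    if not lipids:
        raise ConfigError("lipid selection is empty")
    if residue_selection is None:
        residues = list(topo.residues)
    else:
        residues = [topo.residue_by_id(int(i)) for i in residue_selection]
    if not residues:
        raise ConfigError("residue selection is empty")

    lip_groups = [
        l.headgroup_bead_indices if bead_scope == "headgroup" else l.all_bead_indices
        for l in lipids]
    res_groups = [
        r.sidechain_bead_indices() if residue_bead_scope == "sidechain"
        else r.bead_indices
        for r in residues]
    lip_flat, lip_starts = _grouped_bead_arrays(lip_groups)
    res_flat, res_starts = _grouped_bead_arrays(res_groups)

    n_frames = traj.n_frames
    n_lip, n_res = len(lipids), len(residues)
    cut2 = float(cutoff) ** 2

    dense = (np.full((n_lip, n_res, n_frames), np.nan)
             if store_distances else None)
    f_list, l_list, r_list = [], [], []

    # frame chunks sized to bound the (chunk, lip_beads, res_beads, 3) temporary
    chunk = max(1, int(4e6 / max(1, len(lip_flat) * len(res_flat))))
    for f0 in range(0, n_frames, chunk):
        f1 = min(n_frames, f0 + chunk)
        P = traj.coordinates[f0:f1][:, lip_flat, :]
        Q = traj.coordinates[f0:f1][:, res_flat, :]
        d2 = _min_image_d2(P, Q, traj.box[f0:f1])
        d2 = np.minimum.reduceat(d2, lip_starts, axis=1)
        d2 = np.minimum.reduceat(d2, res_starts, axis=2)
        if dense is not None:
            dense[:, :, f0:f1] = np.sqrt(d2).transpose(1, 2, 0)
        ff, ll, rr = np.nonzero(d2 <= cut2)
        f_list.append(ff + f0)
        l_list.append(ll)
        r_list.append(rr)

    tl = ContactTimeline(
        lipid_ids=np.array([l.lipid_id for l in lipids], dtype=int),
        lipid_species=np.array([l.species for l in lipids], dtype=object),
        residue_ids=np.array([r.residue_id for r in residues], dtype=int),
        times=np.asarray(traj.times, dtype=float),
        cutoff=float(cutoff),
        frame_idx=np.concatenate(f_list).astype(np.int64),
        lipid_idx=np.concatenate(l_list).astype(np.int64),
        res_idx=np.concatenate(r_list).astype(np.int64),
        species_to_class=dict(topo.species_to_class),
        min_distance=dense)
    return tl


@dataclass
class OccupancyTable:
    """Per-residue occupancy fractions for lipid groups.

    ``data`` has columns ``residue_id``, ``group``, ``occupancy``; occupancy
    is the fraction of frames in which at least one lipid of the group
    contacts the residue.
    """

    data: pd.DataFrame

    def for_group(self, group: str) -> pd.Series:
        sub = self.data[self.data["group"] == group]
        return pd.Series(sub["occupancy"].to_numpy(),
                         index=sub["residue_id"].to_numpy(), name=group)

    def validate(self) -> None:
        occ = self.data["occupancy"].to_numpy()
        if np.any(occ < 0) or np.any(occ > 1):
            raise ValueError("occupancy fractions must lie in [0, 1]")

    @staticmethod
    def aggregate(tables: Sequence["OccupancyTable"]) -> pd.DataFrame:
        """Mean and standard error of occupancy across replicate tables.

        Columns: residue_id, group, mean_occupancy, se_occupancy, n.
        The SE of a single replicate is 0.
        """
        if not tables:
            raise ValueError("no occupancy tables to aggregate")
        stacked = pd.concat([t.data for t in tables], ignore_index=True)
        g = stacked.groupby(["residue_id", "group"])["occupancy"]
        n = len(tables)
        out = g.agg(mean_occupancy="mean").reset_index()
        if n > 1:
            out["se_occupancy"] = g.agg(lambda v: v.std(ddof=1) / np.sqrt(len(v))).to_numpy()
        else:
            out["se_occupancy"] = 0.0
        out["n"] = n
        return out


def residue_occupancy(timeline: ContactTimeline,
                      topo: SystemTopology | None = None,
                      group_by: str = "class") -> OccupancyTable:
    """Per-residue occupancy by lipid species or headgroup class.

    Occupancy(residue, group) is the fraction of frames with >= 1 lipid of
    the group in contact with the residue (lipid identity is ignored).
    """
    if group_by not in ("species", "class"):
        raise ConfigError(f"bad group_by {group_by!r}")
    if timeline.n_frames == 0:
        raise ValueError("timeline has no frames")
    class_map = (topo.species_to_class if topo is not None
                 else timeline.species_to_class)
    if group_by == "class":
        lip_groups = np.array([class_map[s] for s in timeline.lipid_species],
                              dtype=object)
    else:
        lip_groups = timeline.lipid_species
    groups = sorted(set(lip_groups))
    n_frames = timeline.n_frames
    rows = []
    for g in groups:
        in_g = np.isin(timeline.lipid_idx,
                       np.nonzero(lip_groups == g)[0])
        # distinct (residue, frame) pairs with >=1 contacting group lipid
        key = (timeline.res_idx[in_g].astype(np.int64) * n_frames
               + timeline.frame_idx[in_g])
        res_of_pair = np.unique(key) // n_frames
        counts = np.bincount(res_of_pair, minlength=timeline.n_residues)
        for ri, rid in enumerate(timeline.residue_ids):
            rows.append((int(rid), g, counts[ri] / n_frames))
    tab = OccupancyTable(pd.DataFrame(rows, columns=["residue_id", "group",
                                                     "occupancy"]))
    tab.validate()
    return tab


@dataclass
class DensityMap:
    """Leaflet-resolved lateral (x-y) density of selected lipid headgroup
    beads: mean bead count per bin per frame."""

    leaflet: str
    label: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) mean beads per bin per frame

    def to_frame(self) -> pd.DataFrame:
        nx, ny = self.counts.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame({
            "x_lo": self.x_edges[xi.ravel()],
            "x_hi": self.x_edges[xi.ravel() + 1],
            "y_lo": self.y_edges[yi.ravel()],
            "y_hi": self.y_edges[yi.ravel() + 1],
            "mean_count": self.counts.ravel(),
        })


def lateral_density_map(traj: Trajectory, topo: SystemTopology,
                        selection: Iterable[str] | None = None,
                        leaflet: str | None = None,
                        bin_width: float = 0.5) -> DensityMap:
    """Mean headgroup-bead count per x-y bin per frame for a lipid
    species/class selection, optionally restricted to one leaflet.

    The grid is built from the frame-0 box; coordinates are wrapped into the
    primary cell each frame.  No frame alignment is applied (the analyses
    this supports come from simulations with a laterally restrained protein).
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    lx, ly = float(traj.box[0, 0]), float(traj.box[0, 1])
    if bin_width > min(lx, ly):
        raise ConfigError("bin_width exceeds the smallest box edge")
    lipids = topo.lipids_matching(selection)
    if leaflet is not None:
        lipids = [l for l in lipids if l.leaflet == leaflet]
    if not lipids:
        raise ConfigError("density selection is empty")
    beads = np.concatenate([np.asarray(l.headgroup_bead_indices, dtype=np.intp)
                            for l in lipids])
    nx = max(1, int(round(lx / bin_width)))
    ny = max(1, int(round(ly / bin_width)))
    x_edges = np.linspace(0.0, lx, nx + 1)
    y_edges = np.linspace(0.0, ly, ny + 1)
    total = np.zeros((nx, ny))
    for f in range(traj.n_frames):
        xy = traj.coordinates[f][beads, :2].astype(np.float64)
        xy = np.mod(xy, traj.box[f, :2])
        h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges))
        total += h
    label = "all" if selection is None else "+".join(sorted(set(selection)))
    return DensityMap(leaflet=leaflet or "both", label=label,
                      x_edges=x_edges, y_edges=y_edges,
                      counts=total / traj.n_frames)
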