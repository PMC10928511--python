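"""Lipid fingerprinting: depletion-enrichment index and occupancy-outlier
binding-residue detection.

The depletion-enrichment index (DEI) of a headgroup class is the ratio of
its share of the annular shell around the protein to its share of the bulk
membrane.  DEI = 1 means neither enriched nor depleted; shell counts are
pooled over frames before dividing, which keeps the estimate stable when
individual frames have nearly empty shells.  Each class is compared against
the lipids of the leaflet(s) it actually occupies, so that a species
confined to the cytoplasmic leaflet is not diluted by the opposite leaflet.

Binding residues are detected from the per-residue occupancy distribution
of one lipid class using the standard upper Tukey fence
(Q3 + 1.5 x IQR, quartiles by linear interpolation of order statistics):
residues strictly above the fence are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SystemTopology, Trajectory, ConfigError
from .contacts import _min_image_d2

__all__ = [
    "depletion_enrichment",
    "shell_counts",
    "tukey_site_detection",
    "aggregate_dei",
    "SiteDetectionResult",
]


def shell_counts(traj: Trajectory, topo: SystemTopology,
                 shell: float = 0.7) -> tuple[np.ndarray, list]:
    """Per-frame boolean shell membership for every lipid.

    A lipid is in the shell when any of its headgroup beads lies within
    ``shell`` nm (minimum image) of any protein bead.  Returns
    (in_shell (n_frames, n_lipids) bool, lipids list in column order).
    """
    if shell <= 0:
        raise ConfigError("shell radius must be positive")
    lipids = list(topo.lipids)
    if not lipids:
        raise ConfigError("topology contains no lipids")
    prot = topo.protein_bead_indices()
    if prot.size == 0:
        raise ConfigError("topology contains no protein beads")
    head_groups = [np.asarray(l.headgroup_bead_indices, dtype=np.intp)
                   for l in lipids]
    starts = np.zeros(len(head_groups), dtype=np.intp)
    flat: list[int] = []
    for gi, g in enumerate(head_groups):
        starts[gi] = len(flat)
        flat.extend(g.tolist())
    flat = np.asarray(flat, dtype=np.intp)

    n_frames = traj.n_frames
    shell2 = float(shell) ** 2
    in_shell = np.zeros((n_frames, len(lipids)), dtype=bool)
    chunk = max(1, int(4e6 / max(1, len(flat) * len(prot))))
    for f0 in range(0, n_frames, chunk):
        f1 = min(n_frames, f0 + chunk)
        P = traj.coordinates[f0:f1][:, flat, :]
        Q = traj.coordinates[f0:f1][:, prot, :]
        d2 = _min_image_d2(P, Q, traj.box[f0:f1]).min(axis=2)
        d2 = np.minimum.reduceat(d2, starts, axis=1)
        in_shell[f0:f1] = d2 <= shell2
    return in_shell, lipids


def depletion_enrichment(traj: Trajectory, topo: SystemTopology,
                         shell: float = 0.7) -> pd.DataFrame:
    """Depletion-enrichment index per headgroup class.

    DEI(class) = [sum_frames n_class_in_shell / sum_frames n_total_in_shell]
    / [N_class / N_total], with both shell and bulk counts restricted to the
    leaflet(s) in which the class resides.

    Returns a table with columns ``lipid_class``, ``leaflet_scope``, ``dei``,
    ``shell_count``, ``bulk_fraction``.
    """
    in_shell, lipids = shell_counts(traj, topo, shell)
    if not in_shell.any():
        raise ConfigError(
            f"no lipid ever entered the {shell} nm shell; use a larger shell")
    classes = np.array([topo.species_to_class[l.species] for l in lipids],
                       dtype=object)
    leaflets = np.array([l.leaflet for l in lipids], dtype=object)
    rows = []
    for cls in sorted(set(classes.tolist())):
        cls_mask = classes == cls
        cls_leaflets = sorted(set(leaflets[cls_mask].tolist()))
        pool = np.isin(leaflets, cls_leaflets)
        n_cls_shell = int(in_shell[:, cls_mask].sum())
        n_pool_shell = int(in_shell[:, pool].sum())
        bulk_frac = cls_mask.sum() / pool.sum()
        if n_pool_shell == 0:
            dei = 0.0
        else:
            dei = (n_cls_shell / n_pool_shell) / bulk_frac
        rows.append((cls, "+".join(cls_leaflets), dei, n_cls_shell,
                     float(bulk_frac)))
    return pd.DataFrame(rows, columns=["lipid_class", "leaflet_scope", "dei",
                                       "shell_count", "bulk_fraction"])


def aggregate_dei(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean and standard error of DEI across replicate tables.

    Columns: lipid_class, leaflet_scope, mean_dei, se_dei, n.
    """
    if not tables:
        raise ValueError("no DEI tables to aggregate")
    stacked = pd.concat(tables, ignore_index=True)
    g = stacked.groupby(["lipid_class", "leaflet_scope"])["dei"]
    out = g.mean().rename("mean_dei").reset_index()
    n = len(tables)
    if n > 1:
        out["se_dei"] = g.agg(lambda v: v.std(ddof=1) / np.sqrt(len(v))).to_numpy()
    else:
        out["se_dei"] = 0.0
    out["n"] = n
    return out


@dataclass(frozen=True)
class SiteDetectionResult:
    """Occupancy-distribution summary and the residues flagged as binding
    residues (strictly above the upper Tukey fence)."""

    q1: float
    q3: float
    iqr: float
    fence: float
    detected_residues: tuple[int, ...]

    def validate(self) -> None:
        if not np.isclose(self.fence, self.q3 + 1.5 * self.iqr):
            raise ValueError("fence must equal Q3 + 1.5 x IQR")


def tukey_site_detection(occupancies: Mapping[int, float] | pd.Series,
                         quartile_method: str = "linear"
                         ) -> SiteDetectionResult:
    """Flag residues whose occupancy lies strictly above Q3 + 1.5 x IQR.

    ``occupancies`` maps residue id -> occupancy fraction for one lipid
    class.  Quartiles use linear interpolation of order statistics by
    default (the pinned convention; the fence value depends on it).
    Requires at least 4 residues; quartiles of fewer values are unstable.
    """
    if isinstance(occupancies, pd.Series):
        ids = np.asarray(occupancies.index, dtype=int)
        vals = occupancies.to_numpy(dtype=float)
    else:
        ids = np.array(list(occupancies.keys()), dtype=int)
        vals = np.array(list(occupancies.values()), dtype=float)
    if vals.size < 4:
        raise ConfigError(
            f"need >= 4 residue occupancies for quartile-based detection, "
            f"got {vals.size}")
    q1, q3 = np.percentile(vals, [25.0, 75.0], method=quartile_method)
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    detected = tuple(sorted(int(i) for i in ids[vals > fence]))
    res = SiteDetectionResult(float(q1), float(q3), float(iqr), float(fence),
                              detected)
    res.validate()
    return res
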