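"""Binding-event detection and residence-time statistics.

Two related duration definitions coexist and are both provided:

strict interaction times
    the length of each maximal run of consecutive frames in which a lipid
    contacts at least ``min_residues`` (default 2) site residues.

binding events ("bridged")
    the interval from the first to the last frame in which a lipid contacts
    two or more site core residues, provided it keeps contacting at least
    one core residue throughout.  Dips from 2 contacts down to 1 do not end
    an event; a drop to 0 does.

Durations are reported as t_last - t_first, so a single-frame event has
duration 0 and is removed by any positive duration threshold.  Residence
estimated as frames-in-run x frame spacing is available separately
(``strict_run_lengths``) and is the natural estimator when comparing with
per-frame kinetic rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SiteDefinition, ConfigError
from .contacts import ContactTimeline

__all__ = [
    "SiteContactCounts",
    "BindingEvent",
    "CountMatrix",
    "site_contact_counts",
    "strict_interaction_times",
    "strict_run_lengths",
    "detect_binding_events",
    "event_statistics",
    "interaction_count_matrix",
]


@dataclass
class SiteContactCounts:
    """Per lipid, per frame: how many site core residues it contacts."""

    lipid_ids: np.ndarray
    lipid_species: np.ndarray
    times: np.ndarray
    counts: np.ndarray  # (n_lipids, n_frames) small ints
    site_name: str = ""
    n_core_residues: int = 0

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.lipid_ids), len(self.times)):
            raise ValueError("counts shape inconsistent with lipids/times")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if self.n_core_residues and np.any(self.counts > self.n_core_residues):
            raise ValueError("contact count exceeds the number of core residues")


@dataclass(frozen=True)
class BindingEvent:
    """One lipid's detected residence at a site."""

    lipid_id: int
    species: str
    start: float  # ns
    end: float  # ns
    start_frame: int
    end_frame: int
    engaged_residues: tuple[int, ...] = ()

    @property
    def duration(self) -> float:
        return self.end - self.start


def site_contact_counts(timeline: ContactTimeline,
                        site: SiteDefinition) -> SiteContactCounts:
    """Count, per lipid and frame, contacts with the site's core residues."""
    present = {int(r): i for i, r in enumerate(timeline.residue_ids)}
    missing = [r for r in site.core_residues if r not in present]
    if missing:
        raise ConfigError(
            f"site {site.name!r}: residues {missing} missing from the timeline")
    core_cols = np.array([present[r] for r in site.core_residues], dtype=np.int64)
    counts = np.zeros((timeline.n_lipids, timeline.n_frames), dtype=np.int16)
    mask = np.isin(timeline.res_idx, core_cols)
    np.add.at(counts, (timeline.lipid_idx[mask], timeline.frame_idx[mask]), 1)
    out = SiteContactCounts(
        lipid_ids=timeline.lipid_ids, lipid_species=timeline.lipid_species,
        times=timeline.times, counts=counts, site_name=site.name,
        n_core_residues=len(site.core_residues))
    out.validate()
    return out


def _runs(mask: np.ndarray):
    """Start and (inclusive) end indices of maximal True runs in a 1D mask."""
    if mask.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return starts, ends


def strict_interaction_times(counts: SiteContactCounts,
                             min_residues: int = 2) -> list[float]:
    """Durations (ns, t_last - t_first) of maximal runs with
    count >= ``min_residues``, across all lipids."""
    if min_residues < 1:
        raise ConfigError("min_residues must be >= 1")
    times = counts.times
    out: list[float] = []
    for row in counts.counts:
        s, e = _runs(row >= min_residues)
        out.extend((times[e] - times[s]).tolist())
    return out


def strict_run_lengths(counts: SiteContactCounts,
                       min_residues: int = 2) -> list[int]:
    """Frame counts of maximal runs with count >= ``min_residues``
    (residence in frames; multiply by the frame spacing for ns)."""
    if min_residues < 1:
        raise ConfigError("min_residues must be >= 1")
    out: list[int] = []
    for row in counts.counts:
        s, e = _runs(row >= min_residues)
        out.extend((e - s + 1).tolist())
    return out


def detect_binding_events(counts: SiteContactCounts,
                          timeline: ContactTimeline | None = None,
                          site: SiteDefinition | None = None
                          ) -> list[BindingEvent]:
    """Detect binding events: within each maximal run of frames with
    count >= 1, the interval from the first to the last frame with
    count >= 2.  Runs never reaching 2 contacts yield no event.

    When ``timeline`` and ``site`` are given, each event records the union
    of site core residues engaged during its frames.
    """
    times = counts.times
    per_lipid_frames = per_lipid_res = None
    core_col_to_id = {}
    if timeline is not None and site is not None:
        present = {int(r): i for i, r in enumerate(timeline.residue_ids)}
        core_col_to_id = {present[r]: r for r in site.core_residues
                         if r in present}
        core_mask = np.isin(timeline.res_idx, list(core_col_to_id))
        order = np.lexsort((timeline.frame_idx[core_mask],
                            timeline.lipid_idx[core_mask]))
        lip_sorted = timeline.lipid_idx[core_mask][order]
        frames_sorted = timeline.frame_idx[core_mask][order]
        res_sorted = timeline.res_idx[core_mask][order]
        bounds = np.searchsorted(lip_sorted, np.arange(counts.counts.shape[0] + 1))
        per_lipid_frames = [frames_sorted[bounds[k]:bounds[k + 1]]
                            for k in range(counts.counts.shape[0])]
        per_lipid_res = [res_sorted[bounds[k]:bounds[k + 1]]
                         for k in range(counts.counts.shape[0])]

    events: list[BindingEvent] = []
    for li, row in enumerate(counts.counts):
        ge1_starts, ge1_ends = _runs(row >= 1)
        ge2 = row >= 2
        for s, e in zip(ge1_starts, ge1_ends):
            inside = np.nonzero(ge2[s:e + 1])[0]
            if inside.size == 0:
                continue
            i, j = s + inside[0], s + inside[-1]
            engaged: tuple[int, ...] = ()
            if per_lipid_frames is not None:
                fr = per_lipid_frames[li]
                lo, hi = np.searchsorted(fr, [i, j + 1])
                engaged = tuple(sorted(
                    core_col_to_id[c]
                    for c in np.unique(per_lipid_res[li][lo:hi])))
            events.append(BindingEvent(
                lipid_id=int(counts.lipid_ids[li]),
                species=str(counts.lipid_species[li]),
                start=float(times[i]), end=float(times[j]),
                start_frame=int(i), end_frame=int(j),
                engaged_residues=engaged))
    return events


def event_statistics(events: Sequence[BindingEvent],
                     thresholds: Sequence[float] = (2000.0, 10000.0),
                     histogram_bins: int | Sequence[float] = 20
                     ) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Count events with duration strictly greater than each threshold,
    split by species, plus an overall duration histogram.

    Returns (table, (hist_counts, bin_edges)); the table has columns
    ``species``, ``threshold_ns``, ``n_events`` and includes an ``all``
    species row per threshold.
    """
    thresholds = [float(t) for t in thresholds]
    if sorted(thresholds) != thresholds:
        raise ConfigError("thresholds must be sorted ascending")
    durations = np.array([e.duration for e in events], dtype=float)
    species = np.array([e.species for e in events], dtype=object)
    rows = []
    for thr in thresholds:
        rows.append(("all", thr, int(np.sum(durations > thr))))
        for sp in sorted(set(species.tolist())):
            rows.append((sp, thr, int(np.sum(durations[species == sp] > thr))))
    table = pd.DataFrame(rows, columns=["species", "threshold_ns", "n_events"])
    if durations.size:
        hist, edges = np.histogram(durations, bins=histogram_bins)
    else:
        hist, edges = np.zeros(0, dtype=int), np.zeros(1)
    return table, (hist, edges)


@dataclass
class CountMatrix:
    """Joint frequency of (contacts in group A, contacts in group B) over
    binding-event frames; entries sum to 1."""

    matrix: np.ndarray  # (|A|+1, |B|+1)
    group_a: tuple[int, ...]
    group_b: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        na, nb = self.matrix.shape
        ai, bi = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
        return pd.DataFrame({"n_contacts_a": ai.ravel(),
                             "n_contacts_b": bi.ravel(),
                             "frequency": self.matrix.ravel()})

    def validate(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("frequencies must be non-negative")
        if not np.isclose(self.matrix.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")


def interaction_count_matrix(timeline: ContactTimeline,
                             events: Sequence[BindingEvent],
                             group_a: Sequence[int],
                             group_b: Sequence[int]) -> CountMatrix:
    """Joint frequency of per-frame contact counts with two residue groups
    (e.g. a linker vs a voltage-sensor binding site), restricted to frames
    inside binding events and normalised over those frames."""
    if not len(group_a) or not len(group_b):
        raise ConfigError("residue groups may not be empty")
    counts_a = site_contact_counts(
        timeline, SiteDefinition("group_a", tuple(int(i) for i in group_a)))
    counts_b = site_contact_counts(
        timeline, SiteDefinition("group_b", tuple(int(i) for i in group_b)))
    lip_row = {int(l): i for i, l in enumerate(timeline.lipid_ids)}
    matrix = np.zeros((len(group_a) + 1, len(group_b) + 1), dtype=float)
    n_frames_total = 0
    for ev in events:
        li = lip_row.get(ev.lipid_id)
        if li is None:
            raise ConfigError(
                f"event lipid {ev.lipid_id} not present in the timeline")
        sl = slice(ev.start_frame, ev.end_frame + 1)
        a = counts_a.counts[li, sl]
        b = counts_b.counts[li, sl]
        np.add.at(matrix, (a.astype(int), b.astype(int)), 1.0)
        n_frames_total += a.size
    if n_frames_total == 0:
        raise ConfigError("no binding-event frames to tally")
    out = CountMatrix(matrix / n_frames_total,
                      tuple(int(i) for i in group_a),
                      tuple(int(i) for i in group_b))
    out.validate()
    return out
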