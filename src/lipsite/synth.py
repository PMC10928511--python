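"""Synthetic membrane trajectories with planted binding kinetics.

The generator reproduces the statistical structure the analysis pipeline
assumes, without any physics: a static ring-shaped protein scaffold spans a
bilayer whose lipids perform leaflet-confined 2D Gaussian random walks with
periodic x-y boundaries.  A designated contiguous block of scaffold
residues forms a binding site: anchors placed midway between consecutive
site residues capture lipids of the binding species.  An unbound binder
within the capture radius of a free anchor binds with probability
``p_bind`` per frame (each anchor holds at most one lipid; simultaneous
candidates are resolved uniformly at random); a bound lipid is tethered to
its anchor with isotropic jitter and unbinds with probability ``p_unbind``
per frame, giving geometrically distributed dwell times with mean
1/p_unbind frames.  Exact bound intervals are recorded as ground truth.

Geometry is chosen so that a tethered lipid contacts exactly the two
residues flanking its anchor at the 0.7 nm cutoff: the scaffold ring radius
is set so consecutive residues are ~0.79 nm apart, placing each anchor
~0.39 nm from its two flanking side-chain beads and >1.1 nm from all
others.  Side-chain beads sit in the cytoplasmic headgroup plane, so only
cytoplasmic-leaflet lipids can reach them.

A direct two-state telegraph generator of site-contact-count timelines and
brute-force O(n^2) window oracles for the event detectors are also provided
for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import (Bead, Residue, Lipid, SystemTopology, Trajectory,
                   SiteDefinition, ConfigError)
from .events import BindingEvent, SiteContactCounts

__all__ = [
    "SpeciesSpec",
    "SynthConfig",
    "SynthGroundTruth",
    "simulate_membrane",
    "simulate_contact_timeline",
    "event_oracle",
    "strict_run_oracle",
    "default_roles_config",
]

#: per-lipid area floor (nm^2) used for the overcrowding check
_MIN_AREA_PER_LIPID = 0.4


@dataclass(frozen=True)
class SpeciesSpec:
    """One lipid population: species code, copy number, leaflet, headgroup
    class and whether it participates in site binding."""

    name: str
    n_lipids: int
    leaflet: str  # "upper" | "lower"
    headgroup_class: str
    binds: bool = False


def _default_species() -> tuple[SpeciesSpec, ...]:
    # Mimics a phosphoinositide-enriched bilayer: a bulk PC background in
    # both leaflets and two minority anionic species (~5% each) confined to
    # the cytoplasmic (lower) leaflet, one of which binds the site.
    return (
        SpeciesSpec("POPC", 180, "lower", "PC"),
        SpeciesSpec("POPC", 200, "upper", "PC"),
        SpeciesSpec("PIPB", 10, "lower", "PIP", binds=True),
        SpeciesSpec("PIPN", 10, "lower", "PA"),
    )


@dataclass
class SynthConfig:
    """Generator parameters (lengths nm, times ns, probabilities per frame).

    Defaults give a 16 x 16 nm bilayer (matching the footprint of an
    enriched-phosphoinositide simulation box) sampled for 20 us at 1 ns
    spacing, a 32-residue scaffold ring with a 4-residue planted site, and
    binding kinetics with a mean bound dwell of 1/p_unbind = 500 frames.
    """

    box: tuple[float, float, float] = (16.0, 16.0, 10.0)
    n_frames: int = 20000
    frame_spacing: float = 1.0  # ns
    n_protein_residues: int = 32
    ring_radius: float | None = None  # default: residue spacing 0.785 nm
    site_residues: tuple[int, ...] = (1, 2, 3, 4)
    capture_radius: float = 0.5
    p_bind: float = 0.5
    p_unbind: float = 0.002
    diffusion_step: float = 0.1  # nm / frame, per axis
    bound_jitter: float = 0.08  # nm, tether jitter per axis
    protein_jitter: float = 0.0  # nm; 0 = static scaffold
    species: tuple[SpeciesSpec, ...] = field(default_factory=_default_species)
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_bind <= 1.0 and 0.0 <= self.p_unbind <= 1.0):
            raise ConfigError("binding probabilities must lie in [0, 1]")
        for name in ("capture_radius", "diffusion_step", "bound_jitter",
                     "frame_spacing"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(e <= 0 for e in self.box):
            raise ConfigError("box edges must be positive")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        site = set(self.site_residues)
        if not site <= set(range(1, self.n_protein_residues + 1)):
            raise ConfigError("site residues must belong to the scaffold")
        if len(self.site_residues) < 2:
            raise ConfigError("the site needs >= 2 residues to place anchors")
        area = self.box[0] * self.box[1]
        for leaf in ("upper", "lower"):
            n = sum(s.n_lipids for s in self.species if s.leaflet == leaf)
            if n * _MIN_AREA_PER_LIPID > area:
                raise ConfigError(
                    f"{n} lipids exceed the placeable area of the {leaf} leaflet")


@dataclass
class SynthGroundTruth:
    """Exact planted bound intervals and the generator parameters.

    ``intervals`` maps lipid id -> list of (start_ns, end_ns, start_frame,
    end_frame, anchor).  ``mean_dwell_frames`` is the analytic mean bound
    dwell (1/p_unbind); ``stationary_bound_probability`` is the two-state
    stationary law p_bind/(p_bind+p_unbind) and applies to the telegraph
    generator (for the spatial generator the on-rate is encounter-limited).
    """

    intervals: dict[int, list[tuple[float, float, int, int, int]]]
    parameters: dict
    mean_dwell_frames: float
    stationary_bound_probability: float | None = None
    bound_state: np.ndarray | None = None  # (n_binders, n_frames) anchor or -1
    binder_lipid_ids: np.ndarray | None = None
    n_frames: int = 0
    frame_spacing: float = 1.0

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def true_dwells_frames(self) -> np.ndarray:
        """Frame counts of all completed (not censored) bound intervals."""
        out = []
        for ivs in self.intervals.values():
            for (_, _, f0, f1, _) in ivs:
                if f1 < self.n_frames - 1:  # exclude intervals cut by the end
                    out.append(f1 - f0 + 1)
        return np.array(out, dtype=int)

    def anchor_bound_fraction(self) -> np.ndarray:
        """Fraction of frames each anchor is occupied."""
        if self.bound_state is None:
            raise ValueError("no bound-state record available")
        n_anchors = int(self.parameters.get("n_anchors", 0))
        out = np.zeros(n_anchors)
        for a in range(n_anchors):
            out[a] = np.mean(np.any(self.bound_state == a, axis=0))
        return out


def _scaffold_geometry(cfg: SynthConfig):
    """Ring positions for scaffold residues and site anchor points."""
    n = cfg.n_protein_residues
    radius = (cfg.ring_radius if cfg.ring_radius is not None
              else 0.785 * n / (2.0 * np.pi))
    cx, cy = cfg.box[0] / 2.0, cfg.box[1] / 2.0
    theta = 2.0 * np.pi * np.arange(n) / n
    ring = np.stack([cx + radius * np.cos(theta),
                     cy + radius * np.sin(theta)], axis=1)
    site = sorted(cfg.site_residues)
    anchors = []
    for a, b in zip(site[:-1], site[1:]):
        anchors.append((ring[a - 1] + ring[b - 1]) / 2.0)
    return ring, np.array(anchors)


def default_roles_config() -> dict:
    """Roles/species mapping matching structures written by this generator."""
    return {
        "lipid_species": {"POPC": "POPC", "PIPB": "PIPB", "PIPN": "PIPN"},
        "species_class": {"POPC": "PC", "PIPB": "PIP", "PIPN": "PA"},
        "headgroup_beads": {"POPC": ["PO4"], "PIPB": ["PO4"], "PIPN": ["PO4"]},
    }


def build_topology(cfg: SynthConfig) -> tuple[SystemTopology, np.ndarray,
                                              np.ndarray, np.ndarray]:
    """Construct the scaffold + lipid topology.

    Returns (topology, ring_xy, anchors_xy, z_levels) where z_levels is
    (z_mid, z_lower_head, z_upper_head, z_lower_tail, z_upper_tail).
    """
    ring, anchors = _scaffold_geometry(cfg)
    z_mid = cfg.box[2] / 2.0
    z = (z_mid, z_mid - 2.0, z_mid + 2.0, z_mid - 1.0, z_mid + 1.0)

    residues: list[Residue] = []
    bead_names: list[str] = []
    idx = 0
    site = set(cfg.site_residues)
    for rid in range(1, cfg.n_protein_residues + 1):
        name = "ARG" if rid in site else "LEU"
        beads = (Bead(idx, "BB", "backbone"), Bead(idx + 1, "SC1", "sidechain"))
        bead_names += ["BB", "SC1"]
        residues.append(Residue(
            residue_id=rid, name=name, beads=beads,
            charge_class="basic" if rid in site else "neutral",
            domain_label="site" if rid in site else "scaffold"))
        idx += 2

    lipids: list[Lipid] = []
    species_class: dict[str, str] = {}
    lid = cfg.n_protein_residues
    for spec in cfg.species:
        species_class[spec.name] = spec.headgroup_class
        for _ in range(spec.n_lipids):
            lid += 1
            lipids.append(Lipid(
                lipid_id=lid, species=spec.name,
                headgroup_bead_indices=(idx,),
                all_bead_indices=(idx, idx + 1),
                leaflet=spec.leaflet, resname=spec.name))
            bead_names += ["PO4", "C1"]
            idx += 2

    topo = SystemTopology(residues=residues, lipids=lipids,
                          species_to_class=species_class,
                          bead_names=tuple(bead_names))
    topo.validate()
    return topo, ring, anchors, z


def site_definition(cfg: SynthConfig, name: str = "planted") -> SiteDefinition:
    return SiteDefinition(name, tuple(sorted(cfg.site_residues)))


def simulate_membrane(cfg: SynthConfig
                      ) -> tuple[SystemTopology, Trajectory, SynthGroundTruth]:
    """Generate a topology, trajectory and exact binding ground truth.

    Reproducible: identical config (including seed) gives identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    topo, ring, anchors, z = build_topology(cfg)
    z_mid, z_lo_head, z_hi_head, z_lo_tail, z_hi_tail = z
    box_xy = np.array(cfg.box[:2])
    n_anchors = anchors.shape[0]
    n_frames = cfg.n_frames

    lipids = topo.lipids
    n_lip = len(lipids)
    is_lower = np.array([l.leaflet == "lower" for l in lipids])
    binds = np.array([
        next(s.binds for s in cfg.species if s.name == l.species)
        and l.leaflet == "lower"
        for l in lipids])
    binder_rows = np.nonzero(binds)[0]

    # state
    xy = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box_xy
    bound_anchor = np.full(n_lip, -1, dtype=np.int32)  # -1 = free
    anchor_holder = np.full(n_anchors, -1, dtype=np.int64)

    n_prot_beads = 2 * cfg.n_protein_residues
    n_beads = n_prot_beads + 2 * n_lip
    coords = np.empty((n_frames, n_beads, 3), dtype=np.float32)

    # static scaffold coordinates (optionally jittered per frame below)
    prot = np.empty((n_prot_beads, 3))
    prot[0::2, :2] = ring
    prot[0::2, 2] = z_mid
    prot[1::2, :2] = ring
    prot[1::2, 2] = z_lo_head
    head_z = np.where(is_lower, z_lo_head, z_hi_head)
    tail_z = np.where(is_lower, z_lo_tail, z_hi_tail)
    head_beads = n_prot_beads + 2 * np.arange(n_lip)

    bound_record = np.full((len(binder_rows), n_frames), -1, dtype=np.int8)
    row_of_binder = {int(r): k for k, r in enumerate(binder_rows)}

    for f in range(n_frames):
        # record current state
        if cfg.protein_jitter > 0:
            coords[f, :n_prot_beads] = prot + rng.normal(
                0.0, cfg.protein_jitter, size=prot.shape)
        else:
            coords[f, :n_prot_beads] = prot
        coords[f, head_beads, 0] = xy[:, 0]
        coords[f, head_beads, 1] = xy[:, 1]
        coords[f, head_beads, 2] = head_z
        coords[f, head_beads + 1, 0] = xy[:, 0]
        coords[f, head_beads + 1, 1] = xy[:, 1]
        coords[f, head_beads + 1, 2] = tail_z
        if binder_rows.size:
            bound_record[:, f] = bound_anchor[binder_rows]

        # unbinding; a lipid released this frame may not rebind until the
        # next frame, so bound dwells follow the geometric law exactly
        just_released = np.zeros(n_lip, dtype=bool)
        bound_rows = np.nonzero(bound_anchor >= 0)[0]
        if bound_rows.size and cfg.p_unbind > 0:
            release = bound_rows[rng.random(bound_rows.size) < cfg.p_unbind]
            anchor_holder[bound_anchor[release]] = -1
            bound_anchor[release] = -1
            just_released[release] = True

        # binding attempts: free binders near a free anchor
        if cfg.p_bind > 0 and binder_rows.size:
            eligible = (bound_anchor[binder_rows] < 0) & ~just_released[binder_rows]
            free_binders = binder_rows[eligible]
            free_anchors = np.nonzero(anchor_holder < 0)[0]
            if free_binders.size and free_anchors.size:
                delta = xy[free_binders][:, None, :] - anchors[free_anchors][None, :, :]
                delta -= box_xy * np.round(delta / box_xy)
                d2 = np.sum(delta * delta, axis=2)
                within = d2 <= cfg.capture_radius ** 2
                for ai, a in enumerate(free_anchors):
                    cand = free_binders[within[:, ai]]
                    cand = cand[bound_anchor[cand] < 0]  # not taken this frame
                    if cand.size == 0:
                        continue
                    accept = cand[rng.random(cand.size) < cfg.p_bind]
                    if accept.size == 0:
                        continue
                    chosen = accept[rng.integers(accept.size)] if accept.size > 1 \
                        else accept[0]
                    bound_anchor[chosen] = a
                    anchor_holder[a] = chosen

        # moves
        free = bound_anchor < 0
        steps = rng.normal(0.0, cfg.diffusion_step, size=(n_lip, 2))
        xy[free] += steps[free]
        bound = np.nonzero(~free)[0]
        if bound.size:
            xy[bound] = (anchors[bound_anchor[bound]]
                         + rng.normal(0.0, cfg.bound_jitter, size=(bound.size, 2)))
        np.mod(xy, box_xy, out=xy)

    times = np.arange(n_frames, dtype=float) * cfg.frame_spacing
    traj = Trajectory(times=times, coordinates=coords,
                      box=np.tile(np.array(cfg.box, dtype=float), (n_frames, 1)))
    traj.validate()
    topo.reference_positions = coords[0].astype(float)

    intervals: dict[int, list[tuple[float, float, int, int, int]]] = {}
    for r in binder_rows:
        lid = lipids[r].lipid_id
        ivs = []
        rec = bound_record[row_of_binder[int(r)]]
        f = 0
        while f < n_frames:
            if rec[f] >= 0:
                a = rec[f]
                f0 = f
                while f + 1 < n_frames and rec[f + 1] == a:
                    f += 1
                ivs.append((times[f0], times[f], f0, f, int(a)))
            f += 1
        intervals[int(lid)] = ivs

    params = asdict(cfg)
    params["species"] = [asdict(s) for s in cfg.species]
    params["n_anchors"] = n_anchors
    gt = SynthGroundTruth(
        intervals=intervals, parameters=params,
        mean_dwell_frames=(1.0 / cfg.p_unbind if cfg.p_unbind > 0 else np.inf),
        stationary_bound_probability=None,
        bound_state=bound_record,
        binder_lipid_ids=np.array([lipids[r].lipid_id for r in binder_rows]),
        n_frames=n_frames, frame_spacing=cfg.frame_spacing)
    return topo, traj, gt


# --------------------------------------------------------------------------
# direct contact-count telegraph generator
# --------------------------------------------------------------------------

def simulate_contact_timeline(p01: float, p10: float,
                              bound_count_dist: Sequence[float] | dict,
                              unbound_count_dist: Sequence[float] | dict,
                              n_frames: int, seed: int = 0
                              ) -> tuple[SiteContactCounts, SynthGroundTruth]:
    """Hidden two-state telegraph chain emitting per-frame site contact
    counts.

    ``p01``/``p10`` are the per-frame unbound->bound and bound->unbound
    transition probabilities.  Count distributions are given over
    {2, 3, 4} for the bound state and {0, 1} for the unbound state, either
    as probability sequences aligned with those supports or as
    {count: probability} dicts.  The initial state is drawn from the
    stationary law p01/(p01+p10).
    """
    if not (0.0 <= p01 <= 1.0 and 0.0 <= p10 <= 1.0):
        raise ConfigError("transition probabilities must lie in [0, 1]")

    def _norm(dist, support):
        if isinstance(dist, dict):
            vals = np.array([float(dist.get(s, 0.0)) for s in support])
        else:
            vals = np.asarray(dist, dtype=float)
            if vals.size != len(support):
                raise ConfigError(
                    f"distribution length {vals.size} != support {support}")
        if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
            raise ConfigError("count distribution must be normalised")
        return vals / vals.sum()

    bound_support = (2, 3, 4)
    unbound_support = (0, 1)
    pb = _norm(bound_count_dist, bound_support)
    pu = _norm(unbound_count_dist, unbound_support)

    rng = np.random.default_rng(seed)
    stationary = p01 / (p01 + p10) if (p01 + p10) > 0 else 0.0
    state = np.empty(n_frames, dtype=np.int8)
    s = 1 if rng.random() < stationary else 0
    u = rng.random(n_frames)
    for f in range(n_frames):
        state[f] = s
        if s == 1:
            if u[f] < p10:
                s = 0
        else:
            if u[f] < p01:
                s = 1

    counts = np.empty(n_frames, dtype=np.int16)
    n_bound = int(state.sum())
    counts[state == 1] = rng.choice(bound_support, size=n_bound, p=pb)
    counts[state == 0] = rng.choice(unbound_support, size=n_frames - n_bound, p=pu)

    times = np.arange(n_frames, dtype=float)
    scc = SiteContactCounts(
        lipid_ids=np.array([0]), lipid_species=np.array(["SYN"], dtype=object),
        times=times, counts=counts[None, :], site_name="telegraph",
        n_core_residues=4)
    scc.validate()

    ivs = []
    f = 0
    while f < n_frames:
        if state[f] == 1:
            f0 = f
            while f + 1 < n_frames and state[f + 1] == 1:
                f += 1
            ivs.append((times[f0], times[f], f0, f, 0))
        f += 1
    gt = SynthGroundTruth(
        intervals={0: ivs},
        parameters={"p01": p01, "p10": p10, "n_frames": n_frames, "seed": seed,
                    "n_anchors": 1},
        mean_dwell_frames=(1.0 / p10 if p10 > 0 else np.inf),
        stationary_bound_probability=stationary,
        # anchor index when bound, -1 when free
        bound_state=np.where(state[None, :] == 1, 0, -1).astype(np.int8),
        binder_lipid_ids=np.array([0]), n_frames=n_frames, frame_spacing=1.0)
    return scc, gt


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------

def _oracle_events_1d(c: np.ndarray, times: np.ndarray):
    """Enumerate all (i, j) windows with count>=2 at both ends and count>=1
    throughout, keep the ones not contained in a larger valid window."""
    n = len(c)
    valid = []
    for i in range(n):
        if c[i] < 2:
            continue
        lo = c[i]
        for j in range(i, n):
            lo = min(lo, c[j])
            if lo < 1:
                break
            if c[j] >= 2:
                valid.append((i, j))
    maximal = []
    for (i, j) in valid:
        contained = any((i2 <= i and j <= j2 and (i2, j2) != (i, j))
                        for (i2, j2) in valid)
        if not contained:
            maximal.append((i, j))
    return sorted(maximal)


def event_oracle(counts: SiteContactCounts) -> list[BindingEvent]:
    """O(n^2) reference implementation of binding-event detection by
    exhaustive window enumeration (same output contract as
    :func:`lipsite.events.detect_binding_events`)."""
    events: list[BindingEvent] = []
    for li, row in enumerate(counts.counts):
        for (i, j) in _oracle_events_1d(np.asarray(row), counts.times):
            events.append(BindingEvent(
                lipid_id=int(counts.lipid_ids[li]),
                species=str(counts.lipid_species[li]),
                start=float(counts.times[i]), end=float(counts.times[j]),
                start_frame=i, end_frame=j))
    return events


def strict_run_oracle(counts: SiteContactCounts,
                      min_residues: int = 2) -> list[float]:
    """O(n^2) reference for strict interaction times: maximal windows in
    which every frame has count >= min_residues."""
    out: list[float] = []
    for row in counts.counts:
        c = np.asarray(row)
        n = len(c)
        windows = []
        for i in range(n):
            if c[i] < min_residues:
                continue
            for j in range(i, n):
                if np.all(c[i:j + 1] >= min_residues):
                    windows.append((i, j))
        maximal = [(i, j) for (i, j) in windows
                   if not any(i2 <= i and j <= j2 and (i2, j2) != (i, j)
                              for (i2, j2) in windows)]
        out.extend(float(counts.times[j] - counts.times[i])
                   for (i, j) in sorted(maximal))
    return out
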