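"""Core data model: topology and trajectory containers, file ingestion, table output.

Unit conventions
----------------
Lengths are nanometres and times are nanoseconds everywhere inside the
package.  Structure/trajectory files (which store angstroms and
picoseconds, following the MDAnalysis convention) are converted on load.
Config files may give lengths with an explicit unit tag (``"4.5 A"``,
``"0.7 nm"``); bare numbers are taken as nm.

Residue ids are taken verbatim from the structure file (1-based, matching
published residue numbering), frame indices are 0-based.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

import MDAnalysis as mda

__all__ = [
    "Bead",
    "Residue",
    "Lipid",
    "SystemTopology",
    "Trajectory",
    "AnalysisConfig",
    "SiteDefinition",
    "TopologyError",
    "TrajectoryError",
    "ConfigError",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "parse_length",
    "write_table",
    "write_json",
    "file_checksum",
]


class TopologyError(ValueError):
    """Raised when a structure file or topology violates its contract."""


class TrajectoryError(ValueError):
    """Raised when a trajectory file or trajectory violates its contract."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


#: 3-letter residue names recognised as protein without extra configuration.
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}

_BASIC = {"ARG", "LYS", "HIS", "HSD", "HSE", "HSP"}
_ACIDIC = {"ASP", "GLU"}

BEAD_ROLES = ("backbone", "sidechain", "other")
CHARGE_CLASSES = ("basic", "acidic", "neutral")
LEAFLETS = ("upper", "lower", "unassigned")


@dataclass(frozen=True)
class Bead:
    """One coarse-grained bead (or atom) belonging to a protein residue."""

    index: int
    name: str
    role: str  # one of BEAD_ROLES


@dataclass(frozen=True)
class Residue:
    """A protein residue with its beads, charge class and optional domain label."""

    residue_id: int
    name: str
    beads: tuple[Bead, ...]
    charge_class: str = "neutral"
    domain_label: str = ""

    @property
    def bead_indices(self) -> tuple[int, ...]:
        return tuple(b.index for b in self.beads)

    def sidechain_bead_indices(self) -> tuple[int, ...]:
        """Side-chain beads; falls back to all beads for residues without one
        (e.g. glycine)."""
        sc = tuple(b.index for b in self.beads if b.role == "sidechain")
        return sc if sc else self.bead_indices


@dataclass(frozen=True)
class Lipid:
    """A lipid molecule: species code, bead indices and leaflet assignment."""

    lipid_id: int
    species: str
    headgroup_bead_indices: tuple[int, ...]
    all_bead_indices: tuple[int, ...]
    leaflet: str = "unassigned"
    resname: str = ""


@dataclass
class SystemTopology:
    """Protein residues plus lipid molecules of a simulated membrane system.

    ``species_to_class`` maps each lipid species code to a headgroup class
    (the grouping used for fingerprints, e.g. all phosphoinositide species
    mapping to one PIP class).  ``bead_names`` and ``reference_positions``
    (nm, one frame) retain enough of the source structure to write it back
    out.
    """

    residues: list[Residue]
    lipids: list[Lipid]
    species_to_class: dict[str, str]
    bead_names: tuple[str, ...] = ()
    reference_positions: np.ndarray | None = None  # (n_beads, 3) nm

    # ------------------------------------------------------------------ access
    @property
    def n_beads(self) -> int:
        n = 0
        for r in self.residues:
            n += len(r.beads)
        for l in self.lipids:
            n += len(l.all_bead_indices)
        return n

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([r.residue_id for r in self.residues], dtype=int)

    def residue_by_id(self, residue_id: int) -> Residue:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        raise TopologyError(f"residue id {residue_id} not present in topology")

    def lipid_by_id(self, lipid_id: int) -> Lipid:
        for l in self.lipids:
            if l.lipid_id == lipid_id:
                return l
        raise TopologyError(f"lipid id {lipid_id} not present in topology")

    def protein_bead_indices(self) -> np.ndarray:
        idx: list[int] = []
        for r in self.residues:
            idx.extend(r.bead_indices)
        return np.array(sorted(idx), dtype=int)

    def lipid_class(self, lipid: Lipid) -> str:
        return self.species_to_class[lipid.species]

    def lipids_matching(self, selection: Iterable[str] | None) -> list[Lipid]:
        """Lipids whose species code *or* headgroup class is in ``selection``
        (``None`` selects all lipids)."""
        if selection is None:
            return list(self.lipids)
        wanted = set(selection)
        out = [
            l for l in self.lipids
            if l.species in wanted or self.species_to_class[l.species] in wanted
        ]
        return out

    # ---------------------------------------------------------------- checks
    def validate(self) -> None:
        seen: set[int] = set()
        for r in self.residues:
            if r.residue_id < 1:
                raise TopologyError(f"residue id {r.residue_id} must be >= 1")
            if r.charge_class not in CHARGE_CLASSES:
                raise TopologyError(
                    f"residue {r.residue_id}: bad charge class {r.charge_class!r}")
            for b in r.beads:
                if b.role not in BEAD_ROLES:
                    raise TopologyError(f"bead {b.index}: bad role {b.role!r}")
                if b.index in seen:
                    raise TopologyError(f"bead index {b.index} appears twice")
                seen.add(b.index)
        for l in self.lipids:
            if not l.headgroup_bead_indices:
                raise TopologyError(
                    f"lipid {l.lipid_id} ({l.species}) has no headgroup bead")
            if l.leaflet not in LEAFLETS:
                raise TopologyError(f"lipid {l.lipid_id}: bad leaflet {l.leaflet!r}")
            if l.species not in self.species_to_class:
                raise TopologyError(
                    f"lipid species {l.species!r} has no headgroup class mapping")
            if not set(l.headgroup_bead_indices) <= set(l.all_bead_indices):
                raise TopologyError(
                    f"lipid {l.lipid_id}: headgroup beads not a subset of its beads")
            for i in l.all_bead_indices:
                if i in seen:
                    raise TopologyError(f"bead index {i} appears twice")
                seen.add(i)


@dataclass
class Trajectory:
    """Frame times (ns), coordinates (nm) and per-frame orthorhombic box (nm)."""

    times: np.ndarray  # (n_frames,) ns, strictly increasing
    coordinates: np.ndarray  # (n_frames, n_beads, 3) nm
    box: np.ndarray  # (n_frames, 3) nm edge lengths

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def validate(self) -> None:
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, beads, 3)")
        if self.n_frames < 1:
            raise TrajectoryError("trajectory must contain at least one frame")
        if self.times.shape != (self.n_frames,):
            raise TrajectoryError("times length must equal the frame count")
        if self.box.shape != (self.n_frames, 3):
            raise TrajectoryError("box must have shape (frames, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("coordinates contain non-finite values")
        if not np.all(self.box > 0):
            raise TrajectoryError("box edge lengths must be positive")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def parse_length(value, default_unit: str = "nm") -> float:
    """Parse a length into nm.  Accepts a bare number (interpreted in
    ``default_unit``) or a string with a unit tag: ``"0.7 nm"``, ``"4.5 A"``,
    ``"4.5 angstrom"``."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        x = float(value)
        unit = default_unit
    elif isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            x, unit = float(parts[0]), default_unit
        elif len(parts) == 2:
            x, unit = float(parts[0]), parts[1]
        else:
            raise ConfigError(f"cannot parse length {value!r}")
    else:
        raise ConfigError(f"cannot parse length {value!r}")
    unit = unit.lower()
    if unit in ("nm",):
        return x
    if unit in ("a", "å", "ang", "angstrom", "angstroms"):
        return x / 10.0
    raise ConfigError(f"unknown length unit {unit!r} in {value!r}")


_LENGTH_FIELDS = ("contact_cutoff", "region_contact_cutoff", "dei_shell",
                  "cluster_cutoff")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their published defaults.

    contact_cutoff
        Lipid-residue interaction cutoff, 0.7 nm.
    region_contact_cutoff
        Headgroup-region (phosphate) contact cutoff, 0.45 nm (4.5 A).
    dei_shell
        Annular-shell radius for the depletion-enrichment index; defaults to
        the contact cutoff.
    cluster_cutoff
        Pairwise-RMSD cutoff for pose clustering, 0.25 nm (2.5 A).
    duration_thresholds
        Binding-event duration thresholds in ns (2 and 10 microseconds).
    quartile_method
        Quartile convention used for the occupancy-outlier fence; pinned to
        linear interpolation of order statistics.
    """

    contact_cutoff: float = 0.7
    region_contact_cutoff: float = 0.45
    dei_shell: float = 0.7
    cluster_cutoff: float = 0.25
    stride: int = 1
    discard: float = 0.0
    alpha: float = 0.05
    duration_thresholds: tuple[float, ...] = (2000.0, 10000.0)
    quartile_method: str = "linear"
    rng_seed: int = 0

    def validate(self) -> None:
        for name in _LENGTH_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie strictly between 0 and 1")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.discard < 0:
            raise ConfigError("discard must be >= 0")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        kwargs = {}
        valid = {f for f in cls.__dataclass_fields__}
        for key, val in raw.items():
            if key not in valid:
                raise ConfigError(f"unknown analysis config key {key!r}")
            if key in _LENGTH_FIELDS:
                val = parse_length(val)
            if key == "duration_thresholds":
                val = tuple(float(v) for v in val)
            kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class SiteDefinition:
    """A named binding site: the core residues whose contacts define binding
    events, plus optional auxiliary residue groups (e.g. a flexible linker)."""

    name: str
    core_residues: tuple[int, ...]
    auxiliary_groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.core_residues:
            raise ConfigError(f"site {self.name!r}: core_residues may not be empty")

    def check(self, topology: SystemTopology) -> None:
        present = set(int(i) for i in topology.residue_ids)
        missing = [i for i in self.core_residues if i not in present]
        for grp in self.auxiliary_groups.values():
            missing += [i for i in grp if i not in present]
        if missing:
            raise ConfigError(
                f"site {self.name!r}: residues {sorted(set(missing))} absent from topology")


# --------------------------------------------------------------------------
# structure ingestion
# --------------------------------------------------------------------------

def _bead_role(name: str, overrides: Mapping[str, str]) -> str:
    if name in overrides:
        role = overrides[name]
        if role not in BEAD_ROLES:
            raise ConfigError(f"bad role {role!r} for bead name {name!r}")
        return role
    if name in ("BB", "CA") or name.startswith("BB"):
        return "backbone"
    if name.startswith("SC") or name == "CB":
        return "sidechain"
    return "other"


def _charge_class(resname: str, overrides: Mapping[str, str]) -> str:
    if resname in overrides:
        cc = overrides[resname]
        if cc not in CHARGE_CLASSES:
            raise ConfigError(f"bad charge class {cc!r} for residue {resname!r}")
        return cc
    if resname in _BASIC:
        return "basic"
    if resname in _ACIDIC:
        return "acidic"
    return "neutral"


def load_structure(path, roles_config: Mapping) -> SystemTopology:
    """Read a PDB or GRO structure into a :class:`SystemTopology`.

    ``roles_config`` supplies what cannot be inferred from chemistry:

    ``lipid_species``
        mapping residue name -> lipid species code; any residue whose name is
        here is a lipid, anything else must be a recognised amino acid.
    ``species_class``
        mapping species code -> headgroup class (fingerprint grouping).
    ``headgroup_beads``
        mapping species code -> list of bead/atom names forming the headgroup.
    ``bead_roles`` (optional)
        overrides for protein bead name -> role; defaults recognise
        BB*/CA as backbone and SC*/CB as sidechain.
    ``charge_class`` (optional)
        overrides for residue name -> charge class (built-in: Arg/Lys/His
        basic, Asp/Glu acidic, rest neutral).
    ``protein_resnames`` (optional)
        extra residue names to accept as protein.
    ``domain_labels`` (optional)
        mapping residue id -> free-text domain label.

    Leaflets are assigned at frame 0: a lipid whose first headgroup bead sits
    above the median headgroup z is ``upper``, below is ``lower``.
    """
    p = Path(path)
    if not p.exists() or p.stat().st_size == 0:
        raise TopologyError(f"structure file {p} is missing or empty")
    u = mda.Universe(str(p))

    lipid_species = dict(roles_config.get("lipid_species", {}))
    species_class = dict(roles_config.get("species_class", {}))
    head_beads = {k: set(v) for k, v in roles_config.get("headgroup_beads", {}).items()}
    role_over = dict(roles_config.get("bead_roles", {}))
    charge_over = dict(roles_config.get("charge_class", {}))
    protein_resnames = STANDARD_AMINO_ACIDS | set(roles_config.get("protein_resnames", ()))
    domain_labels = {int(k): v for k, v in roles_config.get("domain_labels", {}).items()}

    residues: list[Residue] = []
    lipids: list[Lipid] = []
    for res in u.residues:
        rn = str(res.resname)
        if rn in lipid_species:
            sp = lipid_species[rn]
            if sp not in species_class:
                raise TopologyError(
                    f"lipid species {sp!r} (residue name {rn!r}) has no headgroup "
                    f"class mapping in roles_config['species_class']")
            names = head_beads.get(sp, set())
            heads = tuple(int(a.ix) for a in res.atoms if a.name in names)
            if not heads:
                raise TopologyError(
                    f"lipid {int(res.resid)} ({sp}): no headgroup beads; declare them "
                    f"in roles_config['headgroup_beads']")
            lipids.append(Lipid(
                lipid_id=int(res.resid), species=sp,
                headgroup_bead_indices=heads,
                all_bead_indices=tuple(int(i) for i in res.atoms.ix),
                resname=rn))
        elif rn in protein_resnames:
            beads = tuple(
                Bead(int(a.ix), str(a.name), _bead_role(str(a.name), role_over))
                for a in res.atoms)
            residues.append(Residue(
                residue_id=int(res.resid), name=rn, beads=beads,
                charge_class=_charge_class(rn, charge_over),
                domain_label=domain_labels.get(int(res.resid), "")))
        else:
            raise TopologyError(
                f"unknown residue name {rn!r} (residue {int(res.resid)}): not a "
                f"recognised amino acid and not mapped in roles_config['lipid_species']")

    positions_nm = u.atoms.positions.astype(float) / 10.0

    # leaflet split at frame 0: median z of all headgroup beads
    if lipids:
        head_z = np.array([positions_nm[l.headgroup_bead_indices[0], 2] for l in lipids])
        median_z = float(np.median(head_z))
        assigned = []
        for l, z in zip(lipids, head_z):
            if z > median_z:
                leaf = "upper"
            elif z < median_z:
                leaf = "lower"
            else:
                leaf = "unassigned"
            assigned.append(replace(l, leaflet=leaf))
        lipids = assigned

    topo = SystemTopology(
        residues=residues, lipids=lipids, species_to_class=species_class,
        bead_names=tuple(str(n) for n in u.atoms.names),
        reference_positions=positions_nm)
    topo.validate()
    return topo


def write_structure(topology: SystemTopology, path,
                    box: Sequence[float] | None = None) -> None:
    """Write the topology (with its reference positions) back to PDB/GRO.

    ``box`` is an optional orthorhombic cell (nm edge lengths).
    """
    if topology.reference_positions is None:
        raise TopologyError("topology has no reference positions to write")
    entries: list[tuple[int, int, str, tuple[int, ...]]] = []
    for r in topology.residues:
        entries.append((min(r.bead_indices), r.residue_id, r.name, r.bead_indices))
    for l in topology.lipids:
        rn = l.resname or l.species
        entries.append((min(l.all_bead_indices), l.lipid_id, rn, l.all_bead_indices))
    entries.sort()

    n_atoms = topology.n_beads
    atom_resindex = np.empty(n_atoms, dtype=int)
    resids, resnames = [], []
    for ri, (_, rid, rname, beads) in enumerate(entries):
        resids.append(rid)
        resnames.append(rname)
        for b in beads:
            atom_resindex[b] = ri

    u = mda.Universe.empty(
        n_atoms, n_residues=len(entries), atom_resindex=atom_resindex,
        trajectory=True)
    u.add_TopologyAttr("names", list(topology.bead_names))
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames)
    u.atoms.positions = np.asarray(topology.reference_positions) * 10.0
    if box is not None:
        b = np.asarray(box, dtype=float) * 10.0
        u.dimensions = [b[0], b[1], b[2], 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


# --------------------------------------------------------------------------
# trajectory ingestion
# --------------------------------------------------------------------------

def load_trajectory(path, topology: SystemTopology, stride: int = 1,
                    discard: float = 0.0) -> Trajectory:
    """Read an XTC/TRR/DCD trajectory, discard early frames and stride.

    Frames with time < ``discard`` (ns) are removed first, then every
    ``stride``-th remaining frame is retained.  Times are preserved from the
    file.  Only orthorhombic boxes are accepted.
    """
    if stride < 1:
        raise TrajectoryError("stride must be >= 1")
    if discard < 0:
        raise TrajectoryError("discard must be >= 0")
    n_expected = topology.n_beads
    u = mda.Universe.empty(n_expected, trajectory=True)
    try:
        u.load_new(str(path))
    except (ValueError, IOError) as exc:
        raise TrajectoryError(
            f"could not read trajectory {path} for a {n_expected}-bead topology "
            f"(bead-count mismatch?): {exc}") from exc
    if u.trajectory.n_atoms != n_expected:
        raise TrajectoryError(
            f"trajectory has {u.trajectory.n_atoms} beads but topology has "
            f"{n_expected}")

    times, coords, boxes = [], [], []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise TrajectoryError(f"frame {ts.frame}: missing box dimensions")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise TrajectoryError(
                f"frame {ts.frame}: triclinic box (angles {dims[3:]}) not supported; "
                f"orthorhombic boxes only")
        times.append(float(ts.time) / 1000.0)  # ps -> ns
        coords.append(ts.positions.astype(np.float64) / 10.0)  # A -> nm
        boxes.append(np.asarray(dims[:3], dtype=float) / 10.0)

    times_arr = np.array(times)
    keep = np.nonzero(times_arr >= discard)[0][::stride]
    if keep.size == 0:
        raise TrajectoryError(
            f"zero frames remain after discarding times < {discard} ns")
    traj = Trajectory(
        times=times_arr[keep],
        coordinates=np.stack([coords[i] for i in keep]),
        box=np.stack([boxes[i] for i in keep]))
    traj.validate()
    return traj


# --------------------------------------------------------------------------
# tabular output
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as CSV with its documented column header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
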