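"""Shared fixtures: programmatic toy membrane systems."""

from __future__ import annotations

import numpy as np
import pytest

from lipsite.core import Bead, Residue, Lipid, SystemTopology, Trajectory


def build_system(res_positions, lipid_frames, box=(10.0, 10.0, 10.0),
                 times=None, species=None, leaflets=None,
                 species_to_class=None):
    """Construct a toy topology + trajectory.

    res_positions: (n_res, 3) static side-chain bead positions (nm).
    lipid_frames: (n_frames, n_lip, 3) per-frame lipid head-bead positions.
    """
    res_positions = np.asarray(res_positions, dtype=float)
    lipid_frames = np.asarray(lipid_frames, dtype=float)
    n_res = res_positions.shape[0]
    n_frames, n_lip, _ = lipid_frames.shape
    species = species or ["LIPA"] * n_lip
    leaflets = leaflets or ["lower"] * n_lip
    if species_to_class is None:
        species_to_class = {s: s for s in set(species)}

    residues = [
        Residue(residue_id=i + 1, name="LEU",
                beads=(Bead(i, "SC1", "sidechain"),))
        for i in range(n_res)]
    lipids = [
        Lipid(lipid_id=n_res + j + 1, species=species[j],
              headgroup_bead_indices=(n_res + j,),
              all_bead_indices=(n_res + j,), leaflet=leaflets[j],
              resname=species[j])
        for j in range(n_lip)]
    topo = SystemTopology(residues=residues, lipids=lipids,
                          species_to_class=dict(species_to_class),
                          bead_names=tuple(["SC1"] * n_res + ["PO4"] * n_lip))
    topo.validate()

    coords = np.empty((n_frames, n_res + n_lip, 3))
    coords[:, :n_res] = res_positions[None, :, :]
    coords[:, n_res:] = lipid_frames
    if times is None:
        times = np.arange(n_frames, dtype=float)
    traj = Trajectory(times=np.asarray(times, dtype=float),
                      coordinates=coords,
                      box=np.tile(np.asarray(box, dtype=float), (n_frames, 1)))
    traj.validate()
    return topo, traj


@pytest.fixture
def toy_system():
    return build_system
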