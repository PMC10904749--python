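"""Periodic-boundary geometry, leaflet assignment, and canonical orientation.

The simulation cell is periodic in x and y; z is treated as non-periodic
for analysis (the water slab separates images along the normal, and the
bilayer midplane defines z = 0). Lower-leaflet analyses mirror z so that
every leaflet is analysed with outward normal +z and positive depths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateBilayerError, TypingError
from .model import LIPID_KINDS, SimulationFrame, Trajectory


def min_image_displacement(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Displacement q - p with x and y wrapped into [-L/2, L/2); z unwrapped.

    Broadcasts over leading dimensions.
    """
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    d = np.atleast_1d(d)
    out = d.copy()
    for ax in (0, 1):
        L = float(box[ax])
        out[..., ax] = d[..., ax] - L * np.floor(d[..., ax] / L + 0.5)
    return out


def lateral_min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance in the xy plane only."""
    d = min_image_displacement(p, q, box)
    return np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)


def phosphorus_index(atoms: pd.DataFrame) -> np.ndarray:
    mask = atoms["molecule_kind"].isin(LIPID_KINDS) & (atoms["element"] == "P")
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) == 0:
        raise TypingError("no lipid phosphorus atoms present")
    return idx


def midplane_z(frame: SimulationFrame, atoms: pd.DataFrame) -> float:
    """Bilayer midplane: mean z of all lipid phosphorus atoms."""
    return float(frame.coordinates[phosphorus_index(atoms), 2].mean())


def center_on_midplane(frame: SimulationFrame, atoms: pd.DataFrame) -> SimulationFrame:
    """Shift z so the phosphorus midplane sits at z = 0."""
    z0 = midplane_z(frame, atoms)
    coords = frame.coordinates.copy()
    coords[:, 2] -= z0
    return SimulationFrame(coords, frame.box, frame.frame_index)


def center_trajectory(traj: Trajectory) -> Trajectory:
    """Center every frame on its own phosphorus midplane (in place on a copy)."""
    pidx = phosphorus_index(traj.atoms)
    coords = traj.coordinates.copy()
    coords[:, :, 2] -= coords[:, pidx, 2].mean(axis=1, keepdims=True)
    out = Trajectory(
        atoms=traj.atoms,
        coordinates=coords,
        boxes=traj.boxes,
        traj_id=traj.traj_id,
        weights=traj.weights,
        temperature=traj.temperature,
        potential_energy=traj.potential_energy,
        excluded=traj.excluded,
    )
    return out


def mass_weighted_com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    m = np.asarray(masses, dtype=float)
    return (coords * m[:, None]).sum(axis=0) / m.sum()


def assign_leaflets(frame: SimulationFrame, atoms: pd.DataFrame) -> pd.DataFrame:
    """Assign each lipid, peptide, water, and ion to a leaflet.

    A lipid is *upper* if its phosphorus z exceeds the midplane, else
    *lower*. A peptide joins the leaflet whose phosphorus center of mass
    is nearer to the peptide center of mass. Waters and ions follow the
    sign of their position relative to the midplane.
    """
    coords = frame.coordinates
    z0 = midplane_z(frame, atoms)
    out = atoms.copy()
    out["leaflet"] = "none"

    pidx = phosphorus_index(atoms)
    upper_p = pidx[coords[pidx, 2] > z0]
    lower_p = pidx[coords[pidx, 2] <= z0]
    if len(upper_p) == 0 or len(lower_p) == 0:
        raise DegenerateBilayerError("a leaflet has zero lipids")

    is_lipid = atoms["molecule_kind"].isin(LIPID_KINDS).to_numpy()
    for mol_id, grp in atoms[is_lipid].groupby("molecule_id"):
        p_rows = grp.index[grp["element"] == "P"]
        if len(p_rows) == 0:
            raise TypingError(f"lipid molecule {mol_id} lacks a phosphorus atom")
        ipos = atoms.index.get_indexer(p_rows)
        side = "upper" if coords[ipos, 2].mean() > z0 else "lower"
        out.loc[grp.index, "leaflet"] = side

    com_upper = mass_weighted_com(coords[upper_p], atoms["mass"].to_numpy()[upper_p])
    com_lower = mass_weighted_com(coords[lower_p], atoms["mass"].to_numpy()[lower_p])
    is_pep = (atoms["molecule_kind"] == "peptide").to_numpy()
    for mol_id, grp in atoms[is_pep].groupby("molecule_id"):
        ipos = atoms.index.get_indexer(grp.index)
        heavy = grp["is_heavy"].to_numpy()
        com = mass_weighted_com(coords[ipos][heavy], grp["mass"].to_numpy()[heavy])
        d_up = np.linalg.norm(min_image_displacement(com, com_upper, frame.box))
        d_lo = np.linalg.norm(min_image_displacement(com, com_lower, frame.box))
        out.loc[grp.index, "leaflet"] = "upper" if d_up <= d_lo else "lower"

    other = ~(is_lipid | is_pep)
    for mol_id, grp in atoms[other].groupby("molecule_id"):
        ipos = atoms.index.get_indexer(grp.index)
        out.loc[grp.index, "leaflet"] = "upper" if coords[ipos, 2].mean() > z0 else "lower"
    return out


def canonical_orientation(frame: SimulationFrame, leaflet: str) -> SimulationFrame:
    """Mirror z about the midplane (assumed at z = 0) for lower-leaflet analyses.

    Upper-leaflet frames are returned as a copy, unchanged. Applying the
    operation twice is the identity.
    """
    coords = frame.coordinates.copy()
    if leaflet == "lower":
        coords[:, 2] = -coords[:, 2]
    return SimulationFrame(coords, frame.box, frame.frame_index)
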