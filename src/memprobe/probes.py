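"""Per-frame peptide geometry probes.

Center-of-mass depth z_CM, per-residue depth profiles P(z; i) with
insertion calls, the helix tilt angle gamma, the azimuthal rotation
angle beta, the interpeptide (dimer) angle alpha, and the radius of
gyration. All probes expect canonical orientation: the midplane at
z = 0 and the analysed leaflet's outward normal along +z (lower-leaflet
peptides are mirrored internally using the atom table's leaflet labels).

Angle conventions
-----------------
The helix-region vector h runs from the center of mass of the first
half of the region's residues to that of the last half (N->C); for an
odd residue count the middle residue is dropped from both halves.
gamma = angle(h, +z): 90 deg means parallel to the bilayer. beta is
measured for one residue's C-alpha about the helix axis in the frame
(x' || h, y' = z x h normalized, z' = x' cross y'); 90 deg points up
toward water, 270 deg down. alpha keeps the signed N->C direction of
both h vectors, so antiparallel helices give 180 deg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    ArityError,
    DegenerateGeometryError,
    EmptySampleError,
    TypingError,
)
from .geometry import mass_weighted_com
from .model import (
    BilayerGeometry,
    PeptideRegions,
    SimulationFrame,
    Trajectory,
    span_residues,
)


def _peptide_sel(traj: Trajectory, peptide_id: int, heavy: bool = True) -> np.ndarray:
    idx = traj.atom_index(molecule_kind="peptide", molecule_id=peptide_id)
    if heavy:
        idx = idx[traj.atoms["is_heavy"].to_numpy()[idx]]
    if len(idx) == 0:
        raise TypingError(f"peptide {peptide_id} has no heavy atoms")
    return idx


def _canonical_coords(traj: Trajectory, frame: SimulationFrame, peptide_id: int) -> np.ndarray:
    """Frame coordinates mirrored if the peptide lives in the lower leaflet."""
    leaflet = traj.atoms.loc[
        traj.atoms["molecule_id"] == peptide_id, "leaflet"
    ].iloc[0]
    coords = frame.coordinates
    if leaflet == "lower":
        coords = coords.copy()
        coords[:, 2] = -coords[:, 2]
    return coords


def peptide_com_z(traj: Trajectory, frame: SimulationFrame, peptide_id: int) -> float:
    """Mass-weighted heavy-atom center-of-mass depth above the midplane."""
    idx = _peptide_sel(traj, peptide_id)
    coords = _canonical_coords(traj, frame, peptide_id)
    masses = traj.atoms["mass"].to_numpy()[idx]
    return float(mass_weighted_com(coords[idx], masses)[2])


def radius_of_gyration(traj: Trajectory, frame: SimulationFrame, peptide_id: int) -> float:
    """Mass-weighted RMS distance of heavy atoms from their center of mass."""
    idx = _peptide_sel(traj, peptide_id)
    coords = frame.coordinates[idx]
    masses = traj.atoms["mass"].to_numpy()[idx]
    com = mass_weighted_com(coords, masses)
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * d2).sum() / masses.sum()))


def _region_halves(residues: list[int]) -> tuple[list[int], list[int]]:
    n = len(residues)
    half = n // 2
    return residues[:half], residues[n - half:]


def region_vector(
    traj: Trajectory, coords: np.ndarray, peptide_id: int, region: tuple[int, int]
) -> np.ndarray:
    """N->C vector h between the half-region heavy-atom centers of mass."""
    residues = span_residues(region)
    if len(residues) < 2:
        raise DegenerateGeometryError("region needs at least 2 residues")
    first, last = _region_halves(residues)
    masses = traj.atoms["mass"].to_numpy()
    coms = []
    for chunk in (first, last):
        idx = traj.atom_index(
            molecule_kind="peptide", molecule_id=peptide_id, residue_index=tuple(chunk)
        )
        idx = idx[traj.atoms["is_heavy"].to_numpy()[idx]]
        coms.append(mass_weighted_com(coords[idx], masses[idx]))
    h = coms[1] - coms[0]
    if np.linalg.norm(h) < 1e-10:
        raise DegenerateGeometryError("zero-length helix-region vector")
    return h


def tilt_angle(
    traj: Trajectory,
    frame: SimulationFrame,
    peptide_id: int,
    region: tuple[int, int] = (6, 14),
) -> float:
    """Tilt gamma (degrees in [0, 180]) between h and the bilayer normal."""
    coords = _canonical_coords(traj, frame, peptide_id)
    h = region_vector(traj, coords, peptide_id, region)
    cosg = np.clip(h[2] / np.linalg.norm(h), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosg)))


def rotation_angle(
    traj: Trajectory,
    frame: SimulationFrame,
    peptide_id: int,
    residue: int = 19,
    region: tuple[int, int] = (15, 20),
) -> float:
    """Rotation beta (degrees in [0, 360)) of a residue about the helix axis."""
    coords = _canonical_coords(traj, frame, peptide_id)
    h = region_vector(traj, coords, peptide_id, region)
    xhat = h / np.linalg.norm(h)
    yp = np.cross([0.0, 0.0, 1.0], xhat)
    n = np.linalg.norm(yp)
    if n < 1e-8:
        raise DegenerateGeometryError(
            "helix axis parallel to the bilayer normal: beta undefined"
        )
    yp = yp / n
    zp = np.cross(xhat, yp)

    residues = span_residues(region)
    masses = traj.atoms["mass"].to_numpy()
    idx = traj.atom_index(
        molecule_kind="peptide", molecule_id=peptide_id, residue_index=tuple(residues)
    )
    idx = idx[traj.atoms["is_heavy"].to_numpy()[idx]]
    axis_point = mass_weighted_com(coords[idx], masses[idx])

    ca = traj.atom_index(
        molecule_kind="peptide", molecule_id=peptide_id,
        residue_index=residue, atom_name="CA",
    )
    if len(ca) != 1:
        raise TypingError(f"residue {residue} of peptide {peptide_id} lacks a CA atom")
    v = coords[ca[0]] - axis_point
    v_perp = v - np.dot(v, xhat) * xhat
    beta = np.degrees(np.arctan2(np.dot(v_perp, zp), np.dot(v_perp, yp)))
    return float(beta % 360.0)


def interpeptide_angle(
    traj: Trajectory,
    frame: SimulationFrame,
    leaflet: str,
    region: tuple[int, int] = (15, 20),
) -> float:
    """Dimer angle alpha between the two peptides' C-terminal h vectors."""
    peptides = traj.peptide_ids(leaflet)
    if len(peptides) != 2:
        raise ArityError(f"leaflet {leaflet!r} has {len(peptides)} peptides, need 2")
    hs = []
    for pid in peptides:
        coords = _canonical_coords(traj, frame, pid)
        h = region_vector(traj, coords, pid, region)
        hs.append(h / np.linalg.norm(h))
    cosa = np.clip(np.dot(hs[0], hs[1]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosa)))


def residue_z(traj: Trajectory, frame: SimulationFrame, peptide_id: int, residue: int) -> float:
    """Heavy-atom center-of-mass depth of one residue (backbone + side chain)."""
    coords = _canonical_coords(traj, frame, peptide_id)
    idx = traj.atom_index(
        molecule_kind="peptide", molecule_id=peptide_id, residue_index=residue
    )
    idx = idx[traj.atoms["is_heavy"].to_numpy()[idx]]
    masses = traj.atoms["mass"].to_numpy()[idx]
    return float(mass_weighted_com(coords[idx], masses)[2])


def residue_depth_profile(
    traj: Trajectory,
    geometry: BilayerGeometry | None = None,
    bin_width: float = 0.5,
    z_range: tuple[float, float] = (-5.0, 40.0),
):
    """Weighted P(z; i) histograms, mean depths, and inserted fractions.

    A residue is inserted in a frame iff its depth z(i) is strictly below
    z_P. Returns ``(profile_df, hist_df)``: per-residue summary plus the
    normalized long-format histograms.
    """
    geometry = geometry or BilayerGeometry()
    w = traj.effective_weights
    if w.sum() <= 0:
        raise EmptySampleError("all frames excluded or zero-weighted")
    edges = np.arange(z_range[0], z_range[1] + bin_width, bin_width)
    rows, hist_rows = [], []
    masses = traj.atoms["mass"].to_numpy()
    heavy = traj.atoms["is_heavy"].to_numpy()
    leaflet_of = traj.atoms.groupby("molecule_id")["leaflet"].first()
    for pid in traj.peptide_ids():
        sign = -1.0 if leaflet_of[pid] == "lower" else 1.0
        residues = sorted(
            traj.atoms.loc[traj.atoms["molecule_id"] == pid, "residue_index"].unique()
        )
        for res in residues:
            idx = traj.atom_index(
                molecule_kind="peptide", molecule_id=pid, residue_index=res
            )
            idx = idx[heavy[idx]]
            m = masses[idx]
            zs = sign * (traj.coordinates[:, idx, 2] * m).sum(axis=1) / m.sum()
            mean_z = float((w * zs).sum() / w.sum())
            inserted = float((w * (zs < geometry.z_P)).sum() / w.sum())
            hist, _ = np.histogram(zs, bins=edges, weights=w)
            total = hist.sum()
            if total > 0:
                hist = hist / total
            rows.append(
                dict(peptide_id=pid, residue=res, mean_z=mean_z, inserted_fraction=inserted)
            )
            centers = 0.5 * (edges[:-1] + edges[1:])
            for c, p in zip(centers, hist):
                if p > 0:
                    hist_rows.append(dict(peptide_id=pid, residue=res, z=c, P=p))
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)


def angle_table(
    traj: Trajectory,
    regions: PeptideRegions | None = None,
) -> pd.DataFrame:
    """One row per (frame, peptide): z_CM, gamma, beta, R_g.

    Frames where beta is undefined (vertical helix) carry NaN there.
    Excluded frames are kept in the table (weight bookkeeping is the
    caller's job via ``Trajectory.effective_weights``).
    """
    regions = regions or PeptideRegions()
    rows = []
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        for pid in traj.peptide_ids():
            try:
                beta = rotation_angle(
                    traj, frame, pid, regions.rotation_residue, regions.alt_tilt_region
                )
            except DegenerateGeometryError:
                beta = np.nan
            rows.append(
                dict(
                    frame=f,
                    peptide_id=pid,
                    z_cm=peptide_com_z(traj, frame, pid),
                    gamma=tilt_angle(traj, frame, pid, regions.tilt_region),
                    beta=beta,
                    r_gyr=radius_of_gyration(traj, frame, pid),
                )
            )
    return pd.DataFrame(rows)
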