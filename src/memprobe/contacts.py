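"""Side-chain contacts, dimer contact counts, and the periodic-image screen.

A contact exists between two residues when their side-chain heavy-atom
centers of mass are separated by less than 6.5 A (minimum image in x
and y). C_d is the number of such interpeptide contacts between the two
peptides of a leaflet. Glycine, having no side-chain heavy atom, uses
its C-alpha position.

The periodic-image screen flags frames in which any pair of side-chain
centroids — across peptides or within one — is in contact only through
an x/y periodic image (minimum-image distance below the cutoff while
the direct distance is not). Flagged frames are excluded (weight zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ArityError, EmptySampleError, TypingError
from .geometry import mass_weighted_com, min_image_displacement
from .model import SimulationFrame, Trajectory

CONTACT_CUTOFF = 6.5
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass
class ContactSet:
    """Interpeptide contacts in one leaflet of one frame."""

    frame_index: int
    leaflet: str
    pairs: pd.DataFrame  # residue_i, residue_j, distance

    @property
    def c_d(self) -> int:
        return len(self.pairs)


def sidechain_centroid(
    traj: Trajectory, frame: SimulationFrame, peptide_id: int, residue: int
) -> np.ndarray:
    """Mass-weighted center of the residue's side-chain heavy atoms."""
    idx = traj.atom_index(
        molecule_kind="peptide", molecule_id=peptide_id, residue_index=residue
    )
    if len(idx) == 0:
        raise TypingError(f"peptide {peptide_id} has no residue {residue}")
    names = traj.atoms["atom_name"].to_numpy()[idx]
    heavy = traj.atoms["is_heavy"].to_numpy()[idx]
    side = idx[heavy & ~np.isin(names, list(BACKBONE_NAMES))]
    if len(side) == 0:  # Gly: fall back to C-alpha
        side = idx[names == "CA"]
        if len(side) == 0:
            raise TypingError(f"residue {residue} has neither side chain nor CA")
    masses = traj.atoms["mass"].to_numpy()[side]
    return mass_weighted_com(frame.coordinates[side], masses)


def _peptide_centroids(traj: Trajectory, frame: SimulationFrame, peptide_id: int):
    residues = sorted(
        traj.atoms.loc[traj.atoms["molecule_id"] == peptide_id, "residue_index"].unique()
    )
    cents = np.array(
        [sidechain_centroid(traj, frame, peptide_id, r) for r in residues]
    )
    return residues, cents


def interpeptide_contacts(
    traj: Trajectory,
    frame: SimulationFrame,
    leaflet: str,
    cutoff: float = CONTACT_CUTOFF,
) -> ContactSet:
    """All residue pairs with centroid distance strictly below the cutoff."""
    peptides = traj.peptide_ids(leaflet)
    if len(peptides) != 2:
        raise ArityError(f"leaflet {leaflet!r} has {len(peptides)} peptides, need 2")
    res_a, cent_a = _peptide_centroids(traj, frame, peptides[0])
    res_b, cent_b = _peptide_centroids(traj, frame, peptides[1])
    disp = min_image_displacement(cent_a[:, None, :], cent_b[None, :, :], frame.box)
    dist = np.sqrt((disp**2).sum(-1))
    ii, jj = np.nonzero(dist < cutoff)
    pairs = pd.DataFrame(
        dict(
            residue_i=[res_a[i] for i in ii],
            residue_j=[res_b[j] for j in jj],
            distance=dist[ii, jj],
        )
    )
    return ContactSet(frame_index=frame.frame_index, leaflet=leaflet, pairs=pairs)


def contact_series(
    traj: Trajectory, leaflet: str, cutoff: float = CONTACT_CUTOFF
) -> pd.DataFrame:
    """Per-frame C_d plus the pair lists for one leaflet."""
    rows = []
    for f in range(traj.n_frames):
        cs = interpeptide_contacts(traj, traj.frame(f), leaflet, cutoff)
        rows.append(dict(frame=f, leaflet=leaflet, c_d=cs.c_d, pairs=cs.pairs))
    return pd.DataFrame(rows)


def _pair_label(traj: Trajectory, residue_i: int, residue_j: int) -> str:
    """One-letter residue-pair label, e.g. 'A17-A20'."""
    pep = traj.atoms[traj.atoms["molecule_kind"] == "peptide"]
    three_to_one = {
        "GLY": "G", "MET": "M", "ALA": "A", "SER": "S", "LYS": "K",
        "ILE": "I", "VAL": "V", "LEU": "L", "ARG": "R", "ASN": "N",
        "ASP": "D", "CYS": "C", "GLN": "Q", "GLU": "E", "HIS": "H",
        "PHE": "F", "PRO": "P", "THR": "T", "TRP": "W", "TYR": "Y",
    }

    def one(res):
        names = pep.loc[pep["residue_index"] == res, "residue_name"]
        return three_to_one.get(names.iloc[0], "X") if len(names) else "X"

    return f"{one(residue_i)}{residue_i}-{one(residue_j)}{residue_j}"


def contact_probability_table(
    traj: Trajectory,
    leaflets: tuple[str, ...] = ("upper", "lower"),
    cutoff: float = CONTACT_CUTOFF,
    frame_mask: np.ndarray | None = None,
    traj_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Weighted per-residue-pair contact probabilities plus the mean C_d.

    ``frame_mask`` restricts to a state (e.g. mature-dimer frames only).
    Probabilities pool both leaflets with the trajectory frame weights.
    ``traj_ids`` maps each frame to an independent trajectory; per-pair
    standard errors over trajectory means (SE = s/sqrt(n)) are then added.
    """
    w = traj.effective_weights.copy()
    if frame_mask is not None:
        w = np.where(np.asarray(frame_mask, dtype=bool), w, 0.0)
    if w.sum() <= 0:
        raise EmptySampleError("no frames selected for the contact table")

    counts: dict[tuple[int, int], float] = {}
    by_traj: dict[int, dict[tuple[int, int], float]] = {}
    traj_w: dict[int, float] = {}
    mean_cd, total_w = 0.0, 0.0
    for leaflet in leaflets:
        for f in range(traj.n_frames):
            if w[f] == 0:
                continue
            cs = interpeptide_contacts(traj, traj.frame(f), leaflet, cutoff)
            mean_cd += w[f] * cs.c_d
            total_w += w[f]
            tid = int(traj_ids[f]) if traj_ids is not None else 0
            traj_w[tid] = traj_w.get(tid, 0.0) + w[f]
            for _, row in cs.pairs.iterrows():
                key = (int(row["residue_i"]), int(row["residue_j"]))
                counts[key] = counts.get(key, 0.0) + w[f]
                by_traj.setdefault(tid, {})[key] = by_traj.get(tid, {}).get(key, 0.0) + w[f]
    norm = total_w  # one sample per (frame, leaflet) pair
    rows = []
    n_traj = len(traj_w)
    for (i, j), c in sorted(counts.items()):
        row = dict(
            residue_i=i, residue_j=j,
            label=_pair_label(traj, i, j), P_c=c / norm,
        )
        if traj_ids is not None and n_traj >= 2:
            per = [by_traj.get(t, {}).get((i, j), 0.0) / tw for t, tw in traj_w.items()]
            row["SE"] = float(np.std(per, ddof=1) / np.sqrt(n_traj))
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("P_c", ascending=False, ignore_index=True)
    return table, mean_cd / total_w


def flag_periodic_image_artifacts(
    traj: Trajectory, cutoff: float = CONTACT_CUTOFF, apply: bool = True
):
    """Mask frames whose peptide contacts exist only through a periodic image.

    Returns ``(mask, fraction)``; with ``apply`` the trajectory's
    ``excluded`` mask is set so flagged frames carry weight zero.
    """
    peptides = traj.peptide_ids()
    mask = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        cents = [
            _peptide_centroids(traj, frame, pid)[1] for pid in peptides
        ]
        flagged = False
        for a in range(len(cents)):
            for b in range(a, len(cents)):
                direct = cdist(cents[a], cents[b])
                disp = min_image_displacement(
                    cents[a][:, None, :], cents[b][None, :, :], frame.box
                )
                wrapped = np.sqrt((disp**2).sum(-1))
                through_image = (wrapped < cutoff) & (direct >= cutoff)
                if a == b:
                    np.fill_diagonal(through_image, False)
                if through_image.any():
                    flagged = True
                    break
            if flagged:
                break
        mask[f] = flagged
    if apply:
        traj.excluded = traj.excluded | mask
    return mask, float(mask.mean())


def bound_fraction(traj: Trajectory, cutoff: float = 4.0) -> float:
    """Weighted fraction of (frame, peptide) samples bound to the bilayer.

    A peptide is bound in a frame iff any of its heavy atoms lies within
    ``cutoff`` of any lipid heavy atom (minimum image in x, y).
    """
    w = traj.effective_weights
    if w.sum() <= 0:
        raise EmptySampleError("all frames excluded")
    lipid_idx = traj.atom_index(molecule_kind=("DMPC", "DMPG"), is_heavy=True)
    total, bound = 0.0, 0.0
    for f in range(traj.n_frames):
        if w[f] == 0:
            continue
        frame = traj.frame(f)
        lip = frame.coordinates[lipid_idx]
        for pid in traj.peptide_ids():
            idx = traj.atom_index(molecule_kind="peptide", molecule_id=pid, is_heavy=True)
            pep = frame.coordinates[idx]
            disp = min_image_displacement(pep[:, None, :], lip[None, :, :], frame.box)
            dmin = np.sqrt((disp**2).sum(-1)).min()
            total += w[f]
            bound += w[f] * (dmin < cutoff)
    return bound / total
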