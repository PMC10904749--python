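"""Hand-built miniature trajectories for unit tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from memprobe.constants import mass_of
from memprobe.model import ATOM_COLUMNS, Trajectory


def atom(
    atom_id,
    molecule_id,
    kind,
    residue_index=1,
    residue_name="ALA",
    atom_name="CA",
    element=None,
    lipid_group="none",
    leaflet="none",
):
    element = element or atom_name[0]
    return (
        atom_id,
        molecule_id,
        kind,
        residue_index,
        residue_name,
        atom_name,
        element,
        mass_of(element),
        element != "H",
        lipid_group,
        leaflet,
    )


def make_traj(rows, frames, box=(59.0, 59.0, 74.0), **kw) -> Trajectory:
    atoms = pd.DataFrame(rows, columns=list(ATOM_COLUMNS))
    coords = np.asarray(frames, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    boxes = np.tile(np.asarray(box, dtype=float), (coords.shape[0], 1))
    return Trajectory(atoms=atoms, coordinates=coords, boxes=boxes, **kw)


def two_peptide_rows(n_residues=1, with_cb=True, leaflet="upper"):
    """Two tiny peptides (CA [+ CB] per residue) in one leaflet."""
    rows = []
    aid = 0
    for mol in (0, 1):
        for res in range(1, n_residues + 1):
            rows.append(atom(aid, mol, "peptide", res, "ALA", "CA", leaflet=leaflet))
            aid += 1
            if with_cb:
                rows.append(atom(aid, mol, "peptide", res, "ALA", "CB", leaflet=leaflet))
                aid += 1
    return rows


def water_rows(n, leaflet="upper", start_mol=100):
    rows = []
    aid = 0
    for k in range(n):
        mol = start_mol + k
        for name in ("OH2", "H1", "H2"):
            rows.append(
                atom(aid, mol, "water", 1, "TIP3", name,
                     element="O" if name == "OH2" else "H", leaflet=leaflet)
            )
            aid += 1
    return rows
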