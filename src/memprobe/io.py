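"""File I/O: PDB/DCD trajectories in, typed :class:`Trajectory` out.

Reading and writing of the coordinate formats goes through MDAnalysis;
this module adds molecule typing (residue-name rules), per-frame
midplane centering, and leaflet assignment on top.

The portable trajectory dialect is a PDB topology plus a multi-model PDB
(one MODEL per frame); DCD coordinate files are accepted as well. The
multi-model PDB carries a single CRYST1 record, so per-frame box changes
survive only through DCD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASS, mass_of
from .errors import FormatError, TypingError
from .geometry import assign_leaflets, center_trajectory
from .model import ATOM_COLUMNS, LIPID_KINDS, Trajectory, validate_atom_table

#: 3-letter codes accepted as peptide residues.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}

DEFAULT_RESIDUE_KINDS = {
    **{aa: "peptide" for aa in AMINO_ACIDS},
    "DMPC": "DMPC",
    "DMPG": "DMPG",
    "HOH": "water",
    "TIP3": "water",
    "TIP": "water",
    "WAT": "water",
    "SPC": "water",
    "SOD": "ion",
    "CLA": "ion",
    "NA": "ion",
    "CL": "ion",
    "POT": "ion",
}

#: Lipid atom-name -> headgroup/tail group. P is the L2 phosphate marker.
DEFAULT_LIPID_GROUPS = {
    "P": "L2",
    "L1": "L1",
    "L2": "L2",
    "L3": "L3",
    "L4": "L4",
    "L5": "L5",
}

DEFAULT_ELEMENTS = {
    "P": "P",
    "SOD": "NA",
    "CLA": "CL",
    "NA": "NA",
    "CL": "CL",
    "OH2": "O",
    "OW": "O",
}


@dataclass
class TypingRules:
    """Configurable residue/atom typing tables (merged over the defaults)."""

    residue_kinds: dict = field(default_factory=dict)
    lipid_groups: dict = field(default_factory=dict)
    elements: dict = field(default_factory=dict)

    def kind_of(self, resname: str) -> str:
        table = {**DEFAULT_RESIDUE_KINDS, **self.residue_kinds}
        key = resname.strip().upper()
        if key not in table:
            raise TypingError(f"no typing rule for residue name {resname!r}")
        return table[key]

    def lipid_group_of(self, atom_name: str) -> str:
        table = {**DEFAULT_LIPID_GROUPS, **self.lipid_groups}
        key = atom_name.strip().upper()
        if key not in table:
            raise TypingError(f"no lipid-group rule for lipid atom name {atom_name!r}")
        return table[key]

    def element_of(self, atom_name: str, pdb_element: str = "") -> str:
        if pdb_element and pdb_element.strip().upper() in ATOMIC_MASS:
            return pdb_element.strip().upper()
        table = {**DEFAULT_ELEMENTS, **self.elements}
        key = atom_name.strip().upper()
        if key in table:
            return table[key]
        alpha = "".join(c for c in key if c.isalpha())
        if alpha[:1] in ATOMIC_MASS:
            return alpha[:1]
        raise TypingError(f"cannot infer element for atom name {atom_name!r}")


def _universe(topology_path, coordinate_paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(topology_path), *[str(p) for p in coordinate_paths])
        except (ValueError, OSError, EOFError) as exc:
            raise FormatError(f"failed to read trajectory: {exc}") from exc


def build_atom_table(universe, rules: TypingRules | None = None) -> pd.DataFrame:
    """Type every atom of an MDAnalysis universe into the canonical table."""
    rules = rules or TypingRules()
    ag = universe.atoms
    names = [str(n) for n in ag.names]
    resnames = [str(r) for r in ag.resnames]
    resids = [int(r) for r in ag.resids]
    try:
        chains = [str(c) for c in ag.chainIDs]
    except AttributeError:
        chains = [str(s) for s in ag.segids]
    try:
        pdb_elements = [str(e) for e in ag.elements]
    except AttributeError:
        pdb_elements = [""] * len(names)

    kinds = [rules.kind_of(r) for r in resnames]
    mol_keys: dict[tuple, int] = {}
    rows = []
    for i in range(len(names)):
        kind = kinds[i]
        key = ("pep", chains[i]) if kind == "peptide" else (kind, chains[i], resids[i])
        mol_id = mol_keys.setdefault(key, len(mol_keys))
        element = rules.element_of(names[i], pdb_elements[i])
        group = rules.lipid_group_of(names[i]) if kind in LIPID_KINDS else "none"
        rows.append(
            (
                i,
                mol_id,
                kind,
                resids[i] if kind == "peptide" else 1,
                resnames[i],
                names[i],
                element,
                mass_of(element),
                element != "H",
                group,
                "none",
            )
        )
    atoms = pd.DataFrame(rows, columns=list(ATOM_COLUMNS))
    return validate_atom_table(atoms)


def load_trajectory(
    topology_path,
    coordinate_paths: Sequence,
    typing_rules: TypingRules | None = None,
    traj_id: int = 0,
    center: bool = True,
) -> Trajectory:
    """Read a topology plus coordinate frames into a fully typed Trajectory.

    By default every frame is recentered on its phosphorus midplane and
    leaflets are assigned from the first frame.
    """
    if not coordinate_paths:
        raise FormatError("no coordinate files given")
    u = _universe(topology_path, coordinate_paths)
    atoms = build_atom_table(u, typing_rules)

    coords, boxes = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.n_atoms != len(atoms):
                raise FormatError(
                    f"frame {ts.frame}: atom count {ts.n_atoms} != topology {len(atoms)}"
                )
            coords.append(ts.positions.astype(float).copy())
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise FormatError(f"frame {ts.frame}: missing box dimensions")
            boxes.append(ts.dimensions[:3].astype(float).copy())
    traj = Trajectory(
        atoms=atoms,
        coordinates=np.stack(coords),
        boxes=np.stack(boxes),
        traj_id=traj_id,
    )
    if center:
        traj = center_trajectory(traj)
        traj = traj.with_atoms(assign_leaflets(traj.frame(0), traj.atoms))
    return traj


# -- writing -----------------------------------------------------------------

_CHAIN_ALPHABET = "ABCDEFGHJK"


def _writer_universe(traj: Trajectory):
    import MDAnalysis as mda

    atoms = traj.atoms
    pep_ids = traj.peptide_ids()
    chain_of_pep = {m: _CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)] for i, m in enumerate(pep_ids)}
    kind_chain = {"DMPC": "L", "DMPG": "L", "water": "W", "ion": "I"}

    res_keys: dict[tuple, int] = {}
    chain_resid_counter: dict[str, int] = {}
    atom_resindex = np.empty(len(atoms), dtype=int)
    resids, resnames, chainids = [], [], []
    for i, row in enumerate(atoms.itertuples(index=False)):
        if row.molecule_kind == "peptide":
            chain = chain_of_pep[row.molecule_id]
            key = (row.molecule_id, row.residue_index)
        else:
            chain = kind_chain[row.molecule_kind]
            key = (row.molecule_id, 1)
        if key not in res_keys:
            res_keys[key] = len(res_keys)
            if row.molecule_kind == "peptide":
                resid = row.residue_index
            else:
                chain_resid_counter[chain] = chain_resid_counter.get(chain, 0) + 1
                resid = ((chain_resid_counter[chain] - 1) % 9999) + 1
            resids.append(resid)
            resnames.append(row.residue_name)
            chainids.append(chain)
        atom_resindex[i] = res_keys[key]

    n_res = len(res_keys)
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=n_res,
        n_segments=1,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["atom_name"].tolist())
    u.add_TopologyAttr("elements", atoms["element"].str.capitalize().tolist())
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("chainIDs", [chainids[r] for r in atom_resindex])
    return u


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a multi-model PDB that :func:`load_trajectory` reads back."""
    import MDAnalysis as mda

    path = Path(path)
    u = _writer_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[i]
                u.dimensions = [*traj.boxes[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)

    # Re-emit a CRYST1 record inside every MODEL block: the PDB trajectory
    # reader only parses box records it finds within a frame's byte range.
    lines = path.read_text().splitlines()
    out_lines = []
    frame = 0
    for line in lines:
        out_lines.append(line)
        if line.startswith("MODEL"):
            lx, ly, lz = traj.boxes[min(frame, traj.n_frames - 1)]
            out_lines.append(
                f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
            )
            frame += 1
    path.write_text("\n".join(out_lines) + "\n")
    return path
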