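"""Core data model: typed atoms, frames, trajectories, and geometry settings.

The atom table is a :class:`pandas.DataFrame` with one row per atom
(columns listed in :data:`ATOM_COLUMNS`); :class:`AtomRecord` is the
record-level view of a single row. Coordinates live in a dense
``(n_frames, n_atoms, 3)`` float array on the :class:`Trajectory`, with
:class:`SimulationFrame` acting as a light per-frame view.

Conventions
-----------
* Lengths in Angstrom, the bilayer midplane defines z = 0 (recomputed per
  frame from phosphorus atoms), the outward normal is +z after canonical
  orientation (see :mod:`memprobe.geometry`).
* Excluded frames (periodic-image artifacts) carry weight zero in every
  average: use :attr:`Trajectory.effective_weights`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

MOLECULE_KINDS = ("peptide", "DMPC", "DMPG", "water", "ion")
LIPID_KINDS = ("DMPC", "DMPG")
LIPID_GROUPS = ("L1", "L2", "L3", "L4", "L5", "none")
LEAFLETS = ("upper", "lower", "none")

#: Columns of the atom table, in canonical order.
ATOM_COLUMNS = (
    "atom_id",
    "molecule_id",
    "molecule_kind",
    "residue_index",
    "residue_name",
    "atom_name",
    "element",
    "mass",
    "is_heavy",
    "lipid_group",
    "leaflet",
)


@dataclass(frozen=True)
class AtomRecord:
    """One typed atom. ``residue_index`` is 1-based within its molecule."""

    atom_id: int
    molecule_id: int
    molecule_kind: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    mass: float
    is_heavy: bool
    lipid_group: str = "none"
    leaflet: str = "none"


def atoms_to_frame(records: Sequence[AtomRecord]) -> pd.DataFrame:
    """Build the canonical atom table from records."""
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(ATOM_COLUMNS))
    return validate_atom_table(df)


def validate_atom_table(atoms: pd.DataFrame) -> pd.DataFrame:
    """Check atom-table invariants; returns the table unchanged."""
    missing = set(ATOM_COLUMNS) - set(atoms.columns)
    if missing:
        raise ConfigError(f"atom table missing columns: {sorted(missing)}")
    bad_kind = set(atoms["molecule_kind"]) - set(MOLECULE_KINDS)
    if bad_kind:
        raise ConfigError(f"unknown molecule kinds: {sorted(bad_kind)}")
    pep = atoms[atoms["molecule_kind"] == "peptide"]
    if len(pep) and not pep["residue_index"].between(1, 21).all():
        raise ConfigError("peptide residue_index must lie in [1, 21]")
    is_lipid = atoms["molecule_kind"].isin(LIPID_KINDS)
    if (atoms.loc[~is_lipid, "lipid_group"] != "none").any():
        raise ConfigError("lipid_group must be 'none' for non-lipid atoms")
    if (atoms.loc[is_lipid, "lipid_group"] == "none").any():
        raise ConfigError("lipid atoms must carry a lipid_group L1-L5")
    phos = atoms[is_lipid & (atoms["element"] == "P")]
    if len(phos) and (phos["lipid_group"] != "L2").any():
        raise ConfigError("phosphorus atoms must carry lipid_group L2")
    return atoms


@dataclass
class SimulationFrame:
    """Coordinates (n_atoms, 3) in Angstrom plus the periodic box for one time point."""

    coordinates: np.ndarray
    box: np.ndarray  # (Lx, Ly, Lz)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ConfigError("non-finite coordinates")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ConfigError("box edges must be three positive lengths")


@dataclass
class Trajectory:
    """Ordered frames over one constant atom table.

    ``weights`` are per-frame statistical weights (WHAM or uniform);
    ``excluded`` marks frames removed by the periodic-image screen.
    """

    atoms: pd.DataFrame
    coordinates: np.ndarray  # (F, N, 3)
    boxes: np.ndarray  # (F, 3)
    traj_id: int = 0
    weights: np.ndarray | None = None
    temperature: np.ndarray | None = None
    potential_energy: np.ndarray | None = None
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        validate_atom_table(self.atoms)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ConfigError("coordinates must have shape (F, N, 3)")
        if self.coordinates.shape[1] != len(self.atoms):
            raise ConfigError(
                f"coordinate atom count {self.coordinates.shape[1]} "
                f"!= atom table length {len(self.atoms)}"
            )
        f = self.n_frames
        if self.weights is None:
            self.weights = np.ones(f)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ConfigError("frame weights must be >= 0")
        if self.excluded is None:
            self.excluded = np.zeros(f, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        for arr_name in ("weights", "excluded"):
            if len(getattr(self, arr_name)) != f:
                raise ConfigError(f"{arr_name} length != n_frames")

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def effective_weights(self) -> np.ndarray:
        """Frame weights with excluded frames forced to zero."""
        return np.where(self.excluded, 0.0, self.weights)

    def frame(self, i: int) -> SimulationFrame:
        return SimulationFrame(self.coordinates[i], self.boxes[i], frame_index=i)

    def frames(self) -> Iterator[SimulationFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- selections ------------------------------------------------------
    def peptide_ids(self, leaflet: str | None = None) -> list[int]:
        pep = self.atoms[self.atoms["molecule_kind"] == "peptide"]
        if leaflet is not None:
            pep = pep[pep["leaflet"] == leaflet]
        return sorted(pep["molecule_id"].unique())

    def atom_index(self, **conditions) -> np.ndarray:
        """Positional indices of atoms matching equality ``conditions``.

        Values may be scalars or collections (membership test).
        """
        mask = np.ones(len(self.atoms), dtype=bool)
        for col, val in conditions.items():
            series = self.atoms[col]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= series.isin(val).to_numpy()
            else:
                mask &= (series == val).to_numpy()
        return np.flatnonzero(mask)

    def with_atoms(self, atoms: pd.DataFrame) -> "Trajectory":
        return replace(self, atoms=atoms)


@dataclass
class BilayerGeometry:
    """Bilayer reference geometry and analysis thresholds.

    ``z_P`` is the average distance of a leaflet's phosphorus center of
    mass from the midplane in the peptide-free bilayer; residues below it
    count as inserted. ``near_radius``/``distant_radius`` bound the
    near / proximal / distant lateral lipid regions around a peptide.
    """

    z_P: float = 17.56
    near_radius: float = 6.0
    distant_radius: float = 21.5
    temperature: float = 330.0

    def __post_init__(self) -> None:
        if not (0 < self.near_radius < self.distant_radius):
            raise ConfigError("need 0 < near_radius < distant_radius")
        if self.z_P <= 0:
            raise ConfigError("z_P must be positive")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")


@dataclass
class PeptideRegions:
    """Residue spans (1-based, inclusive) used by the orientation probes."""

    tilt_region: tuple[int, int] = (6, 14)
    alt_tilt_region: tuple[int, int] = (15, 20)
    alpha_region: tuple[int, int] = (15, 20)
    rotation_residue: int = 19
    nt_region: tuple[int, int] = (1, 11)
    ct_region: tuple[int, int] = (12, 21)

    def __post_init__(self) -> None:
        for name in ("tilt_region", "alt_tilt_region", "alpha_region", "nt_region", "ct_region"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= 21):
                raise ConfigError(f"{name} must be a non-empty span within [1, 21]")
        if not 1 <= self.rotation_residue <= 21:
            raise ConfigError("rotation_residue must lie in [1, 21]")


def span_residues(span: tuple[int, int]) -> list[int]:
    lo, hi = span
    return list(range(lo, hi + 1))
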