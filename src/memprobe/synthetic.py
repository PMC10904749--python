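"""Synthetic membrane-peptide systems with planted ground truth.

Every downstream stage of the package is tested against trajectories
generated here, because no deposited trajectories exist for this system.
The generator emulates the study conditions — a two-leaflet DMPC/DMPG
(3:2) bilayer slab of 98 pseudo-lipids in a 59 x 59 x 74 A cell with one
or two 21-residue amphipathic helices per leaflet — while keeping every
planted quantity (center-of-mass depth, tilt, rotation, contact counts,
water-wire depths, leaflet labels) on record for recovery tests.

Model choices (documented in docs/methods.md):

* Lipids are 5-bead stacks: head beads L1/L2/L3 near the head-group
  height (L2 is the phosphorus marker) and two "melted" tail beads
  L4/L5 resampled uniformly between the midplane and the head each
  frame, so density columns show a plateau that drops sharply at the
  head height. The head height is lowered near peptides to plant a
  bilayer thinning.
* Peptides are ideal alpha-helices (rise 1.5 A/residue, 100 deg/residue,
  C-alpha radius 2.3 A) with a single side-chain pseudo-atom per residue
  (CB at 4.3 A from the axis; Gly has none and uses CA). Backbone N, C,
  O sit opposite the CA/CB side at a radius chosen so each residue's
  heavy-atom center of mass lies exactly on the helix axis; planted
  tilt/rotation/depth are therefore recovered exactly at zero noise.
* Water fills |z| > z_P on a sparse lattice with no inter-water hydrogen
  bonds; planted wires are rigid vertical O-H...O chains (2.5 A links,
  collinear H) descending to an exact planted depth.

All lateral coordinates are wrapped into [0, L), as a periodic MD engine
would store them, so frames planted at the box boundary genuinely
straddle the periodic image.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import mass_of
from .errors import ConfigError
from .model import ATOM_COLUMNS, Trajectory, validate_atom_table
from .wham import ReplicaEnsemble

PGLA_SEQUENCE = "GMASKAGAIAGKIAKVALKAL"

AA_THREE = {
    "G": "GLY", "M": "MET", "A": "ALA", "S": "SER", "K": "LYS",
    "I": "ILE", "V": "VAL", "L": "LEU",
}

_RISE = 1.5
_TWIST = 100.0
_R_CA = 2.3
_R_CB = 4.3
_WIRE_STEP = 2.5
_OH = 0.96


@dataclass
class SyntheticConfig:
    """Planted parameters for :func:`generate_system`.

    Defaults reproduce the high peptide:lipid-ratio study conditions:
    a 59 x 59 x 74 A cell, 30 DMPC + 19 DMPG lipids per leaflet, two
    peptides per leaflet at depth 11.6 A with tilt 107 deg and rotation
    105 deg (Lys19), head groups at z_P = 17.56 A, a planted 6.3 A
    thinning, a 16% lipid depletion around peptides, water wires to
    8.5 A, and 8.5% of frames planted at the periodic boundary.
    """

    n_frames: int = 50
    box: tuple = (59.0, 59.0, 74.0)
    dmpc_per_leaflet: int = 30
    dmpg_per_leaflet: int = 19
    z_p_target: float = 17.56
    peptides_per_leaflet: int = 2
    peptide_z: float = 11.6
    tilt: float = 107.0
    rotation: float = 105.0
    rotation_residue: int = 19
    dimer: bool = False
    dimer_contacts: int = 16
    peptide_separation: float = 14.8
    depletion_radius: float = 6.0
    depletion_strength: float = 0.16
    thinning_delta: float = 6.3
    thinning_inner: float = 6.0
    thinning_outer: float = 21.5
    water_spacing: float = 4.5
    wire_depths: tuple = (8.5,)
    n_sodium: int = 38
    n_chloride: int = 20
    artifact_fraction: float = 0.085
    noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not (0 <= self.tilt <= 180):
            raise ConfigError("tilt must lie in [0, 180] degrees")
        if not (0 <= self.rotation < 360):
            raise ConfigError("rotation must lie in [0, 360) degrees")
        if self.peptides_per_leaflet not in (1, 2):
            raise ConfigError("peptides_per_leaflet must be 1 or 2")
        lx, ly, lz = self.box
        n_lip = self.dmpc_per_leaflet + self.dmpg_per_leaflet
        if n_lip * 20.0 > lx * ly:
            raise ConfigError("overfilled box: lipid area exceeds box area")
        if self.z_p_target + 3.0 > lz / 2:
            raise ConfigError("box too short in z for the head-group height")
        if not (0 <= self.artifact_fraction < 1):
            raise ConfigError("artifact_fraction must lie in [0, 1)")
        if not (0 <= self.depletion_strength <= 1):
            raise ConfigError("depletion_strength must lie in [0, 1]")
        if any(d <= 0 or d >= self.z_p_target for d in self.wire_depths):
            raise ConfigError("wire depths must lie in (0, z_P)")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator planted, for recovery tests."""

    config: SyntheticConfig
    peptide_leaflet: dict  # molecule_id -> leaflet
    molecule_leaflet: dict  # molecule_id -> leaflet, all molecules
    planted_orientation: pd.DataFrame  # peptide_id, z_cm, tilt, rotation (canonical)
    frame_z_cm: pd.DataFrame  # frame, peptide_id, z_cm (canonical, from jittered coords)
    frame_contacts: pd.DataFrame  # frame, leaflet, c_d
    base_contact_pairs: dict  # leaflet -> list of (res_i, res_j) at frame geometry, noise-free
    wire_depths: dict  # leaflet -> list of planted depths
    artifact_frames: np.ndarray  # bool per frame

    def save(self, path) -> Path:
        path = Path(path)
        payload = {
            "config": asdict(self.config),
            "peptide_leaflet": {str(k): v for k, v in self.peptide_leaflet.items()},
            "molecule_leaflet": {str(k): v for k, v in self.molecule_leaflet.items()},
            "planted_orientation": self.planted_orientation.to_dict(orient="records"),
            "frame_z_cm": self.frame_z_cm.to_dict(orient="records"),
            "frame_contacts": self.frame_contacts.to_dict(orient="records"),
            "base_contact_pairs": {k: [list(p) for p in v] for k, v in self.base_contact_pairs.items()},
            "wire_depths": {k: list(v) for k, v in self.wire_depths.items()},
            "artifact_frames": self.artifact_frames.astype(int).tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


# -- ideal helix -------------------------------------------------------------

def _helix_frame(tilt_deg: float, azimuth_deg: float):
    """Helix axis u plus the (y', z') radial frame used by the rotation angle."""
    g = np.deg2rad(tilt_deg)
    phi = np.deg2rad(azimuth_deg)
    u = np.array([np.sin(g) * np.cos(phi), np.sin(g) * np.sin(phi), np.cos(g)])
    zhat = np.array([0.0, 0.0, 1.0])
    yp = np.cross(zhat, u)
    n = np.linalg.norm(yp)
    if n < 1e-12:  # vertical helix: radial frame is arbitrary
        yp = np.array([np.cos(phi), np.sin(phi), 0.0])
    else:
        yp = yp / n
    zp = np.cross(u, yp)
    return u, yp, zp


def build_helix_peptide(
    tilt: float,
    rotation: float,
    rotation_residue: int,
    azimuth: float,
    com: np.ndarray,
    sequence: str = PGLA_SEQUENCE,
):
    """Ideal helix with radially mass-balanced residues.

    Returns (coords, atom_names, residue_names, residue_indices).
    The heavy-atom mass-weighted center of mass equals ``com`` exactly
    and every residue's center of mass lies on the helix axis.
    """
    u, yp, zp = _helix_frame(tilt, azimuth)
    m_ca = mass_of("C")
    m_cb = mass_of("C")
    m_nco = mass_of("N") + mass_of("C") + mass_of("O")

    coords, names, resnames, resids, masses = [], [], [], [], []
    for i, aa in enumerate(sequence, start=1):
        t = _RISE * (i - (len(sequence) + 1) / 2)
        theta = np.deg2rad(rotation + _TWIST * (i - rotation_residue))
        dhat = np.cos(theta) * yp + np.sin(theta) * zp
        has_cb = aa != "G"
        w = (m_ca * _R_CA + (m_cb * _R_CB if has_cb else 0.0)) / m_nco
        res3 = AA_THREE[aa]
        for name, axial, radial in (
            ("N", t - 0.4, -w),
            ("CA", t, _R_CA),
            ("C", t + 0.4, -w),
            ("O", t + 0.6, -w),
        ):
            coords.append(axial * u + radial * dhat)
            names.append(name)
            resnames.append(res3)
            resids.append(i)
            masses.append(mass_of(name[0]))
        if has_cb:
            coords.append(t * u + _R_CB * dhat)
            names.append("CB")
            resnames.append(res3)
            resids.append(i)
            masses.append(m_cb)
    coords = np.array(coords)
    masses = np.array(masses)
    coords += np.asarray(com) - (coords * masses[:, None]).sum(0) / masses.sum()
    return coords, names, resnames, resids


def _sidechain_centroids(coords: np.ndarray, names, resids) -> np.ndarray:
    """Per-residue side-chain centroid: CB, or CA where there is no CB."""
    names = np.asarray(names)
    resids = np.asarray(resids)
    out = []
    for i in sorted(set(resids.tolist())):
        sel = (resids == i) & (names == "CB")
        if not sel.any():
            sel = (resids == i) & (names == "CA")
        out.append(coords[sel][0])
    return np.array(out)


def _count_contacts(cent_a: np.ndarray, cent_b: np.ndarray, box, cutoff: float = 6.5):
    """Brute-force double loop over residue pairs; minimum image in x, y."""
    pairs = []
    for i in range(len(cent_a)):
        for j in range(len(cent_b)):
            d = cent_b[j] - cent_a[i]
            for ax in (0, 1):
                L = box[ax]
                d[ax] -= L * np.round(d[ax] / L)
            if float(np.sqrt((d**2).sum())) < cutoff:
                pairs.append((i + 1, j + 1))
    return pairs


def _plan_dimer(cfg: SyntheticConfig):
    """Scan lateral separation / azimuth / z-offset for an exact contact count."""
    cx, cy = cfg.box[0] / 2, cfg.box[1] / 2
    target = cfg.dimer_contacts
    for phi_b, dz in itertools.product((270.0, 90.0, 0.0, 180.0), (0.0, 0.4, 0.8, 1.2)):
        prev = -1
        for s in np.arange(18.0, 3.0, -0.02):
            com_a = np.array([cx - s / 2, cy, cfg.peptide_z])
            com_b = np.array([cx + s / 2, cy, cfg.peptide_z + dz])
            ca, na, _, ra = build_helix_peptide(
                cfg.tilt, cfg.rotation, cfg.rotation_residue, 90.0, com_a
            )
            cb, nb, _, rb = build_helix_peptide(
                cfg.tilt, cfg.rotation, cfg.rotation_residue, phi_b, com_b
            )
            n = len(
                _count_contacts(
                    _sidechain_centroids(ca, na, ra),
                    _sidechain_centroids(cb, nb, rb),
                    cfg.box,
                )
            )
            if n == target:
                return (com_a, 90.0), (com_b, phi_b)
            if n > target and prev >= 0 and prev < target:
                break  # stepped over the target for this combo
            prev = n
    raise ConfigError(f"could not plant a dimer with exactly {target} contacts")


def _peptide_placements(cfg: SyntheticConfig):
    """Canonical (upper-leaflet) COM and azimuth per peptide in a leaflet."""
    cx, cy = cfg.box[0] / 2, cfg.box[1] / 2
    if cfg.peptides_per_leaflet == 1:
        return [(np.array([cx, cy, cfg.peptide_z]), 90.0)]
    if cfg.dimer:
        return list(_plan_dimer(cfg))
    s = cfg.peptide_separation
    return [
        (np.array([cx - s / 2, cy, cfg.peptide_z]), 90.0),
        (np.array([cx + s / 2, cy, cfg.peptide_z]), 90.0),
    ]


# -- system assembly ---------------------------------------------------------

def _lipid_sites(cfg: SyntheticConfig, rng: np.random.Generator):
    """Jittered lateral grid sites for one leaflet, species assigned."""
    n = cfg.dmpc_per_leaflet + cfg.dmpg_per_leaflet
    lx, ly = cfg.box[0], cfg.box[1]
    ncol = int(np.ceil(np.sqrt(n * lx / ly)))
    nrow = int(np.ceil(n / ncol))
    sx, sy = lx / ncol, ly / nrow
    sites = np.array(
        [((i + 0.5) * sx, (j + 0.5) * sy) for j in range(nrow) for i in range(ncol)]
    )[:n]
    species = np.array(["DMPC"] * cfg.dmpc_per_leaflet + ["DMPG"] * cfg.dmpg_per_leaflet)
    rng.shuffle(species)
    return sites, species, (sx, sy)


def _head_height(cfg: SyntheticConfig, r: np.ndarray) -> np.ndarray:
    """Planted head-group height vs lateral distance to the nearest peptide."""
    delta = cfg.thinning_delta / 2.0
    zp = cfg.z_p_target
    ramp = np.clip((r - cfg.thinning_inner) / (cfg.thinning_outer - cfg.thinning_inner), 0, 1)
    return zp - delta * (1 - ramp)


def _min_lateral(points: np.ndarray, refs: np.ndarray, box) -> np.ndarray:
    d = points[:, None, :] - refs[None, :, :]
    for ax in (0, 1):
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return np.sqrt((d**2).sum(-1)).min(axis=1)


def _build_wire(x: float, y: float, depth: float, z_p: float, sign: float):
    """Rigid vertical H-bond chain from above z_P down to an exact depth."""
    n_links = int(np.ceil((z_p + 0.5 - depth) / _WIRE_STEP))
    z_top = depth + _WIRE_STEP * n_links
    coords, names = [], []
    for k in range(n_links + 1):
        oz = z_top - _WIRE_STEP * k
        o = np.array([x, y, sign * oz])
        coords.append(o)
        names.append("OH2")
        if k < n_links:  # donate downward along the chain
            coords.append(o + np.array([0.0, 0.0, -sign * _OH]))
        else:  # deepest water: no acceptor below
            coords.append(o + np.array([_OH, 0.0, 0.0]))
        names.append("H1")
        coords.append(o + np.array([0.0, _OH, 0.0]))
        names.append("H2")
    return np.array(coords), names


def _wire_positions(cfg: SyntheticConfig):
    lx, ly = cfg.box[0], cfg.box[1]
    spots = [(lx / 4, ly / 4), (3 * lx / 4, 3 * ly / 4), (lx / 4, 3 * ly / 4), (3 * lx / 4, ly / 4)]
    if len(cfg.wire_depths) > len(spots):
        step = lx / (len(cfg.wire_depths) + 1)
        spots = [((k + 1) * step, ly / 5) for k in range(len(cfg.wire_depths))]
    return spots[: len(cfg.wire_depths)]


def generate_system(config: SyntheticConfig):
    """Build a trajectory plus its ground truth. Deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lx, ly, lz = cfg.box

    records = []  # static per-atom typing info
    base_coords = []  # noise-free template coordinates
    mol_leaflet: dict[int, str] = {}
    next_mol = 0

    # --- peptides -----------------------------------------------------------
    placements = _peptide_placements(cfg)
    pep_atoms: list[tuple[int, slice]] = []  # (molecule_id, atom span)
    pep_leaflet: dict[int, str] = {}
    planted_rows = []
    pep_res_info = {}
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        for com, azim in placements:
            coords, names, resnames, resids = build_helix_peptide(
                cfg.tilt, cfg.rotation, cfg.rotation_residue, azim, com
            )
            coords = coords.copy()
            coords[:, 2] *= sign
            start = len(base_coords)
            for (x, y, z), name, res3, ri in zip(coords, names, resnames, resids):
                element = name[0]
                records.append(
                    (len(records), next_mol, "peptide", ri, res3, name, element,
                     mass_of(element), True, "none", leaflet)
                )
                base_coords.append((x, y, z))
            pep_atoms.append((next_mol, slice(start, len(base_coords))))
            pep_leaflet[next_mol] = leaflet
            mol_leaflet[next_mol] = leaflet
            pep_res_info[next_mol] = (list(names), list(resids))
            planted_rows.append(
                dict(peptide_id=next_mol, leaflet=leaflet, z_cm=cfg.peptide_z,
                     tilt=cfg.tilt, rotation=cfg.rotation)
            )
            next_mol += 1
    planted = pd.DataFrame(planted_rows)

    # --- lipids (template only; beads are rebuilt per frame) ----------------
    lipid_info = []  # per lipid: (molecule_id, leaflet sign, site, species, atom span)
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        sites, species, spacing = _lipid_sites(cfg, rng)
        for site, sp in zip(sites, species):
            start = len(base_coords)
            for name, group, z in (
                ("L1", "L1", cfg.z_p_target + 1.0),
                ("P", "L2", cfg.z_p_target),
                ("L3", "L3", cfg.z_p_target - 1.0),
                ("L4", "L4", cfg.z_p_target - 6.0),
                ("L5", "L5", cfg.z_p_target - 10.0),
            ):
                element = "P" if name == "P" else "C"
                records.append(
                    (len(records), next_mol, sp, 1, sp, name, element,
                     mass_of(element), True, group, leaflet)
                )
                base_coords.append((site[0], site[1], sign * z))
            lipid_info.append((next_mol, sign, np.array(site), sp, slice(start, len(base_coords))))
            mol_leaflet[next_mol] = leaflet
            next_mol += 1
    lipid_spacing = spacing

    # --- waters: planted wires then sparse bulk lattice ---------------------
    wire_truth = {"upper": [], "lower": []}
    wire_xy = _wire_positions(cfg)
    water_blocks = []  # (coords, names) per molecule handled below

    def add_water_molecule(coords3, names3, leaflet):
        nonlocal next_mol
        for (x, y, z), name in zip(coords3, names3):
            element = "O" if name.startswith("O") else "H"
            records.append(
                (len(records), next_mol, "water", 1, "TIP3", name, element,
                 mass_of(element), element != "H", "none", leaflet)
            )
            base_coords.append((x, y, z))
        mol_leaflet[next_mol] = leaflet
        next_mol += 1

    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        for (wx, wy), depth in zip(wire_xy, cfg.wire_depths):
            coords, names = _build_wire(wx, wy, depth, cfg.z_p_target, sign)
            for k in range(0, len(coords), 3):
                add_water_molecule(coords[k : k + 3], names[k : k + 3], leaflet)
            wire_truth[leaflet].append(float(depth))

    # bulk lattice: O-O spacing > 4 A so no hydrogen bonds form among bulk
    z_lo, z_hi = cfg.z_p_target + 1.5, lz / 2 - 1.5
    zs = np.arange(z_lo, z_hi, cfg.water_spacing)
    nxy = int(lx / cfg.water_spacing)
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        for z in zs:
            for i in range(nxy):
                for j in range(nxy):
                    x = (i + 0.5) * lx / nxy
                    y = (j + 0.5) * ly / nxy
                    if any((x - wx) ** 2 + (y - wy) ** 2 < 4.5**2 for wx, wy in wire_xy):
                        continue
                    o = np.array([x, y, sign * z])
                    coords3 = [o, o + np.array([_OH, 0, 0]),
                               o + np.array([-0.24, 0.93, 0.0])]
                    add_water_molecule(coords3, ["OH2", "H1", "H2"], leaflet)

    # --- ions high in the water slab ---------------------------------------
    for ion_name, element, count in (("SOD", "NA", cfg.n_sodium), ("CLA", "CL", cfg.n_chloride)):
        for k in range(count):
            sign = 1.0 if k % 2 == 0 else -1.0
            leaflet = "upper" if sign > 0 else "lower"
            x = (0.5 + (k // 2)) * lx / max(1, (count + 1) // 2)
            y = ly * (0.3 if ion_name == "SOD" else 0.7)
            records.append(
                (len(records), next_mol, "ion", 1, ion_name, ion_name, element,
                 mass_of(element), True, "none", leaflet)
            )
            base_coords.append((x % lx, y, sign * (lz / 2 - 2.5)))
            mol_leaflet[next_mol] = leaflet
            next_mol += 1

    atoms = pd.DataFrame(records, columns=list(ATOM_COLUMNS))
    validate_atom_table(atoms)
    base = np.array(base_coords)
    n_atoms = len(atoms)
    masses = atoms["mass"].to_numpy()

    is_water = (atoms["molecule_kind"] == "water").to_numpy()
    is_ion = (atoms["molecule_kind"] == "ion").to_numpy()
    static = is_water | is_ion  # rigid: keeps planted H-bond geometry exact

    # --- artifact frame selection ------------------------------------------
    n_art = int(round(cfg.artifact_fraction * cfg.n_frames))
    artifact = np.zeros(cfg.n_frames, dtype=bool)
    if n_art:
        artifact[rng.choice(cfg.n_frames, size=n_art, replace=False)] = True

    pep_com_xy = {
        leaflet: np.array([
            [np.mean(base[sl, 0]), np.mean(base[sl, 1])]
            for mol, sl in pep_atoms if pep_leaflet[mol] == leaflet
        ])
        for leaflet in ("upper", "lower")
    }

    frames = np.empty((cfg.n_frames, n_atoms, 3))
    z_cm_rows, contact_rows = [], []
    for f in range(cfg.n_frames):
        coords = base.copy()

        # lipids: fresh lateral jitter, depletion, planted head height, melted tails
        for mol, sign, site, sp, sl in lipid_info:
            leaflet = "upper" if sign > 0 else "lower"
            xy = site + rng.uniform(-lipid_spacing[0] / 3, lipid_spacing[0] / 3, 2)
            refs = pep_com_xy[leaflet]
            r = _min_lateral(xy[None, :], refs, cfg.box)[0]
            if r < cfg.depletion_radius and rng.random() < cfg.depletion_strength:
                for _ in range(200):  # relocate outside the depletion zone
                    xy = np.array([rng.uniform(0, lx), rng.uniform(0, ly)])
                    r = _min_lateral(xy[None, :], refs, cfg.box)[0]
                    if r >= cfg.depletion_radius:
                        break
            zh = float(_head_height(cfg, np.array([r]))[0])
            tails = rng.uniform(2.0, max(2.5, zh - 3.0), 2)
            zvals = np.array([zh + 1.0, zh, zh - 1.0, tails[0], tails[1]])
            coords[sl, 0] = xy[0]
            coords[sl, 1] = xy[1]
            coords[sl, 2] = sign * zvals

        if cfg.noise > 0:
            jitter = rng.normal(0.0, cfg.noise, size=(n_atoms, 3))
            jitter[static] = 0.0
            coords += jitter

        if artifact[f]:
            # park the first upper-leaflet peptide on the x boundary
            mol, sl = pep_atoms[0]
            com_x = float(
                (coords[sl, 0] * masses[sl]).sum() / masses[sl].sum()
            )
            coords[sl, 0] -= com_x

        coords[:, 0] %= lx
        coords[:, 1] %= ly
        frames[f] = coords

        # per-frame ground truth from the generator's own arithmetic
        for mol, sl in pep_atoms:
            w = masses[sl]
            z = float((coords[sl, 2] * w).sum() / w.sum())
            if pep_leaflet[mol] == "lower":
                z = -z
            z_cm_rows.append(dict(frame=f, peptide_id=mol, z_cm=z))
        for leaflet in ("upper", "lower"):
            members = [(m, sl) for m, sl in pep_atoms if pep_leaflet[m] == leaflet]
            if len(members) == 2:
                cents = []
                for m, sl in members:
                    names, resids = pep_res_info[m]
                    cents.append(_sidechain_centroids(coords[sl], names, resids))
                pairs = _count_contacts(cents[0], cents[1], cfg.box)
                contact_rows.append(dict(frame=f, leaflet=leaflet, c_d=len(pairs)))

    base_pairs = {}
    for leaflet in ("upper", "lower"):
        members = [(m, sl) for m, sl in pep_atoms if pep_leaflet[m] == leaflet]
        if len(members) == 2:
            cents = []
            for m, sl in members:
                names, resids = pep_res_info[m]
                cents.append(_sidechain_centroids(base[sl], names, resids))
            base_pairs[leaflet] = _count_contacts(cents[0], cents[1], cfg.box)

    traj = Trajectory(
        atoms=atoms,
        coordinates=frames,
        boxes=np.tile(np.array(cfg.box), (cfg.n_frames, 1)),
        traj_id=cfg.seed,
    )
    truth = SyntheticGroundTruth(
        config=cfg,
        peptide_leaflet=pep_leaflet,
        molecule_leaflet=mol_leaflet,
        planted_orientation=planted,
        frame_z_cm=pd.DataFrame(z_cm_rows),
        frame_contacts=pd.DataFrame(contact_rows),
        base_contact_pairs=base_pairs,
        wire_depths=wire_truth,
        artifact_frames=artifact,
    )
    return traj, truth


# -- replica-ladder oracle ---------------------------------------------------

def generate_replica_energies(
    ladder, n_samples: int, spring_constant: float, seed: int = 0
) -> ReplicaEnsemble:
    """Harmonic-oscillator samples U = k x^2 / 2 at every ladder temperature.

    The analytic Boltzmann moment <x^2>_T = k_B T / k makes this the
    closed-form oracle for WHAM reweighting.
    """
    ladder = np.asarray(ladder, dtype=float)
    if ladder.ndim != 1 or len(ladder) < 1 or np.any(np.diff(ladder) <= 0):
        raise ConfigError("temperature ladder must be strictly increasing")
    if spring_constant <= 0:
        raise ConfigError("spring constant must be positive")
    from .constants import R_KCAL

    rng = np.random.default_rng(seed)
    xs, us, ts = [], [], []
    for T in ladder:
        sigma = np.sqrt(R_KCAL * T / spring_constant)
        x = rng.normal(0.0, sigma, n_samples)
        xs.append(x)
        us.append(0.5 * spring_constant * x**2)
        ts.append(np.full(n_samples, T))
    return ReplicaEnsemble(
        temperatures=np.concatenate(ts),
        energies=np.concatenate(us),
        ladder=ladder,
        payload=np.concatenate(xs),
    )


# -- secondary-structure label fixture ---------------------------------------

SECONDARY_CODES = ("H", "G", "I", "T", "C")


def emit_secondary_labels(
    probabilities,
    n_frames: int,
    peptides=(0, 1, 2, 3),
    residues=range(1, 22),
    seed: int = 0,
    path=None,
) -> pd.DataFrame:
    """Draw per-frame per-residue one-letter secondary-structure codes.

    ``probabilities`` maps code -> probability, either one dict for all
    residues or a per-residue mapping ``{residue: {code: p}}``.
    """
    residues = list(residues)
    if all(isinstance(v, dict) for v in probabilities.values()):
        per_res = {int(r): dict(v) for r, v in probabilities.items()}
    else:
        per_res = {r: dict(probabilities) for r in residues}
    for r in residues:
        if r not in per_res:
            raise ConfigError(f"no probabilities for residue {r}")
        total = sum(per_res[r].values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"probabilities for residue {r} sum to {total}, not 1")

    rng = np.random.default_rng(seed)
    rows = []
    for r in residues:
        codes = list(per_res[r])
        p = np.array([per_res[r][c] for c in codes])
        draws = rng.choice(len(codes), size=(n_frames, len(peptides)), p=p)
        for f in range(n_frames):
            for ip, pep in enumerate(peptides):
                rows.append((f, pep, r, codes[draws[f, ip]]))
    df = pd.DataFrame(rows, columns=["frame", "peptide", "residue", "code"])
    df = df.sort_values(["frame", "peptide", "residue"], ignore_index=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df
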