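"""Cylindrical density maps, bilayer boundary/thinning, and lipid regions.

The volume number density n(r, z) of lipid heavy atoms (or water) is
accumulated around each peptide center of mass as a function of the
lateral minimum-image distance r and the depth z above the midplane,
permuting leaflets and peptides so every (leaflet, peptide) choice
contributes one symmetry copy with the reference at r = 0 and outward
normal +z. Cell volumes are annular: 2 pi r dr dz (exact for the
annulus).

The bilayer boundary z_b(r) is the half-maximum point of each r column
against the distant-region plateau; the thickness is D(r) = 2 z_b(r)
and the thinning is Delta D = D(distant) - D(near).

Lipids (represented by their phosphorus atoms) are classified by the
lateral distance to the nearest same-leaflet peptide center of mass:
near (r < 6 A), proximal (6 < r < 21.5 A), distant (r > 21.5 A), with
region areas obtained by Monte-Carlo integration of the same rule over
the periodic cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError, EmptySampleError
from .geometry import mass_weighted_com, min_image_displacement
from .model import BilayerGeometry, SimulationFrame, Trajectory

_AREA_MC_SEED = 1234  # fixed internal seed for area integration


@dataclass
class DensityGrid:
    """Binned n(r, z) in A^-3 with per-cell sample counts."""

    r_edges: np.ndarray
    z_edges: np.ndarray
    values: np.ndarray  # (n_r, n_z)
    counts: np.ndarray
    species: str

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def cell_volumes(self) -> np.ndarray:
        dr = np.diff(self.r_edges)
        dz = np.diff(self.z_edges)
        return 2 * np.pi * self.r_centers[:, None] * dr[:, None] * dz[None, :]

    def to_long(self) -> pd.DataFrame:
        r, z = np.meshgrid(self.r_centers, self.z_centers, indexing="ij")
        return pd.DataFrame(
            dict(r=r.ravel(), z=z.ravel(), n=self.values.ravel())
        )

    def to_matrix(self, path) -> None:
        """Plain-text matrix (rows = r bins, columns = z bins) for plotting."""
        header = "r\\z " + " ".join(f"{z:.3f}" for z in self.z_centers)
        lines = [header] + [
            f"{r:.3f} " + " ".join(f"{v:.6g}" for v in row)
            for r, row in zip(self.r_centers, self.values)
        ]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class BoundaryProfile:
    """z_b(r) and D(r) = 2 z_b(r); NaN where the column never crosses."""

    r_centers: np.ndarray
    z_b: np.ndarray
    plateau: float

    @property
    def D(self) -> np.ndarray:
        return 2.0 * self.z_b


def _peptide_com_xy(traj: Trajectory, frame: SimulationFrame, peptide_id: int) -> np.ndarray:
    idx = traj.atom_index(molecule_kind="peptide", molecule_id=peptide_id, is_heavy=True)
    masses = traj.atoms["mass"].to_numpy()[idx]
    return mass_weighted_com(frame.coordinates[idx], masses)[:2]


def density_map(
    traj: Trajectory,
    species: str = "lipid",
    geometry: BilayerGeometry | None = None,
    r_max: float = 25.0,
    dr: float = 1.0,
    dz: float = 0.5,
    z_max: float = 30.0,
) -> DensityGrid:
    """Accumulate n(r, z) over all (leaflet, peptide) reference choices."""
    geometry = geometry or BilayerGeometry()
    if r_max > float(np.min(traj.boxes[:, :2])) / np.sqrt(2.0):
        raise ConfigError("r_max exceeds half the box diagonal")
    if species == "lipid":
        sel = traj.atom_index(molecule_kind=("DMPC", "DMPG"), is_heavy=True)
    elif species == "water":
        sel = traj.atom_index(molecule_kind="water", is_heavy=True)
    else:
        sel = traj.atom_index(molecule_kind=species, is_heavy=True)

    r_edges = np.arange(0.0, r_max + dr, dr)
    z_edges = np.arange(0.0, z_max + dz, dz)
    counts = np.zeros((len(r_edges) - 1, len(z_edges) - 1))
    w = traj.effective_weights
    if w.sum() <= 0:
        raise EmptySampleError("all frames excluded")

    total_ref_weight = 0.0
    for f in range(traj.n_frames):
        if w[f] == 0:
            continue
        frame = traj.frame(f)
        coords = frame.coordinates[sel] if len(sel) else np.empty((0, 3))
        for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
            for pid in traj.peptide_ids(leaflet):
                com = _peptide_com_xy(traj, frame, pid)
                total_ref_weight += w[f]
                if len(coords) == 0:
                    continue
                disp = min_image_displacement(
                    np.array([com[0], com[1], 0.0]), coords, frame.box
                )
                r = np.sqrt(disp[:, 0] ** 2 + disp[:, 1] ** 2)
                z = sign * coords[:, 2]
                h, _, _ = np.histogram2d(
                    r, z, bins=(r_edges, z_edges), weights=np.full(len(r), w[f])
                )
                counts += h
    if total_ref_weight == 0:
        raise EmptySampleError("no peptide reference choices available")
    dr_arr = np.diff(r_edges)
    dz_arr = np.diff(z_edges)
    r_cent = 0.5 * (r_edges[:-1] + r_edges[1:])
    volumes = 2 * np.pi * r_cent[:, None] * dr_arr[:, None] * dz_arr[None, :]
    values = counts / (volumes * total_ref_weight)
    return DensityGrid(r_edges, z_edges, values, counts, species)


def bilayer_boundary(
    grid: DensityGrid,
    geometry: BilayerGeometry | None = None,
    threshold_fraction: float = 0.5,
    plateau_z_band: tuple[float, float] = (2.0, 12.0),
) -> BoundaryProfile:
    """Half-maximum bilayer boundary per r column.

    The plateau is the mean density over distant-region cells within
    ``plateau_z_band``; z_b(r) is the first z (ascending, linear
    interpolation between bin centers) where the column falls below
    ``threshold_fraction`` times the plateau.
    """
    geometry = geometry or BilayerGeometry()
    rc, zc = grid.r_centers, grid.z_centers
    core = (rc[:, None] > geometry.distant_radius) & (
        (zc[None, :] >= plateau_z_band[0]) & (zc[None, :] <= plateau_z_band[1])
    )
    if not core.any():
        raise CoverageError("no distant-region core cells in the grid")
    plateau = float(grid.values[core].mean())
    if plateau <= 0:
        raise CoverageError("distant-region plateau density is zero")
    level = threshold_fraction * plateau

    z_b = np.full(len(rc), np.nan)
    for i in range(len(rc)):
        col = grid.values[i]
        above = col >= level
        if not above.any():
            continue
        last = np.max(np.flatnonzero(above))
        if last == len(col) - 1:
            continue  # never crosses within the grid
        z0, z1 = zc[last], zc[last + 1]
        v0, v1 = col[last], col[last + 1]
        z_b[i] = z0 + (v0 - level) / (v0 - v1) * (z1 - z0) if v0 != v1 else z1
    return BoundaryProfile(r_centers=rc, z_b=z_b, plateau=plateau)


def thinning(profile: BoundaryProfile, geometry: BilayerGeometry | None = None) -> float:
    """Delta D = mean D(r) in the distant region minus the near region."""
    geometry = geometry or BilayerGeometry()
    near = profile.r_centers < geometry.near_radius
    distant = profile.r_centers > geometry.distant_radius
    d_near = profile.D[near]
    d_dist = profile.D[distant]
    if np.all(np.isnan(d_near)) or np.all(np.isnan(d_dist)):
        raise CoverageError("boundary undefined in the near or distant region")
    return float(np.nanmean(d_dist) - np.nanmean(d_near))


# -- lipid regions -----------------------------------------------------------

REGIONS = ("near", "proximal", "distant")


def _classify_r(r: np.ndarray, geometry: BilayerGeometry) -> np.ndarray:
    out = np.where(
        r < geometry.near_radius,
        "near",
        np.where(r <= geometry.distant_radius, "proximal", "distant"),
    )
    return out


def classify_lipid_regions(
    traj: Trajectory, frame: SimulationFrame, geometry: BilayerGeometry | None = None
) -> pd.DataFrame:
    """Region label per lipid: lateral distance to nearest same-leaflet peptide."""
    geometry = geometry or BilayerGeometry()
    rows = []
    for leaflet in ("upper", "lower"):
        pep_xy = np.array(
            [_peptide_com_xy(traj, frame, pid) for pid in traj.peptide_ids(leaflet)]
        )
        pidx = traj.atom_index(
            molecule_kind=("DMPC", "DMPG"), lipid_group="L2", leaflet=leaflet
        )
        if len(pidx) == 0:
            continue
        sub = traj.atoms.iloc[pidx]
        pts = frame.coordinates[pidx]
        if len(pep_xy) == 0:
            r = np.full(len(pidx), np.inf)
        else:
            disp = min_image_displacement(
                pts[:, None, :],
                np.column_stack([pep_xy, np.zeros(len(pep_xy))])[None, :, :],
                frame.box,
            )
            r = np.sqrt(disp[..., 0] ** 2 + disp[..., 1] ** 2).min(axis=1)
        labels = _classify_r(r, geometry)
        for k in range(len(pidx)):
            rows.append(
                dict(
                    molecule_id=int(sub.iloc[k]["molecule_id"]),
                    kind=sub.iloc[k]["molecule_kind"],
                    leaflet=leaflet,
                    r=float(r[k]),
                    region=labels[k],
                )
            )
    return pd.DataFrame(rows)


def region_areas(
    peptide_xy: np.ndarray,
    box,
    geometry: BilayerGeometry | None = None,
    n_samples: int = 20000,
    seed: int = _AREA_MC_SEED,
) -> dict:
    """Monte-Carlo areas of the near/proximal/distant partition of the cell.

    The three areas sum exactly to Lx * Ly because every sample point
    lands in exactly one region.
    """
    geometry = geometry or BilayerGeometry()
    rng = np.random.default_rng(seed)
    lx, ly = float(box[0]), float(box[1])
    pts = rng.uniform(0, 1, size=(n_samples, 2)) * np.array([lx, ly])
    if len(peptide_xy) == 0:
        return {"near": 0.0, "proximal": 0.0, "distant": lx * ly}
    pts3 = np.column_stack([pts, np.zeros(n_samples)])
    refs = np.column_stack([np.asarray(peptide_xy), np.zeros(len(peptide_xy))])
    disp = min_image_displacement(pts3[:, None, :], refs[None, :, :], box)
    r = np.sqrt(disp[..., 0] ** 2 + disp[..., 1] ** 2).min(axis=1)
    labels = _classify_r(r, geometry)
    total = lx * ly
    return {reg: total * float((labels == reg).mean()) for reg in REGIONS}


@dataclass
class RegionDensityTable:
    """Surface number densities per region (A^-2), Table-1 style."""

    table: pd.DataFrame  # region, n_s_l, n_s_DMPG, n_s_DMPC, area, SE columns

    def value(self, region: str, column: str) -> float:
        return float(self.table.set_index("region").loc[region, column])

    def derived_ratios(self) -> dict:
        """Headline statistics: near DMPC:DMPG ratio and near-vs-distant drop."""
        near_pc = self.value("near", "n_s_DMPC")
        near_pg = self.value("near", "n_s_DMPG")
        near_l = self.value("near", "n_s_l")
        dist_l = self.value("distant", "n_s_l")
        return {
            "near_dmpc_dmpg_ratio": near_pc / near_pg,
            "near_vs_distant_drop_percent": 100.0 * (1.0 - near_l / dist_l),
        }


def combine_region_tables(tables) -> RegionDensityTable:
    """Mean +- SE over independent trajectories (SE = s/sqrt(n), n >= 2)."""
    if len(tables) < 2:
        raise ConfigError("need at least 2 trajectory tables for standard errors")
    cols = ("n_s_l", "n_s_DMPG", "n_s_DMPC", "area")
    rows = []
    for reg in REGIONS:
        row = dict(region=reg)
        for col in cols:
            vals = np.array([t.value(reg, col) for t in tables])
            row[col] = float(vals.mean())
            row[col + "_SE"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        rows.append(row)
    return RegionDensityTable(table=pd.DataFrame(rows))


def surface_densities(
    traj: Trajectory,
    geometry: BilayerGeometry | None = None,
    area_samples: int = 20000,
) -> RegionDensityTable:
    """Weighted-mean phosphorus surface densities per region and species."""
    geometry = geometry or BilayerGeometry()
    w = traj.effective_weights
    if w.sum() <= 0:
        raise EmptySampleError("all frames excluded")
    acc = {reg: dict(w=0.0, l=0.0, pg=0.0, pc=0.0, area=0.0) for reg in REGIONS}
    for f in range(traj.n_frames):
        if w[f] == 0:
            continue
        frame = traj.frame(f)
        classified = classify_lipid_regions(traj, frame, geometry)
        for leaflet in ("upper", "lower"):
            pep_xy = np.array(
                [_peptide_com_xy(traj, frame, pid) for pid in traj.peptide_ids(leaflet)]
            )
            areas = region_areas(pep_xy, frame.box, geometry, n_samples=area_samples)
            sub = classified[classified["leaflet"] == leaflet]
            for reg in REGIONS:
                area = areas[reg]
                if area <= 0:
                    continue  # zero-area region: skip this frame for it
                grp = sub[sub["region"] == reg]
                n_pg = (grp["kind"] == "DMPG").sum()
                n_pc = (grp["kind"] == "DMPC").sum()
                a = acc[reg]
                a["w"] += w[f]
                a["l"] += w[f] * (n_pg + n_pc) / area
                a["pg"] += w[f] * n_pg / area
                a["pc"] += w[f] * n_pc / area
                a["area"] += w[f] * area
    rows = []
    for reg in REGIONS:
        a = acc[reg]
        if a["w"] == 0:
            rows.append(dict(region=reg, n_s_l=np.nan, n_s_DMPG=np.nan,
                             n_s_DMPC=np.nan, area=np.nan))
            continue
        rows.append(
            dict(
                region=reg,
                n_s_l=a["l"] / a["w"],
                n_s_DMPG=a["pg"] / a["w"],
                n_s_DMPC=a["pc"] / a["w"],
                area=a["area"] / a["w"],
            )
        )
    return RegionDensityTable(table=pd.DataFrame(rows))
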