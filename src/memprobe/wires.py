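"""Water-wire detection: hydrogen-bonded chains penetrating the bilayer.

A hydrogen bond between water oxygens D (donor) and A (acceptor)
requires d(D-A) < 4 A and an angle D-H...A above 150 deg (minimum image
in x, y). A water wire is a connected component of the undirected
hydrogen-bond graph that contains at least one water below the
phosphorus plane z_P and at least one at or above it (connection to
bulk); its depth is the smallest member oxygen z below z_P.

Only waters with oxygen z below z_P + a 4 A bulk buffer enter the
graph, which keeps bulk connectivity decidable locally.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptySampleError, TypingError
from .geometry import min_image_displacement
from .model import BilayerGeometry, SimulationFrame, Trajectory

HB_DISTANCE = 4.0
HB_ANGLE = 150.0
BULK_BUFFER = 4.0


@dataclass
class WaterWire:
    members: tuple  # water molecule ids
    depth: float
    leaflet: str


def _water_arrays(traj: Trajectory, water_idx: np.ndarray):
    """Group selected water atom indices into (mol_id, O index, H indices)."""
    sub = traj.atoms.iloc[water_idx]
    out = []
    for mol_id, grp in sub.groupby("molecule_id"):
        names = grp["atom_name"].str.upper()
        o_rows = grp.index[names.str.startswith("O")]
        h_rows = grp.index[names.str.startswith("H")]
        if len(o_rows) != 1 or len(h_rows) != 2:
            raise TypingError(f"water molecule {mol_id} must have one O and two H atoms")
        out.append(
            (
                int(mol_id),
                int(traj.atoms.index.get_indexer(o_rows)[0]),
                traj.atoms.index.get_indexer(h_rows),
            )
        )
    return out


def hydrogen_bonds(
    traj: Trajectory,
    frame: SimulationFrame,
    water_mol_ids=None,
    distance_cutoff: float = HB_DISTANCE,
    angle_cutoff: float = HB_ANGLE,
) -> pd.DataFrame:
    """All directed O-H...O bonds among the selected waters.

    Returns columns donor, acceptor (molecule ids), distance, angle.
    """
    idx = traj.atom_index(molecule_kind="water")
    if water_mol_ids is not None:
        sel = traj.atoms["molecule_id"].isin(water_mol_ids).to_numpy()
        idx = idx[sel[idx]]
    waters = _water_arrays(traj, idx)
    if not waters:
        return pd.DataFrame(columns=["donor", "acceptor", "distance", "angle"])

    coords = frame.coordinates
    box = frame.box
    o_pos = np.array([coords[o] for _, o, _ in waters])
    wrapped = o_pos.copy()
    wrapped[:, 0] %= box[0]
    wrapped[:, 1] %= box[1]
    zspan = max(1.0, float(np.ptp(o_pos[:, 2]))) * 10 + 100
    tree = cKDTree(
        np.column_stack([wrapped[:, 0], wrapped[:, 1], wrapped[:, 2] - wrapped[:, 2].min()]),
        boxsize=[box[0], box[1], zspan],
    )
    candidate = tree.query_pairs(distance_cutoff, output_type="ndarray")

    rows = []
    for i, j in candidate:
        d_vec = min_image_displacement(o_pos[i], o_pos[j], box)
        dist = float(np.linalg.norm(d_vec))
        if dist >= distance_cutoff:
            continue
        for donor, acceptor, sign in ((i, j, 1.0), (j, i, -1.0)):
            _, o_d, h_rows = waters[donor]
            a_pos = o_pos[donor] + sign * d_vec
            for h in h_rows:
                h_pos = coords[h]
                v1 = coords[o_d] - h_pos
                v2 = a_pos - h_pos
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if ang > angle_cutoff:
                    rows.append(
                        dict(
                            donor=waters[donor][0],
                            acceptor=waters[acceptor][0],
                            distance=dist,
                            angle=ang,
                        )
                    )
    return pd.DataFrame(rows, columns=["donor", "acceptor", "distance", "angle"])


def find_water_wires(
    traj: Trajectory,
    frame: SimulationFrame,
    geometry: BilayerGeometry | None = None,
) -> list[WaterWire]:
    """Connected H-bond components linking sub-z_P waters to bulk, per leaflet."""
    geometry = geometry or BilayerGeometry()
    wires: list[WaterWire] = []
    water_idx = traj.atom_index(molecule_kind="water")
    sub = traj.atoms.iloc[water_idx]
    coords = frame.coordinates
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        leaf = sub[sub["leaflet"] == leaflet]
        o_rows = leaf.index[leaf["atom_name"].str.upper().str.startswith("O")]
        o_idx = traj.atoms.index.get_indexer(o_rows)
        mol_ids = leaf.loc[o_rows, "molecule_id"].to_numpy()
        depth_z = sign * coords[o_idx, 2]  # canonical: positive into this leaflet's water
        in_graph = depth_z < geometry.z_P + BULK_BUFFER
        if not in_graph.any():
            continue
        graph_ids = mol_ids[in_graph]
        bonds = hydrogen_bonds(traj, frame, water_mol_ids=set(graph_ids.tolist()))
        g = nx.Graph()
        g.add_nodes_from(graph_ids.tolist())
        for _, row in bonds.iterrows():
            g.add_edge(int(row["donor"]), int(row["acceptor"]))
        z_of = dict(zip(mol_ids.tolist(), depth_z.tolist()))
        for comp in nx.connected_components(g):
            zs = np.array([z_of[m] for m in comp])
            below = zs[zs < geometry.z_P]
            if len(below) and (zs >= geometry.z_P).any():
                wires.append(
                    WaterWire(
                        members=tuple(sorted(comp)),
                        depth=float(below.min()),
                        leaflet=leaflet,
                    )
                )
    return wires


def wire_penetration_profile(
    traj: Trajectory,
    geometry: BilayerGeometry | None = None,
    bin_width: float = 0.5,
    per_frame_deepest: bool = False,
):
    """Cumulative penetration probability P_ww(z) and the median wire depth.

    P_ww(z) is the weighted fraction of wires (pooled over frames and
    leaflets) with depth <= z; the median is the smallest z with
    P_ww >= 0.5. ``per_frame_deepest`` switches to pooling only each
    frame's deepest wire.
    """
    w = traj.effective_weights
    depths, weights = [], []
    for f in range(traj.n_frames):
        if w[f] == 0:
            continue
        frame_wires = find_water_wires(traj, traj.frame(f), geometry)
        ds = [wire.depth for wire in frame_wires]
        if per_frame_deepest and ds:
            ds = [min(ds)]
        depths.extend(ds)
        weights.extend([w[f]] * len(ds))
    if not depths:
        raise EmptySampleError("no water wires found")
    depths = np.asarray(depths)
    weights = np.asarray(weights)
    order = np.argsort(depths)
    depths, weights = depths[order], weights[order]
    cum = np.cumsum(weights) / weights.sum()
    median = float(depths[np.searchsorted(cum, 0.5)])

    z_edges = np.arange(0.0, depths.max() + bin_width, bin_width)
    p_ww = np.array(
        [weights[depths <= z].sum() / weights.sum() for z in z_edges]
    )
    profile = pd.DataFrame(dict(z=z_edges, P_ww=p_ww))
    assert np.all(np.diff(profile["P_ww"]) >= -1e-12), "P_ww must be monotone"
    return profile, median
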