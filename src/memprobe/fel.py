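"""Free-energy landscapes, state partitioning, and the dimer equilibrium.

The 2D surface G(z_DCM, C_d) = -RT ln P is built from the depth of the
two-peptide center of mass and the interpeptide contact count; basins
are found by steepest descent on the sampled grid and saddles by
union-find flooding in ascending G (the G at which two basins first
connect). States: the basin whose minimum has C_d = 0 is the inserted
monomer IM; basins with minima at C_d >= dimer_threshold are mature
dimers D; contact-bearing cells in between are nascent dimers.

The monomer-dimer equilibrium free energy follows

    Delta G_d = -RT ln(c0 V P_d / P_m^2)

with V the simulation volume available to the pair, made dimensionless
through c0 V N_A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AVOGADRO, LITRE_PER_A3, R_KCAL
from .errors import ConfigError, EmptySampleError

STATES = ("IM", "nascent", "D")


def weighted_histogram(values, weights=None, bins=50, range=None):
    """Normalized probability-mass histogram (1D or 2D).

    ``values`` is (n,) for 1D or (n, 2) for 2D; ``bins``/``range``
    follow numpy semantics. Returns ``(P, edges)`` with P summing to 1.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones(len(values))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ConfigError("weights must be >= 0")
    if weights.sum() == 0:
        raise EmptySampleError("all weights zero")
    if values.ndim == 1:
        h, edges = np.histogram(values, bins=bins, range=range, weights=weights)
        return h / h.sum(), edges
    h, xe, ye = np.histogram2d(
        values[:, 0], values[:, 1], bins=bins, range=range, weights=weights
    )
    return h / h.sum(), (xe, ye)


def integer_bins(values: np.ndarray) -> np.ndarray:
    """Bin edges that put each integer in its own bin."""
    lo, hi = int(np.floor(values.min())), int(np.ceil(values.max()))
    return np.arange(lo - 0.5, hi + 1.5, 1.0)


@dataclass
class FESurface:
    """G(z_DCM, C_d) in kcal/mol on sampled cells, offset so min G = 0."""

    z_edges: np.ndarray
    cd_edges: np.ndarray
    P: np.ndarray
    G: np.ndarray  # NaN on unsampled cells
    temperature: float

    @property
    def sampled(self) -> np.ndarray:
        return self.P > 0

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def cd_centers(self) -> np.ndarray:
        return 0.5 * (self.cd_edges[:-1] + self.cd_edges[1:])


def free_energy_surface(P, edges, temperature: float) -> FESurface:
    """G = -RT ln P on sampled cells, shifted to min 0; NaN elsewhere."""
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
        z_edges, cd_edges = np.asarray(edges), np.array([-0.5, 0.5])
    else:
        z_edges, cd_edges = (np.asarray(e) for e in edges)
    total = P.sum()
    if total <= 0:
        raise EmptySampleError("empty probability surface")
    P = P / total
    G = np.full_like(P, np.nan)
    mask = P > 0
    G[mask] = -R_KCAL * temperature * np.log(P[mask])
    G = G - np.nanmin(G)
    return FESurface(z_edges, cd_edges, P, G, temperature)


@dataclass
class StatePartition:
    """Per-cell basin/state labels plus saddles and barriers."""

    basin: np.ndarray  # int per cell, -1 unsampled
    state: np.ndarray  # str per cell, 'unassigned' where unsampled
    minima: list  # (i, j) per basin
    saddles: dict  # frozenset({basin_a, basin_b}) -> G_dagger
    state_saddles: dict  # frozenset({state_a, state_b}) -> lowest G_dagger
    barriers: dict  # (state_from, state_to) -> Delta G_dagger


def _neighbors(i, j, shape):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                yield ni, nj


def _steepest_descent_basins(G: np.ndarray, sampled: np.ndarray):
    """Assign each sampled cell to a local minimum by 8-neighbor descent."""
    shape = G.shape
    order_key = np.full(shape, np.inf)
    order_key[sampled] = G[sampled]
    downhill = {}
    minima = []
    minimum_of = {}
    for i in range(shape[0]):
        for j in range(shape[1]):
            if not sampled[i, j]:
                continue
            best, best_g = (i, j), G[i, j]
            for ni, nj in _neighbors(i, j, shape):
                if sampled[ni, nj] and (
                    G[ni, nj] < best_g
                    or (G[ni, nj] == best_g and (ni, nj) < best)
                ):
                    best, best_g = (ni, nj), G[ni, nj]
            downhill[(i, j)] = best
            if best == (i, j):
                minimum_of[(i, j)] = len(minima)
                minima.append((i, j))
    basin = np.full(shape, -1, dtype=int)
    for i in range(shape[0]):
        for j in range(shape[1]):
            if not sampled[i, j]:
                continue
            path = [(i, j)]
            cur = (i, j)
            while downhill[cur] != cur:
                cur = downhill[cur]
                path.append(cur)
            b = minimum_of[cur]
            for cell in path:
                basin[cell] = b
    return basin, minima


def _flood_saddles(G: np.ndarray, sampled: np.ndarray, basin: np.ndarray):
    """Union-find flooding: G at which two basins first connect."""
    cells = sorted(
        [(i, j) for i in range(G.shape[0]) for j in range(G.shape[1]) if sampled[i, j]],
        key=lambda c: (G[c], c),
    )
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    root_basins = {}
    saddles = {}
    active = set()
    for cell in cells:
        parent[cell] = cell
        root_basins[cell] = {int(basin[cell])}
        for nb in _neighbors(*cell, G.shape):
            if nb not in active:
                continue
            ra, rb = find(cell), find(nb)
            if ra == rb:
                continue
            ba, bb = root_basins[ra], root_basins[rb]
            for x in ba:
                for y in bb:
                    if x != y:
                        key = frozenset((x, y))
                        if key not in saddles:
                            saddles[key] = float(G[cell])
            parent[rb] = ra
            root_basins[ra] = ba | bb
        active.add(cell)
    return saddles


def partition_states(surface: FESurface, dimer_threshold: float = 8.0) -> StatePartition:
    """Basins, saddles, and IM / nascent / D labels on the sampled grid."""
    G, sampled = surface.G, surface.sampled
    if not sampled.any():
        raise EmptySampleError("no sampled cells on the surface")
    basin, minima = _steepest_descent_basins(G, sampled)
    saddles = _flood_saddles(G, sampled, basin)

    cd = surface.cd_centers
    basin_state = []
    for (i, j) in minima:
        c = cd[j]
        if c >= dimer_threshold:
            basin_state.append("D")
        elif c >= 1:
            basin_state.append("nascent")
        else:
            basin_state.append("IM")

    state = np.full(G.shape, "unassigned", dtype=object)
    for i in range(G.shape[0]):
        for j in range(G.shape[1]):
            b = basin[i, j]
            if b < 0:
                continue
            s = basin_state[b]
            if s == "IM" and cd[j] >= 1:
                s = "nascent"  # contact-bearing cells of the monomer basin
            state[i, j] = s

    # lowest saddle between each pair of states
    state_saddles: dict = {}
    for key, g in saddles.items():
        a, b = tuple(key)
        sa, sb = basin_state[a], basin_state[b]
        if sa == sb:
            continue
        skey = frozenset((sa, sb))
        if skey not in state_saddles or g < state_saddles[skey]:
            state_saddles[skey] = g

    barriers = {}
    g_min = {}
    for b, (i, j) in enumerate(minima):
        s = basin_state[b]
        g_min[s] = min(g_min.get(s, np.inf), float(G[i, j]))
    for skey, g in state_saddles.items():
        a, b = tuple(skey)
        barriers[(a, b)] = g - g_min[a]
        barriers[(b, a)] = g - g_min[b]
    return StatePartition(basin, state, minima, saddles, state_saddles, barriers)


@dataclass
class StateSummary:
    """Per-state probabilities, free energies, barriers, and observables."""

    table: pd.DataFrame  # state, P, G, H, gamma, beta, z_cm
    barriers: dict

    def value(self, state: str, column: str) -> float:
        return float(self.table.set_index("state").loc[state, column])


def state_of_frames(
    surface: FESurface,
    partition: StatePartition,
    z_dcm: np.ndarray,
    c_d: np.ndarray,
) -> np.ndarray:
    """Map per-frame (z_DCM, C_d) samples to state labels via their cell."""
    iz = np.clip(np.digitize(z_dcm, surface.z_edges) - 1, 0, len(surface.z_centers) - 1)
    ic = np.clip(np.digitize(c_d, surface.cd_edges) - 1, 0, len(surface.cd_centers) - 1)
    return np.array([str(partition.state[i, j]) for i, j in zip(iz, ic)])


def state_statistics(
    states: np.ndarray,
    weights: np.ndarray,
    temperature: float,
    observables: pd.DataFrame | None = None,
    barriers: dict | None = None,
) -> StateSummary:
    """P(k), G(k) = -RT ln[P(k)/P(IM)], and per-state observable means.

    ``observables`` columns are averaged per state with the same weights.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise EmptySampleError("all weights zero")
    total = weights.sum()
    rows = []
    p_im = weights[states == "IM"].sum() / total
    for k in STATES:
        sel = states == k
        p = weights[sel].sum() / total
        if p > 0 and p_im > 0:
            g = -R_KCAL * temperature * np.log(p / p_im)
        else:
            g = np.nan
        row = dict(state=k, P=p, G=g)
        if observables is not None:
            for col in observables.columns:
                vals = observables[col].to_numpy()[sel]
                wsel = weights[sel]
                ok = np.isfinite(vals)
                row[col] = (
                    float((wsel[ok] * vals[ok]).sum() / wsel[ok].sum())
                    if ok.any() and wsel[ok].sum() > 0
                    else np.nan
                )
        rows.append(row)
    return StateSummary(table=pd.DataFrame(rows), barriers=dict(barriers or {}))


def dimerization_free_energy(
    P_m: float,
    P_d: float,
    V: float,
    T: float,
    c0: float = 1.0,
) -> float:
    """Delta G_d = -RT ln(c0 V P_d / P_m^2) in kcal/mol.

    ``V`` in cubic Angstrom, ``c0`` in mol/L; c0 V is made dimensionless
    via Avogadro's number.
    """
    if not (0 < P_m < 1):
        raise ConfigError("P_m must lie strictly between 0 and 1")
    if P_d <= 0:
        raise ConfigError("P_d must be positive")
    if V <= 0 or T <= 0:
        raise ConfigError("V and T must be positive")
    c0_v = c0 * V * LITRE_PER_A3 * AVOGADRO
    return float(-R_KCAL * T * np.log(c0_v * P_d / P_m**2))


def trajectory_standard_error(per_trajectory_values) -> tuple[float, float]:
    """Mean over trajectory means and SE = s / sqrt(n) (independent samples)."""
    vals = np.asarray(per_trajectory_values, dtype=float)
    if len(vals) < 2:
        raise ConfigError("need at least 2 trajectories for a standard error")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))
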