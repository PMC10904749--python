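"""Helicity observables from external per-residue secondary-structure labels.

Labels are one-letter codes (STRIDE alphabet) supplied as a table with
columns ``frame, peptide, residue, code``; a residue counts as helical
in a frame if its code is alpha- (H), 3-10- (G), or pi-helix (I). The
assignment algorithm itself is out of scope — labels are consumed, not
produced. ``stride_to_csv`` converts STRIDE's native ``ASG`` output into
the CSV schema as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError

HELIX_CODES = frozenset("HGI")
TURN_CODES = frozenset("T")
COIL_CODES = frozenset("C")


@dataclass
class HelicityProfile:
    """Per-residue helix/turn/coil fractions plus region aggregates."""

    per_residue: pd.DataFrame  # residue, H, turn, coil, other, SE
    H_overall: float
    H_nt: float
    H_ct: float
    turn_fraction: float
    coil_fraction: float

    def helical_residue_count(self, threshold: float = 0.5) -> int:
        """Number of residues classified helical, i.e. with H(i) > threshold."""
        return int((self.per_residue["H"] > threshold).sum())


def read_label_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"frame", "peptide", "residue", "code"} - set(df.columns)
    if missing:
        raise ConfigError(f"label table missing columns: {sorted(missing)}")
    return df


def aggregate_secondary(
    labels: pd.DataFrame,
    weights: np.ndarray | None = None,
    residues=range(1, 22),
    nt_region: tuple[int, int] = (1, 11),
    ct_region: tuple[int, int] = (12, 21),
    traj_ids: pd.Series | None = None,
) -> HelicityProfile:
    """Aggregate labels into the helicity profile.

    ``weights`` is an optional per-frame weight vector indexed by the
    ``frame`` column (frames absent from it raise). ``traj_ids`` may map
    each frame to a trajectory id; per-residue standard errors are then
    computed over trajectory means (independent-trajectory errors),
    otherwise SE is left at NaN.
    """
    residues = list(residues)
    peptides = sorted(labels["peptide"].unique())
    frames = sorted(labels["frame"].unique())
    expected = len(frames) * len(peptides) * len(residues)
    covered = labels[labels["residue"].isin(residues)]
    if len(covered.drop_duplicates(["frame", "peptide", "residue"])) < expected:
        have = set(map(tuple, covered[["frame", "peptide", "residue"]].to_numpy()))
        gaps = [
            (f, p, r)
            for f in frames
            for p in peptides
            for r in residues
            if (f, p, r) not in have
        ]
        raise CoverageError(f"missing label entries, first gaps: {gaps[:5]}")

    df = covered.copy()
    if weights is None:
        df["w"] = 1.0
    else:
        weights = np.asarray(weights, dtype=float)
        df["w"] = weights[df["frame"].to_numpy()]
    if df["w"].sum() <= 0:
        raise ConfigError("label weights sum to zero")

    code = df["code"].astype(str).str.upper()
    df["is_H"] = code.isin(HELIX_CODES)
    df["is_T"] = code.isin(TURN_CODES)
    df["is_C"] = code.isin(COIL_CODES)
    df["is_other"] = ~(df["is_H"] | df["is_T"] | df["is_C"])

    def frac(sub: pd.DataFrame, col: str) -> float:
        return float((sub["w"] * sub[col]).sum() / sub["w"].sum())

    rows = []
    for r in residues:
        sub = df[df["residue"] == r]
        se = np.nan
        if traj_ids is not None:
            tid = np.asarray(traj_ids)[sub["frame"].to_numpy()]
            means = [
                frac(sub[tid == t], "is_H") for t in np.unique(tid)
            ]
            if len(means) >= 2:
                se = float(np.std(means, ddof=1) / np.sqrt(len(means)))
        rows.append(
            dict(
                residue=r,
                H=frac(sub, "is_H"),
                turn=frac(sub, "is_T"),
                coil=frac(sub, "is_C"),
                other=frac(sub, "is_other"),
                SE=se,
            )
        )
    per_res = pd.DataFrame(rows)

    def region_mean(span):
        lo, hi = span
        sel = per_res["residue"].between(lo, hi)
        return float(per_res.loc[sel, "H"].mean())

    return HelicityProfile(
        per_residue=per_res,
        H_overall=float(per_res["H"].mean()),
        H_nt=region_mean(nt_region),
        H_ct=region_mean(ct_region),
        turn_fraction=float(per_res["turn"].mean()),
        coil_fraction=float(per_res["coil"].mean()),
    )


def stride_to_csv(stride_output: str, frame: int = 0, peptide: int = 0) -> pd.DataFrame:
    """Convert STRIDE ``ASG`` detail lines for one snapshot into the CSV schema."""
    rows = []
    for line in stride_output.splitlines():
        if line.startswith("ASG"):
            parts = line.split()
            rows.append((frame, peptide, int(parts[3]), parts[5]))
    return pd.DataFrame(rows, columns=["frame", "peptide", "residue", "code"])
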