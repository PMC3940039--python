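"""Relative NOE volume prediction from structures.

The initial build-up rate of an NOE between an isolated proton pair is
proportional to 6J(2w) - J(0), where J is the spectral density at the 1H
Larmor frequency w.  When internal motion is fast compared with global
tumbling, the motional averaging factors out as a generalized order parameter.
For a methyl group hopping among its three staggered rotor sites, the
orientationally averaged dipolar interaction with a distal proton gives an
effective rate (in Angstrom^-6 units)

    sigma_eff = (1/18) * sum_ij [3 cos^2(theta_ij) - 1] / (r_i^3 r_j^3)

with r_i the proton-probe distances and theta_ij the angle subtended at the
probe by methyl protons i and j.  This collapses to the familiar 1/r^6 law in
the far field and is compared here against the two common single-point
approximations (methyl carbon, mean methyl proton position).

All physical prefactors (gamma^4 hbar^2, tau_c, the build-up factor) cancel in
normalized volume ratios within one structure and are not applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError
from .structure_io import (
    InteractionGeometry,
    MethylGroup,
    ProbeSite,
    Structure,
    build_methyl_protons,
    methyl_probe_geometry,
)

#: entry key used throughout table reconciliation: (residue number, methyl atom)
Key = tuple[int, str]

MODES = ("jump", "carbon", "mean-proton")


@dataclass(frozen=True)
class InteractionModel:
    """Which averaging model to use and the distance gate (Angstrom)."""

    mode: str = "jump"
    cutoff: float = 7.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown interaction model {self.mode!r}")
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")


def spectral_density_rigid(tau_c: float, omega: float) -> float:
    """Lorentzian spectral density of rigid isotropic tumbling, J(w) in s/rad."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def buildup_rate_factor(tau_c: float, omega: float) -> float:
    """Signed cross-relaxation frequency factor 6J(2w) - J(0).

    Positive in the extreme-narrowing limit (limit value 2*tau_c), crosses
    zero at w*tau_c = sqrt(5)/2, negative for slow tumbling (negative NOEs).
    """
    return 6.0 * spectral_density_rigid(tau_c, 2.0 * omega) - spectral_density_rigid(
        tau_c, 0.0
    )


def jump_effective_rate(geometry: InteractionGeometry) -> float:
    """Three-site jump effective dipolar rate in Angstrom^-6 units.

    Comparable across methyls only within one structure.
    """
    r = np.asarray(geometry.distances, float)
    if r.shape != (3,) or np.any(r <= 0):
        raise GeometryError("three positive probe-proton distances required")
    p2 = 3.0 * np.cos(np.radians(np.asarray(geometry.angles, float))) ** 2 - 1.0
    inv_r3 = r ** -3.0
    return float(np.einsum("i,ij,j->", inv_r3, p2, inv_r3)) / 18.0


def centroid_rate(methyl: MethylGroup, probe: ProbeSite, centroid: str = "carbon") -> float:
    """Single-point 1/r^6 rate from the methyl carbon or mean proton position."""
    if centroid == "carbon":
        point = methyl.carbon
    elif centroid == "mean-proton":
        point = methyl.mean_proton
    else:
        raise ConfigurationError(f"unknown centroid {centroid!r}")
    r = float(np.linalg.norm(probe.pos - point))
    if r <= 1e-9:
        raise GeometryError("probe coincides with the methyl centroid")
    return r ** -6.0


@dataclass
class PredictedNOETable:
    """Per-methyl raw rates and normalized volumes for one structure.

    ``entries`` columns: chain, resnum, resname, atom, gating_distance_A,
    raw_rate, normalized_volume, merged_from.  ``max_raw`` is the absolute
    maximum raw rate, retained for cross-structure scaling.
    """

    label: str
    mode: str
    cutoff: float
    entries: pd.DataFrame
    max_raw: float = field(default=np.nan)

    def __post_init__(self):
        if len(self.entries) and not np.isfinite(self.max_raw):
            self.max_raw = float(self.entries["raw_rate"].max())

    def __len__(self) -> int:
        return len(self.entries)

    def volumes(self) -> dict[Key, float]:
        """Normalized volume per (resnum, methyl atom) key."""
        return {
            (int(row.resnum), str(row.atom)): float(row.normalized_volume)
            for row in self.entries.itertuples()
        }

    @classmethod
    def from_volumes(
        cls,
        label: str,
        volumes: Mapping[Key, float],
        max_raw: float = 1.0,
        mode: str = "jump",
        cutoff: float = 7.0,
        resnames: Mapping[int, str] | None = None,
    ) -> "PredictedNOETable":
        """Build a table directly from normalized volumes (tabulated data)."""
        rows = [
            {
                "chain": "A",
                "resnum": rn,
                "resname": (resnames or {}).get(rn, ""),
                "atom": atom,
                "gating_distance_A": np.nan,
                "raw_rate": v * max_raw,
                "normalized_volume": v,
                "merged_from": "",
            }
            for (rn, atom), v in volumes.items()
        ]
        return cls(label, mode, cutoff, pd.DataFrame(rows), max_raw=max_raw)

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        df.insert(0, "structure", self.label)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path=None) -> str:
        payload = {
            "structure": self.label,
            "mode": self.mode,
            "cutoff_A": self.cutoff,
            "max_raw_rate": self.max_raw,
            "entries": self.entries.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def predict_noe_table(
    structure: Structure,
    probe: ProbeSite,
    model: InteractionModel = InteractionModel(),
    methyl_selection: str = "*:*:*",
    merge_map: Sequence[tuple[Key, Key]] | None = None,
    exclude: Sequence[Key] | None = None,
    use_explicit_protons: bool = False,
) -> PredictedNOETable:
    """Predict relative methyl->probe NOE volumes under one interaction model.

    Methyls whose carbon lies farther than ``model.cutoff`` from the probe
    proton are excluded (the gating distance is carbon -> probe H).
    ``merge_map`` lists (source, target) key pairs whose raw rates are summed
    into the target entry before normalization - used for chemically
    shift-degenerate methyl pairs that appear as one cross-peak.  ``exclude``
    drops entries outright (per-entry exclusion, contributing nothing).
    """
    methyls = build_methyl_protons(
        structure, methyl_selection, use_explicit=use_explicit_protons
    )
    excl = set(exclude or ())
    rows = []
    for m in methyls:
        key = (m.residue[1], m.carbon_name)
        if key in excl:
            continue
        gate = float(np.linalg.norm(m.carbon - probe.pos))
        if gate > model.cutoff:
            continue
        if model.mode == "jump":
            raw = jump_effective_rate(methyl_probe_geometry(m, probe))
        else:
            raw = centroid_rate(m, probe, centroid=model.mode)
        rows.append(
            {
                "chain": m.residue[0],
                "resnum": m.residue[1],
                "resname": m.residue[2],
                "atom": m.carbon_name,
                "gating_distance_A": gate,
                "raw_rate": raw,
                "normalized_volume": np.nan,
                "merged_from": "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chain", "resnum", "resname", "atom",
            "gating_distance_A", "raw_rate", "normalized_volume", "merged_from",
        ],
    )
    if df.empty:
        warnings.warn(
            f"{structure.label}: no methyl within {model.cutoff} A of the probe",
            stacklevel=2,
        )
        return PredictedNOETable(structure.label, model.mode, model.cutoff, df, max_raw=np.nan)

    for src, dst in merge_map or ():
        idx_src = df.index[(df.resnum == src[0]) & (df.atom == src[1])]
        idx_dst = df.index[(df.resnum == dst[0]) & (df.atom == dst[1])]
        if len(idx_src) == 0 or len(idx_dst) == 0:
            continue  # a partner outside the cutoff merges nothing
        i, j = idx_src[0], idx_dst[0]
        df.loc[j, "raw_rate"] += df.loc[i, "raw_rate"]
        prev = df.loc[j, "merged_from"]
        df.loc[j, "merged_from"] = (prev + "+" if prev else "") + f"{src[0]}:{src[1]}"
        df = df.drop(index=i).reset_index(drop=True)

    max_raw = float(df["raw_rate"].max())
    df["normalized_volume"] = df["raw_rate"] / max_raw
    return PredictedNOETable(structure.label, model.mode, model.cutoff, df, max_raw=max_raw)


def cross_structure_scale(table_a: PredictedNOETable, table_b: PredictedNOETable) -> float:
    """Ratio of absolute maximum raw rates A/B.

    This is the factor by which conformer A's normalized volumes must be
    rescaled when mixed with conformer B's (both tables are internally
    normalized to their own maxima).
    """
    if table_a.mode != table_b.mode:
        raise ConfigurationError(
            f"mode mismatch: {table_a.mode} vs {table_b.mode}"
        )
    if not len(table_a) or not len(table_b):
        raise ConfigurationError("both tables must be non-empty")
    return table_a.max_raw / table_b.max_raw
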