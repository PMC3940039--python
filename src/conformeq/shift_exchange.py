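"""Differential chemical-shift aggregation vs exchange linebroadening.

Per-residue chemical-shift predictions (SPARTA+-style tabular output from an
external predictor) are consumed in a *differential* mode: predicted 15N
shifts from a reference conformational model are compared against one or more
alternative-conformation models, either per structure or as the mean over the
comparison set.  Because absolute shift predictions carry ~2.5 ppm errors that
largely cancel between closely related structures, only the differences are
interpreted.  The resulting |d delta 15N| profile is correlated (Pearson)
against measured conformational-exchange linebroadening, with residues whose
broadening is statistically insignificant (default < 0.4 Hz) or unreliable
(e.g. rapid amide hydrogen exchange) excluded with explicit bookkeeping.

Comparing structures of different sequence variants requires a residue mapping
(e.g. after computationally mutating disparate residues to alanine to put the
models on a common sequence); the mapping is one-to-one and unmapped residues
are reported as skipped, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, MappingError, ParseError


@dataclass
class ShiftPredictionTable:
    """Predicted 15N shift per residue for one structure."""

    label: str
    entries: pd.DataFrame  # columns: resnum, resname, shift_ppm

    def __post_init__(self):
        if self.entries["resnum"].duplicated().any():
            dup = self.entries.loc[self.entries["resnum"].duplicated(), "resnum"].iloc[0]
            raise ParseError(f"{self.label}: duplicated residue number {dup}")

    def shifts(self) -> dict[int, float]:
        return {
            int(r.resnum): float(r.shift_ppm)
            for r in self.entries.itertuples()
            if np.isfinite(r.shift_ppm)
        }

    def missing(self) -> list[int]:
        return [
            int(r.resnum)
            for r in self.entries.itertuples()
            if not np.isfinite(r.shift_ppm)
        ]


def read_prediction_table(path, nucleus: str = "N", label: str | None = None) -> ShiftPredictionTable:
    """Parse a SPARTA+-style whitespace-delimited prediction table.

    Header lines (REMARK/DATA/VARS/FORMAT) are honoured when present; a VARS
    line names the columns (RESID, RESNAME, ATOMNAME, SHIFT, ...).  Without
    headers, rows of four or more fields are read as
    ``resid resname atomname shift`` and rows of three as ``resid resname
    shift`` (all rows then taken as the requested nucleus).  Residues listed
    for other nuclei only are recorded with a missing (NaN) shift, not zero.
    """
    path = Path(path)
    columns: list[str] | None = None
    rows: list[tuple[int, str, str, float]] = []
    seen_resnums: dict[int, None] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith(("REMARK", "DATA", "FORMAT", "#")):
            continue
        if text.startswith("VARS"):
            columns = text.split()[1:]
            continue
        parts = text.split()
        try:
            if columns is not None:
                rec = dict(zip(columns, parts))
                resnum = int(rec["RESID"])
                resname = rec.get("RESNAME", "")
                atom = rec.get("ATOMNAME", nucleus)
                shift = float(rec["SHIFT"])
            elif len(parts) >= 4:
                resnum, resname, atom, shift = (
                    int(parts[0]), parts[1], parts[2], float(parts[3]),
                )
            elif len(parts) == 3:
                resnum, resname, atom, shift = (
                    int(parts[0]), parts[1], nucleus, float(parts[2]),
                )
            else:
                raise ValueError("too few fields")
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from None
        seen_resnums.setdefault(resnum, None)
        if atom == nucleus:
            rows.append((resnum, resname, atom, shift))

    by_res = {rn: np.nan for rn in seen_resnums}
    names = {}
    for resnum, resname, _, shift in rows:
        if np.isfinite(by_res.get(resnum, np.nan)):
            raise ParseError(f"{path}: duplicated residue number {resnum}")
        by_res[resnum] = shift
        names[resnum] = resname
    df = pd.DataFrame(
        {
            "resnum": list(by_res),
            "resname": [names.get(rn, "") for rn in by_res],
            "shift_ppm": list(by_res.values()),
        }
    )
    return ShiftPredictionTable(label or path.stem, df)


@dataclass(frozen=True)
class ResidueMapping:
    """One-to-one residue-number correspondence between two models."""

    pairs: tuple[tuple[int, int], ...]
    note: str = ""  # e.g. "disparate residues mutated to alanine"

    def __post_init__(self):
        ref = [a for a, _ in self.pairs]
        comp = [b for _, b in self.pairs]
        if len(set(ref)) != len(ref) or len(set(comp)) != len(comp):
            raise MappingError("residue mapping is not one-to-one")

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    @classmethod
    def identity(cls, resnums: Sequence[int], note: str = "") -> "ResidueMapping":
        return cls(tuple((r, r) for r in resnums), note=note)


@dataclass
class DifferentialShiftResult:
    """|d delta 15N| per reference residue, plus skipped-residue bookkeeping."""

    table: pd.DataFrame  # resnum + one column per comparison or 'mean'
    skipped: list[int] = field(default_factory=list)
    aggregation: str = "mean-over-structures"


def differential_shift(
    reference: ShiftPredictionTable,
    comparisons: Sequence[ShiftPredictionTable],
    mapping: ResidueMapping | None = None,
    aggregation: str = "mean-over-structures",
) -> DifferentialShiftResult:
    """Absolute differential 15N shifts between a reference and comparisons.

    ``per-structure`` returns |delta_ref - delta_comp| for each comparison;
    ``mean-over-structures`` returns |delta_ref - mean(delta_comp)| (the mean
    taken before the absolute value).  Residues without a mapped or predicted
    shift in every table involved are reported in ``skipped``.
    """
    if aggregation not in ("per-structure", "mean-over-structures"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ref_shifts = reference.shifts()
    if mapping is None:
        mapping = ResidueMapping.identity(sorted(ref_shifts))
    comp_shifts = [c.shifts() for c in comparisons]

    rows, skipped = [], []
    for ref_rn, comp_rn in mapping.pairs:
        if ref_rn not in ref_shifts or any(comp_rn not in cs for cs in comp_shifts):
            skipped.append(ref_rn)
            continue
        deltas = [ref_shifts[ref_rn] - cs[comp_rn] for cs in comp_shifts]
        row: dict = {"resnum": ref_rn}
        if aggregation == "mean-over-structures":
            row["ddelta_ppm"] = abs(float(np.mean(deltas)))
        else:
            for comp, d in zip(comparisons, deltas):
                row[f"ddelta_{comp.label}_ppm"] = abs(d)
        rows.append(row)
    unmapped = sorted(set(ref_shifts) - {a for a, _ in mapping.pairs})
    skipped.extend(unmapped)
    table = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["resnum"])
    return DifferentialShiftResult(table=table, skipped=sorted(skipped), aggregation=aggregation)


@dataclass
class ExchangeBroadeningTable:
    """Measured conformational-exchange linebroadening per residue (Hz)."""

    entries: pd.DataFrame  # columns: resnum, dex_hz, reliable (bool)

    def __post_init__(self):
        df = self.entries.copy()
        if "reliable" not in df.columns:
            df["reliable"] = True
        self.entries = df

    @classmethod
    def from_file(cls, path) -> "ExchangeBroadeningTable":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df)


@dataclass
class BroadeningCorrelation:
    """Pearson r with the paired scatter table and exclusion bookkeeping."""

    pearson_r: float
    pairs: pd.DataFrame  # resnum, ddelta_ppm, dex_hz
    n_used: int
    n_below_threshold: int
    n_unreliable: int
    n_unmatched: int

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.5g")


def correlate_broadening(
    ddelta: DifferentialShiftResult | pd.DataFrame,
    broadening: ExchangeBroadeningTable,
    threshold_hz: float = 0.4,
) -> BroadeningCorrelation:
    """Correlate |d delta 15N| against measured exchange linebroadening.

    Residues flagged unreliable are excluded, as are residues whose
    broadening falls below the significance threshold.  The counts of used,
    threshold-excluded, unreliable and unmatched residues sum to the input
    broadening-table size.
    """
    dtab = ddelta.table if isinstance(ddelta, DifferentialShiftResult) else ddelta
    value_col = [c for c in dtab.columns if c != "resnum"]
    if len(value_col) != 1:
        raise ValueError(
            "correlate_broadening needs a single differential-shift column "
            "(use mean-over-structures aggregation or select one column)"
        )
    dd = dict(zip(dtab["resnum"].astype(int), dtab[value_col[0]].astype(float)))

    used_rows = []
    n_below = n_unreliable = n_unmatched = 0
    for row in broadening.entries.itertuples():
        rn = int(row.resnum)
        if not bool(row.reliable):
            n_unreliable += 1
            continue
        if rn not in dd:
            n_unmatched += 1
            continue
        if float(row.dex_hz) < threshold_hz:
            n_below += 1
            continue
        used_rows.append({"resnum": rn, "ddelta_ppm": dd[rn], "dex_hz": float(row.dex_hz)})
    if len(used_rows) < 3:
        raise InsufficientDataError(
            f"only {len(used_rows)} residue pairs pass the filters"
        )
    pairs = pd.DataFrame(used_rows)
    r = float(stats.pearsonr(pairs["ddelta_ppm"], pairs["dex_hz"]).statistic)
    return BroadeningCorrelation(
        pearson_r=r,
        pairs=pairs,
        n_used=len(used_rows),
        n_below_threshold=n_below,
        n_unreliable=n_unreliable,
        n_unmatched=n_unmatched,
    )
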