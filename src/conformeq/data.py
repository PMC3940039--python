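"""Bundled FKBP12 Trp59 methyl-NOE dataset.

Nine methyl -> indole H-Ne1 cross-peaks of wild-type FKBP12 with the
jump-model volumes predicted from the wild-type (PDB 2PPN) and G89P-variant
(PDB 4N19) crystal structures, and the inter-structure ratio of absolute
maximum rates (0.28).  This is the reference input for the two-conformer
population fit and ships with the package so the analysis runs without any
coordinate download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .mixture_fit import ExperimentalNOETable
from .noe_model import PredictedNOETable

#: wild-type/G89P ratio of absolute maximum predicted rates
FKBP12_SCALE_WT_OVER_G89P = 0.28

#: chemically shift-degenerate methyl pair merged into one cross-peak in the
#: wild-type prediction: Val63 CG1 summed into the Val101 CG2 entry
FKBP12_MERGE_MAP = (((63, "CG1"), (101, "CG2")),)

#: entry excluded from the wild-type prediction despite a tabulated distance
FKBP12_WT_EXCLUDE = ((101, "CG1"),)


@dataclass
class FKBP12NOEData:
    """Experimental volumes, per-conformer predictions, and their scale."""

    experimental: ExperimentalNOETable
    predicted_wt: PredictedNOETable
    predicted_g89p: PredictedNOETable
    scale: float
    distances_wt: dict[tuple[int, str], float]
    distances_g89p: dict[tuple[int, str], float]
    resnames: dict[int, str]


def load_fkbp12_noe_table() -> FKBP12NOEData:
    """Load and validate the bundled FKBP12 methyl-NOE dataset."""
    ref = resources.files("conformeq").joinpath("data/fkbp12_trp59_methyl_noe.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])

    if len(df) != 9:
        raise ValueError(f"bundled NOE table corrupt: {len(df)} rows, expected 9")
    if not np.isclose(df["noe_exp"].max(), 1.0):
        raise ValueError("bundled NOE table corrupt: experimental maximum != 1")
    for col in ("noe_s2_wt", "noe_s2_g89p"):
        vals = df[col].dropna()
        if not np.isclose(vals.max(), 1.0) or (vals <= 0).any():
            raise ValueError(f"bundled NOE table corrupt: bad column {col}")

    resnames = dict(zip(df["resnum"].astype(int), df["resname"]))
    exp = ExperimentalNOETable(
        df.rename(columns={"noe_exp": "volume"})[
            ["resnum", "resname", "atom", "volume"]
        ].copy()
    )

    def predicted(col: str, label: str) -> PredictedNOETable:
        sub = df[df[col].notna()]
        volumes = {
            (int(r.resnum), str(r.atom)): float(getattr(r, col))
            for r in sub.itertuples()
        }
        return PredictedNOETable.from_volumes(
            label, volumes, max_raw=1.0, mode="jump", resnames=resnames
        )

    def distances(col: str) -> dict[tuple[int, str], float]:
        sub = df[df[col].notna()]
        return {
            (int(r.resnum), str(r.atom)): float(getattr(r, col))
            for r in sub.itertuples()
        }

    return FKBP12NOEData(
        experimental=exp,
        predicted_wt=predicted("noe_s2_wt", "2PPN"),
        predicted_g89p=predicted("noe_s2_g89p", "G89P"),
        scale=FKBP12_SCALE_WT_OVER_G89P,
        distances_wt=distances("dist_wt"),
        distances_g89p=distances("dist_g89p"),
        resnames=resnames,
    )


def full_geometry_tables(
    path_wt,
    path_g89p,
    trp_resnum: int = 59,
    mode: str = "jump",
    cutoff: float = 7.0,
):
    """Predict both conformers' NOE tables from deposited coordinate files.

    Builds the indole probe proton from the ring geometry when the file lacks
    hydrogens, applies the degenerate-methyl merge and the wild-type exclusion
    convention, and returns ``(table_wt, table_g89p, scale)``.
    """
    from .noe_model import InteractionModel, cross_structure_scale, predict_noe_table
    from .structure_io import ProbeSite, build_planar_proton, load_structure

    def probe_of(structure):
        chain = structure.atoms[0].chain
        ne1 = structure.find(chain, trp_resnum, "NE1")
        try:
            he1 = structure.find(chain, trp_resnum, "HE1").pos
        except KeyError:
            cd1 = structure.find(chain, trp_resnum, "CD1").pos
            ce2 = structure.find(chain, trp_resnum, "CE2").pos
            he1 = build_planar_proton(ne1.pos, cd1, ce2)
        return ProbeSite((chain, trp_resnum, "TRP"), "HE1", he1, ne1.pos)

    model = InteractionModel(mode=mode, cutoff=cutoff)
    st_wt = load_structure(path_wt)
    st_g = load_structure(path_g89p)
    table_wt = predict_noe_table(
        st_wt, probe_of(st_wt), model,
        merge_map=FKBP12_MERGE_MAP, exclude=FKBP12_WT_EXCLUDE,
    )
    table_g = predict_noe_table(st_g, probe_of(st_g), model)
    return table_wt, table_g, cross_structure_scale(table_wt, table_g)


def centroid_tables_from_distances(
    data: FKBP12NOEData,
) -> tuple[PredictedNOETable, PredictedNOETable, float]:
    """Carbon-centroid (1/r^6) prediction tables from the tabulated carbon
    distances, with the scale recomputed for this mode.

    All tabulated distances enter (the jump-column exclusion is specific to
    the jump model's degenerate-peak bookkeeping).
    """
    raw_wt = {k: d ** -6.0 for k, d in data.distances_wt.items()}
    raw_g = {k: d ** -6.0 for k, d in data.distances_g89p.items()}
    max_wt, max_g = max(raw_wt.values()), max(raw_g.values())
    ta = PredictedNOETable.from_volumes(
        "2PPN", {k: v / max_wt for k, v in raw_wt.items()},
        max_raw=max_wt, mode="carbon", resnames=data.resnames,
    )
    tb = PredictedNOETable.from_volumes(
        "G89P", {k: v / max_g for k, v in raw_g.items()},
        max_raw=max_g, mode="carbon", resnames=data.resnames,
    )
    return ta, tb, max_wt / max_g
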