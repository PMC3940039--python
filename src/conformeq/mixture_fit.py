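"""Two-conformer population fitting against experimental NOE volumes.

An experimental table of normalized methyl->probe NOE volumes is modelled as
a population-weighted admixture of the volumes predicted from two conformer
structures.  Because each predicted table is normalized to its own maximum,
the mixture needs the inter-structure ratio of absolute maximum rates
(``scale``):

    v(k; p) propto p * scale * A(k) + (1 - p) * B(k)

renormalized to its own maximum.  The population p of conformer A is scanned
on a grid and refined by bounded minimization; goodness of fit is the RMSD
over the common entries and the Pearson correlation at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, InsufficientDataError
from .noe_model import (
    InteractionModel,
    Key,
    PredictedNOETable,
    cross_structure_scale,
    predict_noe_table,
)
from .structure_io import ProbeSite, Structure


@dataclass
class ExperimentalNOETable:
    """Normalized experimental cross-peak volumes keyed by (resnum, atom).

    Volumes are assumed pre-normalized against the reference 2D heteronuclear
    correlation peak volumes; on construction they are renormalized so the
    maximum entry is exactly 1.
    """

    entries: pd.DataFrame  # columns: resnum, resname, atom, volume

    def __post_init__(self):
        df = self.entries.copy()
        required = {"resnum", "atom", "volume"}
        if not required <= set(df.columns):
            raise ConfigurationError(
                f"experimental table needs columns {sorted(required)}"
            )
        if df.empty:
            raise ConfigurationError("experimental table is empty")
        if (df["volume"] <= 0).any():
            raise ConfigurationError("experimental volumes must be positive")
        df["volume"] = df["volume"] / df["volume"].max()
        if df.duplicated(subset=["resnum", "atom"]).any():
            raise ConfigurationError("duplicate (resnum, atom) entry")
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def volumes(self) -> dict[Key, float]:
        return {
            (int(r.resnum), str(r.atom)): float(r.volume)
            for r in self.entries.itertuples()
        }

    @classmethod
    def from_file(cls, path) -> "ExperimentalNOETable":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.4g")


@dataclass
class ConformerMixture:
    """Two per-structure prediction tables, their scale, and a population."""

    table_a: PredictedNOETable
    table_b: PredictedNOETable
    scale: float
    population_a: float = 0.5

    def __post_init__(self):
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        if not 0.0 <= self.population_a <= 1.0:
            raise ConfigurationError("population must lie in [0, 1]")


def mixture_predict(mixture: ConformerMixture) -> dict[Key, float]:
    """Predicted normalized volumes over the union of entry keys.

    A key absent from one conformer's table contributes 0 from that conformer
    (its methyl lies beyond the cutoff there, so its predicted rate is
    negligible by the gating convention).
    """
    va = mixture.table_a.volumes()
    vb = mixture.table_b.volumes()
    keys = sorted(set(va) | set(vb))
    if not keys:
        raise ConfigurationError("mixture has no entries")
    p = mixture.population_a
    raw = {
        k: p * mixture.scale * va.get(k, 0.0) + (1.0 - p) * vb.get(k, 0.0)
        for k in keys
    }
    vmax = max(raw.values())
    if vmax <= 0:
        raise ConfigurationError("mixture predicts no positive volume")
    return {k: v / vmax for k, v in raw.items()}


@dataclass
class MixtureFitResult:
    """Optimum population, goodness of fit, residuals, and the scan trace."""

    population: float
    rmsd: float
    pearson_r: float
    residuals: pd.DataFrame  # resnum, atom, experimental, predicted, residual
    scan: pd.DataFrame  # population, rmsd
    n: int
    degenerate: bool = False

    def to_json(self, path=None) -> str:
        payload = {
            "population": self.population,
            "rmsd": self.rmsd,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "degenerate": self.degenerate,
            "residuals": self.residuals.to_dict(orient="records"),
            "scan": self.scan.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _evaluate(
    p: float,
    exp_vol: dict[Key, float],
    table_a: PredictedNOETable,
    table_b: PredictedNOETable,
    scale: float,
    keys: Sequence[Key],
) -> tuple[float, np.ndarray]:
    pred = mixture_predict(ConformerMixture(table_a, table_b, scale, p))
    pv = np.array([pred.get(k, 0.0) for k in keys])
    ev = np.array([exp_vol[k] for k in keys])
    resid = pv - ev
    return float(np.sqrt(np.mean(resid ** 2))), pv


def fit_population(
    experimental: ExperimentalNOETable,
    table_a: PredictedNOETable,
    table_b: PredictedNOETable,
    scale: float,
    grid_step: float = 0.01,
) -> MixtureFitResult:
    """Fit the conformer-A population by grid scan plus bounded refinement.

    The RMSD is computed over all entries common to the experimental table and
    the union of the two predictions (the self-normalizing maximum entry
    included).  The grid argmin (ties broken toward larger p, i.e. toward
    conformer A) is refined to 1e-4; the Pearson r is reported at the optimum.
    """
    exp_vol = experimental.volumes()
    union = set(table_a.volumes()) | set(table_b.volumes())
    keys = sorted(k for k in exp_vol if k in union)
    if len(keys) < 3:
        raise InsufficientDataError(
            f"only {len(keys)} entries common to experiment and predictions"
        )

    grid = np.arange(0.0, 1.0 + 0.5 * grid_step, grid_step)
    grid = np.clip(grid, 0.0, 1.0)
    rmsds = np.array(
        [_evaluate(p, exp_vol, table_a, table_b, scale, keys)[0] for p in grid]
    )
    degenerate = bool(rmsds.max() - rmsds.min() < 1e-12)
    if degenerate:
        p_opt = 0.5
    else:
        # ties toward larger p: scan from the top of the grid
        best = len(grid) - 1 - int(np.argmin(rmsds[::-1]))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda p: _evaluate(p, exp_vol, table_a, table_b, scale, keys)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-5},
        )
        p_opt = float(res.x) if res.fun <= rmsds[best] else float(grid[best])
        p_opt = min(max(p_opt, 0.0), 1.0)
        if round(p_opt, 4) in (round(lo, 4), round(hi, 4)):
            # refinement pinned at the bracket edge: keep the grid argmin
            p_opt = float(grid[best])

    rmsd, pv = _evaluate(p_opt, exp_vol, table_a, table_b, scale, keys)
    ev = np.array([exp_vol[k] for k in keys])
    if np.ptp(pv) == 0 or np.ptp(ev) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(pv, ev).statistic)
    residuals = pd.DataFrame(
        {
            "resnum": [k[0] for k in keys],
            "atom": [k[1] for k in keys],
            "experimental": ev,
            "predicted": pv,
            "residual": pv - ev,
        }
    )
    scan = pd.DataFrame({"population": grid, "rmsd": rmsds})
    return MixtureFitResult(
        population=p_opt,
        rmsd=rmsd,
        pearson_r=r,
        residuals=residuals,
        scan=scan,
        n=len(keys),
        degenerate=degenerate,
    )


def evaluate_population(
    experimental: ExperimentalNOETable,
    table_a: PredictedNOETable,
    table_b: PredictedNOETable,
    scale: float,
    p: float,
) -> tuple[float, float]:
    """RMSD and Pearson r of the mixture at a requested population."""
    exp_vol = experimental.volumes()
    union = set(table_a.volumes()) | set(table_b.volumes())
    keys = sorted(k for k in exp_vol if k in union)
    if len(keys) < 3:
        raise InsufficientDataError("fewer than 3 common entries")
    rmsd, pv = _evaluate(p, exp_vol, table_a, table_b, scale, keys)
    ev = np.array([exp_vol[k] for k in keys])
    r = float(stats.pearsonr(pv, ev).statistic)
    return rmsd, r


def compare_models(
    experimental: ExperimentalNOETable,
    structure_a: Structure,
    structure_b: Structure,
    probe_a: ProbeSite,
    probe_b: ProbeSite,
    models: Sequence[InteractionModel] | None = None,
    merge_map=None,
    exclude_a=None,
    exclude_b=None,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Fit the same experimental table under several interaction models.

    Returns one row per model (jump listed first) with the optimum population,
    RMSD and Pearson r; the inter-structure scale is recomputed per model.
    """
    if models is None:
        models = [InteractionModel(m) for m in ("jump", "carbon", "mean-proton")]
    models = sorted(models, key=lambda m: m.mode != "jump")
    rows = []
    for model in models:
        ta = predict_noe_table(
            structure_a, probe_a, model, merge_map=merge_map, exclude=exclude_a
        )
        tb = predict_noe_table(
            structure_b, probe_b, model, merge_map=merge_map, exclude=exclude_b
        )
        scale = cross_structure_scale(ta, tb)
        fit = fit_population(experimental, ta, tb, scale, grid_step=grid_step)
        rows.append(
            {
                "mode": model.mode,
                "population": fit.population,
                "rmsd": fit.rmsd,
                "pearson_r": fit.pearson_r,
                "scale": scale,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
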