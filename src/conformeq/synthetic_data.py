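"""Synthetic fixtures with known ground truth for every analysis stage.

The scene generator emulates the experimental situation the package targets:
a distal amide probe proton (an indole-like N-H) surrounded by methyl-bearing
valine-like residues at 3-8 Angstrom, existing in two conformers - conformer B
reorients the probe bond vector by a configurable angle (default 83 degrees)
and displaces a configurable subset of the methyl groups.  NOE volumes are
simulated from a known population admixture with multiplicative log-normal
noise (peak-volume errors scale with intensity), and relaxation observables
from known model-free parameters with optional Gaussian noise.  Every
generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .mixture_fit import ConformerMixture, ExperimentalNOETable, mixture_predict
from .noe_model import InteractionModel, cross_structure_scale, predict_noe_table
from .relaxation import (
    ModelFreeParams,
    NucleusConstants,
    RelaxationObservables,
    forward_relaxation,
)
from .structure_io import AtomRecord, ProbeSite, Structure, place_atom

import pandas as pd

# well-separated unit directions for placing methyl residues around the probe
_BASE_DIRECTIONS = np.array(
    [
        [1, 1, 1], [-1, -1, 1], [1, -1, -1], [-1, 1, -1],
        [1, 1, -1], [-1, -1, -1], [1, -1, 1], [-1, 1, 1],
    ],
    dtype=float,
) / np.sqrt(3.0)


@dataclass(frozen=True)
class SceneConfig:
    """Construction parameters of a two-conformer synthetic scene."""

    n_valines: int = 3  # two side-on methyls each
    n_isoleucines: int = 2  # one terminal methyl each, rotor axis aimed at the probe
    probe_flip_deg: float = 83.0  # probe bond-vector reorientation in conformer B
    displaced_fraction: float = 0.67  # fraction of valines displaced in B
    displacement: float = 2.5  # Angstrom; conformer rearrangements of this size
    # move methyl-probe distances by a few Angstrom, as a ring flip does
    r_min: float = 4.5  # methyl-carrier (CB) distance band from the probe H;
    r_max: float = 8.0  # methyl carbons then land roughly 3-8 A from the probe
    p_true: float = 0.8  # population of conformer A
    noise_sigma: float = 0.05  # log-normal sigma on simulated volumes
    seed: int = 0

    def __post_init__(self):
        if not 3.0 <= self.r_min < self.r_max <= 8.5:
            raise GenerationError("distance band must satisfy 3 <= r_min < r_max <= 8.5")
        if not 0.0 <= self.p_true <= 1.0:
            raise GenerationError("p_true must lie in [0, 1]")
        if self.n_valines < 1 or self.n_isoleucines < 0:
            raise GenerationError("need at least one valine")
        if self.n_valines + self.n_isoleucines > len(_BASE_DIRECTIONS):
            raise GenerationError(
                f"at most {len(_BASE_DIRECTIONS)} methyl-bearing residues fit the scene"
            )

    @property
    def n_residues(self) -> int:
        return self.n_valines + self.n_isoleucines


@dataclass
class SyntheticScene:
    """Two conformer structures sharing atom naming, with known ground truth."""

    conformer_a: Structure
    conformer_b: Structure
    probe_a: ProbeSite
    probe_b: ProbeSite
    config: SceneConfig
    displaced_resnums: tuple[int, ...] = ()

    @property
    def p_true(self) -> float:
        return self.config.p_true

    def reference_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Matched coordinate sets (probe-residue frame atoms) for superposition."""
        names = [("NE1",), ("CD1",), ("CE2",)]
        ref_a = np.array([self.conformer_a.find("A", 1, n[0]).pos for n in names])
        ref_b = np.array([self.conformer_b.find("A", 1, n[0]).pos for n in names])
        return ref_a, ref_b

    def predicted_tables(self, model: InteractionModel = InteractionModel(),
                         merge_map=None):
        """Per-conformer predicted NOE tables and their cross-structure scale."""
        ta = predict_noe_table(self.conformer_a, self.probe_a, model, merge_map=merge_map)
        tb = predict_noe_table(self.conformer_b, self.probe_b, model, merge_map=merge_map)
        return ta, tb, cross_structure_scale(ta, tb)

    def write(self, outdir) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pa = outdir / "conformer_a.pdb"
        pb = outdir / "conformer_b.pdb"
        self.conformer_a.write_pdb(pa)
        self.conformer_b.write_pdb(pb)
        return pa, pb


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis)).as_matrix()


def make_scene(config: SceneConfig = SceneConfig()) -> SyntheticScene:
    """Generate a deterministic two-conformer scene from the config seed."""
    rng = np.random.default_rng(config.seed)
    ne1 = np.zeros(3)
    he1_a = np.array([0.0, 0.0, 0.98])
    # in-plane ring neighbors fixing the probe-residue frame
    cd1 = np.array([1.23, 0.0, -0.55])
    ce2 = np.array([-1.23, 0.0, -0.55])

    atoms_probe = [
        AtomRecord("A", 1, "TRP", "NE1", ne1, element="N"),
        AtomRecord("A", 1, "TRP", "CD1", cd1, element="C"),
        AtomRecord("A", 1, "TRP", "CE2", ce2, element="C"),
        AtomRecord("A", 1, "TRP", "HE1", he1_a, element="H"),
    ]

    # Methyl carriers surround the probe the way side chains pack against a
    # buried ring: terminal isoleucine-like methyls press their rotor axes
    # toward the probe proton (the near-axis geometry that separates the jump
    # model from the single-point approximations), while valine-like pairs
    # sit side-on with both methyls at moderate angles.
    atoms_env: list[AtomRecord] = []
    resnum = 2
    for i in range(config.n_isoleucines):
        d = _BASE_DIRECTIONS[i] + 0.10 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        radius = rng.uniform(3.6, 5.0)  # terminal methyls reach closest
        cd1_pos = he1_a + radius * d
        tilt = rng.uniform(5.0, 25.0)
        az = rng.uniform(0.0, 2.0 * math.pi)
        w = _unit(np.cross(d, rng.standard_normal(3)))
        w2 = np.cross(d, w)
        axis = (
            math.cos(math.radians(tilt)) * d
            + math.sin(math.radians(tilt)) * (math.cos(az) * w + math.sin(az) * w2)
        )
        cg1 = cd1_pos + 1.54 * axis
        cb = cg1 + 1.54 * _unit(axis + np.cross(axis, w))
        for name, pos in (("CB", cb), ("CG1", cg1), ("CD1", cd1_pos)):
            atoms_env.append(AtomRecord("A", resnum, "ILE", name, pos, element="C"))
        resnum += 1
    for i in range(config.n_valines):
        d = _BASE_DIRECTIONS[config.n_isoleucines + i] + 0.10 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        radius = rng.uniform(config.r_min, config.r_max)
        cb = he1_a + radius * d
        target = _unit(he1_a - cb)  # CB -> probe direction
        w = _unit(np.cross(target, rng.standard_normal(3)))
        # CB->CA nearly anti to the probe puts both rotor branches side-on
        u = -math.cos(math.radians(12.0)) * target + math.sin(math.radians(12.0)) * w
        ca = cb + 1.54 * u
        ref_point = cb + np.cross(u, target) + w  # non-collinear frame anchor
        phase = rng.uniform(0.0, 360.0)
        cg1 = place_atom(ref_point, ca, cb, 1.54, 109.47, phase)
        cg2 = place_atom(ref_point, ca, cb, 1.54, 109.47, phase + 120.0)
        for name, pos in (("CA", ca), ("CB", cb), ("CG1", cg1), ("CG2", cg2)):
            atoms_env.append(AtomRecord("A", resnum, "VAL", name, pos, element="C"))
        resnum += 1

    conformer_a = Structure("conformer_a", atoms_probe + atoms_env)
    _check_clashes(conformer_a)

    # conformer B: reorient the probe bond vector about an in-plane axis
    rot = _rotation_about(np.array([1.0, 0.0, 0.0]), config.probe_flip_deg)
    he1_b = ne1 + rot @ (he1_a - ne1)

    n_disp = int(round(config.displaced_fraction * config.n_residues))
    displaced = tuple(range(2, 2 + n_disp))
    conformer_b = None
    for _attempt in range(50):  # redraw clashing displacement sets, same stream
        shifts = {
            rn: config.displacement * _unit(rng.standard_normal(3)) for rn in displaced
        }
        atoms_b = []
        for a in conformer_a.atoms:
            if a.name == "HE1":
                atoms_b.append(replace(a, pos=he1_b))
            elif a.resnum in shifts:
                atoms_b.append(replace(a, pos=a.pos + shifts[a.resnum]))
            else:
                atoms_b.append(a)
        candidate = Structure("conformer_b", atoms_b)
        try:
            _check_clashes(candidate)
        except GenerationError:
            continue
        conformer_b = candidate
        break
    if conformer_b is None:
        raise GenerationError(
            "could not place the displaced conformer without atom overlap"
        )

    probe_a = ProbeSite(("A", 1, "TRP"), "HE1", he1_a, ne1)
    probe_b = ProbeSite(("A", 1, "TRP"), "HE1", he1_b, ne1)
    return SyntheticScene(
        conformer_a, conformer_b, probe_a, probe_b, config, displaced
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GenerationError("degenerate random direction")
    return v / n


def _check_clashes(structure: Structure, min_dist: float = 1.5) -> None:
    coords = np.array([a.pos for a in structure.atoms])
    resnums = np.array([a.resnum for a in structure.atoms])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    inter = resnums[:, None] != resnums[None, :]
    if np.any(dist[inter] < min_dist):
        raise GenerationError(
            f"{structure.label}: inter-residue atom contact below {min_dist} A"
        )


def simulate_noe_volumes(
    scene: SyntheticScene,
    model: InteractionModel = InteractionModel(),
    sigma: float | None = None,
    seed: int | None = None,
    merge_map=None,
) -> ExperimentalNOETable:
    """Simulate an experimental NOE table from the scene's true admixture.

    Volumes are the mixture prediction at the scene's true population with
    multiplicative log-normal noise of width ``sigma`` (defaults to the scene
    config; 0 gives noise-free volumes), renormalized to the maximum entry.
    """
    if sigma is None:
        sigma = scene.config.noise_sigma
    rng = np.random.default_rng(scene.config.seed + 1 if seed is None else seed)
    ta, tb, scale = scene.predicted_tables(model, merge_map=merge_map)
    pred = mixture_predict(ConformerMixture(ta, tb, scale, scene.p_true))
    keys = sorted(pred)
    resnames = {
        (a.resnum): a.resname for a in scene.conformer_a.atoms
    }
    noise = np.exp(sigma * rng.standard_normal(len(keys))) if sigma > 0 else np.ones(len(keys))
    rows = [
        {"resnum": k[0], "resname": resnames.get(k[0], ""), "atom": k[1],
         "volume": pred[k] * z}
        for k, z in zip(keys, noise)
    ]
    return ExperimentalNOETable(pd.DataFrame(rows))


@dataclass
class SyntheticRelaxationSet:
    """Known model-free parameters per residue plus a noise configuration."""

    params: Sequence[ModelFreeParams]
    tau_c: float = 5.8e-9
    sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fractional on R1, R2, NOE
    seed: int = 0


def simulate_relaxation(
    rset: SyntheticRelaxationSet,
    constants: NucleusConstants = NucleusConstants(),
) -> list[RelaxationObservables]:
    """Forward-compute (R1, R2, NOE) per residue, with optional Gaussian noise."""
    rng = np.random.default_rng(rset.seed)
    out = []
    for p in rset.params:
        obs = forward_relaxation(p, rset.tau_c, constants)
        vals = obs.as_array()
        noisy = vals * (1.0 + np.asarray(rset.sigma) * rng.standard_normal(3))
        out.append(
            RelaxationObservables(
                r1=float(noisy[0]), r2=float(noisy[1]), noe=float(noisy[2]),
                field_mhz=constants.field_mhz,
            )
        )
    return out
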