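"""Model-free 15N relaxation: spectral densities, forward rates, and fitting.

The extended model-free spectral density with the fast internal motion in the
extreme-narrowing limit is

    J(w) = (2/5) [ S^2 tau_c / (1 + (w tau_c)^2)
                   + (Sf^2 - S^2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_c + 1/tau_e,      S^2 = Sf^2 * Ss^2,

where Sf^2 scales out the fast librational averaging and the slow internal
component with time constant tau_e carries the dispersive term.  R1, R2 and
the steady-state heteronuclear NOE follow from the standard dipolar + axially
symmetric CSA expressions for an amide 15N relaxed by its attached proton.

A two-site jump of the bond vector between orientations separated by
theta_ab with populations (p_a, p_b) has the closed-form order parameter

    S^2 = 1 - 3 p_a p_b sin^2(theta_ab).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .errors import FitError

GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126180e7  # 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1e-7  # T m A^-1


@dataclass(frozen=True)
class NucleusConstants:
    """Physical constants of the 1H-15N spin pair and the spectrometer."""

    field_mhz: float = 600.0  # 1H Larmor frequency, MHz
    r_nh: float = 1.02e-10  # N-H bond length, m
    csa_ppm: float = -126.0  # axially symmetric 15N CSA (indole Ne1 default)

    def __post_init__(self):
        if not 0.95e-10 <= self.r_nh <= 1.10e-10:
            raise ValueError("N-H bond length outside [0.95, 1.10] Angstrom")
        if self.field_mhz <= 0:
            raise ValueError("field must be positive")

    @property
    def omega_h(self) -> float:
        return 2.0 * math.pi * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        return self.omega_h * GAMMA_N / GAMMA_H

    @property
    def dipolar(self) -> float:
        """Dipolar coupling constant d = (mu0/4pi) hbar gammaH gammaN / r^3."""
        return MU0_OVER_4PI * HBAR * GAMMA_H * GAMMA_N / self.r_nh ** 3

    @property
    def csa_constant(self) -> float:
        """CSA interaction constant c = omegaN * CSA / sqrt(3)."""
        return self.omega_n * self.csa_ppm * 1e-6 / math.sqrt(3.0)


@dataclass(frozen=True)
class ModelFreeParams:
    """Extended model-free parameters; total S^2 = Sf^2 * Ss^2 by definition."""

    s2f: float = 1.0
    s2s: float = 1.0
    tau_e: float = 0.0  # s, slow internal component
    rex: float = 0.0  # s^-1, exchange contribution to R2

    def __post_init__(self):
        for name, v in (("s2f", self.s2f), ("s2s", self.s2s)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tau_e < 0 or self.rex < 0:
            raise ValueError("tau_e and rex must be non-negative")

    @property
    def s2(self) -> float:
        return self.s2f * self.s2s

    @classmethod
    def from_total(cls, s2: float, tau_e: float, s2f: float = 1.0, rex: float = 0.0):
        """Build from a total S^2 and the fast-limit Sf^2 (Ss^2 = S^2/Sf^2)."""
        return cls(s2f=s2f, s2s=s2 / s2f, tau_e=tau_e, rex=rex)


@dataclass(frozen=True)
class RelaxationObservables:
    """Measured or predicted R1, R2 (s^-1) and heteronuclear NOE."""

    r1: float
    r2: float
    noe: float
    field_mhz: float = 600.0

    def __post_init__(self):
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("R1 and R2 must be positive")
        if self.noe > 1.0 + abs(GAMMA_H / GAMMA_N):
            raise ValueError("NOE above the theoretical cap")

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.noe])


def extended_spectral_density(params: ModelFreeParams, tau_c: float, omega: float) -> float:
    """Extended model-free J(w) in s/rad (fast motion in extreme narrowing)."""
    s2 = params.s2
    w = abs(omega)
    j = s2 * tau_c / (1.0 + (w * tau_c) ** 2)
    if params.tau_e > 0.0:
        tau_p = 1.0 / (1.0 / tau_c + 1.0 / params.tau_e)
        j += (params.s2f - s2) * tau_p / (1.0 + (w * tau_p) ** 2)
    return 0.4 * j


def forward_relaxation(
    params: ModelFreeParams,
    tau_c: float,
    constants: NucleusConstants = NucleusConstants(),
) -> RelaxationObservables:
    """R1, R2 and heteronuclear NOE from model-free parameters.

    Standard 15N dipolar + CSA expressions; Rex (if any) adds to R2 only.
    """
    wh, wn = constants.omega_h, constants.omega_n
    d2 = constants.dipolar ** 2
    c2 = constants.csa_constant ** 2
    J = lambda w: extended_spectral_density(params, tau_c, w)

    r1 = d2 / 4.0 * (J(wh - wn) + 3.0 * J(wn) + 6.0 * J(wh + wn)) + c2 * J(wn)
    r2 = (
        d2 / 8.0 * (4.0 * J(0) + J(wh - wn) + 3.0 * J(wn) + 6.0 * J(wh) + 6.0 * J(wh + wn))
        + c2 / 6.0 * (4.0 * J(0) + 3.0 * J(wn))
        + params.rex
    )
    noe = 1.0 + d2 / 4.0 * (GAMMA_H / GAMMA_N) * (6.0 * J(wh + wn) - J(wh - wn)) / r1
    return RelaxationObservables(r1=r1, r2=r2, noe=noe, field_mhz=constants.field_mhz)


@dataclass
class ModelFreeFit:
    """Fit result: parameters, residual chi-square, and provenance."""

    params: ModelFreeParams
    chi2: float
    model: str
    tau_c: float
    constants: NucleusConstants
    tau_e_indeterminate: bool = False
    starts_tried: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "s2f": self.params.s2f,
            "s2s": self.params.s2s,
            "s2": self.params.s2,
            "tau_e_ns": self.params.tau_e * 1e9,
            "rex": self.params.rex,
            "chi2": self.chi2,
            "tau_c_ns": self.tau_c * 1e9,
            "field_mhz": self.constants.field_mhz,
            "r_nh_A": self.constants.r_nh * 1e10,
            "csa_ppm": self.constants.csa_ppm,
            "tau_e_indeterminate": self.tau_e_indeterminate,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


_LOG_TE_BOUNDS = (-12.0, -7.5)  # log10 tau_e / s: 1 ps .. ~30 ns


def _unpack(x: np.ndarray, model: str) -> ModelFreeParams:
    if model == "extended":
        s2f, s2s, lte = x
    else:  # simple: S^2 with Sf^2 = 1
        s2f, (s2s, lte) = 1.0, x
    return ModelFreeParams(
        s2f=float(min(max(s2f, 0.0), 1.0)),
        s2s=float(min(max(s2s, 0.0), 1.0)),
        tau_e=float(10.0 ** lte),
    )


def fit_modelfree(
    observables: RelaxationObservables,
    tau_c: float,
    constants: NucleusConstants | None = None,
    model: str = "extended",
    weights: np.ndarray | None = None,
) -> ModelFreeFit:
    """Least-squares model-free fit to (R1, R2, NOE) at fixed tau_c.

    ``model="extended"`` fits (Sf^2, Ss^2, tau_e) - exactly identified by the
    three observables; ``model="simple"`` fits (S^2, tau_e) with Sf^2 = 1.
    Multi-start: a coarse grid over the order parameters and tau_e is ranked
    by chi-square and the best starts are refined with bounded Nelder-Mead
    (unweighted unless ``weights``, interpreted as 1/sigma, are supplied).
    """
    if model not in ("extended", "simple"):
        raise ValueError(f"unknown model {model!r}")
    if constants is None:
        constants = NucleusConstants(field_mhz=observables.field_mhz)
    obs = observables.as_array()
    w = np.ones(3) if weights is None else np.asarray(weights, float)

    def chi2(x: np.ndarray) -> float:
        try:
            p = _unpack(x, model)
        except ValueError:
            return 1e12
        pred = forward_relaxation(p, tau_c, constants)
        return float(np.sum((w * (pred.as_array() - obs)) ** 2))

    te_starts = [0.05e-9, 0.5e-9, 1.5e-9, 3e-9]
    s2_grid = np.arange(0.1, 0.95, 0.1)
    starts = []
    if model == "extended":
        for s2f0 in (0.6, 0.7, 0.8, 0.9, 0.95, 1.0):
            for s2 in s2_grid:
                if s2 > s2f0:
                    continue
                for te0 in te_starts:
                    starts.append([s2f0, s2 / s2f0, math.log10(te0)])
        bounds = [(0.0, 1.0), (0.0, 1.0), _LOG_TE_BOUNDS]
    else:
        for s2 in s2_grid:
            for te0 in te_starts:
                starts.append([s2, math.log10(te0)])
        bounds = [(0.0, 1.0), _LOG_TE_BOUNDS]

    ranked = sorted(starts, key=chi2)[:8]
    best = None
    for x0 in ranked:
        res = optimize.minimize(
            chi2, x0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun - 1e-18 or (
            abs(res.fun - best.fun) <= 1e-18
            and _unpack(res.x, model).s2 > _unpack(best.x, model).s2
        ):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"model-free fit failed from all {len(starts)} starts")

    params = _unpack(best.x, model)
    # tau_e carries no information when the dispersive amplitude vanishes
    indeterminate = bool(params.s2f - params.s2 < 1e-3)
    return ModelFreeFit(
        params=params,
        chi2=float(best.fun),
        model=model,
        tau_c=tau_c,
        constants=constants,
        tau_e_indeterminate=indeterminate,
        starts_tried=len(starts),
    )


@dataclass(frozen=True)
class JumpModelParams:
    """Two-site jump: populations summing to 1 and the inter-state angle."""

    p_a: float
    p_b: float
    theta_ab: float  # degrees

    def __post_init__(self):
        if abs(self.p_a + self.p_b - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        if not 0.0 <= self.theta_ab <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


def jump_order_parameter(params: JumpModelParams | None = None,
                         p_minor: float | None = None,
                         theta_deg: float | None = None) -> float:
    """S^2 = 1 - 3 p_a p_b sin^2(theta) for a two-site bond-vector jump.

    Accepts either a :class:`JumpModelParams` or ``(p_minor, theta_deg)``.
    """
    if params is None:
        if p_minor is None or theta_deg is None:
            raise ValueError("provide JumpModelParams or p_minor and theta_deg")
        params = JumpModelParams(p_a=1.0 - p_minor, p_b=p_minor, theta_ab=theta_deg)
    s = math.sin(math.radians(params.theta_ab))
    return 1.0 - 3.0 * params.p_a * params.p_b * s * s
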