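"""Independent oracle implementations used only to cross-check the package.

These deliberately take different mathematical routes from the library code:
the jump-rate oracle contracts rank-2 spherical harmonics via the addition
theorem instead of summing P2(cos theta) pairs; the Pearson oracle is the
textbook two-pass formula; the relaxation-ratio oracle uses the reduced
spectral-density approximation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import sph_harm_y


def jump_rate_spherical_harmonics(proton_positions: np.ndarray, probe: np.ndarray) -> float:
    """(1/9) * (4pi/5) * sum_m |sum_i Y2m(Omega_i)/r_i^3|^2 in A^-6 units.

    Equivalent to the pairwise P2 contraction by the addition theorem.
    """
    vecs = np.asarray(proton_positions, float) - np.asarray(probe, float)
    r = np.linalg.norm(vecs, axis=1)
    theta = np.arccos(np.clip(vecs[:, 2] / r, -1, 1))  # polar
    phi = np.arctan2(vecs[:, 1], vecs[:, 0])  # azimuth
    total = 0.0
    for m in range(-2, 3):
        s = np.sum(sph_harm_y(2, m, theta, phi) / r ** 3)
        total += abs(s) ** 2
    return float(4.0 * math.pi / 5.0 * total / 9.0)


def pearson_two_pass(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = np.sum((x - mx) * (y - my))
    den = math.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return float(num / den)


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return math.degrees(math.atan2(np.cross(b1, v) @ w, v @ w))


def staggered_phase_scan(
    carbon, antecedent, reference, substituents, build, n_grid: int = 72000
) -> float:
    """Brute-force rotor phase minimizing the worst proton/substituent eclipse.

    ``build(phase_deg)`` must return the three proton positions at that rotor
    phase; ``substituents`` are the antecedent's other substituent positions.
    Returns the optimal phase in degrees (within the 120-degree rotor period).
    """
    best_phase, best_cost = None, None
    for k in range(n_grid):
        phase = 120.0 * k / n_grid
        protons = build(phase)
        cost = max(
            math.cos(math.radians(dihedral_deg(h, carbon, antecedent, s)))
            for h in protons
            for s in substituents
        )
        if best_cost is None or cost < best_cost:
            best_phase, best_cost = phase, cost
    return best_phase


def rigid_r2_over_r1_reduced_j(tau_c: float, field_mhz: float,
                               r_nh: float = 1.02e-10,
                               csa_ppm: float = -126.0) -> float:
    """R2/R1 of a rigid vector via the reduced spectral-density mapping.

    High-frequency densities are collapsed onto J(0.87 wH); an independent
    approximation route, accurate to a few percent for rigid tumbling.
    """
    gh, gn = 2.6752218744e8, -2.7126180e7
    hbar, mu0_4pi = 1.054571817e-34, 1e-7
    wh = 2 * math.pi * field_mhz * 1e6
    wn = wh * gn / gh
    d = mu0_4pi * hbar * gh * gn / r_nh ** 3
    c = wn * csa_ppm * 1e-6 / math.sqrt(3.0)

    def j(w):
        return 0.4 * tau_c / (1.0 + (w * tau_c) ** 2)

    jh = j(0.87 * wh)
    r1 = d * d / 4.0 * (3.0 * j(wn) + 7.0 * jh) + c * c * j(wn)
    r2 = (
        d * d / 8.0 * (4.0 * j(0) + 3.0 * j(wn) + 13.0 * jh)
        + c * c / 6.0 * (4.0 * j(0) + 3.0 * j(wn))
    )
    return r2 / r1
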