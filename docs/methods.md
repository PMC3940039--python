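# Methods

## Scope and data flow

The package chains five analyses: (i) geometric NOE-rate prediction from
coordinates, (ii) two-conformer population fitting against experimental
volumes, (iii) model-free fitting of ¹⁵N relaxation, (iv) two-site jump
order parameters, and (v) population thermodynamics, plus (vi) a
differential chemical-shift / linebroadening correlation. Every stage can be
driven either from real inputs (coordinate files, tabulated volumes,
measured rates) or from the synthetic-data generator.

## Methyl NOE prediction

**Proton building.** Deposited structures rarely carry reliable methyl
hydrogens, so protons are built at idealized geometry: |C–H| = 1.09 Å,
H–C–antecedent angle 109.47°, three rotor positions 120° apart, phased to
the staggered rotamer (anti/gauche to the antecedent's substituents). Only
volume *ratios* within a structure enter the analysis, which makes the
predictions insensitive to the bond-length convention. If a file carries all
three protons of a methyl, a flag allows using them verbatim.

**Jump-averaged rate.** For fast three-site rotor jumps the effective
dipolar rate with a distal proton is

σ_eff = (1/18) Σᵢⱼ [3cos²θᵢⱼ − 1]/(rᵢ³ rⱼ³)   (Å⁻⁶ units)

with rᵢ the proton–probe distances and θᵢⱼ the angle subtended at the probe.
A widely reproduced shorthand for this expression keeps only the rⱼ³ factor
in the denominator; that form is dimensionally inconsistent for a pairwise
dipolar average, and the symmetric rᵢ³rⱼ³ form is the one that satisfies the
far-field 1/r⁶ limit and reproduces the reference predictions, so it is the
one implemented. The implementation is cross-checked in the test suite
against an independent rank-2 spherical-harmonics contraction (addition
theorem) to 10⁻⁸ relative on random geometries.

All physical prefactors (γ⁴ħ², τc, the initial-rate factor 6J(2ω) − J(0))
are identical across methyls within one structure and cancel in normalized
ratios; they are not applied. The initial-rate factor itself is exposed for
sign/regime reasoning (positive in extreme narrowing, zero at ωτc = √5/2,
negative for slow tumbling).

**Gating and bookkeeping.** Methyls whose *carbon* lies beyond the cutoff
(default 7 Å) from the probe proton are excluded; the carbon→probe distance
is the gating distance because that is the convention of the reference
distance tabulation. Chemically shift-degenerate methyl pairs that appear as
one cross-peak are merged by summing raw rates before normalization (the
bundled FKBP12 dataset merges Val63 CG1 into the Val101 CG2 peak, a ~4%
contribution). A per-entry exclusion list handles entries deliberately
omitted from one structure's prediction (the wild-type Val101 CG1 entry in
the bundled dataset).

**Single-point approximations.** `carbon` and `mean-proton` modes compute
1/r⁶ from one point. Mean-proton shares the proton centroid with the jump
average and so agrees with it at second order in (methyl radius/distance);
the carbon is axially offset from that centroid by ~0.36 Å and differs at
first order. Neither captures the angular structure of the jump average:
for probes near the rotor axis the mean-proton model inflates both the
radial and angular parts, which is why it degrades most in the mixture
comparison.

## Two-conformer mixture fit

Predictions from conformers A and B are each normalized to their own
maximum; the fixed inter-structure scale (ratio of absolute maximum raw
rates, A/B) restores their relative intensities. The mixture

v(k; p) ∝ p·scale·A(k) + (1−p)·B(k)

is renormalized to its maximum and compared with the experimental volumes
over all common entries, including the self-normalizing anchor (N = 9 for
the bundled dataset; reconstruction from the tabulated rounded values gives
RMSD 0.088 and r 0.976 at p = 0.80, which sets the tolerance bands used in
tests). RMSD(p) is scanned on a grid (default 1%), the argmin refined by
bounded minimization to 10⁻⁴ inside the bracketing interval, with grid ties
broken toward larger p (toward conformer A — arbitrary, documented). The
scale is an input, not a fit parameter; it defaults to the value computed
from the prediction tables and is overridable. Entries beyond the cutoff in
one conformer contribute exactly zero from that conformer rather than being
dropped. A flat RMSD trace (identical tables) is reported as degenerate with
p = 0.5.

The carbon-centroid comparison can be run either from full geometry or
directly from tabulated carbon→probe distances; the scale is always
recomputed per mode (for the bundled distances, (3.32/4.14)⁶ ≈ 0.266).

## Model-free ¹⁵N relaxation

Extended model-free spectral density with the fast internal motion in the
extreme-narrowing limit (it then contributes no dispersive term):

J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (S_f²−S²)τ′/(1+(ωτ′)²)],  1/τ′ = 1/τc + 1/τₑ

with S² = S_f²·S_s². R₁, R₂ and the heteronuclear NOE use the standard
¹⁵N dipolar + CSA expressions with d = (μ₀/4π)ħγHγN/r³ and c = ωN·CSA/√3
(axially symmetric CSA collinear with N–H). Defaults: r_NH = 1.02 Å (the
dominant systematic knob for the fitted S²; a shorter convention shifts S²
up by several percent), CSA −126 ppm (indole Nε1), field 600 MHz, τc fixed
externally (5.8 ns for the reference system). R_ex is fixed at 0 for the
indole fit — the resonances involved show no exchange broadening.

The fit is unweighted least squares (no uncertainties tabulated for the
reference rates), exactly identified for the extended model (3 observables,
3 parameters). Multi-start: a coarse grid over (S_f², S², τₑ) is ranked by
χ² and the best eight starts are refined with bounded Nelder–Mead on
(S_f², S_s², log₁₀τₑ), bounds [0,1]² × [1 ps, 30 ns]; ties go to lowest χ²
then largest S². τₑ is flagged indeterminate when the dispersive amplitude
S_f² − S² falls below 10⁻³ (e.g. rigid input), since it then carries no
information.

For the two-site jump, S² = 1 − 3p_a p_b sin²θ_ab, symmetric under
p_a ↔ p_b and θ → 180°−θ, bounded by [1 − 3p_a p_b, 1].

## Thermodynamics

ΔG = −RT·ln(p_minor/p_major), positive when the minor state is higher in
free energy; R = 8.314 J mol⁻¹ K⁻¹, default T = 298.15 K (measurements at
25 °C). ΔΔG = ΔG₁ − ΔG₂ requires a shared temperature and is antisymmetric;
over any closed cycle of states it sums to zero.

## Differential shifts vs exchange linebroadening

Absolute structure-based ¹⁵N shift predictions carry ~2.5 ppm errors, so
predictions are consumed only differentially between conformational models
of a common sequence (disparate residues computationally mutated to alanine,
tracked by an explicit one-to-one residue mapping; unmapped residues are
reported, never silently dropped). Aggregation is either per comparison
structure or |δ_ref − mean(δ_comp)| (mean before the absolute value — the
two differ whenever per-structure differences change sign, which the tests
exercise). The correlation with measured Δex linebroadening is Pearson's r
(the choice of statistic is a package decision), over residues that are
flagged reliable and exceed the significance threshold (default 0.4 Hz);
used + below-threshold + unreliable + unmatched counts always sum to the
input size. The shift predictor itself is external; only its tabular output
is parsed.

## Synthetic-data generator

The scene generator emulates the reference situation: a probe N–H proton
(indole-like, with two in-plane ring neighbors fixing its frame) surrounded
by methyl-bearing residues; a second conformer reorients the probe bond
vector by a configurable angle (default 83°) and displaces a subset of the
residues. Design choices that mirror the real packing:

- **ILE-like residues** (default 2) place a single terminal methyl at
  3.6–5.0 Å with its rotor axis tilted only 5–25° from the probe direction —
  the near-axis geometry that separates the jump model from the mean-proton
  approximation.
- **VAL-like residues** (default 3) sit side-on (CB at 4.5–8.0 Å, CB→CA
  nearly anti to the probe), providing moderate-angle methyl pairs and the
  degenerate-pair topology for merge bookkeeping.
- **Conformer contrast**: displacement default 2.5 Å for ~2/3 of the
  residues, matching the magnitude of methyl–probe distance changes a ring
  flip produces in the reference structure pair (up to ~3.5 Å).

Volumes are simulated as the mixture prediction at the true population with
multiplicative log-normal noise (σ default 5%; peak-volume errors scale with
intensity — the error model is a package choice, none being tabulated), then
renormalized. Relaxation observables are forward-computed from known
model-free parameters with optional fractional Gaussian noise. All
generators are pure functions of (config, seed); conformer-B displacement
draws that produce inter-residue contacts below 1.5 Å are redrawn from the
same seeded stream, so generation remains deterministic.

What the generator does **not** emulate: spin diffusion (the analysis
assumes deuteration suppresses it and no relaxation-matrix treatment is
included), anisotropic tumbling, internal motion of the scaffold itself
beyond the two discrete conformers, chemically realistic side-chain
connectivity beyond the atoms the models consume, and experimental
normalization artifacts (the simulated volumes are already
HSQC-compensated by construction). Passing the synthetic recovery tests
therefore demonstrates correctness of the estimators under the stated error
model, not robustness to those unmodelled effects in real spectra.

Under the default conditions, population recovery from σ = 5% noisy volumes
lands within ±0.05 of truth in ≥90% of replicates, and the model-quality
ordering jump < carbon < mean-proton holds for the large majority of seeds.

## Numerical choices and degenerate inputs

- Altloc policy defaults to highest occupancy (ties to the earlier altloc
  letter); the reference variant structure has 0.71/0.29 dual conformers and
  the analysis uses the major one.
- Coordinates are orthogonal Å; no symmetry expansion; residue numbering is
  taken verbatim from the file.
- Superpositions are least-squares rigid-body (Kabsch) on user-specified
  reference atom sets; bond-vector angles are measured after superposition
  and clipped into [0°, 180°].
- Coincident probe/proton positions, non-positive distances, empty
  selections and mode mismatches raise typed errors; a cutoff that excludes
  every methyl produces an empty table with a warning, not an error.
- Probe H–heavy bond lengths are validated to [0.8, 1.2] Å; built planar
  (indole N–H) protons use 0.98 Å along the exterior ring bisector.

## Problem sizes

The bundled dataset has 9 NOE entries; synthetic scenes default to 5
residues (8 methyls). Statistical checks in the test suite use 1000 random
geometries for the rate-oracle comparison, 200 noisy replicates for
population recovery, and 100 random parameter sets for model-free
round-trips — sizes at which the checked proportions are stable from seed
to seed.

## Known limitations

- No relaxation-matrix (spin-diffusion) NOE treatment; initial-rate regime
  only.
- No three-or-more conformer mixtures; no per-entry volume weighting.
- No global τc or diffusion-tensor optimization; isotropic tumbling only.
- The two-site jump S² ignores fast librational averaging (which scales
  well-ordered amide order parameters to ~0.85), so it is an upper-bound
  style estimate to compare with, not a replacement for, the model-free S².
- mmCIF input is parsed by gemmi; exotic altloc schemes beyond per-atom
  letters are not specially handled.
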