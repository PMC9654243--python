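# Methods

This note records the model implemented by `hopct`, the numerical and
design choices made where the underlying theory leaves freedom, and what
the synthetic-data generators do and do not establish.

## Model and assumptions

The package treats a charge-transfer reaction as a transition between
two diabatic states that are vibrational ground states of two minima
(R, P) of the *same* electronic ground state, embedded in a
semiclassical atomistic environment. The key assumptions inherited from
that picture:

- the QC (e.g. a guanine base) is rigid or semi-rigid, so a single set
  of unperturbed electronic properties (energies, per-state ESP
  charges, transition dipoles) describes it at every frame;
- the environment acts only electrostatically, through the potential at
  each QC atom (first order, via the per-state charges) and the field
  at the center of mass (off-diagonal, via transition dipoles);
- donor and acceptor are electronically independent, so the two-center
  transition energy is the sum of two one-center redox energy changes
  (reaction schemes I/II); the schemes agree exactly when the partner's
  charge state does not perturb the QC, and the package provides a
  far-separated synthetic construction to verify that;
- outside a tiny transition region the kinetics is classical (rate
  equations); inside it, a Landau–Zener single passage decides the
  adiabatic fraction;
- R and P share harmonic modes and frequencies, differing in minimum
  position (and possibly slightly in frequency, which is tolerated and
  audited rather than assumed away).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| temperature | K | 300 | thermal energy k_BT classifies quantum vs semiclassical modes and scales ΔA‡ |
| ΔV (short-range diagonal term) | hartree | 0 | rigid shift inside one species; cancels in all within-species transition energies, so it only matters between redox species where no general recipe exists |
| validity window on \|⟨ΔU⟩\|/σ | — | (3, 10) | Gaussian range must include ΔU = 0 without the crossing being implausibly far out; violations warn, never fail |
| equal-frequency tolerance | relative | 5% | paired R/P modes beyond it trigger a warning (shared-frequency assumption strained) |
| Duschinsky mixing threshold | squared element | 0.8 | below it the independent-mode picture behind the per-mode coupling sum degrades; warned |
| quadrature | hartree | 1e-12 abs per integral, ±8 ground-state widths | overlaps/coupling integrals must be exact to far below any physically meaningful coupling |

## Numerical choices

**⟨v⟩ estimator.** The mean |dΔU/dt| is estimated by forward
per-interval differences on the sampling grid. For a series that is
smooth on the frame spacing, forward and central differences agree; for
a series that is rough at the sampling interval (the Ornstein–Uhlenbeck
generator is the extreme case: nowhere differentiable), a central
difference spans 2·dt and systematically underestimates the grid-scale
speed by √2, which would bias the rate by the same factor relative to
crossing counting on that grid. The forward estimator keeps the
Gaussian rate and the brute-force crossing oracle mutually consistent
at any sampling interval. The central-difference and folded-Gaussian
(√(2/π)·σ_v) variants are both computed and reported so the user can
detect under-resolved sampling: a large gap between forward and central
estimates means the measured rate carries a sampling-scale ambiguity
that only a finer frame spacing can resolve.

**Diabatization.** c₁, c₂ are computed in closed form
(c₁ = (1/√(1−S) + 1/√(1+S))/2, c₂ = (1/√(1−S) − 1/√(1+S))/2), which
satisfies both defining identities exactly for |S| < 1; |S| ≥ 1
(coincident minima) is rejected as degenerate.

**Per-mode coupling curves.** The electronic energy change along each
quantum mode follows the R parabola up to the R/P parabola intersection
and the P parabola beyond it. The per-mode parabola minima are taken
degenerate, because at the diabatic crossing the *total* R and P
energies are equal and no per-mode offset is defined by the theory;
with equal frequencies this puts the switch point midway between the
minima (for unequal frequencies, at ω_P·Δβ/(ω_R+ω_P)). Overlaps use
the exact two-frequency displaced-Gaussian formula, which reduces to
exp(−ωΔβ²/4) when ω_R = ω_P. Integrals are adaptive quadrature
(`scipy.integrate.quad`) with the switch point passed as a breakpoint.

**Landau–Zener variant.** The standard two-state single-passage
expression χ = 1 − exp(−2πH²/(ħ·v_cr)) with ħ = 1. When no crossing
ensemble is available (the Gaussian-approximation regime), v_cr
defaults to ⟨v⟩ from the series statistics. Both the variant and the
velocity used are recorded in the pipeline report so results remain
auditable against alternative conventions.

**Eigenvalue ties.** Eigenvectors are sign-fixed (first nonzero
coefficient positive) so degenerate spectra yield reproducible
ground-state coefficients.

**Landau profile.** Histogram binning defaults to Freedman–Diaconis;
A(ΔU) = −k_BT·ln(density) on occupied bins; the quadratic is fitted
within 2σ of the profile minimum, excluding (and warning about) empty
bins in range. Degenerate inputs — constant series, fewer than three
occupied bins, non-positive curvature — are flagged or rejected rather
than silently fitted.

**Center of mass.** The field expansion point is the mass-weighted
center of the fixed reference geometry (rigid-QC assumption); per-frame
geometries can be supplied to `QCStateSet.center_of_mass` when the QC
is flexible.

## Synthetic data: what it emulates, what it does not

The generators exist so every stage is testable without electronic
structure or MD inputs:

- `gen_ou_series` emulates stationary Gaussian transition-energy
  fluctuations with exact discretization (stationary moments exact at
  any dt, so oracle comparisons carry no integrator bias). Real MD
  transition energies are smooth below the frame spacing and carry
  non-exponential correlation structure; the OU fixture therefore
  exercises the statistics, not the dynamics, of real data.
- `gen_toy_qc` / `gen_redox_pair` produce structurally valid state sets
  (charge sums, dipole symmetry, ascending energies) with an imposed
  ionization gap; they have no quantum-chemical realism.
- `gen_env_trajectory` produces labeled fluctuating point charges. In
  the imposed-covariance modes the two sources share anchor sites and
  base charges with a common scalar breathing fluctuation (negated for
  anticorrelation) — this guarantees the imposed correlation sign
  propagates to the transition-energy contributions, at the price of
  physically unrealistic coincident sources. It validates the
  decomposition machinery, not solvent/DNA electrostatics.
- `gen_harmonic_pair` builds displaced equal-frequency minima with a
  shared orthonormal eigenvector basis, plus optional frequency jitter
  and a two-mode rotation to exercise the audit warnings.

Consequently, passing tests demonstrate internal consistency (formula
correctness against independent oracles, exact identities, recovery of
imposed parameters) — not agreement with experimental CT rates, which
requires real MD perturbation trajectories and quantum-chemical QC
properties supplied by the user.

Problem sizes used by the test suite and the acceptance script were
chosen to make sampling error comfortably smaller than the checked
tolerances: 10⁷ OU steps for the rate/crossing comparison (≈3500
crossings at mean = 3σ, ≈2% counting error against a 10% tolerance),
2×10⁴ PMM frames for the end-to-end recovery (moment sampling error
≈5% against 10%), and ≥10⁵ samples for distributional checks.

## Known limitations

- No Duschinsky rotation of the wavefunctions: mode mixing is detected
  and warned about, not propagated into the overlaps.
- The semiclassical-coordinate shift between minima is reported but not
  corrected for; a large shift undermines the factorized ground-state
  ansatz.
- Scheme II environments must be supplied by the caller with the
  correct intermediate charge states; the package validates alignment,
  not charge-state consistency.
- Perturbation effects on H_RP are neglected (unperturbed vibrational
  states throughout), as appropriate for rigid QCs.
- Anharmonicity, excited vibrational states, proton-transfer coupling
  and electronic non-adiabatic couplings are out of scope.
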