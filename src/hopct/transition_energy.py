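"""Charge-transfer transition energies from per-frame perturbations.

The hole hop D+ + A -> D + A+ is split into two one-electron redox steps
on electronically independent quantum centers.  Scheme I reduces the
donor first and then oxidizes the acceptor; scheme II runs the acceptor
oxidation first (with frames generated in the matching intermediate
charge states).  Per frame,

    dU = dU(D+ -> D; donor frame) + dU(A -> A+; acceptor frame)

and the diabatic crossing is dU = 0.  The module also decomposes the
series into environment-source contributions (solvent vs helix) and
reconstructs the Landau free-energy profile A(dU) = -kB T ln rho(dU).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .constants import thermal_energy
from .pmm import (
    PerturbationFrame,
    QCStateSet,
    ValidationError,
    redox_energy_change,
)

logger = logging.getLogger("hopct")

__all__ = [
    "TransitionEnergySeries",
    "FreeEnergyProfile",
    "ContributionReport",
    "scheme_I_series",
    "scheme_II_series",
    "decompose_contributions",
    "landau_free_energy",
]

_TIME_ALIGN_TOL = 1e-9
_STEP_SUM_TOL = 1e-10


@dataclass
class TransitionEnergySeries:
    """Time-ordered charge-transfer transition energies (hartree)."""

    times: np.ndarray
    values: np.ndarray
    scheme: str = "I"
    step_values: np.ndarray | None = None  # (n, 2): per-step energies
    contributions: dict | None = None  # source label -> per-frame series
    unperturbed_offsets: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values differ in length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("transition energies must be finite")
        if self.step_values is not None:
            self.step_values = np.asarray(self.step_values, dtype=float)
            if self.step_values.shape != (len(self.values), 2):
                raise ValidationError("step_values must be (n_frames, 2)")
            if np.max(
                np.abs(self.step_values.sum(axis=1) - self.values), initial=0.0
            ) > _STEP_SUM_TOL:
                raise ValidationError("step values do not sum to totals")
        if self.contributions is not None:
            self.contributions = {
                k: np.asarray(v, dtype=float) for k, v in self.contributions.items()
            }
            for k, v in self.contributions.items():
                if v.shape != self.values.shape:
                    raise ValidationError(f"contribution '{k}' has wrong length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FreeEnergyProfile:
    """Histogram-based Landau free energy along the transition energy."""

    bin_centers: np.ndarray  # only bins with nonzero counts
    a_values: np.ndarray  # hartree, up to an additive constant
    mode: float  # dU at the fitted minimum
    curvature: float  # quadratic coefficient * 2 (d2A/dU2), hartree^-1
    fit_range: tuple  # (lo, hi) of dU used in the fit
    temperature: float


@dataclass
class ContributionReport:
    """Source decomposition of a transition-energy series."""

    mean_total: float
    means: dict  # source label -> mean contribution
    additivity_residual: float
    regression_slope: float | None
    regression_intercept: float | None
    regression_r: float | None
    source_pair: tuple | None


def _check_aligned(donor_frames, acceptor_frames):
    if len(donor_frames) != len(acceptor_frames):
        raise ValidationError("donor and acceptor frame sequences differ in length")
    for i, (fd, fa) in enumerate(zip(donor_frames, acceptor_frames)):
        if abs(fd.time - fa.time) > _TIME_ALIGN_TOL * max(1.0, abs(fd.time)):
            raise ValidationError(
                f"donor/acceptor frames misaligned at index {i}: "
                f"{fd.time} vs {fa.time}"
            )


def _series_from_steps(
    step1_pair, step2_pair, step1_frames, step2_frames, scheme, sources
):
    """Shared scheme driver: two redox steps evaluated frame by frame."""
    qc_i1, qc_f1 = step1_pair
    qc_i2, qc_f2 = step2_pair
    times = np.array([f.time for f in step1_frames], dtype=float)
    n = len(times)
    steps = np.empty((n, 2))
    for i, (f1, f2) in enumerate(zip(step1_frames, step2_frames)):
        steps[i, 0] = redox_energy_change(qc_i1, qc_f1, f1)
        steps[i, 1] = redox_energy_change(qc_i2, qc_f2, f2)
    values = steps.sum(axis=1)

    contributions = None
    if sources:
        # Re-evaluate the PMM with source-filtered perturbations rather
        # than subtracting: the diagonalization is not exactly linear.
        contributions = {}
        for lab in sources:
            c = np.empty(n)
            for i, (f1, f2) in enumerate(zip(step1_frames, step2_frames)):
                c[i] = redox_energy_change(
                    qc_i1, qc_f1, f1.restricted_to(lab)
                ) + redox_energy_change(qc_i2, qc_f2, f2.restricted_to(lab))
            contributions[lab] = c

    offsets = (
        float(qc_f1.state_energies[0] - qc_i1.state_energies[0]),
        float(qc_f2.state_energies[0] - qc_i2.state_energies[0]),
    )
    series = TransitionEnergySeries(
        times=times,
        values=values,
        scheme=scheme,
        step_values=steps,
        contributions=contributions,
        unperturbed_offsets=offsets,
    )
    if n >= 3 and series.values.mean() < 0:
        warnings.warn(
            "sampled mean transition energy is negative: the reactant "
            "ensemble should sit at dU > 0 — R/P labels may be swapped",
            stacklevel=2,
        )
    return series


def _common_sources(donor_frames, acceptor_frames):
    first = donor_frames[0] if len(donor_frames) else None
    if first is None or first.source_components is None:
        return None
    labels = list(first.source_components)
    for f in list(donor_frames) + list(acceptor_frames):
        if f.source_components is None or list(f.source_components) != labels:
            return None
    return labels


def scheme_I_series(
    donor_cation: QCStateSet,
    donor_neutral: QCStateSet,
    acceptor_neutral: QCStateSet,
    acceptor_cation: QCStateSet,
    donor_frames,
    acceptor_frames,
) -> TransitionEnergySeries:
    """Transition energies via scheme I: donor reduction, then acceptor
    oxidation (e- + D+ + A -> D + A -> D + A+ + e-).

    Frames must be time-aligned between the two centers; they should be
    generated with the reactant charge states (hole on the donor) since
    scheme I treats the partner species as part of the environment in its
    reactant state.
    """
    _check_aligned(donor_frames, acceptor_frames)
    sources = _common_sources(donor_frames, acceptor_frames)
    return _series_from_steps(
        (donor_cation, donor_neutral),
        (acceptor_neutral, acceptor_cation),
        donor_frames,
        acceptor_frames,
        scheme="I",
        sources=sources,
    )


def scheme_II_series(
    donor_cation: QCStateSet,
    donor_neutral: QCStateSet,
    acceptor_neutral: QCStateSet,
    acceptor_cation: QCStateSet,
    donor_frames,
    acceptor_frames,
) -> TransitionEnergySeries:
    """Transition energies via scheme II: acceptor oxidation first
    (D+ + A -> D+ + A+ + e- -> D + A+).

    The caller supplies frames consistent with the intermediate charge
    states (acceptor frames see D+ in the environment; donor frames see
    A+).  The two schemes agree when donor and acceptor perturb each
    other negligibly.
    """
    _check_aligned(donor_frames, acceptor_frames)
    sources = _common_sources(donor_frames, acceptor_frames)
    series = _series_from_steps(
        (acceptor_neutral, acceptor_cation),
        (donor_cation, donor_neutral),
        acceptor_frames,
        donor_frames,
        scheme="II",
        sources=sources,
    )
    # report offsets in (step1, step2) order of the scheme as run
    return series


def decompose_contributions(series: TransitionEnergySeries) -> ContributionReport:
    """Dissect the mean transition energy into environment-source parts.

    Reports each source's mean contribution, the additivity residual
    <dU_total> - sum of source means (zero to first order: the diagonal
    of the perturbed Hamiltonian is linear in the potentials), and the
    least-squares regression of the first source's per-frame contribution
    on the second's (negative slope = anticorrelated sources).
    """
    if not series.contributions:
        raise ValidationError("series carries no per-source contributions")
    means = {k: float(v.mean()) for k, v in series.contributions.items()}
    mean_total = float(series.values.mean())
    residual = mean_total - sum(means.values())
    slope = intercept = rvalue = None
    pair = None
    labels = list(series.contributions)
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        pair = (b, a)
        x = series.contributions[b]
        y = series.contributions[a]
        if np.ptp(x) > 0:
            res = _stats.linregress(x, y)
            slope, intercept, rvalue = (
                float(res.slope),
                float(res.intercept),
                float(res.rvalue),
            )
    return ContributionReport(
        mean_total=mean_total,
        means=means,
        additivity_residual=float(residual),
        regression_slope=slope,
        regression_intercept=intercept,
        regression_r=rvalue,
        source_pair=pair,
    )


def landau_free_energy(
    series: TransitionEnergySeries,
    temperature: float,
    n_bins: int | None = None,
) -> FreeEnergyProfile:
    """Histogram estimate of the Landau free energy A(dU).

    A(dU) = -kB T ln rho(dU) up to an additive constant; a quadratic is
    fitted to the occupied bins within two sample standard deviations of
    the profile minimum.  For Gaussian fluctuations the curvature equals
    kB T / sigma^2 and the mode coincides with the sample mean.
    """
    kbt = thermal_energy(temperature)
    x = series.values
    if len(x) < 10:
        raise ValidationError("need at least 10 samples for a profile")
    if n_bins is None:
        edges = np.histogram_bin_edges(x, bins="fd")
    else:
        edges = np.histogram_bin_edges(x, bins=int(n_bins))
    counts, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    if occupied.sum() < 3:
        raise ValidationError("fewer than 3 occupied histogram bins")
    centers_o = centers[occupied]
    a_vals = -kbt * np.log(counts[occupied])

    sigma = float(x.std(ddof=1))
    mode0 = centers_o[np.argmin(a_vals)]
    lo, hi = mode0 - 2 * sigma, mode0 + 2 * sigma
    in_range = (centers_o >= lo) & (centers_o <= hi)
    n_empty = int(((centers >= lo) & (centers <= hi) & ~occupied).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} empty bins inside the quadratic fit range were excluded",
            stacklevel=2,
        )
    if in_range.sum() < 3:
        raise ValidationError("fewer than 3 occupied bins in the fit range")
    coeffs = np.polyfit(centers_o[in_range], a_vals[in_range], deg=2)
    curvature = 2.0 * coeffs[0]
    mode = -coeffs[1] / (2.0 * coeffs[0]) if coeffs[0] != 0 else mode0
    if curvature <= 0:
        warnings.warn(
            "non-positive fitted curvature: distribution is not Gaussian-like",
            stacklevel=2,
        )
    return FreeEnergyProfile(
        bin_centers=centers_o,
        a_values=a_vals,
        mode=float(mode),
        curvature=float(curvature),
        fit_range=(float(lo), float(hi)),
        temperature=float(temperature),
    )
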