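"""Synthetic fixtures: OU transition-energy series, toy quantum centers,
labeled point-charge environments, displaced harmonic minima pairs, and
the brute-force level-crossing oracle.

The Ornstein-Uhlenbeck generator emulates stationary Gaussian
transition-energy fluctuations; the crossing counter provides the
independent rate estimate that the Gaussian-approximation formula must
reproduce.  All generators are deterministic under their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .pmm import PointChargeEnvironment, QCStateSet, ValidationError
from .transition_energy import TransitionEnergySeries

logger = logging.getLogger("hopct")

__all__ = [
    "OUParams",
    "gen_ou_series",
    "count_level_crossings",
    "gen_toy_qc",
    "gen_redox_pair",
    "gen_env_trajectory",
    "gen_harmonic_pair",
]


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck parameters for a synthetic dU series.

    mean/sigma in hartree, tau (correlation time) and dt in a.u. time.
    dt must resolve the correlation time (dt < tau/2).
    """

    mean: float
    sigma: float
    tau: float
    dt: float
    n_steps: int
    seed: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.dt >= self.tau / 2:
            raise ValidationError("dt must be < tau/2 to resolve the process")
        if self.n_steps < 2:
            raise ValidationError("need at least 2 steps")


def gen_ou_series(p: OUParams) -> TransitionEnergySeries:
    """Exact-discretization OU path started from the stationary law.

    X_{k+1} = mean + rho (X_k - mean) + sigma sqrt(1 - rho^2) xi_k with
    rho = exp(-dt/tau); stationary moments are exact at any dt (no
    integrator bias to pollute oracle comparisons).
    """
    rng = np.random.default_rng(p.seed)
    rho = np.exp(-p.dt / p.tau)
    noise = rng.standard_normal(p.n_steps)
    scale = np.full(p.n_steps, p.sigma * np.sqrt(1.0 - rho * rho))
    scale[0] = p.sigma  # stationary start: first sample at full std
    # AR(1) recursion y_k = rho y_{k-1} + scaled noise, vectorized
    y = lfilter([1.0], [1.0, -rho], noise * scale)
    times = np.arange(p.n_steps, dtype=float) * p.dt
    return TransitionEnergySeries(times=times, values=p.mean + y, scheme="I")


def count_level_crossings(
    series: TransitionEnergySeries | np.ndarray,
    level: float = 0.0,
    direction: str = "down",
    times: np.ndarray | None = None,
):
    """Count sign changes of (value - level) in one direction.

    ``direction`` is "down" (above -> below; the reactant at dU > 0
    reaching the crossing), "up", or "both".  Returns (count, rate per
    a.u. time over the spanned interval).
    """
    if isinstance(series, TransitionEnergySeries):
        values, times = series.values, series.times
    else:
        values = np.asarray(series, dtype=float)
        if times is None:
            raise ValidationError("times required when passing a bare array")
        times = np.asarray(times, dtype=float)
    if len(values) < 2:
        raise ValidationError("need at least 2 points")
    s = values - level
    down = (s[:-1] > 0) & (s[1:] <= 0)
    up = (s[:-1] <= 0) & (s[1:] > 0)
    if direction == "down":
        count = int(down.sum())
    elif direction == "up":
        count = int(up.sum())
    elif direction == "both":
        count = int(down.sum() + up.sum())
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    total_time = float(times[-1] - times[0])
    return count, count / total_time if total_time > 0 else float("nan")


def gen_toy_qc(
    seed: int,
    n_atoms: int = 4,
    n_states: int = 3,
    total_charge: int = 0,
    species_label: str | None = None,
    energy_offset: float = 0.0,
    geometry: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> QCStateSet:
    """Random but valid quantum-center state set.

    Charges sum to ``total_charge`` per state, dipoles are symmetric,
    energies ascend from ``energy_offset``.  Passing ``geometry`` and
    ``masses`` lets two redox species share the same nuclei.
    """
    rng = np.random.default_rng(seed)
    if masses is None:
        masses = rng.uniform(1800.0, 30000.0, size=n_atoms)
    if geometry is None:
        geometry = rng.uniform(-2.0, 2.0, size=(n_atoms, 3))
    charges = rng.uniform(-0.5, 0.5, size=(n_states, n_atoms))
    charges += (total_charge - charges.sum(axis=1))[:, None] / n_atoms
    gaps = rng.uniform(0.05, 0.25, size=n_states - 1)
    energies = energy_offset + np.concatenate([[0.0], np.cumsum(gaps)])
    dipoles = {}
    for l in range(n_states):
        for lp in range(l + 1, n_states):
            dipoles[(l, lp)] = rng.uniform(-1.0, 1.0, size=3)
    return QCStateSet(
        species_label=species_label or f"toy_q{total_charge}_{seed}",
        total_charge=total_charge,
        atom_masses=np.asarray(masses, float),
        reference_geometry=np.asarray(geometry, float),
        state_energies=energies,
        state_charges=charges,
        transition_dipoles=dipoles,
    )


def gen_redox_pair(
    seed: int,
    n_atoms: int = 4,
    n_states: int = 3,
    ionization_gap: float = 0.2796,
):
    """A (neutral, cation) pair on the same nuclei.

    The cation ground state sits ``ionization_gap`` hartree above the
    neutral ground state, so the unperturbed oxidation transition energy
    is exactly the gap and a donor/acceptor pair of the same species has
    null total unperturbed transition energy.
    """
    rng = np.random.default_rng(seed)
    masses = rng.uniform(1800.0, 30000.0, size=n_atoms)
    geometry = rng.uniform(-2.0, 2.0, size=(n_atoms, 3))
    neutral = gen_toy_qc(
        seed + 1,
        n_atoms,
        n_states,
        total_charge=0,
        species_label=f"toy_neutral_{seed}",
        geometry=geometry,
        masses=masses,
    )
    cation = gen_toy_qc(
        seed + 2,
        n_atoms,
        n_states,
        total_charge=1,
        species_label=f"toy_cation_{seed}",
        energy_offset=ionization_gap,
        geometry=geometry,
        masses=masses,
    )
    return neutral, cation


def gen_env_trajectory(
    seed: int,
    n_frames: int,
    sources: tuple = ("solvent", "helix"),
    n_charges_per_source: int = 6,
    radius: float = 8.0,
    base_charge_scale: float = 1.0,
    charge_scale: float = 0.1,
    position_noise: float = 0.3,
    covariance_sign: int = 0,
):
    """Sequence of labeled point-charge environments around the origin.

    Each source owns fixed anchor sites on a shell of the given radius
    (bohr); per frame the positions jitter and the charges fluctuate.
    ``covariance_sign`` (+1/-1/0) imposes the sign of the correlation
    between the first two sources' fluctuations.  In the correlated
    modes the second source mirrors the first's anchor sites and base
    charges and the fluctuation is a shared scalar breathing mode (the
    second source's negated for -1), so the imposed sign provably
    propagates to downstream transition-energy contributions instead of
    depending on how random couplings happen to combine.
    """
    rng = np.random.default_rng(seed)
    anchors = {}
    base_q = {}
    for k, src in enumerate(sources):
        if covariance_sign != 0 and k == 1:
            anchors[src] = anchors[sources[0]].copy()
            base_q[src] = base_q[sources[0]].copy()
            continue
        direc = rng.standard_normal((n_charges_per_source, 3))
        direc /= np.linalg.norm(direc, axis=1)[:, None]
        anchors[src] = direc * radius
        base_q[src] = base_charge_scale * rng.uniform(
            -1.0, 1.0, size=n_charges_per_source
        )
    frames = []
    for _ in range(n_frames):
        common = rng.standard_normal()
        positions, charges, labels = [], [], []
        for k, src in enumerate(sources):
            pos = anchors[src] + position_noise * rng.standard_normal(
                (n_charges_per_source, 3)
            )
            if covariance_sign != 0 and len(sources) >= 2 and k <= 1:
                fluct = common if k == 0 else covariance_sign * common
                q = base_q[src] * (1.0 + charge_scale * fluct)
            else:
                q = base_q[src] + charge_scale * rng.standard_normal(
                    n_charges_per_source
                )
            positions.append(pos)
            charges.append(q)
            labels.extend([src] * n_charges_per_source)
        frames.append(
            PointChargeEnvironment(
                positions=np.vstack(positions),
                charges=np.concatenate(charges),
                labels=labels,
            )
        )
    return frames


def gen_harmonic_pair(
    seed: int,
    n_modes: int = 5,
    dim: int | None = None,
    freq_range_cm: tuple = (300.0, 1800.0),
    displacement_range: tuple = (0.0, 20.0),
    freq_jitter: float = 0.0,
    rotation_angle: float = 0.0,
):
    """Displaced harmonic minima pair sharing orthonormal eigenvectors.

    Frequencies are drawn in ``freq_range_cm`` (cm^-1, converted to
    hartree); displacements along the shared modes in
    ``displacement_range`` (mass-weighted a.u.).  ``freq_jitter`` applies
    a relative perturbation to the P frequencies and ``rotation_angle``
    rotates the first two P eigenvectors, exercising the Duschinsky
    mixing and frequency-mismatch warnings.
    """
    from .constants import cm1_to_hartree
    from .vibronic import HarmonicMinimum

    rng = np.random.default_rng(seed)
    if dim is None:
        dim = n_modes + 3
    basis, _ = np.linalg.qr(rng.standard_normal((dim, n_modes)))
    freqs = np.sort(
        cm1_to_hartree(rng.uniform(freq_range_cm[0], freq_range_cm[1], n_modes))
    )
    geo_r = rng.uniform(-5.0, 5.0, size=dim)
    disp = rng.uniform(displacement_range[0], displacement_range[1], size=n_modes)
    disp *= rng.choice([-1.0, 1.0], size=n_modes)
    geo_p = geo_r + basis @ disp

    vec_p = basis.copy()
    if rotation_angle != 0.0 and n_modes >= 2:
        c, s = np.cos(rotation_angle), np.sin(rotation_angle)
        rot = np.eye(n_modes)
        rot[0, 0] = rot[1, 1] = c
        rot[0, 1], rot[1, 0] = -s, s
        vec_p = basis @ rot
    freqs_p = freqs.copy()
    if freq_jitter:
        freqs_p = freqs * (1.0 + freq_jitter * rng.uniform(-1, 1, n_modes))

    min_r = HarmonicMinimum(
        label="R",
        frequencies=freqs,
        eigenvectors=basis,
        minimum_geometry=geo_r,
        minimum_energy=0.0,
    )
    min_p = HarmonicMinimum(
        label="P",
        frequencies=freqs_p,
        eigenvectors=vec_p,
        minimum_geometry=geo_p,
        minimum_energy=0.0,
    )
    return min_r, min_p
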