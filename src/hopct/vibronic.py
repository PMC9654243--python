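"""Vibronic diabatization for hopping between two harmonic minima.

The reactant (R) and product (P) minima of the electronic ground state
are described by mass-weighted normal modes.  Modes with hbar*omega
above the thermal energy are quantum; the rest (including the zero-
frequency roto-translations) are semiclassical.  The vibrational ground
states phi_R, phi_P factorize over the quantum modes, and their overlap

    S = prod_l <phi_P,l | phi_R,l>

fixes the orthonormal diabatic states eta_R = c1 phi_R - c2 phi_P,
eta_P = -c2 phi_R + c1 phi_P through

    c1^2 + c2^2 = 1 / (1 - S^2),    2 c1 c2 = S / (1 - S^2).

The diabatic coupling at the crossing is assembled per quantum mode from
the switched harmonic energy curve: the electronic energy follows the R
parabola up to the R/P parabola intersection and the P parabola beyond,

    H_RP = S * sum_l [ <phi_P,l| g_l |phi_R,l> / <phi_P,l|phi_R,l>
                       - <phi_R,l| g_l |phi_R,l> ],

with g_l the switched curve minus the pure R parabola.  Because the
total R and P energies are degenerate at the crossing, the per-mode
parabola minima are taken degenerate, putting the intersection midway
between the two minima for equal frequencies.

Mass-weighted coordinates, hartree energies, hbar = 1 throughout.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import thermal_energy
from .pmm import ValidationError

logger = logging.getLogger("hopct")

__all__ = [
    "HarmonicMinimum",
    "ModePairing",
    "CouplingResult",
    "classify_modes",
    "duschinsky_matrix",
    "mode_displacements",
    "ground_state_overlap",
    "diabatization_coeffs",
    "coupling_at_crossing",
    "pair_modes",
]

_ORTHO_TOL = 1e-8
_MIXING_WARN = 0.8
_FREQ_MATCH_WARN = 0.05
_QUAD_EPSABS = 1e-12
_WIDTHS = 8.0  # integration range in ground-state widths around both minima


@dataclass
class HarmonicMinimum:
    """One harmonic minimum: frequencies, eigenvectors, geometry.

    ``frequencies`` are in hartree (hbar*omega); ``eigenvectors`` are the
    mass-weighted Hessian eigenvectors as orthonormal columns (3N x n);
    ``minimum_geometry`` is the 3N mass-weighted coordinate vector in
    sqrt(m_e)*bohr.
    """

    label: str
    frequencies: np.ndarray
    eigenvectors: np.ndarray
    minimum_geometry: np.ndarray
    minimum_energy: float = 0.0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.minimum_geometry = np.asarray(self.minimum_geometry, dtype=float)
        if np.any(self.frequencies < 0):
            raise ValidationError("imaginary (negative) frequencies rejected")
        dim, n = self.eigenvectors.shape
        if len(self.frequencies) != n:
            raise ValidationError("frequency count != eigenvector columns")
        if len(self.minimum_geometry) != dim:
            raise ValidationError("minimum_geometry length != eigenvector rows")
        gram = self.eigenvectors.T @ self.eigenvectors
        if np.max(np.abs(gram - np.eye(n))) > _ORTHO_TOL:
            raise ValidationError("eigenvector columns are not orthonormal")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class ModePairing:
    """Duschinsky analysis and R->P mode correspondence."""

    duschinsky: np.ndarray  # J = V_R^T V_P
    pairing: np.ndarray  # pairing[i] = P-mode index matched to R mode i
    displacements: np.ndarray  # quantum-mode displacements, 0 on semiclassical
    per_mode_overlaps: np.ndarray  # 1 on semiclassical modes
    quantum_mask: np.ndarray
    freq_r: np.ndarray
    freq_p: np.ndarray  # paired P frequencies, R ordering
    semiclassical_shift: float  # norm of the displacement outside quantum modes


@dataclass
class CouplingResult:
    total_overlap: float
    c1: float
    c2: float
    h_rp: float
    per_mode_terms: np.ndarray


def classify_modes(frequencies, temperature: float) -> np.ndarray:
    """Quantum iff hbar*omega exceeds kB*T; zero modes are semiclassical."""
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs < 0):
        raise ValidationError("imaginary (negative) frequency")
    kbt = thermal_energy(temperature)
    return (freqs > kbt) & (freqs > 0)


def duschinsky_matrix(min_r: HarmonicMinimum, min_p: HarmonicMinimum) -> np.ndarray:
    """J = V_R^T V_P: inner products of R and P mass-weighted eigenvectors.

    When both eigenvector sets span the same subspace, rows and columns of
    J*J (element-wise square) sum to one.
    """
    if min_r.eigenvectors.shape[0] != min_p.eigenvectors.shape[0]:
        raise ValidationError("R and P minima have different 3N dimensions")
    return min_r.eigenvectors.T @ min_p.eigenvectors


def _greedy_pairing(j: np.ndarray) -> np.ndarray:
    """One-to-one R->P mode assignment by descending |J| magnitude."""
    nr, npp = j.shape
    order = np.argsort(-np.abs(j), axis=None)
    pairing = np.full(nr, -1, dtype=int)
    used_p = np.zeros(npp, dtype=bool)
    assigned = 0
    for flat in order:
        r, p = divmod(int(flat), npp)
        if pairing[r] == -1 and not used_p[p]:
            pairing[r] = p
            used_p[p] = True
            assigned += 1
            if assigned == min(nr, npp):
                break
    return pairing


def mode_displacements(
    min_r: HarmonicMinimum,
    min_p: HarmonicMinimum,
    pairing: np.ndarray,
    quantum_mask: np.ndarray | None = None,
):
    """Per-mode minimum displacements projected on the R eigenvectors.

    Returns (delta_beta, semiclassical_shift).  delta_beta[l] is the
    component of x_P,min - x_R,min along the R eigenvector of pair l for
    quantum modes and 0 otherwise; the semiclassical shift collects the
    norm of everything else (semiclassical-mode projections plus any
    residual outside the eigenvector span) and is excluded from overlap
    products.
    """
    dx = min_p.minimum_geometry - min_r.minimum_geometry
    proj = min_r.eigenvectors.T @ dx
    if quantum_mask is None:
        quantum_mask = np.ones(min_r.n_modes, dtype=bool)
    delta = np.where(quantum_mask, proj, 0.0)
    residual = dx - min_r.eigenvectors @ proj
    semi_sq = float(np.sum(proj[~quantum_mask] ** 2) + residual @ residual)
    return delta, math.sqrt(semi_sq)


def pair_modes(
    min_r: HarmonicMinimum, min_p: HarmonicMinimum, temperature: float
) -> ModePairing:
    """Full Duschinsky analysis: matrix, pairing, displacements, overlaps.

    Warns when a paired squared Duschinsky element falls below 0.8 (mode
    mixing undermines the independent-mode picture) and when paired R/P
    frequencies differ by more than 5%.
    """
    j = duschinsky_matrix(min_r, min_p)
    pairing = _greedy_pairing(j)
    quantum_mask = classify_modes(min_r.frequencies, temperature)
    freq_p_paired = min_p.frequencies[pairing]

    diag2 = np.array([j[i, pairing[i]] ** 2 for i in range(min_r.n_modes)])
    weak = diag2[quantum_mask] < _MIXING_WARN
    if np.any(weak):
        warnings.warn(
            f"{int(weak.sum())} paired quantum modes have squared Duschinsky "
            f"elements below {_MIXING_WARN}: significant mode mixing",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(freq_p_paired - min_r.frequencies) / np.where(
            min_r.frequencies > 0, min_r.frequencies, 1.0
        )
    if np.any(rel[quantum_mask] > _FREQ_MATCH_WARN):
        warnings.warn(
            "paired R/P frequencies differ by more than 5% on some quantum "
            "modes; the shared-frequency assumption is strained",
            stacklevel=2,
        )

    delta, semi_shift = mode_displacements(min_r, min_p, pairing, quantum_mask)
    overlaps, _ = ground_state_overlap(
        delta, min_r.frequencies, quantum_mask, freq_p=freq_p_paired
    )
    return ModePairing(
        duschinsky=j,
        pairing=pairing,
        displacements=delta,
        per_mode_overlaps=overlaps,
        quantum_mask=quantum_mask,
        freq_r=min_r.frequencies,
        freq_p=freq_p_paired,
        semiclassical_shift=semi_shift,
    )


def _overlap_1d(omega_r: float, omega_p: float, delta: float) -> float:
    """Overlap of two displaced harmonic ground states (exact).

    Equal frequencies: exp(-omega * delta^2 / 4).  Unequal:
    sqrt(2 sqrt(wr wp)/(wr+wp)) * exp(-wr wp delta^2 / (2 (wr+wp))).
    """
    wr, wp = float(omega_r), float(omega_p)
    pref = math.sqrt(2.0 * math.sqrt(wr * wp) / (wr + wp))
    return pref * math.exp(-wr * wp * delta * delta / (2.0 * (wr + wp)))


def ground_state_overlap(
    delta_beta, freq_r, quantum_mask, freq_p=None
):
    """Per-mode ground-state overlaps and their product S over quantum modes.

    Uses the exact displaced-Gaussian overlap per mode (reducing to
    exp(-omega delta^2/4) for equal R/P frequencies); semiclassical modes
    contribute 1 and are excluded from the product.
    """
    delta_beta = np.asarray(delta_beta, dtype=float)
    freq_r = np.asarray(freq_r, dtype=float)
    quantum_mask = np.asarray(quantum_mask, dtype=bool)
    freq_p = freq_r if freq_p is None else np.asarray(freq_p, dtype=float)
    if np.any(freq_r[quantum_mask] <= 0) or np.any(freq_p[quantum_mask] <= 0):
        raise ValidationError("quantum modes must have positive frequencies")
    overlaps = np.ones(len(delta_beta))
    for l in np.nonzero(quantum_mask)[0]:
        overlaps[l] = _overlap_1d(freq_r[l], freq_p[l], delta_beta[l])
    s = float(np.prod(overlaps[quantum_mask])) if quantum_mask.any() else 1.0
    return overlaps, s


def diabatization_coeffs(s: float) -> tuple[float, float]:
    """Closed-form (c1, c2) of the symmetric orthogonalization.

    With a = 1/sqrt(1-S) and b = 1/sqrt(1+S), c1 = (a+b)/2 and
    c2 = (a-b)/2 satisfy c1^2 + c2^2 = 1/(1-S^2) and
    2 c1 c2 = S/(1-S^2) exactly; c1 > 0 and c2 carries the sign of S.
    """
    if not -1.0 < s < 1.0:
        raise ValidationError(
            f"|S| must be < 1 for non-degenerate minima, got S={s}"
        )
    a = 1.0 / math.sqrt(1.0 - s)
    b = 1.0 / math.sqrt(1.0 + s)
    return (a + b) / 2.0, (a - b) / 2.0


def _phi(beta, omega, center):
    """Harmonic ground-state wavefunction in mass-weighted coordinates."""
    return (omega / math.pi) ** 0.25 * np.exp(-0.5 * omega * (beta - center) ** 2)


def _mode_term(omega_r, omega_p, delta, overlap):
    """One quantum mode's contribution to the Eq. for H_RP.

    The R parabola sits at 0, the P parabola at ``delta``, both with
    degenerate minima.  g(beta) is zero on the R side of the intersection
    and equals the P-minus-R parabola difference beyond it.
    """
    if delta == 0.0:
        return 0.0
    # the sign of delta is immaterial: reflecting beta maps one case to the other
    d = abs(delta)
    # crossing of (wr^2/2) b^2 = (wp^2/2) (b-d)^2 between the minima
    bc = omega_p * d / (omega_r + omega_p)

    def g(b):
        after = b > bc
        vr = 0.5 * omega_r**2 * b**2
        vp = 0.5 * omega_p**2 * (b - d) ** 2
        return np.where(after, vp - vr, 0.0)

    width = 1.0 / math.sqrt(min(omega_r, omega_p))
    lo = min(0.0, d) - _WIDTHS * width
    hi = max(0.0, d) + _WIDTHS * width

    def integrand_pr(b):
        return _phi(b, omega_p, d) * g(b) * _phi(b, omega_r, 0.0)

    def integrand_rr(b):
        return _phi(b, omega_r, 0.0) * g(b) * _phi(b, omega_r, 0.0)

    kwargs = dict(epsabs=_QUAD_EPSABS, epsrel=1e-10, limit=400, points=[bc, 0.0, d])
    i_pr, err1 = quad(integrand_pr, lo, hi, **kwargs)
    i_rr, err2 = quad(integrand_rr, lo, hi, **kwargs)
    if err1 > 1e-8 * max(1.0, abs(i_pr)) or err2 > 1e-8 * max(1.0, abs(i_rr)):
        raise ValidationError("quadrature did not converge for a mode integral")
    return i_pr / overlap - i_rr


def coupling_at_crossing(
    pairing: ModePairing | None = None,
    delta_beta=None,
    freq_r=None,
    quantum_mask=None,
    freq_p=None,
) -> CouplingResult:
    """Diabatic coupling at the crossing from switched harmonic curves.

    Accepts either a :class:`ModePairing` or raw arrays.  For each
    quantum mode the two 1D integrals <phi_P|g|phi_R>/<phi_P|phi_R> and
    <phi_R|g|phi_R> are evaluated by adaptive quadrature and summed;
    H_RP = S * sum of per-mode terms.  A zero total displacement gives
    S = 1 (degenerate minima) and a zero coupling, and is flagged.
    """
    if pairing is not None:
        delta_beta = pairing.displacements
        freq_r = pairing.freq_r
        freq_p = pairing.freq_p
        quantum_mask = pairing.quantum_mask
    delta_beta = np.asarray(delta_beta, dtype=float)
    freq_r = np.asarray(freq_r, dtype=float)
    quantum_mask = np.asarray(quantum_mask, dtype=bool)
    freq_p = freq_r if freq_p is None else np.asarray(freq_p, dtype=float)

    overlaps, s = ground_state_overlap(delta_beta, freq_r, quantum_mask, freq_p=freq_p)
    if abs(s) >= 1.0:
        warnings.warn(
            "total overlap S = 1 (coincident minima): diabatization is "
            "degenerate and the coupling vanishes",
            stacklevel=2,
        )
        c1, c2 = 1.0, 0.0
    else:
        c1, c2 = diabatization_coeffs(s)

    terms = np.zeros(len(delta_beta))
    for l in np.nonzero(quantum_mask)[0]:
        try:
            terms[l] = _mode_term(freq_r[l], freq_p[l], delta_beta[l], overlaps[l])
        except ValidationError as exc:
            raise ValidationError(f"mode {l}: {exc}") from exc
    h_rp = s * float(terms.sum())
    return CouplingResult(
        total_overlap=s, c1=c1, c2=c2, h_rp=h_rp, per_mode_terms=terms
    )
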