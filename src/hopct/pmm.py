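"""Perturbed Matrix Method (PMM) core.

A quantum center (QC) — here typically a guanine base — is described by a
small set of unperturbed electronic states (energies, per-state atomic
partial charges, inter-state transition dipoles).  The semiclassical
environment enters through the electric potential it creates at each QC
atom and the electric field at the QC center of mass.  The perturbed
electronic Hamiltonian in the unperturbed-state basis is

    H[l, l]  = U0[l] + sum_n V_n * q_n[l] + dV
    H[l, l'] = - E_G . mu[l, l']          (l != l')

and its lowest eigenvalue is the perturbed ground-state energy used to
build charge-transfer transition energies.  All quantities are in Hartree
atomic units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("hopct")

__all__ = [
    "QCStateSet",
    "PerturbationFrame",
    "PerturbedState",
    "PointChargeEnvironment",
    "coulomb_perturbation",
    "build_perturbed_hamiltonian",
    "perturbed_eigenstates",
    "redox_energy_change",
]

_CHARGE_SUM_TOL = 1e-6
_SOURCE_SUM_TOL = 1e-10
_MIN_SEPARATION = 1e-6


class ValidationError(ValueError):
    """Raised when an input object violates its structural contract."""


class DegenerateGeometryError(ValidationError):
    """Raised when an environment charge (nearly) coincides with a QC atom."""


@dataclass
class QCStateSet:
    """Unperturbed electronic states of one quantum-center redox species.

    Parameters
    ----------
    species_label:
        Free-form name, e.g. ``"guanine_cation"``.
    total_charge:
        Net charge of the species in units of e.
    atom_masses:
        Per-atom masses in electron-mass units.
    reference_geometry:
        (n_atoms, 3) positions in bohr.
    state_energies:
        Unperturbed electronic energies in hartree, ground state first,
        non-decreasing.
    state_charges:
        (n_states, n_atoms) atomic partial charges per state; each row
        must sum to ``total_charge``.
    transition_dipoles:
        Mapping (l, l') -> 3-vector in e*bohr for l != l'; symmetric.
    delta_v:
        Short-range scalar correction added to every diagonal element.
        It shifts the whole spectrum rigidly, so transition energies
        within one species never depend on it.
    """

    species_label: str
    total_charge: int
    atom_masses: np.ndarray
    reference_geometry: np.ndarray
    state_energies: np.ndarray
    state_charges: np.ndarray
    transition_dipoles: dict = field(default_factory=dict)
    delta_v: float = 0.0

    def __post_init__(self):
        self.atom_masses = np.asarray(self.atom_masses, dtype=float)
        self.reference_geometry = np.asarray(self.reference_geometry, dtype=float)
        self.state_energies = np.asarray(self.state_energies, dtype=float)
        self.state_charges = np.asarray(self.state_charges, dtype=float)
        if self.reference_geometry.shape != (self.n_atoms, 3):
            raise ValidationError(
                f"reference_geometry shape {self.reference_geometry.shape} "
                f"!= ({self.n_atoms}, 3)"
            )
        if self.state_charges.shape != (self.n_states, self.n_atoms):
            raise ValidationError(
                f"state_charges shape {self.state_charges.shape} != "
                f"({self.n_states}, {self.n_atoms})"
            )
        if np.any(np.diff(self.state_energies) < 0):
            raise ValidationError("state_energies must be non-decreasing")
        sums = self.state_charges.sum(axis=1)
        bad = np.abs(sums - self.total_charge) > _CHARGE_SUM_TOL
        if np.any(bad):
            raise ValidationError(
                f"state charges must sum to total_charge={self.total_charge}; "
                f"per-state sums {sums.tolist()}"
            )
        # symmetrize / validate transition dipoles
        dip = {}
        for (l, lp), mu in self.transition_dipoles.items():
            mu = np.asarray(mu, dtype=float)
            if mu.shape != (3,):
                raise ValidationError(f"transition dipole ({l},{lp}) is not a 3-vector")
            key, rkey = (l, lp), (lp, l)
            if rkey in dip and not np.allclose(dip[rkey], mu):
                raise ValidationError(
                    f"transition dipoles ({l},{lp}) and ({lp},{l}) disagree"
                )
            dip[key] = mu
            dip[rkey] = mu
        self.transition_dipoles = dip

    @property
    def n_atoms(self) -> int:
        return len(self.atom_masses)

    @property
    def n_states(self) -> int:
        return len(self.state_energies)

    def center_of_mass(self, geometry: np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted center of the reference (or a supplied) geometry."""
        geo = self.reference_geometry if geometry is None else np.asarray(geometry)
        m = self.atom_masses
        return (m[:, None] * geo).sum(axis=0) / m.sum()

    def dipole_matrix_element(self, l: int, lp: int) -> np.ndarray:
        return self.transition_dipoles.get((l, lp), np.zeros(3))


@dataclass
class PerturbationFrame:
    """Electrostatic perturbation on one QC at one time point.

    ``atom_potentials`` is the electric potential V_n at each QC atom
    (hartree per e) and ``field_at_com`` the field at the QC center of
    mass (hartree per e*bohr).  ``source_components`` optionally splits
    both by environment source (e.g. ``"solvent"`` / ``"helix"``); the
    per-source pieces must sum to the totals.
    """

    time: float
    atom_potentials: np.ndarray
    field_at_com: np.ndarray
    source_components: dict | None = None

    def __post_init__(self):
        self.atom_potentials = np.asarray(self.atom_potentials, dtype=float)
        self.field_at_com = np.asarray(self.field_at_com, dtype=float)
        if self.field_at_com.shape != (3,):
            raise ValidationError("field_at_com must be a 3-vector")
        if self.source_components is not None:
            comp = {}
            v_sum = np.zeros_like(self.atom_potentials)
            e_sum = np.zeros(3)
            for label, (v, e) in self.source_components.items():
                v = np.asarray(v, dtype=float)
                e = np.asarray(e, dtype=float)
                if v.shape != self.atom_potentials.shape:
                    raise ValidationError(
                        f"source '{label}' potentials have wrong length"
                    )
                comp[label] = (v, e)
                v_sum += v
                e_sum += e
            if (
                np.max(np.abs(v_sum - self.atom_potentials), initial=0.0)
                > _SOURCE_SUM_TOL
                or np.max(np.abs(e_sum - self.field_at_com)) > _SOURCE_SUM_TOL
            ):
                raise ValidationError(
                    "per-source perturbation components do not sum to totals"
                )
            self.source_components = comp

    @property
    def n_atoms(self) -> int:
        return len(self.atom_potentials)

    def restricted_to(self, sources) -> "PerturbationFrame":
        """A frame containing only the listed sources' contributions."""
        if self.source_components is None:
            raise ValidationError("frame has no per-source components")
        if isinstance(sources, str):
            sources = {sources}
        missing = set(sources) - set(self.source_components)
        if missing:
            raise ValidationError(f"unknown sources {sorted(missing)}")
        v = np.zeros_like(self.atom_potentials)
        e = np.zeros(3)
        for label in sources:
            vs, es = self.source_components[label]
            v = v + vs
            e = e + es
        return PerturbationFrame(self.time, v, e)


@dataclass
class PerturbedState:
    """Spectral decomposition of one perturbed electronic Hamiltonian."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, same order as eigenvalues
    ground_energy: float
    ground_coefficients: np.ndarray


@dataclass
class PointChargeEnvironment:
    """Point charges surrounding a QC, optionally tagged by source."""

    positions: np.ndarray  # (m, 3) bohr
    charges: np.ndarray  # (m,) e
    labels: list | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.positions) != len(self.charges):
            raise ValidationError("positions and charges differ in length")
        if self.labels is not None and len(self.labels) != len(self.charges):
            raise ValidationError("labels and charges differ in length")


def coulomb_perturbation(
    env: PointChargeEnvironment,
    qc_positions: np.ndarray,
    com: np.ndarray,
    source_filter=None,
    time: float = 0.0,
) -> PerturbationFrame:
    """Bare Coulomb potentials and field from environment point charges.

    V_n = sum_j q_j / |r_n - r_j|;  E_G = sum_j q_j (R_com - r_j)/|R_com - r_j|^3.
    A positive charge produces a positive potential.  When the environment
    carries labels, per-source components are stored on the frame.
    """
    qc_positions = np.asarray(qc_positions, dtype=float).reshape(-1, 3)
    com = np.asarray(com, dtype=float)

    def _sums(mask):
        pos = env.positions[mask]
        q = env.charges[mask]
        if len(q) == 0:
            return np.zeros(len(qc_positions)), np.zeros(3)
        d = qc_positions[:, None, :] - pos[None, :, :]  # (n, m, 3)
        r = np.linalg.norm(d, axis=2)
        if np.any(r <= _MIN_SEPARATION):
            raise DegenerateGeometryError(
                "environment charge coincides with a QC atom position"
            )
        v = (q[None, :] / r).sum(axis=1)
        dc = com[None, :] - pos
        rc = np.linalg.norm(dc, axis=1)
        if np.any(rc <= _MIN_SEPARATION):
            raise DegenerateGeometryError("environment charge coincides with the COM")
        e = (q[:, None] * dc / rc[:, None] ** 3).sum(axis=0)
        return v, e

    all_mask = np.ones(len(env.charges), dtype=bool)
    if source_filter is not None:
        if env.labels is None:
            raise ValidationError("source_filter given but environment has no labels")
        if isinstance(source_filter, str):
            source_filter = {source_filter}
        all_mask = np.array([lab in source_filter for lab in env.labels], dtype=bool)

    v_tot, e_tot = _sums(all_mask)
    sources = None
    if env.labels is not None:
        sources = {}
        for lab in dict.fromkeys(env.labels):  # stable order
            if source_filter is not None and lab not in source_filter:
                continue
            mask = np.array([x == lab for x in env.labels], dtype=bool) & all_mask
            sources[lab] = _sums(mask)
    return PerturbationFrame(time, v_tot, e_tot, source_components=sources)


def build_perturbed_hamiltonian(qc: QCStateSet, frame: PerturbationFrame) -> np.ndarray:
    """Assemble the perturbed electronic Hamiltonian matrix (hartree)."""
    if frame.n_atoms != qc.n_atoms:
        raise ValidationError(
            f"frame has {frame.n_atoms} atom potentials, QC has {qc.n_atoms} atoms"
        )
    n = qc.n_states
    diag = (
        qc.state_energies
        + qc.state_charges @ frame.atom_potentials
        + qc.delta_v
    )
    h = np.diag(diag)
    for l in range(n):
        for lp in range(l + 1, n):
            mu = qc.transition_dipoles.get((l, lp))
            if mu is None:
                continue
            val = -float(frame.field_at_com @ mu)
            h[l, lp] = val
            h[lp, l] = val
    return h


def perturbed_eigenstates(h: np.ndarray) -> PerturbedState:
    """Diagonalize a perturbed Hamiltonian; ascending eigenvalues.

    Eigenvector sign convention: first nonzero coefficient positive, so
    degenerate spectra yield reproducible ground-state coefficients.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValidationError("Hamiltonian must be square")
    if np.max(np.abs(h - h.T), initial=0.0) > 1e-10:
        raise ValidationError("Hamiltonian is not symmetric within 1e-10")
    w, v = np.linalg.eigh(0.5 * (h + h.T))
    for k in range(v.shape[1]):
        col = v[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            v[:, k] = -col
    return PerturbedState(
        eigenvalues=w,
        eigenvectors=v,
        ground_energy=float(w[0]),
        ground_coefficients=v[:, 0],
    )


def perturbed_ground_energy(qc: QCStateSet, frame: PerturbationFrame) -> float:
    """Lowest eigenvalue of the perturbed Hamiltonian for one frame."""
    return perturbed_eigenstates(build_perturbed_hamiltonian(qc, frame)).ground_energy


def redox_energy_change(
    qc_initial: QCStateSet, qc_final: QCStateSet, frame: PerturbationFrame
) -> float:
    """Perturbed ground-energy change of a redox step under one frame.

    Both state sets must describe the same nuclei (same atom count); the
    same perturbation frame applies to both because the nuclear skeleton —
    and hence the environment — is shared by the two redox species.
    """
    if qc_initial.n_atoms != qc_final.n_atoms:
        raise ValidationError(
            "initial and final redox species have different atom counts"
        )
    e_i = perturbed_ground_energy(qc_initial, frame)
    e_f = perturbed_ground_energy(qc_final, frame)
    return e_f - e_i
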