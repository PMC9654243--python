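"""File formats, run configuration, and the end-to-end rate pipeline.

On-disk formats (all plain text):

* QC properties: JSON, schema ``hopct-qc-1`` (energies in hartree,
  geometry in bohr, charges in e, dipoles in e*bohr).
* Perturbation frames: JSON-lines, one frame per line with keys ``time``,
  ``v`` (per-atom potentials), ``e`` (field 3-vector), optional
  ``sources`` mapping label -> {"v": [...], "e": [...]}.
* Point-charge environments: extended-XYZ dialect with columns
  ``element x y z charge [label]``; coordinates in angstrom on disk,
  converted to bohr on read.
* Normal modes: text blocks FREQUENCIES (cm^-1), EIGENVECTORS (row-major
  3N x n), GEOMETRY (element mass x y z; amu and angstrom), MIN_ENERGY
  (hartree).
* Series: two-column (time, dU) text with a ``#``-prefixed metadata
  header; step and per-source contributions as extra columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import constants as const
from .kinetics import (
    effective_rate,
    gaussian_rate,
    kinetic_trace,
    landau_zener_chi,
    series_stats,
    transmission_alpha,
)
from .pmm import (
    PerturbationFrame,
    PointChargeEnvironment,
    QCStateSet,
    ValidationError,
)
from .transition_energy import (
    TransitionEnergySeries,
    decompose_contributions,
    landau_free_energy,
    scheme_I_series,
    scheme_II_series,
)
from .vibronic import HarmonicMinimum, coupling_at_crossing, pair_modes

logger = logging.getLogger("hopct")

QC_FORMAT = "hopct-qc-1"

__all__ = [
    "read_qc_properties",
    "write_qc_properties",
    "read_frames",
    "write_frames",
    "read_environment_xyz",
    "write_environment_xyz",
    "read_normal_modes",
    "write_normal_modes",
    "read_series",
    "write_series",
    "RunConfig",
    "load_config",
    "run_rate_pipeline",
]


# --------------------------------------------------------------------- QC JSON

def write_qc_properties(qc: QCStateSet, path) -> None:
    dipoles = [
        {"states": [l, lp], "dipole": list(map(float, mu))}
        for (l, lp), mu in qc.transition_dipoles.items()
        if l < lp
    ]
    doc = {
        "format": QC_FORMAT,
        "species_label": qc.species_label,
        "total_charge": qc.total_charge,
        "n_atoms": qc.n_atoms,
        "atom_masses": qc.atom_masses.tolist(),
        "reference_geometry": qc.reference_geometry.tolist(),
        "state_energies": qc.state_energies.tolist(),
        "state_charges": qc.state_charges.tolist(),
        "transition_dipoles": dipoles,
        "delta_v": qc.delta_v,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_qc_properties(path) -> QCStateSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("format") != QC_FORMAT:
        raise ValidationError(
            f"{path}: expected format {QC_FORMAT!r}, got {doc.get('format')!r}"
        )
    required = [
        "species_label",
        "total_charge",
        "atom_masses",
        "reference_geometry",
        "state_energies",
        "state_charges",
    ]
    for key in required:
        if key not in doc:
            raise ValidationError(f"{path}: missing field {key!r}")
    dipoles = {}
    for entry in doc.get("transition_dipoles", []):
        l, lp = entry["states"]
        dipoles[(int(l), int(lp))] = np.asarray(entry["dipole"], dtype=float)
    try:
        return QCStateSet(
            species_label=doc["species_label"],
            total_charge=int(doc["total_charge"]),
            atom_masses=doc["atom_masses"],
            reference_geometry=doc["reference_geometry"],
            state_energies=doc["state_energies"],
            state_charges=doc["state_charges"],
            transition_dipoles=dipoles,
            delta_v=float(doc.get("delta_v", 0.0)),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- frames JSONL

def write_frames(frames, path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            doc = {
                "time": f.time,
                "v": f.atom_potentials.tolist(),
                "e": f.field_at_com.tolist(),
            }
            if f.source_components:
                doc["sources"] = {
                    lab: {"v": v.tolist(), "e": e.tolist()}
                    for lab, (v, e) in f.source_components.items()
                }
            fh.write(json.dumps(doc) + "\n")


def read_frames(path):
    frames = []
    last_t = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            doc = json.loads(line)
            sources = None
            if "sources" in doc:
                sources = {
                    lab: (np.asarray(sv["v"], float), np.asarray(sv["e"], float))
                    for lab, sv in doc["sources"].items()
                }
            try:
                frame = PerturbationFrame(
                    time=float(doc["time"]),
                    atom_potentials=doc["v"],
                    field_at_com=doc["e"],
                    source_components=sources,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: frame {i}: {exc}") from exc
            if last_t is not None and frame.time <= last_t:
                raise ValidationError(
                    f"{path}: frame {i}: times not strictly increasing"
                )
            last_t = frame.time
            frames.append(frame)
    return frames


# ------------------------------------------------------------ extended XYZ env

def write_environment_xyz(envs, path, comment: str = "") -> None:
    """Write environment snapshots as concatenated extended-XYZ blocks
    (angstrom on disk)."""
    if isinstance(envs, PointChargeEnvironment):
        envs = [envs]
    with open(path, "w") as fh:
        for k, env in enumerate(envs):
            fh.write(f"{len(env.charges)}\n")
            fh.write(f"{comment or f'frame {k}'}\n")
            for j in range(len(env.charges)):
                x, y, z = const.bohr_to_angstrom(env.positions[j])
                lab = f" {env.labels[j]}" if env.labels is not None else ""
                fh.write(
                    f"X {x:.10f} {y:.10f} {z:.10f} {env.charges[j]:.10f}{lab}\n"
                )


def read_environment_xyz(path):
    """Read one or more extended-XYZ point-charge snapshots (angstrom ->
    bohr).  Columns: element x y z charge [label]."""
    envs = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValidationError(f"{path}: bad atom count line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValidationError(f"{path}: truncated snapshot at line {i + 1}")
        positions, charges, labels = [], [], []
        has_labels = None
        for row in block:
            parts = row.split()
            if len(parts) not in (5, 6):
                raise ValidationError(
                    f"{path}: expected 'element x y z charge [label]', got {row!r}"
                )
            positions.append([float(p) for p in parts[1:4]])
            charges.append(float(parts[4]))
            if has_labels is None:
                has_labels = len(parts) == 6
            if has_labels != (len(parts) == 6):
                raise ValidationError(f"{path}: inconsistent label column")
            if has_labels:
                labels.append(parts[5])
        envs.append(
            PointChargeEnvironment(
                positions=const.angstrom_to_bohr(np.asarray(positions)),
                charges=np.asarray(charges),
                labels=labels if has_labels else None,
            )
        )
        i += 2 + n
    return envs


# ------------------------------------------------------------ normal-mode text

def write_normal_modes(
    minimum: HarmonicMinimum, masses_amu, path, elements=None
) -> None:
    """Write a minimum to the plain-text normal-mode format.

    ``masses_amu`` are per-atom masses in amu; the stored geometry is
    de-mass-weighted back to angstrom.
    """
    masses_amu = np.asarray(masses_amu, dtype=float)
    n_at = len(masses_amu)
    if elements is None:
        elements = ["X"] * n_at
    m_me = masses_amu * const.AMU_ME
    cart_bohr = minimum.minimum_geometry.reshape(n_at, 3) / np.sqrt(m_me)[:, None]
    cart_ang = const.bohr_to_angstrom(cart_bohr)
    with open(path, "w") as fh:
        fh.write(f"# hopct normal-mode file, minimum {minimum.label}\n")
        fh.write("FREQUENCIES\n")
        fh.write(
            " ".join(f"{const.hartree_to_cm1(w):.8f}" for w in minimum.frequencies)
            + "\n"
        )
        fh.write("EIGENVECTORS\n")
        for row in minimum.eigenvectors:
            fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")
        fh.write("GEOMETRY\n")
        for el, m, xyz in zip(elements, masses_amu, cart_ang):
            fh.write(f"{el} {m:.8f} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
        fh.write("MIN_ENERGY\n")
        fh.write(f"{minimum.minimum_energy:.12e}\n")


def read_normal_modes(path, label: str = "R"):
    """Read a normal-mode file; returns (HarmonicMinimum, masses_amu,
    elements).  Frequencies cm^-1 -> hartree; geometry amu/angstrom ->
    mass-weighted atomic units; eigenvectors are taken as already
    mass-weighted and orthonormal."""
    sections: dict[str, list[str]] = {}
    current = None
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s in ("FREQUENCIES", "EIGENVECTORS", "GEOMETRY", "MIN_ENERGY"):
            current = s
            sections[current] = []
            continue
        if current is None:
            raise ValidationError(f"{path}: data before any section header")
        sections[current].append(s)
    for need in ("FREQUENCIES", "EIGENVECTORS", "GEOMETRY"):
        if need not in sections:
            raise ValidationError(f"{path}: missing {need} block")
    freqs = const.cm1_to_hartree(
        np.array(" ".join(sections["FREQUENCIES"]).split(), dtype=float)
    )
    vecs = np.array([row.split() for row in sections["EIGENVECTORS"]], dtype=float)
    elements, masses_amu, cart = [], [], []
    for row in sections["GEOMETRY"]:
        parts = row.split()
        if len(parts) != 5:
            raise ValidationError(f"{path}: GEOMETRY rows are 'element mass x y z'")
        elements.append(parts[0])
        masses_amu.append(float(parts[1]))
        cart.append([float(p) for p in parts[2:5]])
    masses_amu = np.asarray(masses_amu)
    cart_bohr = const.angstrom_to_bohr(np.asarray(cart))
    mw_geo = (cart_bohr * np.sqrt(masses_amu * const.AMU_ME)[:, None]).ravel()
    e_min = 0.0
    if "MIN_ENERGY" in sections and sections["MIN_ENERGY"]:
        e_min = float(sections["MIN_ENERGY"][0])
    minimum = HarmonicMinimum(
        label=label,
        frequencies=freqs,
        eigenvectors=vecs,
        minimum_geometry=mw_geo,
        minimum_energy=e_min,
    )
    return minimum, masses_amu, elements


# ------------------------------------------------------------------ series text

def write_series(series: TransitionEnergySeries, path) -> None:
    header = [
        f"# scheme = {series.scheme}",
        f"# unperturbed_offsets = {series.unperturbed_offsets[0]!r} "
        f"{series.unperturbed_offsets[1]!r}",
    ]
    cols = [series.times, series.values]
    names = ["time_au", "dU_hartree"]
    if series.step_values is not None:
        cols += [series.step_values[:, 0], series.step_values[:, 1]]
        names += ["step1_hartree", "step2_hartree"]
    if series.contributions:
        for lab, v in series.contributions.items():
            cols.append(v)
            names.append(f"contrib_{lab}")
    header.append("# columns = " + " ".join(names))
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.12e")


def read_series(path) -> TransitionEnergySeries:
    meta = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
    data = np.loadtxt(path, ndmin=2)
    names = meta.get("columns", "time_au dU_hartree").split()
    cols = {name: data[:, k] for k, name in enumerate(names)}
    steps = None
    if "step1_hartree" in cols:
        steps = np.column_stack([cols["step1_hartree"], cols["step2_hartree"]])
    contributions = {
        name[len("contrib_"):]: cols[name]
        for name in names
        if name.startswith("contrib_")
    } or None
    offsets = (0.0, 0.0)
    if "unperturbed_offsets" in meta:
        a, b = meta["unperturbed_offsets"].split()
        offsets = (float(a), float(b))
    return TransitionEnergySeries(
        times=cols["time_au"],
        values=cols["dU_hartree"],
        scheme=meta.get("scheme", "I"),
        step_values=steps,
        contributions=contributions,
        unperturbed_offsets=offsets,
    )


# ------------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """Configuration for the end-to-end rate pipeline (paths + knobs)."""

    donor_cation: str
    donor_neutral: str
    acceptor_neutral: str
    acceptor_cation: str
    donor_frames: str
    acceptor_frames: str
    temperature: float = 300.0
    scheme: str = "I"  # "I" | "II" | "both"
    alpha: object = 1.0  # "computed" or a fixed value in [0, 1]
    min_r: str | None = None  # normal-mode files, required if alpha="computed"
    min_p: str | None = None
    output_dir: str = "hopct_out"
    n_bins: int | None = None
    trace_points: int = 200

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.scheme not in ("I", "II", "both"):
            raise ValidationError("scheme must be 'I', 'II' or 'both'")
        if self.alpha == "computed":
            if not (self.min_r and self.min_p):
                raise ValidationError(
                    "alpha='computed' requires min_r and min_p normal-mode files"
                )
        else:
            self.alpha = float(self.alpha)
            if not 0.0 <= self.alpha <= 1.0:
                raise ValidationError("fixed alpha must lie in [0, 1]")


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return RunConfig(**doc)


def run_rate_pipeline(config: RunConfig) -> dict:
    """Scheme series -> moments -> Gaussian rate -> transmission ->
    effective rate and kinetic trace; writes a JSON report plus series
    and free-energy-profile files into ``config.output_dir``.

    Returns the report dictionary (all rates both in a.u. and s^-1).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    qcs = {
        name: read_qc_properties(getattr(config, name))
        for name in ("donor_cation", "donor_neutral", "acceptor_neutral", "acceptor_cation")
    }
    donor_frames = read_frames(config.donor_frames)
    acceptor_frames = read_frames(config.acceptor_frames)

    schemes = ["I", "II"] if config.scheme == "both" else [config.scheme]
    report = {
        "temperature_K": config.temperature,
        "defaults": {
            "landau_zener": "single-passage chi = 1 - exp(-2 pi H^2 / v_cr)",
            "v_estimator": "forward per-interval differences (central and folded-Gaussian variants reported)",
            "per_mode_offset": "degenerate per-mode parabola minima (midpoint crossing)",
            "com": "mass-weighted center of the reference geometry",
        },
        "schemes": {},
    }
    series_by_scheme = {}
    for scheme in schemes:
        fn = scheme_I_series if scheme == "I" else scheme_II_series
        series = fn(
            qcs["donor_cation"],
            qcs["donor_neutral"],
            qcs["acceptor_neutral"],
            qcs["acceptor_cation"],
            donor_frames,
            acceptor_frames,
        )
        series_by_scheme[scheme] = series
        write_series(series, outdir / f"series_scheme_{scheme}.dat")
        stats = series_stats(series)
        kin = gaussian_rate(stats, config.temperature)
        entry = {
            "mean_du_hartree": kin.mean_du,
            "variance_hartree2": kin.variance,
            "mean_v_au": kin.mean_v,
            "mean_v_spectral_au": stats.mean_v_spectral,
            "activation_hartree": kin.activation,
            "activation_kJ_per_mol": kin.activation * const.HARTREE_KJMOL,
            "k_ra_au": kin.k_ra,
            "k_ra_per_s": const.rate_au_to_per_s(kin.k_ra),
            "validity_ratio": kin.validity_ratio,
            "unperturbed_offsets_hartree": list(series.unperturbed_offsets),
        }
        if series.contributions:
            dec = decompose_contributions(series)
            entry["contributions"] = {
                "means_hartree": dec.means,
                "additivity_residual_hartree": dec.additivity_residual,
                "regression_slope": dec.regression_slope,
                "regression_pair": list(dec.source_pair) if dec.source_pair else None,
            }
        try:
            profile = landau_free_energy(series, config.temperature, config.n_bins)
            entry["free_energy"] = {
                "mode_hartree": profile.mode,
                "curvature_hartree_inv": profile.curvature,
            }
            np.savetxt(
                outdir / f"profile_scheme_{scheme}.dat",
                np.column_stack([profile.bin_centers, profile.a_values]),
                header="dU_hartree A_hartree",
            )
        except ValidationError as exc:
            entry["free_energy"] = {"error": str(exc)}
        report["schemes"][scheme] = entry

    main_scheme = schemes[0]
    kin_main = report["schemes"][main_scheme]
    k_ra = kin_main["k_ra_au"]

    if config.alpha == "computed":
        min_r, _, _ = read_normal_modes(config.min_r, label="R")
        min_p, _, _ = read_normal_modes(config.min_p, label="P")
        pairing = pair_modes(min_r, min_p, config.temperature)
        coup = coupling_at_crossing(pairing)
        v_cr = kin_main["mean_v_au"]  # no crossing ensemble: default to <v>
        chi = landau_zener_chi(coup.h_rp, v_cr)
        lz = transmission_alpha([chi], coupling=coup.h_rp)
        report["coupling"] = {
            "S": coup.total_overlap,
            "c1": coup.c1,
            "c2": coup.c2,
            "h_rp_hartree": coup.h_rp,
            "v_cr_au": v_cr,
            "chi": chi,
        }
        alpha = lz.alpha
    else:
        alpha = float(config.alpha)
    prefactor = alpha * (2.0 - alpha)
    k_ct = effective_rate(k_ra, alpha) if alpha > 0 else 0.0

    report["alpha"] = alpha
    report["prefactor"] = prefactor
    report["k_ct_au"] = k_ct
    report["k_ct_per_s"] = const.rate_au_to_per_s(k_ct)

    if k_ct > 0:
        t_end = 5.0 / k_ct
        times = np.linspace(0.0, t_end, config.trace_points)
        trace = kinetic_trace(k_ra, alpha, times)
        np.savetxt(
            outdir / "kinetic_trace.dat",
            np.column_stack([trace.times, trace.ra_fraction, trace.p_fraction]),
            header="time_au RA P",
        )
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
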