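import numpy as np
import pytest

from hopct import (
    OUParams,
    coulomb_perturbation,
    gen_env_trajectory,
    gen_ou_series,
    gen_redox_pair,
    gen_toy_qc,
)
from hopct.pmm import PerturbationFrame


@pytest.fixture(scope="session")
def redox_pair():
    """(neutral, cation) toy species sharing the same nuclei."""
    return gen_redox_pair(seed=11, n_atoms=4, n_states=3, ionization_gap=0.2796)


@pytest.fixture(scope="session")
def toy_qc():
    return gen_toy_qc(seed=3, n_atoms=4, n_states=3, total_charge=0)


@pytest.fixture()
def zero_frame():
    def _make(n_atoms, time=0.0):
        return PerturbationFrame(time, np.zeros(n_atoms), np.zeros(3))

    return _make


@pytest.fixture(scope="session")
def labeled_frames(redox_pair):
    """Per-source perturbation frames from a labeled environment."""
    neutral, _ = redox_pair
    envs = gen_env_trajectory(seed=21, n_frames=40, covariance_sign=-1)
    com = neutral.center_of_mass()
    return [
        coulomb_perturbation(env, neutral.reference_geometry, com, time=float(i))
        for i, env in enumerate(envs)
    ]


def build_pipeline_inputs(tmp_path, ou_params, alpha=1.0, scheme="I"):
    """Write QC/frames/config files for an OU-driven end-to-end run.

    Uniform atom potentials +-u/2 on the donor/acceptor shift the two
    redox gaps by exactly -u/2 - (+(-u/2)) ... i.e. the gauge identity
    makes the scheme-I transition energy reproduce the OU driver u(t)
    to machine precision, so the pipeline's rate can be compared with
    the closed-form rate of the known generator parameters.
    """
    import yaml

    from hopct import io as hio

    ou = gen_ou_series(ou_params)
    neutral, cation = gen_redox_pair(seed=11, n_atoms=4)
    paths = {}
    for name, qc in (
        ("donor_cation", cation),
        ("donor_neutral", neutral),
        ("acceptor_neutral", neutral),
        ("acceptor_cation", cation),
    ):
        p = tmp_path / f"{name}.json"
        hio.write_qc_properties(qc, p)
        paths[name] = str(p)
    n_at = neutral.n_atoms
    zeros3 = np.zeros(3)
    for tag, sign in (("donor", -0.5), ("acceptor", +0.5)):
        frames = []
        for t, u in zip(ou.times, ou.values):
            v = np.full(n_at, sign * u)
            frames.append(
                PerturbationFrame(
                    t,
                    v,
                    zeros3,
                    source_components={
                        "solvent": (0.7 * v, zeros3),
                        "helix": (0.3 * v, zeros3),
                    },
                )
            )
        p = tmp_path / f"{tag}_frames.jsonl"
        hio.write_frames(frames, p)
        paths[f"{tag}_frames"] = str(p)
    cfg = dict(
        paths,
        temperature=300.0,
        scheme=scheme,
        alpha=alpha,
        output_dir=str(tmp_path / "out"),
    )
    cfg_path = tmp_path / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return cfg_path, ou


@pytest.fixture(scope="session")
def ou_series_short():
    return gen_ou_series(OUParams(mean=0.03, sigma=0.01, tau=1.0, dt=0.02,
                                  n_steps=200_000, seed=5))
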