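"""Mode classification, Duschinsky analysis, displaced-oscillator
overlaps, diabatization coefficients, and the coupling at crossing."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import fsolve

from hopct import (
    ValidationError,
    classify_modes,
    coupling_at_crossing,
    diabatization_coeffs,
    duschinsky_matrix,
    gen_harmonic_pair,
    ground_state_overlap,
    mode_displacements,
    pair_modes,
)
from hopct.constants import cm1_to_hartree, thermal_energy
from hopct.vibronic import HarmonicMinimum


def _phi(b, w, c):
    return (w / math.pi) ** 0.25 * np.exp(-0.5 * w * (b - c) ** 2)


class TestClassifyModes:
    def test_zero_frequency_is_semiclassical(self):
        mask = classify_modes([0.0, cm1_to_hartree(1000.0)], 300.0)
        assert mask.tolist() == [False, True]

    @pytest.mark.parametrize(
        "freq_cm,expected", [(1000.0, True), (50.0, False)]
    )
    def test_thermal_threshold_at_300k(self, freq_cm, expected):
        # physical-constants oracle: compare hbar*omega with kB*T directly
        assert (cm1_to_hartree(freq_cm) > thermal_energy(300.0)) is expected
        mask = classify_modes([cm1_to_hartree(freq_cm)], 300.0)
        assert bool(mask[0]) is expected

    def test_imaginary_mode_rejected(self):
        with pytest.raises(ValidationError):
            classify_modes([-1e-4], 300.0)


class TestDuschinsky:
    def test_identical_bases_give_identity(self):
        min_r, min_p = gen_harmonic_pair(seed=81, n_modes=4)
        j = duschinsky_matrix(min_r, min_p)
        assert np.allclose(j, np.eye(4), atol=1e-12)

    def test_two_mode_rotation_recovered(self):
        theta = 0.3
        min_r, min_p = gen_harmonic_pair(seed=83, n_modes=2, rotation_angle=theta)
        j = duschinsky_matrix(min_r, min_p)
        expected = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        assert np.allclose(j, expected, atol=1e-12)
        assert j[0, 0] ** 2 == pytest.approx(math.cos(theta) ** 2, abs=1e-12)

    def test_squared_rows_and_columns_sum_to_one(self):
        min_r, min_p = gen_harmonic_pair(seed=85, n_modes=5, rotation_angle=0.7)
        j2 = duschinsky_matrix(min_r, min_p) ** 2
        assert np.allclose(j2.sum(axis=0), 1.0, atol=1e-6)
        assert np.allclose(j2.sum(axis=1), 1.0, atol=1e-6)

    def test_mixing_warning(self):
        min_r, min_p = gen_harmonic_pair(seed=87, n_modes=3, rotation_angle=0.8)
        with pytest.warns(UserWarning, match="mode mixing"):
            pair_modes(min_r, min_p, 300.0)

    def test_frequency_mismatch_warning(self):
        min_r, min_p = gen_harmonic_pair(seed=89, n_modes=3, freq_jitter=0.2)
        with pytest.warns(UserWarning, match="frequencies differ"):
            pair_modes(min_r, min_p, 300.0)


class TestModeDisplacements:
    def test_coincident_minima(self):
        min_r, min_p = gen_harmonic_pair(seed=91, n_modes=3,
                                         displacement_range=(0.0, 0.0))
        pairing = np.arange(3)
        delta, shift = mode_displacements(min_r, min_p, pairing)
        assert np.allclose(delta, 0.0)
        assert shift == pytest.approx(0.0, abs=1e-12)

    def test_single_eigenvector_displacement(self):
        min_r, min_p = gen_harmonic_pair(seed=93, n_modes=3,
                                         displacement_range=(0.0, 0.0))
        d = 4.2
        min_p = HarmonicMinimum(
            label="P",
            frequencies=min_p.frequencies,
            eigenvectors=min_p.eigenvectors,
            minimum_geometry=min_r.minimum_geometry + d * min_r.eigenvectors[:, 1],
        )
        delta, shift = mode_displacements(min_r, min_p, np.arange(3))
        assert delta[1] == pytest.approx(d, abs=1e-12)
        assert delta[[0, 2]] == pytest.approx([0.0, 0.0], abs=1e-12)
        assert shift == pytest.approx(0.0, abs=1e-10)

    def test_parseval_partition(self):
        """Quantum projections plus semiclassical shift preserve the norm
        of the geometry difference."""
        min_r, min_p = gen_harmonic_pair(seed=95, n_modes=4, dim=9)
        rng = np.random.default_rng(95)
        # add a component outside the eigenvector span
        extra = rng.standard_normal(9)
        extra -= min_r.eigenvectors @ (min_r.eigenvectors.T @ extra)
        min_p = HarmonicMinimum(
            label="P",
            frequencies=min_p.frequencies,
            eigenvectors=min_p.eigenvectors,
            minimum_geometry=min_p.minimum_geometry + extra,
        )
        mask = np.array([True, True, False, True])
        delta, shift = mode_displacements(min_r, min_p, np.arange(4), mask)
        dx = min_p.minimum_geometry - min_r.minimum_geometry
        assert np.sum(delta**2) + shift**2 == pytest.approx(dx @ dx, rel=1e-12)


class TestGroundStateOverlap:
    def test_no_displacement_gives_unity(self):
        overlaps, s = ground_state_overlap(
            np.zeros(3), np.full(3, 0.01), np.ones(3, dtype=bool)
        )
        assert s == 1.0
        assert np.allclose(overlaps, 1.0)

    @pytest.mark.parametrize("omega,delta", [(0.005, 6.0), (0.02, 3.5), (0.001, 25.0)])
    def test_matches_quadrature_oracle(self, omega, delta):
        _, s = ground_state_overlap(
            np.array([delta]), np.array([omega]), np.array([True])
        )
        numeric, _ = quad(
            lambda b: _phi(b, omega, 0.0) * _phi(b, omega, delta),
            -200.0,
            200.0 + delta,
            epsabs=1e-13,
        )
        assert s == pytest.approx(numeric, abs=1e-10)

    def test_unequal_frequency_overlap_matches_quadrature(self):
        wr, wp, delta = 0.004, 0.006, 5.0
        _, s = ground_state_overlap(
            np.array([delta]), np.array([wr]), np.array([True]), freq_p=np.array([wp])
        )
        numeric, _ = quad(
            lambda b: _phi(b, wr, 0.0) * _phi(b, wp, delta), -300.0, 300.0,
            epsabs=1e-13,
        )
        assert s == pytest.approx(numeric, abs=1e-10)

    def test_monotone_decrease_with_displacement(self):
        freqs = np.array([0.01])
        mask = np.array([True])
        values = [
            ground_state_overlap(np.array([d]), freqs, mask)[1]
            for d in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestDiabatization:
    def test_orthogonal_local_states(self):
        assert diabatization_coeffs(0.0) == (1.0, 0.0)

    def test_root_finding_oracle(self):
        s = 0.1

        def equations(x):
            c1, c2 = x
            return [
                c1**2 + c2**2 - 1.0 / (1.0 - s**2),
                2.0 * c1 * c2 - s / (1.0 - s**2),
            ]

        c1o, c2o = fsolve(equations, [1.0, 0.05], xtol=1e-14)
        c1, c2 = diabatization_coeffs(s)
        assert c1 == pytest.approx(c1o, abs=1e-10)
        assert c2 == pytest.approx(c2o, abs=1e-10)

    @pytest.mark.parametrize("s", [-0.9, -0.3, 0.05, 0.5, 0.95])
    def test_eta_states_orthonormal(self, s):
        """eta_R, eta_P expanded over the nonorthogonal {phi_R, phi_P}
        basis with Gram matrix [[1, S], [S, 1]] are orthonormal."""
        c1, c2 = diabatization_coeffs(s)
        gram = np.array([[1.0, s], [s, 1.0]])
        eta_r = np.array([c1, -c2])
        eta_p = np.array([-c2, c1])
        assert eta_r @ gram @ eta_r == pytest.approx(1.0, abs=1e-10)
        assert eta_p @ gram @ eta_p == pytest.approx(1.0, abs=1e-10)
        assert eta_r @ gram @ eta_p == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            diabatization_coeffs(1.0)


class TestCouplingAtCrossing:
    def test_zero_displacement_zero_coupling(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = coupling_at_crossing(
                delta_beta=np.zeros(2),
                freq_r=np.full(2, 0.01),
                quantum_mask=np.ones(2, dtype=bool),
            )
        assert res.h_rp == 0.0
        assert res.total_overlap == 1.0

    @pytest.mark.parametrize("omega,delta", [(0.008, 4.0), (0.003, 10.0)])
    def test_single_mode_matches_dense_grid_oracle(self, omega, delta):
        """H_RP against a trapezoid-rule evaluation on a dense grid."""
        mask = np.array([True])
        res = coupling_at_crossing(
            delta_beta=np.array([delta]), freq_r=np.array([omega]), quantum_mask=mask
        )
        b = np.linspace(-12.0 / math.sqrt(omega), delta + 12.0 / math.sqrt(omega),
                        2_000_001)
        bc = delta / 2.0
        g = np.where(
            b > bc, 0.5 * omega**2 * (b - delta) ** 2 - 0.5 * omega**2 * b**2, 0.0
        )
        pr = np.trapezoid(_phi(b, omega, delta) * g * _phi(b, omega, 0.0), b)
        rr = np.trapezoid(_phi(b, omega, 0.0) * g * _phi(b, omega, 0.0), b)
        s = math.exp(-omega * delta**2 / 4.0)
        expected = s * (pr / s - rr)
        assert res.h_rp == pytest.approx(expected, rel=1e-8)

    def test_three_mode_product_matches_factorized_quadrature(self):
        deltas = np.array([3.0, -5.0, 8.0])
        freqs = np.array([0.012, 0.007, 0.004])
        mask = np.ones(3, dtype=bool)
        _, s = ground_state_overlap(deltas, freqs, mask)
        numeric = 1.0
        for d, w in zip(deltas, freqs):
            val, _ = quad(
                lambda b, w=w, d=d: _phi(b, w, 0.0) * _phi(b, w, d),
                -400.0, 400.0, epsabs=1e-13,
            )
            numeric *= val
        assert s == pytest.approx(numeric, abs=1e-8)

    def test_far_displacement_shrinks_coupling(self):
        """Doubling a strongly displaced mode's shift reduces |H_RP|:
        the Gaussian overlap decay beats the polynomial integral growth."""
        freqs = np.array([0.008, 0.006])
        mask = np.ones(2, dtype=bool)
        h = []
        for factor in (1.0, 2.0):
            res = coupling_at_crossing(
                delta_beta=np.array([3.0, 15.0 * factor]),
                freq_r=freqs,
                quantum_mask=mask,
            )
            h.append(abs(res.h_rp))
        assert h[1] < h[0]

    def test_decays_to_zero_with_total_displacement(self):
        freqs = np.array([0.01])
        mask = np.array([True])
        values = [
            abs(
                coupling_at_crossing(
                    delta_beta=np.array([d]), freq_r=freqs, quantum_mask=mask
                ).h_rp
            )
            # past the |H| ~ d exp(-w d^2/4) turnover at d = sqrt(2/w) ~ 14
            for d in (20.0, 40.0, 80.0)
        ]
        assert values[0] > values[1] > values[2]
        assert values[2] < 1e-6

    def test_pipeline_from_harmonic_pair(self):
        min_r, min_p = gen_harmonic_pair(seed=97, n_modes=4,
                                         displacement_range=(2.0, 8.0))
        pairing = pair_modes(min_r, min_p, 300.0)
        res = coupling_at_crossing(pairing)
        assert 0.0 < res.total_overlap < 1.0
        assert res.c1 > 0
        # Eqs. relating c1, c2 to S hold for the assembled result
        s = res.total_overlap
        assert res.c1**2 + res.c2**2 == pytest.approx(1 / (1 - s**2), abs=1e-10)
        assert 2 * res.c1 * res.c2 == pytest.approx(s / (1 - s**2), abs=1e-10)
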