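"""Tests for the surface-hopping propagation engine."""

import numpy as np
import pytest

from spinhop import (
    PropagatorSettings,
    apply_decoherence,
    attempt_hop,
    build_uracil_lvc_model,
    diagonalize_tracked,
    hop_probabilities,
    propagate_amplitudes,
    run_trajectory,
    velocity_verlet_step,
)
from spinhop.initial_conditions import (
    InitialCondition,
    NormalModeSet,
    sample_wigner,
)
from spinhop.units import FS_TO_AU_TIME


def _random_hermitian(rng, n):
    A = rng.normal(0, 1, (n, n)) + 1j * rng.normal(0, 1, (n, n))
    return (A + A.conj().T) / 2


class TestDiagonalizeTracked:
    def test_already_diagonal_with_identity_reference(self):
        H = np.diag([1.0, 3.0, 2.0]).astype(complex)
        e, U = diagonalize_tracked(H, np.eye(3, dtype=complex))
        np.testing.assert_allclose(e, [1.0, 3.0, 2.0])
        np.testing.assert_allclose(U, np.eye(3), atol=1e-12)

    def test_symmetric_two_by_two_closed_form(self):
        c = 0.37
        e, U = diagonalize_tracked(np.array([[0, c], [c, 0]], dtype=complex))
        np.testing.assert_allclose(e, [-c, c], atol=1e-14)

    def test_unitarity_and_diagonality(self, rng):
        H = _random_hermitian(rng, 13)
        e, U = diagonalize_tracked(H)
        D = U.conj().T @ H @ U
        off = D - np.diag(np.diagonal(D))
        assert np.linalg.norm(off) < 1e-10
        np.testing.assert_allclose(U.conj().T @ U, np.eye(13), atol=1e-12)

    def test_phase_continuity_along_a_path(self, rng):
        """diag(U_prev^dagger U) stays real-positive along a slowly varying
        Hamiltonian path."""
        H0 = _random_hermitian(rng, 6)
        V = _random_hermitian(rng, 6) * 0.05
        _, U = diagonalize_tracked(H0)
        for k in range(1, 40):
            _, U_new = diagonalize_tracked(H0 + k * 0.02 * V, U)
            d = np.diagonal(U.conj().T @ U_new)
            assert np.all(d.real > 0)
            assert np.max(np.abs(d.imag)) < 1e-8
            U = U_new

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValueError):
            diagonalize_tracked(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestVelocityVerlet:
    def test_zero_gradient_gives_uniform_motion(self):
        q = np.array([0.0])
        v = np.array([2e-3])
        m = np.array([1000.0])
        g = np.zeros(1)
        for _ in range(10):
            q, v, g = velocity_verlet_step(
                q, v, m, g, lambda x: np.zeros(1), 20.0
            )
        np.testing.assert_allclose(v, [2e-3], atol=1e-18)
        np.testing.assert_allclose(q, [2e-3 * 200.0], atol=1e-12)

    def test_harmonic_motion_matches_cosine(self):
        """1000 velocity-Verlet steps at dt = 0.5 fs track the analytic
        harmonic solution to a relative error below 1e-3 per period."""
        omega = 1.8e-3  # a.u.
        m = 1.0 / omega
        dt = 0.5 * FS_TO_AU_TIME
        q = np.array([1.0])
        v = np.array([0.0])
        grad = lambda x: m * omega**2 * x
        g = grad(q)
        amp_err = 0.0
        period = 2 * np.pi / omega
        for step in range(1, 1001):
            q, v, g = velocity_verlet_step(q, v, m * np.ones(1), g, grad, dt)
            exact = np.cos(omega * step * dt)
            amp_err = max(amp_err, abs(q[0] - exact))
        n_periods = 1000 * dt / period
        assert amp_err / n_periods < 1e-3

    def test_time_reversal_symmetry(self):
        omega = 2e-3
        m = np.array([1.0 / omega])
        grad = lambda x: (omega**2 / omega) * x  # m w^2 x with m = 1/w
        q0 = np.array([0.7])
        v0 = np.array([1.3e-3])
        g = grad(q0)
        q, v = q0.copy(), v0.copy()
        for _ in range(50):
            q, v, g = velocity_verlet_step(q, v, m, g, grad, 20.0)
        v = -v
        for _ in range(50):
            q, v, g = velocity_verlet_step(q, v, m, g, grad, 20.0)
        np.testing.assert_allclose(q, q0, atol=1e-10)
        np.testing.assert_allclose(-v, v0, atol=1e-10)


class TestAmplitudePropagation:
    def test_constant_diagonal_acquires_pure_phases(self):
        E = np.array([0.1, 0.25])
        H = np.diag(E).astype(complex)
        c0 = np.array([0.6, 0.8], dtype=complex)
        dt = 0.5 * FS_TO_AU_TIME
        c = propagate_amplitudes(c0, H, H, dt, 0.02 * FS_TO_AU_TIME)
        np.testing.assert_allclose(c, c0 * np.exp(-1j * E * dt), atol=1e-12)

    def test_norm_conserved_over_many_steps(self, rng):
        n = 5
        H0 = _random_hermitian(rng, n) * 0.05
        H1 = _random_hermitian(rng, n) * 0.05
        c = np.zeros(n, dtype=complex)
        c[0] = 1.0
        dt = 0.5 * FS_TO_AU_TIME
        for k in range(2000):
            s = 0.5 * (1 + np.sin(k / 50))
            c = propagate_amplitudes(
                c, H0 + s * (H1 - H0), H0 + (s + 0.01) * (H1 - H0), dt,
                0.02 * FS_TO_AU_TIME,
            )
        assert abs(np.sum(np.abs(c) ** 2) - 1.0) < 1e-9

    def test_rabi_oscillation_closed_form(self):
        """Two-level constant coupling reproduces the Rabi formula."""
        delta = 2e-3   # detuning (E2 - E1)
        v = 1.5e-3     # coupling
        H = np.array([[0.0, v], [v, delta]], dtype=complex)
        c = np.array([1.0, 0.0], dtype=complex)
        dt = 0.5 * FS_TO_AU_TIME
        n_steps = 400
        for _ in range(n_steps):
            c = propagate_amplitudes(c, H, H, dt, 0.02 * FS_TO_AU_TIME)
        t = n_steps * dt
        omega_r = np.sqrt(v**2 + (delta / 2) ** 2)
        p2_exact = (v**2 / omega_r**2) * np.sin(omega_r * t) ** 2
        assert abs(np.abs(c[1]) ** 2 - p2_exact) < 1e-6


class TestHopping:
    def test_unchanged_amplitudes_give_zero_probabilities(self):
        c = np.array([0.8, 0.6], dtype=complex)
        p = hop_probabilities(c, c, 0)
        np.testing.assert_array_equal(p, np.zeros(2))

    def test_complete_transfer_limit(self):
        before = np.array([1.0, 0.0, 0.0], dtype=complex)
        after = np.array([1e-8, 0.0, 1.0], dtype=complex)
        p = hop_probabilities(before, after, 0)
        assert p[2] == pytest.approx(1.0, abs=1e-7)
        assert p[0] == 0.0 and p[1] == 0.0

    def test_probability_vector_contract(self, rng):
        for _ in range(100):
            b = rng.normal(0, 1, 4) + 1j * rng.normal(0, 1, 4)
            b /= np.linalg.norm(b)
            a = rng.normal(0, 1, 4) + 1j * rng.normal(0, 1, 4)
            a /= np.linalg.norm(a)
            p = hop_probabilities(b, a, 2)
            assert np.all(p >= 0)
            assert p[2] == 0.0
            assert p.sum() <= 1.0 + 1e-12

    def test_no_hop_when_probabilities_zero(self, rng):
        v = np.array([1e-3])
        new, v2, outcome = attempt_hop(
            0, np.zeros(3), np.array([0.0, 0.1, 0.2]), v, np.array([2000.0]), rng
        )
        assert new == 0 and outcome is None
        np.testing.assert_array_equal(v, v2)

    def test_downward_hop_conserves_total_energy(self, rng):
        masses = np.array([2000.0, 1500.0])
        v = np.array([1e-3, -2e-3])
        energies = np.array([0.05, 0.02])
        probs = np.array([0.0, 1.0])
        e_kin0 = 0.5 * np.sum(masses * v**2)
        new, v2, outcome = attempt_hop(0, probs, energies, v, masses, rng)
        assert new == 1 and outcome == (1, False)
        e_kin1 = 0.5 * np.sum(masses * v2**2)
        total0 = energies[0] + e_kin0
        total1 = energies[1] + e_kin1
        assert abs(total1 - total0) < 1e-10

    def test_insufficient_kinetic_energy_frustrates_upward_hop(self, rng):
        masses = np.array([2000.0])
        v = np.array([1e-4])
        energies = np.array([0.0, 0.5])
        new, v2, outcome = attempt_hop(
            0, np.array([0.0, 1.0]), energies, v, masses, rng
        )
        assert new == 0
        assert outcome == (1, True)
        np.testing.assert_array_equal(v2, v)


class TestDecoherence:
    def test_pure_active_state_is_fixed_point(self):
        c = np.array([0.0, 1.0, 0.0], dtype=complex)
        out = apply_decoherence(c, np.array([0.0, 0.1, 0.3]), 1, 0.05, 20.0, 0.1)
        np.testing.assert_allclose(out, c, atol=1e-15)

    def test_degenerate_state_not_damped(self):
        c = np.array([0.6, 0.8], dtype=complex)
        out = apply_decoherence(c, np.array([0.2, 0.2]), 1, 0.05, 20.0, 0.1)
        np.testing.assert_allclose(np.abs(out), np.abs(c), atol=1e-15)

    def test_damping_factor_matches_hand_computed_value(self):
        """Two states, gap 0.1 hartree, E_kin 0.05 hartree, dt 0.5 fs."""
        gap, e_kin, alpha = 0.1, 0.05, 0.1
        dt = 0.5 * FS_TO_AU_TIME
        tau = (1.0 / gap) * (1.0 + alpha / e_kin)
        expected = np.exp(-dt / tau)
        c = np.array([0.3, np.sqrt(1 - 0.09)], dtype=complex)
        out = apply_decoherence(c, np.array([0.1, 0.2]), 1, e_kin, dt, alpha)
        assert abs(out[0]) / abs(c[0]) == pytest.approx(expected, rel=1e-12)
        # norm restored via the active amplitude
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)


def _single_state_model():
    return build_uracil_lvc_model(
        {
            "n_singlets": 1,
            "n_triplets": 0,
            "epsilon_ev": [0.0],
            "kappa_ev": [[0.05, -0.03, 0.02]],
            "lambda_ev": [],
            "eta_cm1": [],
            "mu0": [[0.0, 0.0, 0.0]],
        }
    )


def _ic_from(model, state, seed):
    sample = sample_wigner(NormalModeSet.from_model(model), 1, seed)[0]
    return InitialCondition(
        sample=sample, initial_state=state,
        excitation_energy_ev=1.0, oscillator_strength=0.0,
    )


class TestRunTrajectory:
    def test_single_surface_adiabatic_limit(self):
        """One-state model: no hops and total-energy drift below 1e-6
        hartree over 1 ps."""
        model = _single_state_model()
        traj = run_trajectory(
            model, _ic_from(model, 0, 21), PropagatorSettings(seed=1)
        )
        assert traj.hop_events == []
        drift = np.max(np.abs(traj.total_energy - traj.total_energy[0]))
        assert drift < 1e-6

    def test_spin_purity_without_soc(self, uracil_model_no_soc):
        """All SOC constants zero + singlet start: triplet populations are
        identically zero along the trajectory."""
        model = uracil_model_no_soc
        traj = run_trajectory(
            model, _ic_from(model, 2, 22),
            PropagatorSettings(t_max_fs=100.0, seed=2),
        )
        assert np.all(traj.mch_multiplicity == 1)

    def test_determinism_under_fixed_seed(self, uracil_model):
        ic = _ic_from(uracil_model, 2, 23)
        s = PropagatorSettings(t_max_fs=50.0, seed=77)
        a = run_trajectory(uracil_model, ic, s)
        b = run_trajectory(uracil_model, ic, s)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.populations, b.populations)
        np.testing.assert_array_equal(a.active, b.active)
        assert len(a.hop_events) == len(b.hop_events)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            PropagatorSettings(dt_fs=0.5, dt_electronic_fs=0.03)
        with pytest.raises(ValueError):
            PropagatorSettings(t_max_fs=-1.0)
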