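"""Choi extension, Wootters concurrence, RHP measure, solver comparison."""

import numpy as np
import pytest

import qmebench as qb
from qmebench.experiments import make_propagator
from qmebench.nonmarkov import bell_state_projector
from qmebench.trajectory import Trajectory


def werner(p):
    return p * bell_state_projector() + (1 - p) * np.eye(4) / 4.0


class TestConcurrence:
    def test_maximally_entangled(self):
        assert qb.concurrence(bell_state_projector()) == pytest.approx(1.0)

    def test_product_state(self):
        rho = np.kron(np.diag([0.3, 0.7]), np.diag([0.6, 0.4])).astype(complex)
        assert qb.concurrence(rho) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p,expected", [(0.5, 0.25), (1 / 3, 0.0), (0.9, 0.85)])
    def test_werner_closed_form(self, p, expected):
        assert qb.concurrence(werner(p)) == pytest.approx(expected, abs=1e-12)

    def test_random_separable_mixtures(self):
        """Convex mixtures of product states are unentangled."""
        rng = np.random.default_rng(3)
        for _ in range(500):
            n = rng.integers(2, 5)
            w = rng.dirichlet(np.ones(n))
            rho = np.zeros((4, 4), dtype=complex)
            for wi in w:
                a = rng.normal(size=2) + 1j * rng.normal(size=2)
                b = rng.normal(size=2) + 1j * rng.normal(size=2)
                a /= np.linalg.norm(a)
                b /= np.linalg.norm(b)
                psi = np.kron(a, b)
                rho += wi * np.outer(psi, psi.conj())
            assert qb.concurrence(rho) <= 1e-10

    def test_nonhermitian_rejected(self):
        bad = np.eye(4, dtype=complex) / 4
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            qb.concurrence(bad)

    def test_positivity_flag_on_unphysical_state(self):
        rho = np.diag([0.6, 0.5, -0.05, -0.05]).astype(complex)
        val, flag = qb.concurrence(rho, return_flag=True)
        assert flag


class TestChoiPropagate:
    def test_identity_dynamics(self):
        """No Hamiltonian, no bath: the Bell state persists, concurrence 1."""
        m = qb.DimerModel(omega0=0, J=0, lam=0, gamma=50, T=300)
        ext = qb.choi_propagate(make_propagator("tc2", m, K=2),
                                np.arange(0.0, 101.0, 1.0))
        series, flag = qb.concurrence_series(ext)
        np.testing.assert_allclose(series, 1.0, atol=1e-10)
        assert not flag

    def test_unitary_dynamics_preserves_entanglement(self):
        m = qb.DimerModel(omega0=70, J=100, lam=0, gamma=50, T=300)
        ext = qb.choi_propagate(make_propagator("tl2", m, K=2),
                                np.arange(0.0, 201.0, 1.0))
        series, _ = qb.concurrence_series(ext)
        np.testing.assert_allclose(series, 1.0, atol=1e-8)

    def test_initial_state_is_bell_projector(self):
        m = qb.DimerModel(omega0=70, J=100, lam=5, gamma=50, T=300)
        ext = qb.choi_propagate(make_propagator("tc2", m, K=4),
                                np.arange(0.0, 11.0, 1.0))
        np.testing.assert_allclose(ext.states[0], bell_state_projector(),
                                   atol=1e-12)
        assert np.max(np.abs(np.einsum("tii->t", ext.states) - 1)) < 1e-9

    def test_depolarizing_toy_map_gives_werner(self):
        """Φ(ρ) = p(t)ρ + (1−p)I/2·tr(ρ) ⇒ Werner Choi state."""
        grid = np.arange(0.0, 101.0, 1.0)
        ps = np.exp(-grid / 40.0)

        def prop(rho0, g, allow_nonhermitian=False):
            tr = np.trace(rho0)
            states = np.array([p * rho0 + (1 - p) * tr * np.eye(2) / 2 for p in ps])
            return states

        ext = qb.choi_propagate(prop, grid)
        series, _ = qb.concurrence_series(ext)
        expected = np.maximum(0.0, (3 * ps - 1) / 2)
        np.testing.assert_allclose(series, expected, atol=1e-10)

    def test_hermitian_fallback_decomposition(self):
        """Solvers that reject non-Hermitian input still yield the Choi state."""
        m = qb.DimerModel(omega0=70, J=100, lam=5, gamma=50, T=300)
        base = make_propagator("tc2", m, K=4)
        grid = np.arange(0.0, 51.0, 1.0)

        def strict(rho0, g, allow_nonhermitian=False):
            if np.max(np.abs(rho0 - rho0.conj().T)) > 1e-10:
                raise ValueError("Hermitian input only")
            return base(rho0, g)

        a = qb.choi_propagate(strict, grid)
        b = qb.choi_propagate(base, grid)
        np.testing.assert_allclose(a.states, b.states, atol=1e-10)


class TestRHPMeasure:
    def test_monotone_series_is_markovian(self):
        t = np.arange(10.0)
        res = qb.rhp_measure(t, np.linspace(1, 0, 10), epsilon=0.0)
        assert res.N == 0.0

    def test_known_revival_value(self):
        """Series (1, 0.5, 0.7, 0): ∫|dE| − [E(0) − E(end)] = 0.4."""
        res = qb.rhp_measure(np.arange(4.0), np.array([1.0, 0.5, 0.7, 0.0]),
                             epsilon=0.0)
        assert res.N == pytest.approx(0.4, abs=1e-14)

    def test_epsilon_suppresses_small_ripple(self):
        series = np.array([1.0, 0.9, 0.9 + 5e-7, 0.8])
        assert qb.rhp_measure(np.arange(4.0), series, epsilon=1e-6).N == 0.0
        assert qb.rhp_measure(np.arange(4.0), series, epsilon=0.0).N > 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            qb.rhp_measure(np.array([0.0, 1.0]), np.array([1.0, 0.5]))

    def test_grid_refinement_stability(self, grid800):
        """N is stable under refining the sampling grid beyond 1 fs."""
        m = qb.DimerModel(omega0=70, J=100, lam=100, gamma=50, T=300)
        prop = make_propagator("tc2", m, K=4)
        grid_fine = np.arange(0.0, 801.0, 0.5)
        n1 = qb.measure_from_extended(qb.choi_propagate(prop, grid800)).N
        n2 = qb.measure_from_extended(qb.choi_propagate(prop, grid_fine)).N
        assert n2 == pytest.approx(n1, rel=0.02)


class TestCompareSolvers:
    def _traj(self, states, times):
        return Trajectory(times=times, states=states)

    def test_identical_trajectories(self):
        t = np.arange(0.0, 10.0)
        states = np.array([np.diag([0.7, 0.3]).astype(complex)] * 10)
        rep = qb.compare_solvers(self._traj(states, t), self._traj(states, t))
        assert rep.max_population_deviation == 0.0
        assert rep.mean_coherence_deviation == 0.0
        assert rep.min_fidelity == pytest.approx(1.0, abs=1e-12)

    def test_resampling(self):
        t1 = np.arange(0.0, 10.0)
        t2 = np.arange(0.0, 8.5, 0.5)
        f = lambda t: np.array([[1 - 0.01 * t, 0], [0, 0.01 * t]], dtype=complex)
        a = self._traj(np.array([f(t) for t in t1]), t1)
        b = self._traj(np.array([f(t) for t in t2]), t2)
        with pytest.raises(ValueError):
            qb.compare_solvers(a, b)  # a's grid extends past b's
        rep = qb.compare_solvers(b, a)  # b's grid sits inside a's
        assert rep.max_population_deviation < 1e-12

    def test_dimension_mismatch(self):
        t = np.arange(0.0, 5.0)
        a = self._traj(np.array([np.eye(2, dtype=complex) / 2] * 5), t)
        b = Trajectory(times=t, states=np.array([np.eye(4, dtype=complex) / 4] * 5))
        with pytest.raises(ValueError):
            qb.compare_solvers(a, b)
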