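"""HEOM reference propagator: bookkeeping, exactness checks, convergence."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import comb

import qmebench as qb


@pytest.fixture(scope="module")
def weak_model():
    return qb.DimerModel(omega0=70, J=100, lam=5, gamma=50, T=300)


class TestBookkeeping:
    @pytest.mark.parametrize("depth,K", [(4, 2), (1, 0), (6, 3), (2, 5)])
    def test_ado_count_formula(self, depth, K):
        indices = qb.enumerate_hierarchy(depth, K + 1)
        assert len(indices) == qb.ado_count(depth, K)
        assert len(indices) == int(comb(depth + K + 1, depth, exact=True))
        # bijective with ordinal, zero index first
        assert [hi.ordinal for hi in indices] == list(range(len(indices)))
        assert indices[0].n == (0,) * (K + 1)
        assert len({hi.n for hi in indices}) == len(indices)
        assert all(hi.tier <= depth for hi in indices)

    def test_example_35(self):
        assert qb.ado_count(4, 2) == 35

    def test_config_validation(self):
        with pytest.raises(ValueError):
            qb.HEOMConfig(depth=0, K=0)
        with pytest.raises(ValueError):
            qb.HEOMConfig(depth=2, K=-1)

    def test_expansion_size_mismatch_rejected(self, weak_model):
        corr = qb.correlation_expansion(weak_model, 3)
        with pytest.raises(ValueError):
            qb.build_hierarchy(weak_model, corr, qb.HEOMConfig(depth=3, K=2))

    def test_ado_cap(self, weak_model):
        corr = qb.correlation_expansion(weak_model, 3)
        cfg = qb.HEOMConfig(depth=8, K=3, ado_cap=10)
        with pytest.raises(ResourceWarning):
            qb.build_hierarchy(weak_model, corr, cfg)

    def test_zero_coupling_no_intertier_blocks(self):
        m = qb.DimerModel(omega0=70, J=100, lam=0, gamma=50, T=300)
        gen = qb.build_hierarchy(m, qb.correlation_expansion(m, 2),
                                 qb.HEOMConfig(depth=3, K=2))
        M = gen.matrix.toarray()
        # only block-diagonal entries survive
        for i in range(gen.n_ado):
            for j in range(gen.n_ado):
                if i != j:
                    assert not np.any(M[4 * i:4 * i + 4, 4 * j:4 * j + 4])


class TestPropagation:
    def test_zero_coupling_unitary(self):
        m = qb.DimerModel(omega0=70, J=100, lam=0, gamma=50, T=300)
        gen = qb.build_hierarchy(m, qb.correlation_expansion(m, 1),
                                 qb.HEOMConfig(depth=2, K=1))
        H = qb.exciton_basis(m).hamiltonian_exciton()
        rho0 = np.array([[0.6, 0.2j], [-0.2j, 0.4]], dtype=complex)
        grid = np.arange(0.0, 201.0, 1.0)
        traj = qb.propagate_heom(gen, rho0, grid)
        for t, rho in zip(grid[::50], traj.states[::50]):
            U = expm(-1j * H * t)
            np.testing.assert_allclose(rho, U @ rho0 @ U.conj().T, atol=1e-9)

    def test_hermiticity_random_initials(self, weak_model):
        gen = qb.build_hierarchy(weak_model, qb.correlation_expansion(weak_model, 1),
                                 qb.HEOMConfig(depth=3, K=1))
        rng = np.random.default_rng(11)
        grid = np.arange(0.0, 41.0, 10.0)
        for _ in range(100):
            A = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
            rho = A + A.conj().T
            rho = rho / np.trace(rho).real if abs(np.trace(rho).real) > 0.2 \
                else rho + 2 * np.eye(2)
            rho = rho / np.trace(rho)
            traj = qb.propagate_heom(gen, rho, grid)
            assert traj.hermiticity_defect() < 1e-10

    def test_trace_and_positivity(self, weak_model):
        cfg = qb.converge_heom(weak_model, 1e-4)
        gen = qb.build_hierarchy(weak_model,
                                 qb.correlation_expansion(weak_model, cfg.K), cfg)
        rho0 = np.array([[1, 0], [0, 0]], dtype=complex)
        traj = qb.propagate_heom(gen, rho0, np.arange(0.0, 801.0, 1.0))
        assert np.max(np.abs(traj.trace() - 1)) < 1e-8
        mins = [np.linalg.eigvalsh(0.5 * (r + r.conj().T))[0] for r in traj.states]
        assert min(mins) > -1e-8

    def test_pure_dephasing_exact(self):
        """J = 0: a deep hierarchy reproduces the analytic dephasing law."""
        m = qb.DimerModel(omega0=70, J=0, lam=50, gamma=50, T=250)
        cfg = qb.HEOMConfig(depth=16, K=2)
        corr = qb.correlation_expansion(m, cfg.K)
        gen = qb.build_hierarchy(m, corr, cfg)
        rho0 = np.full((2, 2), 0.5, dtype=complex)
        grid = np.arange(0.0, 401.0, 4.0)
        traj = qb.propagate_heom(gen, rho0, grid)
        S = qb.exciton_basis(m).S
        dS2 = (S[0, 0] - S[1, 1]).real ** 2
        c, nu, delta = corr.c, corr.nu, corr.terminator_amplitude

        def decay(t):
            val = sum(ck.real * (t / nk + (np.exp(-nk * t) - 1.0) / nk**2)
                      for ck, nk in zip(c, nu))
            return dS2 * (val + delta * t)

        expected = 0.5 * np.exp(-np.array([decay(t) for t in grid])) \
            * np.exp(-1j * m.omega0_ang * grid)
        # truncation error at depth 16 sits near 3e-6 and halves per tier
        assert np.max(np.abs(traj.states[:, 0, 1] - expected)) < 1e-5

    def test_detailed_balance_weak_coupling(self, weak_model):
        """Long-time population ratio approaches the exciton Boltzmann factor."""
        cfg = qb.converge_heom(weak_model, 1e-4)
        gen = qb.build_hierarchy(weak_model,
                                 qb.correlation_expansion(weak_model, cfg.K), cfg)
        rho0 = np.array([[1, 0], [0, 0]], dtype=complex)
        traj = qb.propagate_heom(gen, rho0, np.arange(0.0, 6001.0, 10.0))
        ratio = traj.states[-1, 0, 0].real / traj.states[-1, 1, 1].real
        b = qb.exciton_basis(weak_model)
        boltz = np.exp(-b.splitting_ang / qb.thermal_angular(weak_model.T))
        assert ratio == pytest.approx(boltz, rel=0.10)


class TestConvergence:
    def test_zero_coupling_minimal(self):
        m = qb.DimerModel(omega0=70, J=100, lam=0, gamma=50, T=300)
        cfg = qb.converge_heom(m, 1e-4)
        assert (cfg.depth, cfg.K) == (1, 0)

    def test_weak_coupling_modest_depth(self, weak_model):
        cfg = qb.converge_heom(weak_model, 1e-4)
        assert cfg.depth <= 8

    def test_matsubara_count_monotone_in_temperature(self):
        """Colder baths never need fewer Matsubara terms at equal tolerance."""
        Ks = {}
        for T in (200.0, 300.0):
            m = qb.DimerModel(omega0=70, J=100, lam=5, gamma=50, T=T)
            Ks[T] = qb.converge_heom(m, 1e-4).K
        assert Ks[200.0] >= Ks[300.0]

    def test_cap_error_carries_history(self, weak_model):
        with pytest.raises(qb.HEOMConvergenceError) as info:
            qb.converge_heom(weak_model, 1e-12, max_depth=2, max_K=1)
        assert len(info.value.history) > 0
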