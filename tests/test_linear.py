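"""Linear integrator networks: modes, loading, energy — against closed forms.

The canonical 2-neuron system A = [[0, 5], [0, -1]] has hand-computable
dynamics (x(t) = (5 c2 (1 - e^-t) + c1, c2 e^-t) from x(0) = (c1, c2)) and is
used as the analytic oracle throughout.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from infoload.errors import ConfigError, StepSizeError
from infoload.linear import (
    LinearNetwork,
    Trajectory,
    PiecewiseConstantInput,
    amplifying_modes,
    henrici_index,
    loading_vectors,
    make_feedforward_network,
    make_random_network,
    optimal_loading_input,
    persistent_amplitude,
    persistent_direction,
    persistent_modes,
    simulate,
    total_energy,
)

LEFT_EV = np.array([1.0, 5.0]) / np.sqrt(26.0)  # left eigenvector of the integrator


def angle_deg(u, v):
    return np.degrees(np.arccos(np.clip(abs(u @ v), 0.0, 1.0)))


class TestRandomNetworkConstruction:
    @pytest.mark.parametrize("kind", ["symmetric", "unconstrained"])
    def test_integrator_invariant(self, kind):
        """Eigenvalue surgery puts exactly one eigenvalue of W at Re = 1."""
        net = make_random_network(64, kind, gain=0.8, seed=3)
        net.check_integrator()
        if kind == "symmetric":
            assert np.max(np.abs(net.weights - net.weights.T)) < 1e-12

    def test_deterministic_given_seed(self):
        a = make_random_network(30, "unconstrained", seed=5)
        b = make_random_network(30, "unconstrained", seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_persistent_vector_is_eigenvector(self):
        net = make_random_network(80, "unconstrained", seed=7)
        v = persistent_direction(net)
        resid = net.weights @ v - v
        assert np.linalg.norm(resid) < 1e-8

    def test_random_direction_near_orthogonal_to_persistent(self):
        """Random unit vectors in high dimension barely overlap the persistent
        mode (|cos| median < 0.1 across seeds at n=1000)."""
        rng = np.random.default_rng(0)
        cos = []
        for seed in range(12):
            net = make_random_network(1000, "unconstrained", gain=0.8, seed=seed)
            u = rng.standard_normal(1000)
            u /= np.linalg.norm(u)
            cos.append(abs(u @ persistent_direction(net)))
        assert np.median(cos) < 0.1

    def test_invalid_args(self):
        with pytest.raises(ConfigError):
            make_random_network(1, "symmetric")
        with pytest.raises(ConfigError):
            make_random_network(10, "symmetric", gain=-1.0)

    def test_feedforward_network_geometry(self):
        """Source channels are orthogonal to the slow invariant subspace."""
        net = make_feedforward_network(60, seed=2)
        net.check_integrator()
        pm = persistent_modes(net, top_frac=0.25)
        proj = np.linalg.norm(pm.basis.T @ net.channels, axis=0) ** 2
        assert np.all(proj < 1e-8)


class TestSimulate:
    def test_zero_vector_field_fixed_point(self):
        net = LinearNetwork(np.eye(3))  # A = 0
        v = np.array([1.0, -2.0, 0.5])
        tr = simulate(net, x0=v, T=2.0, dt=0.05)
        assert np.allclose(tr.states, v)

    def test_closed_form_two_neuron(self, canonical_net):
        """x(3) from x0=(0,1): (5(1-e^-3), e^-3) = (4.751, 0.0498)."""
        tr = simulate(canonical_net, x0=[0.0, 1.0], T=3.0, dt=0.01)
        assert np.allclose(tr.states[-1], [4.751, 0.0498], atol=5e-4)

    def test_noisy_trials_seeded(self, canonical_net):
        net = LinearNetwork(canonical_net.weights, noise_sigma=0.3)
        a = simulate(net, x0=[0.0, 1.0], T=1.0, dt=0.02, n_trials=4, seed=9)
        b = simulate(net, x0=[0.0, 1.0], T=1.0, dt=0.02, n_trials=4, seed=9)
        assert np.array_equal(a, b)
        c = simulate(net, x0=[0.0, 1.0], T=1.0, dt=0.02, n_trials=4, seed=10)
        assert not np.array_equal(a, c)

    def test_piecewise_input_matches_euler(self, canonical_net):
        inp = PiecewiseConstantInput([0.0, 0.5], [[1.0, 2.0]])
        exact = simulate(canonical_net, input_fn=inp, T=1.0, dt=0.01)
        # independent fine-step Euler oracle
        x = np.zeros(2)
        A = canonical_net.A
        h = 1e-4
        for k in range(int(1.0 / h)):
            x = x + h * (A @ x + inp(k * h))
        assert np.allclose(exact.states[-1], x, atol=1e-3)

    def test_step_size_guard(self, canonical_net):
        with pytest.raises(StepSizeError):
            simulate(canonical_net, x0=[1.0, 0.0], T=1.0, dt=2.0)

    def test_exactly_one_of_x0_and_input(self, canonical_net):
        with pytest.raises(ConfigError):
            simulate(canonical_net, T=1.0)


class TestPersistentModes:
    def test_hand_eigendecomposition(self):
        W = np.array([[0.5, 0.5], [0.5, 0.5]])
        net = LinearNetwork(W, kind="symmetric")
        ms = persistent_modes(net, top_frac=0.5)
        assert np.allclose(sorted(np.real(ms.eigenvalues)), [-1.0, 0.0], atol=1e-12)
        assert angle_deg(ms.top, np.array([1.0, 1.0]) / np.sqrt(2)) < 1e-6

    def test_left_eigenvector_canonical(self, canonical_net):
        ms = persistent_modes(canonical_net, top_frac=0.5)
        assert angle_deg(ms.top, np.array([1.0, 0.0])) < 1e-8
        assert angle_deg(ms.left_directions[:, 0], LEFT_EV) < 1e-6

    def test_top_frac_selection(self):
        net = LinearNetwork(np.eye(3) + np.diag([0.0, -2.0, -3.0]))
        ms = persistent_modes(net, top_frac=1 / 3)
        assert ms.n_modes == 1
        assert angle_deg(ms.top, np.eye(3)[0]) < 1e-10

    def test_conjugate_pair_kept_together(self):
        # rotation block plus decaying real mode: pair straddles nothing here,
        # but both real/imag parts must enter as orthonormal directions
        A = np.zeros((4, 4))
        A[0, 1], A[1, 0] = 1.0, -1.0        # eigenvalues +/- i (Re 0)
        A[2, 2], A[3, 3] = -1.0, -2.0
        net = LinearNetwork(np.eye(4) + A)
        ms = persistent_modes(net, top_frac=0.25)  # nominal k=1 -> pair kept
        assert ms.n_modes == 2
        assert np.allclose(ms.basis.T @ ms.basis, np.eye(2), atol=1e-10)


class TestAmplifyingModes:
    def test_canonical_value_and_oracle_agreement(self, canonical_A):
        """Top Gramian eigenvector at T=10 against the quadrature route and a
        brute-force search over unit directions (energy maximization)."""
        ms = amplifying_modes(canonical_A, top_frac=0.5, horizon=10.0,
                              method="eig")
        ms_q = amplifying_modes(canonical_A, top_frac=0.5, horizon=10.0,
                                method="quadrature")
        assert angle_deg(ms.top, ms_q.top) < 1e-4
        # frozen closed-form value (hand-computed Gramian entries):
        # Q = [[10, 45.0002], [45.0002, 213.0023]]
        assert np.allclose(np.abs(ms.top), [0.20714, 0.97831], atol=1e-4)
        # brute-force oracle on an angular grid
        thetas = np.linspace(0, np.pi, 3600, endpoint=False)
        best, best_e = None, -1.0
        for th in thetas:
            u = np.array([np.cos(th), np.sin(th)])
            e = 0.0
            x = u.copy()
            E = expm(canonical_A * 0.005)
            for _ in range(2000):
                e += 0.005 * x @ x
                x = E @ x
            if e > best_e:
                best, best_e = u, e
        assert angle_deg(ms.top, best) < 0.2

    def test_long_horizon_converges_to_left_eigenvector(self, canonical_A):
        """Angle to the integrator's left eigenvector decreases in T and is
        below 1 degree for T >= 10; distance < 0.01 by T=15."""
        angles = [angle_deg(amplifying_modes(canonical_A, 0.5, horizon=T).top,
                            LEFT_EV) for T in (2.0, 5.0, 10.0, 15.0)]
        assert all(np.diff(angles) < 0) and angles[2] < 1.0
        d = np.linalg.norm(amplifying_modes(canonical_A, 0.5, horizon=15.0).top
                           - LEFT_EV)
        assert d < 0.01

    def test_symmetric_dynamics_amp_equals_persistent(self):
        net = make_random_network(100, "symmetric", seed=4)
        am = amplifying_modes(net.A, 0.25, horizon=10.0)
        assert abs(am.top @ persistent_direction(net)) > 1 - 1e-6

    def test_eig_and_quadrature_agree_on_random_net(self):
        net = make_random_network(40, "unconstrained", seed=8)
        a = amplifying_modes(net.A, 0.25, horizon=2.0, method="eig")
        b = amplifying_modes(net.A, 0.25, horizon=2.0, method="quadrature")
        assert angle_deg(a.top, b.top) < 1e-4
        assert np.allclose(a.values, b.values, rtol=1e-6)

    def test_three_neuron_brute_force(self):
        """Gramian top eigenvector matches energy maximization on a grid."""
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3)) * 0.7 - np.eye(3)
        ms = amplifying_modes(A, top_frac=1 / 3, horizon=4.0)
        # brute-force on a spherical Fibonacci grid (~0.17 deg spacing)
        n = 1_500_000
        i = np.arange(n)
        phi = np.arccos(1 - 2 * (i + 0.5) / n)
        theta = np.pi * (1 + 5**0.5) * i
        U = np.stack([np.sin(phi) * np.cos(theta),
                      np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
        Q = np.zeros((3, 3))
        E = expm(A * 0.002)
        M = np.eye(3)
        for _ in range(2000):
            Q += 0.002 * M.T @ M
            M = M @ E
        energies = np.einsum("ij,jk,ik->i", U, Q, U)
        best = U[np.argmax(energies)]
        assert angle_deg(ms.top, best) < 0.2


class TestOptimalLoading:
    def test_zero_horizon_returns_readout(self, canonical_A):
        p = np.array([0.6, 0.8])
        assert np.allclose(np.abs(optimal_loading_input(canonical_A, p, T=0.0)),
                           np.abs(p))

    def test_symmetric_eigenvector_invariance(self):
        net = make_random_network(30, "symmetric", seed=6)
        w, V = np.linalg.eigh(net.A)
        p = V[:, 3]
        for T in (0.5, 2.0, 10.0):
            u = optimal_loading_input(net.A, p, T=T)
            assert abs(u @ p) > 1 - 1e-9

    def test_canonical_amplification(self, canonical_A, canonical_net):
        """Optimal loading of the (1,0) readout achieves persistent amplitude
        sqrt(26) ~ 5.099 vs 1.0 for loading along (1,0) itself."""
        p = np.array([1.0, 0.0])
        u = optimal_loading_input(canonical_A, p, T=10.0)
        assert np.allclose(np.abs(u), [0.19612, 0.98058], atol=1e-4)
        amp = persistent_amplitude(canonical_net, u, T=50.0)
        assert abs(amp - np.sqrt(26.0)) < 1e-3
        assert abs(persistent_amplitude(canonical_net, p, T=50.0) - 1.0) < 1e-9

    def test_numeric_matches_closed_form(self, canonical_A):
        p = np.array([1.0, 0.0])
        u_cf = optimal_loading_input(canonical_A, p, T=10.0)
        u_num = optimal_loading_input(canonical_A, p, T=10.0, method="numeric",
                                      seed=0)
        assert angle_deg(u_cf, u_num) < 0.5


class TestHenriciIndex:
    @pytest.mark.parametrize("A, atol", [
        # the sqrt in the formula amplifies rounding to ~sqrt(eps) when the
        # squared eigenvalue sum is irrational
        (np.array([[2.0, 1.0], [1.0, -1.0]]), 1e-7),           # symmetric
        (np.array([[0.0, 1.0], [-1.0, 0.0]]), 1e-10),          # rotation
        (np.diag([3.0, -1.0, 0.5]), 1e-10),                    # diagonal
    ])
    def test_normal_matrices_are_zero(self, A, atol):
        assert henrici_index(A) < atol

    def test_nilpotent_is_one(self):
        assert abs(henrici_index(np.array([[0.0, 1.0], [0.0, 0.0]])) - 1.0) < 1e-12

    def test_canonical_value(self, canonical_A):
        assert abs(henrici_index(canonical_A) - np.sqrt(25.0 / 26.0)) < 1e-10

    def test_zero_matrix_rejected(self):
        with pytest.raises(ConfigError):
            henrici_index(np.zeros((3, 3)))


class TestTotalEnergy:
    def test_zero_trajectory(self):
        assert total_energy(Trajectory(np.zeros((10, 4)), dt=0.1)) == 0.0

    def test_pure_decay_half(self):
        net = LinearNetwork(np.zeros((2, 2)))  # A = -I
        x0 = np.array([0.8, 0.6])
        tr = simulate(net, x0=x0, T=20.0, dt=0.002)
        assert abs(total_energy(tr) - 0.5) < 1e-3

    def test_canonical_closed_form(self, canonical_net):
        """Integral of ||x||^2 over [0, 10] from x0=(0,1) is 213.002."""
        tr = simulate(canonical_net, x0=[0.0, 1.0], T=10.0, dt=0.001)
        assert abs(total_energy(tr) - 213.002) < 0.1


class TestEnsembleProperties:
    def test_symmetric_equivalence_ensemble(self):
        """Top amplifying == top persistent for symmetric networks, 100 draws."""
        for seed in range(100):
            net = make_random_network(100, "symmetric", seed=seed)
            am = amplifying_modes(net.A, 0.25, horizon=10.0)
            assert abs(am.top @ persistent_direction(net)) > 1 - 1e-6

    def test_size_scaling_orthogonality(self):
        """Median |cos(top amplifying, persistent mode)| decreases with N for
        unconstrained networks."""
        med = {}
        for n in (100, 300, 1000):
            cos = []
            for seed in range(20):
                net = make_random_network(n, "unconstrained", seed=seed)
                am = amplifying_modes(net.A, top_frac=1.0 / n, horizon=10.0,
                                      method="eig")
                cos.append(abs(am.top @ persistent_direction(net)))
            med[n] = np.median(cos)
        assert med[100] > med[300] > med[1000]

    def test_energy_near_optimality_at_long_delays(self):
        """Scaled to equal persistent amplitude at time T, the amplifying-mode
        input's energy approaches the true minimum as the delay grows: the
        excess over the closed-form optimum (u* = Q^-1 w, the generalized
        Rayleigh minimizer of energy per squared amplitude) shrinks
        monotonically with T and is within 5% by T = 80 tau."""
        from scipy.linalg import expm as _expm

        from infoload.linear import _eig_lr

        def excess_ratio(A, T):
            n = 400
            Q = np.zeros(A.shape)
            E = _expm(A * (T / n))
            M = np.eye(A.shape[0])
            for _ in range(n):
                Q += (T / n) * M.T @ M
                M = M @ E
            ev, VL, VR = _eig_lr(A)
            i = int(np.argmin(np.abs(ev)))
            v1 = VR[:, i].real
            v1 /= np.linalg.norm(v1)
            u1 = VL[:, i].real
            u1 = u1 / (u1 @ v1)
            w = _expm(A.T * T) @ u1  # persistent amplitude(u) = |w @ u|

            def cost(u):
                return (u @ Q @ u) / (w @ u) ** 2

            u_star = np.linalg.solve(Q, w)  # exact minimizer
            top = amplifying_modes(A, top_frac=0.01, horizon=T,
                                   method="eig").top
            return cost(top) / cost(u_star)

        for seed in range(10):
            net = make_random_network(100, "unconstrained", seed=seed)
            ratios = [excess_ratio(net.A, T) for T in (10.0, 20.0, 40.0, 80.0)]
            assert all(np.diff(ratios) < 0)
            assert ratios[-1] <= 1.05


class TestLoadingVectors:
    def test_two_condition_pairs_are_opposite(self):
        net = make_feedforward_network(40, seed=1)
        for strat in ("persistent", "amplifying", "random"):
            U = loading_vectors(net, strat, n_conditions=2, seed=3)
            assert np.allclose(U[0], -U[1])
            assert np.allclose(np.linalg.norm(U, axis=1), 1.0)

    def test_unknown_strategy(self):
        net = make_feedforward_network(20, seed=1)
        with pytest.raises(ConfigError):
            loading_vectors(net, "optimal", n_conditions=2)
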