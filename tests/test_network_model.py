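"""Network model: node dynamics, coupling matrices, graphs, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tvcoupling.network_model import (
    CouplingSpec,
    NetworkSystem,
    consensus_dynamics,
    consensus_rhs,
    coupling_at,
    lorenz_dynamics,
    lorenz_rhs,
    network_rhs,
    rk4_step,
    simulate_ensemble,
    watts_strogatz_graph,
    NodeDynamics,
)


class TestLorenz:
    def test_fixed_point_at_origin(self):
        assert np.allclose(lorenz_rhs(np.zeros(3)), 0.0)

    def test_hand_substitution(self):
        # a(y-x)=0, cx-y-xz = 28-1-1 = 26, xy-bz = 1-8/3
        out = lorenz_rhs(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(out, [0.0, 26.0, -5.0 / 3.0])

    def test_chaotic_defaults(self):
        dyn = lorenz_dynamics()
        assert dyn.params == {"a": 10.0, "b": 8.0 / 3.0, "c": 28.0}
        assert dyn.n == 3

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            lorenz_rhs(np.array([np.nan, 0.0, 0.0]))

    def test_batched_evaluation_matches_loop(self, rng):
        states = rng.normal(size=(5, 4, 3))
        out = lorenz_rhs(states)
        for i in range(5):
            for j in range(4):
                assert np.allclose(out[i, j], lorenz_rhs(states[i, j]))


class TestConsensus:
    def test_intrinsic_dynamics_vanish(self):
        assert consensus_rhs(np.array([5.0]))[0] == 0.0
        assert np.all(consensus_rhs(np.ones((7, 3, 1))) == 0.0)

    def test_symmetric_coupling_conserves_state_sum(self):
        # symmetric row-sum-zero coupling: d/dt sum_i x_i = 0
        spec = CouplingSpec(
            N=5,
            weight_fns={(0, 1): 1.0, (1, 2): 0.5, (2, 3): 1.2, (3, 4): 0.8},
            symmetric=True,
        )
        system = NetworkSystem(consensus_dynamics(), spec, np.eye(1))
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=5)
        total0 = X.sum()
        rhs = lambda x, t: network_rhs(system, x, t)
        t = 0.0
        for _ in range(1000):
            X = rk4_step(rhs, X, t, 1e-3)
            t += 1e-3
        assert abs(X.sum() - total0) <= 1e-9  # per unit of simulated time


class TestCouplingAt:
    def _spec50(self):
        edges = {(i, (i + 1) % 50): 1.0 for i in range(50)}
        edges[(0, 2)] = lambda t: abs(np.sin(t))
        return CouplingSpec(N=50, weight_fns=edges, symmetric=True)

    def test_time_varying_entry(self):
        spec = self._spec50()
        assert coupling_at(spec, 0.0)[0, 2] == 0.0
        assert np.isclose(coupling_at(spec, np.pi / 2)[0, 2], 1.0)

    @pytest.mark.parametrize("t", [0.0, 0.3, 1.7, np.pi, 10.0])
    def test_row_sums_vanish(self, t):
        C = coupling_at(self._spec50(), t)
        assert np.max(np.abs(C.sum(axis=1))) <= 1e-12

    def test_negative_weight_function_rejected(self):
        spec = CouplingSpec(N=3, weight_fns={(0, 1): lambda t: np.sin(t)})
        with pytest.raises(ValueError, match="negative|< 0"):
            coupling_at(spec, 3.5)  # sin(3.5) < 0

    def test_self_coupling_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            CouplingSpec(N=3, weight_fns={(1, 1): 1.0})


class TestWattsStrogatz:
    def test_ring_lattice_at_p_zero(self):
        edges = watts_strogatz_graph(50, 4, 0.0, seed=0)
        deg = np.zeros(50, dtype=int)
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        assert np.all(deg == 4)

    @pytest.mark.parametrize("p,seed", [(0.1, 0), (0.5, 1), (0.5, 99), (1.0, 7)])
    def test_edge_count_preserved(self, p, seed):
        assert len(watts_strogatz_graph(50, 4, p, seed)) == 100

    def test_deterministic_given_seed(self):
        a = watts_strogatz_graph(50, 4, 0.5, seed=42)
        b = watts_strogatz_graph(50, 4, 0.5, seed=42)
        assert a == b

    def test_protected_edges_survive_rewiring(self):
        edges = watts_strogatz_graph(50, 4, 1.0, seed=3, keep_edges=[(0, 2), (1, 3)])
        assert (0, 2) in edges and (1, 3) in edges

    @pytest.mark.parametrize("N,k", [(10, 3), (10, 10)])
    def test_invalid_degree_rejected(self, N, k):
        with pytest.raises(ValueError):
            watts_strogatz_graph(N, k, 0.5, seed=0)


class TestNetworkRhs:
    def test_agrees_with_dense_kronecker_oracle(self, rng):
        spec = CouplingSpec(
            N=6,
            weight_fns={
                (0, 1): lambda t: abs(np.sin(t)),
                (1, 2): 0.7,
                (3, 4): 1.3,
                (5, 0): 0.2,
            },
        )
        gamma = rng.normal(size=(3, 3))
        system = NetworkSystem(lorenz_dynamics(), spec, gamma)
        X = rng.normal(size=18)
        t = 0.8
        C = coupling_at(spec, t)
        F = lorenz_rhs(X.reshape(6, 3)).ravel()
        dense = F + np.kron(C, gamma) @ X
        assert np.allclose(network_rhs(system, X, t), dense, atol=1e-12)

    def test_uncoupled_network_reduces_to_intrinsic_dynamics(self, rng):
        spec = CouplingSpec(N=4, weight_fns={(0, 1): 0.0})
        system = NetworkSystem(lorenz_dynamics(), spec, np.eye(3))
        X = rng.normal(size=12)
        assert np.allclose(
            network_rhs(system, X, 1.0), lorenz_rhs(X.reshape(4, 3)).ravel()
        )

    def test_pure_consensus_is_coupling_matvec(self, rng):
        spec = CouplingSpec(N=5, weight_fns={(0, 1): 1.0, (2, 3): 2.0}, symmetric=True)
        system = NetworkSystem(consensus_dynamics(), spec, np.eye(1))
        X = rng.normal(size=5)
        assert np.allclose(network_rhs(system, X, 0.0), coupling_at(spec, 0.0) @ X)


class TestRK4:
    def test_zero_field_leaves_state_unchanged(self):
        X = np.array([1.0, -2.0, 3.0])
        out = rk4_step(lambda x, t: np.zeros_like(x), X, 0.0, 0.1)
        assert np.array_equal(out, X)

    def test_matches_exponential_decay(self):
        out = rk4_step(lambda x, t: -x, np.array([1.0]), 0.0, 0.01)
        assert abs(out[0] - np.exp(-0.01)) <= 1e-10

    def test_fourth_order_convergence_on_lorenz(self):
        dyn = lorenz_dynamics()
        rhs = lambda x, t: dyn.rhs(x)
        x0 = np.array([1.0, 1.0, 1.0])

        def integrate(h, T=1.0):
            x, t = x0.copy(), 0.0
            for _ in range(int(round(T / h))):
                x = rk4_step(rhs, x, t, h)
                t += h
            return x

        ref = integrate(1e-4)
        ratio = np.linalg.norm(integrate(2e-3) - ref) / np.linalg.norm(
            integrate(1e-3) - ref
        )
        assert 10.0 < ratio < 22.0  # halving h cuts global error ~2^4

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            rk4_step(lambda x, t: x, np.ones(2), 0.0, 0.0)


class TestSimulateEnsemble:
    def _small_system(self):
        spec = CouplingSpec(N=3, weight_fns={(0, 1): 0.5, (1, 2): 0.5}, symmetric=True)
        return NetworkSystem(lorenz_dynamics(), spec, np.eye(3))

    def test_same_seed_bit_identical(self):
        sys_ = self._small_system()
        kw = dict(K=4, t_end=0.2, h=1e-3, seed=7, snapshot_times=[0.1])
        a = simulate_ensemble(sys_, **kw)
        b = simulate_ensemble(sys_, **kw)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.times, b.times)

    def test_snapshot_pair_times_recorded(self):
        ens = simulate_ensemble(
            self._small_system(), K=2, t_end=0.3, h=1e-3, seed=0,
            snapshot_times=[0.1, 0.2], dt_snap=1e-6,
        )
        for t in (0.1, 0.2):
            ens.index_of(t)
            ens.index_of(t + 1e-6)

    def test_central_records_backward_offset(self):
        ens = simulate_ensemble(
            self._small_system(), K=2, t_end=0.3, h=1e-3, seed=0,
            snapshot_times=[0.2], dt_snap=1e-3, central=True,
        )
        ens.index_of(0.2 - 1e-3)

    def test_divergent_trajectory_flagged_not_fatal(self):
        blowup = NodeDynamics(name="blowup", n=1, rhs=lambda s: s**3)
        spec = CouplingSpec(N=2, weight_fns={(0, 1): 0.0})
        sys_ = NetworkSystem(blowup, spec, np.eye(1))
        with pytest.warns(RuntimeWarning, match="diverged"):
            ens = simulate_ensemble(
                sys_, K=3, t_end=5.0, h=1e-2, init_box=(1.0, 2.0), seed=0,
                snapshot_times=[4.0],
            )
        assert ens.diverged.all()

    def test_npz_round_trip(self, tmp_path):
        ens = simulate_ensemble(
            self._small_system(), K=2, t_end=0.1, h=1e-3, seed=3,
            snapshot_times=[0.05],
        )
        path = tmp_path / "ens.npz"
        ens.save_npz(path)
        back = type(ens).load_npz(path)
        assert np.array_equal(back.states, ens.states)
        assert back.dt_snap == ens.dt_snap


@settings(deadline=None, max_examples=25)
@given(t=st.floats(0.0, 50.0, allow_nan=False))
def test_coupling_row_sums_vanish_for_all_times(t):
    spec = CouplingSpec(
        N=8,
        weight_fns={(0, 1): lambda s: abs(np.sin(s)), (2, 5): 1.0, (6, 7): 0.3},
        symmetric=True,
    )
    C = coupling_at(spec, t)
    assert np.max(np.abs(C.sum(axis=1))) <= 1e-12
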