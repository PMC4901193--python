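"""Coupled dynamical networks with continuously time-varying coupling.

The model is a network of ``N`` identical ``n``-dimensional units

    dx_i/dt = f(x_i) + sum_j c_ij(t) * Gamma @ x_j,

where the off-diagonal coupling strengths ``c_ij(t) >= 0`` vary continuously
with time, the diagonal entries of ``C(t)`` are defined as the negative
off-diagonal row sums (so every row of ``C(t)`` sums to zero, a
Laplacian-like convention), and the inner coupling matrix ``Gamma`` selects
which state components of a neighbour drive which components of a node.

Stacking the node states into ``X = (x_1, ..., x_N)`` the network reads

    dX/dt = F(X) + (C(t) kron Gamma) X,

which is the form consumed by the identification pipeline: a small ensemble
of trajectories started from random initial conditions supplies snapshots
``X(t)``, ``X(t*)`` from which ``C(t)`` is recovered row by row.

This module defines the network containers, the node dynamics used in the
experiments (the chaotic Lorenz oscillator and the trivial consensus agent),
a seeded Watts–Strogatz small-world generator, a classical fourth-order
Runge–Kutta integrator, and the batched ensemble simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "NodeDynamics",
    "CouplingSpec",
    "NetworkSystem",
    "TrajectoryEnsemble",
    "DivergenceError",
    "lorenz_rhs",
    "lorenz_dynamics",
    "consensus_rhs",
    "consensus_dynamics",
    "coupling_at",
    "watts_strogatz_graph",
    "network_rhs",
    "rk4_step",
    "simulate_ensemble",
]

# Weight functions available by name in config files / CSV edge lists.
# Each id maps to a factory taking the edge's parameter dict.
WEIGHT_FN_REGISTRY: dict[str, Callable[..., Callable[[float], float]]] = {
    "const": lambda value=1.0: (lambda t: float(value)),
    "abs_sin": lambda scale=1.0: (lambda t: float(scale) * abs(np.sin(t))),
    "log1p": lambda scale=1.0: (lambda t: float(scale) * np.log1p(t)),
}


class DivergenceError(RuntimeError):
    """Raised when an integration step produces a non-finite state."""


@dataclass(frozen=True)
class NodeDynamics:
    """Intrinsic dynamics of a single node.

    ``rhs`` maps a state array of shape ``(..., n)`` to its time derivative
    of the same shape; it must be deterministic, finite for finite input,
    and broadcast over leading axes (the simulator integrates whole
    ensembles as one batched array).
    """

    name: str
    n: int
    params: Mapping[str, float] = field(default_factory=dict)
    rhs: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("node dimension n must be >= 1")
        if self.rhs is None:
            raise ValueError("rhs callable is required")


def lorenz_rhs(state: np.ndarray, params: Mapping[str, float] | None = None) -> np.ndarray:
    """Lorenz vector field (a(y−x), cx − y − xz, xy − bz).

    Defaults a=10, b=8/3, c=28 place the system in the familiar chaotic
    regime. ``state`` has shape ``(..., 3)``; the field is evaluated
    componentwise over leading axes.
    """
    p = {"a": 10.0, "b": 8.0 / 3.0, "c": 28.0}
    if params:
        p.update(params)
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != 3:
        raise ValueError("Lorenz state must have last dimension 3")
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite Lorenz state")
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    return np.stack(
        [p["a"] * (y - x), p["c"] * x - y - x * z, x * y - p["b"] * z], axis=-1
    )


def lorenz_dynamics(a: float = 10.0, b: float = 8.0 / 3.0, c: float = 28.0) -> NodeDynamics:
    """Lorenz oscillator node with the classical chaotic parameters."""
    params = {"a": a, "b": b, "c": c}
    return NodeDynamics(name="lorenz", n=3, params=params,
                        rhs=lambda s: lorenz_rhs(s, params))


def consensus_rhs(state: np.ndarray) -> np.ndarray:
    """Intrinsic dynamics of a consensus agent: identically zero.

    All motion of a multi-agent consensus network comes from the coupling
    term; with a symmetric row-sum-zero ``C`` the state average is conserved.
    """
    return np.zeros_like(np.asarray(state, dtype=float))


def consensus_dynamics() -> NodeDynamics:
    """One-dimensional agent with f == 0 (pure consensus dynamics)."""
    return NodeDynamics(name="consensus", n=1, params={}, rhs=consensus_rhs)


WeightFn = Callable[[float], float]


@dataclass
class CouplingSpec:
    """Potential edges and their (possibly time-varying) weights.

    ``weight_fns`` maps an ordered pair ``(i, j)`` (0-based, link j -> i) to
    either a nonnegative constant or a scalar function of time. When
    ``symmetric`` is true every key is mirrored, so a single entry defines
    both directions. Diagonal entries are never user-specified: they are
    always derived as negative row sums by :func:`coupling_at`.
    """

    N: int
    weight_fns: dict[tuple[int, int], WeightFn | float]
    symmetric: bool = False

    # split weights once: constant entries become a cached base matrix,
    # time-varying ones are re-evaluated per call
    _base: np.ndarray = field(init=False, repr=False, default=None)  # type: ignore[assignment]
    _varying: list[tuple[int, int, WeightFn]] = field(init=False, repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("a coupled network needs N >= 2 nodes")
        entries: dict[tuple[int, int], WeightFn | float] = {}
        for (i, j), w in self.weight_fns.items():
            if i == j:
                raise ValueError(f"self-coupling ({i},{i}) is not allowed; "
                                 "diagonal entries are derived")
            if not (0 <= i < self.N and 0 <= j < self.N):
                raise ValueError(f"edge ({i},{j}) out of range for N={self.N}")
            entries[(i, j)] = w
            if self.symmetric:
                entries[(j, i)] = w
        base = np.zeros((self.N, self.N))
        varying: list[tuple[int, int, WeightFn]] = []
        for (i, j), w in entries.items():
            if callable(w):
                varying.append((i, j, w))
            else:
                w = float(w)
                if w < 0:
                    raise ValueError(f"negative coupling weight at ({i},{j})")
                base[i, j] = w
        object.__setattr__(self, "_base", base)
        object.__setattr__(self, "_varying", varying)

    @property
    def support(self) -> set[tuple[int, int]]:
        """Ordered pairs (i, j) that may carry a nonzero weight."""
        pairs = set(self.weight_fns)
        if self.symmetric:
            pairs |= {(j, i) for (i, j) in pairs}
        return pairs

    def support_mask(self) -> np.ndarray:
        """Boolean N x N off-diagonal mask of the potential edges."""
        mask = np.zeros((self.N, self.N), dtype=bool)
        for i, j in self.support:
            mask[i, j] = True
        return mask


def coupling_at(spec: CouplingSpec, t: float) -> np.ndarray:
    """Evaluate the N x N coupling matrix C(t).

    Off-diagonal entry (i, j) is the weight of the link j -> i at time
    ``t`` (zero off the support); each diagonal entry is the negative sum of
    the off-diagonal entries in its row, so every row sums to exactly zero.
    """
    if t < 0:
        raise ValueError("coupling is defined for t >= 0")
    C = spec._base.copy()
    for i, j, fn in spec._varying:
        w = float(fn(t))
        if w < 0:
            raise ValueError(
                f"coupling function for edge ({i},{j}) returned {w} < 0 at t={t}"
            )
        C[i, j] = w
    np.fill_diagonal(C, 0.0)
    C[np.arange(spec.N), np.arange(spec.N)] = -C.sum(axis=1)
    return C


@dataclass(frozen=True)
class NetworkSystem:
    """A network: node dynamics + coupling spec + inner coupling matrix."""

    dynamics: NodeDynamics
    coupling: CouplingSpec
    gamma: np.ndarray

    def __post_init__(self) -> None:
        gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if gamma.shape != (self.dynamics.n, self.dynamics.n):
            raise ValueError(
                f"gamma must be {self.dynamics.n} x {self.dynamics.n}, got {gamma.shape}"
            )
        object.__setattr__(self, "gamma", gamma)

    @property
    def N(self) -> int:
        return self.coupling.N

    @property
    def n(self) -> int:
        return self.dynamics.n

    @property
    def state_dim(self) -> int:
        return self.N * self.n


def watts_strogatz_graph(
    N: int,
    k: int,
    p: float,
    seed: int,
    keep_edges: Iterable[tuple[int, int]] = (),
) -> set[tuple[int, int]]:
    """Seeded Watts–Strogatz small-world edge set (undirected pairs i < j).

    Starts from a ring of ``N`` nodes each linked to its ``k`` nearest
    neighbours, then visits the lattice edges in canonical order (offset 1..
    k/2, node 0..N-1) and, with probability ``p``, keeps the near end of the
    edge and reconnects the far end to a uniformly random node, rejecting
    self-loops and duplicates. Exactly ``N*k/2`` edges are always retained.

    ``keep_edges`` lists undirected pairs that are exempt from rewiring —
    used when designated edges must survive the random draw.
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    if k >= N:
        raise ValueError("k must be < N")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    protected = {tuple(sorted(e)) for e in keep_edges}
    edges: set[tuple[int, int]] = set()
    for off in range(1, k // 2 + 1):
        for u in range(N):
            edges.add(tuple(sorted((u, (u + off) % N))))
    for off in range(1, k // 2 + 1):
        for u in range(N):
            e = tuple(sorted((u, (u + off) % N)))
            if e in protected or e not in edges:
                continue
            if rng.random() < p:
                # keep u, reconnect the far end uniformly at random
                for _ in range(8 * N):
                    w = int(rng.integers(N))
                    cand = tuple(sorted((u, w)))
                    if w != u and cand not in edges:
                        edges.remove(e)
                        edges.add(cand)
                        break
                # a saturated node keeps its lattice edge
    return edges


def network_rhs(system: NetworkSystem, X: np.ndarray, t: float) -> np.ndarray:
    """Full network vector field F(X) + (C(t) kron Gamma) X.

    ``X`` has shape ``(..., N*n)``; leading axes batch independent
    trajectories. The Kronecker product is never materialised: the coupling
    term is evaluated blockwise as ``Gamma (sum_j c_ij x_j)``.
    """
    X = np.asarray(X, dtype=float)
    N, n = system.N, system.n
    if X.shape[-1] != N * n:
        raise ValueError(f"state length {X.shape[-1]} != N*n = {N * n}")
    blocks = X.reshape(X.shape[:-1] + (N, n))
    F = system.dynamics.rhs(blocks)
    C = coupling_at(system.coupling, t)
    # row i of the coupling term: Gamma @ (sum_j C[i,j] x_j)
    coupled = np.einsum("ij,...jk,lk->...il", C, blocks, system.gamma)
    return (F + coupled).reshape(X.shape)


def rk4_step(
    rhs: Callable[[np.ndarray, float], np.ndarray],
    X: np.ndarray,
    t: float,
    h: float,
) -> np.ndarray:
    """One classical fourth-order Runge–Kutta step from t to t+h."""
    if h <= 0:
        raise ValueError("step size h must be > 0")
    return _rk4_signed(rhs, X, t, h, check=True)


def _rk4_signed(rhs, X, t, h, check=False):
    # internal variant also used for the tiny backward step that central
    # difference snapshots need (h < 0 integrates the flow in reverse)
    X = np.asarray(X, dtype=float)
    k1 = rhs(X, t)
    k2 = rhs(X + 0.5 * h * k1, t + 0.5 * h)
    k3 = rhs(X + 0.5 * h * k2, t + 0.5 * h)
    k4 = rhs(X + h * k3, t + h)
    out = X + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if check and not np.all(np.isfinite(out)):
        raise DivergenceError(f"non-finite state after RK4 step at t={t}")
    return out


@dataclass
class TrajectoryEnsemble:
    """States of K trajectories recorded on a shared time grid.

    ``states`` has shape ``(K, T, N*n)``; ``diverged`` flags trajectories
    that left the finite range during integration (their states are NaN from
    the divergence time on and they are skipped by snapshot extraction).
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    h: float
    dt_snap: float
    diverged: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 3 or self.states.shape[1] != self.times.size:
            raise ValueError("states must have shape (K, len(times), N*n)")
        if self.diverged is None:
            self.diverged = np.zeros(self.states.shape[0], dtype=bool)

    @property
    def K(self) -> int:
        return int(self.states.shape[0])

    def index_of(self, t: float, atol: float = 1e-12) -> int:
        """Index of time ``t`` on the recording grid (error if absent)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > atol * max(1.0, abs(t)):
            raise KeyError(
                f"t={t} is not on the recording grid; nearest recorded time "
                f"is {self.times[idx]}"
            )
        return idx

    def to_frame(self, N: int, n: int):
        """Long-format table (trajectory, time, node, component, value)."""
        import pandas as pd

        K, T, d = self.states.shape
        if d != N * n:
            raise ValueError("N*n does not match state dimension")
        traj, ti, node, comp = np.meshgrid(
            np.arange(K), np.arange(T), np.arange(N), np.arange(n), indexing="ij"
        )
        return pd.DataFrame(
            {
                "trajectory": traj.ravel(),
                "time": self.times[ti.ravel()],
                "node": node.ravel(),
                "component": comp.ravel(),
                "value": self.states.reshape(K, T, N, n).ravel(),
            }
        )

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            times=self.times,
            states=self.states,
            seed=self.seed,
            h=self.h,
            dt_snap=self.dt_snap,
            diverged=self.diverged,
        )

    @classmethod
    def load_npz(cls, path) -> "TrajectoryEnsemble":
        with np.load(path) as d:
            return cls(
                times=d["times"],
                states=d["states"],
                seed=int(d["seed"]),
                h=float(d["h"]),
                dt_snap=float(d["dt_snap"]),
                diverged=d["diverged"],
            )


def simulate_ensemble(
    system: NetworkSystem,
    K: int,
    t_end: float,
    h: float = 1e-3,
    init_box: tuple[float, float] = (-5.0, 5.0),
    seed: int = 0,
    snapshot_times: Iterable[float] | None = None,
    dt_snap: float = 1e-6,
    central: bool = False,
) -> TrajectoryEnsemble:
    """Integrate K trajectories from i.i.d. uniform initial conditions.

    Initial states are drawn uniformly per component from ``init_box`` using
    ``seed``; all trajectories are advanced together with classical RK4 at
    step ``h`` (the last step before a recording time is shortened so grid
    times are hit exactly). Around every requested snapshot time ``t`` the
    state is additionally recorded at ``t + dt_snap`` (and ``t - dt_snap``
    when ``central``) via a single fine RK4 step, which is all the
    difference-quotient observation model consumes.

    The ensemble is a pure function of its arguments: the same inputs give
    bit-identical output.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if h <= 0 or t_end <= 0:
        raise ValueError("h and t_end must be > 0")
    if dt_snap <= 0:
        raise ValueError("dt_snap must be > 0")
    if snapshot_times is None:
        snapshot_times = [t_end]
    snaps = sorted(set(float(t) for t in snapshot_times))
    if snaps and (snaps[0] < 0 or snaps[-1] > t_end):
        raise ValueError("snapshot times must lie in [0, t_end]")

    record: set[float] = {0.0, float(t_end)}
    for t in snaps:
        record.add(t)
        record.add(t + dt_snap)
        if central:
            record.add(t - dt_snap)
    times = np.array(sorted(record))
    if times[0] < 0:
        raise ValueError("central snapshot at t=0 needs t >= dt_snap")

    rng = np.random.default_rng(seed)
    lo, hi = init_box
    d = system.state_dim
    X = rng.uniform(lo, hi, size=(K, d))

    rhs = lambda state, t: network_rhs(system, state, t)
    out = np.empty((K, times.size, d))
    alive = np.ones(K, dtype=bool)
    t_cur = 0.0
    out[:, 0, :] = X
    for idx in range(1, times.size):
        t_next = times[idx]
        span = t_next - t_cur
        nsteps = max(1, int(np.ceil(span / h - 1e-12)))
        step = span / nsteps
        for s in range(nsteps):
            with np.errstate(over="ignore", invalid="ignore"):
                X = _rk4_signed(rhs, X, t_cur + s * step, step)
            # kill runaway trajectories before they overflow inside an RK4
            # stage (node rhs contracts reject non-finite states)
            bad = ~np.all(np.isfinite(X), axis=1) | (
                np.max(np.abs(X), axis=1) > 1e6
            )
            if np.any(bad & alive):
                alive &= ~bad
            # park dead trajectories at the origin so the batched rhs stays
            # finite; their records are NaN below
            X[~alive] = 0.0
        t_cur = t_next
        out[:, idx, :] = X
        out[~alive, idx, :] = np.nan
    if not np.all(alive):
        warnings.warn(
            f"{int((~alive).sum())} of {K} trajectories diverged and are "
            "flagged; they are excluded from snapshot extraction",
            RuntimeWarning,
        )
    return TrajectoryEnsemble(
        times=times, states=out, seed=seed, h=h, dt_snap=dt_snap, diverged=~alive
    )
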