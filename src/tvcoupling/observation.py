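"""From trajectory snapshots to per-row linear identification systems.

At an identification time ``t`` the network satisfies

    Y(t) = dX/dt - F(X(t)) = (C(t) kron Gamma) X(t) = M_t X(t),

and the derivative is approximated by a first-order difference quotient
``(X(t*) - X(t)) / (t* - t)`` with ``t*`` close to ``t``. Each of the K
observed trajectories contributes one linear equation per unknown row of
``M_t``; stacking the K state vectors as rows, appending an all-ones row
(whose zero target encodes the row-sum-zero convention of ``C(t)``), and
normalising columns to unit Euclidean norm (the conditioning step behind
restricted-isometry-style recovery guarantees) yields the underdetermined
system ``A_t m_i = y_i`` that the sparse solvers consume.

Two quotient schemes are supported: forward (``t* = t + dt``, the default,
truncation error O(dt)) and central (``(X(t+dt) - X(t-dt)) / 2dt``, O(dt^2),
preferred for noisy data where larger dt trades truncation against noise
amplification).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .network_model import NodeDynamics, TrajectoryEnsemble

__all__ = [
    "SnapshotSet",
    "LinearSystem",
    "NoiseModel",
    "sample_snapshots",
    "add_uniform_noise",
    "compute_targets",
    "assemble_system",
    "normalize_columns",
]


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. uniform observation noise on every recorded state component."""

    low: float
    high: float
    seed: int
    kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("noise interval must satisfy low <= high")


@dataclass(frozen=True)
class SnapshotSet:
    """K observed snapshot pairs around one identification time.

    ``x_t`` holds the K state vectors at the evaluation time ``t`` (rows of
    the design matrix; also where F is evaluated), ``x_star`` the states at
    ``t* = t + dt``. For the central scheme ``x_pre`` additionally holds the
    states at ``t - dt`` and the quotient denominator is ``2 dt``.
    """

    t: float
    dt: float
    x_t: np.ndarray
    x_star: np.ndarray
    x_pre: Optional[np.ndarray] = None
    noise_level: float = 0.0
    noise_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        x_t = np.atleast_2d(np.asarray(self.x_t, dtype=float))
        x_star = np.atleast_2d(np.asarray(self.x_star, dtype=float))
        object.__setattr__(self, "x_t", x_t)
        object.__setattr__(self, "x_star", x_star)
        if x_t.shape != x_star.shape or x_t.shape[0] < 1:
            raise ValueError("x_t and x_star must be equal-shaped, K >= 1")
        if self.x_pre is not None:
            x_pre = np.atleast_2d(np.asarray(self.x_pre, dtype=float))
            if x_pre.shape != x_t.shape:
                raise ValueError("x_pre must match x_t in shape")
            object.__setattr__(self, "x_pre", x_pre)

    @property
    def K(self) -> int:
        return int(self.x_t.shape[0])

    @property
    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """The K (X_k(t), X_k(t*)) pairs."""
        return list(zip(self.x_t, self.x_star))

    @property
    def scheme(self) -> str:
        return "central" if self.x_pre is not None else "forward"

    def quotient(self) -> np.ndarray:
        """Difference-quotient derivative estimates, shape (K, nN)."""
        if self.x_pre is not None:
            return (self.x_star - self.x_pre) / (2.0 * self.dt)
        return (self.x_star - self.x_t) / self.dt

    def to_frame(self):
        """Long-format table (observation, which, component, value)."""
        import pandas as pd

        frames = []
        slots = {"t": self.x_t, "tstar": self.x_star}
        if self.x_pre is not None:
            slots["tpre"] = self.x_pre
        for which, arr in slots.items():
            K, d = arr.shape
            k, c = np.meshgrid(np.arange(K), np.arange(d), indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "observation": k.ravel(),
                        "which": which,
                        "component": c.ravel(),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        """Delimited export: a `# key=value` header plus the long table."""
        seed = "" if self.noise_seed is None else int(self.noise_seed)
        header = (
            f"# t={self.t} dt={self.dt} noise_level={self.noise_level} "
            f"noise_seed={seed}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SnapshotSet":
        import pandas as pd

        with open(path) as fh:
            fields = fh.readline().lstrip("# ").split()
            meta = dict(item.split("=", 1) for item in fields)
            df = pd.read_csv(fh)
        slots = {}
        for which, grp in df.groupby("which"):
            grp = grp.sort_values(["observation", "component"])
            K = grp["observation"].nunique()
            slots[which] = grp["value"].to_numpy().reshape(K, -1)
        seed = meta.get("noise_seed", "")
        return cls(
            t=float(meta["t"]),
            dt=float(meta["dt"]),
            x_t=slots["t"],
            x_star=slots["tstar"],
            x_pre=slots.get("tpre"),
            noise_level=float(meta["noise_level"]),
            noise_seed=int(seed) if seed else None,
        )


def sample_snapshots(
    ensemble: TrajectoryEnsemble,
    t: float,
    central: bool = False,
) -> SnapshotSet:
    """Extract the noiseless snapshot pairs at identification time ``t``.

    Uses the ensemble's recorded fine-offset states at ``t + dt_snap`` (and
    ``t - dt_snap`` for the central scheme). Diverged trajectories are
    skipped. Raises ``KeyError`` naming the nearest recorded time when ``t``
    is not on the grid.
    """
    i0 = ensemble.index_of(t)
    i1 = ensemble.index_of(t + ensemble.dt_snap)
    keep = ~ensemble.diverged
    if not np.any(keep):
        raise ValueError("all trajectories diverged; no observations left")
    x_t = ensemble.states[keep, i0, :].copy()
    x_star = ensemble.states[keep, i1, :].copy()
    x_pre = None
    if central:
        ipre = ensemble.index_of(t - ensemble.dt_snap)
        x_pre = ensemble.states[keep, ipre, :].copy()
    return SnapshotSet(t=t, dt=ensemble.dt_snap, x_t=x_t, x_star=x_star, x_pre=x_pre)


def add_uniform_noise(
    snapshots: SnapshotSet, low: float, high: float, seed: int
) -> SnapshotSet:
    """Corrupt every stored state component with i.i.d. U[low, high] noise.

    Both members of each pair (all three for central snapshots) are
    perturbed independently — the observer never sees clean states. The
    input set is not modified.
    """
    if high < low:
        raise ValueError("noise interval must satisfy low <= high")
    rng = np.random.default_rng(seed)
    x_t = snapshots.x_t + rng.uniform(low, high, size=snapshots.x_t.shape)
    x_star = snapshots.x_star + rng.uniform(low, high, size=snapshots.x_star.shape)
    x_pre = None
    if snapshots.x_pre is not None:
        x_pre = snapshots.x_pre + rng.uniform(low, high, size=snapshots.x_pre.shape)
    return replace(
        snapshots,
        x_t=x_t,
        x_star=x_star,
        x_pre=x_pre,
        noise_level=float(high),
        noise_seed=seed,
    )


def compute_targets(snapshots: SnapshotSet, dynamics: NodeDynamics) -> np.ndarray:
    """Per-row targets Y_k = quotient_k - F(X_k(t)), returned as (nN, K).

    Row ``r`` of the result holds, for each observation, the value that row
    ``r`` of ``M_t`` must reproduce; it is later padded with a trailing zero
    for the ones-row constraint.
    """
    n = dynamics.n
    K, d = snapshots.x_t.shape
    if d % n != 0:
        raise ValueError(f"state length {d} is not a multiple of n={n}")
    blocks = snapshots.x_t.reshape(K, d // n, n)
    F = dynamics.rhs(blocks).reshape(K, d)
    Y = snapshots.quotient() - F
    return Y.T.copy()


@dataclass(frozen=True)
class LinearSystem:
    """The assembled per-time identification system.

    ``A_raw`` is the (K+1) x nN design matrix: K observed state vectors as
    rows plus a final all-ones row. ``targets`` is nN x (K+1); row r is the
    target vector of unknown row r of ``M_t``, padded with a trailing zero
    that forces row r to annihilate the ones vector (the linear image of the
    row-sum-zero convention). ``A_norm`` has unit-Euclidean-norm columns;
    ``col_norms`` maps solutions of the normalised system back via
    ``x = x_norm / col_norms``.
    """

    A_raw: np.ndarray
    A_norm: np.ndarray
    col_norms: np.ndarray
    targets: np.ndarray
    t: float = 0.0
    dt: float = 0.0
    noise_level: float = 0.0
    n: int = 1  # node state dimension (for structure-aware reduced solves)

    @property
    def m(self) -> int:
        return int(self.A_raw.shape[0])

    @property
    def q(self) -> int:
        return int(self.A_raw.shape[1])


def normalize_columns(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each column of ``A`` to unit Euclidean norm.

    Returns the normalised matrix and the vector of original column norms
    ``d`` such that ``A = A_norm * d`` columnwise; a solution ``x_norm`` of
    the normalised system corresponds to ``x = x_norm / d``. A zero column
    is an uninformative unknown and raises, naming the column.
    """
    A = np.asarray(A, dtype=float)
    norms = np.linalg.norm(A, axis=0)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(
            f"column {int(zero[0])} of the design matrix is identically zero "
            "(uninformative unknown); cannot normalize"
        )
    return A / norms, norms


def assemble_system(snapshots: SnapshotSet, dynamics: NodeDynamics) -> LinearSystem:
    """Build the full normalised linear system for one identification time."""
    K, d = snapshots.x_t.shape
    A_raw = np.vstack([snapshots.x_t, np.ones((1, d))])
    Y = compute_targets(snapshots, dynamics)  # (nN, K)
    targets = np.hstack([Y, np.zeros((d, 1))])
    A_norm, col_norms = normalize_columns(A_raw)
    return LinearSystem(
        A_raw=A_raw,
        A_norm=A_norm,
        col_norms=col_norms,
        targets=targets,
        t=snapshots.t,
        dt=snapshots.dt,
        noise_level=snapshots.noise_level,
        n=dynamics.n,
    )
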