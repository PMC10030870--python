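"""Baseline force-directed layout: gradient descent directly on coordinates.

The dynamics are x_i <- x_i - eps * (LX + dV_NN/dx)_i, i.e. explicit Euler on
the gradient flow of the layout loss.  Plain gradient descent is the baseline
whose per-mode convergence the spectral analysis describes; an
adaptive-moment (Adam) optimizer is available behind a flag, and any
comparison between direct optimization and a neural reparametrization should
use the same optimizer family for both.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyParams, total_gradient, total_loss
from .graph import Graph, Layout

__all__ = ["Trajectory", "StopRule", "init_layout", "run_fdl", "converged", "AdamState"]


@dataclass
class Trajectory:
    """Recorded optimization history at a fixed step cadence."""

    steps: list = field(default_factory=list)
    energies: list = field(default_factory=list)
    wall_times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)  # optional sparse Layouts
    mode_overlaps: list = field(default_factory=list)  # optional |psi_i^T X| rows

    def record(self, step, energy, wall_time, snapshot=None, overlaps=None):
        self.steps.append(int(step))
        self.energies.append(float(energy))
        self.wall_times.append(float(wall_time))
        if snapshot is not None:
            self.snapshots.append((int(step), snapshot))
        if overlaps is not None:
            self.mode_overlaps.append(np.asarray(overlaps, dtype=float))

    @property
    def final_energy(self) -> float:
        return self.energies[-1]

    @property
    def final_step(self) -> int:
        return self.steps[-1]


@dataclass(frozen=True)
class StopRule:
    """Stop when the relative energy change over ``window`` steps falls below
    ``rel_tol``, or at ``max_steps``."""

    rel_tol: float = 1e-5
    window: int = 50
    max_steps: int = 100_000

    def __post_init__(self):
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def converged(trajectory: Trajectory, stop: StopRule) -> bool:
    """True iff |E(t) - E(t - window)| / max(|E(t)|, tiny) < rel_tol for the
    last recorded step, using the earliest recorded step at least ``window``
    steps back."""
    if len(trajectory.steps) < 2:
        return False
    t = trajectory.steps[-1]
    e_t = trajectory.energies[-1]
    prev = None
    for s, e in zip(reversed(trajectory.steps[:-1]), reversed(trajectory.energies[:-1])):
        if t - s >= stop.window:
            prev = e
            break
    if prev is None:
        return False
    return abs(e_t - prev) / max(abs(e_t), 1e-30) < stop.rel_tol


def init_layout(n: int, dim: int = 3, scale: float = 1.0, seed: int | None = None) -> Layout:
    """Random initial configuration: i.i.d. Gaussian coordinates, sd = scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return Layout(rng.normal(0.0, 1.0, size=(n, dim)) * scale)


class AdamState:
    """Minimal Adam optimizer over a flat list of arrays (shared with the
    neural models so baseline and reparametrized runs use the same family)."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _quiet_overflow(fn):
    """Silence numpy overflow warnings inside optimizer loops: a runaway step
    is detected and handled as divergence, not worth a warning per entry."""
    import functools

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        with np.errstate(over="ignore", invalid="ignore"):
            return fn(*args, **kwargs)

    return wrapper


@_quiet_overflow
def run_fdl(
    graph: Graph,
    init: Layout,
    params: EnergyParams | None = None,
    stop: StopRule | None = None,
    record_every: int = 10,
    method: str = "cell_list",
    optimizer: str = "gd",
    track_modes: np.ndarray | None = None,
    snapshot_every: int | None = None,
) -> tuple[Layout, Trajectory]:
    """Lay out ``graph`` by gradient descent on the coordinates.

    Parameters
    ----------
    track_modes:
        Optional N x k matrix of eigenvectors; the per-step overlap magnitudes
        ||psi_i^T X|| are recorded alongside the energies.
    optimizer:
        ``gd`` (plain descent, the analytical baseline) or ``adam``.

    Returns the final layout and the recorded trajectory.  If the first step
    increases the energy the learning rate is halved (with a warning) and the
    run restarts; a non-finite energy aborts with advice to lower epsilon.
    """
    params = (params or EnergyParams()).resolve(graph.n_nodes)
    stop = stop or StopRule()
    eps = params.epsilon
    e0 = total_loss(graph, Layout(init.coords), params, method)

    for _attempt in range(12):
        x = init.coords.copy()
        opt = AdamState([x.shape], eps) if optimizer == "adam" else None
        if optimizer not in ("gd", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        traj = Trajectory()
        t0 = time.perf_counter()

        def _record(step, energy):
            traj.record(
                step,
                energy,
                time.perf_counter() - t0,
                snapshot=Layout(x.copy())
                if snapshot_every and step % snapshot_every == 0
                else None,
                overlaps=np.linalg.norm(track_modes.T @ x, axis=1)
                if track_modes is not None
                else None,
            )

        _record(0, e0)
        diverged = False
        for step in range(1, stop.max_steps + 1):
            if not np.all(np.isfinite(x)):
                if step > record_every:
                    diverged = True
                break  # first-interval blowup: retry with smaller eps
            g = total_gradient(graph, Layout(x), params, method)
            if opt is None:
                x -= eps * g
            else:
                opt.step([x], [g])
            if step % record_every == 0 or step == stop.max_steps:
                bad = not np.all(np.isfinite(x))
                e = np.inf if bad else total_loss(graph, Layout(x), params, method)
                if step <= record_every and (not np.isfinite(e) or (e > e0 and e0 > 0)):
                    break  # first record rose or blew up: retry with smaller eps
                if not np.isfinite(e):
                    diverged = True
                    break
                _record(step, e)
                if converged(traj, stop):
                    break
        else:
            pass
        if diverged:
            raise RuntimeError(
                "energy diverged (non-finite); use a smaller learning rate epsilon"
            )
        if len(traj.steps) > 1 or stop.max_steps < record_every:
            return Layout(x), traj
        # energy increased on the first recorded step: halve and retry
        warnings.warn(
            f"energy increased on the first step; halving epsilon to {eps / 2:.3g}",
            stacklevel=2,
        )
        eps = eps / 2.0
    raise RuntimeError("energy still increases after repeated halving of epsilon")
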