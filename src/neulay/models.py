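"""Neural reparametrization of node positions and per-graph training.

Instead of optimizing the coordinate matrix X directly, X is expressed as
the output of a small network with trainable parameters theta and the same
layout loss is minimized over theta by the chain rule:

    d theta_a / dt = -eps * sum_i (d x_i / d theta_a) (d L / d x_i).

Two architectures:

* NodeMLP — X = sigma(Z W + b) from a trainable N x h embedding Z.  No graph
  information enters the forward pass.
* NeuLay / NeuLay-2 — graph-convolutional layers G1 = sigma(F Z W1) and
  G2 = sigma(F G1 W2) with F = f(A) the normalized adjacency; the layer
  outputs are concatenated with Z, G = [Z | G1 | G2], and projected to
  coordinates X = sigma_out(G W + b).  One-layer NeuLay is the special case
  with zero-width second layer.  Propagating through F amplifies the
  gradient of every outlier eigenmode by its eigenvalue, which is what
  accelerates the slow modes of the force-directed dynamics.

Training is per-graph: parameters are re-initialized and re-trained for each
layout.  Gradients are exact reverse-mode (hand-derived; the loss gradient
with respect to X comes from the analytic energy gradients), and they are
validated against central finite differences in the test suite.

The output nonlinearity defaults to the identity: a saturating output would
confine coordinates to a bounded box, which conflicts with layouts whose
natural extent grows with N.  ``sigma_out="tanh"`` restores a saturating
projection for users who want it.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyParams, total_gradient, total_loss
from .fdl import AdamState, StopRule, Trajectory, _quiet_overflow, converged
from .graph import Graph, Layout
from .spectral import OperatorView, operator_view

__all__ = [
    "NodeMLPParams",
    "NeuLay2Params",
    "nodemlp_forward",
    "neulay2_forward",
    "init_params",
    "train_model",
    "save_params",
    "load_params",
]

CHECKPOINT_VERSION = 1

_SIGMAS = {
    "tanh": (np.tanh, lambda p: 1.0 - np.tanh(p) ** 2),
    "identity": (lambda p: p, lambda p: np.ones_like(p)),
}


def _sigma(tag: str):
    try:
        return _SIGMAS[tag]
    except KeyError:
        raise ValueError(f"unknown nonlinearity {tag!r}") from None


@dataclass
class NodeMLPParams:
    """theta = {Z, W, b} for X = sigma(Z W + b)."""

    Z: np.ndarray  # N x h
    W: np.ndarray  # h x d
    b: np.ndarray  # d
    sigma: str = "identity"

    def __post_init__(self):
        if self.Z.shape[1] != self.W.shape[0] or self.W.shape[1] != self.b.shape[0]:
            raise ValueError("inconsistent parameter shapes")
        if self.Z.shape[1] < self.W.shape[1]:
            raise ValueError("embedding width h must be >= output dimension d")

    def tensors(self):
        return [self.Z, self.W, self.b]


@dataclass
class NeuLay2Params:
    """theta = {Z, W1, W2, W, b} for the (up to) two-layer GCN architecture.

    Zero-width W1/W2 (shape (*, 0)) drop the corresponding layer, so the
    one-layer NeuLay and an embedding-only model are special cases of the
    same parameter set.
    """

    Z: np.ndarray  # N x h
    W1: np.ndarray  # h x h1
    W2: np.ndarray  # h1 x h2
    W: np.ndarray  # (h + h1 + h2) x d
    b: np.ndarray  # d
    sigma_hidden: str = "tanh"
    sigma_out: str = "identity"

    def __post_init__(self):
        h, h1, h2 = self.Z.shape[1], self.W1.shape[1], self.W2.shape[1]
        if self.W1.shape[0] != h or self.W2.shape[0] != h1:
            raise ValueError("inconsistent GCN weight shapes")
        if self.W.shape[0] != h + h1 + h2 or self.W.shape[1] != self.b.shape[0]:
            raise ValueError("projection width must equal h + h1 + h2")

    @property
    def widths(self):
        return (self.Z.shape[1], self.W1.shape[1], self.W2.shape[1])

    def tensors(self):
        return [self.Z, self.W1, self.W2, self.W, self.b]


def nodemlp_forward(params: NodeMLPParams, return_cache: bool = False):
    """X = sigma(Z W + b), row-wise."""
    act, _ = _sigma(params.sigma)
    pre = params.Z @ params.W + params.b
    x = act(pre)
    return (x, {"pre": pre}) if return_cache else x


def _nodemlp_backward(params: NodeMLPParams, cache, dx):
    _, dact = _sigma(params.sigma)
    dpre = dx * dact(cache["pre"])
    return [dpre @ params.W.T, params.Z.T @ dpre, dpre.sum(axis=0)]


def neulay2_forward(
    op: OperatorView, params: NeuLay2Params, return_cache: bool = False
):
    """G1 = sigma(F Z W1); G2 = sigma(F G1 W2); X = sigma_out([Z|G1|G2] W + b)."""
    act, _ = _sigma(params.sigma_hidden)
    act_out, _ = _sigma(params.sigma_out)
    fz = op.apply(params.Z)
    p1 = fz @ params.W1
    g1 = act(p1)
    fg1 = op.apply(g1)
    p2 = fg1 @ params.W2
    g2 = act(p2)
    g = np.concatenate([params.Z, g1, g2], axis=1)
    pre = g @ params.W + params.b
    x = act_out(pre)
    if not return_cache:
        return x
    return x, {"fz": fz, "p1": p1, "g1": g1, "fg1": fg1, "p2": p2, "g": g, "pre": pre}


def _neulay2_backward(op: OperatorView, params: NeuLay2Params, cache, dx):
    """Exact reverse-mode gradients of the loss w.r.t. [Z, W1, W2, W, b],
    given dL/dX.  F is symmetric, so its adjoint is itself."""
    _, dact = _sigma(params.sigma_hidden)
    _, dact_out = _sigma(params.sigma_out)
    h, h1, _h2 = params.widths

    dpre = dx * dact_out(cache["pre"])
    dw = cache["g"].T @ dpre
    db = dpre.sum(axis=0)
    dg = dpre @ params.W.T
    dz = dg[:, :h].copy()
    dg1 = dg[:, h : h + h1].copy()
    dg2 = dg[:, h + h1 :]

    dp2 = dg2 * dact(cache["p2"])
    dw2 = cache["fg1"].T @ dp2
    dg1 += op.apply(dp2) @ params.W2.T

    dp1 = dg1 * dact(cache["p1"])
    dw1 = cache["fz"].T @ dp1
    dz += op.apply(dp1) @ params.W1.T
    return [dz, dw1, dw2, dw, db]


def init_params(
    n: int,
    dims: tuple[int, int, int, int],
    seed: int | None = None,
    scale: float = 1.0,
    model: str = "neulay2",
    sigma_out: str = "identity",
):
    """Random initialization: Z ~ N(0, scale^2), weights ~ N(0, 1/fan_in), b=0.

    ``dims`` is (h, h1, h2, d); h1/h2 are ignored for ``nodemlp`` and h2 is
    forced to zero for one-layer ``neulay``.
    """
    h, h1, h2, d = dims
    if h < 1 or d < 1:
        raise ValueError("embedding and output dims must be positive")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, scale, size=(n, h))
    if model == "nodemlp":
        w = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, d))
        return NodeMLPParams(z, w, np.zeros(d), sigma=sigma_out)
    if model == "neulay":
        h2 = 0
    elif model != "neulay2":
        raise ValueError(f"unknown model {model!r}")
    w1 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, h1))
    w2 = rng.normal(0.0, 1.0 / np.sqrt(max(h1, 1)), size=(h1, h2))
    w = rng.normal(0.0, 1.0 / np.sqrt(h + h1 + h2), size=(h + h1 + h2, d))
    return NeuLay2Params(z, w1, w2, w, np.zeros(d), sigma_out=sigma_out)


def save_params(params, path) -> None:
    """Serialize trained parameters to a version-tagged JSON checkpoint."""
    import json
    from pathlib import Path

    if isinstance(params, NodeMLPParams):
        payload = {
            "model": "nodemlp",
            "sigma": params.sigma,
            "tensors": {"Z": params.Z.tolist(), "W": params.W.tolist(), "b": params.b.tolist()},
        }
    else:
        payload = {
            "model": "neulay2",
            "sigma_hidden": params.sigma_hidden,
            "sigma_out": params.sigma_out,
            "widths": list(params.widths),
            "tensors": {
                "Z": params.Z.tolist(), "W1": params.W1.tolist(),
                "W2": params.W2.tolist(), "W": params.W.tolist(), "b": params.b.tolist(),
            },
        }
    payload["checkpoint_version"] = CHECKPOINT_VERSION
    Path(path).write_text(json.dumps(payload))


def load_params(path):
    """Load a checkpoint written by :func:`save_params`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    if payload.get("checkpoint_version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"unsupported checkpoint version {payload.get('checkpoint_version')!r}"
        )
    t = {k: np.asarray(v, dtype=float) for k, v in payload["tensors"].items()}
    if payload["model"] == "nodemlp":
        return NodeMLPParams(t["Z"], t["W"], t["b"], sigma=payload["sigma"])
    h, h1, h2 = payload["widths"]
    return NeuLay2Params(
        t["Z"].reshape(-1, h), t["W1"].reshape(h, h1), t["W2"].reshape(h1, h2),
        t["W"], t["b"],
        sigma_hidden=payload["sigma_hidden"], sigma_out=payload["sigma_out"],
    )


def loss_param_gradient(graph, params, eparams, op=None, method="cell_list"):
    """Gradient of the layout loss w.r.t. every parameter tensor (chain rule)."""
    if isinstance(params, NodeMLPParams):
        x, cache = nodemlp_forward(params, return_cache=True)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite forward output")
        dx = total_gradient(graph, Layout(x), eparams, method)
        return _nodemlp_backward(params, cache, dx)
    x, cache = neulay2_forward(op, params, return_cache=True)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite forward output")
    dx = total_gradient(graph, Layout(x), eparams, method)
    return _neulay2_backward(op, params, cache, dx)


def _forward(params, op):
    if isinstance(params, NodeMLPParams):
        return nodemlp_forward(params)
    return neulay2_forward(op, params)


@_quiet_overflow
def train_model(
    graph: Graph,
    model: str = "neulay2",
    eparams: EnergyParams | None = None,
    stop: StopRule | None = None,
    seed: int | None = None,
    record_every: int = 10,
    hidden: tuple[int, int, int] | None = None,
    dim: int = 3,
    optimizer: str = "gd",
    operator: OperatorView | str = "full",
    method: str = "cell_list",
    init_scale: float = 1.0,
    track_modes: np.ndarray | None = None,
) -> tuple[Layout, Trajectory, object]:
    """Train a reparametrized layout on ``graph`` by gradient descent on theta.

    The objective is exactly the force-directed loss of the induced layout,
    so trajectories are directly comparable with :func:`neulay.fdl.run_fdl`
    (use the same optimizer family and learning rate for fair comparisons).

    ``operator`` is the matrix the GCN layers propagate through: "full",
    "top" or "bulk" (or a prebuilt :class:`OperatorView`) — substituting the
    outlier projection or its complement isolates the spectral origin of the
    speedup.

    Returns (final layout, trajectory, trained parameters).
    """
    eparams = (eparams or EnergyParams()).resolve(graph.n_nodes)
    stop = stop or StopRule()
    n = graph.n_nodes
    if hidden is None:
        w = min(n, 100)
        hidden = (w, w, w)
    op = None
    if model != "nodemlp":
        op = operator if isinstance(operator, OperatorView) else operator_view(graph, operator)
    params = init_params(n, (*hidden, dim), seed=seed, scale=init_scale, model=model)
    x0 = _forward(params, op)
    e0 = total_loss(graph, Layout(x0), eparams, method)
    eps = eparams.epsilon

    for _attempt in range(12):
        theta = init_params(n, (*hidden, dim), seed=seed, scale=init_scale, model=model)
        tensors = theta.tensors()
        opt = AdamState([t.shape for t in tensors], eps) if optimizer == "adam" else None
        if optimizer not in ("gd", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        traj = Trajectory()
        t0 = time.perf_counter()

        def _record(step, energy, x):
            traj.record(
                step,
                energy,
                time.perf_counter() - t0,
                overlaps=np.linalg.norm(track_modes.T @ x, axis=1)
                if track_modes is not None
                else None,
            )

        _record(0, e0, x0)
        diverged = False
        for step in range(1, stop.max_steps + 1):
            try:
                grads = loss_param_gradient(graph, theta, eparams, op, method)
            except FloatingPointError:
                if step > record_every:
                    diverged = True
                break  # first-interval blowup: retry with smaller eps
            if opt is None:
                for t, g in zip(tensors, grads):
                    t -= eps * g
            else:
                opt.step(tensors, grads)
            if step % record_every == 0 or step == stop.max_steps:
                x = _forward(theta, op)
                bad = not np.all(np.isfinite(x))
                e = np.inf if bad else total_loss(graph, Layout(x), eparams, method)
                if step <= record_every and (not np.isfinite(e) or (e > e0 and e0 > 0)):
                    break  # first record rose or blew up: retry with smaller eps
                if not np.isfinite(e):
                    diverged = True
                    break
                _record(step, e, x)
                if converged(traj, stop):
                    break
        if diverged:
            raise RuntimeError(
                "training loss diverged (non-finite); use a smaller learning "
                "rate epsilon"
            )
        if len(traj.steps) > 1 or stop.max_steps < record_every:
            return Layout(_forward(theta, op)), traj, theta
        warnings.warn(
            f"loss increased on the first step; halving epsilon to {eps / 2:.3g}",
            stacklevel=2,
        )
        eps = eps / 2.0
    raise RuntimeError("loss still increases after repeated halving of epsilon")
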