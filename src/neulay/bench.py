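"""Reproducible experiment harness: generate or load graphs, run layout
models under shared conditions, and aggregate speed/quality metrics.

A :class:`RunConfig` fully determines an experiment: the graph (generator
family + parameters or an input file), the models to compare, the energy and
stopping parameters, and the seeds.  Identical configs with identical seeds
reproduce final energies to floating-point determinism.  Results bundles
embed the resolved config and library versions for auditability; wall-clock
numbers are always recorded but flagged hardware-dependent.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .energy import EnergyParams
from .fdl import StopRule, init_layout, run_fdl
from .generators import GeneratorSpec
from .graph import Graph, read_graph, write_layout
from .metrics import speedup
from .models import train_model
from .spectral import eigendecompose, normalized_operator, operator_view

__all__ = ["RunConfig", "run_experiment", "load_config"]

KNOWN_MODELS = ("fdl", "nodemlp", "neulay", "neulay2")


@dataclass
class RunConfig:
    """Declarative experiment description (YAML/JSON serializable)."""

    generator: dict | None = None  # {"family": ..., "parameters": {...}}
    input_path: str | None = None
    input_format: str = "edgelist"
    models: list = field(default_factory=lambda: ["fdl", "neulay2"])
    energy: dict = field(default_factory=dict)  # EnergyParams kwargs
    stop: dict = field(default_factory=dict)  # StopRule kwargs
    hidden: list | None = None
    operator: str = "full"
    optimizer: str = "adam"
    dim: int = 3
    seeds: list = field(default_factory=lambda: [0])
    record_every: int = 10
    init_scale: float = 1.0
    delta: float = 0.05  # target-crossing tolerance for speedups
    outdir: str | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("config needs at least one model")
        if not self.seeds:
            raise ValueError("config needs at least one seed")
        unknown = set(self.models) - set(KNOWN_MODELS)
        if unknown:
            raise ValueError(f"unknown model(s): {sorted(unknown)}")

    def build_graph(self, seed: int | None = None) -> Graph:
        if (self.generator is None) == (self.input_path is None):
            raise ValueError("config needs exactly one of generator/input_path")
        if self.input_path is not None:
            return read_graph(self.input_path, self.input_format)
        spec = GeneratorSpec(
            self.generator["family"],
            dict(self.generator.get("parameters", {})),
            seed=self.generator.get("seed", seed),
        )
        out = spec.build()
        return out[0] if isinstance(out, tuple) else out


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    return RunConfig(**data)


def _manifest(config: RunConfig) -> dict:
    import networkx
    import scipy

    return {
        "config": asdict(config),
        "versions": {
            "neulay": _pkg_version,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "networkx": networkx.__version__,
            "platform": platform.platform(),
        },
        "note": "wall-clock timings are hardware-dependent: not comparable across machines",
    }


def _single_run(graph, model, seed, config, eparams, stop, op_view):
    if model == "fdl":
        init = init_layout(graph.n_nodes, config.dim, config.init_scale, seed=seed)
        layout, traj = run_fdl(
            graph, init, eparams, stop,
            record_every=config.record_every, optimizer=config.optimizer,
        )
    else:
        hidden = tuple(config.hidden) if config.hidden else None
        layout, traj, _ = train_model(
            graph, model, eparams, stop, seed=seed,
            record_every=config.record_every, hidden=hidden, dim=config.dim,
            optimizer=config.optimizer,
            operator=op_view if model in ("neulay", "neulay2") else "full",
            init_scale=config.init_scale,
        )
    return layout, traj


def run_experiment(config: RunConfig) -> dict:
    """Run every (model, seed) combination and aggregate the results.

    Returns a bundle dict with per-run records, per-model medians, speedups
    of each neural model against the paired-seed FDL run (when ``fdl`` is in
    the model list), and a config/version manifest.  If ``config.outdir`` is
    set, trajectories (CSV), final layouts (CSV) and the report (JSON) are
    written there.
    """
    eparams = EnergyParams(**config.energy)
    stop = StopRule(**config.stop)
    graph = config.build_graph(seed=config.seeds[0])
    op_view = None
    if any(m in ("neulay", "neulay2") for m in config.models):
        if config.operator == "full":
            op_view = operator_view(graph, "full")
        else:
            dec = eigendecompose(normalized_operator(graph), mode="full")
            op_view = operator_view(graph, config.operator, dec)

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    runs = []
    trajs: dict[tuple[str, int], object] = {}
    for model in config.models:
        for seed in config.seeds:
            rec = {"model": model, "seed": seed}
            try:
                layout, traj = _single_run(
                    graph, model, seed, config, eparams, stop, op_view
                )
            except Exception as exc:  # record the failure, keep the bundle
                rec["error"] = f"{type(exc).__name__}: {exc}"
                runs.append(rec)
                continue
            trajs[(model, seed)] = traj
            rec.update(
                final_energy=traj.final_energy,
                steps=traj.final_step,
                wall_time=traj.wall_times[-1],
            )
            runs.append(rec)
            if outdir:
                tag = f"{model}_seed{seed}"
                _write_traj(traj, outdir / f"traj_{tag}.csv")
                write_layout(graph, layout, outdir / f"coords_{tag}.csv")

    aggregates = {}
    for model in config.models:
        energies = [r["final_energy"] for r in runs if r["model"] == model and "error" not in r]
        steps = [r["steps"] for r in runs if r["model"] == model and "error" not in r]
        if energies:
            aggregates[model] = {
                "median_final_energy": float(np.median(energies)),
                "median_steps": float(np.median(steps)),
                "n_runs": len(energies),
            }

    speedups = {}
    if "fdl" in config.models:
        for model in config.models:
            if model == "fdl":
                continue
            step_ratios, time_ratios = [], []
            for seed in config.seeds:
                tf, tm = trajs.get(("fdl", seed)), trajs.get((model, seed))
                if tf is None or tm is None:
                    continue
                sr, tr = speedup(tf, tm, delta=config.delta)
                if sr is not None:
                    step_ratios.append(sr)
                    time_ratios.append(tr)
            if step_ratios:
                speedups[model] = {
                    "median_step_speedup": float(np.median(step_ratios)),
                    "median_time_speedup": float(np.median(time_ratios)),
                }

    bundle = {
        "graph": {"n_nodes": graph.n_nodes, "n_links": graph.n_links},
        "runs": runs,
        "aggregates": aggregates,
        "speedups_vs_fdl": speedups,
        "manifest": _manifest(config),
    }
    if outdir:
        (outdir / "report.json").write_text(json.dumps(bundle, indent=1, default=str))
        _write_aggregate_csv(runs, outdir / "aggregate.csv")
    return bundle


def _write_traj(traj, path) -> None:
    lines = ["step,energy,wall_time"]
    lines += [
        f"{s},{e!r},{t!r}" for s, e, t in zip(traj.steps, traj.energies, traj.wall_times)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _write_aggregate_csv(runs, path) -> None:
    cols = ["model", "seed", "final_energy", "steps", "wall_time", "error"]
    lines = [",".join(cols)]
    for r in runs:
        lines.append(",".join(str(r.get(c, "")) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
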