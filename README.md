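# neulay

Force-directed graph layout accelerated by graph-convolutional
reparametrization, with spectral-outlier analysis and layout-quality
metrics.

## The problem

Force-directed layout (FDL) is how network visualization tools place nodes:
links act as springs, a short-range repulsion keeps nodes apart, and the
layout is the minimum of the total energy

&nbsp;&nbsp;&nbsp;&nbsp;ℒ(X) = ½ Σ_{i<j} A_ij |x_i − x_j|² + a_N Σ_{i<j} exp(−|x_i − x_j|²/4r₀²),

found by gradient descent on the N×d coordinate matrix X.  Plain descent is
slow on large networks and gets trapped in high-energy "hairball" layouts:
the slow modes of the dynamics are exactly the large-scale structures
(communities, spatial neighborhoods) a viewer wants to see.

This package implements the direct optimizer together with a family of
neural reparametrizations — **NodeMLP** (X = σ(ZW + b) from a trainable
embedding Z) and **NeuLay / NeuLay-2** (one or two graph-convolutional
layers over the normalized adjacency f(A) = D̃^{−1/2}(A+I)D̃^{−1/2},
concatenated with Z and projected to coordinates) — trained per graph on
the same energy via the chain rule, dθ/dt = −ε Σᵢ (∂xᵢ/∂θ)(∂ℒ/∂xᵢ).
Propagating through f(A) amplifies the gradient of each eigenmode by its
eigenvalue, so the **outlier eigenvalues** of the spectrum — one per block
in a stochastic block model, tens in a random geometric graph — are sped up
the most.  The package includes the machinery to test this mechanism
directly: outlier detection, the A_top/A_bulk operator split, per-mode
overlap tracking against the analytic decay rate ε(⟨k⟩ − λᵢ), and quality
metrics (energy ratios, step-count speedups, link-length distributions,
community silhouette, geometric-randomization nulls).

It is aimed at network scientists who want fast, interpretable 2-D/3-D
layouts of (biological and other) networks, and at anyone studying why
neural reparametrization accelerates energy minimization on graphs.

## Worked example

Lay out a 100-node stochastic block model (four blocks of 25,
p_in = 0.5, p_out = 0.02) with the direct optimizer and with NeuLay-2:

```
$ neulay generate --family sbm --blocks 25,25,25,25 --p-in 0.5 --p-out 0.02 \
      --seed 7 --out g.gml
wrote g.gml (100 nodes, 708 links)

$ neulay run --model fdl --input g.gml --seed 1 --out fdl.csv \
      --traj fdl_traj.csv --max-steps 3000
fdl: final energy 16.1365 after 1050 steps

$ neulay run --model neulay2 --input g.gml --seed 1 --out nl2.csv \
      --traj nl2_traj.csv --max-steps 3000
neulay2: final energy 16.1202 after 1980 steps

$ neulay spectral --input g.gml --out spec.json
4 outlier eigenvalue(s) of 100
```

Both optimizers reach the same energy basin (16.14 vs 16.12 — NeuLay-2
slightly deeper), but they get there at very different speeds: counting the
steps to come within 5% of the FDL final energy,

```
steps to within 5% of FDL final: fdl 480, neulay2 50   (step speedup 9.6)
```

NeuLay-2 separates the four blocks an order of magnitude earlier.  The
spectral report explains why: the operator's four outlier eigenvalues
(1.0, 0.913, 0.883, 0.881, against a bulk edge near 0.39) are one per
planted block, and those are precisely the slow modes of the direct
dynamics that the GCN layers accelerate.  `fdl.csv` / `nl2.csv` hold the
coordinates (`node_id,x,y,z`), and the trajectory CSVs the recorded
step/energy/wall-time curves.

The same pipeline is available as a library (`neulay.run_fdl`,
`neulay.train_model`, `neulay.eigendecompose`, `neulay.speedup`, ...) and as
a config-driven harness (`neulay bench --config cfg.yaml`) that writes
per-run trajectories, aggregate tables and a JSON report embedding the
resolved configuration.  See `docs/methods.md` for the model, parameter
defaults, the outlier rule, and the benchmark design.

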