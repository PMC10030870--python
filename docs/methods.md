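# Methods

## The layout model

An undirected graph with symmetric non-negative adjacency `A` (N nodes) is
laid out in d-dimensional Euclidean space (d = 2 or 3) by minimizing

    L(X) = V_el(X) + V_NN(X)

over the N×d coordinate matrix `X`, where

    V_el = 1/2 Σ_{i<j} A_ij |x_i − x_j|²  =  1/2 Tr[Xᵀ L X],    L = D − A,
    V_NN = a_N Σ_{i<j} exp(−|x_i − x_j|² / 4 r0²).

The elastic term treats links as unit springs of zero rest length; the
Gaussian term is a short-range repulsion that prevents node overlap.  The
repulsion is often printed with a positive exponent in the literature, but a
repulsive potential must decay with distance; we use the negative exponent
throughout.  The short range is what makes the pair sum truncatable: pairs
farther apart than a cutoff (default 4·r0, per-pair truncation error e⁻⁴)
contribute negligibly, and a linked-cell grid with spacing equal to the
cutoff (rebuilt every step; correctness over micro-optimization) evaluates
energy and forces in O(N) for spread-out layouts.  A brute-force untruncated
evaluation is kept as the smooth reference; tests bound the difference by
`a_N · N² · exp(−cutoff²/4r0²)`.

With these conventions the gradient of the elastic term is exactly `L X`,
the sum convention is unordered pairs everywhere, and the linearized
dynamics below carry no stray factors of 2.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `a_N` | repulsion amplitude | `1/N` | keeps total repulsion O(N), comparable to the O(links) elastic term on sparse graphs |
| `r0` | repulsion range (layout length units) | 0.1 | sets the node "hard-core" scale relative to an O(1) initial layout |
| `cutoff` | interaction cutoff | `4·r0` | per-pair truncation error < e⁻⁴ |
| `ε` | learning rate | 0.01 | stable for plain descent on all benchmark families used here |
| `scale` | sd of the Gaussian initial coordinates | 1.0 | O(1) random start |

All are configurable (`EnergyParams`, `init_layout`).  Coordinates are
unitless and no bounding box is imposed.

## Direct optimization (FDL)

`run_fdl` iterates explicit Euler on the gradient flow,
`x ← x − ε (LX + ∂V_NN/∂x)`.  If the first recorded step raises the energy,
ε is halved with a warning and the run restarts; a non-finite energy later
in the run aborts with advice to lower ε.  Runs stop when the relative
energy change over a `window` of steps (default 50) falls below `rel_tol`
(default 1e-5) or at `max_steps`.  Wall-clock time is measured around the
step loop only and is recorded but hardware-dependent; step counts are the
comparable quantity.

## Neural reparametrization

Rather than optimizing `X` directly, `X` is the output of a small network
with parameters θ, trained per graph on the same loss via the chain rule
(dθ/dt = −ε Σ_i (∂x_i/∂θ)(∂L/∂x_i)):

* **NodeMLP** — `X = σ(Z W + b)` from a trainable N×h embedding `Z`; no
  graph information in the forward pass.
* **NeuLay / NeuLay-2** — graph-convolutional layers `G1 = σ(f(A) Z W⁽¹⁾)`,
  `G2 = σ(f(A) G1 W⁽²⁾)` with the normalized operator
  `f(A) = D̃^{−1/2}(A+I)D̃^{−1/2}`; the concatenation `G = [Z|G1|G2]` is
  projected to coordinates `X = σ_out(G W + b)`.  One GCN layer (NeuLay) is
  the zero-width-`W⁽²⁾` special case; more than two layers slow computation
  without improving convergence and are not implemented.

Forward and reverse passes are written directly in numpy; the reverse-mode
gradients are exact (the operator is symmetric, so its adjoint is itself)
and are validated against central finite differences at 1e-4 of the gradient
scale.  Near-zero gradient components (the output bias of a
translation-invariant loss) are compared at that absolute scale, since their
relative error is finite-difference noise.

Hidden nonlinearity is tanh.  The output nonlinearity defaults to the
*identity*: a saturating output confines coordinates to a box and fights the
natural growth of a layout's extent with N; a tanh output remains available
(`sigma_out="tanh"`) and its gradients are tested.

Default widths are h = h1 = h2 = min(N, 100).  `Z` is initialized
N(0, scale²) and weights N(0, 1/fan_in), so the induced initial layout has
the same O(scale) extent as the direct method's random start.

### Optimizer family

Plain gradient descent on θ at the coordinate-space learning rate diverges:
the reparametrization Jacobian multiplies the effective coordinate step by
roughly the total embedding width.  Rather than hand-tuning a per-model
rate, every comparison between direct and reparametrized optimization uses
the adaptive-moment (Adam) optimizer for **both** sides at the same ε —
whatever is compared, the optimizer family is shared.  Plain descent remains
the default for `run_fdl` itself and is the dynamics used in the mode-decay
analysis, where the linearized GD flow is the object under test.

## Spectral analysis

For near-regular graphs `L ≈ ⟨k⟩I − A`, so under elastic-only plain GD the
overlap `ψᵢᵀX` with the i-th adjacency eigenvector decays independently at
rate `ε(⟨k⟩ − λᵢ)` per step.  Modes with the largest λᵢ are the slow modes;
in community and geometric graphs these are exactly the eigenvalues that
separate from the bulk of the spectrum.  `predicted_decay_rate` implements
the rate (clipped at zero — for non-regular graphs the Perron eigenvalue
exceeds ⟨k⟩, yet the overlap cannot grow under a PSD Laplacian) and warns
when the degree coefficient of variation exceeds 0.2.  On a ring the
prediction is exact to the discretization error (<1%); on the 27-node open
cubic lattice the boundary pushes the degree CV to 0.204 and the prediction
for the slowest modes is off by ~15–18% — an intrinsic limit of the
near-regularity approximation at this size, not a fitting artifact, and the
corresponding acceptance check records it.

### Outlier detection

The outlier set should contain the eigenvalues of `f(A)` that separate from
the bulk.  A tempting operationalization — thresholding at the spectrum's
mean plus one standard deviation — systematically overcounts: for a
semicircle-like bulk about 20% of the bulk always lies above its own
mean + σ (the semicircle's upper tail), and the outliers can never inflate σ
enough to push the threshold past the bulk edge (their variance contribution
is bounded by ~p²·block_size < 3·⟨k⟩ in a block model).  The package
therefore thresholds at

    median + 2 · (IQR / 1.349),

a robust bulk-edge estimate: the quartiles are set by the bulk alone, and
for a semicircle of radius R the threshold lands at ≈1.2 R — just above the
support edge, below any separated eigenvalue.  With this rule an assortative
SBM has exactly one outlier per block (checked in the test suite at block
counts 2, 4, 8), Erdős–Rényi graphs have at most the Perron eigenvalue,
Barabási–Albert graphs none, and random geometric graphs tens (their
spectrum has a broad cascade of structural modes).  The mean + σ variant is
kept as `outlier_set(..., rule="mean_std")` for comparison.  Ties with the
threshold are excluded (strict inequality).

`split_operator` forms `A_top = Σ_{i∈Out} λ̃ᵢψᵢψᵢᵀ` and
`A_bulk = f(A) − A_top` (exact reconstruction ≤1e-9); the split matrices are
substituted into the GCN as-is, without re-normalization.  `OperatorView`
applies the top part in its rank-|Out| factorized form, so ablation runs do
not densify the operator.  Outliers are detected and the operator is split
on `f(A)` — the matrix the GCN actually propagates — while the decay-rate
analysis uses the raw adjacency spectrum; both spectra are exposed.

With a full decomposition available for N ≤ 5000, `eigendecompose` uses a
dense symmetric solver; above that an iterative top-k solver (k = 64
default) provides the leading pairs, with outlier statistics computed over
the available slice (flagged, and reasonable as long as k comfortably
exceeds the true outlier count).  The top/bulk split requires the full mode.

## Metrics

* **Energy ratio** ΔE = E_FDL/E_model of final energies; >1 means the model
  found a deeper minimum.
* **Convergence time**: first recorded step (and wall-time) with energy
  ≤ (1+δ)·target, δ = 0.05 by default, target = the paired FDL run's final
  energy; `speedup` is the ratio of FDL's to the model's cost.  Step ratios
  are asserted in tests; wall-clock ratios are reported only.
* **Link-length distributions**, globally and per community (internal links
  only; default 50 equal-width bins on [0, max]); a spatially localized
  community has a narrow internal distribution.
* **Geometric randomization**: permute which node sits at which coordinate,
  holding the coordinate multiset and the graph fixed — the null model
  against which "links are short" is judged.
* **Cluster separation**: mean silhouette coefficient of nodes in layout
  space under the community labels (standard a/b formulation, Euclidean
  distances).  This is a transparent stand-in for an unspecified spatial
  similarity score and is labelled as such in reports; singleton communities
  are skipped with a warning.

All metrics are invariant under rigid motions of the layout.

## Synthetic benchmark families

Generators (all seeded, all returning simple undirected graphs) emulate the
study conditions: Erdős–Rényi and Barabási–Albert (no large-scale structure;
BA from a complete m-clique seed, the standard convention), the stochastic
block model (planted communities; defaults p_in = 0.5, p_out = 0.02 at block
size 25 give a clean eigen-gap between block modes ≈0.87–1.0 and bulk edge
≈0.45), random geometric graphs (uniform points in the unit hypercube, hard
walls, link iff distance ≤ radius), and the simple cubic lattice (known
optimal layout; 27 nodes at side 3).  They reproduce the analytic link-count
and degree expectations (binomial means, BA tail exponent ≈3, RGG mean
degree vs a Monte-Carlo boundary-corrected oracle) but are idealized: no
degree correction in the SBM, no weights, no real-network degree
correlations.  Passing benchmarks on them demonstrates the mechanism —
outlier modes drive the speedup — not performance on any particular real
network.

## Benchmark problem sizes

The acceptance-level experiments run at desk scale, chosen so the full suite
completes on a single CPU: dominance and ablation instances are an 8-block
SBM with 50-node blocks (N = 400) and a 2-D RGG with N = 500 (radius 0.06),
3 paired seeds (dominance and ablations); the ER/BA null-case
ablations use N = 300; the energy-ratio trend uses BA graphs N ∈ {100, 300,
1000} with 3 seeds under a fixed 1200-step budget (at a fixed budget the
ratio measures how far FDL's slow modes leave it from the optimum — its
trapping — which at these sizes is the observable form of the
converged-energy gap seen at much larger N); step caps are 1200–4000 rather
than unbounded.  Medians are reported throughout.

## Numerical choices and degenerate inputs

* Node order is the sorted label order; all matrices are indexed by it, so
  rereading the same file reproduces results bit-for-bit.
* Duplicate edges collapse to the maximum weight; self-loops are dropped
  (their elastic energy is constant and the GCN operator adds I itself);
  real-network weights are kept by default with a `binarize` flag.
* Single nodes, empty graphs, zero-width layers, zero-scale initializations
  and disconnected graphs are all defined and tested; a disconnected RGG
  simply has several components laid out independently (components farther
  apart than the cutoff do not interact).
* Degenerate eigenvalues make individual eigenvectors arbitrary within the
  eigenspace; overlap-based diagnostics on degenerate spectra should be
  interpreted per eigenspace.
* The two-node equilibrium bond length is cross-checked against independent
  scalar minimization to 1e-3.

## Known limitations

* Long-range (1/r) repulsion and Barnes–Hut summation are out of scope; the
  short-range force suffices for the neural models but direct FDL on very
  large sparse graphs may benefit from long-range forces this package does
  not provide.
* Gradients are dense in the number of *pairs within the cutoff*; tightly
  collapsed layouts of large graphs approach O(N²) per step.
* Training is per-graph by design; there is no transfer across graphs.
* Attention-based or message-passing architectural variants and
  minibatched/sampled propagation are not implemented.
* Wall-clock speedups depend on hardware and library BLAS; only step-count
  comparisons are asserted anywhere.
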