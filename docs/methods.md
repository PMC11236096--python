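# Methods

## The model: indirect noise as random-walk diffusion

Inferred interaction networks — gene regulatory networks above all — are
contaminated by *transitive* artefacts: when gene A regulates B and B
regulates C, most inference pipelines also report an A–C edge, and edges
between nodes joined by many short paths get inflated weights. We model
this corruption as a diffusion acting on the random walk of the
underlying true network and denoise by applying the exact inverse of
that diffusion.

A weighted undirected graph `W` (symmetric, nonnegative, zero diagonal)
defines a random walk through `g(W) = D⁻¹W`, where `D` is the diagonal
degree matrix. On transition matrices the forward diffusion with
intensity `m > 1` is

    f_m(P) = (Σ_{k≥1} P^k / m^k) / (Σ_{k≥1} 1/m^k) = (m−1) P (mI − P)⁻¹ ,

i.e. the walk blended with the probability of every longer path,
discounted geometrically in path length. The series converges because
`ρ(P/m) = 1/m < 1` for stochastic `P`. Its exact functional inverse is

    f_m⁻¹(P) = m ((m−1) I + P)⁻¹ P ,

which strips the accumulated indirect contributions of *all* path
lengths in a single linear solve. Both operators preserve row sums;
`f_m⁻¹` may produce negative entries when the input walk was not
actually generated by forward diffusion (sparse graphs are the typical
offender). The walk is mapped back to a graph by
`h(P) = α · diag(π) P` with `π` the stationary distribution (`πP = π`);
for the reversible walk of an undirected graph `π ∝ degree`, so `h`
restores degree information and `h(g(W)) = W / ΣW` up to the scale `α`.

The denoiser is the composite `B_m = h ∘ f_m⁻¹ ∘ g` with a correction
sandwich:

1. **Preprocess** `W̃ = W + ε₁J + ε₂I` (`J` all-ones). This makes the
   graph complete, hence the walk irreducible, and tames negative
   entries in the inverse step. Auto mode uses `ε₁ = ε₂ = 1` for
   unweighted graphs and the minimum nonzero weight otherwise, so the
   offsets never dominate real edges.
2. `P_obs = g(W̃)`, `P_dir = f_m⁻¹(P_obs)`.
3. **Negative-row correction**: each row whose minimum is below
   `−10⁻¹²` is shifted by subtracting that minimum (per-row `β`).
4. **Row renormalisation** (default): the shift breaks row sums, so rows
   are rescaled to probability before the stationary distribution is
   computed. The literal alternative — using the dominant left
   eigenvector of the uncorrected matrix — is available via
   `renormalize_rows=False`; within-row rankings are unaffected by the
   rescaling.
5. `W_dir = h(P̃_dir)`, symmetrised as `(M + Mᵀ)/2`, diagonal zeroed.

The output is a *complete* weighted matrix: pairs absent from the input
may gain a small weight, and transitively supported edges are deflated.
Everything is deterministic; complexity is `O(n³)` (one matrix solve,
one eigen-decomposition).

### What the operator actually deflates

The inverse diffusion removes what paths can explain. An edge closing a
short cycle (a chord across a path) is *path-redundant* and drops to the
bottom of the ranking; a bridge with no alternative path has no indirect
component to strip and is, if anything, boosted — connectivity-critical
edges are the ones forward diffusion would have spread the most. Tests
assert both directions on hand-built graphs.

### Parameter choices

| parameter | default | meaning |
|---|---|---|
| `m` | 4 | path-length decay base; larger m discounts long paths more and denoises more gently. Values near 1 over-denoise aggressively (the series weights long paths heavily) and are not recommended; the CLI `msweep` command scans a grid. |
| `ε₁, ε₂` | auto | preprocessing offsets (see above). |
| `α` | match input sum | output scale of `h`; rescales weights only, never rankings. Default matches the preprocessed input's total weight. |

`from_transition` keeps an optional `zero_diagonal` switch: the forward
graph operator `F_m = h ∘ f_m ∘ g` retains the self-loop mass that
even-length return paths genuinely carry, because discarding it would
make `F_m` non-invertible; the denoiser's final output always zeroes the
diagonal since self-loops are not meaningful edges in this domain.

## Stationary-distribution solver

Dense left eigen-decomposition up to 2000 nodes (consistent with the
`O(n³)` budget of the pipeline), power iteration (tolerance `10⁻¹²`, at
most `10⁵` iterations) above. A unit eigenvalue of multiplicity above
one means a reducible chain; this raises with advice to preprocess
(`ε₁ > 0` guarantees irreducibility). The residual `‖πP − π‖∞` is
checked against `10⁻⁸`.

## Baselines

- **Network deconvolution (ND)** inverts the transitive-closure series
  per eigenvalue: `λ → λ/(1+λ)` after linearly rescaling the input so
  every mapped eigenvalue lies in `(−1, 1)` with the extreme one equal
  to `scale` (default 0.9, the published tunable-scaling convention).
- **Network enhancement (NE)** builds a k-nearest-neighbour localised
  kernel `T` and iterates `W ← α T W T + (1−α) T`. Neighbourhood sizes
  below `k` fall back to all positive neighbours (logged). Defaults
  `k = min(20, n−1)`, `α = 0.9`, 2 iterations — the published defaults;
  benchmark reports record the settings used.
- **Silencer** solves `S = (C − I + D((C−I)C)) C⁻¹` (`D` keeps the
  diagonal only). On a chain correlation structure with
  `r_xz = r_xy·r_yz` it zeroes the indirect entry exactly. It does not
  shrink *average* off-diagonal magnitude on generic matrices — only
  transitively explained entries — and the tests reflect that.
- **Partial correlation (ICM)**: `S = C⁻¹`,
  `P_ij = −S_ij/√(S_ii S_jj)`, unit diagonal.

Singular inputs to silencer/ICM raise; ridge repair `C + δI` happens
only on explicit opt-in, because silent regularisation changes the
method. Signed outputs are ranked by absolute value — evaluation
concerns edge existence, not sign.

Binary simulated networks are fed to the correlation-based baselines
through the embedding `C = W/(ρ(W)+1) + I`, which is positive definite
with unit diagonal and preserves the off-diagonal ranking.

## Synthetic noisy networks

True networks: the n-cycle, Erdős–Rényi `G(n, p)` and Barabási–Albert
preferential attachment (star seed on `e+1` nodes, then `e` edges per
new node). Disconnected ER draws are regenerated with an incremented
seed rather than repaired by edge surgery, keeping the random-graph
model intact. Benchmark defaults mirror the simulation study:
`n = 50`, `p = 0.3`, `e = 3`, noise proportions 0.1–0.5.

Noise edges are added between non-adjacent pairs with probability
proportional to a path-proximity score

    s_ij = Σ_{k=2..4} (A^k)_ij / decay^k        (decay = 4)

— the more and the shorter the existing paths between two nodes, the
likelier a spurious edge. The quota
`round(q/(1−q) · |E_true|)` makes injected edges exactly the requested
fraction `q` of the noisy network (the 20-node cycle with 15 added edges
gives `15/35 ≈ 0.43`). Injected edges carry the mean existing edge
weight, so unweighted graphs stay unweighted. Zero-score pairs are used
(uniformly, with a log notice) only when the quota cannot otherwise be
met. Seeds derive as `base + 1000·proportion_index + replicate_index`,
so any sweep cell regenerates in isolation.

An alternative kernel (`kernel="diffusion"`) scores candidate pairs by
the weight the forward diffusion operator itself assigns them. It
matters because the two kernels emulate different noise mechanisms: raw
path counts concentrate noise on hub pairs of heterogeneous-degree
graphs, where the per-walk transitive support is small, producing noise
that *no* inverse-of-diffusion method (nor eigen-deconvolution, nor
partial correlation) can separate from signal; diffusion-scored noise is
by construction the transitive artefact these methods remove. On
degree-homogeneous graphs (cycle, ER) the distinction is minor; on
scale-free graphs it decides whether denoising can help at all. Passing
benchmarks on these simulations therefore demonstrate removal of
*transitive* noise under the stated placement mechanism — not robustness
to arbitrary spurious edges, and not performance on real expression-
derived networks, whose noise is also correlated with measurement and
inference biases the generator does not emulate.

## Evaluation

Edge rankings cover all `C(n, 2)` unordered pairs (denoised matrices are
complete; absent pairs score 0 and ties break lexicographically, so
every metric is deterministic). AUROC uses the Mann–Whitney rank
formulation (ties count ½) and is cross-checked against an independent
implementation in the tests; AUPR is the step-wise non-interpolated
area (average precision), the standard convention in network-inference
benchmarking. Confusion counts at top-k and the TP-versus-k retention
curve follow the keep-the-top-k-edges protocol. The benchmark harness
aggregates mean ± sd per method × topology × noise proportion over
replicates (default 20; the flag goes up to the study's 100), always
including the undenoised input as baseline, and records per-cell method
failures as missing values instead of aborting.

## Known limitations

- The denoiser assumes the observed walk was (approximately) generated
  by forward diffusion; the further the truth from that assumption, the
  more the negative-row correction distorts, and output quality degrades
  gracefully rather than failing loudly.
- Dense `O(n³)` linear algebra throughout; no sparse path for very large
  networks.
- Undirected model only; directed regulatory edges are symmetrised at
  the I/O boundary.
- `ε`-preprocessing makes the output complete; downstream consumers
  should threshold or rank rather than treat small weights as edges.
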