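# rendor — reverse network diffusion for denoising interaction networks

Inferred interaction networks, gene regulatory networks (GRNs) in
particular, are riddled with *indirect* edges: if many short paths join
two genes through intermediaries, inference methods tend to report a
(spurious) edge between them, and true edges backed by many parallel
paths get inflated weights. `rendor` models this corruption as a
random-walk diffusion on the underlying true network and removes it by
applying the exact inverse of that diffusion.

For a weighted undirected network `W` with random walk `P = D⁻¹W`, the
forward diffusion with intensity `m > 1`,

```
f_m(P) = (m−1) P (mI − P)⁻¹  =  normalised Σ_{k≥1} P^k / m^k ,
```

adds the probability of all paths of length k, discounted by `1/m^k`.
Denoising applies its exact functional inverse

```
f_m⁻¹(P) = m ((m−1) I + P)⁻¹ P ,
```

mapped back to a graph via the stationary distribution:
`W_dir = h(f_m⁻¹(g(W̃)))` with `g(W) = D⁻¹W`, `h(P) = α·diag(π)P`, and
`W̃ = W + ε₁J + ε₂I` a small offset that keeps the walk irreducible.
Negative rows produced on inputs that violate the diffusion assumption
are corrected by a per-row shift.

The package also provides four established comparator denoisers
(network deconvolution, network enhancement, silencer, partial
correlation), a generator of simulated noisy networks with ground-truth
signal/noise edge labels, and an AUROC/AUPR/top-k evaluation suite.

## Worked example

Corrupt a 20-node cycle with 15 indirect edges (noise placed
preferentially between nodes already joined by short paths), then
denoise:

```python
import rendor as rd

spec = rd.NoisySimSpec(topology="circular", n=20,
                       noise_proportion=15/35, seed=7)
net = rd.make_noisy_network(spec)          # 35 edges, 15 labelled noise
den = rd.rendor_denoise(net.weights, m=4)  # complete denoised matrix

truth = net.signal_pairs()
for name, M in [("noisy input", net.weights), ("denoised", den)]:
    r = rd.matrix_to_ranking(M)
    c = rd.confusion_at_k(r, truth, 20)
    print(f"{name:12s} AUROC={rd.auroc(r, truth):.3f} "
          f"AUPR={rd.aupr(r, truth):.3f} TP@20={c['tp']} FP@20={c['fp']}")
```

```
noisy input  AUROC=0.956 AUPR=0.571 TP@20=11 FP@20=9
denoised     AUROC=0.972 AUPR=0.750 TP@20=13 FP@20=7
```

The noisy input cannot distinguish true cycle edges from injected
chords (all carry weight 1); after reverse diffusion, keeping the top
20 edges recovers 13 of the 20 true edges instead of 11, and both
ranking metrics rise — the transitively explainable chords have been
deflated below the true edges.

The same pipeline from the shell:

```sh
rendor simulate --topology circular --n 20 --noise-prop 0.4286 --seed 7 --out-dir sim/
rendor denoise  --method rendor --m 4 --in sim/*.edges.tsv --out denoised.tsv
rendor evaluate --scores denoised.tsv --truth sim/*.labels.tsv --k 20
rendor benchmark --config sweep.yaml --out report.tsv   # ER/BA noise sweep
rendor msweep   --in sim/*.edges.tsv --truth sim/*.labels.tsv --out msweep.tsv
```

Networks are read and written as plain TSV (3-column edge lists or
labelled adjacency matrices); rectangular TF×gene matrices can be
zero-padded to square with `rendor.pad_to_square`. See
`docs/methods.md` for the model, parameter meanings, and the
generator's assumptions.

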