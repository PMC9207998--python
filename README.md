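# dcovnet

Directed functional connectivity from haemodynamic time series via
**differential covariance**, with end-to-end synthetic validation.

Resting-state fMRI gives one BOLD trace per brain region, and the usual
way to relate regions — the covariance matrix — is symmetric and polluted
by indirect correlations (chains and common inputs).  When the underlying
activity is modelled as a linear dynamical system `dV/dt = W V + ξ`, a
node's derivative reflects its *inputs* and its value reflects its
*outputs*, so the covariance between a derivative and a signal is directed:

- `Δc[i,j] = cov(dz_i, z_j)` — raw differential covariance (row = sink,
  column = source);
- `Δp` — the same after regressing all remaining nodes out of each pair
  (removes chain and common-input effects);
- `Δs` — the sparse part of `min α‖Δs‖₁ + ‖L‖_*  s.t.  Δs + L = Δp`,
  which strips a low-rank component due to unobserved common inputs.

Around this core the package provides, for people who analyse
node-by-time imaging matrices:

- **Neural-signal reconstruction**: the four-state Balloon–Windkessel
  forward model and its linearised inversion
  `z = p₄y⁗ + p₃y‴ + p₂y″ + p₁ẏ + p₀y ∝ q₁V̇ + q₀V`;
- **Benchmark estimators**: covariance, precision, L1/L2-regularised
  precision, conditional Granger causality with χ² significance;
- **Edge significance**: node-wise autoregressive bootstrap (BIC-selected
  orders, spectrum-preserving independent surrogates, Gaussian-null
  two-sided p-values, threshold binarization, sparsity matching);
- **Structure match**: structural-connectivity strength of significant
  edges (SCS) and its average (ASCS), pooled over subjects and thresholds;
- **Graph topology**: degrees, shortest paths, triangles, global/local
  efficiency, clustering, transitivity, modularity with a seeded module
  search — for binary directed and undirected networks;
- **Behavior linkage**: confound regression of a per-subject network
  statistic and significance-ranked correlations with behavioral measures;
- **Synthetic ground truth** (`dcovnet.synthkit`): stable sparse directed
  networks, Ornstein–Uhlenbeck dynamics, Balloon-model BOLD with TR
  downsampling, surrogate structural matrices (ordinal 1–7 tracing scale
  or symmetric diffusion scale), and behavior tables with a planted
  coupling — so every stage is testable without any external dataset.

See `docs/methods.md` for model details, parameter defaults and the
design rationale.

## Worked example

```python
import numpy as np
from dcovnet import (BalloonParams, generate_network, simulate_neural,
                     balloon_forward, downsample, backward_reconstruct,
                     partial_differential_covariance, significance_pipeline,
                     binarize, surrogate_sc, scs_values, topology_report)

net = generate_network(n_nodes=8, density=0.25, self_decay=1.0, seed=42)
v = simulate_neural(net, T=120_000, dt=0.01, noise_sd=1.0, seed=43)
y = downsample(balloon_forward(v, BalloonParams.hcp()), TR=0.5)
z = backward_reconstruct(y, BalloonParams.hcp())

sig = significance_pipeline(z, partial_differential_covariance,
                            n_surrogates=500, seed=44)
network = binarize(sig, threshold=0.01)
sc = surrogate_sc(net, "mouse")
print(f"significant edges at p<0.01: {network.n_edges} "
      f"(true couplings: {int(net.support().sum())})")
print(f"mean structural strength of selected edges: "
      f"{scs_values([network], sc).ascs:.2f} "
      f"(all pairs: {sc.weights[~np.eye(8, dtype=bool)].mean():.2f})")
rep = topology_report(network, seed=0)
print(f"global efficiency E = {rep.global_efficiency:.3f}, "
      f"clustering C = {rep.clustering:.3f}, modularity Q = {rep.modularity:.3f}")
```

Output:

```
significant edges at p<0.01: 17 (true couplings: 14)
mean structural strength of selected edges: 4.00 (all pairs: 2.39)
global efficiency E = 0.372, clustering C = 0.438, modularity Q = 0.000
```

The pipeline simulates an 8-node ground-truth system, turns it into
BOLD at TR = 0.5 s, reconstructs surrogate neural signals, and keeps the
partial-dCov edges that beat 500 AR-bootstrap surrogates at p < 0.01.
The 17 surviving edges sit on anatomically strong connections (mean
ordinal strength 4.00 versus 2.39 over all pairs — on the 1–7 scale the
true couplings occupy the 6–7 bins), and the binary network's topology
report summarises its integration (E) and segregation (C, Q).

## Command line

```sh
dcovnet simulate    --config cfg.json --out sim/
dcovnet reconstruct --in sim/bold.tsv --params balloon.json --out z.tsv
dcovnet estimate    --in z.tsv --method dcov-p --out fc.tsv
dcovnet testsig     --in z.tsv --method dcov-p --surrogates 1000 --seed 7 --out sig.tsv
dcovnet compare-sc  --sig sig.tsv --sc sim/sc.tsv --thresholds 0.05,0.01 --out ascs.tsv
dcovnet topology    --in sig.tsv.binary_0.05.tsv --directed yes --seed 0 --out report.json
dcovnet run         --config run.json     # staged pipeline + provenance manifest
```

Time series travel as TSV (first column = node label) with a JSON sidecar
holding the sampling interval and signal kind; matrices as labeled square
TSVs; significance tables in long format (source, sink, empirical,
null_mean, null_sd, p).

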