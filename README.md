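# iccmix

High-dimensional **mixture linear regression** for heterogeneous populations,
estimated by **imputation-conditional consistency (ICC)** with per-component
sparse fits. The motivating application is drug-sensitivity prediction from
gene expression: different tumour subpopulations respond to a drug through
different genes, so a single sparse regression underfits, while a mixture of
sparse regressions clusters the samples *and* selects a gene set per cluster.

## Model

Each response is drawn from a K-component Gaussian mixture of regressions

```
f(y_i | θ) = Σ_k π_k φ(y_i | x_i' β_k, σ_k²),     x_i ∈ R^p,  p ≫ n,
```

with sparse coefficient vectors β_k. Treating the latent memberships
τ_1..τ_n as missing data, the ICC chain alternates:

- **I-step** — sample each τ_i from its membership posterior
  `P(τ_i = k | θ) ∝ π_k φ(y_i | x_i'β_k, σ_k²)`;
- **CC-step** — per imputed cluster χ_k: set `π_k = |χ_k|/n`, estimate β_k by
  **SIS-MCP** (sure independence screening to d = ⌊n_k/log n_k⌋ features,
  then MCP-penalized least squares along a λ path, λ chosen by an extended
  BIC), and set `σ_k² = RSS_k / (|χ_k| − Card(β_k) − 1)`.

This yields two interleaved Markov chains over labels and parameters. After a
burn-in of t₀ iterations the label chain is aggregated by **consensus
clustering**: the dissimilarity `d_ij = (T−t₀) − #{t > t₀ : τ_i^(t) = τ_j^(t)}`
is clustered hierarchically (average linkage, cut at K), and a final SIS-MCP
fit per consensus cluster gives the reported model. The number of components
is chosen by the **average BIC**, the mean of the per-iteration BIC over the
post-burn-in chain, minimized over a grid of K.

## Worked example

```python
import iccmix

# three-component benchmark design: n=600, p=2000, three slopes of 3 per
# component (one feature shared), sigma=1
config = iccmix.SimulationConfig()
data = iccmix.generate_dataset(config, seed=7)

result, trace = iccmix.fit_mixture(data.X, data.y, K=3, T=500, t0=100, seed=11)
print("cluster sizes:", result.sizes.tolist())
for k, fit in enumerate(result.fits):
    print(f"component {k}: support {fit.support.tolist()}, "
          f"sigma {result.model.sigmas[k]:.2f}")
```

Output from this exact run:

```
cluster sizes: [204, 193, 203]
component 0: support [0, 5, 6], sigma 0.84
component 1: support [0, 3, 4], sigma 0.84
component 2: support [0, 1, 2], sigma 0.67
```

Each consensus cluster recovers one generating component: the three selected
feature triples are exactly the true supports (feature 0 is the shared one),
and the cluster sizes are close to the true 200/200/200 split. The fitted σ
values sit below the generating σ = 1 because the consensus assigns each
ambiguous sample to whichever component happens to explain it best, which
biases the within-cluster residual spread low.

Choosing K and predicting:

```python
report = iccmix.select_K(data.X, data.y, K_grid=[2, 3, 4], T=500, t0=100, seed=3)
print(report.selected_K)            # -> 3 (smallest average BIC)

train, test = iccmix.split_train_test(data, fraction=0.8, scheme="shuffled", seed=5)
result, _ = iccmix.fit_mixture(train.X, train.y, K=3, T=500, t0=100, seed=5)
pred = iccmix.predict(result.model, test.X, test.y, mode="posterior-with-response")
print(round(pred.corr, 3), round(pred.rmse, 3))   # -> 0.824 2.926
```

A command-line surface wraps the same pipeline:

```bash
iccmix simulate --n-per-comp 200,200,200 --p 2000 --seed 1 --out run/
iccmix fit --data run/data.csv --k 3 --iters 500 --burn-in 100 --seed 2 --out run/fit/
iccmix select-k --data run/data.csv --grid 1,2,3,4 --seed 3 --out run/k/
iccmix replicate-tables --reps 20 --seed 4 --out run/tables/
```

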