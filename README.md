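# tcmix

Model-based clustering of time-course gene-expression profiles with normal
mixtures of linear mixed models with AR(1) random effects.

Time-course experiments (yeast cell-cycle microarrays being the canonical
case) produce one short expression trajectory per gene. Two kinds of
correlation make naive mixture clustering of such profiles unreliable: a
gene's measurements are serially dependent over time, and genes in the same
co-regulated cluster move together. `tcmix` is for analysts who want a
clustering that models both. Conditional on membership of component h, a
gene's profile over the m time points is

    y_j = X_h β_h + u_jh + v_h + ε_jh ,

where X_h β_h is a periodic first-order Fourier mean
a₀ + a₁ cos(2πt/ω_h) + b₁ sin(2πt/ω_h) (or a cubic B-spline mean for
non-periodic genes), u_jh ~ N(0, θ²_h A(ρ_h)) is a gene-specific random
effect with stationary AR(1) covariance A(ρ)[i,j] = ρ^|i−j|/(1−ρ²),
v_h ~ N(0, d²_h I) is a cluster random effect shared by all genes of the
component (the coregulation term), and ε_jh ~ N(0, σ²_h I) is measurement
error. The parameters are estimated by a closed-form EM that proceeds
conditionally on the estimated cluster effects; genes are assigned by
maximum posterior probability. The package also ships the two standard
comparison baselines (a mixture with AR(1) *residual* covariance θ²A(ρ)
only, and k-means), the misclassification/Rand/adjusted-Rand metrics, BIC
selection of the number of clusters, a global grid search over periods, and
a synthetic-data generator for the model's three canonical simulation
regimes. See `docs/methods.md` for the estimator details.

## Worked example

Simulate one dataset from the full-model regime (three clusters, periods
6/10/16, 24 time points, shared cluster effects), then fit the proposed
model and the AR(1)-residual baseline:

```python
import numpy as np
from tcmix import preset, generate, fit, fit_kim, compare_partitions

cfg = preset("t1", n_genes=400, seed=42)
ds = generate(cfg)

res = fit(ds.data, g=3, design=ds.true_model.design,
          init="true-partition", labels=ds.true_labels,
          periods=np.array(cfg.periods))
base = fit_kim(ds.data, g=3, design=ds.true_model.design, init=ds.true_model)

for name, r in [("full model", res), ("AR(1)-residual baseline", base)]:
    m = compare_partitions(ds.true_labels, r.labels)
    print(f"{name}: error {m.error_rate:.3f}  Rand {m.rand:.3f}  "
          f"adjusted Rand {m.adjusted_rand:.3f}")
```

prints

```
full model: error 0.005  Rand 0.993  adjusted Rand 0.987
AR(1)-residual baseline: error 0.100  Rand 0.857  adjusted Rand 0.713
```

The full model recovers the partition almost perfectly because its cluster
random effect captures the coherent shift shared by each cluster's genes;
the baseline, which models serial correlation but not coregulation,
misplaces ten percent of the genes. The fitted first component
(`res.model.components[0]`) reads
`p=0.587 beta=[0.21 1.09 0.30] theta2=0.49 rho=0.61 sigma2=1.01 d2=0.25`,
close to the generating values p=0.585, β=(0.3, 1.03, 0.06), θ²=0.5,
ρ=0.6, σ²=1, d²=0.4 — d² is the one parameter this estimator is known to
shrink.

The same operations are available from a shell:

```sh
tcmix simulate --preset t1 --n-genes 400 --replicates 1 --seed 42 --out sim/
tcmix fit --input sim/rep0000_matrix.tsv --g 3 --period 10 --init kmeans --out fit/
tcmix evaluate --true sim/rep0000_labels.tsv --pred fit/labels.tsv
tcmix replicate-study --preset t1 --replicates 100 --seed 1 --out study/
tcmix select --input matrix.tsv --g 4 --period-grid 60:90 --out sel/
```

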