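# psychae

Can an autoencoder replace PCA for establishing the construct validity of
a questionnaire when the sample is small and the item distributions are
skewed?  `psychae` is a Monte Carlo benchmark pipeline for that question,
aimed at psychometrics and health-measurement researchers.  It bundles:

- a generator of correlated multivariate **non-normal** item responses
  with controlled communality, skewness and kurtosis — Fleishman cubic
  margins Y = a + bZ + cZ² + dZ³ combined through pairwise intermediate
  correlations ρ solving
  r = ρ(b₁b₂+3b₁d₂+3d₁b₂+9d₁d₂) + ρ²(2c₁c₂) + ρ³(6d₁d₂)
  and a principal-component factor pattern F = V·diag(√λ);
- five dimension reducers with a common encode/reconstruct contract and a
  3-unit latent space: PCA, a simple linear autoencoder, a tied-weight
  autoencoder (decoder = encoder transpose), a 7-hidden-layer deep
  autoencoder, and an independent-feature autoencoder penalizing latent
  covariance and non-orthogonal weights;
- reconstruction metrics (MSE, MAE, and a sign-based normalized Euclidean
  distance) scored on held-out data;
- a factorial experiment driver (3 communality structures × 3
  non-normality scenarios × 27 sample sizes from 100 to 1000, replicated)
  with tidy results and mean/SD summary tables;
- a max-|weight| item-to-construct assignment workflow.

The population model is a 15-item instrument with three 5-item latent
blocks.  The high-communality structure (within-block r = 0.7, between
0.2) has spectrum {5.8, 2.8, 2.8, 0.3×12}, so rank-3 reconstruction of
standardized data has a closed-form error floor of 12·0.3/15 = 0.24 —
the package's built-in oracle for everything downstream.

## Worked example

```python
import numpy as np
from psychae import (SCENARIOS, ReducerConfig, fit_autoencoder, fit_pca,
                     generate, mse, standardize_apply, standardize_fit,
                     study_structures)

structure = study_structures()["high"]          # within 0.7 / between 0.2
dataset = generate(structure, SCENARIOS["s2"], n=2000, seed=11)  # skew 1, kurt 3

rng = np.random.default_rng(99)
perm = rng.permutation(2000)
test, train = dataset.data[perm[:400]], dataset.data[perm[400:]]
scaler = standardize_fit(train)
train, test = standardize_apply(scaler, train), standardize_apply(scaler, test)

pca = fit_pca(train, 3)
tied = fit_autoencoder(train, ReducerConfig("tied_ae", seed=5))
print(f"PCA  test MSE: {mse(test, pca.reconstruct(test)):.3f}")
print(f"tied test MSE: {mse(test, tied.reconstruct(test)):.3f}")
```

```
PCA  test MSE: 0.265
tied test MSE: 0.265
```

Both sit just above the 0.24 population floor: by the Eckart–Young
theorem a converged *linear* bottleneck-3 model can match PCA but never
beat it on a shared scale, and the tied autoencoder does exactly that to
three decimals.  (Reports of linear autoencoders far below the PCA floor
on the same data indicate the two algorithms were scored on different
preprocessing scales.)

The same objects drive the CLI:

```
psychae generate --structure high --scenario s2 --n 1000 --seed 7 --out data.csv
psychae run-grid --config configs/full_study.yaml --replicates 1 --out runs/
psychae assign --data data.csv --variant tied_ae --bottleneck 3 --seed 7 --out constructs.csv
```

`assign` classifies each item to the construct with its largest absolute
bottleneck weight.  On high-communality synthetic data the best
converged autoencoder recovers the three generating blocks for 15/15
items in every replicate of `analysis/03_construct_assignment.py`, while
unrotated PCA components structurally cannot separate all three blocks —
see `docs/methods.md` for the rotation-identifiability analysis.

## Analysis drivers

Numbered scripts under `analysis/` reproduce the study's tables at desk
scale and write CSVs under `results/`:

1. `01_generator_fidelity.py` — moment and correlation fidelity of the
   generator per structure × scenario (worst pairwise correlation error
   0.0076 at n = 200 000, within Monte Carlo noise).
2. `02_benchmark_reducers.py` — all five reducers over the full factorial
   at four sample sizes, with mean/SD summaries by communality and by
   normality (~3 min).
3. `03_construct_assignment.py` — block-recovery of the max-|weight|
   assignment across variants and replicates.

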