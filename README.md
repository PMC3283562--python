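# sparsesca

Sparse simultaneous component analysis (sparse SCA) for integrating
multiple data blocks measured on the same samples — for example a
GC-MS and an LC-MS metabolite table for the same set of fermentation
runs, or transcript and protein abundances for the same tissues.

Ordinary simultaneous component analysis extends PCA to several coupled
blocks `X_1 … X_K` (all `I × J_k`, shared samples) by forcing one set of
component scores. Interpreting its components means weighing every one
of the `Σ_k J_k` variables, which is hopeless for omics-scale data.
Sparse SCA shrinks most coefficients to exactly zero by penalized least
squares, with penalties that can respect the block structure.

## Model

With `X_c = [X_1 … X_K]` (columns mean-centered, unit norm), the
package estimates one of two penalized decompositions:

* **sparse weights** — minimize over `W_c` (sparse) and orthonormal `P_c`

  `‖X_c − X_c W_c P_cᵀ‖² + λ_L‖W_c‖₁ + λ_R‖W_c‖₂² + λ_G Σ_k ‖W_k‖₂ + λ_E Σ_k ‖W_k‖₁,₂²`

* **sparse loadings** — minimize over orthonormal `T` and sparse `P_c`

  `‖X_c − T P_cᵀ‖² + (the same penalties on P_c)`

The four penalties combine freely and yield the familiar sparse
approaches as special cases: lasso (`λ_L`), ridge (`λ_R`), elastic net,
group lasso (`λ_G`, mixed ℓ2,1: drops entire blocks), sparse group
lasso, and elitist (exclusive) lasso (`λ_E`, mixed ℓ1,2: selects within
every block, drops none). All λ = 0 recovers ordinary SCA; a single
block recovers (sparse) PCA.

Estimation alternates a closed-form orthogonal-Procrustes update of the
constrained factor with a majorization-minimization (MM) update of the
penalized factor, so the loss never increases. Tuning parameters can be
given directly or as fractions `f` of the ratio `‖X_c‖² / |W_ref|_{p,q}`
between maximal lack of fit and the penalty norm of the unpenalized
solution, which makes values comparable across penalties and data sets
(see `docs/methods.md`).

## Worked example

Generate a synthetic two-platform dataset (28 samples, 144 + 44
variables) whose true loadings are sparse *between* blocks — component
1 lives only in the second block, components 2–3 only in the first —
and recover that structure with a group-lasso penalized model:

```python
import numpy as np
from sparsesca import (SparseSCA, SimulationDesign, generate_base_matrix,
                       generate_dataset, preprocess, ordinary_sca,
                       lambda_from_fraction, aligned_classification_rate)

base = generate_base_matrix(seed=7)                # 28 x (144 + 44), two blocks
design = SimulationDesign(model_kind="loadings", structure="between",
                          sparsity=0.5, noise=0.30)
data, truth = generate_dataset(design, base, seed=42)
prep = preprocess(data)

W_ref, *_ = ordinary_sca(prep, 3)
lam_g = lambda_from_fraction(1.0, prep, W_ref, "group")
lam_r = lambda_from_fraction(1e-3, prep, W_ref, "ridge")
print(f"lambda_group = {lam_g:.3f}, lambda_ridge = {lam_r:.4f}")

est = SparseSCA(n_components=3, model="loadings", lambda_group=lam_g,
                lambda_ridge=lam_r, center_scale=False, tol=1e-10).fit(prep)
print(f"fit = {est.vaf_:.3f}, iterations = {est.n_iter_}, converged = {est.converged_}")
print("zero percentage per (block, component):")
print(est.report_.zero_summary.per_block_component_pct)
rate = aligned_classification_rate(truth.zero_pattern,
                                   np.abs(est.loadings_) <= 1e-8)
print(f"zero-pattern classification rate = {rate:.3f}")
```

prints

```
lambda_group = 5.175, lambda_ridge = 0.0627
fit = 0.480, iterations = 113, converged = True
zero percentage per (block, component):
[[  0.   0. 100.]
 [100. 100.   0.]]
zero-pattern classification rate = 1.000
```

The fitted model explains 48% of the variance with 30% of it being
noise, zeroes the first (144-variable) block on one component and the
second (44-variable) block on the other two, and classifies every
variable's selected/dropped status correctly.

`SparseSCA` follows the scikit-learn estimator protocol
(`fit`/`transform`/`inverse_transform`, `get_params`/`set_params`) and
composes with sklearn pipelines. A command line mirrors the library:

```sh
sparsesca fit data.csv --blocks blocks.yaml --model weights -R 5 \
    --f-lasso 0.5 --f-ridge 0.001 --f-group 0.1 --out results/
sparsesca grid data.csv --blocks blocks.yaml --preset lasso -R 5 --out grids/
sparsesca simulate --replicates 5 --seed 1 --out sim/
```

`fit` writes coefficients, scores and a JSON run summary; `grid` runs a
fraction grid for a named sparse approach plus the solution-selection
filters (drop all-zero components, low fit, insufficient per-block
sparsity); `simulate` runs the synthetic recovery study.

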