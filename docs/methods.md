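# Methods

## Model

Given K data blocks `X_k` (I samples × J_k variables) on a shared
sample mode, every column of the concatenated matrix
`X_c = [X_1 … X_K]` (p = Σ_k J_k columns) is mean-centered and scaled
to unit norm, so `‖X_c‖² = p` and no variable or block dominates by
scale alone. No further block weighting is applied. Constant columns
are an error rather than silently dropped: dropping would desynchronize
the block bookkeeping and the reported variable names.

Two penalized decompositions are estimated for a chosen number of
components R:

* **weights model** — `X_c ≈ X_c W_c P_cᵀ` with `P_cᵀP_c = I`; the
  sparse weights W_c give a regression-style reading of each component
  as a short weighted sum of variables;
* **loadings model** — `X_c ≈ T P_cᵀ` with `TᵀT = I`; the sparse
  loadings P_c are (approximately) correlations of variables with
  components, and a zero loading forces the reconstructed variable to
  zero.

The combined penalty on the coefficient matrix C (W_c or P_c) is

    λ_L ‖C‖₁  +  λ_R ‖C‖₂²  +  λ_G Σ_{k,r} s_k ‖c_kr‖₂
        +  λ_E Σ_{k,r} (Σ_{j∈k} |c_jkr|)²

where `c_kr` is block k's coefficient vector on component r. Group and
elitist structure is defined per (block, component) pair, not pooled
over components, so that individual components can drop a block — the
behavior the solution-selection filters rely on.

`s_k` is 1 by default (`group_size_scaling=False`). The classic
group-lasso block-size adjustment `s_k = √J_k` is available, but the
unweighted form is the default because it is the form the
majorization update actually implements in the original formulation of
this method, and it is the form under which the method's published
qualitative behavior (block recovery saturating around fraction
f_G ≈ 10, see below) reproduces. The fraction-based tuning always
measures the reference mixed ℓ2,1 norm with the √J_k weights
(the textbook definition), independent of the applied form.

The elitist (exclusive) lasso is implemented as the squared per-block
ℓ1 norm. Combining group and elitist penalties triggers a warning:
each interferes with the other's selection behavior.

## Algorithm

Alternating minimization with a guaranteed non-increasing loss:

1. initialize the penalized factor from the truncated SVD of `X_c`
   (additional multistarts perturb this start with seeded Gaussian
   noise of 0.1 × its root-mean-square);
2. update the constrained factor in closed form (orthogonal Procrustes):
   `P_c = V Uᵀ` from the SVD `U S Vᵀ` of `W_cᵀ X_cᵀ X_c`, or
   `T = V Uᵀ` from the SVD of `P_cᵀ X_cᵀ` — the trace-maximizing
   column-orthonormal factor;
3. stop when the loss decrease falls below `tol` (absolute, default
   1e-12; a relative criterion is optional) or after `max_iter`
   (default 5000) iterations;
4. update the penalized factor by one majorization-minimization step
   and return to 2.

Each non-smooth penalty term is majorized by a quadratic that touches
it at the current iterate, giving a diagonal surrogate matrix

    D_sup = (λ_L/2) D₁ + (λ_G/2) D₂ + λ_E D₃ + λ_R I

with `D₁ = 1/|c°|`, `D₂ = s_k/‖c°_kr‖`, `D₃ = (Σ_j |c°_jkr|)/|c°_jkr|`
evaluated at the supporting point. The weights update then solves, per
component r, the p×p system `(D_r + X_cᵀX_c) w_r = X_cᵀX_c p_r`
(the full Kronecker system is block diagonal, so R small solves
suffice); the loadings update is elementwise,
`p_jr = (X_cᵀT)_jr / (1 + d_jr)`. When the active variable count
exceeds 2I and the diagonal is positive, the weights solve goes through
the Woodbury identity (an I×I solve instead of p×p); both routes agree
to ~1e-15 and the choice is automatic (`use_woodbury="auto"`).

Numerical safeguards:

* MM denominators are floored at `epsilon_floor = 1e-10` (the exact
  majorizer is undefined at zero);
* coefficients whose magnitude falls below `freeze_threshold = 1e-9`
  are fixed at exactly zero for the remaining iterations (standard
  MM-for-ℓ1 practice; MM alone approaches zero only asymptotically);
* after convergence, magnitudes at or below `zero_threshold = 1e-8`
  are reported as exact zeros;
* the unpenalized weights model with p > I is refused with an error
  suggesting a ridge penalty: the system is underdetermined (at most I
  non-zero weights per component already fit perfectly, so the
  "solution" is arbitrary);
* reported components are ordered by decreasing explained variance and
  signed so each coefficient column's largest-magnitude entry is
  positive (the model is invariant to column permutation and sign, so a
  reporting convention is needed for reproducibility); SVD ties are
  accepted as returned by the backend.

Convexity of each conditional subproblem plus the sandwich inequality
makes the loss non-increasing; the fixed point can still be a local
minimum of the joint problem, hence the multistart option. With all
penalties zero the procedure reproduces the truncated-SVD solution
exactly. The fully unpenalized loadings model has a unique solution
even with p > I (no ridge needed); with sparsity penalties active the
joint problem is multimodal and multistarts genuinely matter.

## Fraction-based tuning and solution selection

Absolute λ values are hard to compare across penalties, so each is set
as `λ = f · ‖X_c‖² / |W_ref|` — the penalty's value is expressed as a
fraction f of the ratio between the maximal lack of fit (`‖X_c‖² = p`)
and the penalty norm of the ordinary SCA coefficients at the same R
(recomputed once per data set). Standard grids:
`{0, 1e-4, 1e-3, 1e-2, 0.1, 0.2, 0.5, 1}` for data analysis and
`{0, 1e-3, 0.1, 0.5, 10}` for the simulation study.

`filter_solutions` applies four independent rules to grid summaries:
drop solutions with (1) an all-zero component, (2) a component with
non-zero coefficients in more than one block (optional — it encodes a
substantive preference for platform-exclusive components, not part of
the method), (3) fit below 0.40, (4) any block less than 50% zero.

## Synthetic data generator

The generator emulates a two-platform metabolomics design: a base
matrix of 28 samples × (144 + 44) variables with correlated columns
(seeded rank-5 structure plus Gaussian noise, preprocessed). Each
dataset then follows the validation recipe literally: bootstrap the 28
rows; take the rank-3 SVD of the bootstrap sample; set true scores to
the left singular vectors and true coefficients to the right singular
vectors scaled by the singular values; impose zeros —

* *between* blocks: block 1 zeroed on component 1, block 2 on
  components 2–3;
* *within* blocks: a uniform random sample of round(sparsity · p · R)
  coefficient cells (sparsity 0.5 or 0.9), resampled (with a logged
  warning) if a whole component would vanish;
* *both*: the union of the two;

build the noiseless part as `T Cᵀ` (loadings kind) or `X_b C Vᵀ`
(weights kind, with the bootstrapped base as X and the orthonormal
right singular vectors as loadings — the singular-value scaling stays
on the coefficient matrix that carries the zero pattern); add Gaussian
noise with variance `σ² = q/(1−q) · ‖truth‖²/(I·p)` so the residual
accounts for a target fraction q (0.05 or 0.30) of the total variation.
The realized fraction is stored alongside the nominal one. The full
crossing — model kind × structure × sparsity × noise — gives 24
conditions; 5 replicates each give 120 datasets.

Recovery is scored as the proportion of coefficient cells whose
zero/non-zero status is classified correctly, after aligning estimated
to true components by the best column permutation (the decomposition is
permutation invariant; R = 3 gives 6 candidates).

What the generator does *not* emulate: real metabolite tables have
heavier-tailed intensities, block-specific noise, and correlated
(non-Gaussian) measurement error. Passing recovery checks on this
generator demonstrates that the penalties select the structure they are
designed for, not that any particular real data set will be recovered
at these rates.

## Recovery study protocol

The packaged study analyzes each dataset, after preprocessing, under
four approaches — lasso, group lasso, elitist lasso, sparse group lasso
(lasso fraction varying, group fraction fixed at 10) — over the
simulation f grid, each including a small ridge fraction (1e-3) so the
weights model is well posed at f = 0 with p > I. Grid cells use solver
settings tol 1e-6 / max_iter 400 (the defaults, 1e-12 / 5000, apply
everywhere else); these are the study's settings of record and all
reported rates derive from them. Summaries take, per approach, the
best-over-f median classification rate, excluding failed cells and
degenerate all-zero solutions (which trivially "classify" every
variable as dropped).

On this protocol (weights-kind generation, 30% noise, 5 replicates):
the group lasso recovers between-block structure best among the single
penalties; the elitist lasso recovers within-block structure (90%
zeros) best; the sparse group lasso leads for combined structure at 50%
sparsity, while at 90% sparsity the lasso and elitist lasso overtake
the group lasso; and analyzing with the weights model misclassifies
less than analyzing with the loadings model. These are the orderings
the acceptance tests assert; `scripts/acceptance.py` recomputes the
underlying rates.

## Known limitations

* One λ per penalty, shared by all components and blocks; per-component
  or per-block tuning is out of scope.
* No principled tuning-parameter selection (cross-validation,
  information criteria): grids plus the selection filters are the
  supported workflow.
* Weights-kind sparse structure is only weakly identified from the data
  (a dense loading matrix decouples the data's appearance from W's zero
  pattern), so recovery rates for weights-generated data plateau well
  below 1 even at low noise; the loadings model recovers its structure
  almost perfectly at low noise. Both behaviors are inherent to the
  models, not solver artifacts.
* The MM iteration has a linear convergence rate; tight tolerances on
  large problems can take thousands of iterations (each iteration is
  cheap).
* Missing data, categorical variables, and block weighting schemes are
  not handled.
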