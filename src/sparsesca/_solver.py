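"""Alternating Procrustes / majorization-minimization solver core.

Two penalized low-rank models of the concatenated data ``X_c`` (I
samples x p variables, p = sum_k J_k) are estimated:

* sparse weights:   minimize ||X_c - X_c W_c P_c'||^2 + penalties(W_c)
  with P_c' P_c = I;
* sparse loadings:  minimize ||X_c - T P_c'||^2 + penalties(P_c)
  with T' T = I.

Both alternate a closed-form orthogonal-Procrustes update of the
constrained factor (P_c, resp. T) with a majorization-minimization (MM)
update of the penalized factor.  The MM surrogate replaces the
non-smooth penalties by the quadratic built from
:func:`sparsesca.penalties.majorizer_diagonal`, so each update is a
linear solve (weights) or an elementwise scaling (loadings), and the
loss is non-increasing over iterations.

Coefficients whose magnitude falls below ``freeze_threshold`` are fixed
at exactly zero for the remaining iterations: the exact majorizer is
undefined at zero and this is the standard MM-for-l1 device.  The
per-component linear systems ``(D_r + X'X) w_r = X'X p_r`` are solved
directly, or through the Woodbury identity when the active variable
count is large relative to I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .blocks import BlockSpec, MultiBlockMatrix
from .penalties import PenaltyConfig, majorizer_diagonal, penalty_value

__all__ = [
    "SolverOptions",
    "FitReport",
    "ZeroSummary",
    "ordinary_sca",
    "update_orthogonal_P",
    "update_orthogonal_T",
    "update_weights",
    "update_loadings",
    "loss_weights",
    "loss_loadings",
    "fit_sparse_weights",
    "fit_sparse_loadings",
    "variance_accounted",
    "zero_pattern",
]


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings of the alternating algorithm.

    tol : absolute loss-difference stopping threshold (default 1e-12);
        set ``relative=True`` to use a relative criterion instead.
    max_iter : iteration cap (default 5000).
    n_starts : number of multistart runs; the first start is the
        truncated-SVD warm start, further starts perturb it with seeded
        Gaussian noise.
    seed : seed for the multistart perturbations.
    epsilon_floor : floor on MM denominators.
    zero_threshold : magnitudes at or below this are reported as exact
        zeros after convergence.
    freeze_threshold : magnitudes below this are frozen at zero during
        iterations.
    use_woodbury : "auto" (Woodbury when active variables > 2*I), "on",
        or "off".
    """

    tol: float = 1e-12
    max_iter: int = 5000
    n_starts: int = 1
    seed: int | None = None
    epsilon_floor: float = 1e-10
    zero_threshold: float = 1e-8
    freeze_threshold: float = 1e-9
    use_woodbury: str = "auto"
    relative: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.use_woodbury not in ("auto", "on", "off"):
            raise ValueError("use_woodbury must be 'auto', 'on' or 'off'")


@dataclass
class ZeroSummary:
    """Zero-pattern bookkeeping of a coefficient matrix."""

    pattern: np.ndarray  # boolean, True where coefficient is zero
    overall_pct: float
    per_component_pct: np.ndarray  # (R,)
    per_block_pct: np.ndarray  # (K,)
    per_block_component_pct: np.ndarray  # (K, R)
    per_component_counts: np.ndarray  # (R,) zero counts


@dataclass
class FitReport:
    """Diagnostics of one solver run."""

    loss_per_iteration: np.ndarray
    iterations: int
    converged: bool
    fit: float
    residual_ss: float
    zero_summary: ZeroSummary
    start_losses: np.ndarray
    best_start: int
    fit_clipped: bool = False


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, MultiBlockMatrix) else np.asarray(X, float)


def _blockspec(X, blocks) -> BlockSpec:
    if isinstance(X, MultiBlockMatrix):
        return X.blocks
    if blocks is None:
        return BlockSpec.from_sizes([np.asarray(X).shape[1]])
    return blocks


# ---------------------------------------------------------------------------
# ordinary (unpenalized) simultaneous component analysis


def ordinary_sca(X, R: int):
    """Truncated-SVD solution of the concatenated data.

    Returns ``(W, P, T, fit, singular_values)`` with ``W = P`` the top-R
    right singular vectors, ``T = X W`` the scores, and
    ``fit = sum_{r<=R} s_r^2 / sum_r s_r^2``.
    """
    values = _values(X)
    I, p = values.shape
    if not 1 <= R <= min(I, p):
        raise ValueError(f"R must be in [1, {min(I, p)}], got {R}")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    W = Vt[:R].T
    T = values @ W
    fit = float((s[:R] ** 2).sum() / (s**2).sum())
    return W, W.copy(), T, fit, s


# ---------------------------------------------------------------------------
# Procrustes updates


def _procrustes_from_M(M: np.ndarray) -> np.ndarray:
    """Maximizer of tr(M Q) over column-orthonormal Q, via Q = V U'."""
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return Vt.T @ U.T


def update_orthogonal_P(X, W) -> np.ndarray:
    """Optimal orthonormal loadings given weights: P = V U' from the SVD
    U S V' of ``M = W' X' X``; maximizes tr(M P)."""
    values = _values(X)
    W = np.asarray(W, float)
    M = W.T @ (values.T @ values)
    s = np.linalg.svd(M, compute_uv=False)
    if s.size and s[-1] < 1e-12 * max(1.0, s[0]):
        warnings.warn(
            "M = W'X'X is rank deficient; the Procrustes maximizer is not "
            "unique (requested components exceed rank)",
            UserWarning,
            stacklevel=2,
        )
    return _procrustes_from_M(M)


def update_orthogonal_T(X, P) -> np.ndarray:
    """Optimal orthonormal scores given loadings: T = V U' from the SVD
    of ``M = P' X'``; maximizes tr(P' X' T) with T'T = I."""
    values = _values(X)
    P = np.asarray(P, float)
    M = P.T @ values.T
    s = np.linalg.svd(M, compute_uv=False)
    if s.size and s[-1] < 1e-12 * max(1.0, s[0]):
        warnings.warn(
            "M = P'X' is rank deficient; the Procrustes maximizer is not "
            "unique (requested components exceed rank)",
            UserWarning,
            stacklevel=2,
        )
    return _procrustes_from_M(M)


# ---------------------------------------------------------------------------
# losses


def loss_weights(X, W, P, config: PenaltyConfig, blocks=None) -> float:
    """Generic sparse-weights objective:
    ``||X - X W P'||^2 + penalties(W)``."""
    values = _values(X)
    spec = _blockspec(X, blocks)
    W = np.asarray(W, float)
    P = np.asarray(P, float)
    resid = values - (values @ W) @ P.T
    return float((resid**2).sum()) + penalty_value(W, config, spec)


def loss_loadings(X, T, P, config: PenaltyConfig, blocks=None) -> float:
    """Generic sparse-loadings objective:
    ``||X - T P'||^2 + penalties(P)``."""
    values = _values(X)
    spec = _blockspec(X, blocks)
    T = np.asarray(T, float)
    P = np.asarray(P, float)
    resid = values - T @ P.T
    return float((resid**2).sum()) + penalty_value(P, config, spec)


# ---------------------------------------------------------------------------
# MM updates


def _solve_component(G, Xv, D_r, b_r, active, use_woodbury):
    """Solve (D_r + X'X) w = b restricted to the active variables."""
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return np.zeros(G.shape[0])
    d = D_r[idx]
    b = b_r[idx]
    I = Xv.shape[0]
    woodbury = use_woodbury == "on" or (
        use_woodbury == "auto" and idx.size > 2 * I and np.all(d > 0)
    )
    w = np.zeros(G.shape[0])
    if woodbury and np.all(d > 0):
        # (D + X'X)^-1 b = D^-1 b - D^-1 X' (I + X D^-1 X')^-1 X D^-1 b
        Xa = Xv[:, idx]
        dinv_b = b / d
        Xdinv = Xa / d[None, :]
        core = np.eye(I) + Xdinv @ Xa.T
        rhs = Xa @ dinv_b
        y = scipy.linalg.solve(core, rhs, assume_a="pos")
        w[idx] = dinv_b - Xdinv.T @ y
    else:
        A = G[np.ix_(idx, idx)] + np.diag(d)
        try:
            w[idx] = scipy.linalg.solve(A, b, assume_a="sym")
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                "singular MM system; add a ridge penalty (lambda_ridge > 0)"
            ) from exc
    return w


def update_weights(
    X,
    P,
    W_current,
    config: PenaltyConfig,
    blocks=None,
    epsilon_floor: float = 1e-10,
    active=None,
    use_woodbury: str = "auto",
) -> np.ndarray:
    """One MM update of the component weights at fixed orthonormal P.

    Solves, independently per component r, the surrogate's stationarity
    system ``(D_r + X'X) w_r = X'X p_r`` with ``D_r`` the component's
    slice of the majorizer diagonal evaluated at ``W_current``.  The
    optional boolean ``active`` mask holds frozen-at-zero coefficients
    fixed.  When the active variable count exceeds 2*I (and the diagonal
    is positive) the Woodbury identity is used; both routes agree to
    high precision.
    """
    values = _values(X)
    spec = _blockspec(X, blocks)
    P = np.asarray(P, float)
    W0 = np.asarray(W_current, float)
    if W0.ndim == 1:
        W0 = W0[:, None]
    if P.shape != W0.shape:
        raise ValueError("P and W_current must have the same shape")
    I, p = values.shape
    if config.is_unpenalized and p > I:
        raise np.linalg.LinAlgError(
            "the unpenalized weights model is underdetermined when the "
            "number of variables exceeds the number of samples; include a "
            "ridge penalty (lambda_ridge > 0)"
        )
    G = values.T @ values
    B = G @ P
    D = majorizer_diagonal(W0, config, spec, epsilon_floor=epsilon_floor)
    if active is None:
        active = np.ones_like(W0, dtype=bool)
    W = np.empty_like(W0)
    for r in range(W0.shape[1]):
        W[:, r] = _solve_component(G, values, D[:, r], B[:, r], active[:, r], use_woodbury)
    return W


def update_loadings(
    X,
    T,
    P_current,
    config: PenaltyConfig,
    blocks=None,
    epsilon_floor: float = 1e-10,
    active=None,
) -> np.ndarray:
    """One MM update of the loadings at fixed orthonormal scores T.

    Elementwise: ``p_jr = (X'T)_jr / (1 + d_jr)`` with ``d_jr`` the
    majorizer diagonal at ``P_current``; frozen coefficients stay zero.
    """
    values = _values(X)
    spec = _blockspec(X, blocks)
    T = np.asarray(T, float)
    P0 = np.asarray(P_current, float)
    if P0.ndim == 1:
        P0 = P0[:, None]
    C = values.T @ T
    if C.shape != P0.shape:
        raise ValueError("T and P_current shapes do not conform")
    D = majorizer_diagonal(P0, config, spec, epsilon_floor=epsilon_floor)
    P = C / (1.0 + D)
    if active is not None:
        P = np.where(active, P, 0.0)
    return P


# ---------------------------------------------------------------------------
# summaries


def variance_accounted(X, coefficients, P=None, T=None) -> tuple:
    """Variance accounted for: ``1 - ||X - Xhat||^2 / ||X||^2``.

    For the weights model pass ``coefficients=W`` and ``P``; for the
    loadings model pass ``coefficients=P_loadings`` and ``T``.  Returns
    ``(fit, clipped)`` where ``clipped`` flags a negative raw value.
    """
    values = _values(X)
    total = float((values**2).sum())
    if T is not None:
        recon = np.asarray(T, float) @ np.asarray(coefficients, float).T
    elif P is not None:
        recon = (values @ np.asarray(coefficients, float)) @ np.asarray(P, float).T
    else:
        raise ValueError("supply P (weights model) or T (loadings model)")
    raw = 1.0 - float(((values - recon) ** 2).sum()) / total
    return raw, raw < 0


def zero_pattern(coefficients, zero_threshold: float, blocks: BlockSpec) -> ZeroSummary:
    """Classify coefficients as zero (|value| <= threshold) and report
    zero percentages overall, per block, per component, and per
    (block, component) cell."""
    if zero_threshold < 0:
        raise ValueError("zero_threshold must be >= 0")
    C = np.asarray(coefficients, float)
    if C.ndim == 1:
        C = C[:, None]
    pattern = np.abs(C) <= zero_threshold
    K = blocks.n_blocks
    R = C.shape[1]
    per_bc = np.empty((K, R))
    per_b = np.empty(K)
    for k, s in enumerate(blocks.slices()):
        per_bc[k] = pattern[s, :].mean(axis=0) * 100.0
        per_b[k] = pattern[s, :].mean() * 100.0
    return ZeroSummary(
        pattern=pattern,
        overall_pct=float(pattern.mean() * 100.0),
        per_component_pct=pattern.mean(axis=0) * 100.0,
        per_block_pct=per_b,
        per_block_component_pct=per_bc,
        per_component_counts=pattern.sum(axis=0),
    )


# ---------------------------------------------------------------------------
# full fits


def _order_and_sign(coeffs, partner, score_norms):
    """Apply the reporting convention: columns sorted by decreasing
    explained variance, largest-magnitude coefficient entry positive.
    ``partner`` columns are permuted/flipped in lockstep so the
    reconstruction is unchanged."""
    order = np.argsort(-score_norms, kind="stable")
    coeffs = coeffs[:, order].copy()
    partner = partner[:, order].copy()
    for r in range(coeffs.shape[1]):
        col = coeffs[:, r]
        if col.any():
            j = np.argmax(np.abs(col))
            if col[j] < 0:
                coeffs[:, r] *= -1
                partner[:, r] *= -1
    return coeffs, partner, order


def _svd_start(values, R):
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    return U, s, Vt


def _multistart_inits(base, rng, n_starts):
    yield base
    scale = 0.1 * float(np.sqrt(np.mean(base**2))) or 0.1
    for _ in range(n_starts - 1):
        yield base + rng.normal(scale=scale, size=base.shape)


def fit_sparse_weights(X, config: PenaltyConfig, R: int, options: SolverOptions | None = None, blocks=None):
    """Estimate the sparse-weights model by alternating Procrustes and
    MM updates.

    Returns ``(W, P, report)``: W the (p x R) sparse weight matrix (with
    sub-threshold entries set to exact zero), P the orthonormal loading
    matrix, and a :class:`FitReport`.  With all penalties zero (and more
    samples than variables) the solution coincides with the truncated
    SVD.
    """
    options = options or SolverOptions()
    values = _values(X)
    spec = _blockspec(X, blocks)
    I, p = values.shape
    if not 1 <= R <= min(I, p):
        raise ValueError(f"R must be in [1, {min(I, p)}], got {R}")
    if config.is_unpenalized and p > I:
        raise np.linalg.LinAlgError(
            "the unpenalized weights model is underdetermined when the "
            "number of variables exceeds the number of samples; include a "
            "ridge penalty (lambda_ridge > 0)"
        )
    G = values.T @ values
    total_ss = float(np.trace(G))
    _, s, Vt = _svd_start(values, R)
    base_init = Vt[:R].T
    rng = np.random.default_rng(options.seed)

    best = None
    start_losses = []
    for start_idx, W in enumerate(_multistart_inits(base_init, rng, options.n_starts)):
        W = W.copy()
        active = np.ones_like(W, dtype=bool)
        losses = []
        converged = False
        P = None
        for _ in range(options.max_iter):
            # Step 2: Procrustes update of P
            P = _procrustes_from_M(W.T @ G)
            loss = _loss_weights_from_G(G, total_ss, W, P, config, spec)
            losses.append(loss)
            # Step 3: stop criterion on the loss difference
            if len(losses) >= 2:
                diff = losses[-2] - losses[-1]
                ref = abs(losses[-2]) if options.relative else 1.0
                if diff < options.tol * max(ref, np.finfo(float).tiny):
                    converged = True
                    break
            # Step 4: MM update of W
            D = majorizer_diagonal(W, config, spec, epsilon_floor=options.epsilon_floor)
            B = G @ P
            for r in range(R):
                W[:, r] = _solve_component(
                    G, values, D[:, r], B[:, r], active[:, r], options.use_woodbury
                )
            if not config.is_unpenalized:
                freeze = np.abs(W) < options.freeze_threshold
                W[freeze] = 0.0
                active &= ~freeze
        run = (losses[-1], start_idx, W, P, np.asarray(losses), converged)
        start_losses.append(losses[-1])
        if best is None or run[0] < best[0]:
            best = run

    _, best_start, W, P, losses, converged = best
    W[np.abs(W) <= options.zero_threshold] = 0.0
    score_norms = ((values @ W) ** 2).sum(axis=0)
    W, P, _ = _order_and_sign(W, P, score_norms)
    fit, clipped = variance_accounted(values, W, P=P)
    resid = values - (values @ W) @ P.T
    report = FitReport(
        loss_per_iteration=losses,
        iterations=len(losses),
        converged=converged,
        fit=fit,
        residual_ss=float((resid**2).sum()),
        zero_summary=zero_pattern(W, options.zero_threshold, spec),
        start_losses=np.asarray(start_losses),
        best_start=best_start,
        fit_clipped=clipped,
    )
    return W, P, report


def _loss_weights_from_G(G, total_ss, W, P, config, spec):
    WG = W.T @ G
    rss = total_ss - 2.0 * float(np.trace(WG @ P)) + float(np.sum((W.T @ G) * W.T))
    return rss + penalty_value(W, config, spec)


def fit_sparse_loadings(X, config: PenaltyConfig, R: int, options: SolverOptions | None = None, blocks=None):
    """Estimate the sparse-loadings model (orthonormal scores T, penalized
    loadings P).  Returns ``(T, P, report)``.

    Unlike the weights model this problem is well posed with more
    variables than samples even without a ridge penalty.
    """
    options = options or SolverOptions()
    values = _values(X)
    spec = _blockspec(X, blocks)
    I, p = values.shape
    if not 1 <= R <= min(I, p):
        raise ValueError(f"R must be in [1, {min(I, p)}], got {R}")
    total_ss = float((values**2).sum())
    U, s, Vt = _svd_start(values, R)
    base_init = Vt[:R].T * s[:R][None, :]
    rng = np.random.default_rng(options.seed)

    best = None
    start_losses = []
    for start_idx, P in enumerate(_multistart_inits(base_init, rng, options.n_starts)):
        P = P.copy()
        active = np.ones_like(P, dtype=bool)
        losses = []
        converged = False
        T = None
        for _ in range(options.max_iter):
            T = _procrustes_from_M(P.T @ values.T)
            loss = _loss_loadings_fast(values, total_ss, T, P, config, spec)
            losses.append(loss)
            if len(losses) >= 2:
                diff = losses[-2] - losses[-1]
                ref = abs(losses[-2]) if options.relative else 1.0
                if diff < options.tol * max(ref, np.finfo(float).tiny):
                    converged = True
                    break
            D = majorizer_diagonal(P, config, spec, epsilon_floor=options.epsilon_floor)
            P = (values.T @ T) / (1.0 + D)
            P[~active] = 0.0
            if not config.is_unpenalized:
                freeze = np.abs(P) < options.freeze_threshold
                P[freeze] = 0.0
                active &= ~freeze
        run = (losses[-1], start_idx, T, P, np.asarray(losses), converged)
        start_losses.append(losses[-1])
        if best is None or run[0] < best[0]:
            best = run

    _, best_start, T, P, losses, converged = best
    P[np.abs(P) <= options.zero_threshold] = 0.0
    contrib = (P**2).sum(axis=0)  # T orthonormal: SS explained per component
    P, T, _ = _order_and_sign(P, T, contrib)
    fit, clipped = variance_accounted(values, P, T=T)
    resid = values - T @ P.T
    report = FitReport(
        loss_per_iteration=losses,
        iterations=len(losses),
        converged=converged,
        fit=fit,
        residual_ss=float((resid**2).sum()),
        zero_summary=zero_pattern(P, options.zero_threshold, spec),
        start_losses=np.asarray(start_losses),
        best_start=best_start,
        fit_clipped=clipped,
    )
    return T, P, report


def _loss_loadings_fast(values, total_ss, T, P, config, spec):
    rss = total_ss - 2.0 * float(np.sum((values.T @ T) * P)) + float((P**2).sum())
    return rss + penalty_value(P, config, spec)
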