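"""Independent convex-solver oracle for penalized least-squares tests.

Minimizes, over a single coefficient vector w,

    w' A w - 2 b' w + lam_l ||w||_1
        + sum_k lam_g * s_k * ||w_k||_2 + lam_e * sum_k (sum_j |w_jk|)^2

with A symmetric PSD (the ridge is folded into A).  This covers both
one-component subproblems of the sparse SCA objectives at a fixed
orthonormal partner factor:

* weights model, fixed P:  A = X'X + lam_r I, b = X'X p;
* loadings model, fixed T: A = (1 + lam_r) I,  b = X' t.

Solved by FISTA (accelerated proximal gradient) with closed-form
proximal operators: soft-thresholding (lasso), per-block group
soft-thresholding, their composition (sparse group lasso), and the
exclusive-lasso prox computed by sorting.  This is deliberately a
different algorithmic route from the package's
majorization-minimization solver.
"""

from __future__ import annotations

import numpy as np


def soft_threshold(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def group_soft_threshold(v, t):
    """Prox of t*||.||_2 (one group)."""
    n = np.linalg.norm(v)
    if n <= t:
        return np.zeros_like(v)
    return (1.0 - t / n) * v


def exclusive_lasso_prox(v, mu):
    """Prox of mu * (sum_j |v_j|)^2 (one group).

    Solves min_u 0.5||u - v||^2 + mu*(sum|u|)^2.  The solution is
    u_j = sign(v_j) * max(|v_j| - 2*mu*S, 0) with S = sum|u| found by
    scanning the sorted magnitudes.
    """
    if mu == 0:
        return v.copy()
    a = np.abs(v)
    order = np.argsort(-a)
    a_sorted = a[order]
    csum = np.cumsum(a_sorted)
    S = 0.0
    m_used = 0
    for m in range(1, a.size + 1):
        S_m = csum[m - 1] / (1.0 + 2.0 * mu * m)
        upper = a_sorted[m - 1]
        lower = a_sorted[m] if m < a.size else 0.0
        if upper > 2.0 * mu * S_m >= lower:
            S, m_used = S_m, m
            break
    else:  # all shrink to zero only if v == 0
        S = csum[-1] / (1.0 + 2.0 * mu * a.size)
    return np.sign(v) * np.maximum(a - 2.0 * mu * S, 0.0)


def _prox(v, t, slices, lam_l, lam_g, lam_e, scales):
    if lam_e > 0 and (lam_l > 0 or lam_g > 0):
        raise ValueError("elitist prox not combined with lasso/group here")
    u = v
    if lam_l > 0:
        u = soft_threshold(u, t * lam_l)
    if lam_g > 0:
        u = u.copy()
        for k, s in enumerate(slices):
            u[s] = group_soft_threshold(u[s], t * lam_g * scales[k])
    if lam_e > 0:
        u = u.copy()
        for s in slices:
            u[s] = exclusive_lasso_prox(u[s], t * lam_e)
    return u


def objective(w, A, b, slices, lam_l, lam_g, lam_e, scales):
    val = float(w @ A @ w - 2.0 * b @ w)
    if lam_l:
        val += lam_l * np.abs(w).sum()
    if lam_g:
        for k, s in enumerate(slices):
            val += lam_g * scales[k] * np.linalg.norm(w[s])
    if lam_e:
        for s in slices:
            val += lam_e * np.abs(w[s]).sum() ** 2
    return val


def fista(
    A,
    b,
    slices,
    lam_l=0.0,
    lam_g=0.0,
    lam_e=0.0,
    scales=None,
    n_iter=50000,
    tol=1e-14,
):
    """FISTA minimizer of the penalized quadratic (see module docstring)."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    n = b.size
    if scales is None:
        scales = np.ones(len(slices))
    L = 2.0 * float(np.linalg.eigvalsh(A).max())
    if lam_e > 0:
        # the elitist term itself is smooth-ish but handled in the prox;
        # its curvature adds at most 2*lam_e*J per group to L via the
        # prox, no change needed (prox handles it exactly)
        pass
    step = 1.0 / L
    w = np.zeros(n)
    y = w.copy()
    t_acc = 1.0
    prev_obj = np.inf
    for it in range(n_iter):
        grad = 2.0 * (A @ y - b)
        w_new = _prox(y - step * grad, step, slices, lam_l, lam_g, lam_e, scales)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        y = w_new + ((t_acc - 1.0) / t_new) * (w_new - w)
        w, t_acc = w_new, t_new
        if it % 200 == 0:
            obj = objective(w, A, b, slices, lam_l, lam_g, lam_e, scales)
            if prev_obj - obj < tol * max(1.0, abs(obj)):
                # restart check: accept only if a plain prox step is a fixpoint
                g2 = 2.0 * (A @ w - b)
                w_chk = _prox(w - step * g2, step, slices, lam_l, lam_g, lam_e, scales)
                if np.max(np.abs(w_chk - w)) < 1e-10:
                    break
            prev_obj = obj
    return w
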