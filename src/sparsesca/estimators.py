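"""Scikit-learn style estimators for (sparse) simultaneous component
analysis.

:class:`OrdinarySCA` is the unpenalized model (a truncated SVD of the
column-concatenated blocks); :class:`SparseSCA` adds combinable lasso,
ridge, group-lasso and elitist-lasso penalties on either the component
weights or the loadings.  Both follow the sklearn transformer protocol
(``fit`` / ``transform`` / ``inverse_transform``, ``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and can be
placed in sklearn pipelines.

Input can be a plain array (one block), a :class:`~sparsesca.blocks.MultiBlockMatrix`,
or an array plus ``block_sizes``.  By default columns are mean-centered
and scaled to unit norm at fit time; the stored centers/scales are
reused by ``transform``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import _solver
from .blocks import BlockSpec, MultiBlockMatrix, preprocess
from ._solver import SolverOptions
from .penalties import PenaltyConfig

__all__ = ["OrdinarySCA", "SparseSCA"]


class _SCABase(TransformerMixin, BaseEstimator):
    def _resolve_input(self, X):
        """Return (values, BlockSpec) applying centering/scaling."""
        if isinstance(X, MultiBlockMatrix):
            mbm = X if X.preprocessed or not self.center_scale else preprocess(X)
            values, spec = mbm.values, mbm.blocks
            if self.center_scale and not X.preprocessed:
                raw = np.asarray(X.values, float)
                self.column_means_ = raw.mean(axis=0)
                self.column_scales_ = np.linalg.norm(raw - self.column_means_, axis=0)
            else:
                self.column_means_ = np.zeros(values.shape[1])
                self.column_scales_ = np.ones(values.shape[1])
            return values, spec
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValueError("X must be a 2-d array (samples x variables)")
        if not np.all(np.isfinite(values)):
            raise ValueError("X contains non-finite entries")
        if self.block_sizes is not None:
            spec = BlockSpec.from_sizes(self.block_sizes)
        else:
            spec = BlockSpec.from_sizes([values.shape[1]])
        if spec.n_columns != values.shape[1]:
            raise ValueError(
                f"block_sizes cover {spec.n_columns} columns but X has "
                f"{values.shape[1]}"
            )
        if self.center_scale:
            mbm = preprocess(MultiBlockMatrix(values, spec))
            raw = values
            self.column_means_ = raw.mean(axis=0)
            self.column_scales_ = np.linalg.norm(raw - self.column_means_, axis=0)
            return mbm.values, spec
        self.column_means_ = np.zeros(values.shape[1])
        self.column_scales_ = np.ones(values.shape[1])
        return values, spec

    def _apply_preprocessing(self, X):
        values = X.values if isinstance(X, MultiBlockMatrix) else np.asarray(X, float)
        return (values - self.column_means_) / self.column_scales_


class OrdinarySCA(_SCABase):
    """Unpenalized simultaneous component analysis (truncated SVD).

    Parameters
    ----------
    n_components : int
        Number of components R.
    block_sizes : sequence of int, optional
        Column partition (ignored when fitting a MultiBlockMatrix).
    center_scale : bool
        Center and unit-norm scale the columns at fit time.

    Attributes
    ----------
    weights_ : (p, R) ndarray — component weights W_c (= loadings here).
    loadings_ : (p, R) ndarray — loadings P_c.
    scores_ : (I, R) ndarray — component scores T = X W.
    explained_variance_ratio_fit_ : float — sum of top-R squared singular
        values over the total.
    singular_values_ : ndarray — all singular values of the data.
    """

    def __init__(self, n_components=2, block_sizes=None, center_scale=True):
        self.n_components = n_components
        self.block_sizes = block_sizes
        self.center_scale = center_scale

    def fit(self, X, y=None):
        values, spec = self._resolve_input(X)
        W, P, T, fit, s = _solver.ordinary_sca(values, self.n_components)
        self.blocks_ = spec
        self.weights_ = W
        self.loadings_ = P
        self.scores_ = T
        self.explained_variance_ratio_fit_ = fit
        self.singular_values_ = s
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        return self._apply_preprocessing(X) @ self.weights_

    def inverse_transform(self, T):
        check_is_fitted(self, "loadings_")
        scaled = np.asarray(T, float) @ self.loadings_.T
        return scaled * self.column_scales_ + self.column_means_


class SparseSCA(_SCABase):
    """Sparse simultaneous component analysis.

    Penalized low-rank decomposition of column-concatenated data blocks
    sharing a sample mode.  ``model="weights"`` penalizes the component
    weights W_c in ``X_c ~ X_c W_c P_c'`` (P_c orthonormal);
    ``model="loadings"`` penalizes the loadings P_c in ``X_c ~ T P_c'``
    (T orthonormal).  Estimation alternates a closed-form orthogonal
    Procrustes update with a majorization-minimization update, so the
    objective is non-increasing over iterations.

    Parameters
    ----------
    n_components : int
        Number of components R.
    model : {"weights", "loadings"}
    lambda_lasso, lambda_ridge, lambda_group, lambda_elitist : float
        Non-negative penalty tuning parameters.
    preset : str, optional
        Named sparse approach (see :data:`sparsesca.penalties.PRESETS`);
        validates that only that approach's penalties are active.
    group_size_scaling : bool
        Multiply each block's group-lasso term by sqrt(J_k).
    block_sizes : sequence of int, optional
    center_scale : bool
    tol, max_iter, n_starts, random_state, epsilon_floor,
    zero_threshold, use_woodbury :
        Solver settings; see :class:`sparsesca._solver.SolverOptions`.

    Attributes
    ----------
    weights_ : (p, R) ndarray or None — sparse W_c (weights model only).
    loadings_ : (p, R) ndarray — P_c (orthonormal for the weights model,
        sparse for the loadings model).
    scores_ : (I, R) ndarray — X W (weights model) or orthonormal T.
    report_ : FitReport — loss trajectory, fit, zero-pattern summary.
    vaf_ : float — variance accounted for.
    n_iter_ : int
    """

    def __init__(
        self,
        n_components=2,
        model="weights",
        lambda_lasso=0.0,
        lambda_ridge=0.0,
        lambda_group=0.0,
        lambda_elitist=0.0,
        preset=None,
        group_size_scaling=False,
        block_sizes=None,
        center_scale=True,
        tol=1e-12,
        max_iter=5000,
        n_starts=1,
        random_state=None,
        epsilon_floor=1e-10,
        zero_threshold=1e-8,
        use_woodbury="auto",
    ):
        self.n_components = n_components
        self.model = model
        self.lambda_lasso = lambda_lasso
        self.lambda_ridge = lambda_ridge
        self.lambda_group = lambda_group
        self.lambda_elitist = lambda_elitist
        self.preset = preset
        self.group_size_scaling = group_size_scaling
        self.block_sizes = block_sizes
        self.center_scale = center_scale
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.random_state = random_state
        self.epsilon_floor = epsilon_floor
        self.zero_threshold = zero_threshold
        self.use_woodbury = use_woodbury

    def _penalty_config(self) -> PenaltyConfig:
        return PenaltyConfig(
            lambda_lasso=self.lambda_lasso,
            lambda_ridge=self.lambda_ridge,
            lambda_group=self.lambda_group,
            lambda_elitist=self.lambda_elitist,
            group_size_scaling=self.group_size_scaling,
            preset=self.preset,
        )

    def _solver_options(self) -> SolverOptions:
        return SolverOptions(
            tol=self.tol,
            max_iter=self.max_iter,
            n_starts=self.n_starts,
            seed=self.random_state,
            epsilon_floor=self.epsilon_floor,
            zero_threshold=self.zero_threshold,
            use_woodbury=self.use_woodbury,
        )

    def fit(self, X, y=None):
        if self.model not in ("weights", "loadings"):
            raise ValueError("model must be 'weights' or 'loadings'")
        values, spec = self._resolve_input(X)
        config = self._penalty_config()
        options = self._solver_options()
        if self.model == "weights":
            W, P, report = _solver.fit_sparse_weights(
                values, config, self.n_components, options, blocks=spec
            )
            self.weights_ = W
            self.loadings_ = P
            self.scores_ = values @ W
        else:
            T, P, report = _solver.fit_sparse_loadings(
                values, config, self.n_components, options, blocks=spec
            )
            self.weights_ = None
            self.loadings_ = P
            self.scores_ = T
        self.blocks_ = spec
        self.report_ = report
        self.vaf_ = report.fit
        self.n_iter_ = report.iterations
        self.loss_path_ = report.loss_per_iteration
        self.converged_ = report.converged
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        """Project (preprocessed) data onto the components.

        Weights model: ``T = X W``.  Loadings model: least-squares
        scores ``X P (P'P)^-1``.
        """
        check_is_fitted(self, "loadings_")
        values = self._apply_preprocessing(X)
        if self.model == "weights":
            return values @ self.weights_
        P = self.loadings_
        return values @ (P @ np.linalg.pinv(P.T @ P))

    def inverse_transform(self, T):
        check_is_fitted(self, "loadings_")
        scaled = np.asarray(T, float) @ self.loadings_.T
        return scaled * self.column_scales_ + self.column_means_

    @property
    def sparse_coefficients_(self):
        """The penalized coefficient matrix (W_c or P_c)."""
        check_is_fitted(self, "loadings_")
        return self.weights_ if self.model == "weights" else self.loadings_
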