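"""Fraction-based tuning, penalty grids, and solution selection.

Absolute values of the tuning parameters are hard to set because their
effect depends on the scale of the data and of the unpenalized
solution.  Each lambda is therefore expressed as a fraction f of the
ratio between the maximal lack of fit and the maximal penalty value:

    lambda_{p,q} = f * ||X_c||^2 / |W_ref|_{p,q}

where ``|.|_{p,q}`` is the penalty's own (mixed) norm and ``W_ref`` is
the coefficient matrix of the ordinary (unpenalized) SCA solution at
the same number of components.  With preprocessed data ``||X_c||^2``
equals the column count.

:func:`run_grid` fits one model per point of a fraction grid and
summarizes fit and zero percentages; :func:`filter_solutions` applies
the selection rules used to sieve grid solutions: drop solutions with
an all-zero component, components spanning several blocks (optional),
fit below a floor (default 0.40), or insufficient per-block sparsity
(default 50% zeros).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _solver
from .blocks import BlockSpec, MultiBlockMatrix
from ._solver import SolverOptions
from .penalties import (
    PENALTY_IDS,
    PRESETS,
    PenaltyConfig,
    elitist_penalty,
    group_lasso_penalty,
    lasso_norm,
    ridge_norm_sq,
)

__all__ = [
    "F_GRID_DATA_ANALYSIS",
    "F_GRID_SIMULATION",
    "FractionGrid",
    "SolutionSummary",
    "reference_penalty_norm",
    "lambda_from_fraction",
    "run_grid",
    "filter_solutions",
    "summaries_to_frame",
]

# Fraction grid used for the metabolomics-style data analysis.
F_GRID_DATA_ANALYSIS = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 0.2, 0.5, 1.0)
# Coarser grid used in the simulation study.
F_GRID_SIMULATION = (0.0, 1e-3, 0.1, 0.5, 10.0)


def reference_penalty_norm(
    W_ref, penalty_id: str, blocks: BlockSpec, group_size_scaling: bool = True
) -> float:
    """The penalty's own norm of the reference coefficients."""
    if penalty_id == "lasso":
        return lasso_norm(W_ref)
    if penalty_id == "ridge":
        return ridge_norm_sq(W_ref)
    if penalty_id == "group":
        return group_lasso_penalty(W_ref, blocks, group_size_scaling)
    if penalty_id == "elitist":
        return elitist_penalty(W_ref, blocks)
    raise ValueError(f"unknown penalty id {penalty_id!r}")


def lambda_from_fraction(
    f: float,
    X,
    reference_coefficients,
    penalty_id: str,
    blocks: BlockSpec | None = None,
    group_size_scaling: bool = True,
) -> float:
    """Translate a fraction f into an absolute tuning parameter.

    ``lambda = f * ||X_c||^2 / |W_ref|_{p,q}`` with ``W_ref`` the
    ordinary-SCA coefficients.  ``f = 0`` maps to ``lambda = 0``
    regardless of the reference norm.

    For the group penalty the reference mixed l2,1 norm is, by default,
    the sqrt(J_k)-weighted sum of block norms (the textbook group-lasso
    definition), independent of whether the applied penalty carries the
    block-size factor.
    """
    if f < 0:
        raise ValueError("f must be >= 0")
    if f == 0:
        return 0.0
    if isinstance(X, MultiBlockMatrix):
        values, spec = X.values, X.blocks
    else:
        values = np.asarray(X, float)
        spec = blocks if blocks is not None else BlockSpec.from_sizes([values.shape[1]])
    norm = reference_penalty_norm(
        reference_coefficients, penalty_id, spec, group_size_scaling
    )
    if norm <= 0:
        raise ValueError(
            f"reference coefficients have zero {penalty_id} norm; cannot "
            "scale the tuning parameter"
        )
    total_ss = float((values**2).sum())
    return float(f) * total_ss / norm


@dataclass(frozen=True)
class FractionGrid:
    """Cartesian fraction grid for one named sparse approach.

    ``fractions`` maps each of the preset's active penalty ids to the f
    values to cross.  Penalties the preset does not activate stay 0.
    """

    preset: str
    fractions: dict
    model: str = "weights"
    n_components: int = 5

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.model not in ("weights", "loadings"):
            raise ValueError("model must be 'weights' or 'loadings'")
        allowed = set(PRESETS[self.preset])
        frac = {k: tuple(float(v) for v in vs) for k, vs in self.fractions.items()}
        extra = set(frac) - allowed
        if extra:
            raise ValueError(
                f"preset {self.preset!r} does not use penalties {sorted(extra)}"
            )
        for k, vs in frac.items():
            if any(v < 0 for v in vs):
                raise ValueError(f"negative fraction for {k!r}")
        object.__setattr__(self, "fractions", frac)

    def points(self):
        """Yield dicts mapping penalty id -> fraction, one per grid cell."""
        ids = [p for p in PENALTY_IDS if p in self.fractions]
        if not ids:
            yield {}
            return
        for combo in itertools.product(*(self.fractions[p] for p in ids)):
            yield dict(zip(ids, combo))


@dataclass
class SolutionSummary:
    """Fit and sparseness summary of one fitted grid cell."""

    preset: str
    model: str
    n_components: int
    fractions: dict
    lambdas: dict
    fit: float | None = None
    overall_zero_pct: float | None = None
    per_component_zero_counts: np.ndarray | None = None
    per_component_zero_pct: np.ndarray | None = None
    per_block_zero_pct: np.ndarray | None = None
    per_block_component_zero_pct: np.ndarray | None = None
    converged: bool | None = None
    iterations: int | None = None
    coefficients: np.ndarray | None = None
    error: str | None = None
    # selection flags, populated by filter_solutions
    has_all_zero_component: bool = False
    has_mixed_block_component: bool = False
    fit_below_threshold: bool = False
    insufficient_block_sparsity: bool = False

    @property
    def failed(self) -> bool:
        return self.error is not None


def run_grid(
    X,
    grid: FractionGrid,
    options: SolverOptions | None = None,
    blocks: BlockSpec | None = None,
    keep_coefficients: bool = True,
):
    """Fit one sparse SCA model per grid point and summarize each.

    The fraction-to-lambda scaling uses the ordinary SCA coefficients at
    the same R, computed once.  Per-cell solver failures are recorded in
    the summary's ``error`` field without aborting the remaining cells.
    """
    options = options or SolverOptions()
    if isinstance(X, MultiBlockMatrix):
        values, spec = X.values, X.blocks
    else:
        values = np.asarray(X, float)
        spec = blocks if blocks is not None else BlockSpec.from_sizes([values.shape[1]])
    W_ref, _, _, _, _ = _solver.ordinary_sca(values, grid.n_components)
    p = values.shape[1]

    summaries = []
    for point in grid.points():
        lambdas = {pid: 0.0 for pid in PENALTY_IDS}
        try:
            for pid, f in point.items():
                lambdas[pid] = lambda_from_fraction(
                    f, values, W_ref, pid, spec
                )
            config = PenaltyConfig(
                lambda_lasso=lambdas["lasso"],
                lambda_ridge=lambdas["ridge"],
                lambda_group=lambdas["group"],
                lambda_elitist=lambdas["elitist"],
            )
            if grid.model == "weights":
                C, _, report = _solver.fit_sparse_weights(
                    values, config, grid.n_components, options, blocks=spec
                )
            else:
                _, C, report = _solver.fit_sparse_loadings(
                    values, config, grid.n_components, options, blocks=spec
                )
            zs = report.zero_summary
            summaries.append(
                SolutionSummary(
                    preset=grid.preset,
                    model=grid.model,
                    n_components=grid.n_components,
                    fractions=dict(point),
                    lambdas=lambdas,
                    fit=report.fit,
                    overall_zero_pct=zs.overall_pct,
                    per_component_zero_counts=zs.per_component_counts.copy(),
                    per_component_zero_pct=zs.per_component_pct.copy(),
                    per_block_zero_pct=zs.per_block_pct.copy(),
                    per_block_component_zero_pct=zs.per_block_component_pct.copy(),
                    converged=report.converged,
                    iterations=report.iterations,
                    coefficients=C.copy() if keep_coefficients else None,
                )
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            summaries.append(
                SolutionSummary(
                    preset=grid.preset,
                    model=grid.model,
                    n_components=grid.n_components,
                    fractions=dict(point),
                    lambdas=lambdas,
                    error=str(exc),
                )
            )
    return summaries


def filter_solutions(
    summaries,
    fit_min: float = 0.40,
    block_zero_min: float = 0.50,
    block_exclusive: bool = True,
):
    """Apply the solution-selection rules; return the retained summaries.

    A solution is dropped when (1) any component has all coefficients
    zero, (2) any component has non-zero coefficients in more than one
    block (only when ``block_exclusive``), (3) its fit is below
    ``fit_min``, or (4) any block has a zero fraction below
    ``block_zero_min``.  Failed cells are always dropped.  Flags are set
    on every summary; the rules are independent so their order is
    immaterial.
    """
    retained = []
    for s in summaries:
        if s.failed:
            continue
        s.has_all_zero_component = bool(np.any(s.per_component_zero_pct >= 100.0 - 1e-12))
        nonzero_blocks = (s.per_block_component_zero_pct < 100.0 - 1e-12).sum(axis=0)
        s.has_mixed_block_component = bool(np.any(nonzero_blocks > 1))
        s.fit_below_threshold = bool(s.fit < fit_min)
        s.insufficient_block_sparsity = bool(
            np.any(s.per_block_zero_pct / 100.0 < block_zero_min)
        )
        drop = (
            s.has_all_zero_component
            or (block_exclusive and s.has_mixed_block_component)
            or s.fit_below_threshold
            or s.insufficient_block_sparsity
        )
        if not drop:
            retained.append(s)
    return retained


def summaries_to_frame(summaries):
    """Tabulate grid summaries (one row per cell) as a DataFrame."""
    import pandas as pd

    if not summaries:
        cols = ["preset", "model", "R"]
        for pid in PENALTY_IDS:
            cols += [f"f_{pid}", f"lambda_{pid}"]
        cols += ["fit", "zeros_pct", "converged", "error"]
        return pd.DataFrame(columns=cols)
    rows = []
    for s in summaries:
        row = {
            "preset": s.preset,
            "model": s.model,
            "R": s.n_components,
        }
        for pid in PENALTY_IDS:
            row[f"f_{pid}"] = s.fractions.get(pid, 0.0)
            row[f"lambda_{pid}"] = s.lambdas.get(pid, 0.0)
        row["fit"] = s.fit
        row["zeros_pct"] = s.overall_zero_pct
        if s.per_component_zero_counts is not None:
            for r, c in enumerate(s.per_component_zero_counts):
                row[f"zeros_C{r + 1}"] = int(c)
        row["converged"] = s.converged
        row["error"] = s.error
        rows.append(row)
    return pd.DataFrame(rows)
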