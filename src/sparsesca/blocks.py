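"""Coupled data blocks sharing a common sample mode.

Simultaneous component analysis operates on K data matrices
``X_1 ... X_K`` measured on the same I samples (e.g. a GC-MS and an
LC-MS metabolite table for the same fermentation runs).  The blocks are
held column-concatenated as ``X_c = [X_1 ... X_K]`` of size
``I x sum_k J_k`` together with a :class:`BlockSpec` recording which
columns belong to which block.

The preprocessing convention used throughout the package is that every
variable (column of ``X_c``) is mean-centered and scaled to unit
Euclidean norm, so that ``||X_c||^2`` equals the number of columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockSpec",
    "MultiBlockMatrix",
    "preprocess",
    "concatenate",
    "scores_from_weights",
]

_CENTER_TOL = 1e-10


@dataclass(frozen=True)
class BlockSpec:
    """Partition of concatenated columns into contiguous named blocks.

    Parameters
    ----------
    block_names : tuple of str
        One label per block (e.g. ``("GC-MS", "LC-MS")``).
    block_sizes : tuple of int
        Number of variables J_k in each block; all must be >= 1.
    """

    block_names: tuple
    block_sizes: tuple

    def __post_init__(self):
        names = tuple(str(n) for n in self.block_names)
        sizes = tuple(int(s) for s in self.block_sizes)
        object.__setattr__(self, "block_names", names)
        object.__setattr__(self, "block_sizes", sizes)
        if len(names) != len(sizes):
            raise ValueError(
                f"{len(names)} block names but {len(sizes)} block sizes"
            )
        if len(sizes) < 1:
            raise ValueError("at least one block is required")
        if any(s < 1 for s in sizes):
            raise ValueError(f"all block sizes must be >= 1, got {sizes}")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate block names: {names}")

    @classmethod
    def from_sizes(cls, sizes, names=None) -> "BlockSpec":
        sizes = tuple(int(s) for s in sizes)
        if names is None:
            names = tuple(f"block{k + 1}" for k in range(len(sizes)))
        return cls(tuple(names), sizes)

    @property
    def n_blocks(self) -> int:
        """K, the number of blocks."""
        return len(self.block_sizes)

    @property
    def n_columns(self) -> int:
        """Total number of variables, sum_k J_k."""
        return int(sum(self.block_sizes))

    @property
    def offsets(self) -> tuple:
        """Half-open 0-based column ranges, one ``(start, stop)`` per block."""
        stops = np.cumsum(self.block_sizes)
        starts = np.concatenate([[0], stops[:-1]])
        return tuple((int(a), int(b)) for a, b in zip(starts, stops))

    def slices(self) -> tuple:
        return tuple(slice(a, b) for a, b in self.offsets)

    def column_block_index(self) -> np.ndarray:
        """Block index (0-based) of every concatenated column."""
        return np.repeat(np.arange(self.n_blocks), self.block_sizes)


@dataclass
class MultiBlockMatrix:
    """Column-concatenated multi-block data ``X_c`` with its partition.

    Attributes
    ----------
    values : ndarray of shape (I, sum_k J_k)
    blocks : BlockSpec
    preprocessed : bool
        True when every column has mean 0 and unit norm.
    sample_ids, variable_names : optional label sequences carried through
        I/O; not used in computation.
    """

    values: np.ndarray
    blocks: BlockSpec
    preprocessed: bool = False
    sample_ids: tuple | None = None
    variable_names: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix (samples x variables)")
        if self.values.shape[1] != self.blocks.n_columns:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but the block "
                f"spec covers {self.blocks.n_columns}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in data matrix")
        if self.sample_ids is not None:
            self.sample_ids = tuple(self.sample_ids)
            if len(self.sample_ids) != self.values.shape[0]:
                raise ValueError("sample_ids length does not match row count")
        if self.variable_names is not None:
            self.variable_names = tuple(self.variable_names)
            if len(self.variable_names) != self.values.shape[1]:
                raise ValueError("variable_names length does not match columns")
        if self.preprocessed:
            _check_preprocessed(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def split(self) -> list:
        """Return the per-block matrices ``[X_1, ..., X_K]`` (views copied)."""
        return [self.values[:, s].copy() for s in self.blocks.slices()]


def _check_preprocessed(values: np.ndarray, tol: float = _CENTER_TOL) -> None:
    means = values.mean(axis=0)
    norms = np.linalg.norm(values, axis=0)
    if np.any(np.abs(means) > tol) or np.any(np.abs(norms - 1.0) > tol):
        raise ValueError(
            "matrix flagged preprocessed but columns are not centered "
            "to mean 0 / scaled to norm 1"
        )


def preprocess(X: MultiBlockMatrix) -> MultiBlockMatrix:
    """Center every column to mean 0 and scale it to unit norm.

    After preprocessing ``||X_c||_F^2`` equals the number of columns.
    Idempotent: preprocessing an already preprocessed matrix returns it
    unchanged (up to floating point).

    Raises
    ------
    ValueError
        If a column is constant (zero norm after centering), naming the
        offending column, or if the matrix has fewer than 2 rows.
    """
    values = np.asarray(X.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("preprocessing requires at least 2 samples")
    centered = values - values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    bad = np.flatnonzero(norms <= 1e-12 * max(1.0, float(np.abs(values).max())))
    if bad.size:
        j = int(bad[0])
        name = (
            X.variable_names[j]
            if X.variable_names is not None
            else f"column {j}"
        )
        raise ValueError(
            f"constant column cannot be scaled to unit norm: {name!r} "
            f"(index {j})"
        )
    return MultiBlockMatrix(
        centered / norms,
        X.blocks,
        preprocessed=True,
        sample_ids=X.sample_ids,
        variable_names=X.variable_names,
    )


def concatenate(blocks, names=None, sample_ids=None, variable_names=None) -> MultiBlockMatrix:
    """Concatenate per-block matrices ``[X_1 ... X_K]`` column-wise.

    All blocks must share the same number of rows (samples).
    ``MultiBlockMatrix.split`` round-trips the inputs exactly.
    """
    mats = [np.asarray(b, dtype=float) for b in blocks]
    if not mats:
        raise ValueError("at least one block is required")
    for i, m in enumerate(mats):
        if m.ndim != 2:
            raise ValueError(f"block {i} is not a 2-d matrix")
    row_counts = [m.shape[0] for m in mats]
    if len(set(row_counts)) != 1:
        raise ValueError(
            "blocks must share the same samples; got row counts "
            f"{row_counts}"
        )
    spec = BlockSpec.from_sizes([m.shape[1] for m in mats], names)
    return MultiBlockMatrix(
        np.hstack(mats),
        spec,
        sample_ids=sample_ids,
        variable_names=variable_names,
    )


def scores_from_weights(X: MultiBlockMatrix | np.ndarray, W: np.ndarray) -> np.ndarray:
    """Component scores ``T = X_c W_c`` from a weight matrix.

    ``W`` must have one row per concatenated variable and one column per
    component.
    """
    values = X.values if isinstance(X, MultiBlockMatrix) else np.asarray(X, float)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[0] != values.shape[1]:
        raise ValueError(
            f"weight matrix has {W.shape[0]} rows but data has "
            f"{values.shape[1]} variables"
        )
    return values @ W
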