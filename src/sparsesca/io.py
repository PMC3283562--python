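"""Readers and writers for matrices, block configurations and results.

Matrices travel as delimited text (CSV/TSV): first row variable names,
first column sample ids, remaining cells numeric.  Block definitions
are YAML or JSON mapping block name -> either a list of variable names
or a 1-based inclusive column range (``[start, end]`` or
``"start-end"``).  Output coefficients and scores are CSV, run
summaries JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blocks import BlockSpec, MultiBlockMatrix

__all__ = [
    "read_matrix",
    "read_block_config",
    "load_multiblock",
    "write_coefficients",
    "write_scores",
    "write_summary_json",
]


def read_matrix(path) -> pd.DataFrame:
    """Read a samples x variables matrix from delimited text.

    Delimiter is inferred from the extension (.tsv/.txt -> tab,
    otherwise comma).  The first column is taken as sample ids, the
    header row as variable names.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"matrix file {path} has no data columns")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"non-numeric cells in matrix file {path}: {exc}"
        ) from exc
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value in {path} at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return df


def read_block_config(path) -> dict:
    """Read a block definition (YAML or JSON by extension).

    Returns an ordered mapping block name -> list of variable names or
    ``(start, stop)`` 1-based inclusive column range.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(
            f"block config {path} must map block names to variable lists "
            "or column ranges"
        )
    out = {}
    for name, spec in raw.items():
        if isinstance(spec, str):
            try:
                start, stop = (int(x) for x in spec.split("-"))
            except ValueError as exc:
                raise ValueError(
                    f"block {name!r}: range string must look like '1-144', "
                    f"got {spec!r}"
                ) from exc
            out[str(name)] = (start, stop)
        elif (
            isinstance(spec, (list, tuple))
            and len(spec) == 2
            and all(isinstance(x, int) for x in spec)
        ):
            out[str(name)] = (int(spec[0]), int(spec[1]))
        elif isinstance(spec, (list, tuple)):
            out[str(name)] = [str(v) for v in spec]
        else:
            raise ValueError(
                f"block {name!r}: expected a variable-name list or a "
                f"1-based inclusive range, got {spec!r}"
            )
    return out


def load_multiblock(matrix_path, blocks_path) -> MultiBlockMatrix:
    """Load a matrix and its block definition into a MultiBlockMatrix.

    Columns are reordered so each block occupies a contiguous range in
    the order the config lists the blocks.
    """
    df = read_matrix(matrix_path)
    config = read_block_config(blocks_path)
    columns = []
    sizes = []
    names = []
    for name, spec in config.items():
        if isinstance(spec, tuple):
            start, stop = spec
            if not 1 <= start <= stop <= df.shape[1]:
                raise ValueError(
                    f"block {name!r}: range {start}-{stop} outside the "
                    f"matrix's {df.shape[1]} columns"
                )
            cols = list(df.columns[start - 1 : stop])
        else:
            missing = [v for v in spec if v not in df.columns]
            if missing:
                raise ValueError(
                    f"block {name!r}: variables not in matrix: {missing}"
                )
            cols = list(spec)
        columns.extend(cols)
        sizes.append(len(cols))
        names.append(name)
    if len(set(columns)) != len(columns):
        raise ValueError("blocks assign some columns more than once")
    data = df[columns]
    return MultiBlockMatrix(
        data.to_numpy(dtype=float),
        BlockSpec(tuple(names), tuple(sizes)),
        sample_ids=tuple(str(i) for i in df.index),
        variable_names=tuple(columns),
    )


def _variable_frame(X_blocks: BlockSpec, variable_names):
    block_col = [
        X_blocks.block_names[k] for k in X_blocks.column_block_index()
    ]
    if variable_names is None:
        variable_names = [f"v{j + 1}" for j in range(X_blocks.n_columns)]
    return list(variable_names), block_col


def write_coefficients(path, coefficients, blocks: BlockSpec, variable_names=None):
    """Write a (variables x components) coefficient matrix as CSV with
    block and variable labels."""
    C = np.asarray(coefficients, float)
    names, block_col = _variable_frame(blocks, variable_names)
    df = pd.DataFrame(
        C, columns=[f"C{r + 1}" for r in range(C.shape[1])]
    )
    df.insert(0, "block", block_col)
    df.insert(0, "variable", names)
    df.to_csv(path, index=False, float_format="%.12g")


def write_scores(path, scores, sample_ids=None):
    """Write a (samples x components) score matrix as CSV."""
    T = np.asarray(scores, float)
    ids = (
        list(sample_ids)
        if sample_ids is not None
        else [f"s{i + 1}" for i in range(T.shape[0])]
    )
    df = pd.DataFrame(
        T, index=pd.Index(ids, name="sample"),
        columns=[f"C{r + 1}" for r in range(T.shape[1])],
    )
    df.to_csv(path, float_format="%.12g")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_summary_json(path, summary: dict):
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
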