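"""Synthetic multi-block data with known sparse structure, and recovery
scoring.

The generator follows the validation design used for sparse SCA: a base
matrix plays the role of a real two-platform metabolite table (28
samples, 144 + 44 variables).  For each dataset, rows are bootstrapped
from the base, a rank-3 SVD provides true scores (left singular
vectors) and true coefficients (right singular vectors scaled by the
singular values), zeros are imposed on the coefficients according to a
structure condition, the noiseless data are built from the score-based
or weight-based model, and Gaussian noise is added so that the residual
accounts for a target fraction of the total variation.

Conditions cross model kind (weights / loadings) x structure (within /
between / both) x sparsity (50 / 90 percent zeros) x noise (5 / 30
percent): 24 conditions; with 5 replicates each, 120 datasets.
Recovery is scored as the proportion of coefficient cells whose
zero/non-zero status is correctly classified.

The base matrix itself is synthetic (the original metabolomics data are
not public): a seeded low-rank-plus-noise construction with correlated
columns, preprocessed to centered unit-norm columns.  Everything
downstream of the base follows the design literally.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from . import _solver
from .blocks import BlockSpec, MultiBlockMatrix, preprocess
from ._solver import SolverOptions
from .penalties import PenaltyConfig
from .tuning import F_GRID_SIMULATION, lambda_from_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "generate_base_matrix",
    "generate_dataset",
    "classification_rate",
    "aligned_classification_rate",
    "enumerate_conditions",
    "run_simulation_study",
    "DEFAULT_APPROACHES",
]

STRUCTURES = ("within", "between", "both")
MODEL_KINDS = ("weights", "loadings")
SPARSITY_LEVELS = (0.5, 0.9)
NOISE_LEVELS = (0.05, 0.30)


@dataclass(frozen=True)
class SimulationDesign:
    """One generative condition of the simulation study."""

    model_kind: str = "weights"
    structure: str = "within"
    sparsity: float = 0.5
    noise: float = 0.30
    n_samples: int = 28
    block_sizes: tuple = (144, 44)
    n_components: int = 3

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if not 0 < self.sparsity < 1:
            raise ValueError("sparsity must be in (0, 1)")
        if not 0 < self.noise < 1:
            raise ValueError("noise must be in (0, 1)")

    @property
    def n_variables(self) -> int:
        return int(sum(self.block_sizes))


@dataclass
class GroundTruth:
    """Everything needed to score recovery of one generated dataset."""

    design: SimulationDesign
    seed: int
    coefficients: np.ndarray  # (p, R) true weights or loadings, zeros imposed
    zero_pattern: np.ndarray  # boolean, True where the coefficient is zero
    scores: np.ndarray  # (I, R) true component scores
    partner: np.ndarray  # the unpenalized factor (P for weights kind, T for loadings)
    noiseless: np.ndarray  # (I, p) true data part
    noise_fraction_realized: float


def generate_base_matrix(
    n_samples: int = 28,
    block_sizes=(144, 44),
    seed: int = 0,
    rank: int = 5,
    noise_scale: float = 0.5,
) -> MultiBlockMatrix:
    """Seeded synthetic base matrix with correlated columns.

    A rank-``rank`` random structure plus Gaussian noise, preprocessed
    to centered unit-norm columns.  Stands in for the (undeposited)
    two-platform metabolite table that anchors the simulation design.
    """
    rng = np.random.default_rng(seed)
    spec = BlockSpec.from_sizes(block_sizes)
    p = spec.n_columns
    scores = rng.normal(size=(n_samples, rank))
    load = rng.normal(size=(rank, p))
    values = scores @ load + noise_scale * rng.normal(size=(n_samples, p))
    return preprocess(MultiBlockMatrix(values, spec))


def _between_mask(spec: BlockSpec, R: int) -> np.ndarray:
    """Between-block zero pattern: block 1 dropped from component 1,
    block 2 dropped from components 2..R."""
    mask = np.zeros((spec.n_columns, R), dtype=bool)
    slices = spec.slices()
    mask[slices[0], 0] = True
    if spec.n_blocks > 1:
        for r in range(1, R):
            mask[slices[-1], r] = True
    return mask


def _sample_within(rng, p: int, R: int, sparsity: float) -> np.ndarray:
    n_zero = int(round(sparsity * p * R))
    cells = rng.choice(p * R, size=n_zero, replace=False)
    mask = np.zeros(p * R, dtype=bool)
    mask[cells] = True
    return mask.reshape(p, R)


def generate_dataset(
    design: SimulationDesign,
    base: MultiBlockMatrix,
    seed: int,
    max_pattern_tries: int = 100,
):
    """Generate one dataset and its ground truth.

    Rows are bootstrapped from ``base``; a rank-R SVD of the bootstrap
    sample yields true scores (left singular vectors) and true
    coefficients (right singular vectors x singular values); zeros are
    imposed per the design's structure; the noiseless part is built from
    the score-based model (loadings kind, ``T C'``) or the weight-based
    model (weights kind, ``X_b C P'``); Gaussian noise is calibrated so
    the residual accounts for the design's noise fraction of the total
    variation.

    Returns ``(MultiBlockMatrix, GroundTruth)``.  The returned data are
    NOT preprocessed (preprocess before analysis).
    """
    if base.blocks.block_sizes != tuple(design.block_sizes):
        raise ValueError("base matrix blocks do not match the design")
    if base.n_samples != design.n_samples:
        raise ValueError("base matrix sample count does not match the design")
    rng = np.random.default_rng(seed)
    I, p, R = design.n_samples, design.n_variables, design.n_components
    boot = rng.integers(0, base.n_samples, size=I)
    Xb = base.values[boot]
    U, s, Vt = np.linalg.svd(Xb, full_matrices=False)
    V = Vt[:R].T
    C_full = V * s[:R][None, :]
    T_true = U[:, :R]

    for attempt in range(max_pattern_tries):
        if design.structure == "between":
            mask = _between_mask(base.blocks, R)
        elif design.structure == "within":
            mask = _sample_within(rng, p, R, design.sparsity)
        else:  # both
            mask = _between_mask(base.blocks, R) | _sample_within(
                rng, p, R, design.sparsity
            )
        if not np.any(mask.all(axis=0)):
            break
        logger.warning(
            "zero pattern left an entire component zero (attempt %d); "
            "resampling",
            attempt + 1,
        )
    else:
        raise RuntimeError("could not draw a zero pattern keeping all components")

    C = C_full.copy()
    C[mask] = 0.0

    if design.model_kind == "loadings":
        noiseless = T_true @ C.T
        scores = T_true
        partner = T_true
    else:
        noiseless = Xb @ C @ V.T
        scores = Xb @ C
        partner = V

    p_noise = design.noise
    ss_true = float((noiseless**2).sum())
    sigma2 = p_noise / (1.0 - p_noise) * ss_true / (I * p)
    E = rng.normal(scale=np.sqrt(sigma2), size=(I, p))
    ss_noise = float((E**2).sum())
    realized = ss_noise / (ss_true + ss_noise)
    data = MultiBlockMatrix(noiseless + E, base.blocks)
    truth = GroundTruth(
        design=design,
        seed=int(seed),
        coefficients=C,
        zero_pattern=mask,
        scores=scores,
        partner=partner,
        noiseless=noiseless,
        noise_fraction_realized=realized,
    )
    return data, truth


def classification_rate(true_pattern, estimated_pattern) -> float:
    """Proportion of coefficient cells whose zero/non-zero status agrees."""
    a = np.asarray(true_pattern, dtype=bool)
    b = np.asarray(estimated_pattern, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"pattern shapes differ: {a.shape} vs {b.shape}")
    return float((a == b).mean())


def aligned_classification_rate(true_pattern, estimated_pattern) -> float:
    """Classification rate under the best matching of components.

    The decomposition is invariant to column permutation, so the
    estimated components are aligned to the true ones by the column
    permutation that maximizes agreement before scoring.
    """
    a = np.asarray(true_pattern, dtype=bool)
    b = np.asarray(estimated_pattern, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"pattern shapes differ: {a.shape} vs {b.shape}")
    R = a.shape[1]
    best = 0.0
    for perm in itertools.permutations(range(R)):
        rate = float((a == b[:, list(perm)]).mean())
        best = max(best, rate)
    return best


def enumerate_conditions(
    replicates: int = 5,
    model_kinds=MODEL_KINDS,
    structures=STRUCTURES,
    sparsity_levels=SPARSITY_LEVELS,
    noise_levels=NOISE_LEVELS,
    **dims,
):
    """The full factorial crossing of the study conditions.

    Returns a list of ``(SimulationDesign, replicate_index)`` pairs:
    with the defaults, 24 conditions x 5 replicates = 120 entries.
    """
    out = []
    for mk, st, sp, no in itertools.product(
        model_kinds, structures, sparsity_levels, noise_levels
    ):
        design = SimulationDesign(
            model_kind=mk, structure=st, sparsity=sp, noise=no, **dims
        )
        for rep in range(replicates):
            out.append((design, rep))
    return out


def best_median_classification(
    results,
    by=("structure", "sparsity", "analysis_model", "approach"),
    degenerate_zero_pct: float = 99.95,
):
    """Best-over-f median classification rate per grouping cell.

    Rows with errors, and degenerate all-zero solutions (which trivially
    'classify' every variable as dropped), are excluded; the median over
    replicates is taken at each f, then the maximum over f.
    """
    ok = results[
        results["error"].isna() & (results["zeros_pct"] < degenerate_zero_pct)
    ]
    med = (
        ok.groupby(list(by) + ["f"])["classification_rate"].median().reset_index()
    )
    return med.groupby(list(by))["classification_rate"].max()


# Analysis approaches: penalty id -> how the grid fraction f is mapped.
# Every approach includes a small ridge fraction so the weights model is
# well posed at f = 0 with more variables than samples.
DEFAULT_APPROACHES = {
    "lasso": {"lasso": "f"},
    "group_lasso": {"group": "f"},
    "elitist_ridge": {"elitist": "f"},
    "sparse_group_lasso": {"lasso": "f", "group": 10.0},
}
DEFAULT_RIDGE_FRACTION = 1e-3


def _analysis_config(approach_spec, f, values, W_ref, spec, ridge_fraction):
    fractions = {"ridge": ridge_fraction}
    for pid, v in approach_spec.items():
        fractions[pid] = f if v == "f" else float(v)
    lambdas = {
        pid: lambda_from_fraction(frac, values, W_ref, pid, spec)
        for pid, frac in fractions.items()
    }
    config = PenaltyConfig(
        lambda_lasso=lambdas.get("lasso", 0.0),
        lambda_ridge=lambdas.get("ridge", 0.0),
        lambda_group=lambdas.get("group", 0.0),
        lambda_elitist=lambdas.get("elitist", 0.0),
    )
    return fractions, lambdas, config


def run_simulation_study(
    conditions=None,
    base: MultiBlockMatrix | None = None,
    fractions=F_GRID_SIMULATION,
    approaches=None,
    analysis_models=None,
    options: SolverOptions | None = None,
    seed: int = 0,
    zero_threshold: float = 1e-8,
):
    """Generate every dataset of ``conditions`` and analyze each under a
    grid of penalty approaches; score zero-pattern recovery.

    Parameters
    ----------
    conditions : list of (SimulationDesign, replicate), default the full
        120-dataset crossing from :func:`enumerate_conditions`.
    base : base matrix; generated from ``seed`` when omitted.
    fractions : f values of the analysis grid.
    approaches : mapping name -> penalty spec (see DEFAULT_APPROACHES).
    analysis_models : model kinds to analyze under; default: the same
        kind the dataset was generated under.
    options : solver settings for the per-cell fits.
    seed : master seed; per-dataset seeds are drawn from it.

    Returns a pandas DataFrame with one row per (dataset, analysis
    cell): condition fields, replicate, dataset seed, approach, f,
    analysis model, classification rate, fit, overall zero percent, and
    an error string for failed cells.
    """
    import pandas as pd

    if conditions is None:
        conditions = enumerate_conditions()
    if approaches is None:
        approaches = DEFAULT_APPROACHES
    options = options or SolverOptions()
    master = np.random.default_rng(seed)
    if base is None:
        base = generate_base_matrix(
            n_samples=conditions[0][0].n_samples,
            block_sizes=conditions[0][0].block_sizes,
            seed=int(master.integers(0, 2**31 - 1)),
        )

    rows = []
    for design, rep in conditions:
        ds_seed = int(master.integers(0, 2**31 - 1))
        data, truth = generate_dataset(design, base, ds_seed)
        prep = preprocess(data)
        values, spec = prep.values, prep.blocks
        R = design.n_components
        W_ref, _, _, _, _ = _solver.ordinary_sca(values, R)
        models = analysis_models or (design.model_kind,)
        for analysis_model in models:
            for name, approach_spec in approaches.items():
                for f in fractions:
                    record = {
                        "model_kind": design.model_kind,
                        "structure": design.structure,
                        "sparsity": design.sparsity,
                        "noise": design.noise,
                        "replicate": rep,
                        "dataset_seed": ds_seed,
                        "analysis_model": analysis_model,
                        "approach": name,
                        "f": f,
                        "classification_rate": np.nan,
                        "fit": np.nan,
                        "zeros_pct": np.nan,
                        "error": None,
                    }
                    try:
                        fracs, lambdas, config = _analysis_config(
                            approach_spec, f, values, W_ref, spec,
                            DEFAULT_RIDGE_FRACTION,
                        )
                        if analysis_model == "weights":
                            C, _, report = _solver.fit_sparse_weights(
                                values, config, R, options, blocks=spec
                            )
                        else:
                            _, C, report = _solver.fit_sparse_loadings(
                                values, config, R, options, blocks=spec
                            )
                        est_pattern = np.abs(C) <= zero_threshold
                        record["classification_rate"] = aligned_classification_rate(
                            truth.zero_pattern, est_pattern
                        )
                        record["fit"] = report.fit
                        record["zeros_pct"] = report.zero_summary.overall_pct
                    except (np.linalg.LinAlgError, ValueError) as exc:
                        record["error"] = str(exc)
                    rows.append(record)
    return pd.DataFrame(rows)
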