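"""Penalty terms and their majorization-minimization surrogate.

Four penalties can be combined on a coefficient matrix (component
weights W_c or loadings P_c), each tuned by a non-negative parameter:

* lasso (l1), ``lambda_L * sum |w|`` — selection and shrinkage of
  individual coefficients;
* ridge (squared l2), ``lambda_R * sum w^2`` — shrinkage only, groups
  correlated variables and regularizes underdetermined fits;
* group lasso (mixed l2,1), ``lambda_G * sum_{k,r} sqrt(J_k) ||w_kr||_2``
  — lasso across blocks, ridge within: drops whole blocks;
* elitist lasso (mixed l1,2), ``lambda_E * sum_{k,r} (sum_j |w_jkr|)^2``
  — lasso within blocks, ridge across: selects within every block.

Group and elitist structure is per (block, component) pair.  The
non-smooth penalties are handled by majorization: each is bounded above
by a quadratic in the coefficients that touches it at the current
iterate, giving a diagonal surrogate matrix

    D_sup = (lambda_L/2) D_1 + (lambda_G/2) D_2 + lambda_E D_3 + lambda_R I

whose (j, r) entry this module evaluates.  Denominators are floored at a
small epsilon because the exact majorizer is undefined at zero
coefficients; in the solver, coefficients that fall below a freezing
threshold are fixed at exactly zero instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blocks import BlockSpec

__all__ = [
    "PenaltyConfig",
    "PRESETS",
    "lasso_norm",
    "ridge_norm_sq",
    "group_lasso_penalty",
    "elitist_penalty",
    "penalty_value",
    "majorizer_diagonal",
    "surrogate_penalty_constant",
]

# Table of named sparse approaches: which penalties each activates.
PRESETS = {
    "lasso": ("lasso",),
    "elastic_net": ("lasso", "ridge"),
    "group_lasso": ("group",),
    "sparse_group_lasso": ("lasso", "group"),
    "sparse_group_lasso_ridge": ("lasso", "ridge", "group"),
    "elitist_lasso": ("elitist",),
    "elitist_ridge": ("elitist", "ridge"),
    "sca": (),
}

PENALTY_IDS = ("lasso", "ridge", "group", "elitist")


@dataclass(frozen=True)
class PenaltyConfig:
    """Tuning parameters for the combined penalty.

    Parameters
    ----------
    lambda_lasso, lambda_ridge, lambda_group, lambda_elitist : float
        Non-negative tuning parameters lambda_L, lambda_R, lambda_G,
        lambda_E.
    group_size_scaling : bool
        Include the sqrt(J_k) block-size factor in the applied
        group-lasso term.  Off by default: the majorization the solver
        implements applies the unweighted mixed l2,1 penalty, which is
        what reproduces the published behavior of the method; the
        weighted variant is available for users who want the classic
        group-lasso block-size adjustment.
    preset : str or None
        Name of the sparse approach these lambdas realize, if built via
        :meth:`from_preset`.
    """

    lambda_lasso: float = 0.0
    lambda_ridge: float = 0.0
    lambda_group: float = 0.0
    lambda_elitist: float = 0.0
    group_size_scaling: bool = False
    preset: str | None = None

    def __post_init__(self):
        for name in ("lambda_lasso", "lambda_ridge", "lambda_group", "lambda_elitist"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {v}")
            object.__setattr__(self, name, v)
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(
                    f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
                )
            active = self.active_penalties()
            expected = PRESETS[self.preset]
            if set(active) - set(expected):
                raise ValueError(
                    f"preset {self.preset!r} activates {expected}, but lambdas "
                    f"activate {active}"
                )
        if self.lambda_group > 0 and self.lambda_elitist > 0:
            warnings.warn(
                "combining the group lasso and elitist lasso penalties is "
                "not advised: their selection behaviors interfere",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_preset(cls, preset: str, group_size_scaling: bool = False, **lambdas) -> "PenaltyConfig":
        """Build a config for a named sparse approach.

        ``lambdas`` supplies values keyed by penalty id (``lasso``,
        ``ridge``, ``group``, ``elitist``); only the penalties the preset
        activates may be non-zero.
        """
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        allowed = PRESETS[preset]
        unknown = set(lambdas) - set(PENALTY_IDS)
        if unknown:
            raise ValueError(f"unknown penalty ids {sorted(unknown)}")
        for pid, v in lambdas.items():
            if pid not in allowed and float(v) != 0.0:
                raise ValueError(
                    f"penalty {pid!r} is not part of preset {preset!r}"
                )
        return cls(
            lambda_lasso=float(lambdas.get("lasso", 0.0)),
            lambda_ridge=float(lambdas.get("ridge", 0.0)),
            lambda_group=float(lambdas.get("group", 0.0)),
            lambda_elitist=float(lambdas.get("elitist", 0.0)),
            group_size_scaling=group_size_scaling,
            preset=preset,
        )

    def lambdas(self) -> dict:
        return {
            "lasso": self.lambda_lasso,
            "ridge": self.lambda_ridge,
            "group": self.lambda_group,
            "elitist": self.lambda_elitist,
        }

    def active_penalties(self) -> tuple:
        return tuple(pid for pid, v in self.lambdas().items() if v > 0)

    @property
    def is_unpenalized(self) -> bool:
        return all(v == 0.0 for v in self.lambdas().values())


def _as_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    return W


def _group_scale(blocks: BlockSpec, group_size_scaling: bool) -> np.ndarray:
    if group_size_scaling:
        return np.sqrt(np.asarray(blocks.block_sizes, dtype=float))
    return np.ones(blocks.n_blocks)


def lasso_norm(W) -> float:
    """l1 norm: sum of absolute values of all entries."""
    return float(np.abs(_as_matrix(W)).sum())


def ridge_norm_sq(W) -> float:
    """Squared l2 (Frobenius) norm: sum of squared entries."""
    W = _as_matrix(W)
    return float((W * W).sum())


def group_lasso_penalty(W, blocks: BlockSpec, group_size_scaling: bool = True) -> float:
    """Mixed l2,1 norm: sum over (block, component) of sqrt(J_k)*||w_kr||_2."""
    W = _as_matrix(W)
    scale = _group_scale(blocks, group_size_scaling)
    total = 0.0
    for k, s in enumerate(blocks.slices()):
        total += scale[k] * np.linalg.norm(W[s, :], axis=0).sum()
    return float(total)


def elitist_penalty(W, blocks: BlockSpec) -> float:
    """Mixed l1,2 norm: sum over (block, component) of (sum_j |w_jkr|)^2."""
    W = _as_matrix(W)
    total = 0.0
    for s in blocks.slices():
        total += (np.abs(W[s, :]).sum(axis=0) ** 2).sum()
    return float(total)


def penalty_value(W, config: PenaltyConfig, blocks: BlockSpec) -> float:
    """Total penalty sum with the config's lambdas applied."""
    W = _as_matrix(W)
    total = 0.0
    if config.lambda_lasso > 0:
        total += config.lambda_lasso * lasso_norm(W)
    if config.lambda_ridge > 0:
        total += config.lambda_ridge * ridge_norm_sq(W)
    if config.lambda_group > 0:
        total += config.lambda_group * group_lasso_penalty(
            W, blocks, config.group_size_scaling
        )
    if config.lambda_elitist > 0:
        total += config.lambda_elitist * elitist_penalty(W, blocks)
    return float(total)


def majorizer_diagonal(
    W_current,
    config: PenaltyConfig,
    blocks: BlockSpec,
    epsilon_floor: float = 1e-10,
) -> np.ndarray:
    """Diagonal D_sup of the quadratic penalty surrogate at ``W_current``.

    Entry (j, r) is

        (lambda_L/2)/|w_jr| + (lambda_G/2)*sqrt(J_k)/||w_kr||_2
        + lambda_E * (sum_{j' in k} |w_j'r|)/|w_jr| + lambda_R

    with every denominator floored at ``epsilon_floor``.  Terms whose
    lambda is zero contribute exactly 0 and perform no division.

    Returns an array of the same shape as ``W_current``.
    """
    W = _as_matrix(W_current)
    if epsilon_floor <= 0:
        raise ValueError("epsilon_floor must be positive")
    D = np.zeros_like(W)
    absW = np.abs(W)
    if config.lambda_lasso > 0:
        D += (config.lambda_lasso / 2.0) / np.maximum(absW, epsilon_floor)
    if config.lambda_group > 0:
        scale = _group_scale(blocks, config.group_size_scaling)
        for k, s in enumerate(blocks.slices()):
            gnorm = np.linalg.norm(W[s, :], axis=0)  # per component
            D[s, :] += (config.lambda_group / 2.0) * scale[k] / np.maximum(
                gnorm, epsilon_floor
            )[None, :]
    if config.lambda_elitist > 0:
        for s in blocks.slices():
            l1 = absW[s, :].sum(axis=0)  # per component
            D[s, :] += config.lambda_elitist * l1[None, :] / np.maximum(
                absW[s, :], epsilon_floor
            )
    D += config.lambda_ridge
    return D


def surrogate_penalty_constant(
    W_current, config: PenaltyConfig, blocks: BlockSpec
) -> float:
    """Additive constant making the quadratic surrogate touch the exact
    penalty at the supporting point.

    The surrogate penalty is ``sum_jr D_jr w_jr^2 + c`` with ``c`` the
    value returned here: (lambda_L/2)*||W°||_1 plus
    (lambda_G/2)*sum sqrt(J_k)||w°_kr||; the elitist and ridge terms need
    no constant.
    """
    W = _as_matrix(W_current)
    c = 0.0
    if config.lambda_lasso > 0:
        c += (config.lambda_lasso / 2.0) * lasso_norm(W)
    if config.lambda_group > 0:
        c += (config.lambda_group / 2.0) * group_lasso_penalty(
            W, blocks, config.group_size_scaling
        )
    return float(c)
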