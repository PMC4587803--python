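"""Canonical correlations between parameter groups and the MI-CCA similarity.

Two parameter groups A and B correspond to two sets of sensitivity columns,
i.e. two linear subspaces of observation space.  The canonical correlations
``1 >= rho_1 >= ... >= rho_m >= 0`` (m = min(|A|, |B|)) are the cosines of the
principal angles between those subspaces: ``rho_1`` is the largest achievable
cosine between a linear parameter combination drawn from A and one drawn from
B.  ``rho_1 = 1`` means some combination in A has an impact on the observables
identical to a combination in B (perfect compensation); ``rho_1 = 0`` means
the subspaces are orthogonal.

Under the asymptotic Gaussian posterior of the parameter estimates, the
mutual information between the estimate blocks is a function of the canonical
correlations alone; the similarity used here is

    I(A, B) = -(1/m) * sum_i log(1 - rho_i^2)     [nats]

which diverges as any ``rho_i -> 1``; values are capped by clipping
``rho_i`` at ``1 - 1e-12`` and flagged.  The dendrogram linkage height is the
normalised counterpart ``(1/m) * sum_i (1 - rho_i^2)`` in [0, 1].

Principal angles are computed from orthonormal bases (SVD of the cross-Gram
matrix), never from generalized eigenproblems on Fisher-matrix sub-blocks:
the latter is numerically treacherous for the ill-conditioned (sloppy)
matrices typical of biochemical models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import svd

from .sensitivity import SensitivityMatrix

__all__ = [
    "CcaResult",
    "canonical_correlations",
    "mutual_information",
    "linkage_height",
    "pairwise_cosine",
    "corr_with_rest",
    "RHO_CLIP",
    "RANK_TOL",
]

#: rho is clipped at 1 - RHO_CLIP before evaluating the (divergent) MI.
RHO_CLIP = 1e-12
#: singular values below RANK_TOL * s_max of a block are treated as rank noise.
RANK_TOL = 1e-10


def _resolve_group(S: SensitivityMatrix, group: Sequence) -> list[int]:
    idx = [S.param_index(g) for g in group]
    if len(idx) == 0:
        raise ValueError("parameter group must be non-empty")
    if len(set(idx)) != len(idx):
        raise ValueError("parameter group contains duplicates")
    return idx


def _orthonormal_basis(block: np.ndarray) -> tuple[np.ndarray, int]:
    """Rank-revealing orthonormal basis of the column span."""
    if block.size == 0:
        return np.empty((block.shape[0], 0)), 0
    U, s, _ = svd(block, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.empty((block.shape[0], 0)), 0
    rank = int(np.sum(s > RANK_TOL * s[0]))
    return U[:, :rank], rank


@dataclass
class CcaResult:
    """Ordered canonical correlations between two parameter groups."""

    rhos: np.ndarray
    group_a: list[str]
    group_b: list[str]
    rank_a: int
    rank_b: int
    dropped_zero_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rhos = np.asarray(self.rhos, dtype=float)

    @property
    def m(self) -> int:
        return self.rhos.size

    @property
    def rho1(self) -> float:
        return float(self.rhos[0]) if self.m else 0.0

    @property
    def capped(self) -> bool:
        return bool(np.any(self.rhos > 1.0 - RHO_CLIP))

    @property
    def mutual_information(self) -> float:
        return mutual_information(self)

    @property
    def linkage_height(self) -> float:
        return linkage_height(self)


def canonical_correlations(
    S: SensitivityMatrix,
    group_a: Sequence,
    group_b: Sequence,
    allow_overlap: bool = False,
) -> CcaResult:
    """Canonical correlations (principal-angle cosines) between two groups.

    Exactly ``m = min(|A|, |B|)`` values are returned, descending, each in
    [0, 1]; when the effective rank of a block is lower than its size the
    trailing values are zero-padded.  Zero sensitivity columns inside a group
    are dropped (with a warning) and the subspace of the remaining columns is
    used; two entirely-zero groups are an error.
    """
    ia = _resolve_group(S, group_a)
    ib = _resolve_group(S, group_b)
    if not allow_overlap and set(ia) & set(ib):
        raise ValueError("parameter groups overlap")
    m = min(len(ia), len(ib))

    norms = np.linalg.norm(S.values, axis=0)
    scale = norms.max() if norms.size else 0.0
    dropped = [
        S.param_names[i]
        for i in (*ia, *ib)
        if norms[i] <= RANK_TOL * max(scale, 1.0)
    ]
    if dropped:
        warnings.warn(
            f"zero sensitivity columns dropped from CCA: {sorted(set(dropped))}",
            RuntimeWarning,
            stacklevel=2,
        )
    ia_nz = [i for i in ia if S.param_names[i] not in dropped]
    ib_nz = [i for i in ib if S.param_names[i] not in dropped]
    if not ia_nz and not ib_nz:
        raise ValueError("both parameter groups have only zero sensitivity columns")

    Qa, ra = _orthonormal_basis(S.values[:, ia_nz])
    Qb, rb = _orthonormal_basis(S.values[:, ib_nz])
    if ra == 0 or rb == 0:
        rhos = np.zeros(m)
    else:
        s = svd(Qa.T @ Qb, compute_uv=False)
        s = np.clip(s, 0.0, 1.0)
        rhos = np.zeros(m)
        rhos[: min(m, s.size)] = np.sort(s)[::-1][: min(m, s.size)]
    return CcaResult(
        rhos,
        [S.param_names[i] for i in ia],
        [S.param_names[i] for i in ib],
        ra,
        rb,
        sorted(set(dropped)),
    )


def _rhos_and_m(result) -> tuple[np.ndarray, int]:
    if isinstance(result, CcaResult):
        return result.rhos, result.m
    rhos = np.atleast_1d(np.asarray(result, dtype=float))
    return rhos, rhos.size


def mutual_information(result) -> float:
    """MI-CCA similarity ``-(1/m) sum log(1 - rho_i^2)`` in nats.

    Accepts a :class:`CcaResult` or a bare array of canonical correlations.
    Each rho is clipped at ``1 - 1e-12`` first, so a perfectly compensated
    pair returns a large, finite sentinel value rather than infinity; check
    :attr:`CcaResult.capped` (or compare rhos against the clip) to detect it.
    """
    rhos, m = _rhos_and_m(result)
    if m == 0:
        return 0.0
    clipped = np.minimum(rhos, 1.0 - RHO_CLIP)
    return float(-np.sum(np.log1p(-clipped**2)) / m)


def linkage_height(result) -> float:
    """Dendrogram height ``(1/m) sum (1 - rho_i^2)``; 0 = fully compensated,
    1 = orthogonal."""
    rhos, m = _rhos_and_m(result)
    if m == 0:
        return 1.0
    return float(np.sum(1.0 - rhos**2) / m)


def pairwise_cosine(S: SensitivityMatrix, i, j) -> float:
    """Signed cosine between two sensitivity columns, ``cos(S_i, S_j)``.

    Similarity measures downstream use the absolute value (sign-opposite
    columns are maximally compensative); the signed value is what the Fisher
    matrix off-diagonals normalise to.
    """
    si = S.column(i)
    sj = S.column(j)
    ni, nj = np.linalg.norm(si), np.linalg.norm(sj)
    if ni == 0 or nj == 0:
        zero = S.param_names[S.param_index(i if ni == 0 else j)]
        raise ValueError(f"zero-norm sensitivity column for parameter {zero!r}")
    return float(np.clip(si @ sj / (ni * nj), -1.0, 1.0))


def corr_with_rest(S: SensitivityMatrix, i, rest: Sequence) -> float:
    """First canonical correlation of one parameter against a group.

    Equals |cos| of the angle between ``S_i`` and its orthogonal projection
    onto the span of the rest.  An empty rest gives 0; a zero-norm ``S_i``
    gives 0 with a warning (the sensitivity condition covers that case).
    """
    ii = S.param_index(i)
    rest_idx = _resolve_group(S, rest) if len(rest) else []
    if ii in rest_idx:
        raise ValueError("parameter may not be a member of its own rest group")
    if not rest_idx:
        return 0.0
    si = S.values[:, ii]
    if np.linalg.norm(si) == 0:
        warnings.warn(
            f"parameter {S.param_names[ii]!r} has zero sensitivity; "
            "correlation with the rest reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    res = canonical_correlations(S, [ii], rest_idx)
    return res.rho1
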