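"""LCS dissimilarities between state sequences, with normalized pooling.

For sequences x, y the dissimilarity is d(x, y) = |x| + |y| - 2·L(x, y),
where L is the length of their longest common (not necessarily contiguous)
subsequence. Compound states (e.g. ``RT``) are atomic symbols: no partial
credit between overlapping states. Distances are exact integers before
normalization.

Because the two quarterly dimensions (length 12, max raw distance 24) would
otherwise dominate the annual screening dimension (length 3, max raw
distance 6), each per-dimension matrix is min-max normalized individually
before the three are summed entrywise into the pooled matrix. The
normalization divides by the observed off-diagonal maximum with the minimum
fixed at the theoretical 0 — subtracting a positive observed minimum would
destroy the zero diagonal. Variants (subtracting the observed minimum, or
dividing by the theoretical maximum) are available for sensitivity
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequences import StateSequence


class DistanceError(ValueError):
    pass


class DegenerateDimensionWarning(UserWarning):
    """All pairwise distances in a dimension are zero."""


def lcs_length(x: Sequence, y: Sequence) -> int:
    """Length of the longest common subsequence of two state lists.

    Dynamic programming over the (|x|+1) x (|y|+1) grid.
    """
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        return 0
    prev = [0] * (ny + 1)
    for i in range(nx):
        cur = [0] * (ny + 1)
        xi = x[i]
        for j in range(ny):
            cur[j + 1] = prev[j] + 1 if xi == y[j] else max(cur[j], prev[j + 1])
        prev = cur
    return prev[ny]


def lcs_distance(x: Sequence, y: Sequence) -> int:
    """LCS dissimilarity |x| + |y| - 2·lcs_length(x, y)."""
    return len(x) + len(y) - 2 * lcs_length(x, y)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str  # "raw" | "normalized" | "pooled"
    dimension: str | None = None
    denominator: float | None = None  # normalization denominator, if any

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise DistanceError("values must be square and match labels")
        if not np.isfinite(v).all() or (v < 0).any():
            raise DistanceError("distances must be finite and nonnegative")
        if not np.allclose(v, v.T):
            raise DistanceError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise DistanceError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)


def _lcs_lengths_batch(X: np.ndarray, pair_i: np.ndarray, pair_j: np.ndarray) -> np.ndarray:
    """Vectorized LCS lengths for many pairs of equal-length coded sequences.

    ``X`` is (n_unique, L) integer codes; the DP recurrence runs over the
    L x L grid with all pairs advanced in lockstep.
    """
    L = X.shape[1]
    Xi, Yj = X[pair_i], X[pair_j]
    prev = np.zeros((len(pair_i), L + 1), dtype=np.int32)
    for i in range(L):
        cur = np.zeros_like(prev)
        xi = Xi[:, i : i + 1]
        for j in range(L):
            match = xi[:, 0] == Yj[:, j]
            cur[:, j + 1] = np.where(match, prev[:, j] + 1, np.maximum(cur[:, j], prev[:, j + 1]))
        prev = cur
    return prev[:, L]


def pairwise_distances(sequences: Sequence[StateSequence]) -> DistanceMatrix:
    """Raw LCS distance matrix over one dimension's sequences.

    All sequences must share the dimension and length. Computation
    deduplicates identical sequences and runs a vectorized DP over unique
    pairs, so cohorts with heavily repeated trajectories are cheap.
    """
    if len(sequences) == 0:
        raise DistanceError("no sequences")
    dims = {s.dimension for s in sequences}
    if len(dims) > 1:
        raise DistanceError(f"mixed dimensions: {sorted(dims)}")
    lengths = {len(s.states) for s in sequences}
    if len(lengths) > 1:
        raise DistanceError(f"mixed sequence lengths: {sorted(lengths)}")
    (L,) = lengths

    labels = tuple(s.patient_id for s in sequences)
    symbols = {sym: k for k, sym in enumerate(sorted({st for s in sequences for st in s.states}))}
    coded = np.array([[symbols[st] for st in s.states] for s in sequences], dtype=np.int16)

    uniq, inverse = np.unique(coded, axis=0, return_inverse=True)
    u = len(uniq)
    iu, ju = np.triu_indices(u, k=1)
    d_uniq = np.zeros((u, u))
    if len(iu) and L > 0:
        lcs = _lcs_lengths_batch(uniq, iu, ju)
        d = 2 * L - 2 * lcs
        d_uniq[iu, ju] = d
        d_uniq[ju, iu] = d
    values = d_uniq[np.ix_(inverse, inverse)]
    return DistanceMatrix(labels=labels, values=values, kind="raw",
                          dimension=sequences[0].dimension)


def minmax_normalize(
    m: DistanceMatrix,
    method: str = "observed_max",
    theoretical_max: float | None = None,
) -> DistanceMatrix:
    """Scale a raw matrix onto [0, 1].

    ``observed_max`` (default) divides by the largest off-diagonal entry,
    keeping 0 as the lower anchor. ``observed_range`` subtracts the
    observed off-diagonal minimum first (diagonal stays 0).
    ``theoretical_max`` divides by a supplied maximum attainable distance.
    A matrix with all-zero off-diagonal entries is returned unchanged with
    a :class:`DegenerateDimensionWarning`.
    """
    v = m.values.copy()
    off = ~np.eye(m.n, dtype=bool)
    if m.n < 2 or v[off].max() == 0:
        warnings.warn(
            f"dimension {m.dimension!r}: all pairwise distances are zero",
            DegenerateDimensionWarning,
            stacklevel=2,
        )
        return DistanceMatrix(m.labels, v, "normalized", m.dimension, denominator=None)

    if method == "observed_max":
        denom = float(v[off].max())
        v[off] = v[off] / denom
    elif method == "observed_range":
        lo, hi = float(v[off].min()), float(v[off].max())
        denom = hi - lo
        if denom == 0:
            warnings.warn(
                f"dimension {m.dimension!r}: constant off-diagonal distances",
                DegenerateDimensionWarning,
                stacklevel=2,
            )
            denom = hi
            v[off] = v[off] / denom
        else:
            v[off] = (v[off] - lo) / denom
    elif method == "theoretical_max":
        if theoretical_max is None or theoretical_max <= 0:
            raise DistanceError("theoretical_max must be a positive number")
        denom = float(theoretical_max)
        v = v / denom
    else:
        raise DistanceError(f"unknown normalization method {method!r}")
    return DistanceMatrix(m.labels, v, "normalized", m.dimension, denominator=denom)


def pool(matrices: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Entrywise sum of normalized per-dimension matrices.

    All matrices must share the same label order. Entries of the pooled
    matrix lie in [0, D] for D dimensions.
    """
    if len(matrices) == 0:
        raise DistanceError("nothing to pool")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise DistanceError("label order mismatch between pooled matrices")
    values = np.sum([m.values for m in matrices], axis=0)
    return DistanceMatrix(labels=labels, values=values, kind="pooled")
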