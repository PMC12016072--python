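"""Partitioning around medoids on a precomputed dissimilarity matrix,
plus the cluster-quality indices used for model selection.

The PAM implementation is the classic deterministic BUILD + SWAP scheme:

* BUILD greedily seeds medoids — the first medoid minimizes the total
  distance to all points, each further medoid maximizes the resulting cost
  reduction;
* SWAP repeatedly applies the single best improving (medoid, non-medoid)
  exchange until no exchange lowers the total cost.

All ties break toward the lowest index (lowest (medoid, candidate) pair in
SWAP), so results are reproducible across platforms. Candidate partitions
are scored with the average silhouette width (ASW, higher better), the
point-biserial correlation between distances and the different-cluster
indicator (higher better), and Hubert's C (lower better); the recommended
number of clusters maximizes ASW, with the full index table retained so a
human can weigh the other criteria and visual inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix


class ClusteringError(ValueError):
    pass


class DegenerateIndexWarning(UserWarning):
    """A quality index is undefined on this input (zero variance)."""


def _as_array(m) -> np.ndarray:
    if isinstance(m, DistanceMatrix):
        return m.values
    d = np.asarray(m, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ClusteringError("distance matrix must be square")
    return d


@dataclass(frozen=True)
class ClusterResult:
    k: int
    medoid_indices: tuple[int, ...]  # sorted ascending
    assignment: np.ndarray  # cluster label = position of medoid in medoid_indices
    total_cost: float

    @property
    def labels(self) -> np.ndarray:
        return self.assignment


def _assign(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment; ties go to the lowest medoid index."""
    sub = D[:, medoids]  # medoids sorted ascending, argmin takes first tie
    a = np.argmin(sub, axis=1)
    cost = float(sub[np.arange(len(D)), a].sum())
    return a, cost


def pam(m, k: int) -> ClusterResult:
    """Deterministic PAM clustering of a dissimilarity matrix.

    ``m`` is a :class:`DistanceMatrix` or square array; ``2 <= k < n``.
    """
    D = _as_array(m)
    n = len(D)
    if not (2 <= k < n):
        raise ClusteringError(f"k must satisfy 2 <= k < n={n}, got {k}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        d1 = D[:, medoids].min(axis=1)
        gain = np.maximum(d1[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = sorted(medoids)

    # SWAP: best single improving exchange, repeated
    eps = 1e-12
    while True:
        med = np.array(medoids)
        sub = D[:, med]
        order = np.argsort(sub, axis=1, kind="stable")
        d1 = sub[np.arange(n), order[:, 0]]
        n1 = order[:, 0]  # index into medoid list
        d2 = sub[np.arange(n), order[:, 1]]

        non = np.setdiff1d(np.arange(n), med)
        # contribution of each point j if candidate h is added and j's
        # medoid is NOT the one removed
        gain_other = np.minimum(D[:, non] - d1[:, None], 0.0)  # (n, |non|)
        col_sum = gain_other.sum(axis=0)

        best = (0.0, None)
        for i in range(len(med)):
            owned = n1 == i
            if owned.any():
                repl = (
                    np.minimum(D[np.ix_(owned, non)], d2[owned, None]) - d1[owned, None]
                ).sum(axis=0)
                delta = col_sum - gain_other[owned].sum(axis=0) + repl
            else:
                delta = col_sum
            j = int(np.argmin(delta))
            cand = (float(delta[j]), (int(med[i]), int(non[j])))
            if cand[0] < best[0] - eps or (
                best[1] is not None
                and abs(cand[0] - best[0]) <= eps
                and cand[1] < best[1]
            ):
                best = cand
        if best[1] is None or best[0] >= -eps:
            break
        out_m, in_h = best[1]
        medoids = sorted(set(medoids) - {out_m} | {in_h})

    assignment, cost = _assign(D, medoids)
    # medoids belong to their own cluster by construction (distance 0)
    return ClusterResult(k=k, medoid_indices=tuple(medoids), assignment=assignment,
                         total_cost=cost)


def _check_assignment(D: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    a = np.asarray(assignment)
    if len(a) != len(D):
        raise ClusteringError("assignment length does not match matrix")
    if len(np.unique(a)) < 2:
        raise ClusteringError("need at least 2 clusters")
    return a


def average_silhouette_width(m, assignment) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) over all points.

    a(i): mean distance to own cluster (excluding self); b(i): smallest
    mean distance to another cluster. Members of singleton clusters get
    s(i) = 0.
    """
    D = _as_array(m)
    a = _check_assignment(D, assignment)
    labels = np.unique(a)
    n = len(D)
    mean_to = np.zeros((n, len(labels)))
    sizes = np.zeros(len(labels), dtype=int)
    for li, lab in enumerate(labels):
        mask = a == lab
        sizes[li] = mask.sum()
        mean_to[:, li] = D[:, mask].sum(axis=1)
    own = np.searchsorted(labels, a)
    s = np.zeros(n)
    for i in range(n):
        li = own[i]
        if sizes[li] == 1:
            continue
        ai = mean_to[i, li] / (sizes[li] - 1)
        others = [mean_to[i, lj] / sizes[lj] for lj in range(len(labels)) if lj != li]
        bi = min(others)
        denom = max(ai, bi)
        s[i] = 0.0 if denom == 0 else (bi - ai) / denom
    return float(s.mean())


def point_biserial(m, assignment) -> float:
    """Pearson correlation between pairwise distances and the
    different-cluster indicator over all unordered pairs (higher better).

    Returns NaN with a warning when either vector has zero variance.
    """
    D = _as_array(m)
    a = _check_assignment(D, assignment)
    iu, ju = np.triu_indices(len(D), k=1)
    d = D[iu, ju]
    ind = (a[iu] != a[ju]).astype(float)
    if d.std() == 0 or ind.std() == 0:
        warnings.warn("point-biserial undefined: zero variance", DegenerateIndexWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(d, ind)[0, 1])


def huberts_c(m, assignment) -> float:
    """Hubert's C = (S_w - S_min) / (S_max - S_min), in [0, 1], lower better.

    S_w sums within-cluster pairwise distances; S_min / S_max sum the N_w
    globally smallest / largest off-diagonal distances, N_w = number of
    within-cluster pairs.
    """
    D = _as_array(m)
    a = _check_assignment(D, assignment)
    iu, ju = np.triu_indices(len(D), k=1)
    d = D[iu, ju]
    within = a[iu] == a[ju]
    nw = int(within.sum())
    if nw == 0:
        raise ClusteringError("no within-cluster pairs")
    sw = float(d[within].sum())
    d_sorted = np.sort(d)
    smin = float(d_sorted[:nw].sum())
    smax = float(d_sorted[-nw:].sum())
    if smax == smin:
        warnings.warn("Hubert's C undefined: constant distances", DegenerateIndexWarning,
                      stacklevel=2)
        return float("nan")
    return (sw - smin) / (smax - smin)


@dataclass(frozen=True)
class QualityProfile:
    """Quality indices across candidate cluster counts."""

    table: pd.DataFrame  # columns: k, asw, point_biserial, huberts_c
    recommended_k: int
    results: dict[int, ClusterResult]


def select_k(m, k_min: int = 2, k_max: int = 10) -> QualityProfile:
    """Run PAM and all three indices for each candidate k.

    ``recommended_k`` maximizes ASW (ties toward smaller k); the full table
    is retained so the other indices and visual inspection can inform the
    final choice.
    """
    D = _as_array(m)
    if not (2 <= k_min <= k_max < len(D)):
        raise ClusteringError(f"invalid k range [{k_min}, {k_max}] for n={len(D)}")
    rows, results = [], {}
    for k in range(k_min, k_max + 1):
        res = pam(D, k)
        results[k] = res
        rows.append(
            {
                "k": k,
                "asw": average_silhouette_width(D, res.assignment),
                "point_biserial": point_biserial(D, res.assignment),
                "huberts_c": huberts_c(D, res.assignment),
                "total_cost": res.total_cost,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["asw"].idxmax(), "k"])  # idxmax takes first tie
    return QualityProfile(table=table, recommended_k=best, results=results)
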