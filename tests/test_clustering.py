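"""PAM against exhaustive search, and the three quality indices against
independent textbook-formula recomputation."""

from itertools import combinations

import numpy as np
import pytest

from careseq import (
    average_silhouette_width,
    huberts_c,
    pam,
    point_biserial,
    select_k,
)
from careseq.clustering import ClusteringError


def random_distance_matrix(rng, n):
    """Random symmetric matrix with zero diagonal (Euclidean point cloud)."""
    pts = rng.random((n, 2)) * 10
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return d


def exhaustive_pam_cost(D, k):
    """Optimal k-medoid total cost by enumerating all medoid subsets."""
    n = len(D)
    best = np.inf
    for med in combinations(range(n), k):
        cost = D[:, med].min(axis=1).sum()
        best = min(best, cost)
    return best


def test_two_tight_pairs_get_one_medoid_each():
    # points 0,1 close together; 2,3 close together; pairs far apart
    D = np.array(
        [
            [0, 1, 10, 11],
            [1, 0, 11, 10],
            [10, 11, 0, 1],
            [11, 10, 1, 0],
        ],
        float,
    )
    res = pam(D, 2)
    assert {res.medoid_indices[0]} <= {0, 1} and {res.medoid_indices[1]} <= {2, 3}
    assert res.total_cost == exhaustive_pam_cost(D, 2) == 2.0
    assert (res.assignment[:2] == res.assignment[0]).all()
    assert res.assignment[0] != res.assignment[2]


def test_k_equals_n_rejected_and_n_minus_1_is_exhaustive_optimum(rng):
    D = random_distance_matrix(rng, 6)
    with pytest.raises(ClusteringError):
        pam(D, 6)
    res = pam(D, 5)
    assert res.total_cost == pytest.approx(exhaustive_pam_cost(D, 5))


def test_all_zero_matrix_ties_break_to_lowest_indices():
    D = np.zeros((5, 5))
    res = pam(D, 2)
    assert res.medoid_indices == (0, 1)
    assert res.total_cost == 0.0
    assert (res.assignment == 0).all()  # everyone ties to the lowest medoid


def no_improving_swap(D, medoids, total_cost):
    """Independent exhaustive check that no single exchange lowers the cost."""
    med = set(medoids)
    for m in med:
        for h in range(len(D)):
            if h in med:
                continue
            newm = sorted(med - {m} | {h})
            if D[:, newm].min(axis=1).sum() < total_cost - 1e-9:
                return False
    return True


def test_pam_output_is_swap_optimal_and_bounded_by_optimum(rng):
    """PAM terminates at a single-swap-optimal medoid set (its defining
    guarantee) whose cost can never undercut the exhaustive optimum."""
    for _ in range(60):
        n = int(rng.integers(5, 13))
        k = int(rng.integers(2, 4))
        D = random_distance_matrix(rng, n)
        res = pam(D, k)
        assert no_improving_swap(D, res.medoid_indices, res.total_cost)
        assert res.total_cost >= exhaustive_pam_cost(D, k) - 1e-9


def test_assignment_is_nearest_medoid_and_cost_consistent(rng):
    D = random_distance_matrix(rng, 20)
    res = pam(D, 3)
    med = np.array(res.medoid_indices)
    np.testing.assert_array_equal(res.assignment, np.argmin(D[:, med], axis=1))
    assert res.total_cost == pytest.approx(
        D[np.arange(20), med[res.assignment]].sum()
    )
    # medoids belong to their own cluster
    for pos, m in enumerate(med):
        assert res.assignment[m] == pos


# --- quality indices ------------------------------------------------------

HAND_D = np.array(
    [
        [0.0, 1.0, 6.0, 7.0, 8.0],
        [1.0, 0.0, 5.0, 6.5, 7.5],
        [6.0, 5.0, 0.0, 1.5, 2.0],
        [7.0, 6.5, 1.5, 0.0, 1.0],
        [8.0, 7.5, 2.0, 1.0, 0.0],
    ]
)
HAND_A = np.array([0, 0, 1, 1, 1])


def silhouette_direct(D, a):
    n = len(D)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if a[j] == a[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        ai = np.mean([D[i, j] for j in own])
        bi = min(
            np.mean([D[i, j] for j in range(n) if a[j] == lab])
            for lab in set(a) if lab != a[i]
        )
        vals.append((bi - ai) / max(ai, bi))
    return float(np.mean(vals))


def point_biserial_direct(D, a):
    d, ind = [], []
    n = len(D)
    for i in range(n):
        for j in range(i + 1, n):
            d.append(D[i, j])
            ind.append(1.0 if a[i] != a[j] else 0.0)
    d, ind = np.array(d), np.array(ind)
    return float(
        ((d - d.mean()) * (ind - ind.mean())).sum()
        / np.sqrt(((d - d.mean()) ** 2).sum() * ((ind - ind.mean()) ** 2).sum())
    )


def huberts_c_direct(D, a):
    pairs = [(D[i, j], a[i] == a[j]) for i in range(len(D)) for j in range(i + 1, len(D))]
    sw = sum(d for d, w in pairs if w)
    nw = sum(1 for _, w in pairs if w)
    ds = sorted(d for d, _ in pairs)
    smin, smax = sum(ds[:nw]), sum(ds[-nw:])
    return (sw - smin) / (smax - smin)


def test_indices_match_direct_formulas_on_hand_matrix():
    assert average_silhouette_width(HAND_D, HAND_A) == pytest.approx(
        silhouette_direct(HAND_D, HAND_A)
    )
    assert point_biserial(HAND_D, HAND_A) == pytest.approx(
        point_biserial_direct(HAND_D, HAND_A)
    )
    assert huberts_c(HAND_D, HAND_A) == pytest.approx(huberts_c_direct(HAND_D, HAND_A))


def test_indices_match_direct_formulas_on_random_matrices(rng):
    for _ in range(20):
        n = int(rng.integers(5, 9))
        D = random_distance_matrix(rng, n)
        a = rng.integers(0, 2, size=n)
        if len(np.unique(a)) < 2:
            continue
        assert average_silhouette_width(D, a) == pytest.approx(silhouette_direct(D, a))
        assert point_biserial(D, a) == pytest.approx(point_biserial_direct(D, a))
        if (a[:, None] == a[None]).sum() > n:  # has within pairs
            assert huberts_c(D, a) == pytest.approx(huberts_c_direct(D, a))


def test_asw_boundary_values():
    # two internally-zero, well-separated clusters -> ASW exactly 1
    D = np.array(
        [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], float
    )
    assert average_silhouette_width(D, [0, 0, 1, 1]) == 1.0
    # own cluster farther than the other -> negative ASW
    assert average_silhouette_width(D, [0, 1, 0, 1]) < 0


def test_huberts_c_boundary_values():
    D = np.array(
        [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], float
    )
    assert huberts_c(D, [0, 0, 1, 1]) == 0.0  # within pairs are globally smallest
    assert huberts_c(D, [0, 1, 0, 1]) == 1.0  # within pairs are globally largest


def test_point_biserial_boundary_and_degenerate():
    D = np.array(
        [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], float
    )
    assert point_biserial(D, [0, 0, 1, 1]) == pytest.approx(1.0)
    const = np.ones((4, 4)) - np.eye(4)
    with pytest.warns(UserWarning, match="zero variance"):
        assert np.isnan(point_biserial(const, [0, 0, 1, 1]))


def test_indices_invariant_to_label_permutation_and_scaling(rng):
    D = random_distance_matrix(rng, 8)
    a = np.array([0, 0, 1, 1, 2, 2, 1, 0])
    perm = np.array([2, 0, 1])[a]  # relabel clusters
    for f in (average_silhouette_width, point_biserial, huberts_c):
        assert f(D, a) == pytest.approx(f(D, perm))
        assert f(D, a) == pytest.approx(f(3.7 * D, a))


def test_select_k_recovers_planted_blob_count(rng):
    centers = np.array([[0, 0], [20, 0], [0, 20]])
    pts = np.vstack([c + rng.normal(0, 1.0, size=(12, 2)) for c in centers])
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    profile = select_k(D, 2, 6)
    assert profile.recommended_k == 3
    assert len(profile.table) == 5  # k_max - k_min + 1 rows


def test_swap_never_increases_cost(rng):
    """PAM's final cost never exceeds a BUILD-only greedy seeding cost."""
    for _ in range(20):
        D = random_distance_matrix(rng, 25)
        res = pam(D, 4)
        # greedy BUILD replication
        med = [int(np.argmin(D.sum(0)))]
        while len(med) < 4:
            d1 = D[:, med].min(1)
            gain = np.maximum(d1[:, None] - D, 0).sum(0)
            gain[med] = -np.inf
            med.append(int(np.argmax(gain)))
        build_cost = D[:, med].min(1).sum()
        assert res.total_cost <= build_cost + 1e-9
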