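"""Consensus multi-omic module detection: gap-statistic model selection
(firstSEmax), seeded PAM (k-medoids) ensembles, hard least-squares consensus of
membership matrices, and correlated-cluster merging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .synthetic_data import substream


@dataclass
class Partition:
    labels: pd.Series  # feature -> cluster id (0-based)
    medoids: list  # feature index positions, medoids[c] belongs to cluster c
    cost: float  # total within-cluster distance to medoids


@dataclass
class GapCurve:
    table: pd.DataFrame  # index k; columns gap, se, log_w
    chosen_k: int


@dataclass
class ConsensusResult:
    partition: pd.Series  # feature -> module id (0-based)
    coassignment: pd.DataFrame  # fraction of ensemble runs pairing two features
    merges: list = field(default_factory=list)  # (kept_id, absorbed_id, r)


# ---------------------------------------------------------------------------
# PAM (k-medoids), FastPAM1-style vectorized swap phase
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pam_swap_nb(D, medoids, max_iter):  # pragma: no cover - exercised via _pam_core
    n = D.shape[0]
    k = medoids.shape[0]
    nearest = np.zeros(n, dtype=np.int64)
    d1 = np.zeros(n)
    d2 = np.zeros(n)
    is_medoid = np.zeros(n, dtype=np.bool_)
    extra = np.zeros(k)
    for _ in range(max_iter):
        is_medoid[:] = False
        for j in range(k):
            is_medoid[medoids[j]] = True
        for i in range(n):
            best = np.inf
            second = np.inf
            bi = 0
            for j in range(k):
                d = D[i, medoids[j]]
                if d < best:
                    second = best
                    best = d
                    bi = j
                elif d < second:
                    second = d
            nearest[i] = bi
            d1[i] = best
            d2[i] = second
        best_delta = -1e-9
        bj = -1
        bh = -1
        for h in range(n):
            if is_medoid[h]:
                continue
            base = 0.0
            for j in range(k):
                extra[j] = 0.0
            for i in range(n):
                dih = D[i, h]
                c = dih - d1[i]
                m0 = c if c < 0.0 else 0.0
                base += m0
                t = (dih if dih < d2[i] else d2[i]) - d1[i] - m0
                extra[nearest[i]] += t
            for j in range(k):
                dlt = base + extra[j]
                if dlt < best_delta:
                    best_delta = dlt
                    bj = j
                    bh = h
        if bj < 0:
            break
        medoids[bj] = bh
        medoids[:] = np.sort(medoids)
    # final assignment and cost
    labels = np.zeros(n, dtype=np.int64)
    cost = 0.0
    for i in range(n):
        best = np.inf
        bi = 0
        for j in range(k):
            d = D[i, medoids[j]]
            if d < best:
                best = d
                bi = j
        labels[i] = bi
        cost += best
    return labels, medoids, cost


def _pam_core(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    """Seeded-start PAM on a precomputed distance matrix.

    Initial medoids are drawn uniformly from the rows (no BUILD phase); the
    swap phase evaluates every (medoid, candidate) exchange and applies the
    best strictly-improving one (steepest descent) until a local optimum.
    Equal-cost alternatives resolve to the lowest candidate index, making the
    procedure deterministic given the rng.
    """
    medoids = np.sort(rng.choice(D.shape[0], size=k, replace=False)).astype(np.int64)
    labels, medoids, cost = _pam_swap_nb(np.ascontiguousarray(D, dtype=np.float64), medoids, max_iter)
    return labels, medoids, float(cost)


def pam(X: pd.DataFrame | np.ndarray, k: int, seed: int = 0, D: np.ndarray | None = None) -> Partition:
    """PAM under Euclidean distance with medoids seeded from the data rows."""
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(values))
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= rows")
    if D is None:
        D = _euclidean_matrix(values)
    rng = substream(seed, "pam")
    labels, medoids, cost = _pam_core(D, k, rng)
    return Partition(labels=pd.Series(labels, index=index), medoids=list(medoids), cost=cost)


def _euclidean_matrix(values: np.ndarray) -> np.ndarray:
    sq = (values ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * values @ values.T
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return np.sqrt(D2)


def _within_ss(values: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to the medoids."""
    diffs = values - values[medoids[labels]]
    return float((diffs ** 2).sum())


# ---------------------------------------------------------------------------
# gap statistic with firstSEmax
# ---------------------------------------------------------------------------

def gap_select_k(
    X: pd.DataFrame | np.ndarray,
    kmax: int = 25,
    B: int = 100,
    seed: int = 0,
    kmin: int = 2,
    reference: str = "permute",
) -> GapCurve:
    """Gap curve over k = kmin..kmax with structure-preserving reference sets.

    References are built by independently permuting each column's values across
    rows ('permute', default) or by uniform sampling within each column's range
    ('uniform'). W is the within-cluster sum of squared Euclidean distances to
    the PAM medoids; gap(k) = mean_b log W_ref - log W_data and
    SE(k) = sd_b(log W_ref) * sqrt(1 + 1/B). The chosen k is the smallest one
    whose gap >= max gap - SE(argmax).
    """
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    n = len(values)
    if B < 1:
        raise ValueError("B must be >= 1")
    if kmax >= n:
        raise ValueError("kmax must be < rows")
    rng = substream(seed, "gap")
    refs = []
    for _ in range(B):
        if reference == "permute":
            ref = np.column_stack([rng.permutation(values[:, j]) for j in range(values.shape[1])])
        elif reference == "uniform":
            ref = np.column_stack(
                [
                    rng.uniform(values[:, j].min(), values[:, j].max(), size=n)
                    for j in range(values.shape[1])
                ]
            )
        else:
            raise ValueError(f"unknown reference scheme {reference!r}")
        refs.append((ref, _euclidean_matrix(ref)))
    D = _euclidean_matrix(values)

    ks = list(range(kmin, kmax + 1))
    gaps, ses, log_ws = [], [], []
    for k in ks:
        labels, medoids, _ = _pam_core(D, k, rng)
        log_w = np.log(_within_ss(values, labels, medoids))
        ref_log_w = np.empty(B)
        for b, (ref, Dref) in enumerate(refs):
            rl, rm, _ = _pam_core(Dref, k, rng)
            ref_log_w[b] = np.log(_within_ss(ref, rl, rm))
        gaps.append(ref_log_w.mean() - log_w)
        sd = ref_log_w.std(ddof=1) if B > 1 else 0.0
        ses.append(sd * np.sqrt(1.0 + 1.0 / B))
        log_ws.append(log_w)

    gaps = np.array(gaps)
    ses = np.array(ses)
    imax = int(np.argmax(gaps))
    threshold = gaps[imax] - ses[imax]
    chosen = ks[int(np.flatnonzero(gaps >= threshold)[0])]
    table = pd.DataFrame({"gap": gaps, "se": ses, "log_w": log_ws}, index=pd.Index(ks, name="k"))
    return GapCurve(table=table, chosen_k=chosen)


# ---------------------------------------------------------------------------
# hard least-squares consensus
# ---------------------------------------------------------------------------

def _match_member(member: np.ndarray, consensus: np.ndarray, k: int) -> np.ndarray:
    """Relabeling of member clusters maximizing agreement with the consensus."""
    cont = np.zeros((k, k))
    np.add.at(cont, (member, consensus), 1.0)
    rows, cols = linear_sum_assignment(-cont)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def consensus_objective(ensemble: list, consensus: np.ndarray, k: int) -> float:
    """Sum over members of ||C - B P||_F^2 between one-hot membership matrices,
    with each member's columns optimally matched to the consensus."""
    n = len(consensus)
    total = 0.0
    for member in ensemble:
        perm = _match_member(member, consensus, k)
        agree = int((perm[member] == consensus).sum())
        total += 2.0 * (n - agree)
    return total


def consensus(
    ensemble: list,
    k: int,
    restarts: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Hard least-squares consensus of an ensemble of k-cluster partitions.

    Finds the hard partition minimizing the summed squared Euclidean distance
    between membership matrices after per-member optimal column matching
    (assignment solved exactly). Optimized by alternating relabel/majority-vote
    from several starts (each a randomly chosen ensemble member, plus random
    label vectors if needed); the best objective wins. Label-permutation
    invariant; identical members are returned unchanged.
    """
    members = [np.asarray(m, dtype=int) for m in ensemble]
    if not members:
        raise ValueError("empty ensemble")
    n = len(members[0])
    for m in members:
        if len(m) != n:
            raise ValueError("ensemble members cover different feature sets")
        if m.max() >= k:
            raise ValueError("member labels exceed k")
    rng = substream(seed, "consensus")

    starts = []
    order = rng.permutation(len(members))
    for i in order[:restarts]:
        starts.append(members[i].copy())
    while len(starts) < restarts:
        starts.append(rng.integers(0, k, size=n))

    best_labels, best_obj = None, np.inf
    for start in starts:
        C = start.copy()
        for _ in range(100):
            votes = np.zeros((n, k))
            for member in members:
                perm = _match_member(member, C, k)
                votes[np.arange(n), perm[member]] += 1.0
            new_C = np.argmax(votes, axis=1)  # ties -> lowest label
            if np.array_equal(new_C, C):
                break
            C = new_C
        obj = consensus_objective(members, C, k)
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, C
    return best_labels


# ---------------------------------------------------------------------------
# full consensus module detection
# ---------------------------------------------------------------------------

def detect_modules(
    scaled: pd.DataFrame,
    k: int,
    n_inner: int = 100,
    n_outer: int = 25,
    restarts: int = 5,
    seed: int = 0,
) -> ConsensusResult:
    """Two-level consensus PAM ensemble.

    Outer loop: ``n_outer`` rounds of [``n_inner`` seeded PAM runs -> consensus];
    a final consensus combines the outer-round partitions. The co-assignment
    matrix accumulates pair frequencies over all n_inner * n_outer PAM runs.
    With n_inner = n_outer = 1 this reduces to a single PAM run.
    """
    values = scaled.to_numpy(dtype=float)
    index = scaled.index
    n = len(values)
    D = _euclidean_matrix(values)
    rng = substream(seed, "detect_modules")
    coassign = np.zeros((n, n))
    outer_partitions = []
    for _ in range(n_outer):
        inner = []
        for _ in range(n_inner):
            labels, _, _ = _pam_core(D, k, rng)
            inner.append(labels)
            coassign += labels[:, None] == labels[None, :]
        inner_cons = consensus(inner, k, restarts=restarts, seed=int(rng.integers(2 ** 31)))
        outer_partitions.append(inner_cons)
    final = consensus(outer_partitions, k, restarts=restarts, seed=int(rng.integers(2 ** 31)))
    coassign /= n_inner * n_outer
    return ConsensusResult(
        partition=pd.Series(final, index=index),
        coassignment=pd.DataFrame(coassign, index=index, columns=index),
    )


def merge_correlated(
    result: ConsensusResult,
    scaled: pd.DataFrame,
    r_threshold: float = 0.85,
) -> ConsensusResult:
    """Merge clusters whose mean condition-profiles are highly correlated.

    Average-linkage hierarchical clustering on distance 1 - r between cluster
    mean profiles, cut at height 1 - r_threshold; clusters within the same
    branch are combined (relabeled to the lowest member id). The merge record
    lists combined pairs with their correlations.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must lie in (0, 1)")
    labels = result.partition
    ids = sorted(labels.unique())
    if len(ids) < 2:
        return result
    profiles = np.vstack(
        [scaled.loc[labels.index[labels == c]].mean(axis=0).to_numpy() for c in ids]
    )
    R = np.corrcoef(profiles)
    dist = np.clip(1.0 - R, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    branches = fcluster(Z, t=1.0 - r_threshold, criterion="distance")

    mapping, merges = {}, []
    for branch in np.unique(branches):
        group = [ids[i] for i in np.flatnonzero(branches == branch)]
        keep = min(group)
        for c in group:
            mapping[c] = keep
        for c in group:
            if c != keep:
                merges.append((keep, c, float(R[ids.index(keep), ids.index(c)])))
    merged = labels.map(mapping)
    return ConsensusResult(
        partition=merged, coassignment=result.coassignment, merges=result.merges + merges
    )
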