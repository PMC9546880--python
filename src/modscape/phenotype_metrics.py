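"""Well-level phenotype quantification from single-cell tables and lineage
tracks: neighbor counts, CSR-normalized k-NN distances, mean-shift cluster
sizes, DAPI cell-cycle gating, EdU fractions, lineage migration, and the
treatment-comparison statistics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .synthetic_data import LineageSet, substream
from ._stats import bh_adjust


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def neighbor_counts(
    cells: pd.DataFrame, field: tuple, radius: float = 100.0
) -> tuple[pd.Series, float]:
    """Number of other cell centroids within ``radius`` of each focal cell.

    Focal cells closer than ``radius`` to any image border are excluded;
    neighbors may lie in the margin. Returns (per-focal-cell counts, well mean;
    NaN if no focal cells).
    """
    if cells.empty:
        return pd.Series(dtype=float), float("nan")
    w, h = float(field[0]), float(field[1])
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    interior = (
        (xy[:, 0] >= radius) & (xy[:, 0] <= w - radius)
        & (xy[:, 1] >= radius) & (xy[:, 1] <= h - radius)
    )
    if not interior.any():
        return pd.Series(dtype=float), float("nan")
    tree = cKDTree(xy)
    counts = tree.query_ball_point(xy[interior], r=radius, return_length=True) - 1
    series = pd.Series(counts, index=cells.index[interior])
    return series, float(series.mean())


def expected_knn_distance(lam: float, j: int) -> float:
    """E[distance to the j-th nearest neighbor] under CSR with intensity lam:
    Gamma(j + 1/2) / ((j-1)! * sqrt(lam * pi))."""
    if lam <= 0:
        raise ValueError("intensity must be > 0")
    return math.exp(gammaln(j + 0.5) - gammaln(j)) / math.sqrt(lam * math.pi)


def normalized_neighbor_distance(
    cells: pd.DataFrame, field: tuple, k: int = 4, margin: float = 100.0
) -> dict:
    """Mean k-NN distance of focal cells, normalized by its CSR expectation.

    observed: mean over focal (interior) cells of the mean distance to their k
    nearest neighbors. expected: the CSR k-NN mean E[r_j] averaged over
    j = 1..k at intensity lam = n / area. Two normalizations are returned:
    ``ratio`` (k-matched expectation, default) and ``ce1`` (observed divided by
    the 1-NN Clark-Evans expectation).
    """
    n = len(cells)
    if n <= k:
        raise ValueError("need more cells than k")
    w, h = float(field[0]), float(field[1])
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    interior = (
        (xy[:, 0] >= margin) & (xy[:, 0] <= w - margin)
        & (xy[:, 1] >= margin) & (xy[:, 1] <= h - margin)
    )
    if not interior.any():
        raise ValueError("no interior cells after margin exclusion")
    tree = cKDTree(xy)
    dists, _ = tree.query(xy[interior], k=k + 1)
    observed = float(dists[:, 1:].mean())
    lam = n / (w * h)
    expected_k = float(np.mean([expected_knn_distance(lam, j) for j in range(1, k + 1)]))
    expected_1 = expected_knn_distance(lam, 1)
    return {
        "observed": observed,
        "expected": expected_k,
        "ratio": observed / expected_k,
        "ce1": observed / expected_1,
    }


def mean_shift_cluster_size(
    cells: pd.DataFrame, bandwidth: float, tol: float = 1e-3, max_iter: int = 300
) -> tuple[np.ndarray, float]:
    """Flat-kernel mean shift on centroids; returns (labels, mean cells/cluster).

    Each point iterates to the mean of points within ``bandwidth`` until the
    shift falls below tol * bandwidth; converged modes within bandwidth / 2 are
    merged and points labelled by nearest mode.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if n == 0:
        return np.array([], dtype=int), float("nan")
    tree = cKDTree(xy)
    modes = xy.copy()
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        for i in idx:
            nbrs = tree.query_ball_point(modes[i], r=bandwidth)
            new = xy[nbrs].mean(axis=0)
            if np.linalg.norm(new - modes[i]) < tol * bandwidth:
                active[i] = False
            modes[i] = new
    # merge modes within bandwidth/2, greedily in index order
    centers: list[np.ndarray] = []
    labels = np.empty(n, dtype=int)
    for i in range(n):
        for c, ctr in enumerate(centers):
            if np.linalg.norm(modes[i] - ctr) < bandwidth / 2.0:
                labels[i] = c
                break
        else:
            centers.append(modes[i])
            labels[i] = len(centers) - 1
    mean_size = n / len(centers)
    return labels, float(mean_size)


def default_bandwidth(n: int, field: tuple) -> float:
    """2x the CSR 1-NN expected distance at the field's density."""
    lam = n / (float(field[0]) * float(field[1]))
    return 2.0 * expected_knn_distance(lam, 1)


# ---------------------------------------------------------------------------
# intensity gating
# ---------------------------------------------------------------------------

def _kmeans2_forgy(x: np.ndarray, rng: np.random.Generator, n_restarts: int = 10):
    """1-D 2-means with Forgy init (two distinct random data points), best of
    ``n_restarts`` by within-cluster sum of squares."""
    best = (np.inf, None)
    distinct = np.unique(x)
    for _ in range(n_restarts):
        if len(distinct) >= 2:
            c = rng.choice(distinct, size=2, replace=False).astype(float)
        else:
            c = np.array([distinct[0], distinct[0] + 1.0])
        for _ in range(100):
            assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
            new_c = c.copy()
            for g in (0, 1):
                if (assign == g).any():
                    new_c[g] = x[assign == g].mean()
            if np.allclose(new_c, c):
                break
            c = new_c
        inertia = float(((x - c[assign]) ** 2).sum())
        if inertia < best[0]:
            best = (inertia, (c.copy(), assign.copy()))
    return best[1]


def gate_cell_cycle(
    dapi_total: np.ndarray | pd.Series,
    n_nuclei: np.ndarray | pd.Series | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Gate cells into G1/G2M by 2-means on total DAPI intensity.

    Multinucleated cells (n_nuclei >= 2) are removed first and labelled '' in
    the output. The higher-mean cluster is G2M. Returns (labels aligned to the
    input, G2M fraction among gated cells). Emits a separation-quality warning
    when the 1-D silhouette of the split is below 0.5.
    """
    dapi = np.asarray(dapi_total, dtype=float)
    keep = np.ones(len(dapi), dtype=bool)
    if n_nuclei is not None:
        keep &= np.asarray(n_nuclei) < 2
    x = dapi[keep]
    if len(x) < 10:
        raise ValueError("need >= 10 gateable cells")
    if np.ptp(x) == 0:
        raise ValueError("constant DAPI values cannot be gated")
    rng = substream(seed, "gate_cell_cycle")
    centers, assign = _kmeans2_forgy(x, rng)
    g2m_cluster = int(np.argmax(centers))
    labels_kept = np.where(assign == g2m_cluster, "G2M", "G1")
    sil = _silhouette_two_groups(x, assign)
    if sil < 0.5:
        warnings.warn(f"weak DAPI bimodality (silhouette {sil:.2f}); gating may be unreliable")
    labels = np.full(len(dapi), "", dtype=object)
    labels[keep] = labels_kept
    frac = float((labels_kept == "G2M").mean())
    return labels, frac


def _silhouette_two_groups(x: np.ndarray, assign: np.ndarray) -> float:
    if len(np.unique(assign)) < 2:
        return 0.0
    D = np.abs(x[:, None] - x[None, :])
    s = np.empty(len(x))
    for g in (0, 1):
        mask = assign == g
        other = ~mask
        a = D[np.ix_(mask, mask)].sum(axis=1) / max(mask.sum() - 1, 1)
        b = D[np.ix_(mask, other)].mean(axis=1)
        s[mask] = (b - a) / np.maximum(a, b)
    return float(np.mean(s))


def edu_fraction(edu: np.ndarray | pd.Series, seed: int = 0) -> float:
    """Fraction EdU+ via 2-means on log intensity; positive = above the midpoint
    of the two cluster means."""
    x = np.log(np.asarray(edu, dtype=float) + 1e-9)
    if len(x) < 10:
        raise ValueError("need >= 10 cells")
    if np.ptp(x) == 0:
        return 0.0
    rng = substream(seed, "edu_fraction")
    centers, _ = _kmeans2_forgy(x, rng)
    midpoint = float(np.mean(centers))
    return float((x > midpoint).mean())


# ---------------------------------------------------------------------------
# lineage migration
# ---------------------------------------------------------------------------

def lineage_migration(lineages: LineageSet, seed: int = 0) -> pd.Series:
    """Accumulated path distance per founder lineage.

    Starting at each lineage's final frame, one terminal descendant is chosen
    uniformly at random (seeded) and traced back through mitotic parents to T0;
    the distance is the sum of stepwise Euclidean displacements along that path.
    Lineages without a path to frame 0 are excluded with a warning.
    """
    rng = substream(seed, "lineage_migration")
    tracks = lineages.tracks
    by_track = {tid: grp.sort_values("frame") for tid, grp in tracks.groupby("track_id")}
    parent_of = {tid: int(grp["parent_id"].iloc[0]) for tid, grp in by_track.items()}
    children: dict = {}
    for tid, pid in parent_of.items():
        if pid >= 0:
            children.setdefault(pid, []).append(tid)

    def founder_of(tid: int) -> int:
        while parent_of.get(tid, -1) >= 0:
            tid = parent_of[tid]
        return tid

    def terminals_of(tid: int) -> list:
        if tid not in children:
            return [tid]
        out = []
        for c in sorted(children[tid]):
            out.extend(terminals_of(c))
        return out

    founders = sorted(t for t, p in parent_of.items() if p < 0)
    result = {}
    for f in founders:
        if by_track[f]["frame"].iloc[0] != 0:
            warnings.warn(f"lineage {f} does not reach T0; excluded")
            continue
        term = terminals_of(f)
        chosen = term[int(rng.integers(len(term)))]
        path = []
        tid = chosen
        while True:
            grp = by_track[tid]
            path.append(grp[["frame", "x", "y"]])
            pid = parent_of[tid]
            if pid < 0:
                break
            tid = pid
        full = pd.concat(path[::-1]).drop_duplicates(subset="frame").sort_values("frame")
        xy = full[["x", "y"]].to_numpy(dtype=float)
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        result[f] = float(steps.sum())
    return pd.Series(result, name="migration_distance")


# ---------------------------------------------------------------------------
# well-level table + comparisons
# ---------------------------------------------------------------------------

def well_phenotypes(
    cells: pd.DataFrame,
    field: tuple,
    lineages: LineageSet | None = None,
    radius: float = 100.0,
    k: int = 4,
    bandwidth: float | None = None,
    seed: int = 0,
) -> pd.Series:
    """Assemble the per-well phenotype row from one cell table (one field)."""
    gated = cells[cells["n_nuclei"] < 2]
    labels, g2m = gate_cell_cycle(gated["dapi_total"].to_numpy(), seed=seed)
    nnd = normalized_neighbor_distance(cells, field, k=k, margin=radius)
    bw = bandwidth if bandwidth is not None else default_bandwidth(len(cells), field)
    _, mean_size = mean_shift_cluster_size(cells, bw)
    _, mean_neighbors = neighbor_counts(cells, field, radius=radius)
    row = {
        "cell_count": float(len(cells)),
        "edu_fraction": edu_fraction(cells["edu"].to_numpy(), seed=seed),
        "g2m_fraction": g2m,
        "mean_krt5": float(cells["krt5"].mean()),
        "mean_neighbors": mean_neighbors,
        "normalized_nn_distance": nnd["ratio"],
        "normalized_nn_distance_ce1": nnd["ce1"],
        "mean_cells_per_cluster": mean_size,
    }
    if lineages is not None:
        row["mean_migration"] = float(lineage_migration(lineages, seed=seed).mean())
    return pd.Series(row)


@dataclass
class PhenotypeComparison:
    overall_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p, q, significant
    method: str


def compare_phenotypes(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    mode: str = "ranks",
    q_max: float = 0.05,
) -> PhenotypeComparison:
    """Treatment comparison of one well-level phenotype.

    mode='ranks' (default): Kruskal-Wallis overall + pairwise Wilcoxon rank-sum
    with BH correction. mode='anova' (migration): one-way ANOVA + Tukey HSD.
    Groups with fewer than 3 wells are excluded with a warning.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    samples, names = [], []
    for name in pd.unique(g):
        x = v[g == name]
        if len(x) < 3:
            warnings.warn(f"group {name!r} has fewer than 3 wells; excluded")
            continue
        samples.append(x)
        names.append(name)
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 3 wells")

    if mode == "ranks":
        overall = float(stats.kruskal(*samples).pvalue)
        rows = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                p = float(stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided").pvalue)
                rows.append((names[i], names[j], p))
        pw = pd.DataFrame(rows, columns=["group_a", "group_b", "p"])
        pw["q"] = bh_adjust(pw["p"].to_numpy())
        method = "kruskal-wallis + pairwise wilcoxon (BH)"
    elif mode == "anova":
        overall = float(stats.f_oneway(*samples).pvalue)
        res = stats.tukey_hsd(*samples)
        rows = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                rows.append((names[i], names[j], float(res.pvalue[i, j])))
        pw = pd.DataFrame(rows, columns=["group_a", "group_b", "p"])
        pw["q"] = pw["p"]  # Tukey HSD is already family-wise adjusted
        method = "anova + tukey hsd"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pw["significant"] = pw["q"] < q_max
    return PhenotypeComparison(overall_p=overall, pairwise=pw, method=method)
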