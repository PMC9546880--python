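"""Attribute dataset variance to design covariates through a PCA subspace:
winsorize -> median-center within replicate -> correlation-scale PCA ->
eigenvalue cutoff -> per-covariate PC assignment (permutation-calibrated
silhouette for categorical, cross-validated lasso for continuous) -> weighted
variance sums with Venn-region overlaps."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.linear_model import LassoCV

from .synthetic_data import substream

logger = logging.getLogger(__name__)

EIGENVALUE_CUTOFF = 0.7


@dataclass
class PcTable:
    """Per-PC eigenvalues (correlation scale), variance weights and retention."""

    table: pd.DataFrame  # columns: eigenvalue, weight, retained
    scores: np.ndarray  # samples x n_pcs


@dataclass
class VarianceAttribution:
    fractions: dict  # covariate -> explained-variance fraction
    venn: dict  # frozenset of covariates -> exclusive region weight
    unexplained: float
    assignments: dict  # covariate -> set of PC indices (0-based)
    pc_table: pd.DataFrame


def preprocess(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    lower: float = 0.005,
    upper: float = 0.995,
) -> pd.DataFrame:
    """Winsorize each feature two-sidedly at the given quantiles, then subtract
    the within-replicate median per feature."""
    if "replicate" not in meta.columns:
        raise ValueError("metadata must carry a 'replicate' column")
    X = matrix.to_numpy(dtype=float)
    lo = np.quantile(X, lower, axis=1, keepdims=True)
    hi = np.quantile(X, upper, axis=1, keepdims=True)
    X = np.clip(X, lo, hi)
    out = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    meta_idx = meta.set_index("sample_id")
    reps = meta_idx.loc[list(matrix.columns), "replicate"]
    for rep, cols in reps.groupby(reps).groups.items():
        cols = list(cols)
        if len(cols) == 1:
            warnings.warn(f"replicate {rep!r} has a single sample; centering is degenerate")
        out[cols] = out[cols].sub(out[cols].median(axis=1), axis=0)
    return out


def pca_retain(matrix: pd.DataFrame, cutoff: float = EIGENVALUE_CUTOFF) -> PcTable:
    """Correlation-scale PCA (features standardized), so eigenvalues average 1
    and the Kaiser-style cutoff is meaningful. PCs below the cutoff are flagged
    discarded; zero-variance features are dropped with a log entry."""
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for PCA")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    dead = sd == 0
    if dead.any():
        logger.info("dropping %d zero-variance features before PCA", int(dead.sum()))
        X = X[~dead]
        sd = sd[~dead]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples are observations: SVD of Z.T (n x p)
    U, s, _ = np.linalg.svd(Z.T, full_matrices=False)
    eig = s ** 2 / (n - 1)
    total = Z.shape[0]  # trace of the correlation matrix
    weights = eig / total
    table = pd.DataFrame(
        {"eigenvalue": eig, "weight": weights, "retained": eig >= cutoff},
        index=[f"PC{i + 1}" for i in range(len(eig))],
    )
    scores = U * s
    return PcTable(table=table, scores=scores)


def _silhouette_from_dist(D: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Mean silhouette width from a precomputed distance matrix (singleton
    clusters score 0)."""
    n = len(codes)
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), codes] = 1.0
    sums = D @ onehot  # i x g: total distance from i to group g
    sizes = onehot.sum(axis=0)
    own = sizes[codes]
    a = sums[np.arange(n), codes] / np.maximum(own - 1, 1)
    mean_other = sums / np.maximum(sizes, 1)[None, :]
    mean_other[np.arange(n), codes] = np.inf
    mean_other[:, sizes == 0] = np.inf
    b = mean_other.min(axis=1)
    s = (b - a) / np.maximum(a, b)
    s[own == 1] = 0.0
    return float(np.mean(s))


def _silhouette_1d(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    return _silhouette_from_dist(np.abs(x[:, None] - x[None, :]), codes, n_groups)


@njit(cache=True)
def _sil_kernel(D, codes, n_groups):  # pragma: no cover - numba
    n = D.shape[0]
    sizes = np.zeros(n_groups)
    for j in range(n):
        sizes[codes[j]] += 1.0
    total = 0.0
    for i in range(n):
        sums = np.zeros(n_groups)
        for j in range(n):
            sums[codes[j]] += D[i, j]
        g = codes[i]
        if sizes[g] <= 1.0:
            continue  # singleton clusters score 0
        a = sums[g] / (sizes[g] - 1.0)
        b = 1e300
        for gg in range(n_groups):
            if gg != g and sizes[gg] > 0:
                m = sums[gg] / sizes[gg]
                if m < b:
                    b = m
        mx = a if a > b else b
        if mx > 0:
            total += (b - a) / mx
    return total / n


@njit(cache=True)
def _sil_null_kernel(D, perms, n_groups):  # pragma: no cover - numba
    out = np.empty(perms.shape[0])
    for b in range(perms.shape[0]):
        out[b] = _sil_kernel(D, perms[b], n_groups)
    return out


def _stratified_permutation(
    codes: np.ndarray, strata: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    if strata is None:
        return rng.permutation(codes)
    out = codes.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = codes[idx[rng.permutation(len(idx))]]
    return out


def assign_pcs(
    scores: np.ndarray,
    covariate: pd.Series | np.ndarray,
    kind: str,
    pcs: list | None = None,
    strata: np.ndarray | pd.Series | None = None,
    B: int = 1000,
    alpha: float = 0.005,
    adjust: str = "none",
    seed: int = 0,
) -> set:
    """Select the PCs significantly associated with one covariate.

    categorical: per PC, the observed mean silhouette of the covariate grouping
    on the PC scores is compared to a seeded label-permutation null (B draws);
    PCs whose permutation p-value falls below ``alpha`` are assigned
    (``adjust='bh'`` additionally BH-corrects across the tested PCs, but the
    discreteness of permutation p-values makes that option conservative).
    When ``strata`` is given (normally the interaction of the remaining design
    covariates), labels are permuted within strata so structure driven by the
    other covariates does not confound the null.
    continuous: PCs with nonzero coefficients in an L1-regularized regression
    of the covariate on the PC scores, penalty by 5-fold cross-validation.
    """
    cov = np.asarray(covariate)
    if len(np.unique(cov)) < 2:
        warnings.warn("constant covariate; no PCs assigned")
        return set()
    if pcs is None:
        pcs = list(range(scores.shape[1]))
    if strata is not None:
        strata = np.asarray(strata)
    rng = substream(seed, "assign_pcs")
    if kind == "categorical":
        codes, uniques = pd.factorize(cov)
        codes = codes.astype(np.int64)
        n_groups = len(uniques)
        perms = np.vstack([_stratified_permutation(codes, strata, rng) for _ in range(B)])
        pvals = np.empty(len(pcs))
        for i, j in enumerate(pcs):
            x = scores[:, j]
            D = np.abs(x[:, None] - x[None, :])
            obs = _sil_kernel(D, codes, n_groups)
            null = _sil_null_kernel(D, perms, n_groups)
            pvals[i] = (1.0 + np.sum(null >= obs)) / (B + 1.0)
        if adjust == "bh":
            from ._stats import bh_adjust

            pvals = bh_adjust(pvals)
        elif adjust != "none":
            raise ValueError(f"unknown adjust {adjust!r}")
        return {j for j, p in zip(pcs, pvals) if p < alpha}
    if kind == "continuous":
        y = cov.astype(float)
        Xs = scores[:, pcs]
        Xs = (Xs - Xs.mean(axis=0)) / np.where(Xs.std(axis=0) == 0, 1, Xs.std(axis=0))
        model = LassoCV(cv=5, random_state=int(rng.integers(2 ** 31)), alphas=50)
        model.fit(Xs, (y - y.mean()) / y.std())
        return {pcs[i] for i, c in enumerate(model.coef_) if abs(c) > 1e-8}
    raise ValueError(f"unknown covariate kind {kind!r}")


def attribute(pc_table: PcTable, assignments: dict) -> VarianceAttribution:
    """Sum retained-PC variance weights per covariate; derive exclusive Venn
    regions from PC-level set intersections. Regions + unexplained sum to 1."""
    table = pc_table.table
    weights = table["weight"].to_numpy()
    retained = set(np.flatnonzero(table["retained"].to_numpy()))
    eff = {cov: set(pcs) & retained for cov, pcs in assignments.items()}
    covs = list(eff)

    fractions = {cov: float(weights[sorted(eff[cov])].sum()) for cov in covs}
    venn: dict = {}
    assigned_any: set = set()
    for cov in covs:
        assigned_any |= eff[cov]
    for pc in assigned_any:
        members = frozenset(c for c in covs if pc in eff[c])
        venn[members] = venn.get(members, 0.0) + float(weights[pc])
    unexplained = 1.0 - float(weights[sorted(assigned_any)].sum()) if assigned_any else 1.0
    return VarianceAttribution(
        fractions=fractions,
        venn=venn,
        unexplained=unexplained,
        assignments=eff,
        pc_table=table,
    )


def attribute_covariates(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: dict | None = None,
    cutoff: float = EIGENVALUE_CUTOFF,
    B: int = 1000,
    alpha: float = 0.005,
    seed: int = 0,
) -> VarianceAttribution:
    """Full pipeline: preprocess -> PCA/retain -> assign -> attribute.

    ``covariates`` maps column name -> 'categorical' | 'continuous'
    (default: ligand/time/replicate, all categorical).
    """
    if covariates is None:
        covariates = {"ligand": "categorical", "time": "categorical", "replicate": "categorical"}
    norm = preprocess(matrix, meta)
    pct = pca_retain(norm, cutoff=cutoff)
    retained = list(np.flatnonzero(pct.table["retained"].to_numpy()))
    meta_idx = meta.set_index("sample_id").loc[list(matrix.columns)]
    assignments = {}
    for cov, kind in covariates.items():
        others = [c for c in covariates if c != cov and c in meta_idx.columns]
        strata = None
        if others:
            strata = pd.factorize(
                meta_idx[others].astype(str).agg("|".join, axis=1)
            )[0]
        assignments[cov] = assign_pcs(
            pct.scores, meta_idx[cov], kind, pcs=retained, strata=strata,
            B=B, alpha=alpha, seed=seed,
        )
    return attribute(pct, assignments)
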