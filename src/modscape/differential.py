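"""CTRL_0-relative fold changes, per-feature Welch tests with BH correction,
signature selection, per-assay module-feature selection, unique/shared set
analysis, and cross-assay concordance / matched-correlation comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .synthetic_data import CONTROL, AssayMatrix, condition_key

#: per-assay |log2FC| thresholds for module-feature selection; RPPA is lower to
#: account for its compressed dynamic range. ATAC features are always retained.
MODULE_LFC_THRESHOLDS = {"RNAseq": 1.5, "CyCIF": 1.5, "GCP": 1.5, "RPPA": 0.75}
VARIANCE_QUARTILE_ASSAYS = ("GCP", "RPPA")


@dataclass
class SignatureSet:
    """Per-ligand significant feature sets plus Unique/Shared labels."""

    per_ligand: dict  # ligand -> set of feature ids
    labels: dict | None = None  # feature -> 'Unique' | 'Shared'


def _log_values(am: AssayMatrix) -> pd.DataFrame:
    """Values on log2 scale; counts get a pseudocount of 1 before log."""
    if am.scale == "counts":
        return np.log2(am.values + 1.0)
    return am.values


def log2fc_vs_control(am: AssayMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Replicate-summarized log2FC per condition versus CTRL at time 0.

    Per condition: median over replicate samples of the feature's log2 value,
    minus the median over CTRL_0 samples.
    """
    logv = _log_values(am)
    ctrl_ids = meta.loc[(meta["ligand"] == CONTROL) & (meta["time"] == 0), "sample_id"]
    if ctrl_ids.empty:
        raise ValueError("no CTRL samples at time 0 in metadata")
    ctrl_med = logv[list(ctrl_ids)].median(axis=1)
    out = {}
    for (lig, t), grp in meta.groupby(["ligand", "time"], sort=False):
        if lig == CONTROL and t == 0:
            continue
        out[condition_key(lig, t)] = logv[list(grp["sample_id"])].median(axis=1) - ctrl_med
    return pd.DataFrame(out)


def test_features(
    am: AssayMatrix,
    meta: pd.DataFrame,
    shrink_variance: bool = False,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Two-sided Welch t-test of each condition's replicates versus CTRL_0, per
    feature, on log-scale values; BH q within each (assay, condition) family.

    Returns a long frame: assay, feature, ligand, time, lfc, p, q. Optional
    variance shrinkage pools each feature's variance toward the assay-wide
    median per-feature variance (weight ``shrink_weight``) before the t-test.
    """
    logv = _log_values(am)
    ctrl_ids = list(meta.loc[(meta["ligand"] == CONTROL) & (meta["time"] == 0), "sample_id"])
    if not ctrl_ids:
        raise ValueError("no CTRL samples at time 0 in metadata")
    if len(ctrl_ids) < 2:
        raise ValueError("need >= 2 CTRL_0 replicates")
    lfc = log2fc_vs_control(am, meta)
    ctrl = logv[ctrl_ids].to_numpy()

    frames = []
    for (lig, t), grp in meta.groupby(["ligand", "time"], sort=False):
        if lig == CONTROL and t == 0:
            continue
        ids = list(grp["sample_id"])
        if len(ids) < 2:
            raise ValueError(f"condition {lig}_{t:g} has fewer than 2 replicates")
        trt = logv[ids].to_numpy()
        if shrink_variance:
            p = _welch_shrunk(trt, ctrl, shrink_weight)
        else:
            with warnings.catch_warnings():
                # identical groups (e.g. all-zero counts) warn and yield NaN
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        # identical zero-variance groups yield NaN; no evidence of change
        p = np.where(np.isnan(p), 1.0, p)
        key = condition_key(lig, t)
        frames.append(
            pd.DataFrame(
                {
                    "assay": am.assay,
                    "feature": logv.index,
                    "ligand": lig,
                    "time": float(t),
                    "lfc": lfc[key].to_numpy(),
                    "p": p,
                    "q": bh_adjust(p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _welch_shrunk(a: np.ndarray, b: np.ndarray, w: float) -> np.ndarray:
    """Welch t with per-feature variances shrunk toward the assay-wide median.

    Shrinking with weight w is equivalent to an empirical-Bayes prior carrying
    d0 = d * w / (1 - w) degrees of freedom, so the reference t distribution
    gains d0 degrees of freedom (cf. moderated-t theory).
    """
    na, nb = a.shape[1], b.shape[1]
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    va = (1 - w) * va + w * np.median(va)
    vb = (1 - w) * vb + w * np.median(vb)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        df = df * (1.0 + w / (1.0 - w)) if w < 1 else np.full_like(df, np.inf)
    return 2 * stats.t.sf(np.abs(tstat), df)


def select_signatures(
    diff: pd.DataFrame,
    q_max: float = 0.01,
    lfc_min: float = 1.5,
    times: Sequence[float] = (24.0, 48.0),
) -> SignatureSet:
    """Feature kept for a ligand if q < q_max and |lfc| >= lfc_min at any of the
    given times (boundary semantics: lfc inclusive, q strict)."""
    sub = diff[diff["time"].isin([float(t) for t in times])]
    hits = sub[(sub["q"] < q_max) & (sub["lfc"].abs() >= lfc_min)]
    per_ligand = {
        lig: set(grp["feature"]) for lig, grp in hits.groupby("ligand", sort=False)
    }
    return SignatureSet(per_ligand=per_ligand)


def set_analysis(signatures: SignatureSet) -> tuple[dict, pd.DataFrame]:
    """Label each significant feature Unique (one ligand) or Shared (>= 2),
    and count unique/total per ligand."""
    if len(signatures.per_ligand) < 2:
        raise ValueError("set analysis needs signatures for >= 2 ligands")
    counts: dict = {}
    for lig, feats in signatures.per_ligand.items():
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    labels = {f: ("Unique" if c == 1 else "Shared") for f, c in counts.items()}
    signatures.labels = labels
    rows = []
    for lig, feats in signatures.per_ligand.items():
        n_unique = sum(1 for f in feats if labels[f] == "Unique")
        rows.append((lig, n_unique, len(feats)))
    table = pd.DataFrame(rows, columns=["ligand", "unique", "total"])
    return labels, table


def select_module_features(
    diffs: Mapping[str, pd.DataFrame],
    lfc_matrices: Mapping[str, pd.DataFrame],
    p_max: float = 0.05,
    times: Sequence[float] = (24.0, 48.0),
) -> dict:
    """Per-assay module-feature selection.

    GCP/RPPA first drop the lowest-variance quartile (variance of the feature's
    fold-change profile); CyCIF/RNAseq/GCP are kept at |lfc| > 1.5 and p < p_max
    in any 24H/48H condition, RPPA at |lfc| > 0.75; all ATAC features retained.
    """
    selected: dict = {}
    for assay, diff in diffs.items():
        feats = list(lfc_matrices[assay].index)
        if assay == "ATAC":
            selected[assay] = feats
            continue
        if assay not in MODULE_LFC_THRESHOLDS:
            raise ValueError(f"unknown assay label {assay!r}")
        if assay in VARIANCE_QUARTILE_ASSAYS:
            variances = lfc_matrices[assay].var(axis=1)
            cut = variances.quantile(0.25)
            feats = [f for f in feats if variances[f] > cut]
        thr = MODULE_LFC_THRESHOLDS[assay]
        sub = diff[diff["time"].isin([float(t) for t in times])]
        hits = set(sub.loc[(sub["lfc"].abs() > thr) & (sub["p"] < p_max), "feature"])
        selected[assay] = [f for f in feats if f in hits]
    return selected


@dataclass
class ConcordanceCounts:
    n_up_up: int
    n_down_down: int
    n_unchanged_both: int
    n_pairs: int


def concordance_counts(
    diff_rna: pd.DataFrame,
    diff_prot: pd.DataFrame,
    cognate_map: Mapping[str, str],
    rna_lfc_min: float = 1.5,
    prot_lfc_min: float = 0.5,
    q_max: float = 0.01,
) -> ConcordanceCounts:
    """Concordance of differential calls between a transcript assay and a
    protein assay over cognate (gene-symbol-matched) feature pairs.

    A (protein feature, condition) pair is concordant-up if both its protein and
    its cognate transcript are significantly up (q < q_max at the assay-specific
    |lfc| threshold); analogously for down; unchanged if neither is significant.
    """
    if not cognate_map:
        raise ValueError("empty cognate map")

    def calls(diff: pd.DataFrame, lfc_min: float) -> pd.DataFrame:
        d = diff.copy()
        d["sig"] = (d["q"] < q_max) & (d["lfc"].abs() >= lfc_min)
        d["dir"] = np.sign(d["lfc"]).where(d["sig"], 0.0)
        return d.set_index(["feature", "ligand", "time"])["dir"]

    rna = calls(diff_rna, rna_lfc_min).to_dict()
    prot = calls(diff_prot, prot_lfc_min)
    up = down = unchanged = total = 0
    for (pfeat, lig, t), dp in prot.items():
        rfeat = cognate_map.get(pfeat)
        if rfeat is None:
            continue
        dr = rna.get((rfeat, lig, t))
        if dr is None:
            continue
        total += 1
        if dp > 0 and dr > 0:
            up += 1
        elif dp < 0 and dr < 0:
            down += 1
        elif dp == 0 and dr == 0:
            unchanged += 1
    return ConcordanceCounts(up, down, unchanged, total)


@dataclass
class MatchedCorrelationResult:
    matched_r: np.ndarray
    mismatched_r: np.ndarray
    p_value: float


def matched_correlation_test(
    zA: pd.DataFrame,
    zB: pd.DataFrame,
    metaA: pd.DataFrame,
    metaB: pd.DataFrame,
) -> MatchedCorrelationResult:
    """Pearson r between every (sample in A, sample in B) pair over shared
    features; Mann-Whitney U compares treatment-matched (same ligand and time)
    versus mismatched pair correlations, two-sided."""
    shared = zA.index.intersection(zB.index)
    if len(shared) < 10:
        raise ValueError("need >= 10 shared features")
    A = zA.loc[shared].to_numpy(dtype=float)
    B = zB.loc[shared].to_numpy(dtype=float)

    def _std(M):
        M = M - M.mean(axis=0, keepdims=True)
        return M / np.linalg.norm(M, axis=0, keepdims=True)

    R = _std(A).T @ _std(B)  # samples_A x samples_B Pearson matrix

    condA = [condition_key(l, t) for l, t in zip(metaA["ligand"], metaA["time"])]
    condB = [condition_key(l, t) for l, t in zip(metaB["ligand"], metaB["time"])]
    match = np.array([[a == b for b in condB] for a in condA])
    if not match.any():
        raise ValueError("no treatment-matched sample pairs")
    matched = R[match]
    mismatched = R[~match]
    stat = stats.mannwhitneyu(matched, mismatched, alternative="two-sided")
    return MatchedCorrelationResult(matched, mismatched, float(stat.pvalue))
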