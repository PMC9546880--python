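"""Synthetic multi-ligand / multi-time / multi-assay experiment generator.

Every downstream stage of the pipeline (differential signatures, scaling,
module detection, variance attribution, phenotype metrics, association) can be
exercised against the planted ground truth produced here, without any external
data. All randomness flows from a single root seed through named substreams so
each generator can be re-run independently and reproducibly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

DEFAULT_LIGANDS = ("PBS", "EGF", "HGF", "OSM", "BMP2+EGF", "IFNG+EGF", "TGFB+EGF")
DEFAULT_TIMES = (0.0, 1.0, 4.0, 8.0, 24.0, 48.0)
CONTROL = "CTRL"

#: default per-assay feature counts (study scale shrunk ~10x)
DEFAULT_ASSAY_SIZES = {"RNAseq": 2000, "RPPA": 300, "CyCIF": 120, "GCP": 60, "ATAC": 100}

RNASEQ_DISPERSION = 0.1
LIBSIZE_LOG_SD = 0.1


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of a root seed; stable across runs and call order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def condition_key(ligand: str, time: float) -> str:
    return f"{ligand}_{time:g}"


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Treatment x time x replicate layout. CTRL is added automatically at time 0."""

    ligands: tuple = DEFAULT_LIGANDS
    times: tuple = DEFAULT_TIMES
    replicates: int = 3
    collections: int = 1
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.ligands)) != len(self.ligands):
            raise ValueError("duplicate ligand labels in design")
        if CONTROL in self.ligands:
            raise ValueError("CTRL is implicit; do not list it as a treatment")
        if 0 not in [float(t) for t in self.times]:
            raise ValueError("times must include 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.collections < 1:
            raise ValueError("collections must be >= 1")


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """One sample row per (ligand, time>0, replicate) plus CTRL at time 0."""
    spec.validate()
    rows = []
    for rep in range(1, spec.replicates + 1):
        coll = (rep - 1) % spec.collections + 1
        rows.append((f"{CONTROL}_0_{rep}", CONTROL, 0.0, rep, coll))
    for lig in spec.ligands:
        for t in spec.times:
            if float(t) == 0.0:
                continue
            for rep in range(1, spec.replicates + 1):
                coll = (rep - 1) % spec.collections + 1
                rows.append((f"{lig}_{float(t):g}_{rep}", lig, float(t), rep, coll))
    return pd.DataFrame(rows, columns=["sample_id", "ligand", "time", "replicate", "collection"])


# ---------------------------------------------------------------------------
# multi-omic matrices with planted modules
# ---------------------------------------------------------------------------

@dataclass
class AssayMatrix:
    """Feature x sample matrix for one modality."""

    values: pd.DataFrame
    assay: str
    scale: str  # 'counts' or 'log'
    gene_symbol: pd.Series | None = None


@dataclass
class ModuleSpec:
    n_modules: int = 6
    features_per_assay_per_module: Mapping[str, int] = field(
        default_factory=lambda: {"RNAseq": 40, "RPPA": 15, "CyCIF": 8, "GCP": 5, "ATAC": 8}
    )
    # module id (1-based) -> {(ligand, time): mean shift in z units}
    effect_profiles: Mapping[int, Mapping[tuple, float]] | None = None
    background_features: Mapping[str, int] = field(
        default_factory=lambda: {"RNAseq": 400, "RPPA": 60, "CyCIF": 30, "GCP": 20, "ATAC": 20}
    )
    noise_sd: Mapping[str, float] | float = 0.3
    covariate_fractions: Mapping[str, float] = field(default_factory=dict)
    #: rank of each planted covariate effect across features; low rank mimics
    #: coordinated (pathway-like) responses and concentrates the effect in a
    #: few principal components
    covariate_rank: int = 2

    def validate(self) -> None:
        if self.n_modules < 0:
            raise ValueError("n_modules must be >= 0")
        for d in (self.features_per_assay_per_module, self.background_features):
            if any(v < 0 for v in d.values()):
                raise ValueError("feature counts must be >= 0")
        sds = self.noise_sd.values() if isinstance(self.noise_sd, Mapping) else [self.noise_sd]
        if any(s <= 0 for s in sds):
            raise ValueError("noise_sd must be > 0")
        fr = dict(self.covariate_fractions)
        if any(not (0.0 <= f <= 1.0) for f in fr.values()):
            raise ValueError("covariate fractions must lie in [0, 1]")
        if sum(fr.values()) > 1.0 + 1e-12:
            raise ValueError("covariate fractions sum to more than 1")

    def assays(self) -> list:
        return sorted(set(self.features_per_assay_per_module) | set(self.background_features))

    def sd_for(self, assay: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[assay])
        return float(self.noise_sd)


@dataclass
class GroundTruth:
    """Planted structure: feature->module map, true per-condition shifts, fractions."""

    feature_module: dict  # feature_id -> module id (background features absent)
    true_lfc: pd.DataFrame  # features x condition keys, true log2FC vs CTRL_0
    module_profiles: pd.DataFrame  # module x condition keys, mean shift in z units
    variance_fractions: dict
    coupling: dict | None = None  # phenotype -> {module: slope}


def default_effect_profiles(
    n_modules: int,
    ligands: Sequence[str] = DEFAULT_LIGANDS,
    times: Sequence[float] = DEFAULT_TIMES,
    amplitude: float = 2.0,
) -> dict:
    """Distinct dense sign patterns (Hadamard rows) over ligands, ramping in time.

    Shift is full amplitude at t >= 24, half at 4 <= t < 24, zero earlier.
    """
    if n_modules > 7:
        raise ValueError("default profiles support at most 7 modules")
    H = hadamard(8)
    profiles: dict = {}
    for m in range(1, n_modules + 1):
        prof = {}
        for j, lig in enumerate(ligands[:7]):
            sign = float(H[m, j + 1])
            for t in times:
                t = float(t)
                if t == 0.0:
                    continue
                if t >= 24.0:
                    shift = amplitude * sign
                elif t >= 4.0:
                    shift = 0.5 * amplitude * sign
                else:
                    shift = 0.0
                prof[(lig, t)] = shift
        profiles[m] = prof
    return profiles


def _structured_noise(
    rng: np.random.Generator,
    design: pd.DataFrame,
    n_features: int,
    noise_sd: float,
    fractions: Mapping[str, float],
    rank: int = 3,
) -> np.ndarray:
    """Noise layer (features x samples) with planted covariate variance fractions.

    Each covariate contributes a rank-``rank`` level-effect component (shared
    level patterns with per-feature loadings, mimicking coordinated responses)
    whose realized (centered, sequentially orthogonalized) sample variance is
    scaled exactly to its target fraction of noise_sd**2; the iid residual takes
    the remainder. With all fractions zero this is plain iid Gaussian noise.
    """
    n = len(design)
    fractions = {k: float(v) for k, v in fractions.items() if v > 0}
    if not fractions:
        return rng.normal(0.0, noise_sd, size=(n_features, n))

    total_var = noise_sd ** 2
    comps: list[np.ndarray] = []
    for cov, frac in fractions.items():
        codes, _ = pd.factorize(design[cov])
        n_levels = codes.max() + 1
        r = min(rank, n_levels - 1) if rank > 0 else n_levels - 1
        patterns = rng.normal(size=(r, n_levels))  # shared level patterns
        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
        loadings = rng.normal(size=(n_features, r))
        # fixed decaying strengths keep the sub-components' eigenvalues apart
        # so PCA does not mix components of different covariates
        strength = np.array([2.0 ** -i for i in range(r)])
        eff = (loadings * strength) @ patterns
        comp = eff[:, codes]
        comp = comp - comp.mean(axis=1, keepdims=True)
        for prev in comps:
            proj = (comp * prev).sum(axis=1, keepdims=True) / (prev * prev).sum(axis=1, keepdims=True)
            comp = comp - proj * prev
        norm = np.sqrt((comp ** 2).sum(axis=1, keepdims=True))
        if np.any(norm == 0):
            raise ValueError(f"degenerate covariate component for {cov!r}")
        comp = comp / norm * np.sqrt(frac * total_var * (n - 1))
        comps.append(comp)

    resid_frac = 1.0 - sum(fractions.values())
    eps = rng.normal(size=(n_features, n))
    eps = eps - eps.mean(axis=1, keepdims=True)
    for prev in comps:
        proj = (eps * prev).sum(axis=1, keepdims=True) / (prev * prev).sum(axis=1, keepdims=True)
        eps = eps - proj * prev
    eps = eps / np.sqrt((eps ** 2).sum(axis=1, keepdims=True)) * np.sqrt(
        max(resid_frac, 0.0) * total_var * (n - 1)
    )
    layer = eps
    for comp in comps:
        layer = layer + comp

    # internal one-way check: each covariate's realized fraction within 5
    # points of target. Checked against component + residual (not the full
    # layer) because the unbalanced CTRL cell lets other covariates leak into
    # this covariate's group means.
    for (cov, frac), comp in zip(fractions.items(), comps):
        expected = frac / (frac + max(resid_frac, 1e-12))
        eta = _mean_eta_squared(comp + eps, design[cov].to_numpy())
        if abs(eta - expected) > 0.05:
            raise RuntimeError(
                f"realized {cov} variance fraction {eta:.3f} misses target {expected:.3f}"
            )
    return layer


def _mean_eta_squared(X: np.ndarray, groups: np.ndarray) -> float:
    """Between-group sum-of-squares fraction, averaged over features (rows)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    ss_tot = (Xc ** 2).sum(axis=1)
    ss_between = np.zeros(X.shape[0])
    for g in np.unique(groups):
        mask = groups == g
        gm = Xc[:, mask].mean(axis=1)
        ss_between += mask.sum() * gm ** 2
    with np.errstate(invalid="ignore"):
        return float(np.nanmean(ss_between / ss_tot))


def generate_multiomic(
    design: pd.DataFrame, mspec: ModuleSpec, seed: int
) -> tuple[dict, GroundTruth]:
    """Emit one AssayMatrix per assay plus the planted GroundTruth.

    Module features share their module's effect profile (log2 shift per
    condition) plus noise. RNAseq is emitted as negative-binomial counts whose
    log2 means follow the profile; other assays as Gaussian log-scale values.
    """
    mspec.validate()
    profiles = mspec.effect_profiles
    if profiles is None and mspec.n_modules > 0:
        ligands = [l for l in design["ligand"].unique() if l != CONTROL]
        times = sorted(design["time"].unique())
        profiles = default_effect_profiles(mspec.n_modules, ligands, times)
    profiles = profiles or {}

    cond_keys = [
        condition_key(l, t)
        for l, t in design[["ligand", "time"]].drop_duplicates().itertuples(index=False)
    ]
    sample_shift = {}  # module -> per-sample shift vector
    for m in range(1, mspec.n_modules + 1):
        prof = profiles.get(m, {})
        sample_shift[m] = np.array(
            [prof.get((l, float(t)), 0.0) for l, t in zip(design["ligand"], design["time"])]
        )

    matrices: dict[str, AssayMatrix] = {}
    feature_module: dict[str, int] = {}
    lfc_rows, lfc_index = [], []
    for assay in mspec.assays():
        rng = substream(seed, f"multiomic/{assay}")
        per_mod = mspec.features_per_assay_per_module.get(assay, 0)
        n_bg = mspec.background_features.get(assay, 0)
        feats, shifts = [], []
        for m in range(1, mspec.n_modules + 1):
            for i in range(per_mod):
                fid = f"{assay}_M{m}_f{i + 1}"
                feats.append(fid)
                feature_module[fid] = m
                shifts.append(sample_shift[m])
        for i in range(n_bg):
            feats.append(f"{assay}_bg_{i + 1}")
            shifts.append(np.zeros(len(design)))
        if not feats:
            continue
        S = np.vstack(shifts)
        noise = _structured_noise(
            rng, design, len(feats), mspec.sd_for(assay), mspec.covariate_fractions,
            rank=mspec.covariate_rank,
        )
        if assay == "RNAseq":
            baseline = rng.uniform(3.0, 8.0, size=(len(feats), 1))
            log2_mu = baseline + S + noise
            libfac = np.exp(rng.normal(0.0, LIBSIZE_LOG_SD, size=len(design)))
            mu = np.exp2(log2_mu) * libfac
            lam = rng.gamma(shape=1.0 / RNASEQ_DISPERSION, scale=mu * RNASEQ_DISPERSION)
            vals = rng.poisson(lam).astype(float)
            scale = "counts"
        else:
            baseline = rng.normal(0.0, 1.0, size=(len(feats), 1))
            vals = baseline + S + noise
            scale = "log"
        df = pd.DataFrame(vals, index=feats, columns=design["sample_id"].to_numpy())
        symbols = pd.Series(feats, index=feats, name="gene_symbol")
        matrices[assay] = AssayMatrix(values=df, assay=assay, scale=scale, gene_symbol=symbols)
        # true log2FC per condition: the planted shift (0 for background)
        key_per_sample = [
            condition_key(l, t) for l, t in zip(design["ligand"], design["time"])
        ]
        first_sample = {}
        for i, k in enumerate(key_per_sample):
            first_sample.setdefault(k, i)
        shift_by_cond = np.zeros((len(feats), len(cond_keys)))
        for j, key in enumerate(cond_keys):
            shift_by_cond[:, j] = S[:, first_sample[key]]
        lfc_rows.append(shift_by_cond)
        lfc_index.extend(feats)

    true_lfc = pd.DataFrame(np.vstack(lfc_rows), index=lfc_index, columns=cond_keys)
    module_profiles = pd.DataFrame(
        0.0, index=range(1, mspec.n_modules + 1), columns=cond_keys
    )
    for m in range(1, mspec.n_modules + 1):
        prof = profiles.get(m, {})
        for (l, t), v in prof.items():
            key = condition_key(l, float(t))
            if key in module_profiles.columns:
                module_profiles.loc[m, key] = v
    gt = GroundTruth(
        feature_module=feature_module,
        true_lfc=true_lfc,
        module_profiles=module_profiles,
        variance_fractions=dict(mspec.covariate_fractions),
    )
    return matrices, gt


def generate_profile_matrix(
    n_modules: int = 6,
    features_per_module: int = 83,
    n_background: int = 0,
    noise_sd: float = 1.0,
    amplitude: float = 2.0,
    seed: int = 0,
    ligands: Sequence[str] = DEFAULT_LIGANDS,
    times: Sequence[float] = (24.0, 48.0),
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature x condition z-profile matrix with planted modules (no assay layer).

    Convenience generator for clustering benchmarks: each module feature is its
    module's profile plus iid Gaussian noise; background features are pure noise.
    Returns (matrix, true module labels; background labelled 0).
    """
    rng = substream(seed, "profile_matrix")
    profiles = default_effect_profiles(n_modules, ligands, times, amplitude=amplitude)
    conds = [(l, float(t)) for l in ligands for t in times]
    cols = [condition_key(l, t) for l, t in conds]
    rows, labels, index = [], [], []
    for m in range(1, n_modules + 1):
        base = np.array([profiles[m].get(c, 0.0) for c in conds])
        for i in range(features_per_module):
            rows.append(base + rng.normal(0.0, noise_sd, size=len(conds)))
            labels.append(m)
            index.append(f"M{m}_f{i + 1}")
    for i in range(n_background):
        rows.append(rng.normal(0.0, noise_sd, size=len(conds)))
        labels.append(0)
        index.append(f"bg_{i + 1}")
    X = pd.DataFrame(np.vstack(rows), index=index, columns=cols)
    return X, pd.Series(labels, index=index, name="module")


# ---------------------------------------------------------------------------
# single-cell imaging tables
# ---------------------------------------------------------------------------

def generate_cells(
    pattern: str,
    n: int,
    field: tuple = (2000.0, 2000.0),
    params: Mapping | None = None,
    seed: int = 0,
    well: str = "A1",
    field_id: int = 1,
) -> pd.DataFrame:
    """Synthetic cell table with planted spatial pattern and marker mixtures.

    Patterns: ``csr`` (uniform), ``thomas`` (Poisson parents, Gaussian-scattered
    offspring wrapped on the field torus), ``grid`` (regular lattice).
    DAPI totals are a two-component mixture at means mu and 2*mu (G1/G2M);
    EdU a two-component log-normal mixture. Truth columns ``true_phase`` and
    ``true_edu`` are included for validation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w, h = float(field[0]), float(field[1])
    if w <= 0 or h <= 0:
        raise ValueError("field dimensions must be positive")
    p = dict(params or {})
    rng = substream(seed, f"cells/{pattern}")

    n_par_realized = None
    if pattern == "csr":
        x = rng.uniform(0, w, n)
        y = rng.uniform(0, h, n)
    elif pattern == "thomas":
        n_parents = int(p.get("n_parents", 10))
        sigma = float(p.get("sigma", 30.0))
        n_par = max(1, int(rng.poisson(n_parents)))
        px = rng.uniform(0, w, n_par)
        py = rng.uniform(0, h, n_par)
        assign = rng.integers(0, n_par, n)
        x = np.mod(px[assign] + rng.normal(0.0, sigma, n), w)
        y = np.mod(py[assign] + rng.normal(0.0, sigma, n), h)
        n_par_realized = int(len(np.unique(assign)))
    elif pattern == "grid":
        ncols = max(1, int(round(np.sqrt(n * w / h))))
        nrows = int(np.ceil(n / ncols))
        if ncols * nrows > w * h:  # denser than 1 cell per px^2
            raise ValueError("n exceeds grid capacity of the field")
        sx, sy = w / ncols, h / nrows
        jj, ii = np.divmod(np.arange(n), ncols)
        x = (ii + 0.5) * sx
        y = (jj + 0.5) * sy
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    dapi_mu = float(p.get("dapi_mu", 1000.0))
    dapi_cv = float(p.get("dapi_cv", 0.10))
    g2m_frac = float(p.get("g2m_frac", 0.5))
    is_g2m = rng.random(n) < g2m_frac
    means = np.where(is_g2m, 2.0 * dapi_mu, dapi_mu)
    dapi = rng.normal(means, dapi_cv * means)
    dapi = np.clip(dapi, 1e-6, None)

    edu_frac = float(p.get("edu_frac", 0.3))
    edu_neg = float(p.get("edu_neg_mu", 100.0))
    edu_pos = float(p.get("edu_pos_mu", 1000.0))
    is_edu = rng.random(n) < edu_frac
    edu = np.exp(rng.normal(np.log(np.where(is_edu, edu_pos, edu_neg)), 0.25))

    krt5 = np.exp(rng.normal(np.log(float(p.get("krt5_mu", 200.0))), 0.4, n))
    multi_frac = float(p.get("multinucleate_frac", 0.0))
    n_nuclei = np.where(rng.random(n) < multi_frac, 2, 1)

    out = pd.DataFrame(
        {
            "well": well,
            "field": field_id,
            "cell_id": np.arange(1, n + 1),
            "x": x,
            "y": y,
            "dapi_total": dapi,
            "edu": edu,
            "krt5": krt5,
            "n_nuclei": n_nuclei,
            "true_phase": np.where(is_g2m, "G2M", "G1"),
            "true_edu": is_edu,
        }
    )
    if n_par_realized is not None:
        out.attrs["n_parents"] = n_par_realized
    return out


# ---------------------------------------------------------------------------
# lineage tracks
# ---------------------------------------------------------------------------

@dataclass
class LineageSet:
    """Tracked lineages: long-format positions plus mitosis events."""

    tracks: pd.DataFrame  # track_id, parent_id (<0 = none), frame, x, y
    frame_interval_h: float
    horizon_h: float
    mitoses: list  # (frame, parent_id, (daughter1, daughter2))


def generate_tracks(
    n_lineages: int,
    motility: Mapping | None = None,
    division_rate: float = 0.0,
    horizon: float = 48.0,
    seed: int = 0,
    frame_interval: float = 0.5,
    field: tuple = (1000.0, 1000.0),
) -> LineageSet:
    """Correlated random walks with Poisson division events.

    ``speed`` is the per-frame Gaussian step s.d. per axis; ``persistence`` in
    [0, 1) autocorrelates successive steps while preserving the marginal step
    distribution. Divisions split a track into two daughters at the parent's
    position and frame.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    mot = dict(motility or {})
    speed = float(mot.get("speed", 5.0))
    persistence = float(mot.get("persistence", 0.0))
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if not (0.0 <= persistence < 1.0):
        raise ValueError("persistence must be in [0, 1)")
    if division_rate < 0:
        raise ValueError("division_rate must be >= 0")

    rng = substream(seed, "tracks")
    n_frames = int(round(horizon / frame_interval))
    p_div = division_rate * frame_interval

    rows: list[tuple] = []
    mitoses: list[tuple] = []
    next_id = 0
    # active: (track_id, parent_id, pos, prev_step)
    active = []
    for _ in range(n_lineages):
        pos = np.array([rng.uniform(0, field[0]), rng.uniform(0, field[1])])
        active.append((next_id, -1, pos, np.zeros(2)))
        rows.append((next_id, -1, 0, pos[0], pos[1]))
        next_id += 1

    for frame in range(1, n_frames + 1):
        new_active = []
        for tid, pid, pos, prev in active:
            step = persistence * prev + np.sqrt(1 - persistence ** 2) * rng.normal(0, speed, 2)
            pos = pos + step
            rows.append((tid, pid, frame, pos[0], pos[1]))
            if frame < n_frames and p_div > 0 and rng.random() < p_div:
                d1, d2 = next_id, next_id + 1
                next_id += 2
                mitoses.append((frame, tid, (d1, d2)))
                rows.append((d1, tid, frame, pos[0], pos[1]))
                rows.append((d2, tid, frame, pos[0], pos[1]))
                new_active.append((d1, tid, pos.copy(), step.copy()))
                new_active.append((d2, tid, pos.copy(), step.copy()))
            else:
                new_active.append((tid, pid, pos, step))
        active = new_active

    tracks = pd.DataFrame(rows, columns=["track_id", "parent_id", "frame", "x", "y"])
    if not np.isfinite(tracks[["x", "y"]].to_numpy()).all():
        raise RuntimeError("non-finite track positions generated")
    return LineageSet(tracks=tracks, frame_interval_h=frame_interval, horizon_h=horizon, mitoses=mitoses)


# ---------------------------------------------------------------------------
# module-coupled phenotypes
# ---------------------------------------------------------------------------

def generate_phenotypes(
    gtruth: GroundTruth,
    design: pd.DataFrame,
    coupling: Mapping[str, Mapping[int, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Well-level phenotypes as linear combinations of true module scores + noise."""
    rng = substream(seed, "phenotypes")
    out = design[["sample_id", "ligand", "time", "replicate"]].copy()
    keys = [condition_key(l, t) for l, t in zip(design["ligand"], design["time"])]
    for phen, slopes in coupling.items():
        signal = np.zeros(len(design))
        for m, slope in slopes.items():
            prof = gtruth.module_profiles.loc[m]
            signal += slope * np.array([prof.get(k, 0.0) for k in keys])
        out[phen] = signal + rng.normal(0.0, noise_sd, len(design))
    gtruth.coupling = {p: dict(s) for p, s in coupling.items()}
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path,
    design: pd.DataFrame,
    matrices: Mapping[str, AssayMatrix],
    gtruth: GroundTruth | None = None,
    cells: pd.DataFrame | None = None,
    lineages: LineageSet | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> None:
    """Write the full synthetic dataset as plain-text TSV/CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design.to_csv(out / "sample_meta.tsv", sep="\t", index=False)
    for assay, am in matrices.items():
        df = am.values.copy()
        df.insert(0, "feature_id", df.index)
        if am.gene_symbol is not None:
            df.insert(1, "gene_symbol", am.gene_symbol.reindex(am.values.index).to_numpy())
        df.to_csv(out / f"{assay}.tsv", sep="\t", index=False)
    if gtruth is not None:
        doc = {
            "feature_module": gtruth.feature_module,
            "variance_fractions": gtruth.variance_fractions,
            "module_profiles": {
                str(m): gtruth.module_profiles.loc[m].to_dict()
                for m in gtruth.module_profiles.index
            },
            "coupling": gtruth.coupling,
        }
        (out / "ground_truth.json").write_text(json.dumps(doc, indent=1))
    if cells is not None:
        cells.to_csv(out / "cells.csv", index=False)
    if lineages is not None:
        lineages.tracks.to_csv(out / "tracks.csv", index=False)
    if phenotypes is not None:
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)


def read_assay_tsv(path: str | Path, scale: str = "log", assay: str | None = None) -> AssayMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("feature_id")
    sym = None
    if "gene_symbol" in df.columns:
        sym = df.pop("gene_symbol")
    name = assay or Path(path).stem
    return AssayMatrix(values=df.astype(float), assay=name, scale=scale, gene_symbol=sym)
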