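"""End-to-end convenience driver: simulate -> differential -> scale ->
module detection -> module scores -> phenotype association, with the planted
ground truth carried along for evaluation."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import association, differential, module_detection, scaling, synthetic_data
from .synthetic_data import DesignSpec, GroundTruth, ModuleSpec, condition_key


@dataclass
class PipelineResult:
    design: pd.DataFrame
    matrices: dict
    ground_truth: GroundTruth
    diffs: dict
    lfc: dict
    selected: dict
    scaled: scaling.ScaledMatrix
    modules: module_detection.ConsensusResult
    scores: pd.DataFrame
    phenotypes: pd.DataFrame | None
    associations: pd.DataFrame | None


def run_pipeline(
    seed: int = 0,
    design_spec: DesignSpec | None = None,
    module_spec: ModuleSpec | None = None,
    k: int | None = None,
    kmax: int = 12,
    gap_B: int = 20,
    n_inner: int = 100,
    n_outer: int = 25,
    merge_r: float = 0.85,
    coupling: dict | None = None,
    phenotype_noise_sd: float = 0.5,
    times: tuple = (24.0, 48.0),
) -> PipelineResult:
    """Run the full analysis on a freshly simulated dataset.

    If ``k`` is None the gap statistic (firstSEmax) chooses it. ``coupling``
    maps phenotype name -> {module: slope}; None couples one phenotype to
    module 1 with slope 1.
    """
    dspec = design_spec or DesignSpec(seed=seed)
    design = synthetic_data.generate_design(dspec)
    mspec = module_spec or ModuleSpec()
    matrices, gt = synthetic_data.generate_multiomic(design, mspec, seed=seed)

    diffs, lfc = {}, {}
    for assay, am in matrices.items():
        diffs[assay] = differential.test_features(am, design)
        full = differential.log2fc_vs_control(am, design)
        cols = [c for c in full.columns if float(c.rsplit("_", 1)[1]) in times]
        lfc[assay] = full[cols]

    selected = differential.select_module_features(diffs, lfc, times=times)
    selected = {a: f for a, f in selected.items() if f}
    scaled = scaling.scale_assays(selected, lfc)

    if k is None:
        gap = module_detection.gap_select_k(scaled.values, kmax=kmax, B=gap_B, seed=seed)
        k = gap.chosen_k
    modules = module_detection.detect_modules(
        scaled.values, k, n_inner=n_inner, n_outer=n_outer, seed=seed
    )
    modules = module_detection.merge_correlated(modules, scaled.values, r_threshold=merge_r)
    scores = association.module_scores(scaled.values, modules)

    phenotypes = associations = None
    if coupling is None:
        coupling = {"motility": {1: 1.0}}
    if coupling:
        wells = synthetic_data.generate_phenotypes(
            gt, design, coupling, noise_sd=phenotype_noise_sd, seed=seed
        )
        keys = [condition_key(l, t) for l, t in zip(wells["ligand"], wells["time"])]
        wells = wells.assign(condition=keys)
        phen_cols = list(coupling)
        phenotypes = wells.groupby("condition")[phen_cols].median()
        phenotypes = phenotypes.loc[[c for c in scores.columns if c in phenotypes.index]]
        associations = association.associate(scores, phenotypes)

    return PipelineResult(
        design=design,
        matrices=matrices,
        ground_truth=gt,
        diffs=diffs,
        lfc=lfc,
        selected=selected,
        scaled=scaled,
        modules=modules,
        scores=scores,
        phenotypes=phenotypes,
        associations=associations,
    )
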