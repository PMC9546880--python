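"""Module expression scores and module-phenotype linear association."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .module_detection import ConsensusResult


def module_scores(scaled: pd.DataFrame, result: ConsensusResult | pd.Series) -> pd.DataFrame:
    """Unweighted mean of member-feature scaled values per condition.

    Returns a module x condition frame. A singleton module's score equals the
    feature's values; an empty module is an error.
    """
    labels = result.partition if isinstance(result, ConsensusResult) else result
    missing = [f for f in scaled.index if f not in labels.index]
    if missing:
        raise ValueError(f"partition does not cover matrix rows, e.g. {missing[0]!r}")
    rows = {}
    for module in sorted(labels.unique()):
        members = labels.index[labels == module]
        members = [m for m in members if m in scaled.index]
        if not members:
            raise ValueError(f"module {module} has no members in the matrix")
        rows[module] = scaled.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T.rename_axis("module")


def associate(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    method: str = "pearson",
    min_conditions: int = 4,
) -> pd.DataFrame:
    """OLS fit of each phenotype on each module score across shared conditions.

    ``scores``: module x condition; ``phenotypes``: condition x phenotype.
    Returns a long frame (module, phenotype, slope, r, p, q) with BH q computed
    over the full module x phenotype grid. Pairs with fewer than
    ``min_conditions`` shared conditions are skipped with a warning.
    """
    rows = []
    for module in scores.index:
        s = scores.loc[module]
        for phen in phenotypes.columns:
            y = phenotypes[phen]
            shared = s.index.intersection(y.index)
            if len(shared) < min_conditions:
                warnings.warn(
                    f"module {module} x {phen!r}: only {len(shared)} shared conditions; skipped"
                )
                continue
            xs, ys = s[shared].to_numpy(float), y[shared].to_numpy(float)
            fit = stats.linregress(xs, ys)
            if method == "pearson":
                r = float(fit.rvalue)
                p = float(fit.pvalue)
            elif method == "spearman":
                sp = stats.spearmanr(xs, ys)
                r, p = float(sp.statistic), float(sp.pvalue)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append((module, phen, float(fit.slope), r, p))
    out = pd.DataFrame(rows, columns=["module", "phenotype", "slope", "r", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
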