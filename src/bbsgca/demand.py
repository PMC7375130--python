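"""Network-demand meta-analysis across task contrasts.

Cognitively demanding task states activate the frontoparietal control
network (FPN) and deactivate the default mode network (DMN).  This module
relates each contrast's mean activation within the seven networks to how
accurately that contrast predicts general cognitive ability, across the
suite of contrasts: single-network Pearson correlations with a two-sided
t-test, and a joint two-predictor (FPN + DMN) regression summarized by the
correlation between fitted and observed accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import NetworkParcellation

__all__ = [
    "DemandTable",
    "network_means",
    "build_demand_table",
    "demand_accuracy_correlation",
    "demand_regression",
]


@dataclass
class DemandTable:
    """One row per contrast: mean activation per network plus the pooled
    cross-validated prediction accuracy."""

    table: pd.DataFrame               # columns: contrast, <network names>, accuracy
    network_names: list[str]

    def __post_init__(self):
        missing = ({"contrast", "accuracy"} | set(self.network_names)) \
            - set(self.table.columns)
        if missing:
            raise ValueError(f"missing demand-table columns: {sorted(missing)}")
        if self.table["contrast"].duplicated().any():
            raise ValueError("duplicate contrast rows")


def network_means(group_map: np.ndarray,
                  parcellation: NetworkParcellation) -> dict[str, float]:
    """Mean of a voxel map within each network.

    For a subjects-by-voxels matrix the subject-average map is taken
    first; with equal weights this equals averaging per-subject network
    means.
    """
    m = np.asarray(group_map, dtype=float)
    if m.ndim == 2:
        m = m.mean(axis=0)
    if m.shape[0] != parcellation.labels.shape[0]:
        raise ValueError("map and parcellation voxel spaces differ")
    out = {}
    for lab, name in parcellation.names.items():
        sel = parcellation.labels == lab
        if not np.any(sel):
            raise ValueError(f"network {name} has no voxels")
        out[name] = float(m[sel].mean())
    return out


def build_demand_table(contrast_maps: dict[str, np.ndarray],
                       accuracies: dict[str, float],
                       parcellation: NetworkParcellation) -> DemandTable:
    """Assemble the per-contrast network-activation / accuracy table."""
    rows = []
    for name, maps in contrast_maps.items():
        row = {"contrast": name, "accuracy": float(accuracies[name])}
        row.update(network_means(maps, parcellation))
        rows.append(row)
    names = list(parcellation.names.values())
    return DemandTable(table=pd.DataFrame(rows), network_names=names)


def demand_accuracy_correlation(table: DemandTable, network: str
                                ) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between one network's mean
    activation and prediction accuracy across contrasts."""
    df = table.table
    if len(df) < 4:
        raise ValueError("need at least 4 contrasts")
    x = df[network].to_numpy()
    y = df["accuracy"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in activation or accuracy")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def demand_regression(table: DemandTable, predictors: tuple[str, str] = ("FPN", "DMN")):
    """Accuracy regressed jointly on FPN and DMN mean activation.

    Returns (statsmodels results, correlation between fitted and observed
    accuracies).  Collinear or constant predictors raise.
    """
    df = table.table
    if len(df) < 5:
        raise ValueError("need at least 5 contrasts")
    X = df[list(predictors)].to_numpy()
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor column")
    Xd = sm.add_constant(X)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("collinear predictors")
    y = df["accuracy"].to_numpy()
    fit = sm.OLS(y, Xd).fit()
    fitted_r = float(np.corrcoef(fit.fittedvalues, y)[0, 1])
    return fit, fitted_r
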