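"""Brain Basis Set (BBS) predictive modeling.

BBS predicts a phenotype from voxelwise brain maps in three steps: (i) PCA
of the train-set subjects-by-voxels matrix gives an orthonormal basis of
component maps; (ii) each subject's map is projected onto the retained
components, giving low-dimensional expression scores; (iii) the phenotype
is regressed on the expression scores jointly with nuisance covariates.
Test-set predictions use only train-estimated quantities: train voxel
means, train components, and train regression coefficients.

The covariate-adjusted comparison follows the train/test-separated scheme:
on test data the adjusted response is y_test - Z_test @ gamma_hat and the
brain-based prediction is X_test @ beta_hat, with gamma_hat and beta_hat
both learned on the train set only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContrastMatrix",
    "BasisSet",
    "BBSModel",
    "CovariateEncoder",
    "covariate_frame",
    "build_basis",
    "expression_scores",
    "fit_bbs",
    "predict_adjusted",
    "consensus_map",
]

DEFAULT_K = 75   # component count; retained basis size


@dataclass
class ContrastMatrix:
    """n subjects x m voxels map matrix for one task contrast."""

    values: np.ndarray
    subject_ids: list[str] | None = None
    contrast_name: str = ""
    mask: object = None               # reference to a voxel mask / NIfTI geometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 subjects")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("contrast matrix contains missing values")
        if self.subject_ids is not None and len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class BasisSet:
    """Top-K principal component maps of a train-set contrast matrix."""

    components: np.ndarray            # (K, m), orthonormal rows
    eigenvalues: np.ndarray           # (K,), descending
    voxel_means: np.ndarray           # (m,), train means
    n_train: int

    @property
    def K(self) -> int:
        return self.components.shape[0]


@dataclass
class BBSModel:
    """Fitted joint regression of the phenotype on expression scores (beta)
    and covariates (gamma)."""

    beta: np.ndarray                  # (K,)
    gamma: np.ndarray                 # (p,)
    basis: BasisSet | None = None
    covariate_names: list[str] = field(default_factory=list)
    response_name: str = "GCA"


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

_CONTINUOUS = ["age", "age_sq", "handedness", "brain_volume", "fd", "fd_sq"]
_CATEGORICAL = ["gender", "recon_version"]


def covariate_frame(table: pd.DataFrame, contrast: str | None = None) -> pd.DataFrame:
    """Raw nuisance-covariate frame from a subject table.

    Mean framewise displacement is task-specific: with ``contrast`` given,
    the ``fd_<contrast>`` column is used, otherwise ``mean_fd``.
    """
    fd = table[f"fd_{contrast}"] if contrast is not None else table["mean_fd"]
    out = pd.DataFrame({
        "age": table["age"],
        "age_sq": table["age"] ** 2,
        "handedness": table["handedness"],
        "brain_volume": table["brain_volume"],
        "fd": fd,
        "fd_sq": fd**2,
        "gender": table["gender"],
        "recon_version": table["recon_version"],
    })
    return out


class CovariateEncoder:
    """Train-fitted covariate design: z-scored continuous columns, dummy-coded
    categoricals, and an intercept.  Test designs reuse train statistics."""

    def __init__(self, continuous: list[str] | None = None,
                 categorical: list[str] | None = None):
        self.continuous = continuous
        self.categorical = categorical
        self.means_: pd.Series | None = None
        self.sds_: pd.Series | None = None
        self.levels_: dict[str, list] = {}
        self.columns_: list[str] = []

    def fit(self, frame: pd.DataFrame) -> "CovariateEncoder":
        if self.continuous is None:
            self.continuous = [c for c in frame.columns
                               if pd.api.types.is_numeric_dtype(frame[c])]
        if self.categorical is None:
            self.categorical = [c for c in frame.columns
                                if c not in self.continuous]
        cont = frame[self.continuous]
        self.means_ = cont.mean()
        self.sds_ = cont.std(ddof=1)
        if np.any(self.sds_ <= 0):
            bad = list(self.sds_.index[self.sds_ <= 0])
            raise ValueError(f"zero-variance covariates: {bad}")
        self.levels_ = {c: sorted(frame[c].astype(str).unique())
                        for c in self.categorical}
        self.columns_ = (["intercept"] + list(self.continuous)
                         + [f"{c}={lv}" for c in self.categorical
                            for lv in self.levels_[c][1:]])
        Z = self.transform(frame)
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate design is rank deficient")
        return self

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        cont = (frame[self.continuous] - self.means_) / self.sds_
        cols = [np.ones(len(frame)), *[cont[c].to_numpy() for c in self.continuous]]
        for c in self.categorical:
            vals = frame[c].astype(str)
            for lv in self.levels_[c][1:]:
                cols.append((vals == lv).to_numpy(dtype=float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Basis, expression, regression
# ---------------------------------------------------------------------------

def _as_values(maps) -> np.ndarray:
    return maps.values if isinstance(maps, ContrastMatrix) else np.asarray(maps, dtype=float)


def build_basis(train_maps, K: int = DEFAULT_K) -> BasisSet:
    """PCA basis of the train maps: voxel means subtracted, SVD of the
    centered matrix, top-K right singular vectors retained.

    K is clipped to n_train - 1 (the PCA rank bound) with a warning.  The
    sign of each component is fixed so its largest-|loading| voxel is
    positive.
    """
    V = _as_values(train_maps)
    n, m = V.shape
    if K > n - 1:
        warnings.warn(f"K={K} exceeds n_train-1={n - 1}; clipping",
                      RuntimeWarning, stacklevel=2)
        K = n - 1
    if K < 1:
        raise ValueError("need K >= 1")
    means = V.mean(axis=0)
    Xc = V - means
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:K]
    flip = np.sign(comps[np.arange(K), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    eig = s[:K] ** 2 / (n - 1)
    return BasisSet(components=comps, eigenvalues=eig, voxel_means=means,
                    n_train=n)


def expression_scores(basis: BasisSet, maps) -> np.ndarray:
    """Project maps onto the basis: (values - train voxel means) @ components^T.

    Train voxel means are reused for test maps; no test statistic enters.
    """
    V = _as_values(maps)
    if V.shape[1] != basis.components.shape[1]:
        raise ValueError("voxel count mismatch with basis")
    return (V - basis.voxel_means) @ basis.components.T


def fit_bbs(expr: np.ndarray, y: np.ndarray, Z: np.ndarray,
            basis: BasisSet | None = None,
            covariate_names: list[str] | None = None) -> BBSModel:
    """Joint ordinary-least-squares fit y = X beta + Z gamma + eps.

    Rank-deficient designs (e.g. K = n_train - 1 plus covariates) are
    solved with the minimum-norm least-squares solution and a warning.
    """
    X = np.asarray(expr, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (X.shape[0] == Z.shape[0] == y.shape[0]):
        raise ValueError("row count mismatch between expr, y and Z")
    A = np.hstack([X, Z])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"design is rank deficient (rank {rank} < {A.shape[1]} columns); "
            "using the minimum-norm solution", RuntimeWarning, stacklevel=2)
    K = X.shape[1]
    return BBSModel(beta=coef[:K], gamma=coef[K:], basis=basis,
                    covariate_names=covariate_names or [])


def predict_adjusted(model: BBSModel, expr_test: np.ndarray,
                     Z_test: np.ndarray, y_test: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Covariate-adjusted observed and predicted responses for a test set.

    y_adj = y_test - Z_test @ gamma_hat ; y_hat = X_test @ beta_hat.
    All coefficients come from the train fit; nothing is re-estimated.
    """
    X = np.asarray(expr_test, dtype=float)
    Z = np.asarray(Z_test, dtype=float)
    y = np.asarray(y_test, dtype=float)
    if X.shape[1] != len(model.beta) or Z.shape[1] != len(model.gamma):
        raise ValueError("shape mismatch with fitted model")
    y_adj = y - Z @ model.gamma
    y_hat = X @ model.beta
    if np.allclose(model.beta, 0.0):
        warnings.warn("all brain coefficients are zero: prediction is "
                      "degenerate and correlations are undefined",
                      RuntimeWarning, stacklevel=2)
    return y_adj, y_hat


def consensus_map(basis: BasisSet, model: BBSModel) -> np.ndarray:
    """Beta-weighted sum of component maps, z-scored over voxels."""
    if len(model.beta) != basis.K:
        raise ValueError("model was not fitted on this basis")
    raw = model.beta @ basis.components
    sd = raw.std()
    if sd == 0:
        raise ValueError("consensus map has zero variance")
    return (raw - raw.mean()) / sd
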