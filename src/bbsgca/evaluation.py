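"""Family-aware cross-validation and permutation inference for BBS models.

Every fold refits the full chain on its train partition only: the bifactor
factor model (GCA scoring), the PCA basis, the covariate encoding, and the
joint regression.  Family members always share a fold, so the model is
never trained on one sibling and tested on another.

Significance uses the Freedman-Lane scheme: the ten behavioral scores are
regressed on the nuisance covariates over the full sample, the residual
rows are permuted, refitted values are added back, and the entire
cross-validation - including per-fold factor refitting - is rerun on the
reconstructed scores.  The observed pooled correlation is located in the
resulting null distribution by rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import factor as _factor
from .bbs import (CovariateEncoder, build_basis, expression_scores, fit_bbs,
                  predict_adjusted, DEFAULT_K)

__all__ = [
    "FoldAssignment",
    "CVResult",
    "PermutationNull",
    "make_family_folds",
    "fisher_average",
    "r2_cv",
    "mse",
    "fold_ci",
    "run_cv",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Subject-to-fold labels (1..k) respecting family structure."""

    labels: np.ndarray
    k: int
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) - set(range(1, self.k + 1)):
            raise ValueError("fold labels outside 1..k")

    def split(self):
        for j in range(1, self.k + 1):
            test = self.labels == j
            yield ~test, test


def make_family_folds(subjects: pd.DataFrame, k: int = 10,
                      seed: int | None = 0) -> FoldAssignment:
    """Assign whole families to folds: shuffle families by seed, then give
    each family to the currently smallest fold."""
    fam = subjects["family_id"].to_numpy()
    families, inverse = np.unique(fam, return_inverse=True)
    if len(families) < k:
        raise ValueError(f"only {len(families)} families for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(families))
    sizes = np.bincount(inverse)
    fold_of_family = np.empty(len(families), dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for fi in order:
        j = int(np.argmin(fold_sizes))
        fold_of_family[fi] = j + 1
        fold_sizes[j] += sizes[fi]
    return FoldAssignment(labels=fold_of_family[inverse], k=k, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def fisher_average(rs) -> float:
    """Fisher r-to-z average of per-fold correlations: tanh(mean(atanh r))."""
    r = np.asarray(rs, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation of |r| >= 1 clamped before Fisher "
                      "transform", RuntimeWarning, stacklevel=2)
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(r))))


def r2_cv(y_adj, y_hat, ybar_train: float) -> float:
    """Cross-validated R^2 referenced to the train-set mean:
    1 - SS(y_adj - y_hat) / SS(y_adj - ybar_train)."""
    y_adj = np.asarray(y_adj, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    denom = np.sum((y_adj - ybar_train) ** 2)
    if denom == 0:
        raise ValueError("zero denominator in R2cv")
    return float(1.0 - np.sum((y_adj - y_hat) ** 2) / denom)


def mse(y_adj, y_hat) -> float:
    """Mean squared prediction error with an n - 1 denominator."""
    y_adj = np.asarray(y_adj, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y_adj) < 2:
        raise ValueError("need at least 2 observations")
    return float(np.sum((y_adj - y_hat) ** 2) / (len(y_adj) - 1))


def fold_ci(per_fold_rs, level: float = 0.95, use_sem: bool = False
            ) -> tuple[float, float]:
    """Normal-theory interval mean +/- z * SD over folds.

    The dispersion is the SD of per-fold correlations (switchable to the
    SEM), so the interval describes fold-to-fold variability around the
    mean accuracy.
    """
    r = np.asarray(per_fold_rs, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 folds")
    z = stats.norm.ppf(0.5 + level / 2)
    disp = r.std(ddof=1)
    if use_sem:
        disp /= np.sqrt(len(r))
    return float(r.mean() - z * disp), float(r.mean() + z * disp)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    per_fold_r: np.ndarray
    pooled_r: float
    r2_cv: float
    mse: float
    ci: tuple[float, float]
    ybar_train: np.ndarray            # per-fold adjusted train mean
    K: int
    contrast_name: str = ""
    fold_models: list | None = None   # per-fold artifacts when requested
    predictions: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast_name,
            "per_fold_r": [float(v) for v in self.per_fold_r],
            "pooled_r": float(self.pooled_r),
            "r2_cv": float(self.r2_cv),
            "mse": float(self.mse),
            "ci_low": float(self.ci[0]),
            "ci_high": float(self.ci[1]),
            "K": int(self.K),
        }


@dataclass
class PermutationNull:
    null_r: np.ndarray
    observed_r: float
    p_value: float
    B: int
    seed: int
    exceeds_all: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_r": float(self.observed_r),
            "p_value": float(self.p_value),
            "B": int(self.B),
            "seed": int(self.seed),
            "exceeds_all": bool(self.exceeds_all),
            "null_mean": float(np.mean(self.null_r)),
            "null_sd": float(np.std(self.null_r, ddof=1)),
        }


class _PreparedFolds:
    """Per-fold quantities that depend only on maps, covariates and the fold
    assignment - reusable across behavioral permutations."""

    def __init__(self, maps, covariates: pd.DataFrame, folds: FoldAssignment,
                 K: int):
        from .bbs import ContrastMatrix
        V = maps.values if isinstance(maps, ContrastMatrix) else np.asarray(maps, dtype=float)
        if V.shape[0] != len(covariates):
            raise ValueError("maps and covariates are not aligned")
        self.folds = folds
        self.items = []
        for train, test in folds.split():
            basis = build_basis(V[train], K)
            enc = CovariateEncoder().fit(covariates.iloc[np.flatnonzero(train)])
            item = {
                "train": np.flatnonzero(train),
                "test": np.flatnonzero(test),
                "basis": basis,
                "encoder": enc,
                "X_train": expression_scores(basis, V[train]),
                "X_test": expression_scores(basis, V[test]),
                "Z_train": enc.transform(covariates.iloc[np.flatnonzero(train)]),
                "Z_test": enc.transform(covariates.iloc[np.flatnonzero(test)]),
            }
            self.items.append(item)


def _behavior_matrix(behavior) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(behavior, pd.DataFrame):
        return behavior.to_numpy(dtype=float), behavior
    return np.asarray(behavior, dtype=float), None


def _cv_over_folds(prepared: _PreparedFolds, B_mat: np.ndarray,
                   behavior_df: pd.DataFrame | None,
                   warm: list | None = None, collect: bool = False):
    """One full CV pass for a given behavioral matrix (n x 10)."""
    per_r, per_r2, per_mse, ybars = [], [], [], []
    models, rows = [], []
    for i, it in enumerate(prepared.items):
        tr, te = it["train"], it["test"]
        fwarm = warm[i] if warm is not None else None
        fm = _factor.fit_bifactor(
            behavior_df.iloc[tr] if behavior_df is not None else B_mat[tr],
            warm=fwarm)
        y_train = _factor.score_subjects(fm, B_mat[tr])
        y_test = _factor.score_subjects(fm, B_mat[te])
        model = fit_bbs(it["X_train"], y_train, it["Z_train"],
                        basis=it["basis"],
                        covariate_names=it["encoder"].columns_)
        y_adj, y_hat = predict_adjusted(model, it["X_test"], it["Z_test"], y_test)
        ybar = float(np.mean(y_train - it["Z_train"] @ model.gamma))
        per_r.append(float(np.corrcoef(y_adj, y_hat)[0, 1]))
        per_r2.append(r2_cv(y_adj, y_hat, ybar))
        per_mse.append(mse(y_adj, y_hat))
        ybars.append(ybar)
        if collect:
            models.append({"factor_model": fm, "basis": it["basis"],
                           "beta": model.beta, "gamma": model.gamma,
                           "encoder": it["encoder"]})
            rows.append(pd.DataFrame({
                "index": te, "fold": i + 1, "y_adjusted": y_adj,
                "y_predicted": y_hat}))
    return per_r, per_r2, per_mse, ybars, models, rows


def run_cv(maps, behavior, covariates: pd.DataFrame, folds: FoldAssignment,
           K: int = DEFAULT_K, contrast_name: str = "",
           return_details: bool = False,
           _prepared: _PreparedFolds | None = None) -> CVResult:
    """Family-aware K-fold cross-validation of the full prediction chain.

    Per fold: the bifactor model is fit on train behavior and scored onto
    train and test subjects; the PCA basis, covariate standardization and
    the joint regression are all train-only; test-side quantities use the
    train coefficients.  Per-fold correlations are pooled with the Fisher
    average; R^2cv and MSE are averaged arithmetically.
    """
    B_mat, behavior_df = _behavior_matrix(behavior)
    prepared = _prepared or _PreparedFolds(maps, covariates, folds, K)
    warm = [{} for _ in prepared.items]
    per_r, per_r2, per_mse, ybars, models, rows = _cv_over_folds(
        prepared, B_mat, behavior_df, warm=warm, collect=return_details)
    return CVResult(
        per_fold_r=np.asarray(per_r),
        pooled_r=fisher_average(per_r),
        r2_cv=float(np.mean(per_r2)),
        mse=float(np.mean(per_mse)),
        ci=fold_ci(per_r),
        ybar_train=np.asarray(ybars),
        K=prepared.items[0]["basis"].K,
        contrast_name=contrast_name,
        fold_models=models if return_details else None,
        predictions=pd.concat(rows, ignore_index=True) if return_details else None,
    )


# ---------------------------------------------------------------------------
# Freedman-Lane permutation test
# ---------------------------------------------------------------------------

def _null_pooled_r(prepared: _PreparedFolds, Y_null: np.ndarray) -> np.ndarray:
    """Pooled CV correlation for each of B reconstructed behavior matrices.

    Y_null has shape (B, n, 10).  The bifactor refits for all folds and
    permutations are solved in one batched call; the per-fold regressions
    reuse the precomputed expression scores and covariate designs.
    """
    B, n, p = Y_null.shape
    nf = len(prepared.items)
    Rs = np.empty((B * nf, p, p))
    stats_cache = []
    for i, it in enumerate(prepared.items):
        Yt = Y_null[:, it["train"], :]                      # (B, n_tr, p)
        mu = Yt.mean(axis=1)
        sd = Yt.std(axis=1, ddof=1)
        Zt = (Yt - mu[:, None, :]) / sd[:, None, :]
        C = np.matmul(Zt.transpose(0, 2, 1), Zt) / (Yt.shape[1] - 1)
        # guard against tiny asymmetries
        Rs[i * B:(i + 1) * B] = 0.5 * (C + C.transpose(0, 2, 1))
        stats_cache.append((mu, sd))
    sol = _factor.bifactor_batch(Rs)
    W = sol["weights"]
    null_z = np.empty((nf, B))
    for i, it in enumerate(prepared.items):
        mu, sd = stats_cache[i]
        Wf = W[i * B:(i + 1) * B]                           # (B, p)
        A = np.hstack([it["X_train"], it["Z_train"]])
        pinv = np.linalg.pinv(A)
        K = it["X_train"].shape[1]
        Yt = Y_null[:, it["train"], :]
        Yte = Y_null[:, it["test"], :]
        y_tr = np.einsum("bnp,bp->bn", (Yt - mu[:, None, :]) / sd[:, None, :], Wf)
        y_te = np.einsum("bnp,bp->bn", (Yte - mu[:, None, :]) / sd[:, None, :], Wf)
        coef = y_tr @ pinv.T                                # (B, K+p)
        y_hat = coef[:, :K] @ it["X_test"].T                # (B, n_te)
        y_adj = y_te - coef[:, K:] @ it["Z_test"].T
        ha = y_hat - y_hat.mean(axis=1, keepdims=True)
        aa = y_adj - y_adj.mean(axis=1, keepdims=True)
        r = np.einsum("bn,bn->b", ha, aa) / np.sqrt(
            np.einsum("bn,bn->b", ha, ha) * np.einsum("bn,bn->b", aa, aa))
        null_z[i] = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    return np.tanh(null_z.mean(axis=0))


def permutation_test(maps, behavior, covariates: pd.DataFrame,
                     folds: FoldAssignment, K: int = DEFAULT_K, B: int = 10000,
                     seed: int = 0, within_family: bool = False,
                     subjects: pd.DataFrame | None = None,
                     observed: CVResult | None = None) -> PermutationNull:
    """Freedman-Lane permutation test of the pooled CV correlation.

    Per iteration the nuisance-only model S = Z gamma + E is fit to the ten
    raw test scores over the full sample, residual rows E are permuted,
    scores are reconstructed as Z gamma_hat + E_perm, and the complete
    cross-validation (bifactor refit per fold included) is rerun.  The
    p-value is the rank of the observed pooled r in the null divided by B;
    an observed value exceeding every null draw is reported as p = 1/B with
    ``exceeds_all`` set.

    ``within_family`` restricts permutations to shuffle subjects within
    families only (an exchangeability-preserving variant; the default
    permutes freely).
    """
    if B < 1:
        raise ValueError("need B >= 1")
    if B < 99:
        warnings.warn(f"B={B} is too small to resolve conventional "
                      "significance levels", RuntimeWarning, stacklevel=2)
    B_mat, behavior_df = _behavior_matrix(behavior)
    n = B_mat.shape[0]
    prepared = _PreparedFolds(maps, covariates, folds, K)
    if observed is None:
        observed = run_cv(maps, behavior, covariates, folds, K,
                          _prepared=prepared)

    enc = CovariateEncoder().fit(covariates)
    Z = enc.transform(covariates)
    coef, *_ = np.linalg.lstsq(Z, B_mat, rcond=None)
    fitted = Z @ coef
    resid = B_mat - fitted

    rng = np.random.default_rng(seed)
    if within_family:
        if subjects is None:
            raise ValueError("within_family permutation needs the subject table")
        fam = subjects["family_id"].to_numpy()
        perms = np.empty((B, n), dtype=int)
        base = np.arange(n)
        for b in range(B):
            perm = base.copy()
            for f in np.unique(fam):
                idx = np.flatnonzero(fam == f)
                perm[idx] = idx[rng.permutation(len(idx))]
            perms[b] = perm
    else:
        perms = np.array([rng.permutation(n) for _ in range(B)])

    Y_null = fitted[None, :, :] + resid[perms]
    null_r = _null_pooled_r(prepared, Y_null)

    count = int(np.sum(null_r >= observed.pooled_r))
    exceeds_all = count == 0
    p = max(count, 1) / B
    return PermutationNull(null_r=null_r, observed_r=float(observed.pooled_r),
                           p_value=float(p), B=B, seed=seed,
                           exceeds_all=exceeds_all)
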