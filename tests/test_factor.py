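"""Bifactor pipeline: ML extraction against an independent oracle,
Schmid-Leiman structure, scoring contracts, ICC and SRMR arithmetic."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from bbsgca import factor as F
from bbsgca import synthetic as syn

from conftest import bifactor_sample


# ---------------------------------------------------------------------------
# ML extraction
# ---------------------------------------------------------------------------

def test_ml_efa_matches_base_r_factanal():
    """Unrotated ML solution cross-checked against R's factanal on the
    same correlation matrix (uniquenesses are rotation-invariant)."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    X, *_ = bifactor_sample(n=600, seed=3)
    R = np.corrcoef(X, rowvar=False)
    _, psi = F.ml_efa(R, 4)
    rcode = """
    R <- as.matrix(read.csv("corr.csv", header=FALSE))
    fit <- factanal(covmat=R, factors=4, rotation="none", n.obs=600)
    write.csv(fit$uniquenesses, "psi.csv", row.names=FALSE)
    """
    import tempfile, os
    with tempfile.TemporaryDirectory() as td:
        np.savetxt(os.path.join(td, "corr.csv"), R, delimiter=",")
        script = os.path.join(td, "run.R")
        with open(script, "w") as f:
            f.write(rcode)
        subprocess.run(["Rscript", "--vanilla", script], cwd=td, check=True,
                       capture_output=True)
        psi_r = pd.read_csv(os.path.join(td, "psi.csv"))["x"].to_numpy()
    assert np.abs(psi - psi_r).max() < 2e-3


def test_batched_efa_agrees_with_sequential():
    rng = np.random.default_rng(1)
    Rs = []
    for s in range(40):
        X, *_ = bifactor_sample(n=250, seed=100 + s)
        Rs.append(np.corrcoef(X, rowvar=False))
    Rs = np.array(Rs)
    out = F.bifactor_batch(Rs)
    assert out["converged"].all()
    for m in range(0, 40, 7):
        sol = F.bifactor_from_corr(Rs[m])
        assert np.abs(sol["general"] - out["general"][m]).max() < 1e-3
        w1 = np.linalg.solve(Rs[m], sol["general"])
        w2 = out["weights"][m]
        cos = w1 @ w2 / np.linalg.norm(w1) / np.linalg.norm(w2)
        assert cos > 1 - 1e-6


# ---------------------------------------------------------------------------
# Schmid-Leiman structure
# ---------------------------------------------------------------------------

def _population_corr(general, group):
    lg = np.asarray(general)
    lf = np.asarray(group)
    psi = 1 - lg**2 - (lf**2).sum(axis=1)
    return np.outer(lg, lg) + lf @ lf.T + np.diag(psi)


@pytest.mark.parametrize("general,group", [
    (0.7, 0.4),
    (0.6, 0.5),
    (0.75, 0.3),
])
def test_schmid_leiman_preserves_communalities_on_hierarchical_population(
        general, group):
    """On an exactly hierarchical population matrix the first-order factor
    correlation is rank-1 plus diagonal, so the Schmid-Leiman split must
    return the first-order communalities exactly."""
    _, blocks = syn.default_behavior_loadings()
    lf = np.where(blocks != 0, group, 0.0)
    R = _population_corr(np.full(10, general), lf)
    sol = F.bifactor_from_corr(R)
    h2_first = np.einsum("jk,jk->j", sol["unrotated"], sol["unrotated"])
    h2_sl = sol["general"]**2 + (sol["group"]**2).sum(axis=1)
    assert np.abs(h2_first - h2_sl).max() < 1e-8
    # and the split recovers the generating loadings
    assert np.abs(sol["general"] - general).max() < 1e-5
    assert np.abs(np.sort(sol["group"].max(axis=1)) -
                  np.sort(lf.max(axis=1))).max() < 1e-5


def test_bifactor_recovers_generating_structure_from_samples():
    X, g, lg, lf, psi = bifactor_sample(n=1000, seed=0)
    m = F.fit_bifactor(X)
    assert np.abs(m.general_loadings - 0.7).max() < 0.1
    num = lg.sum() ** 2
    omega_true = num / (num + np.sum(lf.sum(axis=0) ** 2) + psi.sum())
    assert m.omega_hierarchical == pytest.approx(omega_true, abs=0.05)
    gh = F.score_subjects(m, X)
    assert np.corrcoef(gh, g)[0, 1] > 0.9
    assert m.srmr < 0.05


def test_orthogonal_one_factor_data_yields_no_group_loadings():
    """With zero group variance the group loadings vanish exactly on the
    population matrix.  On finite samples, extracting four factors from
    one-factor data is overfactoring: ML places spurious singleton factors
    on noise (a Heywood configuration the fit flags), but the general
    factor and its scores are unaffected.  (On the exact population matrix
    the higher-order decomposition is unidentified - the null first-order
    factors make the factor correlations arbitrary - so the claim is only
    testable on samples.)"""
    X, g, *_ = bifactor_sample(n=2000, seed=4, group=0.0)
    with pytest.warns(RuntimeWarning):
        m = F.fit_bifactor(X)
    assert m.heywood
    assert np.abs(m.general_loadings - 0.7).max() < 0.1
    assert np.corrcoef(F.score_subjects(m, X), g)[0, 1] > 0.9


def test_refit_stability_on_bootstrap_resample():
    X, *_ = bifactor_sample(n=1000, seed=5)
    rng = np.random.default_rng(6)
    m1 = F.fit_bifactor(X)
    m2 = F.fit_bifactor(X[rng.integers(0, 1000, size=1000)])
    assert np.abs(m1.general_loadings - m2.general_loadings).max() < 0.1


def test_fit_rejects_bad_input():
    X, *_ = bifactor_sample(n=50, seed=7)
    with pytest.raises(ValueError):
        F.fit_bifactor(X[:30])                 # too few subjects
    X2, *_ = bifactor_sample(n=100, seed=7)
    X2[3, 4] = np.nan
    with pytest.raises(ValueError):
        F.fit_bifactor(X2)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def test_train_scores_are_centered_and_train_mean_subject_scores_zero():
    X, *_ = bifactor_sample(n=400, seed=8)
    m = F.fit_bifactor(X)
    s = F.score_subjects(m, X)
    assert abs(s.mean()) < 1e-10
    at_mean = F.score_subjects(m, m.means[None, :])
    assert at_mean[0] == pytest.approx(0.0, abs=1e-12)


def test_scoring_is_invariant_to_affine_rescaling_of_the_battery():
    X, *_ = bifactor_sample(n=400, seed=9)
    a = np.linspace(0.5, 3.0, 10)
    b = np.linspace(-5, 5, 10)
    m1 = F.fit_bifactor(X)
    m2 = F.fit_bifactor(X * a + b)
    s1 = F.score_subjects(m1, X)
    s2 = F.score_subjects(m2, X * a + b)
    np.testing.assert_allclose(s1, s2, atol=1e-8)


def test_scoring_validates_columns():
    X, *_ = bifactor_sample(n=400, seed=10)
    df = pd.DataFrame(X, columns=[f"test_{j+1}" for j in range(10)])
    m = F.fit_bifactor(df)
    wrong = df.rename(columns={"test_1": "other"})
    with pytest.raises(ValueError):
        F.score_subjects(m, wrong)
    with pytest.raises(ValueError):
        F.score_subjects(m, X[:, :9])


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

def _icc_2_1_brute(x, y):
    """Independent oracle: explicit two-way ANOVA table."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ms_r = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
    ss_e = ((data - data.mean(1)[:, None] - data.mean(0)[None, :] + grand) ** 2).sum()
    ms_e = ss_e / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


def test_icc_perfect_agreement_is_one():
    x = np.array([1.0, 2.0, 5.0, 3.0])
    assert F.icc_2_1(x, x) == pytest.approx(1.0)


def test_icc_penalizes_constant_offsets():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(500)
    iccs = [F.icc_2_1(x, x + c) for c in (0.0, 0.5, 1.0, 2.0)]
    assert iccs[0] == pytest.approx(1.0)
    assert all(a > b for a, b in zip(iccs, iccs[1:]))


def test_icc_matches_brute_force_anova_and_pingouin():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])
    expect = _icc_2_1_brute(x, y)
    assert F.icc_2_1(x, y) == pytest.approx(expect, abs=1e-12)
    pingouin = pytest.importorskip("pingouin")
    df = pd.DataFrame({
        "targets": np.repeat(np.arange(4), 2),
        "raters": np.tile(["s1", "s2"], 4),
        "score": np.column_stack([x, y]).ravel(),
    })
    icc_table = pingouin.intraclass_corr(df, targets="targets",
                                         raters="raters", ratings="score")
    ref = icc_table.loc[icc_table["Type"] == "ICC(A,1)", "ICC"].iloc[0]
    assert F.icc_2_1(x, y) == pytest.approx(ref, abs=1e-10)


def test_icc_degenerate_input_raises():
    with pytest.raises(ValueError):
        F.icc_2_1(np.ones(5), np.ones(5))
    with pytest.raises(ValueError):
        F.icc_2_1([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# SRMR
# ---------------------------------------------------------------------------

def test_srmr_examples():
    R = np.eye(3)
    assert F.srmr(R, R) == 0.0
    # constant residual r on every off-diagonal
    O = np.full((4, 4), 0.5)
    np.fill_diagonal(O, 1.0)
    M = np.full((4, 4), 0.3)
    np.fill_diagonal(M, 1.0)
    assert F.srmr(O, M) == pytest.approx(0.2, abs=1e-12)
    # 3x3 with residuals (0.1, -0.2, 0.2) -> sqrt(0.09/3)
    O3 = np.eye(3)
    M3 = np.eye(3)
    O3[1, 0] = O3[0, 1] = 0.1
    O3[2, 0] = O3[0, 2] = -0.2
    O3[2, 1] = O3[1, 2] = 0.2
    assert F.srmr(O3, M3) == pytest.approx(np.sqrt(0.09 / 3), abs=1e-12)
    with pytest.raises(ValueError):
        F.srmr(np.eye(3), np.eye(4))
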