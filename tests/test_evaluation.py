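"""Cross-validation and permutation machinery: fold construction, pooled
metrics, train/test hygiene, and Freedman-Lane determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbsgca import bbs, evaluation as ev, synthetic as syn


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def _family_table(rng, n_families, max_size=5):
    sizes = rng.integers(1, max_size + 1, size=n_families)
    fam = np.repeat([f"F{i}" for i in range(n_families)], sizes)
    return pd.DataFrame({"family_id": fam,
                         "subject_id": [f"S{i}" for i in range(len(fam))]})


def test_singleton_families_give_perfectly_balanced_folds():
    df = pd.DataFrame({"family_id": [f"F{i}" for i in range(100)],
                       "subject_id": [f"S{i}" for i in range(100)]})
    fa = ev.make_family_folds(df, k=10, seed=0)
    assert np.bincount(fa.labels)[1:].tolist() == [10] * 10


def test_families_never_straddle_folds():
    rng = np.random.default_rng(0)
    for trial in range(100):
        df = _family_table(rng, int(rng.integers(12, 60)))
        fa = ev.make_family_folds(df, k=10, seed=int(rng.integers(1 << 30)))
        per_family = pd.Series(fa.labels).groupby(df["family_id"]).nunique()
        assert (per_family == 1).all()


def test_greedy_fold_sizes_for_23_families_of_three():
    df = pd.DataFrame({"family_id": np.repeat([f"F{i}" for i in range(23)], 3),
                       "subject_id": [f"S{i}" for i in range(69)]})
    for seed in range(20):
        fa = ev.make_family_folds(df, k=10, seed=seed)
        counts = np.bincount(fa.labels)[1:]
        assert counts.max() - counts.min() <= 3


def test_too_few_families_raises():
    df = _family_table(np.random.default_rng(1), 5)
    with pytest.raises(ValueError):
        ev.make_family_folds(df, k=10)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_fisher_average_examples():
    assert ev.fisher_average([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
    assert ev.fisher_average([0.0, 0.0]) == 0.0
    expect = np.tanh((np.arctanh(0.3) + np.arctanh(0.7)) / 2)
    assert ev.fisher_average([0.3, 0.7]) == pytest.approx(expect, abs=1e-12)
    assert expect == pytest.approx(0.5288, abs=5e-5)
    with pytest.warns(RuntimeWarning):
        assert ev.fisher_average([1.0, 0.0]) < 1.0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-0.99, 0.99), min_size=2, max_size=12))
def test_fisher_average_stays_within_fold_range(rs):
    pooled = ev.fisher_average(rs)
    assert min(rs) - 1e-12 <= pooled <= max(rs) + 1e-12


def test_r2cv_and_mse_hand_examples():
    y_adj = np.array([1.0, 2.0, 3.0])
    y_hat = np.array([1.0, 1.0, 3.0])
    assert ev.r2_cv(y_adj, y_hat, 2.0) == pytest.approx(0.5, abs=1e-12)
    assert ev.mse(y_adj, y_hat) == pytest.approx(0.5, abs=1e-12)
    assert ev.r2_cv(y_adj, y_adj, 2.0) == 1.0
    assert ev.mse(y_adj, y_adj) == 0.0
    # predicting the train mean when the test mean coincides scores zero
    assert ev.r2_cv(y_adj, np.full(3, 2.0), 2.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        ev.r2_cv(np.full(3, 2.0), y_hat, 2.0)


def test_fold_ci_examples():
    lo, hi = ev.fold_ci([0.5, 0.5, 0.5])
    assert lo == pytest.approx(0.5) and hi == pytest.approx(0.5)
    lo, hi = ev.fold_ci([0.4, 0.6])
    sd = np.std([0.4, 0.6], ddof=1)
    assert lo == pytest.approx(0.5 - 1.959963984540054 * sd, abs=1e-9)
    assert hi == pytest.approx(0.5 + 1.959963984540054 * sd, abs=1e-9)
    lo_sem, hi_sem = ev.fold_ci([0.4, 0.6], use_sem=True)
    assert hi_sem - lo_sem < hi - lo
    with pytest.raises(ValueError):
        ev.fold_ci([0.5])


# ---------------------------------------------------------------------------
# run_cv
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cv_inputs():
    spec = syn.SyntheticSpec(n_subjects=150, n_voxels=250, seed=21)
    coh = syn.generate_cohort(spec)
    parc = syn.make_parcellation(spec)
    maps = syn.generate_contrast_maps(coh, parc, spec, "2bk-0bk")
    folds = ev.make_family_folds(coh, 10, seed=2)
    cov = bbs.covariate_frame(coh, "2bk-0bk")
    return coh, maps, folds, cov


def test_run_cv_is_invariant_to_joint_row_permutation(cv_inputs):
    coh, maps, folds, cov = cv_inputs
    res = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(coh))
    folds_p = ev.FoldAssignment(labels=folds.labels[perm], k=folds.k)
    res_p = ev.run_cv(maps[perm], coh[syn.TEST_NAMES].iloc[perm],
                      cov.iloc[perm].reset_index(drop=True), folds_p, K=30)
    assert res_p.pooled_r == pytest.approx(res.pooled_r, abs=1e-9)
    np.testing.assert_allclose(np.sort(res_p.per_fold_r),
                               np.sort(res.per_fold_r), atol=1e-9)


def test_run_cv_results_are_deterministic(cv_inputs):
    coh, maps, folds, cov = cv_inputs
    r1 = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    r2 = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    assert r1.pooled_r == r2.pooled_r
    assert r1.r2_cv == r2.r2_cv


def test_single_component_suffices_when_signal_lives_in_first_component():
    """A contrast whose g-signal is confined to the dominant component is
    predicted equally well by K=1 and K=75."""
    spec = syn.SyntheticSpec(n_subjects=600, n_voxels=300, seed=22,
                             gca_coupling=1.2, noise_sd=0.25,
                             component_score_sds=(6.0, 0.5, 0.5, 0.5, 0.5))
    coh = syn.generate_cohort(spec)
    parc = syn.make_parcellation(spec)
    maps = syn.generate_contrast_maps(coh, parc, spec, "2bk-0bk")
    folds = ev.make_family_folds(coh, 10, seed=4)
    cov = bbs.covariate_frame(coh, "2bk-0bk")
    r1 = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=1).pooled_r
    r75 = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=75).pooled_r
    assert abs(r1 - r75) <= 0.02


def test_corrupting_one_test_fold_leaves_its_trained_model_untouched(cv_inputs):
    """Leak detector: poisoning the held-out subjects of fold j changes
    predictions but not the coefficients, basis, or factor loadings trained
    without them."""
    coh, maps, folds, cov = cv_inputs
    res = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                    return_details=True)
    j = 1
    test_idx = np.flatnonzero(folds.labels == j)
    rng = np.random.default_rng(99)
    maps_bad = maps.copy()
    maps_bad[test_idx] = rng.standard_normal(maps_bad[test_idx].shape) * 7.0
    beh_bad = coh[syn.TEST_NAMES].copy()
    beh_bad.iloc[test_idx] = rng.standard_normal((len(test_idx), 10))
    res_bad = ev.run_cv(maps_bad, beh_bad, cov, folds, K=30,
                        return_details=True)
    good, bad = res.fold_models[j - 1], res_bad.fold_models[j - 1]
    np.testing.assert_allclose(good["beta"], bad["beta"], atol=1e-10)
    np.testing.assert_allclose(good["gamma"], bad["gamma"], atol=1e-10)
    np.testing.assert_allclose(good["basis"].components,
                               bad["basis"].components, atol=1e-10)
    np.testing.assert_allclose(good["factor_model"].general_loadings,
                               bad["factor_model"].general_loadings,
                               atol=1e-10)
    # but the fold's test-side prediction quality collapses
    assert res_bad.per_fold_r[j - 1] != pytest.approx(res.per_fold_r[j - 1],
                                                      abs=1e-6)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def test_permutation_null_is_seed_deterministic_and_centered(cv_inputs):
    coh, maps, folds, cov = cv_inputs
    res = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    p1 = ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                             B=60, seed=9, observed=res)
    p2 = ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                             B=60, seed=9, observed=res)
    np.testing.assert_array_equal(p1.null_r, p2.null_r)
    assert abs(np.mean(p1.null_r)) < 0.05
    # rank-based p-value against a manual count
    count = int(np.sum(p1.null_r >= res.pooled_r))
    assert p1.p_value == pytest.approx(max(count, 1) / 60)


def test_permutation_p_is_large_when_observed_sits_mid_null(cv_inputs):
    coh, maps, folds, cov = cv_inputs
    res = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    pn = ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                             B=60, seed=10, observed=res)
    fake = ev.CVResult(per_fold_r=res.per_fold_r,
                       pooled_r=float(np.median(pn.null_r)),
                       r2_cv=res.r2_cv, mse=res.mse, ci=res.ci,
                       ybar_train=res.ybar_train, K=res.K)
    pn_mid = ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                                 B=60, seed=10, observed=fake)
    assert 0.3 <= pn_mid.p_value <= 0.7


def test_within_family_permutation_runs_and_differs(cv_inputs):
    coh, maps, folds, cov = cv_inputs
    res = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    pn = ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                             B=20, seed=12, observed=res,
                             within_family=True, subjects=coh)
    # within-family shuffles move little behavioral signal, so the null
    # concentrates near the observed statistic
    assert pn.null_r.std() < 0.2
    with pytest.raises(ValueError):
        ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                            B=5, seed=1, observed=res, within_family=True)


def test_small_B_warns(cv_inputs):
    coh, maps, folds, cov = cv_inputs
    res = ev.run_cv(maps, coh[syn.TEST_NAMES], cov, folds, K=30)
    with pytest.warns(RuntimeWarning, match="too small"):
        ev.permutation_test(maps, coh[syn.TEST_NAMES], cov, folds, K=30,
                            B=10, seed=2, observed=res)
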