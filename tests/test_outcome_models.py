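import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from pseudoscales import (
    ModelConfig,
    SamplingConfig,
    ValidationError,
    fit_logistic,
    results_frame,
    run_scale_models,
    sample_across,
    smote_resample,
)
from pseudoscales.burden_scoring import burden_table

from conftest import PERIOD


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def test_smote_balanced_input_unchanged():
    X = np.arange(20, dtype=float).reshape(10, 2)
    y = np.array([0] * 5 + [1] * 5)
    Xr, yr = smote_resample(X, y, k_neighbors=2, seed=0)
    assert Xr is X and yr is y


def test_smote_two_point_segment_convexity():
    """k=1 with two minority points: every synthetic point lies on the
    segment between them."""
    a, b = np.array([0.0, 0.0]), np.array([2.0, 1.0])
    X = np.vstack([np.random.default_rng(1).normal(10, 1, (40, 2)), a, b])
    y = np.array([0] * 40 + [1] * 2)
    Xr, yr = smote_resample(X, y, k_neighbors=1, seed=5)
    synth = Xr[42:]
    assert len(synth) == 38  # grown to the majority count
    t = (synth - a) @ (b - a) / ((b - a) @ (b - a))
    assert ((t >= 0) & (t <= 1)).all()
    assert np.allclose(synth, a + t[:, None] * (b - a), atol=1e-12)


def test_smote_rebalances_rare_class_counts():
    rng = np.random.default_rng(7)
    n = 5000
    y = (rng.random(n) < 0.016).astype(int)
    X = rng.normal(size=(n, 3)) + y[:, None]
    Xr, yr = smote_resample(X, y, seed=1)
    n_min, n_maj = np.bincount(yr)[1], np.bincount(yr)[0]
    assert n_maj == (y == 0).sum()
    assert abs(n_min - n_maj) <= 1
    # originals retained verbatim
    assert np.array_equal(Xr[:n], X)


def test_smote_preserves_categorical_columns():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(
        {"a": rng.normal(size=50), "flag": rng.integers(0, 2, 50).astype(float)}
    )
    y = np.array([0] * 40 + [1] * 10)
    Xr, yr = smote_resample(X, y, seed=3, categorical_cols=["flag"])
    assert set(Xr["flag"].unique()) <= {0.0, 1.0}


def test_smote_too_few_minority_samples_errors():
    X = np.random.default_rng(0).normal(size=(50, 2))
    y = np.array([0] * 47 + [1] * 3)
    with pytest.raises(ValidationError, match="smaller k"):
        smote_resample(X, y, k_neighbors=5)


def test_smote_deterministic_under_seed():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 2))
    y = (rng.random(200) < 0.1).astype(int)
    X1, _ = smote_resample(X, y, seed=9)
    X2, _ = smote_resample(X, y, seed=9)
    assert np.array_equal(X1, X2)


# ---------------------------------------------------------------------------
# Logistic fits
# ---------------------------------------------------------------------------

def _sim_logit(n, beta, seed, intercept=-1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(intercept + beta * x)).astype(float)
    return pd.DataFrame({"burden": x}), y


def test_fit_logistic_null_calibrated():
    X, y = _sim_logit(10_000, 0.0, seed=0)
    res = fit_logistic(X, y)
    se = (np.log(res.ci_high) - np.log(res.or_per_sd)) / 1.96
    assert abs(np.log(res.or_per_sd)) < 3 * se


def test_fit_logistic_recovers_known_effect():
    """Mean estimated log OR over replicates within 3 MC SE of the truth."""
    truth = 0.1
    coefs = []
    for rep in range(150):
        X, y = _sim_logit(20_000, truth, seed=1000 + rep)
        coefs.append(np.log(fit_logistic(X, y).or_per_sd))
    mc_se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
    assert abs(np.mean(coefs) - truth) < 3 * mc_se


def test_fit_logistic_matches_sklearn_reference():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({"burden": rng.normal(size=4000), "z": rng.normal(size=4000)})
    y = (rng.random(4000) < expit(0.3 * X["burden"] - 0.2 * X["z"])).astype(float)
    ours = fit_logistic(X, y)
    ref = LogisticRegression(C=np.inf, tol=1e-10, max_iter=1000).fit(X, y)
    assert np.log(ours.or_per_sd) == pytest.approx(ref.coef_[0][0], rel=1e-6)


def test_fit_logistic_perfect_separation_flagged():
    X = pd.DataFrame({"burden": np.r_[np.zeros(20), np.ones(20)]})
    y = np.r_[np.zeros(20), np.ones(20)]
    res = fit_logistic(X, y)
    assert not res.converged
    assert res.reason


def test_fit_logistic_ci_brackets_estimate():
    X, y = _sim_logit(5000, 0.2, seed=7)
    res = fit_logistic(X, y)
    assert res.ci_low <= res.or_per_sd <= res.ci_high
    assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# run_scale_models
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def model_inputs(bundled, pools, small_cohort):
    scales = sample_across(
        pools["general"],
        SamplingConfig(pool="general", n_scales=10, seed=31, size_range=(50, 150)),
    )
    bt = burden_table(
        small_cohort["prescriptions"],
        scales,
        PERIOD,
        small_cohort["participants"]["participant_id"],
    )
    return scales, bt


def test_one_result_per_scale_outcome_with_provenance(small_cohort, model_inputs):
    scales, bt = model_inputs
    results = run_scale_models(
        scales,
        bt,
        small_cohort["participants"],
        small_cohort["outcomes"],
        ModelConfig(seed=1),
    )
    assert len(results) == 10
    assert {r.scale_id for r in results} == {s.scale_id for s in scales}
    for r in results:
        assert r.outcome == "death"
        assert r.mode == "across" and r.pool == "general"
        assert r.scale_size == next(s for s in scales if s.scale_id == r.scale_id).size
        if r.converged:
            assert r.ci_low <= r.or_per_sd <= r.ci_high
            assert r.n_used <= 2 * len(small_cohort["participants"])


def test_empty_scale_list_rejected(small_cohort, model_inputs):
    _, bt = model_inputs
    with pytest.raises(ValidationError):
        run_scale_models(
            [], bt, small_cohort["participants"], small_cohort["outcomes"], ModelConfig()
        )


def test_unadjusted_exceeds_adjusted_on_confounded_data(small_cohort, model_inputs):
    """Age raises both prescribing volume and risk, so dropping confounders
    inflates the burden OR."""
    scales, bt = model_inputs
    args = (bt, small_cohort["participants"], small_cohort["outcomes"])
    adj = results_frame(run_scale_models(scales, *args, ModelConfig(adjusted=True, seed=2)))
    una = results_frame(run_scale_models(scales, *args, ModelConfig(adjusted=False, seed=2)))
    adj, una = adj[adj.converged], una[una.converged]
    assert una["or_per_sd"].median() > adj["or_per_sd"].median()


def test_permuted_burden_gives_nominal_type_one_error(small_cohort, model_inputs):
    """Permuting burden across participants severs any true association:
    the positive-and-significant rate should be ~ alpha/2 and the two-sided
    rejection rate ~ alpha."""
    scales, bt = model_inputs
    rng = np.random.default_rng(17)
    pvals, signs = [], []
    for rep in range(15):
        perm = bt.copy()
        for sid, grp in perm.groupby("scale_id"):
            idx = grp.index.to_numpy()
            perm.loc[idx, ["annual_burden", "residual_polypharmacy"]] = (
                grp[["annual_burden", "residual_polypharmacy"]]
                .to_numpy()[rng.permutation(len(idx))]
            )
        res = results_frame(
            run_scale_models(
                scales,
                perm,
                small_cohort["participants"],
                small_cohort["outcomes"],
                ModelConfig(smote=False, seed=rep),
            )
        )
        res = res[res.converged]
        pvals.extend(res["p_value"])
        signs.extend(res["or_per_sd"] > 1)
    pvals = np.array(pvals)
    rate = (pvals < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(pvals))
    assert rate < 0.05 + 3 * se + 0.02
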