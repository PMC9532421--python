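import numpy as np
import pandas as pd
import pytest
from sklearn.svm import LinearSVC

from cfhmc.classify import (
    CfDNAClassifier,
    CfDNAClassifierResults,
    EnsembleConfig,
    LearnerSpec,
    ModelRegistry,
    covariate_feature_filter,
    propensity_weights,
)


def synthetic_matrix(rng, n=80, p=20, effect=2.0, k=5):
    """Separable two-class matrix: first k features shifted in cases."""
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    X = rng.normal(size=(n, p))
    X[y == 1, :k] += effect
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)]), y


SMALL = EnsembleConfig(n_learners=4, cv_folds=4, c_grid=(0.01, 1.0), base_seed=0)


# ---------------------------------------------------------------------------
# covariate filter
# ---------------------------------------------------------------------------


def test_filter_excludes_covariate_copies_and_constants():
    rng = np.random.default_rng(0)
    n = 100
    age = rng.normal(60, 9, n)
    sex = rng.choice(["M", "F"], n)
    X = pd.DataFrame(
        {
            "is_age": age,  # exactly a covariate
            "sex_coded": np.where(sex == "F", 1.0, 0.0) + rng.normal(0, 0.01, n),
            "constant": np.ones(n),
            "indep": rng.normal(size=n),
        }
    )
    covs = pd.DataFrame({"age": age, "sex": sex})
    excluded = covariate_feature_filter(X, covs, alpha=0.01)
    assert {"is_age", "sex_coded", "constant"} <= set(excluded)
    assert "indep" not in excluded


def test_filter_retains_independent_features_at_family_rate():
    rng = np.random.default_rng(1)
    n, p = 300, 400
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    covs = pd.DataFrame({"age": rng.normal(60, 9, n), "vendor": rng.choice(list("ABC"), n)})
    excluded = covariate_feature_filter(X, covs, alpha=0.01)
    # two tests at alpha=0.01 -> family error ~2%; retained rate ~98%
    assert 1 - len(excluded) / p > 0.94


def test_filter_skips_single_level_covariate():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"f": rng.normal(size=30)})
    covs = pd.DataFrame({"vendor": ["V1"] * 30})
    with pytest.warns(UserWarning, match="one level"):
        assert covariate_feature_filter(X, covs) == {}


# ---------------------------------------------------------------------------
# ensemble training
# ---------------------------------------------------------------------------


def test_fit_deterministic_hash():
    rng = np.random.default_rng(3)
    X, y = synthetic_matrix(rng, n=40, p=10)
    h1 = CfDNAClassifier(X, y, config=SMALL).fit().model_hash()
    h2 = CfDNAClassifier(X, y, config=SMALL).fit().model_hash()
    assert h1 == h2
    h3 = CfDNAClassifier(X, y, config=EnsembleConfig(n_learners=4, cv_folds=4, c_grid=(0.01, 1.0), base_seed=1)).fit().model_hash()
    assert h3 != h1


def test_single_learner_full_subsample_reduces_to_plain_svm():
    """n_learners=1, frac=1.0: the learner is a CV-tuned LinearSVC on the full
    (normalized) training matrix; refitting sklearn directly reproduces it."""
    rng = np.random.default_rng(4)
    X, y = synthetic_matrix(rng, n=60, p=12)
    cfg = EnsembleConfig(n_learners=1, subsample_frac=1.0, cv_folds=5, c_grid=(0.01, 1.0), base_seed=2)
    res = CfDNAClassifier(X, y, config=cfg).fit()
    learner = res.learners[0]
    Z = res.state.transform(X.fillna(X.median()))[res.model_features].to_numpy()
    direct = LinearSVC(C=learner.C, max_iter=cfg.max_fit_iter).fit(Z, y)
    np.testing.assert_allclose(learner.coef, direct.coef_.ravel(), atol=1e-6)
    np.testing.assert_allclose(learner.intercept, direct.intercept_[0], atol=1e-6)


def test_prediction_invariances():
    rng = np.random.default_rng(5)
    X, y = synthetic_matrix(rng)
    res = CfDNAClassifier(X, y, config=SMALL).fit()
    Xnew, _ = synthetic_matrix(np.random.default_rng(6), n=20)
    p1 = res.predict(Xnew)
    # learner order does not matter
    res.learners = res.learners[::-1]
    p2 = res.predict(Xnew)
    np.testing.assert_allclose(p1["probability"], p2["probability"])
    # permuting sample order permutes but does not change per-sample outputs
    perm = Xnew.sample(frac=1.0, random_state=1)
    p3 = res.predict(perm).set_index("sample_id")
    np.testing.assert_allclose(
        p3.loc[p1["sample_id"], "probability"].to_numpy(), p1["probability"].to_numpy()
    )


def test_probability_boundary_is_strictly_above_half():
    rng = np.random.default_rng(7)
    X, y = synthetic_matrix(rng, n=30, p=6)
    res = CfDNAClassifier(X, y, config=SMALL).fit()
    # two constant-output learners at 0.4 and 0.6 average to exactly 0.5
    zeros = np.zeros(len(res.model_features))
    mk = lambda i, p: LearnerSpec(
        index=i, seed=i, C=1.0, coef=zeros, intercept=0.0,
        platt_a=0.0, platt_b=float(np.log(p / (1 - p))), holdout_auc=0.5,
    )
    res.learners = [mk(0, 0.4), mk(1, 0.6)]
    out = res.predict(X.iloc[:3])
    np.testing.assert_allclose(out["probability"], 0.5)
    assert not out["call"].any()  # strict > 0.5


def test_serialization_round_trip_and_registry(tmp_path):
    rng = np.random.default_rng(8)
    X, y = synthetic_matrix(rng, n=40, p=8)
    res = CfDNAClassifier(X, y, config=SMALL).fit()
    path = tmp_path / "model.json"
    h = res.save(path)
    loaded = CfDNAClassifierResults.load(path)
    assert loaded.model_hash() == h
    np.testing.assert_allclose(
        loaded.predict(X)["probability"], res.predict(X)["probability"], atol=1e-12
    )
    registry = ModelRegistry(tmp_path / "registry.jsonl")
    registry.register(res)
    registry.verify(loaded)  # registered hash accepted
    res.learners[0].coef = res.learners[0].coef + 1.0  # tampered model
    with pytest.raises(ValueError, match="registry"):
        registry.verify(res)


def test_predict_rejects_missing_features():
    rng = np.random.default_rng(9)
    X, y = synthetic_matrix(rng, n=30, p=6)
    res = CfDNAClassifier(X, y, config=SMALL).fit()
    with pytest.raises(ValueError, match="missing"):
        res.predict(X.drop(columns=["f0"]))


def test_summary_mentions_key_quantities():
    rng = np.random.default_rng(10)
    X, y = synthetic_matrix(rng, n=40, p=8)
    res = CfDNAClassifier(X, y, config=SMALL).fit()
    text = res.summary()
    assert "internal CV AUC" in text and res.model_hash() in text


# ---------------------------------------------------------------------------
# propensity weighting
# ---------------------------------------------------------------------------


def _covariates(rng, n, confounded=False):
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    age = rng.normal(60, 9, n) + (6.0 * y if confounded else 0.0)
    sex = rng.choice(["M", "F"], n)
    return pd.DataFrame({"age": age, "sex": sex}), y


def test_propensity_weights_null_are_unit():
    rng = np.random.default_rng(11)
    covs, y = _covariates(rng, 300, confounded=False)
    w = propensity_weights(covs, y)
    assert w.mean() == pytest.approx(1.0, abs=0.02)
    assert np.all((w > 0.7) & (w < 1.4))
    for cls in (0, 1):
        assert w[y == cls].mean() == pytest.approx(1.0, abs=1e-9)


def test_propensity_weights_balance_confounded_covariate():
    rng = np.random.default_rng(12)
    covs, y = _covariates(rng, 400, confounded=True)
    w = propensity_weights(covs, y)
    age = covs["age"].to_numpy()

    def std_diff(weights):
        m1 = np.average(age[y == 1], weights=weights[y == 1])
        m0 = np.average(age[y == 0], weights=weights[y == 0])
        pooled = np.sqrt((age[y == 1].var() + age[y == 0].var()) / 2)
        return abs(m1 - m0) / pooled

    assert std_diff(np.ones_like(w)) > 0.3  # confounded before weighting
    assert std_diff(w) < 0.1  # balanced after


def test_affected_features_get_larger_weights():
    """Parameter recovery: the planted discriminative features carry larger
    mean absolute SVM weight than the noise features."""
    rng = np.random.default_rng(13)
    X, y = synthetic_matrix(rng, n=100, p=30, effect=1.5, k=6)
    res = CfDNAClassifier(X, y, config=SMALL).fit()
    w = res.mean_abs_weight
    planted = [f"f{i}" for i in range(6)]
    rest = [c for c in w.index if c not in planted]
    assert w[planted].mean() > 2 * w[rest].mean()
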