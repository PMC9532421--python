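"""Linear-SVM ensemble classifier in a Model/Results shape.

:class:`CfDNAClassifier` is built from a samples-by-features matrix, binary
labels and optional covariates; :meth:`CfDNAClassifier.fit` performs the
full training protocol and returns a frozen :class:`CfDNAClassifierResults`:

* quantile normalization of samples followed by per-feature z-scoring, both
  fitted on the training samples only and frozen;
* exclusion of features significantly associated with technical covariates
  (simple-regression t-test for continuous covariates, one-way ANOVA F-test
  for categorical ones);
* an ensemble of 50 learners, each a linear SVM trained on a stratified
  random 80% of the training samples with its cost parameter C chosen by
  highest mean AUC in tenfold cross-validation inside the subsample, and a
  Platt probability calibration fitted on internal 5-fold out-of-fold
  decision values;
* internal cross-validation AUC = mean AUC of each learner on its held-out
  20%; ensemble predictions average the 50 calibrated probabilities, with
  positive calls strictly above 0.5.

The fitted ensemble serializes to a versioned JSON bundle whose MD5 content
hash acts as the model identifier; an append-only registry supports the
frozen-model validation contract (validation refuses unregistered hashes).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .hmc import NormalizationState, quantile_normalize, zscore_fit
from .metrics import roc_auc

__all__ = [
    "EnsembleConfig",
    "LearnerSpec",
    "CfDNAClassifier",
    "CfDNAClassifierResults",
    "covariate_feature_filter",
    "propensity_weights",
    "ModelRegistry",
]

MODEL_FORMAT_VERSION = 1
_WEIGHT_EPS = 1e-8  # |w| above this counts as a selected feature


@dataclass(frozen=True)
class EnsembleConfig:
    n_learners: int = 50
    subsample_frac: float = 0.8
    cv_folds: int = 10
    c_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    base_seed: int = 0
    filter_alpha: float = 0.01  # covariate-association exclusion threshold
    calibration_folds: int = 5
    threshold: float = 0.5
    max_fit_iter: int = 20_000


@dataclass
class LearnerSpec:
    index: int
    seed: int
    C: float
    coef: np.ndarray
    intercept: float
    platt_a: float  # probability = sigmoid(platt_a * decision + platt_b)
    platt_b: float
    holdout_auc: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.platt_a * self.decision(X) + self.platt_b
        return 1.0 / (1.0 + np.exp(-z))

    @property
    def selected_features(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.coef) > _WEIGHT_EPS)


def covariate_feature_filter(
    matrix: pd.DataFrame, covariates: pd.DataFrame, alpha: float = 0.01
) -> dict[str, float]:
    """Features significantly associated with any covariate (p < alpha).

    Continuous covariates use the simple-linear-regression slope t-test
    (equivalently the Pearson correlation t-test); categorical covariates a
    one-way ANOVA F-test, both vectorized across features.  Returns the
    excluded features mapped to their smallest p-value.
    """
    X = matrix.to_numpy(dtype=float)
    n = len(matrix)
    min_p = np.ones(X.shape[1])
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            z = col.to_numpy(dtype=float)
            if np.std(z) == 0:
                warnings.warn(f"covariate {name!r} is constant; skipped")
                continue
            zc = (z - z.mean()) / z.std()
            xm = X.mean(axis=0)
            xs = X.std(axis=0)
            xs_safe = np.where(xs > 0, xs, 1.0)
            r = (zc @ (X - xm)) / (n * xs_safe)
            r = np.clip(r, -0.9999999, 0.9999999)
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
            p = np.where(xs > 0, p, 0.0)  # constant features: excluded by pre-rule
        else:
            groups = col.astype(str).to_numpy()
            levels = np.unique(groups)
            if len(levels) < 2:
                warnings.warn(f"covariate {name!r} has one level; skipped")
                continue
            grand = X.mean(axis=0)
            ss_between = np.zeros(X.shape[1])
            ss_within = np.zeros(X.shape[1])
            for lev in levels:
                sub = X[groups == lev]
                mu = sub.mean(axis=0)
                ss_between += len(sub) * (mu - grand) ** 2
                ss_within += ((sub - mu) ** 2).sum(axis=0)
            df1, df2 = len(levels) - 1, n - len(levels)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ss_between / df1) / (ss_within / df2)
            p = stats.f.sf(f, df1, df2)
            p = np.where(ss_within > 0, p, 0.0)
        min_p = np.minimum(min_p, p)
    excluded = {}
    for j, name in enumerate(matrix.columns):
        if min_p[j] < alpha or matrix[name].std() == 0:
            excluded[name] = float(min_p[j])
    return excluded


def propensity_weights(covariates: pd.DataFrame, labels, seed: int = 0) -> np.ndarray:
    """Stabilized inverse-probability-of-class weights from a logistic
    propensity model, truncated at the 1st/99th percentiles and renormalized
    to mean 1 within each class."""
    y = np.asarray(labels).astype(int)
    X = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    model = LogisticRegression(C=1e4, max_iter=5000, random_state=seed)
    model.fit(X, y)
    p = model.predict_proba(X)[:, 1]
    if np.any(p <= 1e-8) or np.any(p >= 1 - 1e-8):  # (near-)separation
        warnings.warn("propensity model near separation; refitting with ridge penalty")
        model = LogisticRegression(C=1.0, max_iter=5000, random_state=seed)
        model.fit(X, y)
        p = model.predict_proba(X)[:, 1]
    pbar = y.mean()
    w = np.where(y == 1, pbar / p, (1.0 - pbar) / (1.0 - p))
    lo, hi = np.percentile(w, [1, 99])
    w = np.clip(w, lo, hi)
    for cls in (0, 1):
        w[y == cls] /= w[y == cls].mean()
    return w


class CfDNAClassifier:
    """Model: an SVM-ensemble CRC-vs-control classifier on a feature matrix.

    Parameters
    ----------
    features : pandas.DataFrame
        Training samples in rows, features in columns (raw, un-normalized).
        NA entries are imputed by the training-set feature median.
    labels : array-like of {0, 1}
        1 = case (CRC), 0 = control, aligned with ``features`` rows.
    covariates : pandas.DataFrame, optional
        Technical/clinical covariates for the feature-exclusion filter
        (numeric columns treated as continuous, the rest as categorical).
    weights : array-like, optional
        Per-sample training weights (e.g. propensity weights).
    """

    def __init__(self, features, labels, covariates=None, weights=None, config=EnsembleConfig()):
        self.features = features.copy()
        self.labels = np.asarray(labels).astype(int)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree on sample count")
        self.covariates = covariates
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.config = config
        self.feature_medians = self.features.median(axis=0)

    @classmethod
    def from_dataframe(cls, df, label_col, covariate_cols=(), weight_col=None, config=EnsembleConfig()):
        feature_cols = [c for c in df.columns if c != label_col and c not in covariate_cols and c != weight_col]
        return cls(
            df[feature_cols],
            df[label_col].to_numpy(),
            covariates=df[list(covariate_cols)] if covariate_cols else None,
            weights=df[weight_col].to_numpy() if weight_col else None,
            config=config,
        )

    # -- training -----------------------------------------------------------

    def _cv_auc(self, X, y, w, C, rng_seed) -> float:
        folds = min(self.config.cv_folds, np.bincount(y).min())
        if folds < 2:
            return 0.5
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        aucs = []
        for tr, te in skf.split(X, y):
            if y[tr].min() == y[tr].max() or y[te].min() == y[te].max():
                continue
            svc = LinearSVC(C=C, max_iter=self.config.max_fit_iter)
            svc.fit(X[tr], y[tr], sample_weight=None if w is None else w[tr])
            aucs.append(roc_auc(svc.decision_function(X[te]), y[te]))
        return float(np.mean(aucs)) if aucs else 0.5

    def _platt(self, X, y, w, C, seed):
        """Platt scaling on out-of-fold decision values (internal 5-fold CV)."""
        folds = min(self.config.calibration_folds, np.bincount(y).min())
        scores = np.zeros(len(y))
        if folds >= 2:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            for tr, te in skf.split(X, y):
                svc = LinearSVC(C=C, max_iter=self.config.max_fit_iter)
                svc.fit(X[tr], y[tr], sample_weight=None if w is None else w[tr])
                scores[te] = svc.decision_function(X[te])
        else:
            svc = LinearSVC(C=C, max_iter=self.config.max_fit_iter)
            svc.fit(X, y, sample_weight=w)
            scores = svc.decision_function(X)
        lr = LogisticRegression(C=1e6, max_iter=5000)
        lr.fit(scores.reshape(-1, 1), y, sample_weight=w)
        return float(lr.coef_[0, 0]), float(lr.intercept_[0])

    def _subsample(self, rng, y):
        idx = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(y == cls)
            take = max(1, int(round(self.config.subsample_frac * len(cls_idx))))
            take = min(take, len(cls_idx))
            idx.append(rng.choice(cls_idx, size=take, replace=False))
        return np.sort(np.concatenate(idx))

    def fit(self) -> "CfDNAClassifierResults":
        cfg = self.config
        matrix = self.features.fillna(self.feature_medians)

        qn, state = quantile_normalize(matrix)
        Z = zscore_fit(qn, state)

        excluded: dict[str, float] = {}
        for c in state.dropped:
            excluded[c] = 0.0
        if self.covariates is not None:
            excluded.update(covariate_feature_filter(Z, self.covariates, alpha=cfg.filter_alpha))
        model_features = [c for c in Z.columns if c not in excluded]
        if not model_features:
            raise ValueError("no features survive the covariate filter")
        X_all = Z[model_features].to_numpy(dtype=float)
        y = self.labels
        w = self.weights

        learners = []
        for i in range(cfg.n_learners):
            seed = cfg.base_seed + i
            for attempt in range(10):
                rng = np.random.default_rng(seed + 1000 * attempt)
                sub = self._subsample(rng, y)
                if y[sub].min() != y[sub].max():
                    break
                warnings.warn(f"learner {i}: single-class subsample, resampling")
            hold = np.setdiff1d(np.arange(len(y)), sub)
            Xs, ys = X_all[sub], y[sub]
            ws = None if w is None else w[sub]
            cv_aucs = [self._cv_auc(Xs, ys, ws, C, seed) for C in cfg.c_grid]
            best_c = float(cfg.c_grid[int(np.argmax(cv_aucs))])
            svc = LinearSVC(C=best_c, max_iter=cfg.max_fit_iter)
            svc.fit(Xs, ys, sample_weight=ws)
            a, b = self._platt(Xs, ys, ws, best_c, seed)
            spec = LearnerSpec(
                index=i,
                seed=seed,
                C=best_c,
                coef=svc.coef_.ravel().copy(),
                intercept=float(svc.intercept_[0]),
                platt_a=a,
                platt_b=b,
                holdout_auc=np.nan,
            )
            if len(hold) and y[hold].min() != y[hold].max():
                spec.holdout_auc = roc_auc(spec.predict_proba(X_all[hold]), y[hold])
            learners.append(spec)

        return CfDNAClassifierResults(
            model=self,
            learners=learners,
            state=state,
            excluded_features=excluded,
            model_features=model_features,
            config=cfg,
            feature_medians=self.feature_medians[model_features],
        )


class CfDNAClassifierResults:
    """Frozen fitted ensemble: estimates, diagnostics, prediction, summary."""

    def __init__(self, model, learners, state, excluded_features, model_features, config, feature_medians):
        self.model = model
        self.learners = learners
        self.state: NormalizationState = state
        self.excluded_features = excluded_features
        self.model_features = list(model_features)
        self.config = config
        self.feature_medians = feature_medians

    # -- diagnostics --------------------------------------------------------

    @property
    def internal_cv_auc(self) -> float:
        """Mean AUC of each learner on its held-out 20%."""
        aucs = [l.holdout_auc for l in self.learners if np.isfinite(l.holdout_auc)]
        return float(np.mean(aucs)) if aucs else float("nan")

    @property
    def retained_features(self) -> list:
        """De-duplicated union of features selected (nonzero weight) by any learner."""
        sel = set()
        for l in self.learners:
            sel.update(l.selected_features.tolist())
        return [self.model_features[j] for j in sorted(sel)]

    @property
    def mean_abs_weight(self) -> pd.Series:
        W = np.vstack([l.coef for l in self.learners])
        return pd.Series(np.abs(W).mean(axis=0), index=self.model_features)

    # -- prediction ---------------------------------------------------------

    def _transform(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != list(self.state.feature_names):
            missing = set(self.state.feature_names) - set(features.columns)
            if missing:
                raise ValueError(f"prediction matrix missing {len(missing)} training features")
            features = features[list(self.state.feature_names)]
        features = features.fillna(self.feature_medians.reindex(features.columns))
        Z = self.state.transform(features)
        return Z[self.model_features].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Mean calibrated probability over learners; call positive iff > 0.5."""
        X = self._transform(features)
        probs = np.mean([l.predict_proba(X) for l in self.learners], axis=0)
        return pd.DataFrame(
            {
                "sample_id": features.index,
                "probability": probs,
                "call": probs > self.config.threshold,
            }
        ).reset_index(drop=True)

    # -- plotting -----------------------------------------------------------

    def plot_roc(self, features: pd.DataFrame, labels, ax=None):
        """ROC curve of ensemble probabilities on a labelled matrix."""
        from .metrics import roc_curve_points

        import matplotlib.pyplot as plt

        preds = self.predict(features)
        pts = roc_curve_points(preds["probability"].to_numpy(), labels)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(pts["fpr"], pts["tpr"])
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        return ax

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "config": {
                "n_learners": self.config.n_learners,
                "subsample_frac": self.config.subsample_frac,
                "cv_folds": self.config.cv_folds,
                "c_grid": list(self.config.c_grid),
                "base_seed": self.config.base_seed,
                "filter_alpha": self.config.filter_alpha,
                "calibration_folds": self.config.calibration_folds,
                "threshold": self.config.threshold,
            },
            "normalization": self.state.to_dict(),
            "excluded_features": self.excluded_features,
            "model_features": self.model_features,
            "feature_medians": self.feature_medians.tolist(),
            "learners": [
                {
                    "index": l.index,
                    "seed": l.seed,
                    "C": l.C,
                    "coef": np.round(l.coef, 12).tolist(),
                    "intercept": round(l.intercept, 12),
                    "platt_a": round(l.platt_a, 12),
                    "platt_b": round(l.platt_b, 12),
                    "holdout_auc": None if not np.isfinite(l.holdout_auc) else round(l.holdout_auc, 12),
                }
                for l in self.learners
            ],
        }

    def model_hash(self) -> str:
        """MD5 content digest of the serialized ensemble (its identifier)."""
        return hashlib.md5(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    def save(self, path) -> str:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))
        return self.model_hash()

    @classmethod
    def load(cls, path) -> "CfDNAClassifierResults":
        d = json.loads(Path(path).read_text())
        if d["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        cfgd = d["config"]
        cfgd["c_grid"] = tuple(cfgd["c_grid"])
        config = EnsembleConfig(**cfgd)
        learners = [
            LearnerSpec(
                index=ld["index"],
                seed=ld["seed"],
                C=ld["C"],
                coef=np.asarray(ld["coef"], dtype=float),
                intercept=ld["intercept"],
                platt_a=ld["platt_a"],
                platt_b=ld["platt_b"],
                holdout_auc=np.nan if ld["holdout_auc"] is None else ld["holdout_auc"],
            )
            for ld in d["learners"]
        ]
        state = NormalizationState.from_dict(d["normalization"])
        return cls(
            model=None,
            learners=learners,
            state=state,
            excluded_features=d["excluded_features"],
            model_features=d["model_features"],
            config=config,
            feature_medians=pd.Series(d["feature_medians"], index=d["model_features"]),
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "CfDNA ensemble classifier results",
            "=" * 49,
            f"{'learners':<32}{len(self.learners):>17}",
            f"{'input features':<32}{len(self.state.feature_names):>17}",
            f"{'excluded (covariate/zero-var)':<32}{len(self.excluded_features):>17}",
            f"{'model features':<32}{len(self.model_features):>17}",
            f"{'retained (selected) features':<32}{len(self.retained_features):>17}",
            f"{'internal CV AUC (mean 20% holdout)':<38}{self.internal_cv_auc:>11.4f}",
            f"{'decision threshold':<32}{self.config.threshold:>17.2f}",
            f"{'model hash':<16}{self.model_hash():>33}",
            "-" * 49,
            "C parameter choices: "
            + ", ".join(f"{c:g}x{n}" for c, n in pd.Series([l.C for l in self.learners]).value_counts().sort_index().items()),
        ]
        return "\n".join(lines)


class ModelRegistry:
    """Append-only JSON-lines registry of trained model hashes.

    Mirrors a blinded-validation protocol: the validation runner refuses a
    model whose content hash was never logged.
    """

    def __init__(self, path):
        self.path = Path(path)

    def register(self, results: CfDNAClassifierResults, note: str = "") -> str:
        h = results.model_hash()
        entry = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "hash": h,
            "n_learners": len(results.learners),
            "note": note,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        return h

    def hashes(self) -> set:
        if not self.path.exists():
            return set()
        return {json.loads(line)["hash"] for line in self.path.read_text().splitlines() if line}

    def verify(self, results: CfDNAClassifierResults) -> None:
        if results.model_hash() not in self.hashes():
            raise ValueError("model hash not present in registry; refusing to validate")
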