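"""Classifier performance statistics.

AUC via the Mann-Whitney U formulation with tie correction, sensitivity at
a fixed specificity, percentile bootstrap confidence intervals (2000
resamples of predicted samples by default), and binomial call-rate tables
with Wald 95% intervals: percent to two decimals, half-width
1.96*sqrt(p(1-p)/n), bounds clipped to [0, 100] and rounded half-up to
integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "roc_auc",
    "roc_curve_points",
    "sens_at_spec",
    "bootstrap_ci",
    "wald_ci_percent",
    "call_rate_table",
    "PerformanceSummary",
    "performance_summary",
]


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """P(score_case > score_control) + 0.5 * P(equal) via mid-ranks."""
    scores, labels = _check_scores(scores, labels)
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) at every threshold, for plotting."""
    scores, labels = _check_scores(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    # collapse ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / labels.sum()]
    fpr = np.r_[0.0, fps[distinct] / (len(labels) - labels.sum())]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def sens_at_spec(scores, labels, spec: float) -> float:
    """Sensitivity at the loosest cutoff achieving empirical specificity >= spec.

    Calls are positive above the cutoff.  If the requested specificity is
    unattainable, the sensitivity at the strictest cutoff is returned.
    """
    scores, labels = _check_scores(scores, labels)
    controls = scores[labels == 0]
    cases = scores[labels == 1]
    cutoffs = np.unique(scores)
    best = None
    for c in cutoffs:
        specificity = np.mean(controls <= c)
        if specificity >= spec:
            best = c
            break
    if spec <= 0.0:
        return 1.0
    if best is None:
        best = cutoffs[-1]
    return float(np.mean(cases > best))


def bootstrap_ci(statistic, scores, labels, B: int = 2000, seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap CI over B resamples of (score, label) pairs.

    Resamples missing a class are redrawn (the statistic would be undefined).
    """
    scores, labels = _check_scores(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    values = np.empty(B)
    for b in range(B):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
        else:  # pragma: no cover - pathological inputs only
            raise RuntimeError("could not draw a two-class resample")
        values[b] = statistic(scores[idx], labels[idx])
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0**decimals
    return np.floor(x * f + 0.5) / f


def wald_ci_percent(k: int, n: int):
    """Binomial proportion on the percent scale with a Wald 95% interval.

    Returns (percent to 2 dp, integer lower bound, integer upper bound),
    bounds clipped to [0, 100].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = k / n
    percent = _round_half_up(100.0 * p, 2)
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    lo = int(_round_half_up(np.clip(100.0 * (p - half), 0.0, 100.0)))
    hi = int(_round_half_up(np.clip(100.0 * (p + half), 0.0, 100.0)))
    return float(percent), lo, hi


def call_rate_table(predictions: pd.DataFrame, records) -> pd.DataFrame:
    """Per (diagnosis, stage) CRC call rates with Wald 95% CIs.

    ``predictions`` must carry one row per sample with columns ``sample_id``
    and ``call`` (boolean: called CRC).  Rows are ordered by diagnosis then
    stage; empty groups are omitted.
    """
    meta = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "stage": [r.stage if r.stage is not None else 0 for r in records],
        }
    )
    df = predictions.merge(meta, on="sample_id", how="inner")
    missing = set(meta["sample_id"]) - set(df["sample_id"])
    if missing:
        raise ValueError(f"predictions missing for {len(missing)} samples")
    rows = []
    for (diagnosis, stage), sub in df.groupby(["diagnosis", "stage"], sort=True):
        k = int(sub["call"].sum())
        n = len(sub)
        percent, lo, hi = wald_ci_percent(k, n)
        rows.append(
            {
                "diagnosis": diagnosis,
                "stage": stage if stage != 0 else pd.NA,
                "percent_called_crc": percent,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_called": k,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PerformanceSummary:
    auc: float
    auc_ci: tuple
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    sens_at_90_spec: float
    sens_at_90_spec_ci: tuple
    sens_at_95_spec: float
    sens_at_95_spec_ci: tuple
    per_stage_auc: dict


def performance_summary(
    scores,
    labels,
    stages=None,
    threshold: float = 0.5,
    B: int = 2000,
    seed: int = 0,
) -> PerformanceSummary:
    """Headline validation statistics with percentile-bootstrap 95% CIs."""
    scores, labels = _check_scores(scores, labels)

    def sens(s, y):
        return float(np.mean(s[y == 1] > threshold))

    def spec(s, y):
        return float(np.mean(s[y == 0] <= threshold))

    stat_fns = {
        "auc": roc_auc,
        "sens": sens,
        "spec": spec,
        "s90": lambda s, y: sens_at_spec(s, y, 0.90),
        "s95": lambda s, y: sens_at_spec(s, y, 0.95),
    }
    points, cis = {}, {}
    for i, (name, fn) in enumerate(stat_fns.items()):
        points[name] = fn(scores, labels)
        cis[name] = bootstrap_ci(fn, scores, labels, B=B, seed=seed + i)
    per_stage = {}
    if stages is not None:
        stages = np.asarray(stages)
        controls = stages == 0
        for stage in (1, 2, 3, 4):
            mask = controls | (stages == stage)
            if (labels[mask] == 1).any() and (labels[mask] == 0).any():
                per_stage[stage] = roc_auc(scores[mask], labels[mask])
    return PerformanceSummary(
        auc=points["auc"],
        auc_ci=cis["auc"],
        sensitivity=points["sens"],
        sensitivity_ci=cis["sens"],
        specificity=points["spec"],
        specificity_ci=cis["spec"],
        sens_at_90_spec=points["s90"],
        sens_at_90_spec_ci=cis["s90"],
        sens_at_95_spec=points["s95"],
        sens_at_95_spec_ci=cis["s95"],
        per_stage_auc=per_stage,
    )
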