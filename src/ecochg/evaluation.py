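"""Benchmarking and statistics for the detector suite.

Confusion metrics with normal-approximation CIs, ROC/AUC, the DeLong test
for paired AUCs, Fleiss' kappa for multi-rater agreement, and an
end-to-end benchmark runner: stratified 70/30 split, per-method tuning on
the training split only, metrics and pairwise AUC comparisons on the test
split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cnn import TrainConfig, predict as cnn_predict, train_classifier
from .correlation import corr_buffer_split, fit_corr_classifier
from .hotelling import DEFAULT_Q_GRID, build_tvm, hotelling_t2, tune_q
from .preprocess import PreprocessedRecording, preprocess_recording
from .scalogram import cwt_scalogram
from .types import Recording

__all__ = [
    "ConfusionMetrics",
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "delong_one_sided",
    "fleiss_kappa",
    "rater_false_positive_rates",
    "benchmark",
]


@dataclass
class ConfusionMetrics:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ci_accuracy: float
    n: int


def confusion_metrics(decisions, truth) -> ConfusionMetrics:
    """Accuracy, sensitivity and specificity with a 95% accuracy CI.

    The CI is the normal-approximation half-width.  With a one-class truth
    vector, the undefined rate is reported as None.
    """
    d = np.asarray(decisions).astype(bool)
    t = np.asarray(truth).astype(bool)
    if d.shape != t.shape:
        raise ValueError("decisions and truth must have equal length")
    n = t.size
    acc = float(np.mean(d == t))
    sens = float(np.mean(d[t])) if t.any() else None
    spec = float(np.mean(~d[~t])) if (~t).any() else None
    ci = float(1.959964 * np.sqrt(acc * (1 - acc) / n))
    return ConfusionMetrics(accuracy=acc, sensitivity=sens, specificity=spec,
                            ci_accuracy=ci, n=n)


def roc_auc(scores, truth) -> tuple[np.ndarray, float]:
    """Empirical ROC points (FPR, TPR) and trapezoidal AUC.

    Scores must be oriented so larger means more signal-like (map
    Hotelling p-values to 1 - p first).  Ties are handled by
    rank-averaging, making the AUC equal to the Mann-Whitney statistic
    U / (n1 * n0).  Constant scores yield AUC 0.5 with a warning.
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    s = np.asarray(scores, float)
    t = np.asarray(truth).astype(int)
    if len(np.unique(t)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(t, s)
    points = np.column_stack([fpr, tpr])
    if s.min() == s.max():
        warnings.warn("constant scores: AUC set to 0.5")
        return points, 0.5
    return points, float(roc_auc_score(t, s))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n          # P(score > random negative)
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m    # per-negative placements
    auc = float(v10.mean())
    return v10, v01, auc


def delong_one_sided(scores_a, scores_b, truth) -> float:
    """One-sided DeLong test of AUC(a) > AUC(b) on paired scores.

    Small p supports the alternative AUC_a > AUC_b; identical score
    vectors give exactly p = 0.5, and p(a, b) + p(b, a) = 1 for
    continuous scores.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    t = np.asarray(truth).astype(bool)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("scores_a, scores_b and truth must be paired (equal length)")
    if t.all() or not t.any():
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placements(a[t], a[~t])
    v10b, v01b, auc_b = _placements(b[t], b[~t])
    m, n = t.sum(), (~t).sum()
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = s10 / m + s01 / n
    var_diff = float(var[0, 0] + var[1, 1] - 2 * var[0, 1])
    if var_diff <= 0:
        if auc_a == auc_b:
            return 0.5
        return 0.0 if auc_a > auc_b else 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(stats.norm.sf(z))


def fleiss_kappa(labels) -> float:
    """Fleiss' kappa for an items x raters table of categorical labels.

    κ = (P̄ - P̄ₑ) / (1 - P̄ₑ); returns NaN when every item is rated
    unanimously into a single overall category (P̄ₑ = 1, κ undefined).
    """
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

    table = np.asarray(labels)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an items x raters table with >= 2 of each")
    counts, _ = aggregate_raters(table)
    pj = counts.sum(axis=0) / counts.sum()
    if np.max(pj) >= 1.0:
        return float("nan")
    return float(_sm_fleiss(counts, method="fleiss"))


def rater_false_positive_rates(labels: pd.DataFrame, consensus: pd.Series) -> pd.Series:
    """Per-rater round-1 false-positive rate against the consensus label."""
    r1 = labels[labels["round"] == 1]
    out = {}
    for rater, grp in r1.groupby("rater_id"):
        merged = grp.set_index("recording_id").join(consensus.rename("final"))
        neg = merged[~merged["final"].astype(bool)]
        out[rater] = float(neg["response_present"].mean()) if len(neg) else np.nan
    return pd.Series(out, name="false_positive_rate")


@dataclass
class EvalReport:
    """Benchmark outcome: per-method metrics, ROC curves, DeLong matrix."""

    methods: dict = field(default_factory=dict)
    delong: dict = field(default_factory=dict)
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    split_seed: int | None = None

    def to_json(self, path=None) -> str:
        def conv(o):
            if isinstance(o, ConfusionMetrics):
                return o.__dict__
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        payload = {
            # keys starting with "_" hold live objects (models) and are
            # not serialized
            "methods": {
                name: {k: v for k, v in blk.items() if not k.startswith("_")}
                for name, blk in self.methods.items()
            },
            "delong_p_a_greater_b": self.delong,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "split_seed": self.split_seed,
        }
        text = json.dumps(payload, default=conv, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _stratified_split(labels, freqs, train_frac, seed):
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(labels))
    strata = [f"{f}|{l}" for f, l in zip(freqs, labels)]
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, random_state=seed, stratify=strata
    )
    return np.sort(train_idx), np.sort(test_idx)


def benchmark(
    recordings: list[Recording],
    labels,
    detectors: tuple[str, ...] = ("hotelling", "correlation", "dl"),
    split_seed: int = 0,
    train_frac: float = 0.7,
    alpha: float = 0.01,
    q_grid: tuple[int, ...] = DEFAULT_Q_GRID,
    dl_config: TrainConfig | None = None,
    preprocessed: list[PreprocessedRecording] | None = None,
) -> EvalReport:
    """Train and evaluate the requested detectors on a labelled dataset.

    The dataset is split 70/30 stratified by stimulus frequency x label.
    All tuning — the Hotelling Q sweep, the correlation logistic fit, CNN
    training — happens on the training split; accuracy/sensitivity/
    specificity, ROC/AUC and pairwise one-sided DeLong comparisons are
    computed on the test split.  Pass ``preprocessed`` to reuse an
    existing preprocessing pass.

    Hotelling scores enter the ROC as 1 - p.
    """
    y = np.asarray(labels).astype(bool)
    if len(recordings) != len(y):
        raise ValueError("labels must match recordings")
    freqs = [int(r.stimulus.frequency) for r in recordings]
    train_idx, test_idx = _stratified_split(y, freqs, train_frac, split_seed)
    if np.intersect1d(train_idx, test_idx).size:
        raise RuntimeError("leakage: recording present in both splits")

    pre = preprocessed if preprocessed is not None else [
        preprocess_recording(r) for r in recordings
    ]
    if len(pre) != len(recordings):
        raise ValueError("preprocessed list must match recordings")

    report = EvalReport(
        train_ids=[recordings[i].recording_id or int(i) for i in train_idx],
        test_ids=[recordings[i].recording_id or int(i) for i in test_idx],
        split_seed=split_seed,
    )
    y_test = y[test_idx]
    scores: dict[str, np.ndarray] = {}

    if "hotelling" in detectors:
        tuning = tune_q(
            [(pre[i], y[i]) for i in train_idx], alpha=alpha, grid=q_grid
        )
        p_vals = np.array([
            hotelling_t2(
                build_tvm(pre[i], tuning.optimal_q[int(recordings[i].stimulus.frequency)]),
                alpha=alpha,
            ).p_value
            for i in test_idx
        ])
        scores["hotelling"] = 1.0 - p_vals
        dec = p_vals < alpha
        pts, auc = roc_auc(scores["hotelling"], y_test)
        report.methods["hotelling"] = {
            "metrics": confusion_metrics(dec, y_test),
            "auc": auc,
            "roc_points": pts,
            "optimal_q": tuning.optimal_q,
            "scores": scores["hotelling"],
        }

    if "correlation" in detectors:
        rng = np.random.default_rng(split_seed + 1)
        coeff_all = np.array([
            corr_buffer_split(p, seed=rng).corr_coeff for p in pre
        ])
        model = fit_corr_classifier(coeff_all[train_idx], y[train_idx])
        probs = model.predict_proba(coeff_all[test_idx])
        scores["correlation"] = probs
        pts, auc = roc_auc(probs, y_test)
        report.methods["correlation"] = {
            "metrics": confusion_metrics(probs >= 0.5, y_test),
            "auc": auc,
            "roc_points": pts,
            "model": {"intercept": model.intercept, "slope": model.slope,
                      "perfect_separation": model.perfect_separation},
            "scores": probs,
            "_model": model,
        }

    if "dl" in detectors:
        cfg = dl_config or TrainConfig.compact(seed=split_seed + 2)
        scalos = [
            cwt_scalogram(p.derived.dif_trace, p.sampling_rate,
                          recording_id=p.recording_id)
            for p in pre
        ]
        model = train_classifier([scalos[i] for i in train_idx], y[train_idx], cfg)
        probs, dec = cnn_predict(model, [scalos[i] for i in test_idx])
        scores["dl"] = probs
        pts, auc = roc_auc(probs, y_test)
        report.methods["dl"] = {
            "metrics": confusion_metrics(dec, y_test),
            "auc": auc,
            "roc_points": pts,
            "scores": probs,
            "_model": model,
        }

    names = [m for m in ("hotelling", "correlation", "dl") if m in scores]
    for a in names:
        for b in names:
            if a != b:
                report.delong[f"{a}>{b}"] = delong_one_sided(scores[a], scores[b], y_test)
    return report
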