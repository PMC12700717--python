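"""Multi-model staging evaluation over repeated stratified splits.

Four feature sets (clinical, transcriptomic six-biomarker panel, radiomic
textural + perfusion, and their union) are evaluated with three classifier
families (random forest, Gaussian naive Bayes, SVM) on repeated stratified
70/30 train/test splits of the T2c/T3b cohort.  The same splits are reused
across feature sets and models so comparisons are paired.  AUC is computed
with a self-contained Mann–Whitney rank statistic (ties count one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

__all__ = ["auc", "EvalResult", "evaluate", "MODELS", "FEATURE_SETS"]

MODELS = ("random_forest", "naive_bayes", "svm")
FEATURE_SETS = ("clinical", "transcriptomic", "radiomic", "combined")


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative; tied scores contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    # midranks over the pooled sample
    pooled = np.concatenate([pos, neg])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    rank_vals = np.empty(pooled.size)
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        rank_vals[i:j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    ranks[order] = rank_vals
    rank_sum_pos = ranks[: pos.size].sum()
    n1, n0 = pos.size, neg.size
    u = rank_sum_pos - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _make_model(name: str, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm":
        return SVC(random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def _scores(model, x_test) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x_test)[:, 1]
    return model.decision_function(x_test)


@dataclass
class EvalResult:
    """Per-run AUCs and their mean/SD summary."""

    runs: pd.DataFrame  # columns: feature_set, model, run, auc
    hyperparameters: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        g = self.runs.groupby(["feature_set", "model"])["auc"]
        out = g.agg(["mean", "std"]).rename(columns={"mean": "auc_mean", "std": "auc_sd"})
        return out.reset_index()


def evaluate(
    tables: dict[str, pd.DataFrame],
    labels: pd.Series,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    models: tuple[str, ...] = MODELS,
    runs: int = 10,
    seed: int = 0,
    test_size: float = 0.3,
) -> EvalResult:
    """Held-out AUC of each (feature set, model) over repeated splits.

    ``tables`` maps feature-set name to a samples x features table sharing
    the index of ``labels`` (binary, e.g. T2c vs T3b).  Features are
    z-scored with train-split statistics only.  Split partitions are fixed
    by ``seed`` and shared across feature sets and models.
    """
    y = labels.to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if min((y == c).sum() for c in classes) < 3:
        raise ValueError("each class needs at least 3 samples to stratify")
    y01 = (y == classes[1]).astype(int)

    splitter = StratifiedShuffleSplit(n_splits=runs, test_size=test_size,
                                      random_state=seed)
    splits = list(splitter.split(np.zeros(y01.size), y01))

    rows = []
    for set_name in feature_sets:
        table = tables[set_name]
        if not table.index.equals(labels.index):
            table = table.loc[labels.index]
        x = table.to_numpy(dtype=float)
        for model_name in models:
            for run_idx, (tr, te) in enumerate(splits):
                mu = x[tr].mean(axis=0)
                sd = x[tr].std(axis=0)
                sd[sd == 0] = 1.0
                xtr = (x[tr] - mu) / sd
                xte = (x[te] - mu) / sd
                model = _make_model(model_name, seed + run_idx)
                model.fit(xtr, y01[tr])
                rows.append({
                    "feature_set": set_name,
                    "model": model_name,
                    "run": run_idx,
                    "auc": auc(_scores(model, xte), y01[te]),
                })
    hp = {name: repr(_make_model(name, seed).get_params()) for name in models}
    return EvalResult(runs=pd.DataFrame(rows), hyperparameters=hp)
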