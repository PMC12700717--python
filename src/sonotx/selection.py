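"""Stepwise relevance–redundancy feature selection.

Greedy forward selection on a feature table against a binary class label:

1. The priming feature is the one with the largest relevance, the absolute
   Pearson correlation |r(f, y)| with the 0/1-encoded class.
2. Each subsequent candidate is scored by its relevance penalized by its
   mean absolute correlation with the already-retained features
   (``redundancy_sign="minus"``, the default) — most related to the class,
   least related to what is already in the set.  A literal-sum variant
   (``redundancy_sign="plus"``) is also exposed.
3. At every step the procedure computes a monitoring score,
   mean |r(candidate, retained)| + relevance(candidate), and terminates
   when this score drops sharply — below ``drop_ratio`` times the previous
   step's score — or when ``max_features`` is reached.

Ties are broken by lexicographic feature name, making the trace a pure
function of its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionParams", "SelectionTrace", "relevance", "select_features"]


@dataclass(frozen=True)
class SelectionParams:
    drop_ratio: float = 0.5  # "dropped sharply": score_t < drop_ratio * score_{t-1}
    max_features: int = 20
    redundancy_sign: str = "minus"  # "minus" (penalize) or "plus" (literal sum)

    def __post_init__(self):
        if not (0.0 < self.drop_ratio < 1.0):
            raise ValueError("drop_ratio must be in (0, 1)")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.redundancy_sign not in ("minus", "plus"):
            raise ValueError("redundancy_sign must be 'minus' or 'plus'")


@dataclass
class SelectionTrace:
    """Ordered record of a stepwise selection run."""

    selected: list[str]
    scores: list[float]  # monitoring score at each accepted step
    relevances: list[float]
    redundancies: list[float]  # mean |r| with retained set (0 at step 1)
    termination: str  # "score_drop" | "max_features" | "exhausted"

    def __len__(self) -> int:
        return len(self.selected)


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r|; zero-variance input gives 0 by convention."""
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return abs(r)


def relevance(values: np.ndarray, labels: np.ndarray) -> float:
    """Absolute Pearson correlation of a feature with the 0/1-encoded class."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size < 3:
        raise ValueError("need at least 3 samples")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes[1]).astype(float)
    return _abs_pearson(values, y)


def select_features(
    table: pd.DataFrame,
    labels,
    params: SelectionParams | None = None,
) -> SelectionTrace:
    """Run the stepwise selection on a samples x features table.

    Zero-variance columns never win a step (relevance 0 and undefined
    redundancy treated as 0).
    """
    params = params or SelectionParams()
    labels = np.asarray(labels)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if table.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if table.shape[0] != labels.size:
        raise ValueError("labels length must match table rows")

    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes[1]).astype(float)

    rel = np.array([_abs_pearson(x[:, k], y) for k in range(len(cols))])
    # feature-feature |r|, computed lazily column-by-column would be fine at
    # this scale; precompute for clarity
    corr = np.zeros((len(cols), len(cols)))
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            corr[a, b] = corr[b, a] = _abs_pearson(x[:, a], x[:, b])

    order = sorted(range(len(cols)), key=lambda k: (-rel[k], cols[k]))
    first = order[0]
    selected = [first]
    trace = SelectionTrace(
        selected=[cols[first]],
        scores=[float(rel[first])],  # empty retained set: redundancy term is 0
        relevances=[float(rel[first])],
        redundancies=[0.0],
        termination="exhausted",
    )

    remaining = set(range(len(cols))) - {first}
    while remaining:
        if len(selected) >= params.max_features:
            trace.termination = "max_features"
            return trace
        red = {k: float(corr[k, selected].mean()) for k in remaining}
        if params.redundancy_sign == "minus":
            crit = {k: rel[k] - red[k] for k in remaining}
        else:
            crit = {k: rel[k] + red[k] for k in remaining}
        best = min(remaining, key=lambda k: (-crit[k], cols[k]))
        score = red[best] + rel[best]  # literal monitoring score
        if score < params.drop_ratio * trace.scores[-1]:
            trace.termination = "score_drop"
            return trace
        selected.append(best)
        trace.selected.append(cols[best])
        trace.scores.append(float(score))
        trace.relevances.append(float(rel[best]))
        trace.redundancies.append(float(red[best]))
        remaining.remove(best)
    trace.termination = "exhausted"
    return trace
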