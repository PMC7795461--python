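"""The ten classifiers of the study: m1-m10.

Four distance metrics (Canberra, Euclidean, Manhattan, and Euclidean on
min-max-normalized coordinates) each drive a 1-nearest-neighbour rule and a
weighted-voting rule ("811": every training row votes for its own class
with weight inversely proportional to its distance from the query).  Two
further classifiers are epsilon-indiscernibility Naive Bayes variants that
score a class by summing, over attributes, the fraction of the class's
training rows whose value falls within an epsilon-scaled window of the
query's value; the "nb2" variant additionally weights the sum by the class
prior.  Sums rather than products avoid zeroing when a window is empty.

All classifiers are total (coverage 1: every query receives a label) and
fully deterministic: ties are broken by ascending class-label order, with
merged rest-labels (e.g. "156") ordered after numeric labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .features import DecisionTable, FeatureVector, _label_key

__all__ = [
    "METRICS",
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "parse_classifier",
    "distance",
    "classify_1nn",
    "classify_811",
    "classify_nb",
    "classify",
    "predict",
]

METRICS = ("canberra", "euclidean", "manhattan", "maxmin")

# Canonical study names m1..m10 (the "maxminnormalized" metric is Euclidean
# distance on coordinates min-max normalized by the training extrema).
CLASSIFIER_NAMES = (
    "canberra.1nn",
    "canberra.811",
    "eps=0.01.nb",
    "eps=0.01.nb2",
    "euclidean.1nn",
    "euclidean.811",
    "manhattan.1nn",
    "manhattan.811",
    "maxminnormalized.1nn",
    "maxminnormalized.811",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier: family plus its metric / window / regularizer."""

    family: str  # "1nn" | "811" | "nb" | "nb2"
    metric: str = "euclidean"  # ignored by nb/nb2
    eps: float = 0.01  # nb/nb2 indiscernibility window, fraction of attribute range
    delta: float = 1e-10  # 811 vote regularizer

    def __post_init__(self) -> None:
        if self.family not in ("1nn", "811", "nb", "nb2"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.family in ("nb", "nb2") and not 0 < self.eps <= 1:
            raise ValueError("eps must be in (0, 1]")
        if self.family == "811" and self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def name(self) -> str:
        if self.family in ("nb", "nb2"):
            return f"eps={self.eps:g}.{self.family}"
        metric = "maxminnormalized" if self.metric == "maxmin" else self.metric
        return f"{metric}.{self.family}"


def parse_classifier(name: str, delta: float = 1e-10) -> ClassifierSpec:
    """Parse a study classifier name (``canberra.1nn``, ``eps=0.01.nb2``, ``m5``...)."""
    key = name.strip().lower().replace(" ", "")
    if re.fullmatch(r"m(10|[1-9])", key):
        key = CLASSIFIER_NAMES[int(key[1:]) - 1]
    m = re.fullmatch(r"eps=([0-9.eE+-]+)\.(nb2?)", key)
    if m:
        return ClassifierSpec(family=m.group(2), eps=float(m.group(1)))
    m = re.fullmatch(r"(canberra|euclidean|manhattan|maxminnormalized|maxmin)\.(1nn|811)", key)
    if m:
        metric = "maxmin" if m.group(1).startswith("maxmin") else m.group(1)
        return ClassifierSpec(family=m.group(2), metric=metric, delta=delta)
    raise ValueError(
        f"unknown classifier {name!r}; valid names: {', '.join(CLASSIFIER_NAMES)} (or m1..m10)"
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pairwise(metric: str, X: np.ndarray, y: np.ndarray,
              attr_min=None, attr_max=None) -> np.ndarray:
    """Distances from every row of X to the vector y (vectorized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if metric == "euclidean":
        return np.sqrt(((X - y) ** 2).sum(axis=1))
    if metric == "manhattan":
        return np.abs(X - y).sum(axis=1)
    if metric == "canberra":
        num = np.abs(X - y)
        den = np.abs(X) + np.abs(y)
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(den > 0, num / den, 0.0)  # 0/0 terms contribute 0
        return terms.sum(axis=1)
    if metric == "maxmin":
        lo = np.asarray(attr_min, dtype=float)
        rng = np.asarray(attr_max, dtype=float) - lo
        safe = np.where(rng > 0, rng, 1.0)
        Xn = np.where(rng > 0, (X - lo) / safe, 0.0)  # constant attributes map to 0
        yn = np.where(rng > 0, (y - lo) / safe, 0.0)
        return np.sqrt(((Xn - yn) ** 2).sum(axis=1))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def distance(metric: str, x, y, attr_min=None, attr_max=None) -> float:
    """Distance between two descriptor vectors under the given metric.

    ``attr_min``/``attr_max`` are the training-table extrema, used only by
    the ``maxmin`` metric (values outside the training range are not
    clipped; constant attributes map to 0).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return float(_pairwise(metric, x, np.asarray(y, dtype=float), attr_min, attr_max)[0])


def _query_vector(x) -> np.ndarray:
    return x.descriptors if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)


def _argbest(scores: dict, reverse: bool) -> object:
    """Label with the max (reverse) or min score; ties -> lowest label order."""
    best = max(scores.values()) if reverse else min(scores.values())
    tied = [c for c, s in scores.items() if s == best]
    return min(tied, key=_label_key)


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

def classify_1nn(train: DecisionTable, x, metric: str = "euclidean"):
    """Label of the nearest training row; distance ties -> lowest label."""
    d = _pairwise(metric, train.X, _query_vector(x), train.attr_min, train.attr_max)
    best = d.min()
    tied_labels = [train.rows[i].class_label for i in np.flatnonzero(d == best)]
    return min(tied_labels, key=_label_key)


def classify_811(train: DecisionTable, x, metric: str = "euclidean", delta: float = 1e-10):
    """Weighted voting: each row votes for its class with weight 1/(d + delta)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    d = _pairwise(metric, train.X, _query_vector(x), train.attr_min, train.attr_max)
    w = 1.0 / (d + delta)
    votes: dict = {}
    for row, weight in zip(train.rows, w):
        votes[row.class_label] = votes.get(row.class_label, 0.0) + weight
    return _argbest(votes, reverse=True)


def classify_nb(train: DecisionTable, x, eps: float = 0.01, variant: str = "nb"):
    """Epsilon-indiscernibility Naive Bayes.

    Per attribute i and class c, the indiscernibility ratio r[c, i] is the
    fraction of class-c training rows whose attribute-i value lies within
    ``eps * (attr_max[i] - attr_min[i])`` of the query's value (a constant
    attribute degenerates to exact equality).  Scores: ``nb`` sums the
    ratios over attributes; ``nb2`` multiplies the sum by the class prior
    |c| / N.
    """
    if variant not in ("nb", "nb2"):
        raise ValueError(f"variant must be 'nb' or 'nb2', got {variant!r}")
    if not 0 < eps <= 1:
        raise ValueError("eps must be in (0, 1]")
    xv = _query_vector(x)
    window = eps * (train.attr_max - train.attr_min)
    X = train.X
    labels = np.asarray(train.labels, dtype=object)
    hits = np.abs(X - xv) <= window
    scores: dict = {}
    n_total = len(train)
    for c in train.class_set:
        mask = labels == c
        n_c = int(mask.sum())
        ratios = hits[mask].mean(axis=0)  # r[c, i], shape (6,)
        s = float(ratios.sum())
        if variant == "nb2":
            s *= n_c / n_total
        scores[c] = s
    return _argbest(scores, reverse=True)


def classify(train: DecisionTable, x, spec: ClassifierSpec):
    """Apply one of the ten classifiers to a single query."""
    if spec.family == "1nn":
        return classify_1nn(train, x, spec.metric)
    if spec.family == "811":
        return classify_811(train, x, spec.metric, spec.delta)
    return classify_nb(train, x, spec.eps, spec.family)


def predict(train: DecisionTable, queries, spec: ClassifierSpec) -> list:
    """Classify a sequence of queries (feature vectors or raw 6-vectors)."""
    return [classify(train, q, spec) for q in queries]
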