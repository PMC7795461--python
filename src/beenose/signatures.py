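"""Per-class scent signatures (radar-chart data).

Each sensor attribute is min-max normalized into [a, b] over all objects of
a decision table (all classes pooled); the within-class mean of the
normalized values is then squared, giving each class a six-vector of
squared normalized mean intensities in [a^2, b^2] that can be drawn as a
radar polygon.  Squaring stretches the upper range, visually accentuating
differences between strongly responding classes while preserving the
per-attribute ordering of class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import DecisionTable, _label_key
from .synth import SENSORS

__all__ = ["ClassSignature", "minmax_normalize", "class_signature", "signature_to_frame",
           "plot_signature"]


@dataclass
class ClassSignature:
    """Per-class six-vectors of squared normalized mean sensor intensities."""

    classes: list
    values: dict  # class label -> (6,) array in [a^2, b^2] for a >= 0
    a: float
    b: float


def minmax_normalize(values, a: float = 0.0, b: float = 1.0) -> np.ndarray:
    """Affine map sending the minimum of ``values`` to ``a`` and the maximum to ``b``.

    x -> (x - min) * (b - a) / (max - min) + a.  A constant (or singleton)
    input has zero range; by convention every output is then ``a``.
    """
    if b <= a:
        raise ValueError(f"need b > a, got a={a}, b={b}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, a)
    return (values - lo) * (b - a) / (hi - lo) + a


def class_signature(table: DecisionTable, a: float = 0.0, b: float = 1.0,
                    classes=None) -> ClassSignature:
    """Compute the signature of every class in a decision table.

    Normalization extrema are taken over all rows pooled; class means are
    computed per attribute on the normalized values and squared.  A
    requested class with no rows is omitted with a warning.
    """
    X = table.X
    norm = np.column_stack([minmax_normalize(X[:, j], a, b) for j in range(X.shape[1])])
    labels = np.asarray(table.labels, dtype=object)
    if classes is None:
        classes = table.class_set
    out_classes, values = [], {}
    for c in classes:
        mask = labels == c
        if not mask.any():
            warnings.warn(f"class {c!r} has no rows; omitted from signature", stacklevel=2)
            continue
        values[c] = norm[mask].mean(axis=0) ** 2
        out_classes.append(c)
    return ClassSignature(classes=out_classes, values=values, a=a, b=b)


def signature_to_frame(sig: ClassSignature) -> pd.DataFrame:
    """Signature as a tidy frame: one row per class, one column per sensor."""
    data = {"class": sig.classes}
    for j, s in enumerate(SENSORS):
        data[s] = [sig.values[c][j] for c in sig.classes]
    return pd.DataFrame(data)


def plot_signature(sig: ClassSignature, ax=None, title: str | None = None):
    """Convenience radar-polygon rendering of an exported signature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.linspace(0, 2 * np.pi, len(SENSORS), endpoint=False)
    closed = np.concatenate([theta, theta[:1]])
    for c in sig.classes:
        v = sig.values[c]
        ax.plot(closed, np.concatenate([v, v[:1]]), label=f"class {c}")
    ax.set_xticks(theta)
    ax.set_xticklabels(SENSORS)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1))
    return ax
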