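"""Clinical pollen-level categories and evaluation metrics.

Daily concentrations are binned into three allergy-relevant classes per
taxon: low (<= 10 grains/m3, zeros included), medium (<= 75 for birch,
<= 50 for grasses) and high (above the medium bound).  Regression quality
is measured by MAE and RMSE, classification by overall (exact-match)
accuracy plus per-class one-vs-rest confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CategoryScheme",
    "BETULA_SCHEME",
    "POACEAE_SCHEME",
    "scheme_for",
    "categorize",
    "mae",
    "rmse",
    "accuracy",
    "per_class_confusion",
]

CLASS_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered concentration classes for one taxon.

    ``bounds`` are the inclusive upper bounds of all but the last class;
    the last class is unbounded above.  With ``zero_as_none=True`` a fourth
    leading "none" class absorbs exact zeros; by default zeros fall in
    "low" (the conservative clinical reading — the class ranges are printed
    starting at 1 yet their frequencies cover every season day).
    """

    taxon: str
    bounds: tuple[float, ...] = (10.0, 75.0)
    labels: tuple[str, ...] = CLASS_LABELS
    zero_as_none: bool = False

    def __post_init__(self):
        if len(self.bounds) != len(self.labels) - 1:
            raise ValueError("need one bound fewer than labels")
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValueError("bounds must be strictly increasing")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return (("none",) + self.labels) if self.zero_as_none else self.labels


BETULA_SCHEME = CategoryScheme(taxon="Betula", bounds=(10.0, 75.0))
POACEAE_SCHEME = CategoryScheme(taxon="Poaceae", bounds=(10.0, 50.0))


def scheme_for(taxon: str) -> CategoryScheme:
    """Default category scheme for a taxon name."""
    schemes = {"betula": BETULA_SCHEME, "poaceae": POACEAE_SCHEME}
    try:
        return schemes[taxon.lower()]
    except KeyError:
        raise ValueError(f"no default category scheme for taxon {taxon!r}") from None


def categorize(concentration, scheme: CategoryScheme):
    """Map concentration(s) to class label(s).

    Accepts a scalar or array; negative concentrations are rejected.
    """
    c = np.asarray(concentration, dtype=float)
    if (c < 0).any():
        raise ValueError("negative concentration")
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    idx = np.searchsorted(np.asarray(scheme.bounds), c, side="left")
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    if scheme.zero_as_none:
        labels = np.where(c == 0, "none", labels).astype(object)
    return str(labels[0]) if scalar else labels


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error, (1/N) * sum |y_i - yhat_i|."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error, sqrt((1/N) * sum (y_i - yhat_i)^2)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def accuracy(self) -> float:
        """(TP + TN) / (TP + TN + FP + FN)."""
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def per_class_confusion(labels, preds) -> dict[str, ConfusionCounts]:
    """Per-class one-vs-rest confusion counts over two label vectors."""
    labels = np.asarray(labels, dtype=object)
    preds = np.asarray(preds, dtype=object)
    if labels.shape != preds.shape:
        raise ValueError("length mismatch")
    out: dict[str, ConfusionCounts] = {}
    for cls in sorted(set(labels) | set(preds), key=str):
        t, p = labels == cls, preds == cls
        out[str(cls)] = ConfusionCounts(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )
    return out


def accuracy(labels, preds) -> float:
    """Overall exact-match accuracy between two label vectors."""
    labels = np.asarray(labels, dtype=object)
    preds = np.asarray(preds, dtype=object)
    if labels.shape != preds.shape:
        raise ValueError("length mismatch")
    if labels.size == 0:
        raise ValueError("empty input")
    return float(np.mean(labels == preds))
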