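"""Multi-associative graph network: lazy prediction, mutual information,
frequent patterns and association rules.

The graph stores each feature as a *sensory field* — the sorted unique
values observed in training, each held by a sensory neuron with a duplicate
counter and weighted links to its neighbours in value order.  Training rows
become *object neurons* linked by defining connections to one sensory
neuron per feature; identical rows aggregate into a single object neuron
with an incremented counter.  Prediction is lazy ("similarity voting"): a
query value activates each field with a linearly decaying similarity,
activation propagates over the defining connections, and the most activated
objects vote — counter-weighted — for a class (classification) or average
their targets (regression).

The same counter structure supports season characterization: exact
(rational-arithmetic) support/confidence/lift for frequent patterns and
association rules, and discrete mutual information between features and
the target.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "SensoryField",
    "MagnGraph",
    "magn_build",
    "magn_predict",
    "mutual_information",
    "normalized_mi",
    "tercile_bins",
    "Pattern",
    "AssociationRule",
    "mine_patterns",
    "mine_rules",
    "season_rules",
]


# ---------------------------------------------------------------------------
# graph structure


@dataclass
class SensoryField:
    """One feature's sensory neurons: unique values with duplicate counters.

    Numeric fields keep values sorted; ``neighbor_weight(i)`` is the
    similarity link between adjacent neurons, 1 - |v_i - v_{i+1}| / range.
    """

    name: str
    numeric: bool
    values: np.ndarray  # unique, sorted if numeric
    counters: np.ndarray  # int, aligned with values

    @property
    def value_range(self) -> float:
        if not self.numeric or len(self.values) < 2:
            return 0.0
        return float(self.values[-1] - self.values[0])

    def neighbor_weights(self) -> np.ndarray:
        """Similarity weights between adjacent sensory neurons."""
        if not self.numeric or len(self.values) < 2:
            return np.array([])
        rng = self.value_range
        return 1.0 - np.abs(np.diff(self.values.astype(float))) / rng

    def activations(self, query_value, kind: str = "rank") -> np.ndarray:
        """Fuzzy activation of every sensory neuron for a query value.

        Exact matches always activate 1.  For numeric fields the activation
        decays linearly with normalized distance along the field:

        * ``kind="rank"`` (default) — distance measured along the ordered
          neighbor chain: the fraction of sensory neurons separating the
          two values (the query's position interpolated between neurons).
          Robust to heavy-tailed value distributions.
        * ``kind="range"`` — distance as |v - q| / range(field), the same
          normalization as the neighbor weights.

        A single-valued field activates 1 on match, 0 otherwise.
        Categorical fields activate only the exact value; unseen values
        activate nothing.
        """
        if not self.numeric:
            return (self.values == query_value).astype(float)
        v = self.values.astype(float)
        q = float(query_value)
        if len(v) == 1:
            return (v == q).astype(float)
        if kind == "range":
            return np.maximum(0.0, 1.0 - np.abs(v - q) / self.value_range)
        if kind != "rank":
            raise ValueError(f"unknown activation kind {kind!r}")
        m = len(v)
        rq = float(np.interp(q, v, np.arange(m))) / (m - 1)
        rv = np.arange(m) / (m - 1)
        return np.maximum(0.0, 1.0 - np.abs(rv - rq))


@dataclass
class MagnGraph:
    """Sensory fields plus aggregated object neurons.

    ``objects`` maps each distinct (feature tuple, target) to its duplicate
    counter; ``object_index`` holds, per object, the index of its defining
    sensory neuron in every field.
    """

    feature_names: list[str]
    fields: dict[str, SensoryField]
    object_values: np.ndarray  # (n_objects, n_features), object dtype
    object_sensor_idx: np.ndarray  # (n_objects, n_features) int
    object_targets: np.ndarray  # (n_objects,), object dtype
    object_counters: np.ndarray  # (n_objects,) int
    n_rows: int
    field_weights: np.ndarray | None = None  # relevance weights, sum to 1

    @property
    def n_objects(self) -> int:
        return len(self.object_counters)

    def to_dict(self) -> dict:
        """JSON-ready view of the graph for inspection/serialization."""
        return {
            "n_rows": self.n_rows,
            "fields": {
                name: {
                    "numeric": f.numeric,
                    "values": f.values.tolist(),
                    "counters": f.counters.tolist(),
                    "neighbor_weights": f.neighbor_weights().tolist(),
                }
                for name, f in self.fields.items()
            },
            "objects": [
                {
                    "values": dict(zip(self.feature_names, row.tolist())),
                    "target": t,
                    "counter": int(c),
                }
                for row, t, c in zip(
                    self.object_values, self.object_targets, self.object_counters
                )
            ],
        }


def magn_build(
    rows: pd.DataFrame, target: str = "target", weight_fields: bool = True
) -> MagnGraph:
    """Build the associative graph from a feature table.

    ``rows`` holds one training sample per row; every column except
    ``target`` becomes a sensory field.  Duplicate (features, target) rows
    aggregate into one object neuron with an incremented counter.

    With ``weight_fields`` (default) each numeric field receives a
    relevance weight — its normalized mutual information with the target,
    computed from the graph's own value/target co-occurrence counts — used
    by similarity voting to prioritize statistically informative fields.
    A constant target leaves the fields unweighted.
    """
    if rows.empty:
        raise ValueError("empty training data")
    if target not in rows.columns:
        raise ValueError(f"no target column {target!r}")
    feature_names = [c for c in rows.columns if c != target]
    if not feature_names:
        raise ValueError("no feature columns")

    fields: dict[str, SensoryField] = {}
    for name in feature_names:
        col = rows[name]
        numeric = pd.api.types.is_numeric_dtype(col)
        vals, counts = np.unique(col.to_numpy(), return_counts=True)
        fields[name] = SensoryField(
            name=name,
            numeric=numeric,
            values=vals,
            counters=counts.astype(int),
        )

    # aggregate duplicate rows (features + target) into object neurons
    grouped = rows.groupby(feature_names + [target], sort=False, dropna=False).size()
    keys = list(grouped.index)
    if len(feature_names) + 1 == 1:  # single column edge: index not tuple
        keys = [(k,) for k in keys]
    object_values = np.empty((len(keys), len(feature_names)), dtype=object)
    object_targets = np.empty(len(keys), dtype=object)
    for i, key in enumerate(keys):
        key = key if isinstance(key, tuple) else (key,)
        object_values[i, :] = key[:-1]
        object_targets[i] = key[-1]
    counters = grouped.to_numpy().astype(int)

    sensor_idx = np.empty_like(object_values, dtype=int)
    for j, name in enumerate(feature_names):
        f = fields[name]
        sensor_idx[:, j] = np.searchsorted(f.values, object_values[:, j].tolist())

    weights = None
    if weight_fields:
        y = rows[target].to_numpy()
        y = y if not pd.api.types.is_numeric_dtype(rows[target]) else y.astype(float)
        try:
            w = np.array(
                [
                    normalized_mi(rows[name].to_numpy(), y)
                    if fields[name].numeric
                    else normalized_mi(rows[name].to_numpy(dtype=object), y)
                    for name in feature_names
                ]
            )
            if w.sum() > 0:
                weights = w / w.sum()
        except ValueError:
            weights = None  # constant target: uniform voting

    return MagnGraph(
        feature_names=feature_names,
        fields=fields,
        object_values=object_values,
        object_sensor_idx=sensor_idx,
        object_targets=object_targets,
        object_counters=counters,
        n_rows=int(len(rows)),
        field_weights=weights,
    )


def _object_activations(graph: MagnGraph, query: dict, kind: str = "rank") -> np.ndarray:
    """Relevance-weighted per-field activation of every object neuron."""
    acts = np.zeros((graph.n_objects, len(graph.feature_names)))
    for j, name in enumerate(graph.feature_names):
        if name not in query:
            continue  # absent feature contributes zero activation
        field_act = graph.fields[name].activations(query[name], kind=kind)
        acts[:, j] = field_act[graph.object_sensor_idx[:, j]]
    w = graph.field_weights
    if w is None:
        return acts.mean(axis=1)
    return acts @ w


def magn_predict(
    graph: MagnGraph,
    query: dict | pd.Series,
    k: int = 5,
    mode: str = "classification",
    activation: str = "rank",
):
    """Similarity-voting prediction for one query row.

    The query activates each sensory field (activation decaying linearly
    with normalized distance — by default the rank distance along the
    field's neighbor chain), activation propagates to object neurons over
    their defining connections with fields weighted by their mutual
    information with the target, and the top-k most activated objects vote
    with weight activation x duplicate counter.  Classification returns
    the weight-majority label; regression the weighted mean target.
    """
    if graph.n_objects == 0:
        raise ValueError("empty graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    query = dict(query)
    unknown = set(query) - set(graph.feature_names)
    if unknown:
        raise ValueError(f"query features outside graph schema: {sorted(unknown)}")
    act = _object_activations(graph, query, kind=activation)
    order = np.argsort(-act, kind="stable")[: min(k, graph.n_objects)]
    weights = act[order] * graph.object_counters[order]
    if weights.sum() <= 0:
        weights = graph.object_counters[order].astype(float)  # degenerate: count vote
    targets = graph.object_targets[order]
    if mode == "regression":
        return float(np.dot(weights, targets.astype(float)) / weights.sum())
    if mode != "classification":
        raise ValueError(f"unknown mode {mode!r}")
    tally: dict = {}
    for t, w in zip(targets, weights):  # insertion order = descending activation
        tally[t] = tally.get(t, 0.0) + float(w)
    best, best_w = None, -1.0
    for t, w in tally.items():  # ties go to the more activated label
        if w > best_w:
            best, best_w = t, w
    return best


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information (bits) of a discrete joint distribution.

    ``joint[i, j]`` = P(X=i, Y=j); must be non-negative and sum to 1.
    Zero-probability cells contribute nothing.
    """
    p = np.asarray(joint, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"joint probabilities sum to {p.sum()}, not 1")
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(terms[mask].sum())


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def tercile_bins(x: np.ndarray, bins: int = 3) -> np.ndarray:
    """Equal-frequency bin labels (0..bins-1) for a numeric vector.

    Duplicate quantile edges collapse; ties fall in the lower bin.
    """
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="left")


def _joint_from_codes(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    xi, cx = np.unique(cx, return_inverse=True)
    yi, cy = np.unique(cy, return_inverse=True)
    joint = np.zeros((len(xi), len(yi)))
    np.add.at(joint, (cx, cy), 1.0)
    return joint / joint.sum()


def normalized_mi(x, y, bins: int = 3) -> float:
    """Mutual information of x with y, normalized by the entropy of y.

    Numeric inputs are discretized by equal-frequency binning (default
    terciles); categorical inputs are used as-is.  Returns MI(X,Y) / H(Y)
    in [0, 1].  A constant y (zero entropy) is rejected.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    cx = tercile_bins(x, bins) if np.issubdtype(x.dtype, np.number) else x
    cy = tercile_bins(y, bins) if np.issubdtype(y.dtype, np.number) else y
    joint = _joint_from_codes(np.asarray(cx), np.asarray(cy))
    hy = _entropy_bits(joint.sum(axis=0))
    if hy == 0.0:
        raise ValueError("target has zero entropy")
    return mutual_information(joint) / hy


# ---------------------------------------------------------------------------
# frequent patterns and association rules


@dataclass(frozen=True)
class Pattern:
    """A set of (feature, value) items with its exact support."""

    items: frozenset
    count: int
    support: Fraction

    def __repr__(self) -> str:  # stable, readable ordering
        items = ", ".join(f"{f}={v}" for f, v in sorted(self.items, key=str))
        return f"Pattern({{{items}}}, support={float(self.support):.3f})"


@dataclass(frozen=True)
class AssociationRule:
    """A -> B with exact support, confidence and lift."""

    antecedent: frozenset
    consequent: frozenset
    support: Fraction
    confidence: Fraction
    lift: Fraction

    def as_row(self) -> dict:
        fmt = lambda s: " & ".join(f"{f}={v}" for f, v in sorted(s, key=str))
        return {
            "antecedent": fmt(self.antecedent),
            "consequent": fmt(self.consequent),
            "support": float(self.support),
            "confidence": float(self.confidence),
            "lift": float(self.lift),
        }


def _rows_to_itemsets(rows: pd.DataFrame) -> list[frozenset]:
    cols = list(rows.columns)
    return [
        frozenset((c, v) for c, v in zip(cols, rec))
        for rec in rows.itertuples(index=False, name=None)
    ]


def mine_patterns(rows: pd.DataFrame, min_support: float | Fraction) -> list[Pattern]:
    """Level-wise (apriori) frequent-pattern mining with exact counts.

    Items are (column, value) pairs; supports are exact rationals
    count / n_rows.  Returns all itemsets with support >= min_support,
    ordered by descending support then size.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    n = len(rows)
    if n == 0:
        return []
    min_support = Fraction(min_support).limit_denominator(10**9)
    transactions = _rows_to_itemsets(rows)
    min_count = min_support * n  # compare counts to avoid float error

    # level 1
    item_counts: dict = {}
    for t in transactions:
        for it in t:
            item_counts[it] = item_counts.get(it, 0) + 1
    frequent = {
        frozenset([it]): c for it, c in item_counts.items() if c >= min_count
    }
    all_frequent = dict(frequent)
    while frequent:
        prev = sorted(frequent, key=lambda s: sorted(map(str, s)))
        candidates = set()
        for a, b in itertools.combinations(prev, 2):
            u = a | b
            if len(u) != len(a) + 1:
                continue
            # one item per feature; all subsets must be frequent
            if len({f for f, _ in u}) != len(u):
                continue
            if all(u - {x} in frequent for x in u):
                candidates.add(u)
        counts = {c: 0 for c in candidates}
        for t in transactions:
            for c in candidates:
                if c <= t:
                    counts[c] += 1
        frequent = {c: k for c, k in counts.items() if k >= min_count}
        all_frequent.update(frequent)

    patterns = [
        Pattern(items=s, count=c, support=Fraction(c, n))
        for s, c in all_frequent.items()
    ]
    patterns.sort(key=lambda p: (-p.support, len(p.items), sorted(map(str, p.items))))
    return patterns


def mine_rules(
    patterns: list[Pattern],
    rows: pd.DataFrame,
    min_confidence: float | Fraction,
) -> list[AssociationRule]:
    """Association rules from frequent patterns, with exact metrics.

    Every split A -> B of each frequent pattern (A, B non-empty) with
    confidence(A -> B) = support(A u B) / support(A) >= min_confidence is
    returned; lift = confidence / support(B).  Subset supports not present
    in ``patterns`` are counted directly from ``rows``.
    """
    if not 0 < min_confidence <= 1:
        raise ValueError("min_confidence must lie in (0, 1]")
    min_confidence = Fraction(min_confidence).limit_denominator(10**9)
    n = len(rows)
    transactions = _rows_to_itemsets(rows)
    supp_cache: dict[frozenset, Fraction] = {p.items: p.support for p in patterns}

    def support_of(s: frozenset) -> Fraction:
        if s not in supp_cache:
            supp_cache[s] = Fraction(sum(1 for t in transactions if s <= t), n)
        return supp_cache[s]

    rules = []
    for p in patterns:
        if len(p.items) < 2:
            continue
        items = sorted(p.items, key=str)
        for r in range(1, len(items)):
            for ante in itertools.combinations(items, r):
                a = frozenset(ante)
                b = p.items - a
                conf = p.support / support_of(a)
                if conf >= min_confidence:
                    sb = support_of(b)
                    rules.append(
                        AssociationRule(
                            antecedent=a,
                            consequent=b,
                            support=p.support,
                            confidence=conf,
                            lift=conf / sb,
                        )
                    )
    rules.sort(
        key=lambda r: (
            -r.lift,
            -r.confidence,
            -r.support,
            sorted(map(str, r.antecedent)),
            sorted(map(str, r.consequent)),
        )
    )
    return rules


#: meteorological variables whose 3-day means form rule antecedents
RULE_ANTECEDENT_VARS = ("tg", "cc", "hu", "fg", "ss")
TERCILE_NAMES = ("low", "mid", "high")


def season_rules(
    seasons,
    meteo: pd.DataFrame,
    scheme,
    min_support: float = 0.05,
    min_confidence: float = 0.5,
    history_days: int = 3,
) -> tuple[list[AssociationRule], pd.DataFrame]:
    """Mine weather -> pollen-class rules over the pollen seasons.

    For every within-season day with at least ``history_days`` preceding
    meteorological days, the antecedent items are the tercile-binned
    trailing means (previous 3 days) of mean temperature, cloud cover,
    humidity, wind speed and sunshine duration; the consequent is the
    pollen class that day.  Only rules whose consequent is exactly the
    pollen class and whose antecedent is purely meteorological are
    returned, ranked by lift.  The discretized table is returned too.
    """
    from .features import _daily_panel  # shared panel assembly
    from .metrics import categorize

    panel = _daily_panel(seasons, meteo)
    met = panel[list(RULE_ANTECEDENT_VARS)].to_numpy(dtype=float)
    pol = panel["pollen"].to_numpy(dtype=float)
    in_season = panel["in_season"].to_numpy()
    dates = pd.DatetimeIndex(panel["date"])

    rows, classes = [], []
    for i in range(len(panel)):
        if not in_season[i] or i < history_days:
            continue
        if (dates[i] - dates[i - history_days]).days != history_days:
            continue
        rows.append(met[i - history_days : i].mean(axis=0))
        classes.append(categorize(pol[i], scheme))
    if not rows:
        return [], pd.DataFrame()
    mat = np.asarray(rows)
    table = pd.DataFrame(
        {
            f"{v}_3d": [
                TERCILE_NAMES[b] for b in tercile_bins(mat[:, j], 3)
            ]
            for j, v in enumerate(RULE_ANTECEDENT_VARS)
        }
    )
    table["class"] = classes

    patterns = mine_patterns(table, min_support)
    rules = mine_rules(patterns, table, min_confidence)
    rules = [
        r
        for r in rules
        if len(r.consequent) == 1
        and next(iter(r.consequent))[0] == "class"
        and all(f != "class" for f, _ in r.antecedent)
    ]
    return rules, table
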