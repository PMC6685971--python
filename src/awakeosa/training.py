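"""Per-anthropometric-subset classifier training.

Subjects are grouped into overlapping anthropometric subsets (BMI < 35,
age > 50, age <= 50, male, NC > 40, MpS <= 2). Within a subset, feature
values are fenced with boxplot adjacent values learned per severity
group, 3-/4-feature combinations of the reduced feature shortlist are
scored with repeated Random-Forest out-of-bag (OOB) validation, and the
best combination becomes the subset's model; its OOB sensitivity and
specificity are the subset's voting weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import SubjectRecord

__all__ = [
    "SubsetSpec",
    "DEFAULT_SUBSETS",
    "OutlierFences",
    "SubsetModel",
    "CombinationScore",
    "build_subsets",
    "outlier_fences",
    "fit_fences",
    "apply_fences",
    "enumerate_combinations",
    "train_random_forest_oob",
    "score_combinations",
    "select_final_combination",
]

_FIELDS = {
    "bmi": lambda r: r.bmi,
    "age": lambda r: r.age,
    "nc": lambda r: r.neck_circumference,
    "mps": lambda r: r.mallampati,
    "sex": lambda r: r.sex,
}
_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
}


@dataclass(frozen=True)
class SubsetSpec:
    """One anthropometric subgroup defined by a single-field predicate."""

    name: str
    field: str
    op: str
    threshold: float | str
    include_nc: bool = False

    def matches(self, record: SubjectRecord) -> bool:
        if self.field not in _FIELDS:
            raise ValueError(f"unknown anthropometric field {self.field!r}")
        return _OPS[self.op](_FIELDS[self.field](record), self.threshold)


#: The six default subsets; neck circumference joins the candidate
#: feature pool everywhere except in its own subset.
DEFAULT_SUBSETS: tuple[SubsetSpec, ...] = (
    SubsetSpec("bmi_lt_35", "bmi", "<", 35, include_nc=True),
    SubsetSpec("age_gt_50", "age", ">", 50, include_nc=True),
    SubsetSpec("age_le_50", "age", "<=", 50, include_nc=True),
    SubsetSpec("male", "sex", "==", "male", include_nc=True),
    SubsetSpec("nc_gt_40", "nc", ">", 40, include_nc=False),
    SubsetSpec("mps_le_2", "mps", "<=", 2, include_nc=True),
)


def build_subsets(
    records: Sequence[SubjectRecord],
    specs: Sequence[SubsetSpec] = DEFAULT_SUBSETS,
    min_sizes: tuple[int, int] = (30, 20),
    threshold: float = 15.0,
) -> dict[str, list[str]]:
    """Subset memberships (subject ids per spec); a subject may belong to
    several subsets. Warns when a subset's severity groups fall below
    ``min_sizes`` (non-OSA, OSA)."""
    memberships: dict[str, list[str]] = {}
    for spec in specs:
        members = [r for r in records if spec.matches(r)]
        n_osa = sum(r.is_osa(threshold) for r in members)
        n_non = len(members) - n_osa
        if members and (n_non < min_sizes[0] or n_osa < min_sizes[1]):
            warnings.warn(
                f"subset {spec.name}: {n_non} non-OSA / {n_osa} OSA members, "
                f"below the recommended ({min_sizes[0]}, {min_sizes[1]})"
            )
        memberships[spec.name] = [r.subject_id for r in members]
    return memberships


def outlier_fences(values: np.ndarray) -> tuple[float, float]:
    """Boxplot adjacent values: the extreme observations inside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (linear-interpolation quartiles)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise ValueError("need at least 5 values per group for fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return float(inside.min()), float(inside.max())


@dataclass
class OutlierFences:
    """Per-feature merged (lower, upper) bounds from the two severity groups."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for fid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{fid}: lower bound exceeds upper bound")


def fit_fences(df: pd.DataFrame, labels: pd.Series) -> OutlierFences:
    """Merged fences per feature: the lowest lower and highest upper
    adjacent value over the two severity groups (constant features get
    a degenerate fence equal to the constant). Groups with fewer than 5
    usable values contribute their raw extremes, with a warning.
    """
    y = pd.Series(labels).reindex(df.index).astype(bool)
    bounds = {}
    small_groups = False
    for fid in df.columns:
        lows, highs = [], []
        for mask in (~y, y):
            vals = df.loc[mask, fid].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            if vals.size < 5:
                small_groups = True
                lo, hi = float(vals.min()), float(vals.max())
            else:
                lo, hi = outlier_fences(vals)
            lows.append(lo)
            highs.append(hi)
        bounds[fid] = (min(lows), max(highs)) if lows else (-np.inf, np.inf)
    if small_groups:
        warnings.warn("severity group smaller than 5; fences fall back to raw extremes")
    return OutlierFences(bounds)


def apply_fences(df: pd.DataFrame, fences: OutlierFences) -> pd.DataFrame:
    """Mark values outside the merged fences as missing (NaN). Idempotent."""
    out = df.copy()
    for fid, (lo, hi) in fences.bounds.items():
        if fid in out.columns:
            col = out[fid]
            out[fid] = col.where((col >= lo) & (col <= hi))
    return out


def enumerate_combinations(
    feature_ids: Sequence[str],
    sizes: tuple[int, ...] = (3, 4),
    extra_pool: Sequence[str] = (),
    exclusive_groups: Iterable[frozenset[str]] = (),
) -> list[tuple[str, ...]]:
    """All 3- and 4-feature combinations of the candidate pool.

    ``extra_pool`` (e.g. the neck-circumference feature) joins the pool
    as an ordinary candidate. Combinations containing more than one
    member of an exclusive group (alternative features) are omitted.
    """
    pool = list(dict.fromkeys([*feature_ids, *extra_pool]))
    if len(pool) < min(sizes):
        raise ValueError(f"need at least {min(sizes)} candidate features")
    exclusive = [set(g) for g in exclusive_groups]
    combos = []
    for k in sizes:
        for combo in iter_combinations(pool, k):
            if any(len(g.intersection(combo)) > 1 for g in exclusive):
                continue
            combos.append(combo)
    return combos


@dataclass
class OOBMetrics:
    accuracy: float
    sensitivity: float
    specificity: float


def train_random_forest_oob(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 1200,
    seed: int = 0,
) -> tuple[RandomForestClassifier, OOBMetrics]:
    """Random forest with 2/3-in-bag bootstrap and OOB validation.

    Gini splitting, per-split random predictor subsetting, and
    misclassification costs inversely proportional to class prevalence
    (class_weight='balanced'). OOB sensitivity is the OSA (positive
    class) recall, specificity the non-OSA recall, both computed from
    the out-of-bag votes. Deterministic given the seed.
    """
    y = np.asarray(y, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("both severity classes must be present")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_samples=2.0 / 3.0,
        bootstrap=True,
        oob_score=True,
        class_weight="balanced",
        random_state=int(seed) % (2**31 - 1),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # rows never out-of-bag (tiny forests) are handled explicitly below
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        rf.fit(X, y)
    votes = rf.oob_decision_function_
    covered = ~np.isnan(votes[:, 0])
    pred = np.zeros(len(y), dtype=bool)
    pred[covered] = votes[covered, 1] > votes[covered, 0]
    yy, pp = y[covered], pred[covered]
    metrics = OOBMetrics(
        accuracy=float(np.mean(pp == yy)),
        sensitivity=float(np.mean(pp[yy])) if yy.any() else float("nan"),
        specificity=float(np.mean(~pp[~yy])) if (~yy).any() else float("nan"),
    )
    return rf, metrics


@dataclass
class CombinationScore:
    """Repeated-training OOB metrics for one feature combination."""

    combination: tuple[str, ...]
    accuracy: list[float] = field(default_factory=list)
    sensitivity: list[float] = field(default_factory=list)
    specificity: list[float] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def spread(self) -> float:
        return float(np.max(self.accuracy) - np.min(self.accuracy))

    def all_values(self) -> list[float]:
        return [*self.accuracy, *self.sensitivity, *self.specificity]


def _combination_rows(df: pd.DataFrame, labels: pd.Series, combination):
    sub = df[list(combination)].dropna()
    y = pd.Series(labels).reindex(sub.index).astype(bool).to_numpy()
    return sub.to_numpy(dtype=float), y


def score_combinations(
    df: pd.DataFrame,
    labels: pd.Series,
    combinations: Sequence[tuple[str, ...]],
    n_trees: int = 1200,
    reps: int = 3,
    seed: int = 0,
    min_value: float = 0.7,
    window: float = 0.02,
) -> tuple[list[tuple[str, ...]], list[CombinationScore]]:
    """Shortlist combinations by repeated OOB validation.

    Each combination is trained ``reps`` times (seeds seed, seed+1, ...).
    Combinations with any accuracy/sensitivity/specificity value below
    ``min_value`` are dropped; among the rest, those whose mean accuracy
    lies within max(largest accuracy spread, ``window``) of the best
    mean accuracy are shortlisted. Order-invariant in ``combinations``.
    """
    scores = []
    for combo in combinations:
        X, y = _combination_rows(df, labels, combo)
        cs = CombinationScore(tuple(combo))
        if len(np.unique(y)) < 2:
            cs.accuracy = [0.0] * reps
            cs.sensitivity = [0.0] * reps
            cs.specificity = [0.0] * reps
        else:
            for r in range(reps):
                _, m = train_random_forest_oob(X, y, n_trees, seed + r)
                cs.accuracy.append(m.accuracy)
                cs.sensitivity.append(m.sensitivity)
                cs.specificity.append(m.specificity)
        scores.append(cs)

    survivors = [cs for cs in scores if min(cs.all_values()) >= min_value]
    if not survivors:
        warnings.warn("no combination reached the metric floor")
        return [], scores
    max_spread = max(cs.spread for cs in survivors)
    best = max(cs.mean_accuracy for cs in survivors)
    lo = best - max(max_spread, window)
    shortlist = [cs.combination for cs in survivors if cs.mean_accuracy >= lo]
    return shortlist, scores


@dataclass
class SubsetModel:
    """A subset's selected combination, fences, forest and vote weights."""

    spec: SubsetSpec
    combination: tuple[str, ...]
    fences: OutlierFences
    forest: RandomForestClassifier
    oob_accuracy: float
    oob_sensitivity: float
    oob_specificity: float
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.oob_accuracy, self.oob_sensitivity, self.oob_specificity):
            if not (0.0 <= v <= 1.0):
                raise ValueError("OOB metrics must lie in [0, 1]")


def select_final_combination(
    df: pd.DataFrame,
    labels: pd.Series,
    shortlist: Sequence[tuple[str, ...]],
    spec: SubsetSpec,
    fences: OutlierFences,
    n_trees: int = 1200,
    reps: int = 5,
    seed: int = 0,
) -> SubsetModel:
    """Pick the shortlisted combination with the highest mean OOB accuracy
    over ``reps`` repetitions (ties: higher sensitivity + specificity,
    then lexicographic feature ids) and train the subset's final forest.

    The stored OOB sensitivity/specificity — the subset's voting
    weights — are the repetition means.
    """
    if not shortlist:
        raise ValueError("empty shortlist")
    results = []
    for combo in shortlist:
        X, y = _combination_rows(df, labels, combo)
        ms = [train_random_forest_oob(X, y, n_trees, seed + r)[1] for r in range(reps)]
        acc = float(np.mean([m.accuracy for m in ms]))
        sens = float(np.mean([m.sensitivity for m in ms]))
        spec_ = float(np.mean([m.specificity for m in ms]))
        results.append((acc, sens + spec_, tuple(combo), sens, spec_))
    results.sort(key=lambda t: (-t[0], -t[1], t[2]))
    acc, _, combo, sens, spec_ = results[0]
    X, y = _combination_rows(df, labels, combo)
    forest, _ = train_random_forest_oob(X, y, n_trees, seed)
    return SubsetModel(
        spec=spec, combination=combo, fences=fences, forest=forest,
        oob_accuracy=acc, oob_sensitivity=sens, oob_specificity=spec_, seed=seed,
    )
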