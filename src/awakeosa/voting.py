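"""Weighted vote fusion of the per-subset classifiers.

Every subset model casts a raw vote of +1 (OSA) or -1 (non-OSA) for
every subject; the +1 vote is weighted by the model's out-of-bag
sensitivity and the -1 vote by its specificity. The final decision d is
the mean of the non-abstaining weighted votes: d > 0 calls OSA, d < 0
non-OSA, and |d| > 0.7 is flagged high-confidence. A model abstains for
a subject whose combination features are missing after fencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable
from .training import SubsetModel

__all__ = [
    "VotingEnsemble",
    "Decision",
    "ClassificationMetrics",
    "subset_vote",
    "weighted_decision",
    "classify_cohort",
    "evaluate",
    "subset_ablation",
    "combination_ahi_correlation",
]

HIGH_CONFIDENCE = 0.7
ABSTAIN = None


@dataclass
class VotingEnsemble:
    """A set of subset models plus the abstention policy.

    ``abstention='skip'`` (default) drops abstaining models from the
    vote average; ``'zero'`` counts them as zero-weight votes.
    """

    models: list[SubsetModel]
    abstention: str = "skip"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        if self.abstention not in ("skip", "zero"):
            raise ValueError("abstention must be 'skip' or 'zero'")


def subset_vote(model: SubsetModel, features: Mapping[str, float]) -> float | None:
    """One model's weighted vote for one subject.

    Missing combination features (after the model's fences) abstain.
    A raw OSA vote contributes +1 x OOB sensitivity, a non-OSA vote
    -1 x OOB specificity.
    """
    row = {}
    for fid in model.combination:
        v = features.get(fid, float("nan"))
        lo, hi = model.fences.bounds.get(fid, (-np.inf, np.inf))
        if v is None or not np.isfinite(v) or not (lo <= v <= hi):
            return ABSTAIN
        row[fid] = v
    x = np.array([[row[fid] for fid in model.combination]])
    osa = bool(model.forest.predict(x)[0])
    return model.oob_sensitivity if osa else -model.oob_specificity


@dataclass
class Decision:
    """Final fused decision for one subject."""

    d: float
    call: str  # 'osa' | 'non_osa' | 'unclassifiable'
    high_confidence: bool
    tie: bool = False
    votes: list[float | None] = field(default_factory=list)


def weighted_decision(votes: Sequence[float | None], abstention: str = "skip") -> Decision:
    """Average the weighted votes into the final decision d in [-1, 1].

    d > 0 calls OSA, d < 0 non-OSA; d == 0 exactly is called non-OSA
    with a tie flag. All-abstain subjects are unclassifiable.
    """
    votes = list(votes)
    if votes and all(v is None for v in votes):
        return Decision(float("nan"), "unclassifiable", False, votes=votes)
    if abstention == "zero":
        effective = [0.0 if v is None else v for v in votes]
    else:
        effective = [v for v in votes if v is not None]
    if not effective:
        return Decision(float("nan"), "unclassifiable", False, votes=votes)
    d = float(np.mean(effective))
    if not -1.0 <= d <= 1.0:
        raise AssertionError("decision outside [-1, 1]")
    call = "osa" if d > 0 else "non_osa"
    return Decision(d, call, abs(d) > HIGH_CONFIDENCE, tie=(d == 0.0), votes=votes)


def classify_cohort(
    ensemble: VotingEnsemble,
    table: FeatureTable,
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Decision report for each subject of a scaled feature table.

    Every model votes on every subject (subset membership does not gate
    voting). Columns: one weighted vote per model (NaN = abstain), the
    final decision ``d``, the class ``call`` and ``high_confidence``.
    """
    if table.provenance != "scaled":
        raise ValueError("classify_cohort requires a scaled feature table")
    subjects = list(subjects) if subjects is not None else table.subject_ids
    rows = {}
    for sid in subjects:
        features = table.data.loc[sid].to_dict()
        votes = [subset_vote(m, features) for m in ensemble.models]
        decision = weighted_decision(votes, ensemble.abstention)
        rows[sid] = {
            **{f"vote_{m.spec.name}": (np.nan if v is None else v)
               for m, v in zip(ensemble.models, votes)},
            "d": decision.d,
            "call": decision.call,
            "high_confidence": decision.high_confidence,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    n: int
    n_unclassifiable: int = 0


def evaluate(decisions: pd.DataFrame, labels: Mapping[str, bool] | pd.Series) -> ClassificationMetrics:
    """Accuracy / OSA recall (sensitivity) / non-OSA recall (specificity).

    Unclassifiable subjects count as errors for every metric.
    """
    if decisions.empty:
        raise ValueError("empty decision report")
    labels = pd.Series(labels).reindex(decisions.index).astype(bool)
    pred_osa = decisions["call"] == "osa"
    classified = decisions["call"] != "unclassifiable"
    correct = classified & (pred_osa == labels)
    sens = float(correct[labels].mean()) if labels.any() else float("nan")
    spec = float(correct[~labels].mean()) if (~labels).any() else float("nan")
    return ClassificationMetrics(
        accuracy=float(correct.mean()),
        sensitivity=sens,
        specificity=spec,
        n=len(decisions),
        n_unclassifiable=int((~classified).sum()),
    )


def subset_ablation(
    ensemble: VotingEnsemble,
    table: FeatureTable,
    labels: Mapping[str, bool] | pd.Series,
) -> pd.DataFrame:
    """Leave-one-model-out metric deltas (full-ensemble minus ablated).

    Positive deltas mean the removed subset was helping.
    """
    if len(ensemble.models) < 2:
        raise ValueError("ablation needs at least two models")
    base = evaluate(classify_cohort(ensemble, table), labels)
    rows = {}
    for i, model in enumerate(ensemble.models):
        rest = [m for j, m in enumerate(ensemble.models) if j != i]
        m = evaluate(
            classify_cohort(VotingEnsemble(rest, ensemble.abstention), table), labels
        )
        rows[model.spec.name] = {
            "delta_accuracy": base.accuracy - m.accuracy,
            "delta_sensitivity": base.sensitivity - m.sensitivity,
            "delta_specificity": base.specificity - m.specificity,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def combination_ahi_correlation(
    df: pd.DataFrame,
    combination: Sequence[str],
    ahi: Mapping[str, float] | pd.Series,
    scale: str = "linear",
) -> float:
    """Pearson correlation between (log-)AHI and its least-squares fit on
    a feature combination.

    Under ``scale='log'``, subjects with AHI == 0 are dropped with a
    warning. Needs at least 10 usable subjects.
    """
    ahi = pd.Series(ahi).reindex(df.index).astype(float)
    X = df[list(combination)]
    ok = ~(X.isna().any(axis=1) | ahi.isna())
    if scale == "log":
        zero = ahi <= 0
        if (zero & ok).any():
            import warnings

            warnings.warn(f"dropping {int((zero & ok).sum())} subject(s) with AHI <= 0")
        ok &= ~zero
        y = np.log(ahi[ok].to_numpy())
    elif scale == "linear":
        y = ahi[ok].to_numpy()
    else:
        raise ValueError("scale must be 'linear' or 'log'")
    if ok.sum() < 10:
        raise ValueError("need at least 10 subjects for the regression")
    A = np.column_stack([np.ones(ok.sum()), X[ok].to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    if np.std(fitted) == 0:
        return 0.0
    return float(np.corrcoef(fitted, y)[0, 1])
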