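"""Feature reduction: significance, robustness scoring, redundancy
removal and effect-size screening.

The ~250-feature pool is cut to a subset-specific shortlist in stages:

1. significance — Welch's unpaired t-test between severity groups;
   features with p > 0.05 are dropped.
2. robustness — over 20 rounds, each severity group is partitioned into
   random 15-member subgroups covering every individual; for every
   non-OSA x OSA subgroup pairing a feature scores a point when the
   t-test is significant *and* both subgroups pass the Lilliefors
   normality check. Features scoring <= 0.6 x the best observed score
   are dropped.
3. redundancy — features correlated at |r| >= 0.9 are clustered
   (transitively); each cluster keeps the single feature with the best
   single-feature linear-SVM training performance.
4. effect size — Glass's delta (group mean difference over the non-OSA
   SD) is reported for every kept feature and a configurable magnitude
   filter applied.

Later stages never resurrect a feature rejected earlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from ._stats import lilliefors_normal

__all__ = [
    "ReductionConfig",
    "ReductionReport",
    "significance_filter",
    "robustness_scores",
    "redundancy_filter",
    "glass_delta",
    "run_reduction",
]


@dataclass
class ReductionConfig:
    alpha: float = 0.05
    group_size: int = 15
    rounds: int = 20
    corr_threshold: float = 0.9
    delta_min: float = 0.8
    robustness_fraction: float = 0.6
    equal_var: bool = False  # Welch by default
    max_features: int | None = None


@dataclass
class ReductionReport:
    """Per-feature audit trail of the reduction pipeline."""

    table: pd.DataFrame  # p_value, robustness, max_score, glass_delta, stage, kept
    max_robustness: int = 0
    clusters: list[list[str]] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def _group_arrays(df: pd.DataFrame, labels: pd.Series):
    labels = pd.Series(labels).reindex(df.index)
    osa = df.loc[labels.astype(bool)].to_numpy(dtype=float)
    non = df.loc[~labels.astype(bool)].to_numpy(dtype=float)
    return non, osa


def significance_filter(
    df: pd.DataFrame, labels: pd.Series, alpha: float = 0.05, equal_var: bool = False
) -> tuple[list[str], pd.Series]:
    """Unpaired t-test per feature; survivors have p <= alpha.

    Features that are constant or all-missing in either group get p =
    NaN and are excluded.
    """
    non, osa = _group_arrays(df, labels)
    if min(len(non), len(osa)) < 2:
        raise ValueError("need at least 2 subjects per severity group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(non, osa, axis=0, equal_var=equal_var, nan_policy="omit")
    p = pd.Series(np.asarray(res.pvalue, dtype=float), index=df.columns, name="p_value")
    survivors = list(p.index[(p <= alpha).fillna(False)])
    return survivors, p


def _coverage_subgroups(n: int, size: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random disjoint ``size``-member subgroups covering all n individuals.

    Individuals are shuffled and chunked; when n is not a multiple of
    ``size`` the leftover members form the core of a final subgroup
    topped up by resampling already-assigned individuals, so every
    individual is selected at least once per round.
    """
    order = rng.permutation(n)
    full, leftover = divmod(n, size)
    groups = [order[i * size : (i + 1) * size] for i in range(full)]
    if leftover:
        extra = rng.choice(order[: full * size], size=size - leftover, replace=False)
        groups.append(np.concatenate([order[full * size :], extra]))
    return groups


def robustness_scores(
    df: pd.DataFrame,
    labels: pd.Series,
    group_size: int = 15,
    rounds: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    equal_var: bool = False,
) -> tuple[pd.Series, int]:
    """Robustness score per feature plus the maximum attainable score.

    Per round, each severity group is split into covering random
    subgroups of ``group_size``; every non-OSA x OSA subgroup pairing
    contributes one potential point per feature, awarded when the
    t-test p <= alpha and the Lilliefors normality check passes in both
    subgroups (features with missing values in a pairing cannot score it).
    """
    non, osa = _group_arrays(df, labels)
    if len(non) < group_size or len(osa) < group_size:
        raise ValueError(f"both severity groups must have >= {group_size} members")
    rng = np.random.default_rng(seed)
    scores = np.zeros(df.shape[1], dtype=int)
    max_possible = 0
    for _ in range(rounds):
        subs_non = _coverage_subgroups(len(non), group_size, rng)
        subs_osa = _coverage_subgroups(len(osa), group_size, rng)
        normal_non = [_normality_mask(non[g]) for g in subs_non]
        normal_osa = [_normality_mask(osa[g]) for g in subs_osa]
        for gi, g_non in enumerate(subs_non):
            for gj, g_osa in enumerate(subs_osa):
                max_possible += 1
                with np.errstate(invalid="ignore", divide="ignore"):
                    res = stats.ttest_ind(
                        non[g_non], osa[g_osa], axis=0,
                        equal_var=equal_var, nan_policy="omit",
                    )
                p = np.asarray(res.pvalue, dtype=float)
                ok = (p <= alpha) & normal_non[gi] & normal_osa[gj]
                scores += np.where(np.isnan(p), False, ok)
    return pd.Series(scores, index=df.columns, name="robustness"), max_possible


def _normality_mask(x: np.ndarray) -> np.ndarray:
    """Columnwise Lilliefors pass/fail, False for degenerate columns."""
    out = np.zeros(x.shape[1], dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(x, axis=0)
    valid = ~np.any(np.isnan(x), axis=0) & (sd > 0)
    if valid.any():
        out[valid] = lilliefors_normal(x[:, valid])
    return out


def glass_delta(values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> float:
    """Glass's delta: (mean_OSA - mean_nonOSA) / SD_nonOSA."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    control = v[~y]
    sd = np.nanstd(control, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("control (non-OSA) group has zero standard deviation")
    return float((np.nanmean(v[y]) - np.nanmean(control)) / sd)


def _single_feature_svm(values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Training (accuracy, sensitivity + specificity) of a one-feature linear SVM."""
    ok = ~np.isnan(values)
    x, yy = values[ok, None], y[ok]
    if len(np.unique(yy)) < 2:
        return 0.0, 0.0
    clf = SVC(kernel="linear").fit(x, yy)
    pred = clf.predict(x)
    acc = float(np.mean(pred == yy))
    sens = float(np.mean(pred[yy] == True))  # noqa: E712
    spec = float(np.mean(pred[~yy] == False))  # noqa: E712
    return acc, sens + spec


def redundancy_filter(
    df: pd.DataFrame,
    labels: pd.Series,
    survivors: Sequence[str],
    corr_threshold: float = 0.9,
) -> tuple[list[str], list[list[str]]]:
    """Collapse clusters of mutually correlated features (|r| >= threshold,
    transitive closure), keeping per cluster the feature with the best
    single-feature SVM training accuracy (sensitivity + specificity,
    then feature id, as tie-breaks)."""
    survivors = list(survivors)
    if not survivors:
        raise ValueError("no surviving features to filter")
    sub = df[survivors]
    corr = sub.corr().abs().to_numpy()
    n = len(survivors)
    # union-find over |corr| >= threshold edges
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if corr[i, j] >= corr_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    y = pd.Series(labels).reindex(df.index).astype(bool).to_numpy()
    kept, cluster_ids = [], []
    for members in clusters.values():
        names = [survivors[i] for i in members]
        cluster_ids.append(names)
        if len(names) == 1:
            kept.append(names[0])
            continue
        scored = [
            (*_single_feature_svm(sub[name].to_numpy(dtype=float), y), name)
            for name in names
        ]
        # max accuracy, then max sens+spec, then lexicographic id
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        kept.append(scored[0][2])
    kept.sort(key=survivors.index)
    return kept, cluster_ids


def run_reduction(
    df: pd.DataFrame,
    labels: pd.Series,
    config: ReductionConfig | None = None,
    seed: int = 0,
) -> tuple[list[str], ReductionReport]:
    """Full reduction pipeline; returns kept feature ids and the report."""
    config = config or ReductionConfig()
    labels = pd.Series(labels).reindex(df.index).astype(bool)
    report = pd.DataFrame(index=df.columns)
    report["stage"] = "kept"
    report["kept"] = False

    sig, p = significance_filter(df, labels, config.alpha, config.equal_var)
    report["p_value"] = p
    report.loc[~report.index.isin(sig), "stage"] = "significance"
    if not sig:
        warnings.warn("no feature survived the significance stage")
        return [], ReductionReport(report)

    max_rob = 0
    report["robustness"] = 0
    n_non = int((~labels).sum())
    n_osa = int(labels.sum())
    group_size = min(config.group_size, n_non, n_osa)
    if group_size < config.group_size:
        warnings.warn(
            f"severity groups ({n_non}, {n_osa}) smaller than the subgroup "
            f"size {config.group_size}; using subgroups of {group_size}"
        )
    if config.rounds > 0 and group_size < 5:
        warnings.warn("severity groups too small for robustness scoring; stage skipped")
        robust = list(sig)
    elif config.rounds > 0:
        scores, max_possible = robustness_scores(
            df[sig], labels, group_size, config.rounds,
            config.alpha, seed, config.equal_var,
        )
        report.loc[sig, "robustness"] = scores
        max_rob = int(scores.max())
        threshold = config.robustness_fraction * max_rob
        robust = [f for f in sig if scores[f] > threshold]
    else:
        robust = []
    dropped = set(sig) - set(robust)
    report.loc[report.index.isin(dropped), "stage"] = "robustness"
    if not robust:
        warnings.warn("no feature survived the robustness stage")
        return [], ReductionReport(report, max_rob)

    kept, clusters = redundancy_filter(df, labels, robust, config.corr_threshold)
    report.loc[report.index.isin(set(robust) - set(kept)), "stage"] = "redundancy"

    report["glass_delta"] = np.nan
    final = []
    for f in kept:
        try:
            delta = glass_delta(df[f], labels)
        except ValueError:
            delta = float("nan")
        report.loc[f, "glass_delta"] = delta
        if config.delta_min is None or abs(delta) > config.delta_min:
            final.append(f)
        else:
            report.loc[f, "stage"] = "effect_size"

    if config.max_features is not None and len(final) > config.max_features:
        ranked = sorted(
            final,
            key=lambda f: (-report.loc[f, "robustness"], report.loc[f, "p_value"], f),
        )
        for f in ranked[config.max_features :]:
            report.loc[f, "stage"] = "cap"
        final = [f for f in final if f in set(ranked[: config.max_features])]

    report.loc[report.index.isin(final), "kept"] = True
    return final, ReductionReport(report, max_rob, clusters)
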