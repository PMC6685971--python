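"""End-to-end screening pipeline: audio -> features -> subset models ->
weighted vote.

``train_screener`` reproduces the training protocol: stratified
train/blind-test split, [0, 1] feature scaling fit on training rows,
per-subset feature reduction on the feature-extraction pool (AHI <= 10
or >= 20), outlier fencing, 3-/4-feature combination search with
repeated random-forest OOB validation, and finally the
sensitivity/specificity-weighted voting ensemble.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from .catalog import EXCLUSIVE_GROUPS, full_catalog
from .cohort import (
    CohortSplit,
    PHASES,
    SubjectRecord,
    load_audio,
    screen_quality,
    segment_phases,
    split_cohort,
)
from .features import (
    FeatureTable,
    SubjectSignalSummary,
    apply_unit_scaling,
    build_feature_matrix,
    scale_unit_interval,
)
from .fractal import fractal_features
from .reduction import ReductionConfig, ReductionReport, run_reduction
from .spectral import average_bispectra, average_spectra, indirect_bispectrum, welch_psd
from .training import (
    DEFAULT_SUBSETS,
    OutlierFences,
    SubsetModel,
    SubsetSpec,
    apply_fences,
    build_subsets,
    enumerate_combinations,
    fit_fences,
    score_combinations,
    select_final_combination,
)
from .voting import ClassificationMetrics, VotingEnsemble, classify_cohort, evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "Screener",
    "StudyResult",
    "summarize_subject",
    "extract_features",
    "train_screener",
    "screen_table",
    "run_synthetic_study",
    "save_screener",
    "load_screener",
]

#: Feature id under which neck circumference (cm) joins the feature table.
NC_FEATURE = "anthro_nc"


@dataclass
class PipelineConfig:
    """Tunable pipeline settings (defaults follow the published protocol)."""

    threshold: float = 15.0
    fe_bounds: tuple[float, float] = (10.0, 20.0)
    train_fraction: float = 113.0 / 199.0
    snr_threshold_db: float = 10.0
    welch_nperseg: int = 1024
    bis_max_lag: int = 255
    bis_nfft: int = 512
    bis_max_cycles: int | None = None
    bis_excerpt_s: float | None = None
    single_precision: bool = False
    n_trees: int = 1200
    scoring_reps: int = 3
    final_reps: int = 5
    min_metric: float = 0.7
    selection_window: float = 0.02
    shortlist_cap: int | None = None
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    subsets: tuple[SubsetSpec, ...] = DEFAULT_SUBSETS

    @classmethod
    def desk(cls) -> "PipelineConfig":
        """Desk-scale profile: 300 trees, candidate shortlist capped at 6
        features per subset, single-precision bispectra. Same protocol,
        sized for a single-CPU run."""
        return cls(
            n_trees=300,
            single_precision=True,
            bis_max_cycles=2,
            bis_excerpt_s=0.6,
            bis_max_lag=127,
            shortlist_cap=6,
            reduction=ReductionConfig(max_features=4),
        )


def summarize_subject(
    subject_id: str,
    signals: Mapping[str, tuple],
    config: PipelineConfig | None = None,
) -> SubjectSignalSummary:
    """Segment, quality-screen and cycle-average one subject's maneuvers.

    ``signals[maneuver]`` is ``(samples, sampling_rate)`` (extra tuple
    entries are ignored). Maneuver/phase combinations with fewer than
    two clean cycles are left out of the summary (features become NaN).
    """
    config = config or PipelineConfig()
    summary = SubjectSignalSummary(subject_id)
    dtype = np.float32 if config.single_precision else np.float64
    for maneuver, payload in signals.items():
        x, fs = payload[0], payload[1]
        phases, silent = segment_phases(x, fs, maneuver=maneuver)
        phases, _ = screen_quality(phases, silent, config.snr_threshold_db)
        for phase_name in PHASES:
            cycles = [p for p in phases
                      if p.phase == phase_name and p.quality == "clean"]
            if len(cycles) < 2:
                continue
            key = (maneuver, phase_name)
            summary.spectra[key] = average_spectra(
                [welch_psd(c, nperseg=config.welch_nperseg) for c in cycles]
            )
            bis_cycles = cycles[: config.bis_max_cycles]
            excerpt = (
                None if config.bis_excerpt_s is None
                else int(config.bis_excerpt_s * fs)
            )
            summary.bispectra[key] = average_bispectra([
                indirect_bispectrum(
                    c.samples[:excerpt], c.sampling_rate,
                    max_lag=config.bis_max_lag, nfft=config.bis_nfft, dtype=dtype,
                )
                for c in bis_cycles
            ])
            frac = [fractal_features(c.samples) for c in cycles]
            summary.fractal[key] = {
                k: float(np.nanmean([f[k] for f in frac])) for k in frac[0]
            }
    return summary


def extract_features(
    records: Sequence[SubjectRecord],
    signals: Mapping[str, Mapping[str, tuple]],
    config: PipelineConfig | None = None,
    definitions=None,
) -> FeatureTable:
    """Raw feature table for a cohort (catalog features + neck
    circumference as ``anthro_nc``)."""
    config = config or PipelineConfig()
    definitions = definitions if definitions is not None else full_catalog()
    summaries = {}
    for record in records:
        summaries[record.subject_id] = summarize_subject(
            record.subject_id, signals[record.subject_id], config
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_feature_matrix(summaries, definitions)
    table.data[NC_FEATURE] = pd.Series(
        {r.subject_id: r.neck_circumference for r in records}
    )
    return table


@dataclass
class SubsetReport:
    """Training audit for one subset."""

    spec: SubsetSpec
    n_train: int
    n_feature_extraction: int
    candidates: list[str]
    reduction: ReductionReport | None
    n_combinations: int
    shortlist: list[tuple[str, ...]]


@dataclass
class Screener:
    """A trained subgroup-ensemble wakefulness screener."""

    ensemble: VotingEnsemble
    scaling: dict[str, tuple[float, float]]
    split: CohortSplit | None
    reports: list[SubsetReport]
    config: PipelineConfig

    def screen(self, table_raw: FeatureTable) -> pd.DataFrame:
        """Decision report for a raw feature table of new subjects."""
        scaled = apply_unit_scaling(table_raw, self.scaling)
        return classify_cohort(self.ensemble, scaled)


def _labels(records: Sequence[SubjectRecord], threshold: float) -> pd.Series:
    return pd.Series({r.subject_id: r.is_osa(threshold) for r in records})


def train_screener(
    records: Sequence[SubjectRecord],
    table_raw: FeatureTable,
    config: PipelineConfig | None = None,
    seed: int = 0,
    split: CohortSplit | None = None,
) -> Screener:
    """Train the full per-subset ensemble from a raw feature table."""
    config = config or PipelineConfig()
    seeds = np.random.SeedSequence(seed).generate_state(2 + len(config.subsets))
    if split is None:
        split = split_cohort(
            records, config.threshold, config.fe_bounds,
            seed=int(seeds[0] % (2**31 - 1)), train_fraction=config.train_fraction,
        )
    train_ids = [r.subject_id for r in split.train]
    fe_ids = {r.subject_id for r in split.feature_extraction}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled = scale_unit_interval(table_raw, train_ids)
    labels = _labels(split.train, config.threshold)
    memberships = build_subsets(split.train, config.subsets, threshold=config.threshold)

    models: list[SubsetModel] = []
    reports: list[SubsetReport] = []
    for k, spec in enumerate(config.subsets):
        subset_seed = int(seeds[2 + k] % (2**31 - 1))
        member_ids = [sid for sid in memberships[spec.name] if sid in scaled.data.index]
        sub_df = scaled.data.loc[member_ids]
        sub_labels = labels.loc[member_ids]
        fe_mask = [sid in fe_ids for sid in member_ids]
        fe_df = sub_df.loc[fe_mask]
        fe_labels = sub_labels.loc[fe_mask]

        sound_df = fe_df.drop(columns=[NC_FEATURE], errors="ignore")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidates, reduction_report = run_reduction(
                sound_df, fe_labels, config.reduction, seed=subset_seed
            )
        if len(candidates) < 3:
            warnings.warn(f"subset {spec.name}: fewer than 3 candidate features; skipped")
            reports.append(SubsetReport(spec, len(member_ids), len(fe_df),
                                        candidates, reduction_report, 0, []))
            continue

        pool = list(candidates) + ([NC_FEATURE] if spec.include_nc else [])
        fences = fit_fences(sub_df[pool], sub_labels)
        fenced = apply_fences(sub_df[pool], fences)
        combos = enumerate_combinations(
            candidates,
            extra_pool=[NC_FEATURE] if spec.include_nc else [],
            exclusive_groups=EXCLUSIVE_GROUPS,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shortlist, scores = score_combinations(
                fenced, sub_labels, combos, config.n_trees, config.scoring_reps,
                seed=subset_seed, min_value=config.min_metric,
                window=config.selection_window,
            )
        if not shortlist:
            # no combination cleared the metric floor; fall back to the
            # best-scoring one so the subset still casts (weak) votes
            best = max(scores, key=lambda cs: cs.mean_accuracy)
            shortlist = [best.combination]
        if config.shortlist_cap is not None and len(shortlist) > config.shortlist_cap:
            by_acc = {cs.combination: cs.mean_accuracy for cs in scores}
            shortlist = sorted(shortlist, key=lambda c: -by_acc[c])[: config.shortlist_cap]
        model = select_final_combination(
            fenced, sub_labels, shortlist, spec, fences,
            n_trees=config.n_trees, reps=config.final_reps, seed=subset_seed,
        )
        models.append(model)
        reports.append(SubsetReport(
            spec, len(member_ids), len(fe_df), candidates, reduction_report,
            len(combos), shortlist,
        ))
        logger.info(
            "subset %s: %d candidates, %d combinations, selected %s "
            "(OOB acc %.3f, sens %.3f, spec %.3f)",
            spec.name, len(candidates), len(combos), model.combination,
            model.oob_accuracy, model.oob_sensitivity, model.oob_specificity,
        )

    if not models:
        raise RuntimeError("no subset produced a usable model")
    ensemble = VotingEnsemble(models)
    return Screener(ensemble, scaled.scaling, split, reports, config)


def screen_table(screener: Screener, table_raw: FeatureTable) -> pd.DataFrame:
    """Convenience wrapper around :meth:`Screener.screen`."""
    return screener.screen(table_raw)


@dataclass
class StudyResult:
    """Outcome of a full synthetic-cohort training + blind-test run."""

    screener: Screener
    validation: ClassificationMetrics
    blind_test: ClassificationMetrics
    decisions_validation: pd.DataFrame
    decisions_test: pd.DataFrame
    table: FeatureTable


def run_synthetic_study(
    spec=None,
    config: PipelineConfig | None = None,
    seed: int = 7,
) -> StudyResult:
    """Generate a synthetic cohort, train, and blind-test the screener."""
    from .synthetic import SyntheticSpec, simulate_cohort

    spec = spec or SyntheticSpec()
    config = config or PipelineConfig.desk()
    records, signals = simulate_cohort(spec, seed)
    table = extract_features(records, signals, config)
    screener = train_screener(records, table, config, seed=seed)
    scaled = apply_unit_scaling(table, screener.scaling)
    labels = _labels(records, config.threshold)

    train_ids = [r.subject_id for r in screener.split.train]
    test_ids = [r.subject_id for r in screener.split.test]
    dec_train = classify_cohort(screener.ensemble, scaled, train_ids)
    dec_test = classify_cohort(screener.ensemble, scaled, test_ids)
    return StudyResult(
        screener=screener,
        validation=evaluate(dec_train, labels),
        blind_test=evaluate(dec_test, labels),
        decisions_validation=dec_train,
        decisions_test=dec_test,
        table=table,
    )


def _config_to_dict(config: PipelineConfig) -> dict:
    d = {k: v for k, v in vars(config).items() if k not in ("reduction", "subsets")}
    d["reduction"] = vars(config.reduction)
    d["subsets"] = [vars(s) for s in config.subsets]
    return d


def save_screener(screener: Screener, out_dir: str | Path) -> Path:
    """Persist a screener as JSON metadata plus a joblib forest bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "scaling": screener.scaling,
        "config": _config_to_dict(screener.config),
        "models": [
            {
                "subset": vars(m.spec),
                "combination": list(m.combination),
                "fences": {k: list(v) for k, v in m.fences.bounds.items()},
                "oob_accuracy": m.oob_accuracy,
                "oob_sensitivity": m.oob_sensitivity,
                "oob_specificity": m.oob_specificity,
                "seed": m.seed,
            }
            for m in screener.ensemble.models
        ],
    }
    (out_dir / "screener.json").write_text(json.dumps(meta, indent=2))
    joblib.dump([m.forest for m in screener.ensemble.models], out_dir / "forests.joblib")
    return out_dir


def load_screener(in_dir: str | Path) -> Screener:
    """Load a screener persisted by :func:`save_screener`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "screener.json").read_text())
    forests = joblib.load(in_dir / "forests.joblib")
    models = []
    for m, forest in zip(meta["models"], forests):
        models.append(SubsetModel(
            spec=SubsetSpec(**m["subset"]),
            combination=tuple(m["combination"]),
            fences=OutlierFences({k: tuple(v) for k, v in m["fences"].items()}),
            forest=forest,
            oob_accuracy=m["oob_accuracy"],
            oob_sensitivity=m["oob_sensitivity"],
            oob_specificity=m["oob_specificity"],
            seed=m["seed"],
        ))
    cfg = meta["config"]
    config = PipelineConfig(
        **{k: (tuple(v) if isinstance(v, list) else v)
           for k, v in cfg.items() if k not in ("reduction", "subsets")},
        reduction=ReductionConfig(**cfg["reduction"]),
        subsets=tuple(SubsetSpec(**s) for s in cfg["subsets"]),
    )
    scaling = {k: tuple(v) for k, v in meta["scaling"].items()}
    ensemble = VotingEnsemble(models)
    return Screener(ensemble, scaling, split=None, reports=[], config=config)


def load_cohort_audio(records: Sequence[SubjectRecord]) -> dict[str, dict[str, tuple]]:
    """Read every referenced WAV into the in-memory signals mapping."""
    signals: dict[str, dict[str, tuple]] = {}
    for record in records:
        per = {}
        for maneuver, ref in record.audio_refs.items():
            x, fs = load_audio(ref)
            per[maneuver] = (x, fs)
        signals[record.subject_id] = per
    return signals
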