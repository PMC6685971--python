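"""Cohort input handling: manifests, audio, breath-phase segmentation,
quality screening and train/test splitting.

A cohort is described by a CSV manifest with one row per participant::

    subject_id,ahi,age,sex,bmi,nc,mps,mouth_wav,nose_wav[,split]

Each WAV holds one breathing maneuver: five deep breath cycles
(inspiration/expiration) followed by a breath-hold "silent period" used
as the background-noise reference. Recordings are segmented into
alternating inspiratory/expiratory phases with a short-time-energy
envelope; the study protocol marks the first phase as inspiration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

Maneuver = Literal["mouth", "nose"]
Phase = Literal["inspiration", "expiration"]

MANEUVERS: tuple[Maneuver, ...] = ("mouth", "nose")
PHASES: tuple[Phase, ...] = ("inspiration", "expiration")

#: AHI (events/hour) at or above which a subject is labeled OSA.
DEFAULT_AHI_THRESHOLD = 15.0

_MANIFEST_COLUMNS = ("subject_id", "ahi", "age", "sex", "bmi", "nc", "mps")


class ManifestSchemaError(ValueError):
    """Manifest is structurally unusable (missing columns, empty, duplicates)."""


class ManifestValidationError(ValueError):
    """A manifest row holds an out-of-domain value."""


@dataclass
class SubjectRecord:
    """Anthropometrics, AHI and audio references for one participant."""

    subject_id: str
    ahi: float
    age: float
    sex: str
    bmi: float
    neck_circumference: float
    mallampati: int
    audio_refs: dict[str, str] = field(default_factory=dict)
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ManifestValidationError(f"{self.subject_id}: ahi must be >= 0")
        if self.age <= 0:
            raise ManifestValidationError(f"{self.subject_id}: age must be > 0")
        if self.bmi <= 0:
            raise ManifestValidationError(f"{self.subject_id}: bmi must be > 0")
        if self.neck_circumference <= 0:
            raise ManifestValidationError(
                f"{self.subject_id}: neck circumference must be > 0"
            )
        if self.mallampati not in (1, 2, 3, 4):
            raise ManifestValidationError(
                f"{self.subject_id}: mallampati must be in 1..4, got {self.mallampati}"
            )
        sex = str(self.sex).lower()
        if sex not in ("male", "female"):
            raise ManifestValidationError(
                f"{self.subject_id}: sex must be male/female, got {self.sex!r}"
            )
        self.sex = sex
        if self.split not in ("train", "test", "unassigned"):
            raise ManifestValidationError(
                f"{self.subject_id}: split must be train/test/unassigned"
            )

    def severity(self, threshold: float = DEFAULT_AHI_THRESHOLD) -> str:
        """Severity group label: ``osa`` iff AHI >= threshold."""
        return "osa" if self.ahi >= threshold else "non_osa"

    def is_osa(self, threshold: float = DEFAULT_AHI_THRESHOLD) -> bool:
        return self.ahi >= threshold


@dataclass
class BreathPhaseSignal:
    """One inspiratory or expiratory sound segment."""

    samples: np.ndarray
    sampling_rate: float
    maneuver: Maneuver
    phase: Phase
    cycle_index: int
    quality: str = "clean"
    rejection_reason: str | None = None
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate < 4800:
            raise ValueError(
                "sampling_rate must be >= 4800 Hz to resolve the 2100-2400 Hz band"
            )
        if self.samples.size < 0.25 * self.sampling_rate:
            raise ValueError("breath phase shorter than 0.25 s")
        if self.cycle_index < 1:
            raise ValueError("cycle_index starts at 1")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


def load_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read and validate a cohort manifest CSV.

    Raises :class:`ManifestSchemaError` for structural problems and
    :class:`ManifestValidationError` (naming the row) for out-of-domain
    values. Severity group counts are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ManifestSchemaError(f"{path}: empty manifest") from exc
    if df.empty:
        raise ManifestSchemaError(f"{path}: manifest has no rows")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"{path}: missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestSchemaError(f"{path}: duplicate subject_id {dupes}")

    records: list[SubjectRecord] = []
    for idx, row in df.iterrows():
        refs = {}
        for maneuver in MANEUVERS:
            col = f"{maneuver}_wav"
            if col in df.columns and isinstance(row[col], str) and row[col]:
                refs[maneuver] = row[col]
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    ahi=float(row["ahi"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    bmi=float(row["bmi"]),
                    neck_circumference=float(row["nc"]),
                    mallampati=int(row["mps"]),
                    audio_refs=refs,
                    split=str(row["split"]) if "split" in df.columns else "unassigned",
                )
            )
        except ManifestValidationError as exc:
            raise ManifestValidationError(f"{path} row {idx}: {exc}") from exc
    n_osa = sum(r.is_osa() for r in records)
    logger.info(
        "manifest %s: %d subjects (%d non-OSA, %d OSA at AHI >= 15)",
        path.name, len(records), len(records) - n_osa, n_osa,
    )
    return records


def load_audio(ref: str | Path, channel: int | None = None) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file and return (samples in [-1, 1], sampling rate).

    Multichannel files require an explicit ``channel`` selector.
    """
    try:
        fs, data = wavfile.read(str(ref))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises assorted types on corrupt files
        raise IOError(f"unreadable audio file {ref}: {exc}") from exc
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{ref}: multichannel audio; pass channel=<index> to select one"
            )
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return samples, float(fs)


@dataclass
class SegmentationParams:
    """Short-time-energy segmentation settings."""

    frame_s: float = 0.05
    hop_s: float = 0.01
    min_phase_s: float = 0.25
    min_gap_s: float = 0.05


def _frame_energy_db(x: np.ndarray, fs: float, params: SegmentationParams):
    frame = max(int(round(params.frame_s * fs)), 1)
    hop = max(int(round(params.hop_s * fs)), 1)
    n_frames = max(1 + (x.size - frame) // hop, 0)
    if n_frames == 0:
        return np.empty(0), np.empty(0, dtype=int), frame
    idx = np.arange(n_frames) * hop
    windows = np.lib.stride_tricks.sliding_window_view(x, frame)[::hop][:n_frames]
    energy = np.mean(windows**2, axis=1)
    return 10.0 * np.log10(energy + 1e-30), idx, frame


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as half-open (start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def segment_phases(
    signal: np.ndarray,
    sampling_rate: float,
    params: SegmentationParams | None = None,
    override: pd.DataFrame | None = None,
    maneuver: Maneuver = "nose",
) -> tuple[list[BreathPhaseSignal], np.ndarray | None]:
    """Segment a maneuver recording into alternating breath phases.

    Breath bursts are found by thresholding a short-time energy envelope
    (threshold = midpoint between the silent-period and burst median
    energies, bootstrapped from the envelope's own percentiles); phases
    alternate starting with inspiration. The silent period is the
    longest sub-threshold stretch. ``override`` (columns ``phase``,
    ``cycle``, ``start_s``, ``end_s``) replaces automatic boundaries.

    Returns (phases, silent_segment). The silent segment is ``None``
    (with a warning) when no convincing sub-threshold stretch exists.
    """
    params = params or SegmentationParams()
    x = np.asarray(signal, dtype=float)

    if override is not None and len(override):
        phases = []
        for _, row in override.sort_values("start_s").iterrows():
            lo = int(round(row["start_s"] * sampling_rate))
            hi = int(round(row["end_s"] * sampling_rate))
            phases.append(
                BreathPhaseSignal(
                    x[lo:hi], sampling_rate, maneuver, row["phase"],
                    int(row["cycle"]), start_s=row["start_s"],
                )
            )
        last = max(int(round(row["end_s"] * sampling_rate)) for _, row in override.iterrows())
        silent = x[last:] if x.size - last > 0.25 * sampling_rate else None
        return phases, silent

    env_db, starts, frame = _frame_energy_db(x, sampling_rate, params)
    if env_db.size == 0 or np.ptp(env_db) < 3.0:
        warnings.warn("no breath burst found; returning zero phases")
        return [], None

    # bootstrap threshold, then refine as the midpoint between the median
    # burst energy and the median quiet energy
    thresh = 0.5 * (np.percentile(env_db, 10) + np.percentile(env_db, 90))
    for _ in range(2):
        active = env_db > thresh
        if not active.any() or active.all():
            break
        thresh = 0.5 * (np.median(env_db[active]) + np.median(env_db[~active]))
    active = env_db > thresh

    hop = max(int(round(params.hop_s * sampling_rate)), 1)
    min_frames = max(int(round(params.min_phase_s * sampling_rate / hop)), 1)
    min_gap = max(int(round(params.min_gap_s * sampling_rate / hop)), 1)

    runs = _runs(active)
    # close sub-min_gap holes between bursts
    merged: list[tuple[int, int]] = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    bursts = [(lo, hi) for lo, hi in merged if hi - lo >= min_frames]
    if not bursts:
        warnings.warn("no breath burst found; returning zero phases")
        return [], None

    phases = []
    for i, (lo, hi) in enumerate(bursts):
        a = starts[lo]
        b = min(starts[hi - 1] + frame, x.size)
        phase: Phase = PHASES[i % 2]
        phases.append(
            BreathPhaseSignal(
                x[a:b], sampling_rate, maneuver, phase, 1 + i // 2,
                start_s=a / sampling_rate,
            )
        )

    quiet_runs = _runs(~active)
    silent = None
    if quiet_runs:
        lo, hi = max(quiet_runs, key=lambda r: r[1] - r[0])
        a, b = starts[lo], min(starts[hi - 1] + frame, x.size)
        if b - a >= 0.25 * sampling_rate:
            silent = x[a:b]
    if silent is None:
        warnings.warn("no silent period identified; SNR screening will be skipped")
    return phases, silent


def screen_quality(
    phases: Sequence[BreathPhaseSignal],
    silent: np.ndarray | None,
    snr_threshold_db: float = 10.0,
    max_clip_fraction: float = 0.01,
    full_scale: float = 1.0,
) -> tuple[list[BreathPhaseSignal], bool]:
    """Flag phases as clean/rejected; decide subject-level inclusion.

    A phase is rejected when its SNR against the silent period is below
    ``snr_threshold_db`` or more than ``max_clip_fraction`` of samples
    sit at full scale. A subject is excluded when any recorded maneuver
    has fewer than two clean cycles of either phase type. Idempotent.
    """
    if silent is None or np.mean(np.asarray(silent) ** 2) == 0:
        noise_power = None
        if silent is None:
            warnings.warn("no silent period available; SNR check skipped")
    else:
        noise_power = float(np.mean(np.asarray(silent, dtype=float) ** 2))

    out = []
    for p in phases:
        quality, reason = "clean", None
        clip = float(np.mean(np.abs(p.samples) >= 0.99 * full_scale))
        if clip > max_clip_fraction:
            quality, reason = "rejected", f"clipping fraction {clip:.3f}"
        elif noise_power is not None:
            snr = 10.0 * np.log10(float(np.mean(p.samples**2)) / noise_power + 1e-30)
            if snr < snr_threshold_db:
                quality, reason = "rejected", f"SNR {snr:.1f} dB below threshold"
        out.append(replace(p, quality=quality, rejection_reason=reason))

    include = True
    for maneuver in {p.maneuver for p in out}:
        for phase in PHASES:
            n_clean = sum(
                1 for p in out
                if p.maneuver == maneuver and p.phase == phase and p.quality == "clean"
            )
            if n_clean < 2:
                include = False
    return out, include


@dataclass
class CohortSplit:
    """Train/test partition plus the feature-extraction subset of train."""

    train: list[SubjectRecord]
    test: list[SubjectRecord]
    feature_extraction: list[SubjectRecord]
    threshold: float
    fe_bounds: tuple[float, float]


def split_cohort(
    records: Sequence[SubjectRecord],
    threshold: float = DEFAULT_AHI_THRESHOLD,
    fe_bounds: tuple[float, float] = (10.0, 20.0),
    seed: int = 0,
    train_fraction: float = 113.0 / 199.0,
) -> CohortSplit:
    """Partition a cohort into train/test and mark the feature-extraction pool.

    A manifest ``split`` column, when present on every record, is
    honored verbatim; otherwise the split is stratified random within
    severity groups. Feature extraction uses train members with
    AHI <= fe_bounds[0] or AHI >= fe_bounds[1]; train members strictly
    inside the bounds join classifier training only.
    """
    low, high = fe_bounds
    if not (low < threshold < high):
        raise ValueError("fe_bounds must straddle the severity threshold")

    if all(r.split in ("train", "test") for r in records):
        train = [r for r in records if r.split == "train"]
        test = [r for r in records if r.split == "test"]
    else:
        rng = np.random.default_rng(seed)
        train, test = [], []
        for group in ("non_osa", "osa"):
            members = [r for r in records if r.severity(threshold) == group]
            if not members:
                raise ValueError(f"severity group {group} is empty")
            n_train = int(round(train_fraction * len(members)))
            order = rng.permutation(len(members))
            for rank, i in enumerate(order):
                member = replace(members[i], split="train" if rank < n_train else "test")
                (train if rank < n_train else test).append(member)
    for group in ("non_osa", "osa"):
        if not any(r.severity(threshold) == group for r in train):
            raise ValueError(f"severity group {group} empty in training partition")

    fe = [r for r in train if r.ahi <= low or r.ahi >= high]
    return CohortSplit(train, test, fe, threshold, fe_bounds)
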