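"""Feature bank: named spectral, bispectral and fractal descriptors.

Each feature is a :class:`FeatureDefinition` — an operator applied to
the cycle-averaged power spectrum, bispectrum or time signal of one
breathing maneuver/phase over a frequency band (and, for bispectral
operators, along a line in the bifrequency plane). Features are
assembled into a subjects x features table and min-max scaled to [0, 1]
with parameters learned on the training rows only.

Operator conventions: mean/slope/difference statistics are evaluated on
the dB (10 log10) power scale by default, centroid-type and geometric
statistics on the linear scale; "weight center" is the normalized
centroid sum(f * m) / sum(m) whereas first/second order moments are the
unnormalized averages sum(f^k * m) / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .cohort import Maneuver, Phase
from .spectral import BispectrumEstimate, SpectrumEstimate

__all__ = [
    "FeatureDefinition",
    "FeatureTable",
    "SubjectSignalSummary",
    "psd_band_statistic",
    "band_mean_difference",
    "bispectrum_line_statistic",
    "compute_feature",
    "build_feature_matrix",
    "scale_unit_interval",
    "apply_unit_scaling",
]

PSD_OPERATORS = (
    "band_mean",
    "band_mean_difference",
    "slope_mean",
    "centroid",
    "centroid_bandwidth",
    "geometric_mean",
    "first_peak_freq",
    "mean_max_peak_freq",
)
BIS_OPERATORS = ("bis_mean", "bis_moment1", "bis_moment2", "bis_weight_center")
FRACTAL_OPERATORS = ("katz", "higuchi", "hurst")
LINES = ("main_diagonal", "negative_diagonal", "half_f_line", "two_f_line")

Band = tuple[float, float]


@dataclass(frozen=True)
class FeatureDefinition:
    """One named feature: operator x maneuver x phase x band (x line)."""

    feature_id: str
    maneuver: Maneuver
    phase: Phase
    operator: str
    source: Literal["psd", "bispectrum", "time"]
    band: Band | Literal["full"] | None = None
    band_b: Band | None = None  # second band for band_mean_difference
    line: str | None = None
    scale: Literal["linear", "dB"] = "dB"
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source == "bispectrum":
            if self.operator not in BIS_OPERATORS:
                raise ValueError(f"{self.feature_id}: {self.operator} needs a PSD source")
            if self.line not in LINES:
                raise ValueError(f"{self.feature_id}: bispectral feature needs a line")
        elif self.source == "psd":
            if self.operator not in PSD_OPERATORS:
                raise ValueError(f"{self.feature_id}: {self.operator} is not a PSD operator")
        elif self.source == "time":
            if self.operator not in FRACTAL_OPERATORS:
                raise ValueError(f"{self.feature_id}: unknown fractal operator")
        else:
            raise ValueError(f"{self.feature_id}: unknown source {self.source}")


def _band_indices(frequencies: np.ndarray, band: Band, minimum: int = 3) -> np.ndarray:
    f1, f2 = band
    idx = np.flatnonzero((frequencies >= f1) & (frequencies <= f2))
    if idx.size < minimum:
        raise ValueError(f"band {band} intersects the grid in fewer than {minimum} points")
    return idx


def psd_band_statistic(
    spectrum: SpectrumEstimate,
    band: Band,
    operator: str,
    scale: str = "dB",
    prominence_db: float = 3.0,
) -> float:
    """Band statistic of a PSD (see module docstring for conventions).

    Peak-based operators return NaN when no qualifying peak exists.
    """
    f = spectrum.frequencies
    p = spectrum.power
    min_pts = 2 if operator in ("first_peak_freq", "mean_max_peak_freq") else 3
    idx = _band_indices(f, band, minimum=min_pts)
    fb, pb = f[idx], p[idx]
    db = 10.0 * np.log10(pb + 1e-30)
    v = db if scale == "dB" else pb

    if operator == "band_mean":
        return float(np.mean(v))
    if operator == "geometric_mean":
        return float(np.exp(np.mean(np.log(pb + 1e-30))))
    if operator == "slope_mean":
        return float(np.mean(np.diff(v)) / spectrum.df)
    if operator == "centroid":
        return float(np.sum(fb * pb) / np.sum(pb))
    if operator == "centroid_bandwidth":
        c = np.sum(fb * pb) / np.sum(pb)
        return float(np.sqrt(np.sum((fb - c) ** 2 * pb) / np.sum(pb)))
    if operator == "first_peak_freq":
        peaks, _ = find_peaks(db, prominence=prominence_db)
        return float(fb[peaks[0]]) if peaks.size else float("nan")
    if operator == "mean_max_peak_freq":
        peaks, _ = find_peaks(db, prominence=prominence_db)
        return float(np.mean(fb[peaks])) if peaks.size else float("nan")
    raise ValueError(f"unknown PSD operator {operator!r}")


def band_mean_difference(
    spectrum: SpectrumEstimate, band_a: Band, band_b: Band, scale: str = "dB"
) -> float:
    """Difference of the two bands' mean power (band_a minus band_b)."""
    return psd_band_statistic(spectrum, band_a, "band_mean", scale) - psd_band_statistic(
        spectrum, band_b, "band_mean", scale
    )


def _line_samples(
    bispec: BispectrumEstimate, line: str, band: Band | str
) -> tuple[np.ndarray, np.ndarray]:
    """|B| sampled along a bifrequency line, parameterized by f in ``band``."""
    grid = bispec.freq_grid
    if band == "full" or band is None:
        band = (float(grid[0]), float(grid[-1]))
    f1, f2 = band
    idx = np.flatnonzero((grid >= f1) & (grid <= f2))
    if idx.size == 0:
        raise ValueError(f"band {band} does not intersect the bispectral grid")
    f = grid[idx]
    if line == "main_diagonal":
        partner = f
    elif line == "half_f_line":
        partner = 0.5 * f
    elif line == "two_f_line":
        partner = 2.0 * f
    elif line == "negative_diagonal":
        partner = f1 + f2 - f
    else:
        raise ValueError(f"unknown bifrequency line {line!r}")
    j = np.rint(partner / bispec.df).astype(int)
    ok = (j >= 0) & (j < grid.size)
    if not ok.any():
        raise ValueError(f"line {line} leaves the principal domain within band {band}")
    m = np.abs(bispec.values[idx[ok], j[ok]])
    return f[ok], m


def bispectrum_line_statistic(
    bispec: BispectrumEstimate,
    line: str,
    band: Band | str,
    operator: str,
) -> float:
    """Statistic of |B| along a bifrequency line.

    ``bis_mean`` is the mean magnitude; ``bis_weight_center`` the
    magnitude-weighted mean frequency; ``bis_moment1``/``bis_moment2``
    the unnormalized first/second moments sum(f^k |B|) / N.
    """
    f, m = _line_samples(bispec, line, band)
    if operator == "bis_mean":
        return float(np.mean(m))
    if operator == "bis_weight_center":
        s = np.sum(m)
        return float(np.sum(f * m) / s) if s > 0 else float("nan")
    if operator == "bis_moment1":
        return float(np.sum(f * m) / f.size)
    if operator == "bis_moment2":
        return float(np.sum(f**2 * m) / f.size)
    raise ValueError(f"unknown bispectral operator {operator!r}")


@dataclass
class SubjectSignalSummary:
    """Cycle-averaged frequency/time-domain summaries for one subject.

    Keys of the mappings are (maneuver, phase) pairs; missing keys mean
    the subject lacks usable cycles for that combination.
    """

    subject_id: str
    spectra: dict[tuple[str, str], SpectrumEstimate] = field(default_factory=dict)
    bispectra: dict[tuple[str, str], BispectrumEstimate] = field(default_factory=dict)
    fractal: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def compute_feature(defn: FeatureDefinition, summary: SubjectSignalSummary) -> float:
    """Evaluate one feature definition for one subject; NaN when the
    required maneuver/phase summary is missing."""
    key = (defn.maneuver, defn.phase)
    if defn.source == "psd":
        spectrum = summary.spectra.get(key)
        if spectrum is None:
            return float("nan")
        if defn.operator == "band_mean_difference":
            return band_mean_difference(spectrum, defn.band, defn.band_b, defn.scale)
        return psd_band_statistic(spectrum, defn.band, defn.operator, defn.scale)
    if defn.source == "bispectrum":
        bispec = summary.bispectra.get(key)
        if bispec is None:
            return float("nan")
        return bispectrum_line_statistic(bispec, defn.line, defn.band, defn.operator)
    values = summary.fractal.get(key)
    if values is None:
        return float("nan")
    return values[defn.operator]


@dataclass
class FeatureTable:
    """Subjects x features value matrix with scaling state.

    ``data`` holds one row per subject (index = subject id) with NaN as
    the explicit missing marker; ``scaling`` maps feature id to the
    (min, max) learned on training rows once ``provenance == 'scaled'``.
    """

    data: pd.DataFrame
    provenance: Literal["raw", "scaled"] = "raw"
    scaling: dict[str, tuple[float, float]] | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


def build_feature_matrix(
    summaries: Mapping[str, SubjectSignalSummary] | Sequence[SubjectSignalSummary],
    definitions: Sequence[FeatureDefinition],
) -> FeatureTable:
    """Evaluate every definition for every subject (raw, unscaled).

    Column order follows the definition order. Subjects missing a
    required maneuver keep their row, with NaN in the affected columns.
    """
    if not isinstance(summaries, Mapping):
        summaries = {s.subject_id: s for s in summaries}
    ids = [d.feature_id for d in definitions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids in the definition catalog")
    rows = {}
    for sid, summary in summaries.items():
        rows[sid] = [compute_feature(d, summary) for d in definitions]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        warnings.warn(f"feature matrix has {n_missing} missing entries")
    return FeatureTable(df, provenance="raw")


def scale_unit_interval(table: FeatureTable, training_ids: Sequence[str]) -> FeatureTable:
    """Min-max scale every feature to [0, 1] with parameters fit on the
    training rows; non-training rows are transformed with the same
    parameters and clipped to [0, 1]. Features constant on the training
    rows are dropped with a warning. Idempotent on already-scaled data.
    """
    train = table.data.loc[list(training_ids)]
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    constant = hi <= lo
    if constant.any():
        dropped = list(table.data.columns[constant])
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
    keep = table.data.columns[~constant]
    scaling = {c: (float(lo[c]), float(hi[c])) for c in keep}
    scaled = (table.data[keep] - lo[keep]) / (hi[keep] - lo[keep])
    scaled = scaled.clip(0.0, 1.0)
    return FeatureTable(scaled, provenance="scaled", scaling=scaling)


def apply_unit_scaling(
    table: FeatureTable, scaling: Mapping[str, tuple[float, float]]
) -> FeatureTable:
    """Transform a raw table with previously learned scaling parameters
    (for screening cohorts unseen at training time)."""
    cols = [c for c in table.data.columns if c in scaling]
    out = table.data[cols].copy()
    for c in cols:
        lo, hi = scaling[c]
        out[c] = ((out[c] - lo) / (hi - lo)).clip(0.0, 1.0)
    return FeatureTable(out, provenance="scaled", scaling=dict(scaling))
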