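"""Synthetic two-group cohorts for exercising the screening pipeline.

No recordings are distributed with the published cohort, so this module
generates one with the statistical structure the pipeline assumes:

* AHI drawn per severity group from truncated normals matching the
  reported group moments (non-OSA 3.59 +/- 3.95 on [0, 15); OSA
  42.85 +/- 32.72 on [15, inf));
* BMI, neck circumference and Mallampati score tied to AHI through a
  Gaussian copula so the pooled correlations land near the reported
  r = 0.44 (BMI), 0.43 (NC) and 0.26 (MpS);
* per-subject breathing-sound audio: five inspiration/expiration cycles
  of spectrally shaped noise plus a quadratically phase-coupled tone
  triple, followed by a silent period. Above 250 Hz the spectral slope
  rises for OSA subjects and falls for non-OSA subjects, OSA resonances
  sit higher, and the 350-600 / 1000-1700 / 2100-2400 Hz bands carry
  smaller group offsets — so every fixed analysis band holds some group
  information.

The generator reproduces the statistical contrasts the method feeds on,
not tracheal acoustics; see docs/methods.md for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy import stats
from scipy.io import wavfile

from .cohort import SubjectRecord

__all__ = [
    "SyntheticSpec",
    "sample_anthropometrics",
    "synthesize_breath_sound",
    "simulate_cohort",
    "generate_cohort",
    "fractional_gaussian_noise",
]


@dataclass
class GroupParams:
    """Per-severity-group generator settings."""

    ahi_mean: float
    ahi_sd: float
    ahi_bounds: tuple[float, float]
    age_mean: float
    age_sd: float
    male_fraction: float
    bmi_mean: float
    bmi_sd: float
    nc_mean: float
    nc_sd: float
    mps_probs: tuple[float, float, float, float]
    slope_db_per_hz: float      # spectral slope over the contrast band
    resonance_hz: float         # first formant-like resonance center
    resonance2_hz: float
    high_band_gain_db: float    # offset applied over 2100-2400 Hz
    qpc_pair_hz: tuple[float, float]


@dataclass
class SyntheticSpec:
    """Cohort-level generator settings (defaults = study conditions)."""

    n_non_osa: int = 109
    n_osa: int = 90
    sampling_rate: float = 10240.0
    contrast_band: tuple[float, float] = (250.0, 350.0)
    #: latent (within-group) copula correlations of BMI/NC/MpS with AHI,
    #: calibrated so the pooled correlations land near 0.44/0.43/0.26
    latent_link: tuple[float, float, float] = (0.45, 0.18, 0.12)
    slope_jitter: float = 0.012
    resonance_jitter_hz: float = 18.0
    gain_jitter_db: float = 1.2
    qpc_jitter_hz: float = 8.0
    burst_rms: float = 0.08
    noise_floor_rms: float = 0.002
    cycles: int = 5
    inspiration_s: float = 1.0
    expiration_s: float = 0.9
    gap_s: float = 0.3
    silence_s: float = 2.5
    non_osa: GroupParams = field(default_factory=lambda: GroupParams(
        ahi_mean=3.59, ahi_sd=3.95, ahi_bounds=(0.0, 15.0),
        age_mean=48.60, age_sd=12.69, male_fraction=50 / 109,
        bmi_mean=31.79, bmi_sd=7.21, nc_mean=39.81, nc_sd=5.14,
        mps_probs=(59 / 108, 25 / 108, 15 / 108, 9 / 108),
        slope_db_per_hz=-0.030, resonance_hz=300.0, resonance2_hz=1280.0,
        high_band_gain_db=0.0, qpc_pair_hz=(170.0, 260.0),
    ))
    osa: GroupParams = field(default_factory=lambda: GroupParams(
        ahi_mean=42.85, ahi_sd=32.72, ahi_bounds=(15.0, np.inf),
        age_mean=52.18, age_sd=11.55, male_fraction=66 / 90,
        bmi_mean=36.44, bmi_sd=8.01, nc_mean=44.08, nc_sd=3.67,
        mps_probs=(22 / 90, 30 / 90, 22 / 90, 16 / 90),
        slope_db_per_hz=+0.030, resonance_hz=350.0, resonance2_hz=1380.0,
        high_band_gain_db=4.0, qpc_pair_hz=(210.0, 320.0),
    ))

    def __post_init__(self) -> None:
        if self.n_non_osa <= 0 or self.n_osa <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 < self.contrast_band[0] < self.contrast_band[1] < self.sampling_rate / 2):
            raise ValueError("contrast band must lie inside (0, Nyquist)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        """Build a spec from a YAML file of top-level field overrides
        (group parameters under ``non_osa:`` / ``osa:`` mappings)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("non_osa", "osa"):
            if key in raw:
                base = vars(getattr(cls(), key)) | {
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in raw[key].items()
                }
                raw[key] = GroupParams(**base)
        for key in ("contrast_band", "latent_link"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, bounds) -> np.ndarray:
    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd if np.isfinite(bounds[1]) else np.inf
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_anthropometrics(spec: SyntheticSpec, seed: int = 0) -> list[SubjectRecord]:
    """Draw subject records (no audio references) for the cohort.

    A latent 4-variate Gaussian (AHI, BMI, NC, MpS components) with the
    spec's within-group link correlations drives the marginals: AHI via
    a per-group truncated-normal quantile transform, BMI/NC as
    group-mean + sd x latent, MpS by thresholding its latent into the
    per-group category frequencies. Sex and age are drawn per group.
    Deterministic given the seed.
    """
    r_bmi, r_nc, r_mps = spec.latent_link
    R = np.array([
        [1.0, r_bmi, r_nc, r_mps],
        [r_bmi, 1.0, r_bmi * r_nc, r_bmi * r_mps],
        [r_nc, r_bmi * r_nc, 1.0, r_nc * r_mps],
        [r_mps, r_bmi * r_mps, r_nc * r_mps, 1.0],
    ])
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent correlation matrix is not positive definite") from exc

    rng = np.random.default_rng(seed)
    records = []
    for group, params, n in (
        ("non_osa", spec.non_osa, spec.n_non_osa),
        ("osa", spec.osa, spec.n_osa),
    ):
        z = rng.standard_normal((n, 4)) @ chol.T
        u = stats.norm.cdf(z)
        ahi = _truncnorm_ppf(u[:, 0], params.ahi_mean, params.ahi_sd, params.ahi_bounds)
        # keep strictly inside the severity bins
        ahi = np.clip(ahi, params.ahi_bounds[0], None)
        if np.isfinite(params.ahi_bounds[1]):
            ahi = np.minimum(ahi, np.nextafter(params.ahi_bounds[1], 0.0))
        bmi = np.clip(params.bmi_mean + params.bmi_sd * z[:, 1], 15.0, None)
        nc = np.clip(params.nc_mean + params.nc_sd * z[:, 2], 25.0, None)
        cuts = np.cumsum(params.mps_probs)[:3]
        mps = 1 + np.searchsorted(cuts, u[:, 3])
        age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.0, 95.0)
        male = rng.random(n) < params.male_fraction
        tag = "N" if group == "non_osa" else "O"
        for i in range(n):
            records.append(SubjectRecord(
                subject_id=f"{tag}{i + 1:03d}",
                ahi=float(ahi[i]),
                age=float(age[i]),
                sex="male" if male[i] else "female",
                bmi=float(bmi[i]),
                neck_circumference=float(nc[i]),
                mallampati=int(mps[i]),
            ))
    return records


@dataclass
class SubjectAcoustics:
    """Per-subject acoustic phenotype (drawn once, shared by maneuvers)."""

    slope: float
    resonance: float
    resonance2: float
    high_gain: float
    qpc_pair: tuple[float, float]
    level_db: float


def _draw_acoustics(params: GroupParams, spec: SyntheticSpec, rng) -> SubjectAcoustics:
    f1, f2 = params.qpc_pair_hz
    return SubjectAcoustics(
        slope=params.slope_db_per_hz + rng.normal(0.0, spec.slope_jitter),
        resonance=params.resonance_hz + rng.normal(0.0, spec.resonance_jitter_hz),
        resonance2=params.resonance2_hz + rng.normal(0.0, 2 * spec.resonance_jitter_hz),
        high_gain=params.high_band_gain_db + rng.normal(0.0, spec.gain_jitter_db),
        qpc_pair=(f1 + rng.normal(0.0, spec.qpc_jitter_hz),
                  f2 + rng.normal(0.0, spec.qpc_jitter_hz)),
        level_db=rng.normal(0.0, 1.0),
    )


def _envelope_db(f: np.ndarray, acoustics: SubjectAcoustics, spec: SyntheticSpec,
                 maneuver: str, phase: str) -> np.ndarray:
    lo, hi = spec.contrast_band
    env = (
        14.0 * np.exp(-0.5 * ((f - acoustics.resonance) / 160.0) ** 2)
        + 6.0 * np.exp(-0.5 * ((f - acoustics.resonance2) / 260.0) ** 2)
        - 0.004 * f
    )
    slope = acoustics.slope * (0.8 if maneuver == "mouth" else 1.0)
    slope *= 0.7 if phase == "expiration" else 1.0
    env += slope * (np.clip(f, lo, hi) - lo)
    env += acoustics.high_gain / (1.0 + np.exp(-(f - 2100.0) / 40.0))
    if maneuver == "mouth":
        env += 3.0 * np.exp(-0.5 * ((f - 900.0) / 220.0) ** 2)
    return env


def _shaped_burst(n: int, fs: float, acoustics: SubjectAcoustics, spec: SyntheticSpec,
                  maneuver: str, phase: str, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    X = sfft.rfft(white)
    f = sfft.rfftfreq(n, 1.0 / fs)
    gain = 10.0 ** (_envelope_db(f, acoustics, spec, maneuver, phase) / 20.0)
    x = sfft.irfft(X * gain, n)
    rms = np.sqrt(np.mean(x**2))
    x = x / rms if rms > 0 else x
    # quadratically phase-coupled triple riding on the breath noise
    f1, f2 = acoustics.qpc_pair
    t = np.arange(n) / fs
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    x = x + (0.5 * np.cos(2 * np.pi * f1 * t + p1)
             + 0.5 * np.cos(2 * np.pi * f2 * t + p2)
             + 0.35 * np.cos(2 * np.pi * (f1 + f2) * t + p1 + p2))
    target = spec.burst_rms * 10.0 ** (acoustics.level_db / 20.0)
    x *= target / np.sqrt(np.mean(x**2))
    ramp = max(int(0.05 * n), 1)
    window = np.ones(n)
    window[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    window[-ramp:] = window[:ramp][::-1]
    return x * window


def synthesize_breath_sound(
    group: Literal["non_osa", "osa"],
    spec: SyntheticSpec,
    maneuver: Literal["mouth", "nose"] = "nose",
    seed: int = 0,
    acoustics: SubjectAcoustics | None = None,
) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    """One maneuver recording plus its ground-truth phase boundaries.

    Layout: 0.5 s lead-in, then ``cycles`` x (inspiration, gap,
    expiration, gap), then the silent tail. Returns (signal, boundaries)
    where boundaries is a list of (phase, start_s, end_s).
    """
    rng = np.random.default_rng(seed)
    params = spec.osa if group == "osa" else spec.non_osa
    acoustics = acoustics or _draw_acoustics(params, spec, rng)
    fs = spec.sampling_rate

    segments: list[np.ndarray] = [np.zeros(int(0.5 * fs))]
    boundaries: list[tuple[str, float, float]] = []
    cursor = 0.5
    for _ in range(spec.cycles):
        for phase, dur in (("inspiration", spec.inspiration_s),
                           ("expiration", spec.expiration_s)):
            n = int(dur * fs)
            segments.append(_shaped_burst(n, fs, acoustics, spec, maneuver, phase, rng))
            boundaries.append((phase, cursor, cursor + dur))
            cursor += dur
            gap = int(spec.gap_s * fs)
            segments.append(np.zeros(gap))
            cursor += spec.gap_s
    segments.append(np.zeros(int(spec.silence_s * fs)))
    x = np.concatenate(segments)
    if spec.noise_floor_rms > 0:
        x = x + rng.normal(0.0, spec.noise_floor_rms, x.size)
    return x, boundaries


def simulate_cohort(
    spec: SyntheticSpec | None = None, seed: int = 0
) -> tuple[list[SubjectRecord], dict[str, dict[str, tuple[np.ndarray, float, list]]]]:
    """In-memory cohort: records plus per-subject, per-maneuver signals.

    ``signals[subject_id][maneuver]`` is (samples, sampling_rate,
    ground_truth_boundaries). Deterministic given the seed.
    """
    spec = spec or SyntheticSpec()
    records = sample_anthropometrics(spec, seed)
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(records) + 1)[1:]
    signals: dict[str, dict[str, tuple]] = {}
    for i, record in enumerate(records):
        group = record.severity()
        params = spec.osa if group == "osa" else spec.non_osa
        rng = np.random.default_rng(seeds[2 * i] % (2**31 - 1))
        acoustics = _draw_acoustics(params, spec, rng)
        per_maneuver = {}
        for j, maneuver in enumerate(("mouth", "nose")):
            x, bounds = synthesize_breath_sound(
                group, spec, maneuver,
                seed=int(seeds[2 * i + j] % (2**31 - 1)) + j,
                acoustics=acoustics,
            )
            per_maneuver[maneuver] = (x, spec.sampling_rate, bounds)
        signals[record.subject_id] = per_maneuver
    return records, signals


def generate_cohort(
    spec: SyntheticSpec | None = None,
    out_dir: str | Path = "synthetic_cohort",
    seed: int = 0,
) -> Path:
    """Write a manifest CSV plus per-subject WAV files; returns the
    manifest path. Byte-identical for identical seeds."""
    spec = spec or SyntheticSpec()
    out_dir = Path(out_dir)
    (out_dir / "audio").mkdir(parents=True, exist_ok=True)
    records, signals = simulate_cohort(spec, seed)
    rows = []
    for record in records:
        refs = {}
        for maneuver in ("mouth", "nose"):
            x, fs, _ = signals[record.subject_id][maneuver]
            path = out_dir / "audio" / f"{record.subject_id}_{maneuver}.wav"
            pcm = np.clip(np.round(x * 32767), -32768, 32767).astype(np.int16)
            wavfile.write(path, int(fs), pcm)
            refs[maneuver] = str(path)
        rows.append({
            "subject_id": record.subject_id,
            "ahi": round(record.ahi, 3),
            "age": round(record.age, 1),
            "sex": record.sex,
            "bmi": round(record.bmi, 2),
            "nc": round(record.neck_circumference, 2),
            "mps": record.mallampati,
            "mouth_wav": refs["mouth"],
            "nose_wav": refs["nose"],
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def fractional_gaussian_noise(h: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn synthesis (circulant embedding), unit variance."""
    k = np.arange(n + 1)
    g = 0.5 * (np.abs(k - 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h) + np.abs(k + 1) ** (2 * h))
    row = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam[lam < 0] = 0.0
    m = row.size
    w = rng.normal(size=m) + 1j * rng.normal(size=m)
    f = np.fft.fft(np.sqrt(lam / (2 * m)) * w)
    return f.real[:n]
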