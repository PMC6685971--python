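"""Feature definition catalogs.

``published_definitions`` encodes the 26 screening features reported
for the six anthropometric subsets (operator, maneuver/phase, band and
bifrequency line for each), with the convention that features 9 and 10
are alternatives and never enter the same combination.
``exploratory_definitions`` spans the full operator grid over the four
fixed discriminative bands (100-300, 350-600, 1000-1700, 2100-2400 Hz)
for all four maneuver/phase combinations — the ~250-feature pool the
reduction stage starts from. ``full_catalog`` is their concatenation.
"""

from __future__ import annotations

from .features import FeatureDefinition
from .spectral import FIXED_BANDS

__all__ = [
    "published_definitions",
    "exploratory_definitions",
    "full_catalog",
    "EXCLUSIVE_GROUPS",
]

#: Feature ids that may not co-occur inside one combination.
EXCLUSIVE_GROUPS: list[frozenset[str]] = [frozenset({"t2_09", "t2_10"})]

_MP = {"ExpM": ("mouth", "expiration"), "InsM": ("mouth", "inspiration"),
       "ExpN": ("nose", "expiration"), "InsN": ("nose", "inspiration")}


def _psd(i, mp, op, band, tag, band_b=None, scale="dB"):
    m, p = _MP[mp]
    return FeatureDefinition(
        feature_id=f"t2_{i:02d}", maneuver=m, phase=p, operator=op, source="psd",
        band=band, band_b=band_b, scale=scale, tags=(tag,),
    )


def _bis(i, mp, op, line, band, tag):
    m, p = _MP[mp]
    return FeatureDefinition(
        feature_id=f"t2_{i:02d}", maneuver=m, phase=p, operator=op,
        source="bispectrum", band=band, line=line, tags=(tag,),
    )


def published_definitions() -> list[FeatureDefinition]:
    """The 26 subset-specific screening features."""
    return [
        _psd(1, "ExpM", "band_mean_difference", (130, 235), "all", band_b=(1260, 1410)),
        _psd(2, "InsN", "slope_mean", (250, 355), "all"),
        _psd(3, "ExpM", "centroid_bandwidth", (300, 550), "all"),
        _bis(4, "InsM", "bis_moment1", "main_diagonal", (1200, 1515), "all"),
        _psd(5, "InsM", "geometric_mean", (140, 270), "bmi_lt_35"),
        _bis(6, "InsM", "bis_moment1", "half_f_line", (140, 270), "bmi_lt_35"),
        _bis(7, "InsN", "bis_mean", "main_diagonal", (130, 275), "bmi_lt_35"),
        _bis(8, "InsN", "bis_weight_center", "main_diagonal", "full", "bmi_lt_35"),
        _psd(9, "InsN", "band_mean", (130, 280), "age_gt_50"),
        _psd(10, "InsN", "centroid", (80, 560), "age_gt_50"),
        _bis(11, "InsM", "bis_weight_center", "main_diagonal", (130, 230), "age_gt_50"),
        _bis(12, "InsN", "bis_mean", "main_diagonal", (130, 280), "age_gt_50"),
        _bis(13, "InsN", "bis_moment2", "negative_diagonal", (130, 280), "age_gt_50"),
        _psd(14, "InsN", "slope_mean", (270, 370), "age_le_50"),
        _psd(15, "ExpN", "slope_mean", (450, 550), "age_le_50"),
        _bis(16, "InsM", "bis_weight_center", "half_f_line", (390, 510), "age_le_50"),
        _psd(17, "InsN", "slope_mean", (250, 350), "male"),
        _psd(18, "InsN", "first_peak_freq", (0, 550), "male"),
        _psd(19, "InsN", "band_mean", (395, 520), "nc_gt_40"),
        _psd(20, "InsM", "mean_max_peak_freq", (60, 600), "nc_gt_40"),
        _bis(21, "InsM", "bis_weight_center", "two_f_line", (60, 600), "nc_gt_40"),
        _bis(22, "InsN", "bis_weight_center", "main_diagonal", (395, 520), "nc_gt_40"),
        _psd(23, "InsN", "slope_mean", (250, 350), "mps_le_2"),
        _bis(24, "InsM", "bis_weight_center", "two_f_line", (1090, 1460), "mps_le_2"),
        _bis(25, "InsM", "bis_moment1", "two_f_line", (1260, 1460), "mps_le_2"),
        _bis(26, "ExpM", "bis_moment1", "negative_diagonal", (1260, 1410), "mps_le_2"),
    ]


_PSD_BAND_OPS = (
    "band_mean", "geometric_mean", "slope_mean",
    "centroid", "centroid_bandwidth", "mean_max_peak_freq",
)
_BIS_LINE_OPS = (
    ("bis_mean", "main_diagonal"),
    ("bis_weight_center", "main_diagonal"),
    ("bis_moment1", "main_diagonal"),
    ("bis_moment2", "main_diagonal"),
    ("bis_moment2", "negative_diagonal"),
    ("bis_weight_center", "half_f_line"),
    ("bis_weight_center", "two_f_line"),
)


def exploratory_definitions(bands=None) -> list[FeatureDefinition]:
    """Operator grid over the four fixed bands and all maneuvers/phases."""
    bands = list(bands) if bands is not None else list(FIXED_BANDS)
    defs: list[FeatureDefinition] = []
    for mp, (maneuver, phase) in _MP.items():
        tagless = dict(maneuver=maneuver, phase=phase, tags=("exploratory",))
        for f1, f2 in bands:
            stem = f"{mp.lower()}_{int(f1)}_{int(f2)}"
            for op in _PSD_BAND_OPS:
                defs.append(FeatureDefinition(
                    feature_id=f"{stem}_psd_{op}", operator=op, source="psd",
                    band=(f1, f2), **tagless,
                ))
            for op, line in _BIS_LINE_OPS:
                defs.append(FeatureDefinition(
                    feature_id=f"{stem}_{op}_{line}", operator=op, source="bispectrum",
                    band=(f1, f2), line=line, **tagless,
                ))
        defs.append(FeatureDefinition(
            feature_id=f"{mp.lower()}_psd_first_peak_550", operator="first_peak_freq",
            source="psd", band=(0, 550), **tagless,
        ))
        defs.append(FeatureDefinition(
            feature_id=f"{mp.lower()}_psd_band_diff_low_high", operator="band_mean_difference",
            source="psd", band=(130, 235), band_b=(1260, 1410), **tagless,
        ))
        for op in ("katz", "higuchi", "hurst"):
            defs.append(FeatureDefinition(
                feature_id=f"{mp.lower()}_fractal_{op}", operator=op, source="time",
                **tagless,
            ))
    return defs


def full_catalog() -> list[FeatureDefinition]:
    """Published subset features plus the exploratory grid (~250 features)."""
    return published_definitions() + exploratory_definitions()
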