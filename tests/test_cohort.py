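"""Cohort I/O: manifests, audio, phase segmentation, quality, splits."""

import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile

from awakeosa.cohort import (
    ManifestSchemaError,
    ManifestValidationError,
    SubjectRecord,
    load_audio,
    load_manifest,
    screen_quality,
    segment_phases,
    split_cohort,
)

from conftest import make_row


class TestManifest:
    def test_severity_counts_match_cohort_composition(self, manifest_csv, rng):
        rows = [make_row(f"N{i}", ahi=float(rng.uniform(0, 14.9))) for i in range(109)]
        rows += [make_row(f"O{i}", ahi=float(rng.uniform(15, 80))) for i in range(90)]
        records = load_manifest(manifest_csv(rows))
        assert len(records) == 199
        n_osa = sum(r.is_osa() for r in records)
        assert (len(records) - n_osa, n_osa) == (109, 90)

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ManifestSchemaError):
            load_manifest(path)

    def test_missing_column_is_schema_error(self, manifest_csv):
        row = make_row()
        del row["bmi"]
        with pytest.raises(ManifestSchemaError, match="bmi"):
            load_manifest(manifest_csv([row]))

    def test_duplicate_subject_rejected(self, manifest_csv):
        with pytest.raises(ManifestSchemaError, match="duplicate"):
            load_manifest(manifest_csv([make_row("S1"), make_row("S1")]))

    @pytest.mark.parametrize(
        "field,value", [("mps", 5), ("ahi", -1.0), ("bmi", 0.0), ("sex", "x")]
    )
    def test_out_of_domain_value_names_row(self, manifest_csv, field, value):
        with pytest.raises(ManifestValidationError, match="row 1"):
            load_manifest(manifest_csv([make_row("S1"), make_row("S2", **{field: value})]))


class TestAudio:
    def test_mono_wav_roundtrip_length(self, tmp_path):
        fs = 10240
        x = (0.3 * np.sin(2 * np.pi * 100 * np.arange(10 * fs) / fs) * 32767).astype(np.int16)
        path = tmp_path / "a.wav"
        wavfile.write(path, fs, x)
        samples, rate = load_audio(path)
        assert rate == fs and samples.size == 102400
        assert np.max(np.abs(samples)) <= 1.0

    def test_stereo_requires_channel_selector(self, tmp_path):
        fs = 8000
        stereo = np.zeros((fs, 2), dtype=np.int16)
        stereo[:, 0] = 1000
        path = tmp_path / "s.wav"
        wavfile.write(path, fs, stereo)
        with pytest.raises(ValueError, match="channel"):
            load_audio(path)
        left, _ = load_audio(path, channel=0)
        assert np.allclose(left, 1000 / 32768)

    def test_truncated_file_is_io_error(self, tmp_path):
        path = tmp_path / "t.wav"
        path.write_bytes(b"RIFF\x00\x00\x00\x00WAVE")
        with pytest.raises(IOError):
            load_audio(path)


def bursty_signal(fs=10240.0, n_bursts=10, burst_s=0.8, gap_s=0.4, tail_s=2.0, seed=0):
    rng = np.random.default_rng(seed)
    parts, bounds, cursor = [np.zeros(int(0.3 * fs))], [], 0.3
    for i in range(n_bursts):
        parts.append(rng.normal(0, 0.2, int(burst_s * fs)))
        bounds.append((cursor, cursor + burst_s))
        cursor += burst_s
        parts.append(np.zeros(int(gap_s * fs)))
        cursor += gap_s
    parts.append(np.zeros(int(tail_s * fs)))
    x = np.concatenate(parts)
    return x + rng.normal(0, 0.003, x.size), bounds


class TestSegmentation:
    def test_bursts_recovered_with_alternating_phases(self):
        fs = 10240.0
        x, bounds = bursty_signal(fs)
        phases, silent = segment_phases(x, fs)
        assert len(phases) == 10
        labels = [p.phase for p in phases]
        assert labels[0] == "inspiration"
        assert all(a != b for a, b in zip(labels, labels[1:]))
        for p, (start, end) in zip(phases, bounds):
            assert abs(p.start_s - start) <= 0.05
            assert abs((p.start_s + p.duration_s) - end) <= 0.05
        assert silent is not None and silent.size >= 1.5 * fs

    def test_all_zero_signal_yields_no_phases(self):
        with pytest.warns(UserWarning, match="no breath burst"):
            phases, silent = segment_phases(np.zeros(50000), 10240.0)
        assert phases == [] and silent is None

    def test_cycle_count_bounded_by_protocol(self):
        from awakeosa.synthetic import SyntheticSpec, synthesize_breath_sound

        spec = SyntheticSpec()
        x, _ = synthesize_breath_sound("non_osa", spec, "nose", seed=5)
        phases, _ = segment_phases(x, spec.sampling_rate)
        assert len(phases) <= 2 * spec.cycles

    def test_manual_override_wins(self):
        fs = 10240.0
        x, _ = bursty_signal(fs)
        override = pd.DataFrame(
            [{"phase": "inspiration", "cycle": 1, "start_s": 0.3, "end_s": 1.1},
             {"phase": "expiration", "cycle": 1, "start_s": 1.5, "end_s": 2.3}]
        )
        phases, _ = segment_phases(x, fs, override=override)
        assert len(phases) == 2
        assert phases[0].start_s == 0.3 and phases[0].duration_s == pytest.approx(0.8, abs=1e-3)


class TestQuality:
    def _phase(self, rms, fs=10240.0, **kw):
        rng = np.random.default_rng(0)
        from awakeosa.cohort import BreathPhaseSignal

        defaults = dict(maneuver="nose", phase="inspiration", cycle_index=1)
        defaults.update(kw)
        return BreathPhaseSignal(rng.normal(0, rms, int(0.5 * fs)), fs, **defaults)

    def test_low_snr_phase_rejected_at_default_threshold(self):
        silent = np.random.default_rng(1).normal(0, 0.01, 5000)
        # ~3 dB above the 0.01-RMS silent floor: reject at the 10 dB default
        low = self._phase(0.0141)
        high = self._phase(0.2)
        flagged, _ = screen_quality([low, high], silent)
        assert flagged[0].quality == "rejected"
        assert "SNR" in flagged[0].rejection_reason
        assert flagged[1].quality == "clean"

    def test_subject_excluded_without_two_clean_cycles(self):
        silent = np.random.default_rng(1).normal(0, 0.01, 5000)
        phases = [
            self._phase(0.2, cycle_index=1),
            self._phase(0.2, cycle_index=1, phase="expiration"),
            self._phase(0.0141, cycle_index=2),  # rejected inspiration
            self._phase(0.2, cycle_index=2, phase="expiration"),
        ]
        flagged, include = screen_quality(phases, silent)
        assert not include  # only one clean nose inspiration

    def test_clean_cohort_has_no_exclusions_and_screening_is_idempotent(self):
        silent = np.random.default_rng(1).normal(0, 0.001, 5000)
        phases = [self._phase(0.2, cycle_index=i, phase=ph)
                  for i in (1, 2, 3) for ph in ("inspiration", "expiration")]
        once, include = screen_quality(phases, silent)
        assert include and all(p.quality == "clean" for p in once)
        twice, include2 = screen_quality(once, silent)
        assert include2
        assert [(p.quality, p.rejection_reason) for p in once] == [
            (p.quality, p.rejection_reason) for p in twice
        ]

    def test_clipped_phase_rejected(self):
        from awakeosa.cohort import BreathPhaseSignal

        x = np.ones(6000)
        p = BreathPhaseSignal(x * 0.999, 10240.0, "nose", "inspiration", 1)
        flagged, _ = screen_quality([p], None)
        assert flagged[0].quality == "rejected"
        assert "clipping" in flagged[0].rejection_reason


def _records(ahis, **kw):
    return [
        SubjectRecord(f"s{i}", a, 40.0, "male", 30.0, 40.0, 2, **kw)
        for i, a in enumerate(ahis)
    ]


class TestSplit:
    def test_threshold_rule(self):
        split = split_cohort(_records([3, 12, 17, 25]), threshold=15, train_fraction=0.5)
        all_members = split.train + split.test
        non = sorted(r.ahi for r in all_members if not r.is_osa())
        osa = sorted(r.ahi for r in all_members if r.is_osa())
        assert non == [3, 12] and osa == [17, 25]

    def test_feature_extraction_bounds(self):
        split = split_cohort(_records([3, 12, 17, 25]), fe_bounds=(10, 20), train_fraction=1.0)
        # 12 and 17 fall strictly inside the bounds: train-only
        fe = sorted(r.ahi for r in split.feature_extraction)
        assert fe == [3, 25]

    def test_explicit_split_column_honored(self):
        records = _records([3, 12, 17, 25])
        for r, s in zip(records, ["train", "test", "train", "test"]):
            r.split = s
        split = split_cohort(records)
        assert sorted(r.subject_id for r in split.train) == ["s0", "s2"]
        assert sorted(r.subject_id for r in split.test) == ["s1", "s3"]

    def test_every_subject_in_exactly_one_partition(self):
        records = _records(list(np.linspace(0, 60, 40)))
        split = split_cohort(records, seed=3)
        train_ids = {r.subject_id for r in split.train}
        test_ids = {r.subject_id for r in split.test}
        assert not train_ids & test_ids
        assert len(train_ids | test_ids) == 40

    def test_empty_training_group_is_error(self):
        with pytest.raises(ValueError):
            split_cohort(_records([1, 2, 3]), train_fraction=1.0)
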