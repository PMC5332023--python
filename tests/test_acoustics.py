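"""Call feature extraction: envelope, pulses, notes, types, spectra."""

import numpy as np
import pytest

from hyladelim.acoustics import (
    AcousticConfig,
    NoCallDetected,
    NoteSegment,
    classify_call,
    classify_notes,
    detect_pulses,
    extract_call_features,
    extract_envelope,
    read_wav,
    segment_notes,
    spectral_features,
)
from hyladelim.synthetic_data import (
    CallSpec,
    NoteSpec,
    Waveform,
    synthesize_call,
    write_wav,
)

RATE = 44100
BIN_HZ = RATE / 1024  # 43.07 Hz


def _sine(freq=2500.0, dur=0.5, amp=0.8):
    t = np.arange(int(dur * RATE)) / RATE
    return Waveform(samples=amp * np.sin(2 * np.pi * freq * t), rate_hz=RATE)


class TestEnvelope:
    def test_constant_sinusoid_gives_constant_envelope(self):
        env = extract_envelope(_sine(amp=0.8))
        core = env[1000:-1000]
        assert np.all(np.abs(core - 0.8) < 0.02 * 0.8)

    def test_silence_gives_zero(self):
        w = Waveform(samples=np.zeros(RATE // 2), rate_hz=RATE)
        assert np.all(extract_envelope(w) < 1e-12)

    def test_window_longer_than_recording_rejected(self):
        w = Waveform(samples=np.zeros(100), rate_hz=RATE)
        with pytest.raises(ValueError, match="longer than"):
            extract_envelope(w, smooth_ms=50.0)

    def test_pulse_train_has_one_maximum_per_pulse(self, trill_call):
        spec, w = trill_call
        env = extract_envelope(w)
        times = detect_pulses(env, w.rate_hz)
        assert len(times) == spec.notes[0].n_pulses


class TestDetectPulses:
    def test_silence_gives_empty_not_error(self):
        assert detect_pulses(np.zeros(1000), RATE).size == 0

    def test_close_pulses_merged_with_warning(self):
        # two envelope bumps 1 ms apart, below the 2 ms minimum separation
        t = np.arange(int(0.02 * RATE)) / RATE
        env = np.exp(-(((t - 0.010) / 2e-4) ** 2)) + np.exp(
            -(((t - 0.011) / 2e-4) ** 2)
        )
        with pytest.warns(UserWarning, match="merged"):
            times = detect_pulses(env, RATE)
        assert len(times) == 1


class TestSegmentNotes:
    def test_single_note_when_gaps_small(self):
        t = np.arange(10) * 0.008
        notes = segment_notes(t, gap_s=0.02)
        assert len(notes) == 1
        assert notes[0].n_pulses == 10

    def test_gap_splits_notes_and_measures_distance(self):
        t = np.concatenate([np.arange(10) * 0.008, 0.118 + np.arange(4) * 0.007])
        # last pulse of note 1 at 0.072; gap to 0.118 is 0.046
        notes = segment_notes(t, gap_s=0.02)
        assert len(notes) == 2
        dist = notes[1].onset_s - notes[0].offset_s
        assert dist == pytest.approx(0.046, abs=0.008)

    def test_empty_pulse_list_raises_no_call(self):
        with pytest.raises(NoCallDetected):
            segment_notes(np.array([]))

    def test_pulses_inside_note_bounds(self):
        t = np.arange(7) * 0.009
        (note,) = segment_notes(t)
        assert note.onset_s <= t[0] and note.offset_s >= t[-1]


class TestClassification:
    def _note(self, dur, n):
        times = tuple(np.linspace(0.0, dur, n + 2)[1:-1])
        return NoteSegment(onset_s=0.0, offset_s=dur, pulse_times_s=times)

    @pytest.mark.parametrize(
        "dur, n, expected",
        [
            (0.19, 17, "I"),  # long pulsed trill
            (0.03, 4, "II"),  # short secondary note
            (0.06, 8, "I"),  # exactly at both thresholds
            (0.10, 4, "II"),  # long but too few pulses
            (0.03, 12, "II"),  # pulse-rich but too short
        ],
    )
    def test_note_types(self, dur, n, expected):
        (typed,) = classify_notes([self._note(dur, n)])
        assert typed.note_type == expected

    def test_call_type_rules(self):
        one = classify_notes([self._note(0.19, 17)])
        two = classify_notes([self._note(0.03, 4)] * 4)
        mixed = classify_notes(
            [self._note(0.19, 17), self._note(0.03, 4), self._note(0.03, 4)]
        )
        assert classify_call(one) == "advertisement"
        assert classify_call(two) == "aggressive"
        assert classify_call(mixed) == "advertisement"


class TestSpectralFeatures:
    def test_fft_bin_width_is_43_hz(self):
        # 44.1 kHz / 1024-point FFT: the published 43.1 Hz resolution
        assert BIN_HZ == pytest.approx(43.1, abs=0.05)

    def test_pulsed_tone_dominant_within_one_bin(self, trill_call):
        spec, w = trill_call
        env = extract_envelope(w)
        notes = segment_notes(detect_pulses(env, w.rate_hz))
        dominant, _ = spectral_features(w, notes)
        assert abs(dominant - spec.carrier_hz) <= BIN_HZ

    def test_pure_tone_bandwidth_small(self):
        w = _sine(freq=2584.0, dur=0.3)
        notes = [
            NoteSegment(onset_s=0.01, offset_s=0.29, pulse_times_s=(0.15,))
        ]
        _, bw = spectral_features(w, notes)
        # a continuous tone through a Hann window stays within 2 bins at -20 dB
        assert bw <= 2 * BIN_HZ

    def test_call_shorter_than_window_rejected(self):
        w = _sine(dur=0.02)
        notes = [
            NoteSegment(onset_s=0.0, offset_s=0.01, pulse_times_s=(0.005,))
        ]
        with pytest.raises(ValueError, match="FFT window"):
            spectral_features(w, notes)


class TestExtractCallFeatures:
    def test_single_trill_advertisement_round_trip(self, trill_call):
        spec, w = trill_call
        f = extract_call_features(w)
        assert f.n_notes == 1
        assert f.call_type == "advertisement"
        assert f.n_pulses_typeI == 17
        assert f.n_pulses_call == 17
        assert f.typeI_duration_s == pytest.approx(
            0.19, abs=spec.notes[0].pulse_period_s
        )
        assert f.typeII_duration_s is None
        assert f.inter_note_distance_s is None
        assert abs(f.dominant_freq_hz - spec.carrier_hz) <= BIN_HZ

    def test_three_note_call_round_trip(self, two_note_type_call):
        spec, w = two_note_type_call
        f = extract_call_features(w)
        assert f.n_notes == 3
        assert [n.note_type for n in f.notes] == ["I", "II", "II"]
        assert [n.n_pulses for n in f.notes] == [12, 4, 4]
        assert f.call_type == "advertisement"
        assert f.n_pulses_typeII == 4
        assert f.inter_note_distance_s == pytest.approx(0.046, abs=0.008)
        assert abs(f.dominant_freq_hz - 2748.69) <= BIN_HZ

    def test_aggressive_call_round_trip(self):
        spec = CallSpec(
            notes=tuple(NoteSpec(4, 0.033 / 4) for _ in range(4)),
            inter_note_gap_s=0.036,
            carrier_hz=2615.82,
        )
        f = extract_call_features(synthesize_call(spec))
        assert f.n_notes == 4
        assert f.call_type == "aggressive"
        assert f.typeI_duration_s is None

    def test_pulse_counts_exact_across_duties(self):
        for duty in (0.5, 0.7, 0.9):
            spec = CallSpec(
                notes=(
                    NoteSpec(14, 0.008, pulse_duty=duty),
                    NoteSpec(5, 0.007, pulse_duty=duty),
                ),
                inter_note_gap_s=0.04,
                carrier_hz=2600.0,
            )
            f = extract_call_features(synthesize_call(spec))
            assert [n.n_pulses for n in f.notes] == [14, 5]

    def test_rise_time_within_call(self, trill_call):
        _, w = trill_call
        f = extract_call_features(w)
        assert 0 <= f.rise_time_call_s <= f.call_duration_s
        assert 0 <= f.rise_time_typeI_s <= f.typeI_duration_s

    def test_call_duration_bounds_typeI_duration(self, two_note_type_call):
        _, w = two_note_type_call
        f = extract_call_features(w)
        assert f.call_duration_s >= f.typeI_duration_s
        assert f.call_duration_s == pytest.approx(
            f.notes[-1].offset_s - f.notes[0].onset_s
        )

    def test_silence_raises_no_call(self):
        w = Waveform(samples=np.zeros(RATE), rate_hz=RATE)
        with pytest.raises(NoCallDetected):
            extract_call_features(w)

    def test_deterministic(self, trill_call):
        _, w = trill_call
        assert extract_call_features(w) == extract_call_features(w)


class TestWavIO:
    def test_wav_round_trip(self, tmp_path, trill_call):
        _, w = trill_call
        path = tmp_path / "call.wav"
        write_wav(w, path)
        back = read_wav(path)
        assert back.rate_hz == w.rate_hz
        assert np.max(np.abs(back.samples - w.samples)) < 1e-3
        f = extract_call_features(back)
        assert f.n_pulses_call == 17

    def test_multichannel_takes_first_with_warning(self, tmp_path):
        from scipy.io import wavfile

        stereo = np.zeros((RATE // 2, 2), dtype=np.int16)
        t = np.arange(RATE // 2) / RATE
        stereo[:, 0] = (0.5 * np.sin(2 * np.pi * 2500 * t) * 32767).astype(
            np.int16
        )
        path = tmp_path / "stereo.wav"
        wavfile.write(str(path), RATE, stereo)
        with pytest.warns(UserWarning, match="channel"):
            w = read_wav(path)
        assert w.samples.ndim == 1
        assert np.max(np.abs(w.samples)) > 0.4
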