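"""Binary point matching: score traces and peak detections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chorusmatch.matching import ScoreTrace, find_detections, score_template

from conftest import make_spectrogram, make_template


def naive_score(template, survey):
    """Double-loop mean-difference oracle."""
    dur = template.duration_frames
    n_offsets = survey.amplitude.shape[1] - dur + 1
    out = np.zeros(n_offsets)
    on = [(p.freq_bin, p.frame_offset) for p in template.on_points]
    off = [(p.freq_bin, p.frame_offset) for p in template.off_points]
    for t in range(n_offsets):
        mean_on = np.mean([survey.amplitude[b, t + f] for b, f in on])
        if off:
            mean_off = np.mean([survey.amplitude[b, t + f] for b, f in off])
        else:
            mean_off = survey.floor_db
        out[t] = mean_on - mean_off
    return out


def naive_detections(scores, cutoff, min_sep):
    """Independent greedy peak picker: repeatedly take the highest
    remaining peak (earliest on ties), drop peaks within min_sep."""
    peaks = []
    i, n = 0, len(scores)
    while i < n:
        j = i
        while j + 1 < n and scores[j + 1] == scores[i]:
            j += 1
        if (i == 0 or scores[i - 1] < scores[i]) and \
           (j == n - 1 or scores[j + 1] < scores[i]):
            peaks.append(i)
        i = j + 1
    remaining = [p for p in peaks if scores[p] >= cutoff]
    chosen = []
    while remaining:
        best = max(remaining, key=lambda p: (scores[p], -p))
        chosen.append(best)
        remaining = [p for p in remaining if abs(p - best) >= min_sep]
    return sorted(chosen)


def make_trace(scores, hop_s=1.0):
    scores = np.asarray(scores, dtype=float)
    return ScoreTrace(scores=scores, time_axis=np.arange(scores.size) * hop_s,
                      template_name="t", survey_id="s", species="sp")


class TestScoreTemplate:
    def test_uniform_survey_scores_zero(self, rng):
        mask = rng.random((4, 5)) < 0.5
        mask[0, 0] = True   # on set non-empty
        mask[1, 1] = False  # off set non-empty
        template = make_template(mask, first_bin=3)
        survey = make_spectrogram(np.full((12, 20), -17.0))
        trace = score_template(template, survey)
        np.testing.assert_allclose(trace.scores, 0.0, atol=1e-12)

    def test_self_match_attains_maximum(self, rng):
        # score the template against the segment it was binarised from
        amp = -60.0 + 20.0 * rng.random((10, 30))
        amp[3:6, 12:18] = -5.0 + 4.0 * rng.random((3, 6))  # hot call region
        survey = make_spectrogram(amp)
        mask = amp[2:8, 12:18] >= -10.0
        template = make_template(mask, first_bin=2)
        trace = score_template(template, survey)
        assert trace.scores.argmax() == 12

    def test_matches_naive_oracle_on_handbuilt_case(self, rng):
        amp = rng.uniform(-80, 0, size=(3, 4))
        survey = make_spectrogram(amp)
        mask = np.array([[True, False], [False, True], [True, True]])
        template = make_template(mask, first_bin=0)
        trace = score_template(template, survey)
        np.testing.assert_allclose(trace.scores, naive_score(template, survey),
                                   atol=1e-9)

    def test_no_off_points_uses_floor(self):
        template = make_template(np.ones((2, 2), dtype=bool), first_bin=1)
        survey = make_spectrogram(np.full((6, 8), -40.0), floor_db=-120.0)
        trace = score_template(template, survey)
        np.testing.assert_allclose(trace.scores, -40.0 + 120.0)

    def test_parameter_mismatch_errors(self):
        template = make_template(np.ones((2, 2), dtype=bool), first_bin=1,
                                 window_size=512)
        survey = make_spectrogram(np.zeros((6, 8)), window_size=256)
        with pytest.raises(ValueError, match="window_size"):
            score_template(template, survey)

    def test_survey_shorter_than_template_warns_empty(self):
        template = make_template(np.ones((2, 10), dtype=bool), first_bin=1)
        survey = make_spectrogram(np.zeros((6, 4)))
        with pytest.warns(UserWarning, match="shorter"):
            trace = score_template(template, survey)
        assert trace.scores.size == 0

    def test_constant_gain_invariance(self, rng):
        # score is a difference of means: +k dB everywhere cancels
        amp = rng.uniform(-90, 0, size=(8, 25))
        mask = rng.random((4, 6)) < 0.4
        mask[0, 0], mask[1, 1] = True, False
        template = make_template(mask, first_bin=2)
        base = score_template(template, make_spectrogram(amp)).scores
        shifted = score_template(template, make_spectrogram(amp + 7.5)).scores
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_translation_equivariance(self, rng):
        amp = rng.uniform(-70, -10, size=(8, 30))
        mask = rng.random((4, 5)) < 0.5
        mask[0, 0], mask[1, 1] = True, False
        template = make_template(mask, first_bin=2)
        pad = 7
        padded = np.concatenate([np.full((8, pad), -40.0), amp], axis=1)
        t0 = score_template(template, make_spectrogram(amp))
        t1 = score_template(template, make_spectrogram(padded))
        hop_s = 512 / 22050
        d0 = find_detections(t0, 3.0, 3)
        d0_shifted = [round(d.time + pad * hop_s, 9) for d in d0]
        d1 = find_detections(t1, 3.0, 3)
        d1_times = [round(d.time, 9) for d in d1 if d.time >= pad * hop_s - 1e-9]
        assert d0_shifted == d1_times


class TestFindDetections:
    def test_cutoff_above_max_gives_empty(self):
        trace = make_trace([1.0, 5.0, 2.0])
        assert find_detections(trace, 6.0, 1) == []

    def test_plateau_reports_first_frame(self):
        trace = make_trace([0, 4.0, 4.0, 4.0, 0])
        dets = find_detections(trace, 3.0, 1)
        assert len(dets) == 1
        assert dets[0].time == 1.0

    def test_equal_peaks_within_separation_earlier_wins(self):
        trace = make_trace([0, 5.0, 0, 5.0, 0])
        dets = find_detections(trace, 3.0, 3)
        assert [d.time for d in dets] == [1.0]

    def test_scores_at_least_cutoff(self):
        trace = make_trace([0, 3.5, 0, 2.9, 0, 7.0, 0])
        dets = find_detections(trace, 3.0, 1)
        assert all(d.score >= 3.0 for d in dets)
        assert [d.time for d in dets] == [1.0, 5.0]

    def test_min_separation_must_be_positive(self):
        with pytest.raises(ValueError, match="min_separation"):
            find_detections(make_trace([1.0]), 0.0, 0)

    def test_twenty_point_hand_trace_matches_oracle(self):
        scores = [0, 1, 4, 1, 0, 5, 6, 5, 0, 3, 3, 3, 0, 8, 0, 4, 0, 2, 9, 1]
        trace = make_trace(scores)
        got = [int(d.time) for d in find_detections(trace, 3.0, 2)]
        assert got == naive_detections(np.array(scores, float), 3.0, 2)

    @given(
        scores=st.lists(
            st.integers(min_value=-5, max_value=12).map(float),
            min_size=1, max_size=40,
        ),
        cutoff=st.integers(min_value=0, max_value=8).map(float),
        min_sep=st.integers(min_value=1, max_value=6),
    )
    def test_matches_enumeration_oracle(self, scores, cutoff, min_sep):
        trace = make_trace(scores)
        got = [int(d.time) for d in find_detections(trace, cutoff, min_sep)]
        assert got == naive_detections(np.array(scores), cutoff, min_sep)

    @given(
        scores=st.lists(
            st.floats(min_value=-5, max_value=12, allow_nan=False),
            min_size=1, max_size=40,
        ),
        min_sep=st.integers(min_value=1, max_value=5),
    )
    def test_count_monotone_in_cutoff(self, scores, min_sep):
        trace = make_trace(scores)
        counts = [
            len(find_detections(trace, c, min_sep))
            for c in np.linspace(-5, 12, 10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_random_pairs_match_oracles(rng):
    """Randomised cross-check of both the scorer and the peak picker."""
    for _ in range(30):
        n_bins = int(rng.integers(3, 12))
        n_frames = int(rng.integers(6, 30))
        dur = int(rng.integers(2, min(6, n_frames)))
        first_bin = int(rng.integers(0, 3))
        amp = rng.uniform(-90, 0, size=(n_bins + 4, n_frames))
        mask = rng.random((n_bins, dur)) < 0.5
        mask[0, 0] = True
        template = make_template(mask, first_bin=first_bin)
        survey = make_spectrogram(amp)
        trace = score_template(template, survey)
        np.testing.assert_allclose(trace.scores, naive_score(template, survey),
                                   atol=1e-9)
        got = [
            int(round(d.time / (512 / 22050)))
            for d in find_detections(trace, 3.0, 2)
        ]
        assert got == naive_detections(trace.scores, 3.0, 2)
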