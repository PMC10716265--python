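"""Labeling, windowing, validity rules, AF-free interval selection and
cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from afhorizon.annotate import (AGE_GROUPS, ARTIFACT_EXCESS, LOW_HR,
                                SPARSE_R, age_group_of, assemble_cohorts,
                                label_recording, segment_windows,
                                select_af_free_interval, window_is_valid)
from afhorizon.rhythms import AF, ARTIFACT, SINUS
from afhorizon.simulate import AnnotatedRecording, RhythmEpisode, SimProfile

FS = 100.0
WIN = int(600 * FS)


def _episodes(*spans):
    """spans: (length_samples, rhythm) tuples tiling from 0."""
    eps, cur = [], 0
    for n, r in spans:
        eps.append(RhythmEpisode(cur, cur + n, r))
        cur += n
    return eps


def _ann(duration_s, episodes, beat_times, beat_types=None, fs=FS):
    bt = np.asarray(beat_times, float)
    ty = (np.zeros(bt.size, np.int8) if beat_types is None
          else np.asarray(beat_types, np.int8))
    return AnnotatedRecording("R0", fs, duration_s, SimProfile(), 0,
                              bt, ty, np.full(bt.size, SINUS, object),
                              episodes)


class TestLabelRecording:
    def test_af_under_30s_is_negative(self):
        day = int(86400 * FS)
        n_af = int(29 * FS)
        eps = _episodes((1000, SINUS), (n_af, AF),
                        (day - 1000 - n_af, SINUS))
        lab = label_recording(eps, FS)
        assert not lab.af_positive
        assert lab.af_burden == n_af / day

    def test_af_over_30s_is_positive(self):
        day = int(86400 * FS)
        n_af = int(31 * FS)
        eps = _episodes((1000, SINUS), (n_af, AF),
                        (day - 1000 - n_af, SINUS))
        assert label_recording(eps, FS).af_positive

    def test_burden_over_70pct_is_persistent(self):
        n = int(3600 * FS)
        eps = _episodes((int(0.75 * n), AF), (n - int(0.75 * n), SINUS))
        lab = label_recording(eps, FS)
        assert lab.excluded_persistent
        assert lab.af_positive

    def test_structural_errors(self):
        with pytest.raises(ValueError):
            label_recording([], FS)
        with pytest.raises(ValueError):
            label_recording([RhythmEpisode(0, 100, SINUS),
                             RhythmEpisode(50, 200, AF)], FS)
        with pytest.raises(ValueError):
            label_recording([RhythmEpisode(10, 100, SINUS)], FS)


class TestSegmentWindows:
    @pytest.mark.parametrize("interval_s,expected", [
        (86400, 144), (3600, 6), (600, 1), (1500, 2)])
    def test_window_counts(self, interval_s, expected):
        n = int(86400 * FS)
        wins = segment_windows("R0", FS, n, 0, interval_s)
        assert len(wins) == expected
        # tiling: contiguous, non-overlapping
        for i, w in enumerate(wins):
            assert w.start == i * WIN and w.length == WIN

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            segment_windows("R0", FS, WIN, 0, 1200)


class TestWindowValidity:
    def _sinus_600(self):
        return _episodes((WIN, SINUS))

    def test_19_bpm_window_fails_low_hr_only(self):
        beats = np.round(np.linspace(0, WIN - 1, 190)).astype(int)
        ok, reasons = window_is_valid(beats, self._sinus_600(), 0, FS)
        assert not ok and reasons == {LOW_HR}

    def test_121s_artifact_fails_artifact_excess_only(self):
        art0, art1 = int(100 * FS), int(221 * FS)
        eps = _episodes((art0, SINUS), (art1 - art0, ARTIFACT),
                        (WIN - art1, SINUS))
        beats = (np.arange(600) * FS).astype(int)
        beats = beats[(beats < art0) | (beats >= art1)]
        ok, reasons = window_is_valid(beats, eps, 0, FS)
        assert not ok and reasons == {ARTIFACT_EXCESS}

    def test_59_peaks_fails_sparse_r_only(self):
        beats = (np.arange(59) * FS).astype(int)  # 1-s spacing, HR 60
        ok, reasons = window_is_valid(beats, self._sinus_600(), 0, FS)
        assert not ok and reasons == {SPARSE_R}

    def test_long_gap_fails_sparse_r(self):
        # 100 beats, then silence > 30 s, then beats again
        beats = np.concatenate([np.arange(100), 140 + np.arange(400)])
        beats = (beats * FS).astype(int)
        ok, reasons = window_is_valid(beats, self._sinus_600(), 0, FS)
        assert not ok and SPARSE_R in reasons

    def test_clean_window_passes(self):
        beats = (np.arange(600) * FS).astype(int)
        ok, reasons = window_is_valid(beats, self._sinus_600(), 0, FS)
        assert ok and reasons == frozenset()

    def test_injected_artifact_flips_exactly_artifact_excess(self):
        beats = (np.arange(600) * FS).astype(int)
        base = window_is_valid(beats, self._sinus_600(), 0, FS)
        art0, art1 = int(200 * FS), int(321 * FS)
        eps = _episodes((art0, SINUS), (art1 - art0, ARTIFACT),
                        (WIN - art1, SINUS))
        beats2 = beats[(beats < art0) | (beats >= art1)]
        injected = window_is_valid(beats2, eps, 0, FS)
        assert base == (True, frozenset())
        assert injected == (False, frozenset({ARTIFACT_EXCESS}))


class TestIntervalSelection:
    def _beats_everywhere(self, duration_s, skip_spans=()):
        t = np.arange(0.5, duration_s, 1.0)
        for a, b in skip_spans:
            t = t[(t < a) | (t >= b)]
        return t

    def test_af_free_record_starts_at_zero(self):
        dur = 6 * 3600
        ann = _ann(dur, _episodes((int(dur * FS), SINUS)),
                   self._beats_everywhere(dur))
        assert select_af_free_interval(ann, 3600) == 0

    def test_af_in_every_window_returns_none(self):
        dur = 4 * 3600
        spans = []
        cur = 0
        # 40 s of AF at the head of every 10-min window
        while cur < dur:
            spans += [(int(40 * FS), AF), (int(560 * FS), SINUS)]
            cur += 600
        ann = _ann(dur, _episodes(*spans), self._beats_everywhere(dur))
        assert select_af_free_interval(ann, 3600) is None

    def test_target_longer_than_record_returns_none(self):
        dur = 1800
        ann = _ann(dur, _episodes((int(dur * FS), SINUS)),
                   self._beats_everywhere(dur))
        assert select_af_free_interval(ann, 3600) is None

    def _artifact_then_clean(self):
        """First hour poisoned by a >2-min artifact in each window, second
        hour clean."""
        dur = 2 * 3600
        spans = []
        art_spans = []
        for w in range(6):
            a = w * 600 + 100
            spans += [(int(100 * FS), SINUS), (int(130 * FS), ARTIFACT),
                      (int(370 * FS), SINUS)]
            art_spans.append((a, a + 130))
        spans.append((int(3600 * FS), SINUS))
        ann = _ann(dur, _episodes(*spans),
                   self._beats_everywhere(dur, art_spans))
        return ann

    def test_skips_artifact_hour(self):
        ann = self._artifact_then_clean()
        start = select_af_free_interval(ann, 3600)
        assert start == int(3600 * FS)

    def test_earliest_policy_matches_exhaustive_scan(self):
        ann = self._artifact_then_clean()
        # oracle: try every grid start, re-checking AF overlap and validity
        from afhorizon.annotate import window_is_valid as wiv
        fs = ann.fs
        win = int(600 * fs)
        bs = np.round(ann.beat_times * fs).astype(np.int64)
        k = 6
        n_win = ann.n_samples // win
        expected = None
        for s in range(n_win - k + 1):
            good = True
            for w in range(s, s + k):
                a, b = w * win, (w + 1) * win
                af = any(ep.rhythm == AF and ep.start < b and ep.end > a
                         for ep in ann.episodes)
                if af or not wiv(bs, ann.episodes, a, fs)[0]:
                    good = False
                    break
            if good:
                expected = s * win
                break
        assert select_af_free_interval(ann, 3600) == expected

    def test_selected_interval_has_zero_af_samples(self):
        dur = 4 * 3600
        spans = [(int(700 * FS), SINUS), (int(400 * FS), AF),
                 (int((dur - 1100) * FS), SINUS)]
        ann = _ann(dur, _episodes(*spans),
                   self._beats_everywhere(dur, [(700, 1100)]))
        start = select_af_free_interval(ann, 3600)
        assert start is not None
        end = start + int(3600 * FS)
        for ep in ann.episodes:
            if ep.rhythm == AF:
                assert ep.end <= start or ep.start >= end


class TestAgeGroups:
    @pytest.mark.parametrize("age,group", [
        (18, "18-54"), (54.9, "18-54"), (55, "55-64"), (64.5, "55-64"),
        (65, "65-74"), (75, "75-84"), (85, "85-99"), (99, "85-99")])
    def test_mapping(self, age, group):
        assert age_group_of(age) == group

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            age_group_of(17)
        with pytest.raises(ValueError):
            age_group_of(100)


def _manifest(n_per_group, prevalence, seed):
    rng = np.random.default_rng(seed)
    rows = []
    mids = {"18-54": 40, "55-64": 60, "65-74": 70, "75-84": 80, "85-99": 90}
    i = 0
    for g in AGE_GROUPS:
        for _ in range(n_per_group):
            rows.append({"record_id": f"R{i:05d}", "age": mids[g],
                         "af_positive": bool(rng.random() < prevalence)})
            i += 1
    return pd.DataFrame(rows)


class TestAssembleCohorts:
    def test_split_disjoint_and_deterministic(self):
        man = _manifest(400, 0.10, 0)
        a = assemble_cohorts(man, 50, 50, seed=4, per_group_calibration=50,
                             test_total=200)
        b = assemble_cohorts(man, 50, 50, seed=4, per_group_calibration=50,
                             test_total=200)
        assert a.equals(b)
        for s1 in ("TRAIN", "CALIBRATION", "TEST"):
            for s2 in ("TRAIN", "CALIBRATION", "TEST"):
                if s1 != s2:
                    ids1 = set(a.loc[a["split"] == s1, "record_id"])
                    ids2 = set(a.loc[a["split"] == s2, "record_id"])
                    assert not ids1 & ids2

    def test_enrichment_reaches_half_prevalence(self):
        man = _manifest(2000, 0.05, 1)
        out = assemble_cohorts(man, 60, 60, seed=2,
                               per_group_calibration=60, test_total=500)
        merged = out.merge(man, on="record_id")
        train = merged[merged["split"] == "TRAIN"]
        assert 0.40 < train["af_positive"].mean() < 0.60
        calib = merged[merged["split"] == "CALIBRATION"]
        assert calib["af_positive"].mean() < 0.15  # natural prevalence

    def test_no_af_available_means_random_only(self):
        man = _manifest(300, 0.0, 2)
        out = assemble_cohorts(man, 40, 40, seed=3,
                               per_group_calibration=40, test_total=100)
        train = out[out["split"] == "TRAIN"]
        assert len(train) == 40 * len(AGE_GROUPS)

    def test_insufficient_subjects_rejected(self):
        man = _manifest(30, 0.1, 3)
        with pytest.raises(ValueError):
            assemble_cohorts(man, 40, 0, seed=0)
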