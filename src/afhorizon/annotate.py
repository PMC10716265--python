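"""Recording-level labeling, windowing, validity rules and cohort assembly.

Outcome definition: a recording is AF-positive when it contains at least one
AF episode lasting more than 30 s; recordings whose AF burden exceeds 70%
are treated as persistent/near-persistent AF and excluded from modelling.
Analysis proceeds over contiguous, non-overlapping 10-minute windows taken
from an AF-free interval; a window is usable only if it passes three
independent signal-quality rules (mean heart rate at least 20 bpm, no more
than 2 minutes of artifact, R peaks neither too few nor too sparse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rhythms import AF, ARTIFACT
from .simulate import AnnotatedRecording, RhythmEpisode

__all__ = [
    "RecordingLabel", "Window", "ValidityConfig", "AGE_GROUPS",
    "age_group_of", "label_recording", "segment_windows", "window_is_valid",
    "select_af_free_interval", "assemble_cohorts",
    "LOW_HR", "ARTIFACT_EXCESS", "SPARSE_R", "WINDOW_S",
]

WINDOW_S = 600.0

LOW_HR = "LOW_HR"
ARTIFACT_EXCESS = "ARTIFACT_EXCESS"
SPARSE_R = "SPARSE_R"

AF_EPISODE_MIN_S = 30.0     # outcome rule: episodes must persist > 30 s
PERSISTENT_BURDEN = 0.70    # exclusion rule: burden above 70% is persistent AF

#: Age groups used for per-group models and calibration.
AGE_GROUPS = ("18-54", "55-64", "65-74", "75-84", "85-99")
_AGE_EDGES = (18, 55, 65, 75, 85, 100)


def age_group_of(age: float) -> str:
    if not (18 <= age <= 99):
        raise ValueError(f"age {age} outside supported range [18, 99]")
    for name, lo, hi in zip(AGE_GROUPS, _AGE_EDGES[:-1], _AGE_EDGES[1:]):
        if lo <= age < hi:
            return name
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class RecordingLabel:
    af_positive: bool
    af_burden: float
    excluded_persistent: bool


@dataclass(frozen=True)
class Window:
    record_id: str
    start: int            # sample, inclusive
    length: int           # samples (600 s * fs)
    valid: bool = True
    invalid_reasons: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class ValidityConfig:
    """Quantified signal-quality thresholds.

    The sparse-R rule ("too few or too sparse") is quantified as fewer than
    ``min_r_peaks`` usable peaks per window or any non-artifact inter-peak
    gap longer than ``max_gap_s``; the mean heart rate is computed from the
    inter-peak intervals so the three rules stay independent.
    """

    min_mean_hr_bpm: float = 20.0
    max_artifact_s: float = 120.0
    min_r_peaks: int = 60
    max_gap_s: float = 30.0


def _check_partition(episodes: list[RhythmEpisode]):
    if not episodes:
        raise ValueError("episode list is empty")
    cur = episodes[0].start
    if cur != 0:
        raise ValueError("episodes must start at sample 0")
    for ep in episodes:
        if ep.start != cur or ep.end <= ep.start:
            raise ValueError("episodes must form a non-overlapping cover")
        cur = ep.end
    return cur


def label_recording(episodes: list[RhythmEpisode], fs: float) -> RecordingLabel:
    """Apply the outcome (>30 s AF) and persistence (>70% burden) rules.

    Episodes of any length count toward burden; only episodes persisting
    more than 30 s make the recording AF-positive.
    """
    total = _check_partition(episodes)
    af_samples = sum(ep.n_samples for ep in episodes if ep.rhythm == AF)
    af_positive = any(ep.rhythm == AF and ep.n_samples > AF_EPISODE_MIN_S * fs
                      for ep in episodes)
    burden = af_samples / total
    return RecordingLabel(af_positive, burden, burden > PERSISTENT_BURDEN)


def segment_windows(record_id: str, fs: float, n_samples: int,
                    interval_start: int, interval_len_s: float) -> list[Window]:
    """Tile an interval into contiguous 10-minute windows (remainder dropped)."""
    win = int(round(WINDOW_S * fs))
    k = int(interval_len_s // WINDOW_S)
    if interval_start < 0 or interval_start + int(round(interval_len_s * fs)) > n_samples:
        raise ValueError("interval exceeds record bounds")
    return [Window(record_id, interval_start + i * win, win) for i in range(k)]


def _artifact_overlap_s(episodes, a: int, b: int, fs: float) -> float:
    o = 0
    for ep in episodes:
        if ep.rhythm == ARTIFACT:
            o += max(0, min(ep.end, b) - max(ep.start, a))
    return o / fs


def window_is_valid(beat_samples: np.ndarray, episodes: list[RhythmEpisode],
                    window_start: int, fs: float,
                    config: ValidityConfig | None = None):
    """Evaluate the three independent validity rules for one 10-min window.

    ``beat_samples`` are detected R-peak sample indices (any beat type);
    peaks inside artifact segments are not counted as usable, and artifact
    time is subtracted from inter-peak gaps before the sparsity check.
    Returns ``(valid, frozenset(reasons))``.
    """
    cfg = config or ValidityConfig()
    win = int(round(WINDOW_S * fs))
    a, b = int(window_start), int(window_start) + win
    beats = np.asarray(beat_samples)
    beats = beats[(beats >= a) & (beats < b)]
    reasons = set()

    art_mask_edges = [(max(ep.start, a), min(ep.end, b)) for ep in episodes
                      if ep.rhythm == ARTIFACT and ep.start < b and ep.end > a]
    art_s = sum((e - s) for s, e in art_mask_edges) / fs
    if art_s > cfg.max_artifact_s:
        reasons.add(ARTIFACT_EXCESS)

    usable = beats
    for s, e in art_mask_edges:
        usable = usable[(usable < s) | (usable >= e)]

    # mean HR from inter-peak intervals (artifact-free)
    if usable.size >= 2:
        mean_rr_s = float(np.mean(np.diff(usable))) / fs
        if 60.0 / mean_rr_s < cfg.min_mean_hr_bpm:
            reasons.add(LOW_HR)
    else:
        reasons.add(LOW_HR)

    sparse = usable.size < cfg.min_r_peaks
    if not sparse:
        pts = np.concatenate(([a], usable, [b]))
        gaps = np.diff(pts) / fs
        for i in np.nonzero(gaps > cfg.max_gap_s)[0]:
            gap = gaps[i] - _artifact_overlap_s(episodes, int(pts[i]),
                                                int(pts[i + 1]), fs)
            if gap > cfg.max_gap_s:
                sparse = True
                break
    if sparse:
        reasons.add(SPARSE_R)
    return (len(reasons) == 0, frozenset(reasons))


def _grid_flags(ann: AnnotatedRecording, config: ValidityConfig | None):
    """(af_free, valid) flags for every grid-aligned 10-min window."""
    fs = ann.fs
    win = int(round(WINDOW_S * fs))
    n_win = ann.n_samples // win
    beat_samples = np.round(ann.beat_times * fs).astype(np.int64)
    af_free = np.ones(n_win, bool)
    for ep in ann.episodes:
        if ep.rhythm == AF:
            i0 = ep.start // win
            i1 = min((ep.end - 1) // win, n_win - 1)
            af_free[i0:i1 + 1] = False
    valid = np.zeros(n_win, bool)
    edges = np.searchsorted(beat_samples, np.arange(n_win + 1) * win)
    for i in range(n_win):
        beats_i = beat_samples[edges[i]:edges[i + 1]]
        valid[i] = window_is_valid(beats_i, ann.episodes, i * win, fs,
                                   config)[0]
    return af_free, valid


def select_af_free_interval(ann: AnnotatedRecording, target_len_s: float,
                            policy: str = "earliest",
                            config: ValidityConfig | None = None,
                            rng: np.random.Generator | None = None):
    """Find an interval with zero AF samples whose every window is valid.

    The search is over grid-aligned window starts (multiples of 600 s).
    ``policy`` is ``"earliest"`` (default, deterministic and label-blind) or
    ``"random"`` (uniform over qualifying starts, requires ``rng``).
    Returns the start sample, or ``None`` if the recording cannot contribute
    at this length.
    """
    if target_len_s > ann.duration_s:
        return None
    k = int(target_len_s // WINDOW_S)
    if k < 1:
        raise ValueError("target length must be at least 600 s")
    af_free, valid = _grid_flags(ann, config)
    good = af_free & valid
    run = 0
    starts = []
    for i, g in enumerate(good):
        run = run + 1 if g else 0
        if run >= k:
            starts.append(i - k + 1)
    if not starts:
        return None
    win = int(round(WINDOW_S * ann.fs))
    if policy == "earliest":
        return starts[0] * win
    if policy == "random":
        if rng is None:
            raise ValueError("random policy requires an rng")
        return int(rng.choice(starts)) * win
    raise ValueError(f"unknown policy {policy!r}")


def assemble_cohorts(manifest: pd.DataFrame, per_group_random: int,
                     per_group_af_extra: int, seed: int,
                     per_group_calibration: int | None = None,
                     test_total: int | None = None) -> pd.DataFrame:
    """Two-stage enriched training draw plus natural-prevalence calibration
    and test cohorts, subject-disjoint, per age group.

    For each age group, ``per_group_random`` recordings are drawn at random
    for training, then up to ``per_group_af_extra`` additional AF-positive
    recordings (or all that remain) are added, so that with a rare outcome
    the training prevalence approaches 50%. Calibration draws
    ``per_group_calibration`` per group (default: equal to the random draw)
    from the remainder, at natural prevalence; the test cohort draws
    ``test_total`` (default: whatever remains) at random from the rest.

    ``manifest`` must carry ``record_id``, ``age`` and ``af_positive``
    columns and must already exclude persistent-AF recordings.

    Returns a frame with ``record_id``, ``age_group`` and ``split`` in
    {TRAIN, CALIBRATION, TEST}; unassigned recordings are omitted.
    """
    if per_group_calibration is None:
        per_group_calibration = per_group_random
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(77,)))
    df = manifest.copy()
    df["age_group"] = [age_group_of(a) for a in df["age"]]
    assigned = {}
    remaining_ids = set(df["record_id"])

    for group in AGE_GROUPS:
        g = df[(df["age_group"] == group)
               & df["record_id"].isin(remaining_ids)]
        ids = g["record_id"].to_numpy()
        if ids.size < per_group_random:
            raise ValueError(f"not enough recordings in age group {group}")
        train = set(rng.choice(ids, per_group_random, replace=False))
        af_pool = g[~g["record_id"].isin(train) & g["af_positive"]]
        n_extra = min(per_group_af_extra, len(af_pool))
        if n_extra > 0:
            train |= set(rng.choice(af_pool["record_id"].to_numpy(),
                                    n_extra, replace=False))
        for rid in train:
            assigned[rid] = (group, "TRAIN")
        remaining_ids -= train

        pool = df[(df["age_group"] == group)
                  & df["record_id"].isin(remaining_ids)]
        if len(pool) < per_group_calibration:
            raise ValueError(f"not enough recordings left for calibration "
                             f"in age group {group}")
        calib = set(rng.choice(pool["record_id"].to_numpy(),
                               per_group_calibration, replace=False))
        for rid in calib:
            assigned[rid] = (group, "CALIBRATION")
        remaining_ids -= calib

    rest = df[df["record_id"].isin(remaining_ids)]
    n_test = len(rest) if test_total is None else test_total
    if n_test > len(rest):
        raise ValueError("not enough recordings left for the test cohort")
    test = rng.choice(rest["record_id"].to_numpy(), n_test, replace=False)
    for rid in test:
        assigned[rid] = (df.loc[df["record_id"] == rid, "age_group"].iloc[0],
                         "TEST")

    out = pd.DataFrame(
        [{"record_id": rid, "age_group": grp, "split": split}
         for rid, (grp, split) in assigned.items()])
    return out.sort_values("record_id").reset_index(drop=True)
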