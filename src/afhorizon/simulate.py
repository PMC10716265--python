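"""Seeded synthetic ambulatory single-lead ECG cohorts.

The generator produces annotated multi-hour to multi-day recordings with
paroxysmal AF episodes, ectopic beats (PACs/PVCs), other abnormal rhythms,
artifact segments, and a latent subject-level association between AF-prone
status and the statistics of the AF-free signal (elevated PAC rate, altered
heart-rate variability, subtle P/T morphology shift), so that predicting
near-term AF from AF-free windows is a learnable problem.

Simulation is layered:

* :func:`simulate_annotations` builds the cheap annotation-level recording
  (rhythm-episode partition + beat train) for the full duration;
* :mod:`afhorizon.waveform` renders the voltage trace lazily for any sample
  span, so cohort pipelines only ever synthesise the windows they analyse;
* :func:`simulate_recording` composes the two into a fully materialised
  record for interactive use and testing.

All randomness flows from one integer seed through ``np.random.SeedSequence``
spawn keys, so any sub-stream (a subject, a rhythm family, the noise) is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import waveform
from .rhythms import AF, ARTIFACT, AVB, SINUS, SVT

__all__ = [
    "SimProfile", "ECGRecord", "BeatAnnotation", "RhythmEpisode",
    "AnnotatedRecording", "CohortConfig", "simulate_annotations",
    "simulate_recording", "simulate_cohort", "profile_from_row",
    "BURDEN_STRATA",
]

BEAT_CODES = {0: "N", 1: "PAC", 2: "PVC"}
BEAT_N, BEAT_PAC, BEAT_PVC = 0, 1, 2

#: AF-burden strata bounds (fractions): low < 1%, medium 1-10%, high > 10%
BURDEN_STRATA = {"low": (0.0, 0.01), "medium": (0.01, 0.10), "high": (0.10, 1.0)}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class SimProfile:
    """Subject-level generative parameters.

    Rates are per hour (ectopics) or per day (episodes); ``morphology_shift``
    in [0, 1] scales the subtle P/T template perturbation applied to normal
    beats outside AF for AF-prone subjects.
    """

    mean_rr: float = 0.85            # s
    sdnn_target: float = 0.05        # s
    rsa_depth: float = 0.4           # [0, 1]
    pac_rate: float = 2.0            # events / hour
    pvc_rate: float = 1.0            # events / hour
    af_episode_rate: float = 0.0     # episodes / day
    af_episode_duration: tuple[float, float] = (300.0, 0.6)  # (median s, log-sd)
    artifact_rate: float = 4.0       # segments / day
    artifact_duration: float = 40.0  # median s
    morphology_shift: float = 0.0    # [0, 1]
    svt_rate: float = 0.0            # episodes / day
    avb_rate: float = 0.0            # episodes / day
    age: float = 60.0                # years
    sex: str = "F"

    def __post_init__(self):
        if not (0.3 <= self.mean_rr <= 2.0):
            raise ValueError("mean_rr must be in [0.3, 2.0] s")
        for name in ("sdnn_target", "pac_rate", "pvc_rate", "af_episode_rate",
                     "artifact_rate", "svt_rate", "avb_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.rsa_depth <= 1.0 and 0.0 <= self.morphology_shift <= 1.0):
            raise ValueError("rsa_depth and morphology_shift must be in [0, 1]")
        if not (18 <= self.age <= 99):
            raise ValueError("age must be in [18, 99]")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


@dataclass(frozen=True)
class BeatAnnotation:
    sample_index: int
    beat_type: str  # N, PAC, PVC


@dataclass(frozen=True)
class RhythmEpisode:
    start: int      # sample, inclusive
    end: int        # sample, exclusive
    rhythm: str

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class ECGRecord:
    record_id: str
    signal: np.ndarray  # mV
    fs: float
    duration_s: float
    age: float
    sex: str

    def __post_init__(self):
        if int(round(self.duration_s * self.fs)) != self.signal.shape[0]:
            raise ValueError("duration * fs must equal the sample count")


@dataclass
class AnnotatedRecording:
    """Annotation-level recording with lazy waveform rendering."""

    record_id: str
    fs: float
    duration_s: float
    profile: SimProfile
    seed: int
    beat_times: np.ndarray    # seconds, strictly increasing
    beat_types: np.ndarray    # int8 codes (0 N, 1 PAC, 2 PVC)
    beat_rhythms: np.ndarray  # rhythm label per beat (object array of str)
    episodes: list[RhythmEpisode]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def render(self, start: int | None = None, stop: int | None = None) -> np.ndarray:
        return waveform.render_span(
            self, 0 if start is None else int(start),
            self.n_samples if stop is None else int(stop))

    def beat_annotations(self) -> list[BeatAnnotation]:
        idx = np.round(self.beat_times * self.fs).astype(np.int64)
        return [BeatAnnotation(int(i), BEAT_CODES[int(t)])
                for i, t in zip(idx, self.beat_types)]

    def af_burden(self) -> float:
        af = sum(ep.n_samples for ep in self.episodes if ep.rhythm == AF)
        return af / self.n_samples

    def trimmed(self, start: int, stop: int, margin_s: float = 2.0):
        """Copy keeping only beats near [start, stop); rendering of spans
        inside the kept region is unchanged (noise streams are positional)."""
        lo, hi = start / self.fs - margin_s, stop / self.fs + margin_s
        sel = (self.beat_times >= lo) & (self.beat_times <= hi)
        return replace(
            self, beat_times=self.beat_times[sel].copy(),
            beat_types=self.beat_types[sel].copy(),
            beat_rhythms=self.beat_rhythms[sel].copy())


# ---------------------------------------------------------------------------
# episode timeline
# ---------------------------------------------------------------------------

def _draw_episodes(rng, rate_per_day, duration_s, dur_sampler):
    n = rng.poisson(rate_per_day * duration_s / 86400.0)
    starts = np.sort(rng.uniform(0.0, duration_s, n))
    durs = dur_sampler(rng, n)
    return list(zip(starts, durs))


def _af_renewal(profile: SimProfile, duration_s: float, rng) -> list[tuple]:
    """AF episodes as an alternating renewal process.

    Sinus gaps are exponential and episode durations log-normal, with the
    mean cycle length set to 86400 / af_episode_rate, so the expected AF
    burden equals ``rate * mean_duration / 86400`` without the thinning
    bias a rejection scheme would introduce at high rates.
    """
    rate = profile.af_episode_rate
    if rate <= 0:
        return []
    med, sd = profile.af_episode_duration
    mean_dur = med * math.exp(sd ** 2 / 2)
    mean_gap = max(86400.0 / rate - mean_dur, 1.0)
    out = []
    t = rng.exponential(mean_gap)
    while t < duration_s:
        d = math.exp(rng.normal(math.log(med), sd))
        e = min(t + d, duration_s)
        if e - t >= 2.0:
            out.append((t, e, AF))
        t = e + rng.exponential(mean_gap)
    return out


def _place_episodes(profile: SimProfile, duration_s: float, rng) -> list[tuple]:
    """Non-overlapping (start_s, end_s, rhythm) intervals; gaps are sinus.

    AF episodes come first from the renewal process; SVT/AVB and artifact
    segments are then placed by rejection against everything already
    accepted, so the AF process is unperturbed by the others.
    """
    families = [
        (SVT, profile.svt_rate,
         lambda r, n: np.exp(r.normal(math.log(30.0), 0.5, n))),
        (AVB, profile.avb_rate,
         lambda r, n: np.exp(r.normal(math.log(60.0), 0.5, n))),
        (ARTIFACT, profile.artifact_rate,
         lambda r, n: np.exp(r.normal(math.log(profile.artifact_duration), 0.5, n))),
    ]
    accepted: list[tuple] = list(_af_renewal(profile, duration_s, rng))
    for rhythm, rate, sampler in families:
        for s, d in _draw_episodes(rng, rate, duration_s, sampler):
            e = min(s + d, duration_s)
            if e - s < 2.0:
                continue
            if any(s < b and a < e for a, b, _ in accepted):
                continue
            accepted.append((s, e, rhythm))
    accepted.sort()
    return accepted


def _episode_partition(accepted, duration_s, fs) -> list[RhythmEpisode]:
    n = int(round(duration_s * fs))
    bounds = [0]
    labels = []
    cur = 0
    for s, e, rhythm in accepted:
        a, b = int(round(s * fs)), int(round(e * fs))
        a, b = max(a, cur), min(b, n)
        if b <= a:
            continue
        if a > cur:
            bounds.append(a)
            labels.append(SINUS)
        bounds.append(b)
        labels.append(rhythm)
        cur = b
    if cur < n:
        bounds.append(n)
        labels.append(SINUS)
    return [RhythmEpisode(bounds[i], bounds[i + 1], labels[i])
            for i in range(len(labels))]


# ---------------------------------------------------------------------------
# beat train
# ---------------------------------------------------------------------------

_AR_PHI = 0.85          # lag-1 coefficient of the sinus RR AR(1) process
_RESP_FREQ = 0.25       # Hz, respiratory sinus arrhythmia
_AF_MEAN_FACTOR = 0.80  # AF is faster on average
_AF_CV = 0.25           # coefficient of variation of AF RR


def _sinus_rr(profile: SimProfile, n: int, rng) -> np.ndarray:
    """Autocorrelated sinus RR: AR(1) + respiratory modulation."""
    rsa_var = 0.5 * profile.rsa_depth * profile.sdnn_target ** 2
    ar_var = max(profile.sdnn_target ** 2 - rsa_var, 0.0)
    sig_e = math.sqrt(ar_var * (1 - _AR_PHI ** 2))
    warm = 50
    e = rng.normal(0.0, sig_e, n + warm)
    x = lfilter([1.0], [1.0, -_AR_PHI], e)[warm:]
    amp = math.sqrt(2.0 * rsa_var)
    phase = rng.uniform(0, 2 * math.pi)
    rsa = amp * np.sin(2 * math.pi * _RESP_FREQ * profile.mean_rr * np.arange(n) + phase)
    rr = profile.mean_rr + x + rsa
    return np.clip(rr, max(0.25, 0.5 * profile.mean_rr), 2.2 * profile.mean_rr)


def _af_rr(profile: SimProfile, n: int, rng) -> np.ndarray:
    """Serially uncorrelated, irregularly irregular AF RR (shifted gamma)."""
    m = _AF_MEAN_FACTOR * profile.mean_rr
    shift, gmean, sd = 0.4 * m, 0.6 * m, _AF_CV * m
    k = (gmean / sd) ** 2
    rr = shift + rng.gamma(k, gmean / k, n)
    return np.clip(rr, 0.25, 2.2 * profile.mean_rr)


def _block_beats(profile, rhythm, t0, t1, rng):
    """Beat times/types for one rhythm block [t0, t1)."""
    span = t1 - t0
    if rhythm == ARTIFACT or span <= 0:
        return (np.empty(0), np.empty(0, np.int8))
    mean = {SINUS: profile.mean_rr, AF: _AF_MEAN_FACTOR * profile.mean_rr,
            SVT: 0.55 * profile.mean_rr, AVB: 1.7 * profile.mean_rr}[rhythm]
    n_max = int(span / mean * 1.4) + 8
    if rhythm == SINUS:
        rr = _sinus_rr(profile, n_max, rng)
    elif rhythm == AF:
        rr = _af_rr(profile, n_max, rng)
    elif rhythm == SVT:
        rr = np.clip(mean + rng.normal(0, 0.01, n_max), 0.25, None)
    else:  # AVB: slow, mildly variable
        rr = np.clip(mean + rng.normal(0, 0.05 * profile.mean_rr, n_max), 0.4, None)
    t = t0 + 0.3 * mean + np.cumsum(rr)
    t = t[t < t1 - 0.05]
    types = np.zeros(t.shape[0], np.int8)
    if rhythm == SINUS and t.shape[0] > 2:
        p_pac = min(profile.pac_rate * profile.mean_rr / 3600.0, 0.5)
        p_pvc = min(profile.pvc_rate * profile.mean_rr / 3600.0, 0.5)
        u = rng.random(t.shape[0])
        types[u < p_pac] = BEAT_PAC
        types[(u >= p_pac) & (u < p_pac + p_pvc)] = BEAT_PVC
        types[0] = types[-1] = BEAT_N
        # ectopic beats arrive early; following sinus beat is on schedule,
        # which produces the compensatory-pause RR signature
        early = 0.3 * profile.mean_rr
        t = t - early * (types != BEAT_N)
        keep = np.empty(t.shape[0], bool)
        keep[0] = True
        keep[1:] = np.diff(t) > 0.2
        t, types = t[keep], types[keep]
    return t, types


def simulate_annotations(profile: SimProfile, duration_s: float, seed: int,
                         fs: float = 200.0,
                         record_id: str = "sim") -> AnnotatedRecording:
    """Generate the annotation-level recording (no waveform materialised)."""
    if duration_s < 600:
        raise ValueError("duration must be at least 600 s (one analysis window)")
    if fs < 100:
        raise ValueError("fs below 100 Hz undersamples the beat template")
    rng_ep = _rng(seed, 1)
    rng_beat = _rng(seed, 2)
    accepted = _place_episodes(profile, duration_s, rng_ep)
    episodes = _episode_partition(accepted, duration_s, fs)

    times, types, rhythms = [], [], []
    for ep in episodes:
        t, ty = _block_beats(profile, ep.rhythm, ep.start / fs, ep.end / fs, rng_beat)
        if t.size:
            times.append(t)
            types.append(ty)
            rhythms.append(np.full(t.shape[0], ep.rhythm, dtype=object))
    if times:
        bt = np.concatenate(times)
        bty = np.concatenate(types)
        brh = np.concatenate(rhythms)
    else:
        bt = np.empty(0)
        bty = np.empty(0, np.int8)
        brh = np.empty(0, object)
    keep = np.empty(bt.shape[0], bool)
    if bt.size:
        keep[0] = True
        keep[1:] = np.diff(bt) > 0.12
        bt, bty, brh = bt[keep], bty[keep], brh[keep]
    return AnnotatedRecording(record_id, fs, float(duration_s), profile, int(seed),
                              bt, bty, brh, episodes)


def simulate_recording(profile: SimProfile, duration_s: float, seed: int,
                       fs: float = 200.0, record_id: str = "sim"):
    """Fully materialised synthetic recording.

    Returns ``(ECGRecord, list[BeatAnnotation], list[RhythmEpisode])``.
    Identical ``(profile, duration_s, seed)`` give bit-identical output.
    """
    ann = simulate_annotations(profile, duration_s, seed, fs, record_id)
    record = ECGRecord(record_id, ann.render(), fs, float(duration_s),
                       profile.age, profile.sex)
    return record, ann.beat_annotations(), ann.episodes


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Population-level study conditions for synthetic cohorts.

    The AF-prone effect sizes (``pac_rate_mult``, ``sdnn_mult``,
    ``morphology_shift``) encode the assumed association between AF status
    and the AF-free signal; they are design knobs of the simulator, not
    estimates from any dataset.
    """

    fs: float = 200.0
    duration_s: float = 12 * 3600.0
    mean_rr_range: tuple[float, float] = (0.7, 1.0)
    sdnn_base: float = 0.05
    sdnn_logsd: float = 0.25
    rsa_range: tuple[float, float] = (0.2, 0.6)
    pac_rate_median: float = 2.0      # / hour
    pvc_rate_median: float = 1.0      # / hour
    rate_logsd: float = 0.7
    artifact_rate: float = 4.0        # / day
    artifact_duration: float = 40.0   # s
    svt_rate: float = 2.0             # / day
    avb_rate: float = 1.0             # / day
    af_episode_median_s: float = 300.0
    af_episode_logsd: float = 0.6
    # AF-prone effect sizes
    pac_rate_mult: float = 8.0
    sdnn_mult: float = 1.4
    morphology_shift: float = 0.3
    # burden targets are drawn log-uniformly inside these per-stratum bands
    burden_bands: tuple = ((0.002, 0.008), (0.015, 0.08), (0.12, 0.25))
    age_range: tuple[float, float] = (18.0, 95.0)
    age_af_log_odds_per_year: float = 0.05
    male_frac_af: float = 0.58
    male_frac: float = 0.50


_PROFILE_COLS = [f.name for f in fields(SimProfile)]


def profile_from_row(row) -> SimProfile:
    """Rebuild a SimProfile from a cohort-manifest row."""
    kw = {}
    for name in _PROFILE_COLS:
        if name == "af_episode_duration":
            kw[name] = (float(row["af_episode_median_s"]),
                        float(row["af_episode_logsd"]))
        else:
            kw[name] = row[name] if name == "sex" else float(row[name])
    return SimProfile(**kw)


def simulate_cohort(n_subjects: int, af_prevalence: float,
                    burden_mix=(1 / 3, 1 / 3, 1 / 3), seed: int = 0,
                    config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw a cohort manifest: per-subject profiles plus ground truth.

    Exactly ``round(n_subjects * af_prevalence)`` subjects are AF-prone;
    prone subjects carry elevated PAC rate, shifted SDNN and a nonzero
    morphology shift so their AF-free windows differ statistically from
    negatives. Age (and, mildly, sex) is associated with AF-prone status.
    The manifest records the generative ground truth per subject and is
    sufficient to regenerate every recording deterministically.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if not (0.0 <= af_prevalence <= 1.0):
        raise ValueError("af_prevalence must be in [0, 1]")
    burden_mix = np.asarray(burden_mix, float)
    if burden_mix.shape != (3,) or not math.isclose(burden_mix.sum(), 1.0,
                                                    rel_tol=1e-9):
        raise ValueError("burden_mix must be 3 weights summing to 1")
    cfg = config or CohortConfig()
    rng = _rng(seed, 10)

    age = rng.uniform(*cfg.age_range, n_subjects)
    n_af = int(round(n_subjects * af_prevalence))
    w = np.exp(cfg.age_af_log_odds_per_year * (age - 60.0))
    prone = np.zeros(n_subjects, bool)
    if n_af > 0:
        idx = rng.choice(n_subjects, size=n_af, replace=False, p=w / w.sum())
        prone[idx] = True
    p_male = np.where(prone, cfg.male_frac_af, cfg.male_frac)
    sex = np.where(rng.random(n_subjects) < p_male, "M", "F")

    mean_rr = rng.uniform(*cfg.mean_rr_range, n_subjects)
    sdnn = cfg.sdnn_base * np.exp(rng.normal(0, cfg.sdnn_logsd, n_subjects))
    rsa = rng.uniform(*cfg.rsa_range, n_subjects)
    pac = cfg.pac_rate_median * np.exp(rng.normal(0, cfg.rate_logsd, n_subjects))
    pvc = cfg.pvc_rate_median * np.exp(rng.normal(0, cfg.rate_logsd, n_subjects))

    sdnn = np.where(prone, sdnn * cfg.sdnn_mult, sdnn)
    pac = np.where(prone, pac * cfg.pac_rate_mult, pac)
    morph = np.where(prone, cfg.morphology_shift, 0.0)

    strata = list(BURDEN_STRATA)
    stratum_idx = rng.choice(3, size=n_subjects, p=burden_mix)
    lo = np.array([cfg.burden_bands[i][0] for i in stratum_idx])
    hi = np.array([cfg.burden_bands[i][1] for i in stratum_idx])
    target_burden = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    mean_ep_dur = cfg.af_episode_median_s * math.exp(cfg.af_episode_logsd ** 2 / 2)
    af_rate = np.where(prone, target_burden * 86400.0 / mean_ep_dur, 0.0)

    rows = []
    for i in range(n_subjects):
        rows.append({
            "record_id": f"S{i:05d}",
            "age": float(np.clip(age[i], 18.0, 99.0)),
            "sex": sex[i],
            "af_prone": bool(prone[i]),
            "target_burden": float(target_burden[i]) if prone[i] else 0.0,
            "target_stratum": strata[stratum_idx[i]] if prone[i] else "none",
            "subject_seed": int(_rng(seed, 20, i).integers(0, 2 ** 31 - 1)),
            "mean_rr": float(mean_rr[i]),
            "sdnn_target": float(sdnn[i]),
            "rsa_depth": float(rsa[i]),
            "pac_rate": float(pac[i]),
            "pvc_rate": float(pvc[i]),
            "af_episode_rate": float(af_rate[i]),
            "af_episode_median_s": cfg.af_episode_median_s,
            "af_episode_logsd": cfg.af_episode_logsd,
            "artifact_rate": cfg.artifact_rate,
            "artifact_duration": cfg.artifact_duration,
            "morphology_shift": float(morph[i]),
            "svt_rate": cfg.svt_rate,
            "avb_rate": cfg.avb_rate,
        })
    return pd.DataFrame(rows)
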