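"""Single-lead ECG waveform synthesis from beat/rhythm annotations.

Each beat is rendered as a sum of five Gaussian kernels (P, Q, R, S, T)
placed relative to the R peak — the standard low-cost construction for
synthetic ECG morphology. Rendering is a pure function of the annotation
stream, the subject profile and the record seed, and can be evaluated on any
sample span: ``render_span(ann, a, b)`` equals the ``[a, b)`` slice of a full
render. The per-sample noise stream is produced by a counter-based generator
(Philox) advanced to the span start, with normal deviates obtained through
the inverse CDF so that exactly one 64-bit draw is consumed per sample.
"""

from __future__ import annotations

import numpy as np

from .rhythms import AF, ARTIFACT, AVB, SINUS, SVT  # noqa: F401

# (center offset s, amplitude mV, width sigma s) relative to the R peak.
# Offsets for P and T are additionally adapted per beat (PR interval roughly
# fixed, QT scaling with the square root of the local RR, Bazett-like).
BASE_WAVES = {
    "P": (-0.170, 0.110, 0.045),
    "Q": (-0.035, -0.100, 0.012),
    "R": (0.000, 1.050, 0.020),
    "S": (0.038, -0.220, 0.015),
    "T": (0.300, 0.300, 0.085),
}

BEAT_N, BEAT_PAC, BEAT_PVC = 0, 1, 2

BASELINE_NOISE_MV = 0.02
ARTIFACT_NOISE_MV = 1.2
FWAVE_AMP_MV = 0.06      # fibrillatory baseline within AF episodes
FWAVE_FREQ_HZ = 6.1


_NOISE_TILE = 1 << 16


def _noise_stream(seed: int, start: int, n: int) -> np.ndarray:
    """Standard-normal noise for samples [start, start+n).

    The stream is generated in fixed tiles keyed by (seed, tile index), so
    any span renders identically to the corresponding slice of a full
    render (slice consistency by construction).
    """
    t0, t1 = start // _NOISE_TILE, (start + n - 1) // _NOISE_TILE
    tiles = [
        np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(0xECF, t))
        ).standard_normal(_NOISE_TILE)
        for t in range(t0, t1 + 1)
    ]
    buf = np.concatenate(tiles)
    off = start - t0 * _NOISE_TILE
    return buf[off:off + n]


def _wave_params(name, base, rr_prev, beat_types, in_af, morph):
    """Per-beat (center, amp, sigma) arrays for one wave of the template.

    ``morph`` is the subtle P/T morphology perturbation applied to normal
    beats outside AF for AF-prone subjects (dimensionless, 0 = none).
    """
    off, amp0, sig0 = base
    n = rr_prev.shape[0]
    center = np.full(n, off)
    amp = np.full(n, amp0)
    sigma = np.full(n, sig0)
    is_pvc = beat_types == BEAT_PVC
    is_pac = beat_types == BEAT_PAC
    is_n = beat_types == BEAT_N

    if name == "T":
        center = off * np.sqrt(np.clip(rr_prev, 0.3, 2.0) / 0.8)
    if name == "P":
        # no organised P wave during AF; ectopic atrial focus for PACs
        amp = np.where(in_af, 0.0, amp)
        amp = np.where(is_pac, amp * 0.4, amp)
        center = np.where(is_pac, off * 0.7, center)
        shift_mask = is_n & ~in_af
        amp = np.where(shift_mask, amp * (1.0 - 0.5 * morph), amp)
        sigma = np.where(shift_mask, sigma * (1.0 + 0.6 * morph), sigma)
    if name == "T":
        shift_mask = is_n & ~in_af
        amp = np.where(shift_mask, amp * (1.0 - 0.25 * morph), amp)
    if name in ("Q", "R", "S"):
        sigma = np.where(is_pvc, sigma * 3.2, sigma)
        if name == "R":
            amp = np.where(is_pvc, amp * 1.25, amp)
    if name == "T":
        amp = np.where(is_pvc, -1.2 * np.abs(amp), amp)  # discordant T
    if name == "P":
        amp = np.where(is_pvc, 0.0, amp)  # no conducted P before a PVC
    return center, amp, sigma


def _add_waves(out, start, fs, centers_s, amps, sigmas):
    """Scatter-add Gaussian kernels (vectorised over beats)."""
    if centers_s.size == 0:
        return
    half = int(np.ceil(3.5 * float(np.max(sigmas)) * fs)) + 1
    rel = np.arange(-half, half + 1)
    c_idx = np.round(centers_s * fs).astype(np.int64) - start
    idx = c_idx[:, None] + rel[None, :]
    tt = idx / fs + start / fs
    vals = amps[:, None] * np.exp(
        -0.5 * ((tt - centers_s[:, None]) / sigmas[:, None]) ** 2
    )
    ok = (idx >= 0) & (idx < out.shape[0])
    np.add.at(out, idx[ok], vals[ok])


def render_span(ann, start: int, stop: int) -> np.ndarray:
    """Render samples [start, stop) of an annotated recording, in millivolts.

    Parameters
    ----------
    ann : AnnotatedRecording
        Annotation-level recording (beat times/types, rhythm episodes,
        profile, seed) produced by :func:`afhorizon.simulate.simulate_annotations`.
    """
    fs = ann.fs
    n = stop - start
    if n <= 0 or start < 0 or stop > ann.n_samples:
        raise ValueError("span outside record bounds")
    out = np.zeros(n, dtype=np.float64)

    t = (start + np.arange(n)) / fs
    # slow baseline wander (respiration + electrode drift)
    out += 0.04 * np.sin(2 * np.pi * 0.05 * t) + 0.03 * np.sin(2 * np.pi * 0.33 * t)
    out += BASELINE_NOISE_MV * _noise_stream(ann.seed, start, n)

    lo_s, hi_s = start / fs - 1.5, stop / fs + 1.5
    bt = ann.beat_times
    sel = (bt >= lo_s) & (bt <= hi_s)
    times = bt[sel]
    types = ann.beat_types[sel]
    rhythms = ann.beat_rhythms[sel]
    if times.size:
        rr_prev = np.empty_like(times)
        rr_prev[1:] = np.diff(times)
        first = np.searchsorted(bt, times[0])
        rr_prev[0] = (bt[first] - bt[first - 1]) if first > 0 else ann.profile.mean_rr
        in_af = rhythms == AF
        for name, base in BASE_WAVES.items():
            c, a, s = _wave_params(
                name, base, rr_prev, types, in_af, ann.profile.morphology_shift
            )
            _add_waves(out, start, fs, times + c, a, s)

    for ep in ann.episodes:
        a, b = max(ep.start, start), min(ep.end, stop)
        if a >= b:
            continue
        if ep.rhythm == AF:
            tt = np.arange(a, b) / fs
            out[a - start:b - start] += FWAVE_AMP_MV * np.sin(
                2 * np.pi * FWAVE_FREQ_HZ * tt + (ann.seed % 628) / 100.0
            )
        elif ep.rhythm == ARTIFACT:
            # motion/contact artifact: signal replaced by high-amplitude noise
            out[a - start:b - start] = ARTIFACT_NOISE_MV * _noise_stream(
                ann.seed ^ 0x5A5A5A, a, b - a
            )
    return out.astype(np.float32)
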