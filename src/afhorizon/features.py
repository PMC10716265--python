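"""Per-window feature extraction and the fitted normalization pipeline.

HRV metrics are computed on NN intervals: successive inter-beat intervals
whose two endpoint beats are both normal. Intervals adjacent to a PAC or
PVC are discarded rather than interpolated, so ectopy perturbs the ectopic
counts but not the HRV family. Rhythm features are per-window time
fractions of the non-AF abnormal rhythms and of artifact, plus PAC/PVC
counts.

Normalization is fitted on the training split only. Burden/rate-like
features (exponentially distributed in practice) get the offset -> scale ->
1 - exp(-x) map; remaining continuous features get a Box-Cox transform
(maximum-likelihood lambda after a positivity shift) followed by
standardization; learned embeddings are standardized only; binary features
pass through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lombscargle

from .rhythms import ARTIFACT, AVB, SVT

__all__ = [
    "compute_nn_intervals", "compute_hrv", "compute_rhythm_features",
    "FeatureTransform", "fit_transforms", "apply_transforms",
    "invert_transforms", "HRV_NAMES", "ECTOPIC_NAMES", "RHYTHM_NAMES",
    "feature_roles",
]

HRV_NAMES = (
    "nn_mean", "nn_median", "sdnn", "rmssd", "sdsd", "pnn50", "cv_nn",
    "hr_mean", "hr_min", "hr_max", "tri_index",
    "lf_power", "hf_power", "total_power", "lf_hf_ratio",
)
ECTOPIC_NAMES = ("pac_count", "pvc_count")
RHYTHM_NAMES = ("svt_burden", "avb_burden", "artifact_fraction")

_LF_BAND = (0.04, 0.15)   # Hz
_HF_BAND = (0.15, 0.40)   # Hz
_TRI_BIN_S = 1.0 / 128.0  # canonical triangular-index bin width


def compute_nn_intervals(beat_times: np.ndarray, beat_types: np.ndarray
                         ) -> np.ndarray:
    """NN intervals (seconds) from beat times and type codes/labels.

    Only differences between successive beats where *both* endpoints are
    normal are kept; an interval with an ectopic endpoint is dropped.
    ``beat_types`` may be integer codes (0 = N) or string labels ("N").
    """
    t = np.asarray(beat_times, float)
    ty = np.asarray(beat_types)
    if t.shape[0] < 2:
        return np.empty(0)
    is_n = (ty == 0) if np.issubdtype(ty.dtype, np.number) else (ty == "N")
    keep = is_n[:-1] & is_n[1:]
    return np.diff(t)[keep]


def _band_power(t, y, band, n_freq=48):
    f = np.linspace(band[0], band[1], n_freq)
    p = lombscargle(t, y, 2 * np.pi * f, normalize=False)
    return float(np.trapezoid(p, f))


def compute_hrv(nn: np.ndarray, min_nn: int = 60) -> dict[str, float]:
    """The declared short-term HRV battery from one window's NN series.

    Time-domain statistics use the standard definitions (SDNN with sample
    variance; RMSSD as the root mean square of successive differences;
    pNN50 the fraction of successive differences exceeding 50 ms). The
    triangular index is approximated as N over the modal histogram count at
    1/128-s bins. Frequency powers use a Lomb periodogram on the unevenly
    sampled NN series (LF 0.04-0.15 Hz, HF 0.15-0.40 Hz).
    """
    nn = np.asarray(nn, float)
    if nn.shape[0] < min_nn:
        raise ValueError(
            f"need at least {min_nn} NN intervals, got {nn.shape[0]}")
    d = np.diff(nn)
    sdnn = float(np.std(nn, ddof=1))
    out = {
        "nn_mean": float(np.mean(nn)),
        "nn_median": float(np.median(nn)),
        "sdnn": sdnn,
        "rmssd": float(np.sqrt(np.mean(d ** 2))) if d.size else 0.0,
        "sdsd": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        "pnn50": float(np.mean(np.abs(d) > 0.050)) if d.size else 0.0,
        "cv_nn": sdnn / float(np.mean(nn)),
        "hr_mean": 60.0 / float(np.mean(nn)),
        "hr_min": 60.0 / float(np.max(nn)),
        "hr_max": 60.0 / float(np.min(nn)),
    }
    edges = np.arange(nn.min() - _TRI_BIN_S / 2, nn.max() + _TRI_BIN_S,
                      _TRI_BIN_S)
    hist, _ = np.histogram(nn, edges)
    out["tri_index"] = nn.shape[0] / float(hist.max())
    t = np.cumsum(nn)
    y = nn - nn.mean()
    if np.ptp(nn) < 1e-12:
        lf = hf = 0.0
    else:
        lf = _band_power(t, y, _LF_BAND)
        hf = _band_power(t, y, _HF_BAND)
    out["lf_power"] = lf
    out["hf_power"] = hf
    out["total_power"] = lf + hf
    out["lf_hf_ratio"] = lf / hf if hf > 0 else 0.0
    return out


def compute_rhythm_features(episodes, beat_samples, beat_types,
                            window_start: int, fs: float,
                            window_s: float = 600.0) -> dict[str, float]:
    """Rhythm burdens and ectopic counts for one window.

    Burdens are the fraction of window time in each non-AF abnormal rhythm
    (SVT, AVB) plus artifact; ectopic counts are PAC/PVC beats inside the
    window (per-minute rates are derivable by dividing by 10).
    """
    a = int(window_start)
    b = a + int(round(window_s * fs))
    total = b - a
    burden = {SVT: 0, AVB: 0, ARTIFACT: 0}
    for ep in episodes:
        if ep.rhythm in burden:
            burden[ep.rhythm] += max(0, min(ep.end, b) - max(ep.start, a))
    bs = np.asarray(beat_samples)
    ty = np.asarray(beat_types)
    inside = (bs >= a) & (bs < b)
    is_num = np.issubdtype(ty.dtype, np.number)
    pac = int(np.sum(inside & ((ty == 1) if is_num else (ty == "PAC"))))
    pvc = int(np.sum(inside & ((ty == 2) if is_num else (ty == "PVC"))))
    return {
        "svt_burden": burden[SVT] / total,
        "avb_burden": burden[AVB] / total,
        "artifact_fraction": burden[ARTIFACT] / total,
        "pac_count": float(pac),
        "pvc_count": float(pvc),
    }


# ---------------------------------------------------------------------------
# normalization pipeline
# ---------------------------------------------------------------------------

BOXCOX = "BOXCOX"
EXPONENTIAL = "EXPONENTIAL"
PASSTHROUGH = "PASSTHROUGH"
ZSCORE = "ZSCORE"


@dataclass(frozen=True)
class FeatureTransform:
    """Fitted per-feature normalization.

    EXPONENTIAL: y = 1 - exp(-(x - offset) / scale) with the offset and
    scale estimated on the training split (offset = min, scale = mean of
    offset-removed values). BOXCOX: ((x + shift)^lambda - 1) / lambda (log
    at lambda = 0) followed by standardization with the training mean/sd.
    ZSCORE: standardization only (used for learned embeddings).
    PASSTHROUGH: identity (binary or degenerate features).
    """

    kind: str
    offset: float = 0.0
    scale: float = 1.0
    lam: float = 1.0
    shift: float = 0.0
    mean: float = 0.0
    sd: float = 1.0


def feature_roles(columns, embedding_prefix: str = "e") -> dict[str, str]:
    """Default role map: burden/rate-like -> exponential family; embeddings
    -> z-score; sex -> binary; everything else continuous (Box-Cox)."""
    roles = {}
    burden_like = set(RHYTHM_NAMES) | set(ECTOPIC_NAMES) | {
        "lf_power", "hf_power", "total_power", "lf_hf_ratio"}
    for c in columns:
        if c in burden_like:
            roles[c] = "burden"
        elif c == "sex":
            roles[c] = "binary"
        elif c.startswith(embedding_prefix) and c[len(embedding_prefix):].isdigit():
            roles[c] = "embedding"
        else:
            roles[c] = "continuous"
    return roles


def fit_transforms(train: pd.DataFrame,
                   roles: dict[str, str] | None = None
                   ) -> dict[str, FeatureTransform]:
    """Fit the per-feature normalization on training rows only.

    Membership in the exponential family is decided by feature role
    (burden/rate), not by a distribution test, so the pipeline is
    deterministic. Zero-variance features degrade to PASSTHROUGH with a
    warning.
    """
    roles = roles or feature_roles(train.columns)
    out: dict[str, FeatureTransform] = {}
    for col in train.columns:
        x = train[col].to_numpy(float)
        role = roles.get(col, "continuous")
        if role == "binary":
            out[col] = FeatureTransform(PASSTHROUGH)
            continue
        if np.ptp(x) < 1e-12:
            # constant embedding units (dead ReLU) are routine, not notable
            if role != "embedding":
                warnings.warn(f"feature {col!r} has zero variance on train; "
                              "passing through")
            out[col] = FeatureTransform(PASSTHROUGH)
            continue
        if role == "burden":
            offset = float(np.min(x))
            scale = float(np.mean(x - offset))
            if scale <= 0:
                out[col] = FeatureTransform(PASSTHROUGH)
                continue
            out[col] = FeatureTransform(EXPONENTIAL, offset=offset, scale=scale)
        elif role == "embedding":
            out[col] = FeatureTransform(ZSCORE, mean=float(np.mean(x)),
                                        sd=float(np.std(x)))
        else:
            mn = float(np.min(x))
            # margin keeps unseen values at or slightly below the training
            # minimum strictly positive after shifting
            shift = max(0.0, -mn) + 1e-3 * (float(np.ptp(x)) or 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y, lam = stats.boxcox(x + shift)
            out[col] = FeatureTransform(BOXCOX, lam=float(lam), shift=shift,
                                        mean=float(np.mean(y)),
                                        sd=float(np.std(y, ddof=0)))
    return out


def _boxcox(x, lam):
    if abs(lam) < 1e-12:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def _boxcox_inv(y, lam):
    if abs(lam) < 1e-12:
        return np.exp(y)
    return np.power(lam * y + 1.0, 1.0 / lam)


def apply_transforms(features: pd.DataFrame,
                     transforms: dict[str, FeatureTransform]) -> pd.DataFrame:
    """Apply fitted transforms columnwise; unlisted columns pass through."""
    out = features.copy()
    for col, tr in transforms.items():
        if col not in out.columns:
            continue
        x = out[col].to_numpy(float)
        if tr.kind == PASSTHROUGH:
            continue
        if tr.kind == EXPONENTIAL:
            out[col] = 1.0 - np.exp(-(x - tr.offset) / tr.scale)
        elif tr.kind == ZSCORE:
            out[col] = (x - tr.mean) / (tr.sd if tr.sd > 0 else 1.0)
        elif tr.kind == BOXCOX:
            z = x + tr.shift
            if np.any(z <= 0):
                warnings.warn(f"feature {col!r}: values at or below the "
                              "positivity shift were clamped")
                z = np.maximum(z, np.finfo(float).tiny)
            y = _boxcox(z, tr.lam)
            out[col] = (y - tr.mean) / (tr.sd if tr.sd > 0 else 1.0)
        else:
            raise ValueError(f"unknown transform kind {tr.kind!r}")
    return out


def invert_transforms(normalized: pd.DataFrame,
                      transforms: dict[str, FeatureTransform]) -> pd.DataFrame:
    """Invert the (invertible) transforms; recovers inputs to ~1e-9 relative."""
    out = normalized.copy()
    for col, tr in transforms.items():
        if col not in out.columns:
            continue
        y = out[col].to_numpy(float)
        if tr.kind == PASSTHROUGH:
            continue
        if tr.kind == EXPONENTIAL:
            out[col] = tr.offset - tr.scale * np.log1p(-y)
        elif tr.kind == ZSCORE:
            out[col] = y * (tr.sd if tr.sd > 0 else 1.0) + tr.mean
        elif tr.kind == BOXCOX:
            z = y * (tr.sd if tr.sd > 0 else 1.0) + tr.mean
            out[col] = _boxcox_inv(z, tr.lam) - tr.shift
        else:
            raise ValueError(f"unknown transform kind {tr.kind!r}")
    return out
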