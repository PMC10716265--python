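"""Select an AF-free interval and extract one window's feature bundle.

The analysis unit is a 10-minute window taken from an interval with no AF
and no quality failures. HRV metrics are computed on NN intervals (both
endpoint beats normal, intervals touching ectopics dropped); rhythm
features are time fractions; ectopic features are counts.
"""

import numpy as np

from afhorizon import (SimProfile, compute_hrv, compute_nn_intervals,
                       compute_rhythm_features, select_af_free_interval,
                       window_is_valid)
from afhorizon.simulate import simulate_annotations

profile = SimProfile(af_episode_rate=15.0, pac_rate=10.0, pvc_rate=2.0,
                     svt_rate=6.0, age=64, sex="F")
ann = simulate_annotations(profile, duration_s=3 * 3600, seed=7)

start = select_af_free_interval(ann, target_len_s=3600)
print(f"earliest AF-free, quality-clean hour starts at sample {start} "
      f"(= {start / ann.fs / 60:.0f} min)")

fs = ann.fs
win = int(600 * fs)
beat_samples = np.round(ann.beat_times * fs).astype(np.int64)
ok, reasons = window_is_valid(beat_samples, ann.episodes, start, fs)
print(f"first window valid: {ok} (failed rules: {set(reasons) or 'none'})")

sel = (beat_samples >= start) & (beat_samples < start + win)
nn = compute_nn_intervals(ann.beat_times[sel], ann.beat_types[sel])
hrv = compute_hrv(nn)
rhythm = compute_rhythm_features(ann.episodes, beat_samples,
                                 ann.beat_types, start, fs)

print(f"NN intervals: {nn.size}")
print(f"SDNN {hrv['sdnn'] * 1000:.1f} ms, RMSSD {hrv['rmssd'] * 1000:.1f} ms, "
      f"pNN50 {hrv['pnn50']:.2f}, mean HR {hrv['hr_mean']:.0f} bpm")
print(f"LF/HF ratio {hrv['lf_hf_ratio']:.2f}")
print(f"PACs {rhythm['pac_count']:.0f}, PVCs {rhythm['pvc_count']:.0f}, "
      f"SVT burden {rhythm['svt_burden']:.3f}, "
      f"artifact fraction {rhythm['artifact_fraction']:.3f}")
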