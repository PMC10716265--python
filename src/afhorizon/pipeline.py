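"""End-to-end experiment: simulate a cohort, select AF-free intervals,
extract window features, train both model stages, calibrate, evaluate.

The default configuration is the package's reference desk-scale study:
1200 subjects (600 train / 300 calibration / 300 test at natural
prevalence 20%), 12-hour recordings at 200 Hz, AF-free input intervals of
one hour analysed as 10-min and 1-h scenarios, and the demographics-only
(AG) versus all-features comparison evaluated with the percentile/paired
bootstrap. Only the selected windows are ever rendered to voltage, so the
whole experiment runs in minutes on one CPU.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, features
from .annotate import WINDOW_S, age_group_of
from .calibrate import fit_calibration
from .evaluate import paired_bootstrap_test, roc_auc, stratified_report
from .features import compute_hrv, compute_nn_intervals, compute_rhythm_features
from .model import (EncoderConfig, FEATURE_SETS, SequenceModelConfig,
                    encode_windows, predict_risk, train_module_a,
                    train_module_b, weights_checksum)
from .simulate import CohortConfig, profile_from_row, simulate_annotations, simulate_cohort

__all__ = ["PipelineConfig", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 1200
    af_prevalence: float = 0.20
    burden_mix: tuple = (1 / 3, 1 / 3, 1 / 3)
    split_fractions: tuple = (0.5, 0.25, 0.25)   # train/calibration/test
    interval_len_s: float = 3600.0
    scenarios: tuple = (("10min", 1), ("1h", 6))  # (label, windows)
    feature_sets: tuple = ("ag", "all_features")
    windows_per_subject_a: int = 1
    min_nn_per_window: int = 10
    n_boot: int = 1000
    cohort: CohortConfig = field(default_factory=CohortConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    sequence: SequenceModelConfig = field(default_factory=SequenceModelConfig)


@dataclass
class ExperimentResult:
    config: PipelineConfig
    seed: int
    manifest: pd.DataFrame          # + label/burden/split columns
    n_excluded_persistent: int
    n_excluded_no_interval: int
    interval_starts: dict          # record_id -> start sample of input
    window_features: pd.DataFrame
    encoder_history: dict
    encoder_checksum_before_b: str
    encoder_checksum_after_b: str
    module_a_val_auc: float
    scores: dict                     # (feature_set, scenario) -> split scores
    aucs: dict                       # (feature_set, scenario) -> test AUC
    paired: dict                     # scenario -> PairedTestResult vs "ag"
    report: pd.DataFrame             # stratified report, 1-h scenario
    runtime_s: float


def _window_rows(ann, label, interval_start, win_samples, n_windows, cfg):
    """Per-window HRV + rhythm/ectopic features; None if a window is too
    depleted of NN intervals to support the HRV battery."""
    fs = ann.fs
    bt = ann.beat_times
    bs = np.round(bt * fs).astype(np.int64)
    rows = []
    for w in range(n_windows):
        a = interval_start + w * win_samples
        b = a + win_samples
        sel = (bs >= a) & (bs < b)
        nn = compute_nn_intervals(bt[sel], ann.beat_types[sel])
        if nn.shape[0] < cfg.min_nn_per_window:
            return None
        row = compute_hrv(nn, min_nn=cfg.min_nn_per_window)
        row.update(compute_rhythm_features(ann.episodes, bs, ann.beat_types,
                                           a, fs))
        row["window_idx"] = w
        rows.append(row)
    return rows


def _assemble_sequences(df, subjects, cols, n_windows):
    """(N, T, D) array from the normalized window-feature table."""
    if not cols:
        return np.zeros((len(subjects), n_windows, 0))
    sub = df[df["record_id"].isin(subjects)]
    sub = sub[sub["window_idx"] < n_windows]
    sub = sub.sort_values(["record_id", "window_idx"])
    arr = sub[cols].to_numpy(float)
    return arr.reshape(len(subjects), n_windows, len(cols))


def run_experiment(config: PipelineConfig | None = None,
                   seed: int = 0) -> ExperimentResult:
    """Run the full reference experiment; deterministic under ``seed``."""
    t0 = time.time()
    cfg = config or PipelineConfig()
    cc = cfg.cohort
    fs = cc.fs
    win = int(round(WINDOW_S * fs))
    n_win = int(cfg.interval_len_s // WINDOW_S)

    manifest = simulate_cohort(cfg.n_subjects, cfg.af_prevalence,
                               cfg.burden_mix, seed, cc)

    subjects = {}
    labels, burdens, starts = {}, {}, {}
    n_persistent = n_no_interval = 0
    feat_rows = []
    for _, row in manifest.iterrows():
        rid = row["record_id"]
        prof = profile_from_row(row)
        ann = simulate_annotations(prof, cc.duration_s, row["subject_seed"],
                                   fs, rid)
        lab = annotate.label_recording(ann.episodes, fs)
        if lab.excluded_persistent:
            n_persistent += 1
            continue
        start = annotate.select_af_free_interval(ann, cfg.interval_len_s)
        if start is None:
            n_no_interval += 1
            continue
        rows = _window_rows(ann, lab, start, win, n_win, cfg)
        if rows is None:
            n_no_interval += 1
            continue
        for r in rows:
            r["record_id"] = rid
            r["age"] = row["age"]
            r["sex"] = 1.0 if row["sex"] == "M" else 0.0
        feat_rows.extend(rows)
        subjects[rid] = ann.trimmed(start, start + n_win * win)
        labels[rid] = bool(lab.af_positive)
        burdens[rid] = lab.af_burden
        starts[rid] = start

    usable = sorted(subjects)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(401,)))
    order = rng.permutation(len(usable))
    n_us = len(usable)
    n_train = int(round(cfg.split_fractions[0] * n_us))
    n_cal = int(round(cfg.split_fractions[1] * n_us))
    split_of = {}
    for pos, i in enumerate(order):
        rid = usable[i]
        split_of[rid] = ("TRAIN" if pos < n_train else
                         "CALIBRATION" if pos < n_train + n_cal else "TEST")

    manifest = manifest.copy()
    manifest["usable"] = manifest["record_id"].isin(subjects)
    manifest["af_positive"] = manifest["record_id"].map(labels)
    manifest["burden"] = manifest["record_id"].map(burdens)
    manifest["split"] = manifest["record_id"].map(split_of)
    manifest["age_group"] = [age_group_of(a) for a in manifest["age"]]

    by_split = {s: [r for r in usable if split_of[r] == s]
                for s in ("TRAIN", "CALIBRATION", "TEST")}

    # ----- module A: weakly labeled AF-free windows of the training split
    train_ids = by_split["TRAIN"]
    xa, ya = [], []
    for rid in train_ids:
        ann = subjects[rid]
        for w in range(min(cfg.windows_per_subject_a, n_win)):
            a = starts[rid] + w * win
            xa.append(ann.render(a, a + win))
            ya.append(labels[rid])
    xa = np.stack(xa)
    ya = np.asarray(ya, float)
    encoder, enc_history = train_module_a(xa, ya, cfg.encoder, seed)
    del xa
    checksum_before = weights_checksum(encoder)
    val_auc = enc_history["val_auc"][-1] if enc_history["val_auc"] else np.nan

    # ----- embeddings for every analysed window
    emb_rows = {}
    for rid in usable:
        ann = subjects[rid]
        wnds = np.stack([ann.render(starts[rid] + w * win,
                                    starts[rid] + (w + 1) * win)
                         for w in range(n_win)])
        emb_rows[rid] = encode_windows(encoder, wnds)

    wf = pd.DataFrame(feat_rows)
    wf = wf.sort_values(["record_id", "window_idx"]).reset_index(drop=True)
    emb = np.vstack([emb_rows[rid] for rid in sorted(emb_rows)])
    wf = pd.concat([wf, pd.DataFrame(
        emb, columns=[f"e{j}" for j in range(emb.shape[1])],
        index=wf.index)], axis=1)

    # ----- normalization fitted on TRAIN windows only
    feat_cols = [c for c in wf.columns if c not in ("record_id", "window_idx")]
    train_mask = wf["record_id"].isin(train_ids)
    transforms = features.fit_transforms(wf.loc[train_mask, feat_cols])
    wf_norm = wf.copy()
    wf_norm[feat_cols] = features.apply_transforms(wf[feat_cols],
                                                   transforms)[feat_cols]

    demo_cols = ["age", "sex"]
    demo_by_split = {
        s: wf_norm[wf_norm["record_id"].isin(ids) & (wf_norm["window_idx"] == 0)]
        .sort_values("record_id")[demo_cols].to_numpy(float)
        for s, ids in by_split.items()}
    y_by_split = {s: np.array([labels[r] for r in sorted(ids)], float)
                  for s, ids in by_split.items()}

    # ----- module B per (feature set, scenario), with calibration
    scores = {}
    aucs = {}
    models = {}
    for fset_name in cfg.feature_sets:
        fset = FEATURE_SETS[fset_name]
        cols = fset.columns()
        for scen_name, t_wins in cfg.scenarios:
            key = (fset_name, scen_name)
            seqs = {s: _assemble_sequences(wf_norm, sorted(ids), cols, t_wins)
                    for s, ids in by_split.items()}
            demo = {s: (demo_by_split[s] if fset.include_demographics
                        else np.zeros((len(by_split[s]), 0)))
                    for s in by_split}
            cache_key = (fset_name, None) if not fset.use_recurrent else key
            if cache_key in models:
                mdl = models[cache_key]
            else:
                mdl, _ = train_module_b(seqs["TRAIN"], demo["TRAIN"],
                                        y_by_split["TRAIN"], fset,
                                        cfg.sequence, seed)
                models[cache_key] = mdl
            raw_cal = predict_risk(mdl, seqs["CALIBRATION"],
                                   demo["CALIBRATION"])
            raw_test = predict_risk(mdl, seqs["TEST"], demo["TEST"])
            cal_map = fit_calibration(raw_cal, y_by_split["CALIBRATION"])
            scores[key] = {"calibration_raw": raw_cal,
                           "test_raw": raw_test,
                           "test_calibrated": cal_map(raw_test),
                           "calibration_map": cal_map}
            aucs[key] = roc_auc(scores[key]["test_calibrated"],
                                y_by_split["TEST"])
    checksum_after = weights_checksum(encoder)

    # ----- evaluation
    test_ids = sorted(by_split["TEST"])
    y_test = y_by_split["TEST"]
    meta = pd.DataFrame({
        "record_id": test_ids,
        "age": [float(manifest.set_index("record_id").loc[r, "age"])
                for r in test_ids],
        "burden": [burdens[r] for r in test_ids]})
    paired = {}
    report = pd.DataFrame()
    ref = "ag" if "ag" in cfg.feature_sets else None
    for scen_name, _t in cfg.scenarios:
        by_fset = {f: scores[(f, scen_name)]["test_calibrated"]
                   for f in cfg.feature_sets}
        if ref is not None:
            for f in cfg.feature_sets:
                if f != ref:
                    paired[(f, scen_name)] = paired_bootstrap_test(
                        roc_auc, by_fset[f], by_fset[ref], y_test,
                        n_boot=cfg.n_boot, seed=seed)
        if scen_name == cfg.scenarios[-1][0]:
            report = stratified_report(by_fset, y_test, meta,
                                       n_boot=cfg.n_boot, seed=seed,
                                       compare_to=ref)

    return ExperimentResult(
        config=cfg, seed=seed, manifest=manifest,
        n_excluded_persistent=n_persistent,
        n_excluded_no_interval=n_no_interval,
        interval_starts=dict(starts),
        window_features=wf_norm, encoder_history=enc_history,
        encoder_checksum_before_b=checksum_before,
        encoder_checksum_after_b=checksum_after,
        module_a_val_auc=float(val_auc),
        scores=scores, aucs=aucs, paired=paired, report=report,
        runtime_s=time.time() - t0)
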