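"""Plain-text record, annotation and manifest I/O.

Records are stored WFDB-style as a header plus separate annotation files,
but in portable text form: a ``.hea.json`` header, a ``.beats.csv`` beat
annotation table using WFDB beat codes (N normal, A atrial premature,
V ventricular premature), a ``.rhythms.csv`` episode table with WFDB aux
rhythm-change labels ("(N", "(AFIB", "(SVTA", "(BII", "(NOISE"), and an
optional ``.signal.csv`` voltage trace (intended for short excerpts; long
records should be regenerated from the cohort manifest instead of stored).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rhythms import WFDB_AUX
from .simulate import BeatAnnotation, ECGRecord, RhythmEpisode

__all__ = ["write_record", "read_record", "write_manifest", "read_manifest"]

_BEAT_TO_WFDB = {"N": "N", "PAC": "A", "PVC": "V"}
_WFDB_TO_BEAT = {v: k for k, v in _BEAT_TO_WFDB.items()}
_AUX_TO_RHYTHM = {v: k for k, v in WFDB_AUX.items()}


def write_record(directory, record: ECGRecord, beats, episodes,
                 include_signal: bool = True):
    """Write one annotated record as text files under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    stem = d / record.record_id
    header = {"record_id": record.record_id, "fs": record.fs,
              "n_samples": int(record.signal.shape[0]),
              "duration_s": record.duration_s, "units": "mV",
              "age": record.age, "sex": record.sex}
    with open(f"{stem}.hea.json", "w") as fh:
        json.dump(header, fh, indent=1)
    pd.DataFrame({
        "sample": [b.sample_index for b in beats],
        "code": [_BEAT_TO_WFDB[b.beat_type] for b in beats],
    }).to_csv(f"{stem}.beats.csv", index=False)
    pd.DataFrame({
        "start": [e.start for e in episodes],
        "end": [e.end for e in episodes],
        "aux": [WFDB_AUX[e.rhythm] for e in episodes],
    }).to_csv(f"{stem}.rhythms.csv", index=False)
    if include_signal:
        np.savetxt(f"{stem}.signal.csv", record.signal, fmt="%.4f",
                   header="mV", comments="")


def read_record(directory, record_id: str):
    """Read a record written by :func:`write_record`.

    Returns ``(ECGRecord | None, beats, episodes)``; the record is None
    when the signal file was not stored.
    """
    stem = Path(directory) / record_id
    with open(f"{stem}.hea.json") as fh:
        header = json.load(fh)
    bdf = pd.read_csv(f"{stem}.beats.csv")
    beats = [BeatAnnotation(int(r["sample"]), _WFDB_TO_BEAT[r["code"]])
             for _, r in bdf.iterrows()]
    rdf = pd.read_csv(f"{stem}.rhythms.csv")
    episodes = [RhythmEpisode(int(r["start"]), int(r["end"]),
                              _AUX_TO_RHYTHM[r["aux"]])
                for _, r in rdf.iterrows()]
    sig_path = Path(f"{stem}.signal.csv")
    record = None
    if sig_path.exists():
        signal = np.loadtxt(sig_path, skiprows=1).astype(np.float32)
        record = ECGRecord(record_id, signal, header["fs"],
                           header["duration_s"], header["age"],
                           header["sex"])
    return record, beats, episodes


def write_manifest(path, manifest: pd.DataFrame):
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
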