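"""Hierarchical risk models: window encoder (module A) and sequence model
(module B).

Module A is a 1-D convolutional encoder over a raw 10-minute window,
trained with the recording-level AF outcome broadcast to the recording's
AF-free windows (weak labels) under binary cross-entropy. Its 128-unit
second-last fully connected layer provides the learned window embedding;
after training the weights are frozen, which the pipeline asserts by
checksum.

Module B consumes the per-window feature sequence of an input of 10 min to
24 h (1 to 144 windows): a 2-layer bidirectional LSTM, demographics
appended to the concatenated final states, then two fully connected layers
ending in a sigmoid risk score. The demographics-only (AG) configuration
bypasses the recurrent stage entirely so the degeneracy (score depends on
age and sex alone) is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .features import ECTOPIC_NAMES, HRV_NAMES, RHYTHM_NAMES

__all__ = [
    "FeatureSetConfig", "FEATURE_SETS", "EncoderConfig", "WindowEncoder",
    "train_module_a", "encode_windows", "SequenceModelConfig", "RiskModel",
    "train_module_b", "predict_risk", "weights_checksum",
    "save_encoder", "load_encoder",
    "EMBEDDING_DIM", "feature_columns",
]

EMBEDDING_DIM = 128
EMBEDDING_NAMES = tuple(f"e{i}" for i in range(EMBEDDING_DIM))

_GROUP_COLUMNS = {
    "hrv": HRV_NAMES,
    "ectopic": ECTOPIC_NAMES,
    "rhythm": RHYTHM_NAMES,
    "embedding": EMBEDDING_NAMES,
}


@dataclass(frozen=True)
class FeatureSetConfig:
    """One input configuration of the risk model.

    ``window_groups`` are the per-timestep feature families fed to the
    recurrent stage; ``include_demographics`` appends age/sex after it.
    The AG configuration has no window groups and no recurrent stage.
    """

    name: str
    window_groups: tuple[str, ...]
    include_demographics: bool = True

    @property
    def use_recurrent(self) -> bool:
        return len(self.window_groups) > 0

    def columns(self) -> list[str]:
        cols = []
        for g in self.window_groups:
            cols.extend(_GROUP_COLUMNS[g])
        return cols


FEATURE_SETS = {
    "ag": FeatureSetConfig("ag", ()),
    "ag_hrv": FeatureSetConfig("ag_hrv", ("hrv",)),
    "ag_ectopic": FeatureSetConfig("ag_ectopic", ("ectopic",)),
    "ag_hrv_ectopic_rhythm": FeatureSetConfig(
        "ag_hrv_ectopic_rhythm", ("hrv", "ectopic", "rhythm")),
    "dl_only": FeatureSetConfig("dl_only", ("embedding",),
                                include_demographics=False),
    "all_features": FeatureSetConfig(
        "all_features", ("hrv", "ectopic", "rhythm", "embedding")),
}


def feature_columns(config: FeatureSetConfig) -> list[str]:
    return config.columns()


# ---------------------------------------------------------------------------
# module A
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderConfig:
    """Window-encoder architecture and training settings.

    Four conv blocks (kernel 7) with average pooling, a global average
    pool, a 128-unit fully connected layer (the embedding) and a single
    sigmoid output. ``front_pool`` decimates the raw window before the
    first convolution; widths default to a deliberately small stack that
    trains in minutes on one CPU and are configurable upward.
    """

    widths: tuple[int, ...] = (8, 16, 32, 32)
    kernel: int = 7
    pool: int = 4
    front_pool: int = 4
    embedding_dim: int = EMBEDDING_DIM
    lr: float = 1e-3
    epochs: int = 6
    batch_size: int = 16
    val_fraction: float = 0.15


class WindowEncoder:
    """DL module A: raw 10-min window -> 128-d embedding (+ sigmoid head)."""

    def __init__(self, config: EncoderConfig, seed: int):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(101,)))
        self.config = config
        layers = [nn.AvgPool1d(config.front_pool)]
        c_in = 1
        for w in config.widths:
            layers += [nn.Conv1d(c_in, w, config.kernel, rng=rng),
                       nn.ReLU(), nn.AvgPool1d(config.pool)]
            c_in = w
        layers.append(nn.GlobalAvgPool())
        self.backbone = nn.Sequential(layers)
        self.fc_embed = nn.Dense(c_in, config.embedding_dim, rng,
                                 dtype=np.float32)
        self.embed_act = nn.ReLU()
        self.fc_out = nn.Dense(config.embedding_dim, 1, rng, dtype=np.float32)
        self._all = nn.Sequential([self.backbone, self.fc_embed,
                                   self.embed_act, self.fc_out])

    @staticmethod
    def _prep(x: np.ndarray) -> np.ndarray:
        """Per-window standardization of raw signal, shape (B, 1, L)."""
        x = np.asarray(x, np.float32)
        if x.ndim == 1:
            x = x[None, :]
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True) + 1e-6
        return ((x - mu) / sd)[:, None, :]

    def forward_logits(self, x_prepped):
        h = self.backbone.forward(x_prepped)
        e = self.embed_act.forward(self.fc_embed.forward(h))
        return self.fc_out.forward(e), e

    def embed(self, windows: np.ndarray) -> np.ndarray:
        """Embeddings for raw windows (N, L) -> (N, 128), frozen weights."""
        x = self._prep(windows)
        h = self.backbone.forward(x)
        return np.asarray(self.embed_act.forward(self.fc_embed.forward(h)),
                          np.float64)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        logits, _ = self.forward_logits(self._prep(windows))
        return nn.sigmoid(logits.ravel().astype(np.float64))

    def params(self):
        return self._all.params()


def train_module_a(windows: np.ndarray, labels: np.ndarray,
                   config: EncoderConfig | None = None, seed: int = 0):
    """Train the window encoder on weakly labeled AF-free windows.

    ``windows``: raw signal array (N, L); ``labels``: recording-level AF
    outcome broadcast to each window. Refuses a single-class training set.
    Returns ``(encoder, history)`` where history holds per-epoch train loss
    and validation AUC (validation split held out inside this call).
    """
    from .evaluate import roc_auc

    cfg = config or EncoderConfig()
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    enc = WindowEncoder(cfg, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(102,)))
    n = windows.shape[0]
    order = rng.permutation(n)
    n_val = max(int(cfg.val_fraction * n), 2) if cfg.val_fraction > 0 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[tr_idx])) < 2:
        raise ValueError("training labels contain a single class after "
                         "validation split")
    opt = nn.Adam(enc.params(), lr=cfg.lr)
    history = {"train_loss": [], "val_auc": []}
    for epoch in range(cfg.epochs):
        perm = rng.permutation(tr_idx)
        losses = []
        for i in range(0, perm.size, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            xb = enc._prep(windows[idx])
            opt.zero_grad()
            logits, _ = enc.forward_logits(xb)
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            enc._all.backward(dlogits.astype(np.float32))
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val and len(np.unique(y[val_idx])) == 2:
            scores = _batched(enc.predict_proba, windows[val_idx],
                              cfg.batch_size)
            history["val_auc"].append(roc_auc(scores, y[val_idx]))
    return enc, history


def _batched(fn, X, batch):
    out = [fn(X[i:i + batch]) for i in range(0, X.shape[0], batch)]
    return np.concatenate(out)


def encode_windows(encoder: WindowEncoder, windows: np.ndarray,
                   batch_size: int = 16) -> np.ndarray:
    """Embed raw windows in fixed-size chunks (deterministic batching)."""
    return np.stack([
        e for i in range(0, windows.shape[0], batch_size)
        for e in encoder.embed(windows[i:i + batch_size])
    ])


def weights_checksum(model) -> str:
    """SHA-256 checksum over a model's parameters (frozen-weights assert)."""
    if isinstance(model, (WindowEncoder, RiskModel)):
        return nn.params_checksum(model._all)
    return nn.params_checksum(model)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _schema_fingerprint(payload: dict) -> str:
    import hashlib
    import json
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()


def save_encoder(encoder: "WindowEncoder", path, seed: int = 0):
    """Write encoder weights + architecture fingerprint as JSON."""
    import dataclasses
    import json
    schema = {"kind": "window_encoder",
              "config": dataclasses.asdict(encoder.config)}
    payload = {
        "schema": schema,
        "fingerprint": _schema_fingerprint(schema),
        "seed": seed,
        "weights": [p.value.tolist() for p in encoder.params()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_encoder(path) -> "WindowEncoder":
    """Rebuild an encoder from JSON; refuses a tampered/mismatched schema."""
    import json
    with open(path) as fh:
        payload = json.load(fh)
    schema = payload["schema"]
    if (schema.get("kind") != "window_encoder"
            or _schema_fingerprint(schema) != payload["fingerprint"]):
        raise ValueError("schema fingerprint mismatch: refusing to load")
    cfg = EncoderConfig(**{**schema["config"],
                           "widths": tuple(schema["config"]["widths"])})
    enc = WindowEncoder(cfg, payload.get("seed", 0))
    params = enc.params()
    if len(params) != len(payload["weights"]):
        raise ValueError("weight count does not match the architecture")
    for p, w in zip(params, payload["weights"]):
        arr = np.asarray(w, dtype=p.value.dtype)
        if arr.shape != p.value.shape:
            raise ValueError("weight shape does not match the architecture")
        p.value[...] = arr
    return enc


# ---------------------------------------------------------------------------
# module B
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceModelConfig:
    hidden: int = 16
    n_layers: int = 2
    head_width: int = 32
    lr: float = 3e-3
    epochs: int = 40
    batch_size: int = 32
    val_fraction: float = 0.15
    patience: int = 6


class RiskModel:
    """DL module B for one feature-set configuration (and one age group or
    pooled group at desk scale)."""

    def __init__(self, feature_set: FeatureSetConfig, n_features: int,
                 config: SequenceModelConfig, seed: int):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(201,)))
        self.feature_set = feature_set
        self.config = config
        self.n_features = n_features
        n_demo = 2 if feature_set.include_demographics else 0
        if feature_set.use_recurrent:
            if n_features <= 0:
                raise ValueError("empty feature configuration other than AG "
                                 "is rejected")
            self.lstm = nn.BiLSTM(n_features, config.hidden,
                                  config.n_layers, rng)
            head_in = 2 * config.hidden + n_demo
        else:
            if n_demo == 0:
                raise ValueError("the non-recurrent configuration requires "
                                 "demographics")
            self.lstm = None
            head_in = n_demo
        self.fc1 = nn.Dense(head_in, config.head_width, rng)
        self.act = nn.ReLU()
        self.fc2 = nn.Dense(config.head_width, 1, rng)
        mods = ([self.lstm] if self.lstm is not None else []) + \
            [self.fc1, self.act, self.fc2]
        self._all = nn.Sequential(mods)
        self._n_demo = n_demo

    def forward_logits(self, seqs, demo):
        if self.lstm is not None:
            s = self.lstm.forward(seqs)
            h = np.concatenate([s, demo], axis=1) if self._n_demo else s
        else:
            h = demo
        return self.fc2.forward(self.act.forward(self.fc1.forward(h)))

    def backward(self, dlogits):
        dh = self.fc1.backward(self.act.backward(self.fc2.backward(dlogits)))
        if self.lstm is not None:
            ds = dh[:, :dh.shape[1] - self._n_demo] if self._n_demo else dh
            self.lstm.backward(ds)

    def predict(self, seqs, demo):
        """Risk scores in (0, 1); deterministic, batch-composition invariant."""
        logits = self.forward_logits(seqs, demo)
        return nn.sigmoid(logits.ravel())

    def params(self):
        return self._all.params()


def _as_batches(n, batch, rng):
    perm = rng.permutation(n)
    return [perm[i:i + batch] for i in range(0, n, batch)]


def train_module_b(sequences: np.ndarray, demographics: np.ndarray,
                   labels: np.ndarray, feature_set: FeatureSetConfig,
                   config: SequenceModelConfig | None = None,
                   seed: int = 0):
    """Train the sequence risk model.

    ``sequences``: (N, T, D) normalized window-feature sequences (T from 1
    for a 10-min input up to 144 for 24 h; D per the feature set; for the
    AG configuration D may be 0). ``demographics``: (N, 2) normalized
    [age, sex]. Early stopping monitors validation loss.
    """
    cfg = config or SequenceModelConfig()
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    D = sequences.shape[2] if sequences.ndim == 3 else 0
    model = RiskModel(feature_set, D, cfg, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(202,)))
    n = y.shape[0]
    order = rng.permutation(n)
    n_val = max(int(cfg.val_fraction * n), 2) if cfg.val_fraction > 0 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    opt = nn.Adam(model.params(), lr=cfg.lr)
    best = (np.inf, None, 0)
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _as_batches(tr_idx.size, cfg.batch_size, rng):
            ii = tr_idx[idx]
            opt.zero_grad()
            logits = model.forward_logits(sequences[ii], demographics[ii])
            loss, dlogits = nn.bce_with_logits(logits, y[ii])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            logits = model.forward_logits(sequences[val_idx],
                                          demographics[val_idx])
            vloss, _ = nn.bce_with_logits(logits, y[val_idx])
            history["val_loss"].append(vloss)
            if vloss < best[0] - 1e-5:
                best = (vloss, [p.value.copy() for p in model.params()],
                        epoch)
            elif epoch - best[2] >= cfg.patience:
                break
    if best[1] is not None:
        for p, v in zip(model.params(), best[1]):
            p.value[...] = v
    return model, history


def predict_risk(model: RiskModel, sequences: np.ndarray,
                 demographics: np.ndarray) -> np.ndarray:
    """Raw risk scores for feature sequences (any length T >= 1)."""
    if model.lstm is not None and (sequences.ndim != 3
                                   or sequences.shape[1] < 1):
        raise ValueError("sequences must be (N, T, D) with T >= 1")
    return model.predict(sequences, demographics)
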