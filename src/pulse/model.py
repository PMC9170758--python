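"""The Ψ-site convolutional classifier: architecture, training, and CV.

The network reads a one-hot 101×4 sequence window and emits a single
probability-like score (the local pseudouridylation potential, lPPS).
Architecture: two alternately stacked valid convolution + max-pooling
blocks (64 filters of width 8 over the 4 nucleotide channels, then 32
filters of width 8 over the 64 feature channels; pooling width 2),
batch normalization after each convolution, PReLU activations, then a
64-64-1 fully connected head with dropout and a logistic output unit.
Training is SGD with momentum on binary cross-entropy with early
stopping on a validation split.

Hyperparameter selection follows the nested cross-validation protocol:
an inner k-fold grid search on each outer-training portion picks the
setting with the best mean inner validation AUC, the model is refit on
the whole outer-training portion, and out-of-fold predictions are pooled
across outer folds.
"""

from __future__ import annotations

import io
import itertools
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .seqdata import LabeledSample, encode_samples, make_folds

INPUT_LEN = 101
_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and optimizer hyperparameters.

    Defaults are the published architecture constants; the optimizer
    settings (not published) are this package's defaults and are all
    grid-searchable.
    """

    conv1_filters: int = 64
    conv1_len: int = 8
    conv2_filters: int = 32
    conv2_len: int = 8
    pool_len: int = 2
    fc_units: tuple[int, ...] = (64, 64)
    output_units: int = 1
    learning_rate: float = 0.1
    dropout_p: float = 0.5
    momentum: float = 0.9
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    clip_norm: float = 10.0
    bn_momentum: float = 0.9
    bn_eps: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        feature_map_sizes(self)  # raises if the arithmetic is invalid
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def replace(self, **kwargs) -> "ModelConfig":
        d = asdict(self)
        d.update(kwargs)
        d["fc_units"] = tuple(d["fc_units"])
        return ModelConfig(**d)


def feature_map_sizes(config: ModelConfig, input_len: int = INPUT_LEN) -> dict[str, int]:
    """Closed-form layer output lengths for valid convs and width-2 pools.

    For the published constants on a 101-nt input: conv1 94 → pool1 47 →
    conv2 40 → pool2 20, flattened width 20 × 32 = 640.
    """
    l1 = input_len - config.conv1_len + 1
    if l1 < 1:
        raise ValueError(
            f"conv1 kernel {config.conv1_len} exceeds input length {input_len}"
        )
    p1 = l1 // config.pool_len
    l2 = p1 - config.conv2_len + 1
    if l2 < 1:
        raise ValueError(
            f"conv2 kernel {config.conv2_len} exceeds pooled length {p1}"
        )
    p2 = l2 // config.pool_len
    if p2 < 1:
        raise ValueError("second pooling layer produces an empty feature map")
    return {
        "conv1": l1,
        "pool1": p1,
        "conv2": l2,
        "pool2": p2,
        "flatten": p2 * config.conv2_filters,
    }


class PulseNet:
    """The layer stack plus forward/backward plumbing."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        sizes = feature_map_sizes(config)
        c = config
        self.layers: list[nn.Layer] = [
            nn.Conv1D(4, c.conv1_filters, c.conv1_len, rng),
            nn.BatchNorm(c.conv1_filters, c.bn_momentum, c.bn_eps),
            nn.PReLU(c.conv1_filters),
            nn.MaxPool1D(c.pool_len),
            nn.Conv1D(c.conv1_filters, c.conv2_filters, c.conv2_len, rng),
            nn.BatchNorm(c.conv2_filters, c.bn_momentum, c.bn_eps),
            nn.PReLU(c.conv2_filters),
            nn.MaxPool1D(c.pool_len),
            nn.Flatten(),
        ]
        width = sizes["flatten"]
        for units in c.fc_units:
            self.layers.append(nn.Dense(width, units, rng))
            self.layers.append(nn.PReLU(units))
            self.layers.append(nn.Dropout(c.dropout_p, rng))
            width = units
        self.layers.append(nn.Dense(width, c.output_units, rng))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training)
        return nn.sigmoid(out[:, 0])

    def backward(self, p: np.ndarray, y: np.ndarray) -> None:
        # combined sigmoid + BCE gradient wrt the logit
        dlogit = ((p - y) / len(y)).astype(np.float32)[:, None]
        dout = dlogit
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    # -- parameter snapshots -------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                state[f"layer{i}.{name}"] = arr.copy()
            if isinstance(layer, nn.BatchNorm):
                for name, arr in layer.state().items():
                    state[f"layer{i}.{name}"] = arr.copy()
        return state

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                arr[...] = state[f"layer{i}.{name}"]
            if isinstance(layer, nn.BatchNorm):
                for name, arr in layer.state().items():
                    arr[...] = state[f"layer{i}.{name}"]

    @property
    def conv1(self) -> nn.Conv1D:
        return self.layers[0]  # type: ignore[return-value]


@dataclass
class TrainedModel:
    """A trained parameterization with its config and training history."""

    config: ModelConfig
    net: PulseNet
    history: dict[str, list[float]] = field(default_factory=dict)
    stopped_epoch: int = 0

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Scores in [0, 1] for a (n, 101, 4) batch; order preserved."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1:] != (INPUT_LEN, 4):
            raise ValueError(f"expected (n, {INPUT_LEN}, 4) input, got {X.shape}")
        out = np.empty(len(X), dtype=np.float64)
        for start in range(0, len(X), batch_size):
            out[start:start + batch_size] = self.net.forward(
                X[start:start + batch_size], training=False
            )
        return out

    def predict_samples(self, samples: Sequence[LabeledSample]) -> np.ndarray:
        X, _ = encode_samples(samples)
        return self.predict(X)


def build_model(config: ModelConfig) -> PulseNet:
    """Instantiate an untrained network from a validated config."""
    rng = np.random.default_rng(config.seed)
    return PulseNet(config, rng)


def train(
    train_samples: Sequence[LabeledSample] | tuple[np.ndarray, np.ndarray],
    validation_samples: Sequence[LabeledSample] | tuple[np.ndarray, np.ndarray] | None,
    config: ModelConfig,
    net: PulseNet | None = None,
) -> TrainedModel:
    """SGD + momentum on binary cross-entropy with early stopping.

    ``validation_samples=None`` carves a 10% split off the training set
    (seeded) to drive early stopping.  The parameters from the epoch with
    the best validation loss are restored at the end.
    """
    if isinstance(train_samples, tuple):
        X, y = train_samples
    else:
        X, y = encode_samples(train_samples)
    X = X.astype(np.float32)
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(config.seed)
    if validation_samples is None:
        n_val = max(1, int(round(0.1 * len(y))))
        perm = rng.permutation(len(y))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xv, yv = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]
        if len(np.unique(y)) < 2:
            raise ValueError("training split contains a single class")
    elif isinstance(validation_samples, tuple):
        Xv, yv = validation_samples
        Xv = Xv.astype(np.float32)
        yv = np.asarray(yv, dtype=np.float64)
    else:
        Xv, yv = encode_samples(validation_samples)
        Xv = Xv.astype(np.float32)
        yv = yv.astype(np.float64)

    if net is None:
        net = PulseNet(config, rng)
    optimizer = nn.SGDMomentum(net.layers, config.learning_rate, config.momentum,
                               config.clip_norm)

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_state = net.get_state()
    best_epoch = 0
    wait = 0
    stopped = 0
    n = len(y)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            p = net.forward(X[idx], training=True)
            epoch_loss += nn.bce_loss(p, y[idx]) * len(idx)
            net.backward(p, y[idx])
            optimizer.step()
        history["train_loss"].append(epoch_loss / n)

        pv = np.concatenate([
            net.forward(Xv[s:s + 256], training=False)
            for s in range(0, len(yv), 256)
        ])
        val_loss = nn.bce_loss(pv, yv)
        history["val_loss"].append(val_loss)
        stopped = epoch
        if not (np.isfinite(val_loss) and np.isfinite(history["train_loss"][-1])):
            break  # diverged; fall back to the best finite parameters
        if val_loss < best_loss - config.early_stop_min_delta:
            best_loss = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait > config.early_stop_patience:
                break

    net.set_state(best_state)
    return TrainedModel(config=config, net=net, history=history, stopped_epoch=stopped)


def predict(model: TrainedModel, batch) -> np.ndarray:
    """Functional alias for :meth:`TrainedModel.predict`."""
    if not isinstance(batch, np.ndarray):
        batch = np.stack([np.asarray(b, dtype=np.float32) for b in batch])
    return model.predict(batch)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file archive: JSON config + raw weight arrays (versioned)."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "history": model.history,
        "stopped_epoch": model.stopped_epoch,
    }
    state = model.net.get_state()
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            weights = np.load(io.BytesIO(zf.read("weights.npz")))
            state = {k: weights[k] for k in weights.files}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or unreadable model file: {path}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {meta.get('format_version')!r}"
        )
    cfg_dict = meta["config"]
    cfg_dict["fc_units"] = tuple(cfg_dict["fc_units"])
    config = ModelConfig(**cfg_dict)
    net = build_model(config)
    net.set_state(state)
    return TrainedModel(
        config=config,
        net=net,
        history=meta["history"],
        stopped_epoch=meta["stopped_epoch"],
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class GridSpec:
    """Candidate values per tunable hyperparameter, e.g.
    ``GridSpec({"learning_rate": [0.1, 0.01, 0.001], "dropout_p": [0.25, 0.5]})``.
    """

    values: dict[str, list]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("grid is empty")
        for key, vals in self.values.items():
            if not vals:
                raise ValueError(f"empty candidate list for {key!r}")

    def combinations(self) -> list[dict]:
        keys = list(self.values)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.values[k] for k in keys))]


DEFAULT_GRID = GridSpec({"learning_rate": [0.1, 0.01, 0.001], "dropout_p": [0.25, 0.5]})


@dataclass
class CVResult:
    """Pooled out-of-fold predictions plus per-fold bookkeeping."""

    scores: np.ndarray          # one out-of-fold score per sample, input order
    labels: np.ndarray
    fold_index: np.ndarray
    fold_params: list[dict | None]
    config: ModelConfig

    def __post_init__(self) -> None:
        if np.isnan(self.scores).any():
            raise ValueError("pooled out-of-fold predictions are incomplete")


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def cross_validate(
    samples: Sequence[LabeledSample],
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Plain k-fold CV with fixed hyperparameters.

    Each fold's model trains on the other k−1 folds (10% of which is
    held out internally for early stopping) and scores the fold; the
    out-of-fold scores are pooled in input order.
    """
    X, y = encode_samples(samples)
    folds = make_folds(samples, k=k, seed=seed)
    scores = np.full(len(y), np.nan)
    for f in range(k):
        test = folds.fold_index == f
        cfg = config.replace(seed=config.seed + f)
        model = train((X[~test], y[~test]), None, cfg)
        scores[test] = model.predict(X[test])
    return CVResult(scores=scores, labels=y, fold_index=folds.fold_index,
                    fold_params=[None] * k, config=config)


def nested_cv(
    samples: Sequence[LabeledSample],
    grid: GridSpec,
    k_outer: int = 10,
    k_inner: int = 10,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> CVResult:
    """Nested CV with inner grid search.

    For each outer fold, every grid combination is evaluated by
    ``k_inner``-fold CV on the outer-training portion (mean inner
    validation AUC); the best combination is refit on the full
    outer-training portion and scored on the outer test fold.
    """
    if config is None:
        config = ModelConfig()
    combos = grid.combinations()
    X, y = encode_samples(samples)
    outer = make_folds(samples, k=k_outer, seed=seed)
    scores = np.full(len(y), np.nan)
    fold_params: list[dict | None] = []
    for f in range(k_outer):
        test = outer.fold_index == f
        tr_idx = np.flatnonzero(~test)
        if len(combos) == 1:
            best_combo = combos[0]
        else:
            inner = make_folds(tr_idx, k=k_inner, seed=seed * 1000 + f)
            best_combo, best_auc = None, -np.inf
            for combo in combos:
                cfg = config.replace(seed=config.seed + f, **combo)
                aucs = []
                for g in range(k_inner):
                    val = inner.fold_index == g
                    m = train((X[tr_idx[~val]], y[tr_idx[~val]]), None, cfg)
                    aucs.append(_auc(m.predict(X[tr_idx[val]]), y[tr_idx[val]]))
                mean_auc = float(np.mean(aucs))
                if mean_auc > best_auc:
                    best_auc, best_combo = mean_auc, combo
        fold_params.append(best_combo)
        cfg = config.replace(seed=config.seed + f, **best_combo)
        model = train((X[tr_idx], y[tr_idx]), None, cfg)
        scores[test] = model.predict(X[test])
    return CVResult(scores=scores, labels=y, fold_index=outer.fold_index,
                    fold_params=fold_params, config=config)
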