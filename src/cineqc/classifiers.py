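"""Spatio-temporal artefact classifiers: 3D CNN and LRCN.

Two video-classification architectures operate on cropped, intensity
normalised 2D+time sequences:

* **3D CNN** — 6 convolutional layers (stride 1, shape-preserving padding,
  ReLU, dropout), 4 max-pooling layers, then two fully-connected layers
  (1024 units, then one per class) and a softmax readout.
* **LRCN** — a per-frame feature extractor of 6 convolutional and 3 pooling
  layers whose vectorised output feeds an LSTM; the class prediction is read
  from the final LSTM step.

Training uses SGD with momentum on the (optionally class-weighted) cross
entropy, early stopping on validation balanced accuracy, and best-checkpoint
selection.  Filter counts, kernel sizes and the LSTM width are configurable;
``ModelSpec.tiny`` gives a preset small enough for CPU-scale experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.metrics import balanced_accuracy_score

from . import nn
from .phantom import CineSequence

__all__ = [
    "ModelSpec", "TrainConfig", "ModelState", "build_model", "train", "predict",
    "binary_cross_entropy", "inverse_frequency_weights",
    "augment_translation", "augment_gaussian_blur", "encode_dataset", "Trainer",
]

#: label -> class index maps for the binary and 3-class settings
BINARY_CLASSES = {"good": 0, "artefact": 1, "mistriggering": 1, "breathing": 1}
MULTI_CLASSES = {"good": 0, "breathing": 1, "mistriggering": 2}


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``input_shape`` is (height, width, n_frames).  ``conv_channels`` gives
    the six per-layer filter counts.  ``fc_width`` is the first
    fully-connected width of the 3D CNN (1024 by default); ``lstm_hidden``
    the LSTM state width of the LRCN.
    """

    architecture: str
    input_shape: tuple[int, int, int] = (80, 80, 50)
    n_classes: int = 2
    conv_channels: tuple[int, ...] = (16, 32, 32, 64, 64, 128)
    kernel_size: int = 3
    lstm_hidden: int = 128
    fc_width: int = 1024
    dropout_rate: float = 0.5
    init: str = "he"

    def __post_init__(self) -> None:
        if self.architecture not in ("3dcnn", "lrcn"):
            raise ValueError(f"architecture must be '3dcnn' or 'lrcn'; got {self.architecture!r}")
        if len(self.conv_channels) != 6:
            raise ValueError("conv_channels must list 6 filter counts (6 convolutional layers)")
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3; got {self.n_classes}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        h, w, t = self.input_shape
        n_pools = 4 if self.architecture == "3dcnn" else 3
        dims = [h, w] + ([t] if self.architecture == "3dcnn" else [])
        for _ in range(n_pools):
            dims = [d // 2 for d in dims]
        if any(d < 1 for d in dims):
            raise ValueError(
                f"input shape {self.input_shape} incompatible with {n_pools} 2x pooling layers"
            )

    @classmethod
    def tiny(cls, architecture: str, input_shape: tuple[int, int, int],
             n_classes: int = 2) -> "ModelSpec":
        """Small preset for CPU-scale experiments and tests."""
        return cls(architecture=architecture, input_shape=input_shape,
                   n_classes=n_classes, conv_channels=(2, 2, 4, 4, 8, 8),
                   lstm_hidden=16, fc_width=32, dropout_rate=0.0)

    @property
    def label_map(self) -> dict:
        return BINARY_CLASSES if self.n_classes == 2 else MULTI_CLASSES


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the reference protocol)."""

    batch_size: int = 50
    learning_rate: float = 0.0001
    momentum: float = 0.90
    epochs_per_stage: int = 10
    patience: int = 100
    min_rel_improvement: float = 0.005
    class_weights: np.ndarray | str | None = None
    seed: int = 0
    max_epochs: int = 500
    grad_clip: float | None = 5.0    # global L2 gradient-norm cap (LSTM stability)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if not (0.0 < self.min_rel_improvement < 1.0):
            raise ValueError("min_rel_improvement must lie in (0, 1)")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class ModelState:
    """A model: its spec, trainable weights (inside ``net``) and training log."""

    spec: ModelSpec
    net: object
    training_log: list[dict] = field(default_factory=list)

    def copy_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.net.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.net.params(), weights):
            p[...] = w


def build_model(spec: ModelSpec, seed: int = 0) -> ModelState:
    """Randomly initialised model; deterministic given spec and seed."""
    rng = np.random.default_rng(seed)
    h, w, t = spec.input_shape
    ch = spec.conv_channels
    k = spec.kernel_size
    drop = spec.dropout_rate
    kw = dict(rng=rng, init=spec.init)

    def conv_block(conv):
        return [conv, nn.ReLU(), nn.Dropout(drop)]

    if spec.architecture == "3dcnn":
        layers: list = []
        layers += conv_block(nn.Conv3d(1, ch[0], k, **kw))
        layers += conv_block(nn.Conv3d(ch[0], ch[1], k, **kw))
        layers.append(nn.MaxPool3d())
        layers += conv_block(nn.Conv3d(ch[1], ch[2], k, **kw))
        layers.append(nn.MaxPool3d())
        layers += conv_block(nn.Conv3d(ch[2], ch[3], k, **kw))
        layers.append(nn.MaxPool3d())
        layers += conv_block(nn.Conv3d(ch[3], ch[4], k, **kw))
        layers += conv_block(nn.Conv3d(ch[4], ch[5], k, **kw))
        layers.append(nn.MaxPool3d())
        layers.append(nn.Flatten())
        d, hh, ww = t, h, w
        for _ in range(4):
            d, hh, ww = d // 2, hh // 2, ww // 2
        flat = ch[5] * d * hh * ww
        layers.append(nn.Dense(flat, spec.fc_width, **kw))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(drop))
        layers.append(nn.Dense(spec.fc_width, spec.n_classes, **kw))
        net: object = nn.Sequential(layers)
    else:
        feats: list = []
        feats += conv_block(nn.Conv2d(1, ch[0], k, **kw))
        feats += conv_block(nn.Conv2d(ch[0], ch[1], k, **kw))
        feats.append(nn.MaxPool2d())
        feats += conv_block(nn.Conv2d(ch[1], ch[2], k, **kw))
        feats += conv_block(nn.Conv2d(ch[2], ch[3], k, **kw))
        feats.append(nn.MaxPool2d())
        feats += conv_block(nn.Conv2d(ch[3], ch[4], k, **kw))
        feats += conv_block(nn.Conv2d(ch[4], ch[5], k, **kw))
        feats.append(nn.MaxPool2d())
        feats.append(nn.Flatten())
        hh, ww = h, w
        for _ in range(3):
            hh, ww = hh // 2, ww // 2
        feat_dim = ch[5] * hh * ww
        net = nn.LRCNNet(
            features=nn.Sequential(feats),
            lstm=nn.LSTMLast(feat_dim, spec.lstm_hidden, **kw),
            head=nn.Dense(spec.lstm_hidden, spec.n_classes, **kw),
        )
    return ModelState(spec=spec, net=net)


def encode_dataset(seqs: list[CineSequence], spec: ModelSpec,
                   dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into the model's input tensor and integer labels.

    LRCN input is (N, T, H, W); 3D-CNN input is (N, 1, T, H, W).
    """
    h, w, t = spec.input_shape
    xs, ys = [], []
    for s in seqs:
        if s.shape != (h, w, t):
            raise ValueError(f"sequence shape {s.shape} does not match spec input {spec.input_shape}")
        if s.label is None:
            raise ValueError("sequence has no label")
        xs.append(s.frames.transpose(2, 0, 1))     # (T, H, W)
        ys.append(spec.label_map[s.label])
    x = np.stack(xs).astype(dtype)
    if spec.architecture == "3dcnn":
        x = x[:, None, :, :, :]
    return x, np.asarray(ys, dtype=int)


def predict(state: ModelState, seq: CineSequence) -> np.ndarray:
    """Class-probability vector for one sequence (softmax; sums to 1)."""
    h, w, t = state.spec.input_shape
    if seq.shape != (h, w, t):
        raise ValueError(f"sequence shape {seq.shape} does not match spec input "
                         f"{state.spec.input_shape}")
    x = seq.frames.transpose(2, 0, 1)[None].astype(np.float32)
    if state.spec.architecture == "3dcnn":
        x = x[:, None]
    logits = state.net.forward(x, train=False)
    return nn.softmax(logits)[0]


def predict_batch(state: ModelState, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    probs = []
    for i in range(0, x.shape[0], batch_size):
        probs.append(nn.softmax(state.net.forward(x[i:i + batch_size], train=False)))
    return np.concatenate(probs)


def binary_cross_entropy(y: np.ndarray, y_hat: np.ndarray,
                         class_weights: np.ndarray | None = None,
                         eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, optionally weighted per true class.

    ``L = -(1/n) * sum_i w_i * [y_i log yhat_i + (1-y_i) log(1-yhat_i)]``
    with predictions clipped to ``[eps, 1-eps]``.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    p = np.clip(y_hat, eps, 1.0 - eps)
    terms = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=float)[y.astype(int)]
        terms = terms * w
    return float(-terms.mean())


def inverse_frequency_weights(y: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Per-class weights proportional to inverse class frequency.

    Normalised so the majority class has weight 1 (a 224:10 split gives
    weights 1 and 22.4).
    """
    y = np.asarray(y, dtype=int)
    k = n_classes if n_classes is not None else int(y.max()) + 1
    counts = np.bincount(y, minlength=k).astype(float)
    if np.any(counts == 0):
        raise ValueError("every class must be present to derive inverse-frequency weights")
    return counts.max() / counts


def save_checkpoint(state: ModelState, path) -> None:
    """Opaque weight file (npz) plus a JSON sidecar with the full spec."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **{f"p{i}": p for i, p in enumerate(state.net.params())})
    sidecar = path.with_suffix(".json")
    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(state.spec).items()}
    sidecar.write_text(json.dumps({"spec": spec_dict,
                                   "n_epochs_logged": len(state.training_log)}, indent=2))


def load_checkpoint(path) -> ModelState:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_dict = dict(meta["spec"])
    for key in ("input_shape", "conv_channels"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = ModelSpec(**spec_dict)
    state = build_model(spec, seed=0)
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        weights = [data[f"p{i}"] for i in range(len(state.net.params()))]
    state.set_weights(weights)
    return state


class Trainer:
    """Epoch-level training engine shared by plain and curriculum training.

    Holds the optimiser state, the RNG stream, the best validation
    checkpoint and the per-epoch log, so that staged (curriculum) training
    can grow the pool between epochs without resetting momentum or
    reproducibility.
    """

    def __init__(self, state: ModelState, config: TrainConfig,
                 val_set: list[CineSequence]):
        if not val_set:
            raise ValueError("validation set must be non-empty")
        self.state = state
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.opt = nn.SGD(state.net.params(), lr=config.learning_rate,
                          momentum=config.momentum)
        self.x_val, self.y_val = encode_dataset(val_set, state.spec)
        self.best_metric = -np.inf
        self.best_weights = state.copy_weights()
        self.best_epoch = 0
        self.epoch = 0

    def _class_weights(self, y: np.ndarray) -> np.ndarray | None:
        cw = self.config.class_weights
        if cw is None:
            return None
        if isinstance(cw, str):
            if cw != "balanced":
                raise ValueError(f"unknown class_weights mode {cw!r}")
            return inverse_frequency_weights(y, self.state.spec.n_classes)
        return np.asarray(cw, dtype=float)

    def validation_metric(self) -> float:
        probs = predict_batch(self.state, self.x_val,
                              batch_size=min(self.config.batch_size, 32))
        return float(balanced_accuracy_score(self.y_val, probs.argmax(axis=1)))

    def run_epoch(self, x: np.ndarray, y: np.ndarray,
                  ids: list[str] | None = None) -> dict:
        """One pass over the pool (shuffled minibatches), then validation."""
        n = x.shape[0]
        cw = self._class_weights(y)
        sample_w = None if cw is None else cw[y]
        perm = self.rng.permutation(n)
        losses, correct = [], 0
        seen: set[str] = set()
        for i in range(0, n, self.config.batch_size):
            idx = perm[i:i + self.config.batch_size]
            xb, yb = x[idx], y[idx]
            wb = None if sample_w is None else sample_w[idx]
            logits = self.state.net.forward(xb, train=True, rng=self.rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb, wb)
            self.state.net.backward(dlogits)
            grads = self.state.net.grads()
            if self.config.grad_clip is not None:
                nn.clip_global_norm(grads, self.config.grad_clip)
            self.opt.step(self.state.net.params(), grads)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
            if ids is not None:
                seen.update(ids[k] for k in idx)
        self.epoch += 1
        val_metric = self.validation_metric()
        if val_metric > self.best_metric:
            self.best_metric = val_metric
            self.best_weights = self.state.copy_weights()
            self.best_epoch = self.epoch
        record = {
            "epoch": self.epoch,
            "train_loss": float(np.sum(losses) / n),
            "train_accuracy": correct / n,
            "val_balanced_accuracy": val_metric,
            "pool_size": n,
            "seen_ids": sorted(seen) if ids is not None else None,
        }
        self.state.training_log.append(record)
        return record

    def restore_best(self) -> None:
        self.state.set_weights(self.best_weights)


def train(state: ModelState, train_set: list[CineSequence],
          val_set: list[CineSequence], config: TrainConfig) -> ModelState:
    """SGD training with early stopping on validation balanced accuracy.

    Stops once ``patience`` consecutive epochs pass without a relative
    validation improvement of at least ``min_rel_improvement``; returns the
    state restored to its best-validation checkpoint, with the per-epoch log
    populated.
    """
    if not train_set:
        raise ValueError("training set must be non-empty")
    x, y = encode_dataset(train_set, state.spec)
    if np.unique(y).size < 2 and config.class_weights is None:
        raise ValueError(
            "training set contains a single class; provide class_weights to override")
    trainer = Trainer(state, config, val_set)
    best_for_stop = -np.inf
    streak = 0
    for _ in range(config.max_epochs):
        record = trainer.run_epoch(x, y)
        val = record["val_balanced_accuracy"]
        if val >= best_for_stop * (1.0 + config.min_rel_improvement) or best_for_stop <= 0:
            best_for_stop = max(best_for_stop, val)
            streak = 0
        else:
            streak += 1
        if streak >= config.patience:
            break
    trainer.restore_best()
    return state


def augment_translation(seq: CineSequence, max_frac: float = 0.2, seed: int = 0,
                        shift: tuple[int, int] | None = None) -> CineSequence:
    """Random integer translation (zero-filled), the same for every frame.

    Shifts are drawn uniformly in ``[-H*max_frac, H*max_frac]`` /
    ``[-W*max_frac, W*max_frac]`` per axis; ``shift`` pins them for tests.
    The label is preserved.
    """
    if not (0.0 < max_frac < 1.0):
        raise ValueError("max_frac must lie in (0, 1)")
    h, w, _ = seq.shape
    if shift is None:
        rng = np.random.default_rng(seed)
        sr = int(rng.integers(-int(h * max_frac), int(h * max_frac) + 1))
        sc = int(rng.integers(-int(w * max_frac), int(w * max_frac) + 1))
    else:
        sr, sc = shift
    out = np.zeros_like(seq.frames)
    rs_src = slice(max(0, -sr), min(h, h - sr))
    cs_src = slice(max(0, -sc), min(w, w - sc))
    rs_dst = slice(max(0, sr), min(h, h + sr))
    cs_dst = slice(max(0, sc), min(w, w + sc))
    out[rs_dst, cs_dst, :] = seq.frames[rs_src, cs_src, :]
    return seq.with_frames(out, extra_provenance=f"translate(shift=({sr},{sc}))")


def augment_gaussian_blur(seq: CineSequence, sigma: float) -> CineSequence:
    """Per-frame spatial Gaussian blur; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return seq.with_frames(seq.frames.copy(), extra_provenance="blur(sigma=0)")
    out = gaussian_filter(seq.frames, sigma=(sigma, sigma, 0.0))
    return seq.with_frames(out, extra_provenance=f"blur(sigma={sigma})")
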