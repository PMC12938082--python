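"""Three classifier configurations over time-frequency model inputs.

* ``cnn`` — frozen backbone, new classification head (small MLP + softmax)
  trained with Adam, categorical cross-entropy, early stopping that restores
  the weights at minimum validation loss;
* ``cnn_lstm`` — backbone feature map reshaped to a 9-step x 64-feature
  sequence (3x3 spatial regions x contiguous channel-group means), a
  bidirectional LSTM with 256 hidden units, a 512-unit fully connected layer
  with L2 regularization and dropout 0.5, then softmax;
* ``cnn_svm`` — frozen backbone features, global-average-pooled, linear SVM
  (zero trainable backbone parameters).

Training uses batch size 16, up to 100 epochs, initial learning rate 0.001
halved on validation-loss plateaus, and early stopping with patience 15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._autograd import Adam, Tensor, softmax_cross_entropy
from .backbone import BackboneSpec, TinyConvBackbone, get_backbone

MODEL_KINDS = ("cnn", "cnn_lstm", "cnn_svm")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters shared by the trainable heads."""

    epochs: int = 100
    early_stop_patience: int = 15
    batch_size: int = 16
    learning_rate: float = 0.001
    lr_plateau_factor: float = 0.5
    lr_plateau_patience: int = 5
    min_lr: float = 1e-5
    l2: float = 1e-4
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience >= self.epochs:
            raise ValueError("early_stop_patience must be < epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SequenceFeatures:
    steps: int = 9
    features_per_step: int = 64


def sequence_from_feature_map(fmap: np.ndarray, pad_channels: bool = False) -> np.ndarray:
    """Reshape an (H, W, C) feature map to a (9, 64) sequence.

    The spatial grid is split into 3x3 regions (for H = W = 7 the only
    balanced row/column partition is sizes 3, 2, 2) and averaged per region;
    regions are traversed row-major, giving 9 time steps. Channels are
    reduced to 64 features by averaging contiguous groups of ceil(C/64)
    channels. ``C < 64`` raises unless ``pad_channels`` repeats channels up
    to 64 first.
    """
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim != 3:
        raise ValueError(f"expected (H, W, C) feature map, got shape {fmap.shape}")
    h, w, c = fmap.shape
    if c < 64:
        if not pad_channels:
            raise ValueError(f"feature map has {c} < 64 channels (set pad_channels to repeat)")
        reps = int(np.ceil(64 / c))
        fmap = np.tile(fmap, (1, 1, reps))[:, :, :64]
        c = 64
    row_groups = np.array_split(np.arange(h), 3)
    col_groups = np.array_split(np.arange(w), 3)
    g = int(np.ceil(c / 64))
    out = np.empty((9, 64))
    for r in range(3):
        for cc in range(3):
            region = fmap[np.ix_(row_groups[r], col_groups[cc])].mean(axis=(0, 1))
            for k in range(64):
                out[3 * r + cc, k] = region[k * g : (k + 1) * g].mean()
    return out


def _gap(fmaps: np.ndarray) -> np.ndarray:
    """Global average pool (N, H, W, C) -> (N, C)."""
    return fmaps.mean(axis=(1, 2))


# --------------------------------------------------------------------------
# heads
# --------------------------------------------------------------------------


class _SoftmaxHead:
    """GAP features -> dense(hidden) ReLU -> dense(n_classes) softmax."""

    def __init__(self, n_features: int, n_classes: int, rng: np.random.Generator, hidden: int = 128):
        s1 = np.sqrt(2.0 / n_features)
        s2 = np.sqrt(2.0 / hidden)
        self.w1 = Tensor(rng.normal(0, s1, (n_features, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.normal(0, s2, (hidden, n_classes)), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_classes), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> Tensor:
        h = (Tensor(x) @ self.w1 + self.b1).relu()
        return h @ self.w2 + self.b2

    def l2_penalty(self) -> Tensor | None:
        return None


class _LSTMCellParams:
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s = np.sqrt(1.0 / (n_in + n_hidden))
        self.wx = Tensor(rng.normal(0, s, (n_in, 4 * n_hidden)), requires_grad=True)
        self.wh = Tensor(rng.normal(0, s, (n_hidden, 4 * n_hidden)), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.n_hidden = n_hidden

    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b]

    def run(self, xs: list[Tensor]) -> Tensor:
        """Run over the time steps, return the final hidden state (B, H)."""
        nh = self.n_hidden
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, nh)))
        c = Tensor(np.zeros((batch, nh)))
        for x in xs:
            z = x @ self.wx + h @ self.wh + self.b
            i = z[:, 0 * nh : 1 * nh].sigmoid()
            f = z[:, 1 * nh : 2 * nh].sigmoid()
            g = z[:, 2 * nh : 3 * nh].tanh()
            o = z[:, 3 * nh : 4 * nh].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class _BiLSTMHead:
    """(9, 64) sequence -> BiLSTM-256 -> FC-512 (L2, dropout) -> softmax."""

    def __init__(
        self,
        n_classes: int,
        rng: np.random.Generator,
        n_hidden: int = 256,
        n_fc: int = 512,
        l2: float = 1e-4,
        dropout: float = 0.5,
    ):
        self.fwd = _LSTMCellParams(64, n_hidden, rng)
        self.bwd = _LSTMCellParams(64, n_hidden, rng)
        s_fc = np.sqrt(2.0 / (2 * n_hidden))
        self.w_fc = Tensor(rng.normal(0, s_fc, (2 * n_hidden, n_fc)), requires_grad=True)
        self.b_fc = Tensor(np.zeros(n_fc), requires_grad=True)
        s_out = np.sqrt(2.0 / n_fc)
        self.w_out = Tensor(rng.normal(0, s_out, (n_fc, n_classes)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_classes), requires_grad=True)
        self.l2 = l2
        self.p_drop = dropout

    def params(self) -> list[Tensor]:
        return (
            self.fwd.params()
            + self.bwd.params()
            + [self.w_fc, self.b_fc, self.w_out, self.b_out]
        )

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> Tensor:
        # x: (B, 9, 64)
        steps = [Tensor(x[:, t, :]) for t in range(x.shape[1])]
        h_f = self.fwd.run(steps)
        h_b = self.bwd.run(steps[::-1])
        h = h_f.concat(h_b, axis=1)
        fc = (h @ self.w_fc + self.b_fc).relu()
        if train:
            fc = fc.dropout(self.p_drop, rng)
        return fc @ self.w_out + self.b_out

    def l2_penalty(self) -> Tensor | None:
        return self.l2 * ((self.w_fc * self.w_fc).sum() + (self.w_out * self.w_out).sum())


@dataclass
class TrainingLog:
    """Per-epoch optimization history (for checkpoints / learning curves)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr_events: list[tuple[int, float]] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
            "val_loss": self.val_loss,
            "val_acc": self.val_acc,
            "lr_events": [[e, lr] for e, lr in self.lr_events],
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }


class LungSoundModel:
    """A trained classifier configuration (backbone + head)."""

    def __init__(self, kind: str, backbone, classes: np.ndarray, config: TrainConfig):
        self.kind = kind
        self.backbone = backbone
        self.classes = classes
        self.config = config
        self.head = None
        self.svm = None
        self.scaler = None
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None
        self.log = TrainingLog()
        self._trained = False

    # -- feature plumbing --------------------------------------------------
    def _feature_maps(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        fshape = self.backbone.spec.feature_map_shape
        if x.shape[1:] == tuple(fshape):
            return x  # already feature maps
        return self.backbone.features(x)

    def _head_inputs(self, x: np.ndarray) -> np.ndarray:
        fmaps = self._feature_maps(x)
        if self.kind == "cnn_lstm":
            return np.stack([sequence_from_feature_map(f) for f in fmaps])
        if self.kind == "cnn_svm":
            return _gap(fmaps)
        # cnn head flattens the final map: the frequency-axis position of
        # energy is the discriminative cue and pooling would average it away
        return fmaps.reshape(len(fmaps), -1)

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        """Per-feature z-scoring (moments fit on the training set)."""
        if self.norm_mean is None:
            return feats
        return (feats - self.norm_mean) / self.norm_std

    # -- inference ---------------------------------------------------------
    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """Per-class softmax probabilities, or margins for the SVM."""
        if not self._trained:
            raise RuntimeError("model has not been trained")
        feats = self._head_inputs(x)
        if self.kind == "cnn_svm":
            return self.svm.decision_function(self.scaler.transform(feats))
        feats = self._standardize(feats)
        logits = self.head.forward(feats, train=False, rng=np.random.default_rng(0))
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)


def train_model(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    kind: str = "cnn",
    config: TrainConfig | None = None,
    backbone=None,
) -> LungSoundModel:
    """Fit one classifier configuration.

    ``train`` / ``val`` are ``(inputs, labels)`` pairs where inputs are
    either 256x256x3 model images or precomputed backbone feature maps and
    labels are integer class indices (at least two classes required).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"kind must be one of {MODEL_KINDS}, got {kind!r}")
    config = config or TrainConfig()
    x_tr, y_tr = np.asarray(train[0]), np.asarray(train[1])
    x_va, y_va = np.asarray(val[0]), np.asarray(val[1])
    classes = np.unique(y_tr)
    if len(y_tr) == 0 or len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    n_classes = int(classes.max()) + 1

    backbone = backbone or get_backbone("tiny")
    if kind == "cnn_lstm" and backbone.spec.trainable_top_layers > 0 and isinstance(backbone, TinyConvBackbone):
        raise ValueError("the bundled tiny backbone is frozen; trainable_top_layers must be 0")

    model = LungSoundModel(kind, backbone, classes, config)
    feats_tr = model._head_inputs(x_tr)
    feats_va = model._head_inputs(x_va)

    if kind == "cnn_svm":
        model.scaler = StandardScaler().fit(feats_tr)
        model.svm = LinearSVC(C=1.0, random_state=config.seed)
        model.svm.fit(model.scaler.transform(feats_tr), y_tr)
        model._trained = True
        return model

    # standardize head inputs on train-set moments: raw ReLU features have
    # wildly uneven scales, which destabilizes a fixed-learning-rate Adam
    model.norm_mean = feats_tr.mean(axis=0)
    model.norm_std = feats_tr.std(axis=0) + 1e-6
    feats_tr = model._standardize(feats_tr)
    feats_va = model._standardize(feats_va)

    rng = np.random.default_rng(config.seed)
    if kind == "cnn":
        model.head = _SoftmaxHead(feats_tr.shape[1], n_classes, rng)
    else:
        model.head = _BiLSTMHead(n_classes, rng, l2=config.l2, dropout=config.dropout)
    _fit_head(model, feats_tr, y_tr, feats_va, y_va, config, rng)
    model._trained = True
    return model


def _eval_loss_acc(head, x: np.ndarray, y: np.ndarray, rng) -> tuple[float, float]:
    logits = head.forward(x, train=False, rng=rng)
    loss, probs = softmax_cross_entropy(logits, y)
    return float(loss.data), float((probs.argmax(axis=1) == y).mean())


def _fit_head(model, x_tr, y_tr, x_va, y_va, config: TrainConfig, rng) -> None:
    head = model.head
    params = head.params()
    opt = Adam(params, lr=config.learning_rate)
    best_val = np.inf
    best_weights = None
    best_epoch = -1
    since_best = 0
    since_lr_drop = 0
    log = model.log
    n = len(y_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.zero_grad()
            logits = head.forward(xb, train=True, rng=rng)
            loss, probs = softmax_cross_entropy(logits, yb)
            pen = head.l2_penalty()
            total = loss + pen if pen is not None else loss
            total.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval_loss_acc(head, x_va, y_va, rng)
        log.train_loss.append(ep_loss / n)
        log.train_acc.append(ep_correct / n)
        log.val_loss.append(val_loss)
        log.val_acc.append(val_acc)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [p.data.copy() for p in params]
            best_epoch = epoch
            since_best = 0
            since_lr_drop = 0
        else:
            since_best += 1
            since_lr_drop += 1
            if since_lr_drop >= config.lr_plateau_patience and opt.lr > config.min_lr:
                opt.lr = max(opt.lr * config.lr_plateau_factor, config.min_lr)
                log.lr_events.append((epoch, opt.lr))
                since_lr_drop = 0
            if since_best >= config.early_stop_patience:
                log.stopped_epoch = epoch
                break
    if best_weights is not None:  # restore minimum-validation-loss state
        for p, wbest in zip(params, best_weights):
            p.data = wbest
    log.best_epoch = best_epoch
    if log.stopped_epoch < 0:
        log.stopped_epoch = len(log.val_loss) - 1


def predict(model: LungSoundModel, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and per-class scores for a batch.

    Scores are softmax probabilities (rows sum to 1) for the network kinds
    and decision margins for the SVM; labels are the row argmax either way.
    """
    scores = model.decision_values(images)
    labels = scores.argmax(axis=1)
    return labels, scores
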