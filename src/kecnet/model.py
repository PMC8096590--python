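"""KecNet assembly, training, prediction, parameter accounting, metrics.

The architecture (per-layer, input = one 3600-sample normalized segment):

    SincConv1d(32 filters, L=251, stride 1) -> ReLU -> MaxPool(2,2)
    -> Dropout(0.2) -> BatchNorm
    -> Conv1d(16, 5) -> ReLU -> Conv1d(16, 5) -> ReLU -> MaxPool(2,2)
    -> Dropout(0.2) -> BatchNorm -> GAP -> [concat CV scalar]
    -> Dense(16) -> ReLU -> Dropout(0.3) -> Dense(8) -> ReLU
    -> Dense(n_classes) -> softmax

The baseline model used in ablations is identical except the first layer is
a standard convolution with 32 free kernels of length 32.  Training follows
Adam(lr 3e-4, betas 0.9/0.999), batch 128, categorical cross-entropy, fully
seeded (weight init, batch order, dropout masks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import nn
from .preprocessing import AAMI_CLASSES, SegmentDataset
from .sinc import SincParams, WindowSpec, init_cutoffs, sinc_param_gain

__all__ = [
    "KecNetConfig",
    "TrainConfig",
    "KecNetModel",
    "TrainedModel",
    "Metrics",
    "build_kecnet",
    "build_baseline_cnn",
    "count_parameters",
    "train",
    "predict",
    "evaluate",
]


@dataclass
class KecNetConfig:
    """Architecture hyperparameters (defaults are the published ones)."""

    input_length: int = 3600
    sample_rate: float = 360.0
    n_sinc_filters: int = 32
    sinc_kernel_length: int = 251
    baseline_kernel_length: int = 32  # first-layer kernel of the ablation CNN
    conv_filters: int = 16
    conv_kernel: int = 5
    conv_dropout: float = 0.2
    dense_units: tuple[int, int] = (16, 8)
    dense_dropout: float = 0.3
    n_classes: int = 5
    cv_fusion: bool = True
    window: WindowSpec = field(default_factory=WindowSpec)
    init_strategy: str = "band_limited"
    min_band_hz: float = 1.0
    class_order: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        if self.input_length % 4 != 0:
            raise ValueError(
                f"input length must survive two 2x poolings; "
                f"got {self.input_length}, need a multiple of 4"
            )
        if len(self.class_order) != self.n_classes:
            raise ValueError("class_order length must equal n_classes")


@dataclass
class TrainConfig:
    """Optimization recipe (defaults are the published ones)."""

    batch_size: int = 128
    epochs: int = 60
    learning_rate: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")


class KecNetModel:
    """Feature stack + optional CV fusion + dense head, with backprop."""

    def __init__(self, config: KecNetConfig, feature_layers: list[nn.Layer],
                 head_layers: list[nn.Layer]) -> None:
        self.config = config
        self.feature_layers = feature_layers
        self.head_layers = head_layers

    @property
    def layers(self) -> list[nn.Layer]:
        return self.feature_layers + self.head_layers

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, cv: np.ndarray | None,
                training: bool = False) -> np.ndarray:
        """Logits for a batch; ``x`` is (B, M), ``cv`` is (B,) when fused."""
        x = np.asarray(x)
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected segments of length {self.config.input_length}, "
                f"got shape {x.shape}"
            )
        h = x[:, None, :]
        for layer in self.feature_layers:
            h = layer.forward(h, training)
        self._gap_width = h.shape[1]
        if self.config.cv_fusion:
            if cv is None:
                raise ValueError("cv_fusion is enabled but no CV values given")
            h = np.concatenate([h, np.asarray(cv, dtype=h.dtype)[:, None]], axis=1)
        for layer in self.head_layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.head_layers):
            d = layer.backward(d)
        if self.config.cv_fusion:
            d = d[:, : self._gap_width]  # CV is an input, not a parameter
        for layer in reversed(self.feature_layers):
            d = layer.backward(d)
            if d is None:  # reached the (input-gradient-free) first layer
                break

    def recalibrate_bn(self, x: np.ndarray, cv: np.ndarray | None,
                       batch_size: int = 256) -> None:
        """Set BN inference statistics to exact population moments.

        Runs forward passes (dropout off, per-batch normalization) over the
        given data and aggregates each BN layer's input mean/variance.
        """
        bns = [l for l in self.layers if isinstance(l, nn.BatchNorm1d)]
        for l in bns:
            l.start_collect()
        for i in range(0, len(x), batch_size):
            sl = slice(i, i + batch_size)
            self.forward(x[sl], None if cv is None else cv[sl], training=False)
        for l in bns:
            l.finish_collect()

    def predict_proba(self, x: np.ndarray, cv: np.ndarray | None,
                      batch_size: int = 256) -> np.ndarray:
        chunks = []
        for i in range(0, len(x), batch_size):
            sl = slice(i, i + batch_size)
            logits = self.forward(x[sl], None if cv is None else cv[sl],
                                  training=False)
            chunks.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(chunks, axis=0)

    @property
    def sinc_layer(self) -> nn.SincConv1d | None:
        first = self.feature_layers[0]
        return first if isinstance(first, nn.SincConv1d) else None


def _shared_tail(config: KecNetConfig, rng: np.random.Generator, dtype):
    """Everything after the first convolution, identical for both models."""
    cf, ck = config.conv_filters, config.conv_kernel
    feature = [
        nn.ReLU(),
        nn.MaxPool1d(),
        nn.Dropout(config.conv_dropout),
        nn.BatchNorm1d(config.n_sinc_filters, dtype=dtype),
        nn.Conv1dSame(config.n_sinc_filters, cf, ck, rng, dtype=dtype),
        nn.ReLU(),
        nn.Conv1dSame(cf, cf, ck, rng, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool1d(),
        nn.Dropout(config.conv_dropout),
        nn.BatchNorm1d(cf, dtype=dtype),
        nn.GlobalAvgPool(),
    ]
    d1, d2 = config.dense_units
    head_in = cf + (1 if config.cv_fusion else 0)
    head = [
        nn.Dense(head_in, d1, rng, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(config.dense_dropout),
        nn.Dense(d1, d2, rng, dtype=dtype),
        nn.ReLU(),
        nn.Dense(d2, config.n_classes, rng, dtype=dtype),
    ]
    return feature, head


def build_kecnet(config: KecNetConfig = KecNetConfig(), seed: int = 0,
                 dtype=np.float32) -> KecNetModel:
    """Untrained KecNet with seeded initialization."""
    rng = np.random.default_rng(seed)
    sp = init_cutoffs(
        config.n_sinc_filters,
        config.sample_rate,
        strategy=config.init_strategy,
        seed=seed,
        kernel_length=config.sinc_kernel_length,
        min_band=config.min_band_hz,
    )
    sinc = nn.SincConv1d(sp, window=config.window, dtype=dtype)
    feature, head = _shared_tail(config, rng, dtype)
    return KecNetModel(config, [sinc] + feature, head)


def build_baseline_cnn(config: KecNetConfig = KecNetConfig(), seed: int = 0,
                       dtype=np.float32) -> KecNetModel:
    """Ablation baseline: first layer is a free-tap convolution (32 x 32)."""
    rng = np.random.default_rng(seed)
    first = nn.Conv1dSame(1, config.n_sinc_filters, config.baseline_kernel_length,
                          rng, bias=True, first_layer=True, dtype=dtype)
    feature, head = _shared_tail(config, rng, dtype)
    return KecNetModel(config, [first] + feature, head)


def count_parameters(model: KecNetModel) -> tuple[pd.DataFrame, int]:
    """Trainable values per layer plus total.

    For a sinc first layer the table also reports the parameter gain versus
    a standard convolution layer of the same kernel length.
    """
    rows = []
    for i, layer in enumerate(model.layers):
        if layer.n_params == 0:
            continue
        row = {
            "layer_index": i,
            "layer": type(layer).__name__,
            "n_params": layer.n_params,
        }
        if isinstance(layer, nn.SincConv1d):
            row["gain_vs_standard_pct"] = sinc_param_gain(layer.sp.kernel_length)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, int(table["n_params"].sum())


@dataclass
class TrainedModel:
    model: KecNetModel
    history: pd.DataFrame  # epoch, train_loss, train_acc, val_loss, val_acc
    train_config: TrainConfig


def _encode_labels(labels: np.ndarray, class_order: tuple[str, ...]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(class_order)}
    try:
        return np.asarray([lookup[str(l)] for l in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc} not in class order {class_order}") from exc


def _accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == y).mean())


def train(model: KecNetModel, dataset: SegmentDataset,
          tc: TrainConfig = TrainConfig()) -> TrainedModel:
    """Seeded Adam / cross-entropy training on the dataset's train split.

    Validation loss/accuracy are recorded per epoch on the ``val`` split.
    Aborts with a diagnostic if the loss goes non-finite.
    """
    tr = dataset.subset("train")
    va = dataset.subset("val")
    if len(tr.labels) == 0 or len(va.labels) == 0:
        raise ValueError("dataset must carry non-empty train and val splits")
    order = model.config.class_order
    ytr = _encode_labels(tr.labels, order)
    yva = _encode_labels(va.labels, order)
    eye = np.eye(model.config.n_classes)
    Xtr, cvtr = tr.segments, tr.cv
    use_cv = model.config.cv_fusion

    rng = np.random.default_rng(tc.seed)
    model.set_rng(rng)
    opt = nn.Adam(lr=tc.learning_rate, beta1=tc.beta1, beta2=tc.beta2)

    records = []
    for epoch in range(tc.epochs):
        perm = rng.permutation(len(ytr))
        losses, correct = [], 0
        for i in range(0, len(perm), tc.batch_size):
            idx = perm[i:i + tc.batch_size]
            logits = model.forward(Xtr[idx], cvtr[idx] if use_cv else None,
                                   training=True)
            loss, dlogits, probs = nn.cross_entropy_with_grad(logits, eye[ytr[idx]])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // tc.batch_size}"
                )
            model.backward(dlogits)
            opt.step(model.layers)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == ytr[idx]).sum())

        # precise BN statistics over (a cap of) the training data before
        # evaluating: with few steps per epoch the running estimates lag.
        # The evenly spaced subsample spans all classes (splits keep
        # class-contiguous order).
        cap = min(len(ytr), 512)
        pick = np.linspace(0, len(ytr) - 1, cap).astype(int)
        model.recalibrate_bn(Xtr[pick], cvtr[pick] if use_cv else None)
        pva = model.predict_proba(va.segments, va.cv if use_cv else None)
        val_loss = float(-np.log(pva[np.arange(len(yva)), yva] + 1e-12).mean())
        records.append({
            "epoch": epoch + 1,
            "train_loss": float(np.sum(losses) / len(ytr)),
            "train_acc": correct / len(ytr),
            "val_loss": val_loss,
            "val_acc": _accuracy(pva, yva),
        })
    return TrainedModel(model=model, history=pd.DataFrame(records), train_config=tc)


def predict(model: KecNetModel, segments: np.ndarray,
            cv: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties go to the lower index)."""
    probs = model.predict_proba(np.asarray(segments),
                                None if cv is None else np.asarray(cv))
    labels = np.asarray(model.config.class_order)[probs.argmax(axis=1)]
    return probs, labels


@dataclass
class Metrics:
    """Confusion counts and the three summary rates.

    ``acc`` is overall correctness; ``sen`` (recall) and ``pre`` (precision)
    are unweighted macro-averages of the per-class one-vs-rest reductions.
    """

    confusion: np.ndarray
    acc: float
    sen: float
    pre: float
    per_class: pd.DataFrame

    def as_dict(self) -> dict:
        return {"acc": self.acc, "sen": self.sen, "pre": self.pre}


def evaluate(y_true, y_pred, class_order: tuple[str, ...] = AAMI_CLASSES) -> Metrics:
    """Confusion matrix and ACC / macro-SEN / macro-PRE.

    Classes absent from the truth are skipped in the macro averages with a
    warning (their recall is undefined).
    """
    y_true = np.asarray([str(v) for v in np.asarray(y_true)])
    y_pred = np.asarray([str(v) for v in np.asarray(y_pred)])
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = confusion_matrix(y_true, y_pred, labels=list(class_order))
    total = cm.sum()
    acc = float(np.trace(cm) / total)
    rows, sens, pres = [], [], []
    for i, cls in enumerate(class_order):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        if tp + fn == 0:
            warnings.warn(f"class {cls!r} absent from truth; skipped in macro averages",
                          stacklevel=2)
            rows.append({"class": cls, "sen": np.nan, "pre": np.nan, "support": 0})
            continue
        sen_i = tp / (tp + fn)
        pre_i = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        sens.append(sen_i)
        pres.append(pre_i)
        rows.append({"class": cls, "sen": sen_i, "pre": pre_i,
                     "support": int(tp + fn)})
    return Metrics(
        confusion=cm,
        acc=acc,
        sen=float(np.mean(sens)),
        pre=float(np.mean(pres)),
        per_class=pd.DataFrame(rows),
    )
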