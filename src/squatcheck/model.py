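"""Binary squat-posture classifier: temporal Conv1D stack + bidirectional LSTM.

The full architecture is three 1D convolutions along time (kernel depths
5, 3, 3; filters 32, 64, 64) over the 20 delta-feature channels, a
bidirectional LSTM with 64 total outputs (32 hidden units per direction,
final states concatenated), a 32-unit fully connected layer, and a 2-class
softmax. Training uses Adam (lr 0.003) with dropout 0.3 after each
convolution and after the FC layer. Two ablation variants drop either the
LSTM (``conv_only``: mean-pool over time feeds the FC layer) or the
convolutions (``lstm_only``: the LSTM reads the 20 raw channels).

Labels: the positive class is "correct" posture. ``classify`` returns the
softmax probability of that class.
"""

from __future__ import annotations

import copy
import io
import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GroupShuffleSplit

from .errors import EmptyInputError, SchemaError, TooShortError, ValidationError
from .joints import MODEL_JOINTS, N_CHANNELS
from .nn import Adam, BiLSTM, Conv1D, Dense, Dropout, Layer, MeanPool, softmax, softmax_xent
from .preprocessing import FeatureTensor

LABELS = ("incorrect", "correct")  # index 1 = positive class
CHANNEL_ORDER = tuple(f"{j}_{c}" for j in MODEL_JOINTS for c in ("x", "y"))


@dataclass
class ModelConfig:
    """Architecture and optimizer hyperparameters."""

    variant: str = "full"  # full | conv_only | lstm_only
    conv_kernel_depths: tuple[int, ...] = (5, 3, 3)
    conv_filters: tuple[int, ...] = (32, 64, 64)
    lstm_units: int = 64       # total bidirectional output dimensionality
    fc_units: int = 32
    dropout: float = 0.3
    learning_rate: float = 0.003
    optimizer: str = "adam"
    n_classes: int = 2
    conv_padding: str = "valid"  # valid | same
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_kernel_depths = tuple(self.conv_kernel_depths)
        self.conv_filters = tuple(self.conv_filters)
        if self.variant not in ("full", "conv_only", "lstm_only"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if len(self.conv_kernel_depths) != len(self.conv_filters):
            raise ValidationError(
                "conv_kernel_depths and conv_filters must have equal length"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if self.lstm_units % 2 != 0:
            raise ValidationError("lstm_units (bidirectional total) must be even")
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")
        if self.conv_padding not in ("valid", "same"):
            raise ValidationError(f"conv_padding must be valid|same")


class _Network:
    """Layer stack for one variant, operating on a single (T, 20) sequence."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng((cfg.seed, 0x5EED))
        layers: list[Layer] = []
        c = N_CHANNELS
        if cfg.variant in ("full", "conv_only"):
            for k, f in zip(cfg.conv_kernel_depths, cfg.conv_filters):
                layers.append(Conv1D(k, c, f, rng))
                layers.append(Dropout(cfg.dropout, self.dropout_rng))
                c = f
        if cfg.variant in ("full", "lstm_only"):
            layers.append(BiLSTM(c, cfg.lstm_units // 2, rng))
            c = cfg.lstm_units
        else:
            layers.append(MeanPool())
        layers.append(Dense(c, cfg.fc_units, rng, relu=True))
        layers.append(Dropout(cfg.dropout, self.dropout_rng))
        layers.append(Dense(cfg.fc_units, cfg.n_classes, rng, relu=False))
        self.layers = layers

    @property
    def min_length(self) -> int:
        """Smallest temporal length (feature rows) the variant accepts."""
        if self.cfg.conv_padding == "same" or self.cfg.variant == "lstm_only":
            return 1
        return 1 + sum(k - 1 for k in self.cfg.conv_kernel_depths)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.cfg.conv_padding == "same" and self.cfg.variant != "lstm_only":
            pad = sum(k - 1 for k in self.cfg.conv_kernel_depths)
            left = pad // 2
            x = np.pad(x, ((left, pad - left), (0, 0)))
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BiLSTM):
                for sub, direction in layer.iter_params():
                    for k, v in direction.params.items():
                        out[f"{i}.{sub}.{k}"] = v
            else:
                for k, v in layer.params.items():
                    out[f"{i}.{k}"] = v
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BiLSTM):
                for sub, direction in layer.iter_params():
                    for k, v in direction.grads.items():
                        out[f"{i}.{sub}.{k}"] = v
            else:
                for k, v in layer.grads.items():
                    out[f"{i}.{k}"] = v
        return out

    @property
    def conv_param_count(self) -> int:
        return sum(l.n_params for l in self.layers if isinstance(l, Conv1D))


@dataclass
class TrainedModel:
    """A network plus its configuration and training history."""

    config: ModelConfig
    network: _Network
    training_history: list[dict] = field(default_factory=list)
    channel_order: tuple[str, ...] = CHANNEL_ORDER

    @property
    def min_length(self) -> int:
        return self.network.min_length


@dataclass
class EvalReport:
    """Confusion-matrix metrics with "correct posture" as the positive class."""

    accuracy: float
    precision: float
    recall: float
    confusion: np.ndarray  # rows: true (incorrect, correct); cols: predicted
    n: int

    @staticmethod
    def from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> "EvalReport":
        cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
        tn, fp, fn, tp = cm.ravel()
        total = cm.sum()
        return EvalReport(
            accuracy=float((tp + tn) / total) if total else float("nan"),
            precision=float(tp / (tp + fp)) if tp + fp else float("nan"),
            recall=float(tp / (tp + fn)) if tp + fn else float("nan"),
            confusion=cm,
            n=int(total),
        )


def _as_matrix(feats: FeatureTensor | np.ndarray) -> np.ndarray:
    x = feats.values if isinstance(feats, FeatureTensor) else np.asarray(feats, float)
    if x.ndim != 2 or x.shape[1] != N_CHANNELS:
        raise SchemaError(f"expected (T, {N_CHANNELS}) features, got {x.shape}")
    return x


def _as_label_index(label: int | str) -> int:
    if isinstance(label, str):
        try:
            return LABELS.index(label)
        except ValueError:
            raise ValidationError(f"unknown label {label!r}") from None
    if label not in (0, 1):
        raise ValidationError(f"label index must be 0 or 1, got {label}")
    return int(label)


def build_model(cfg: ModelConfig) -> TrainedModel:
    """Instantiate an untrained model for the configured variant."""
    return TrainedModel(config=cfg, network=_Network(cfg))


def classify(model: TrainedModel, feats: FeatureTensor | np.ndarray) -> float:
    """Softmax probability that the sequence shows correct posture."""
    x = _as_matrix(feats)
    if x.shape[0] < model.min_length:
        raise TooShortError(
            f"variant {model.config.variant!r} needs at least "
            f"{model.min_length} feature rows, got {x.shape[0]}"
        )
    logits = model.network.forward(x, train=False)
    return float(softmax(logits)[1])


def predict_label(model: TrainedModel, feats: FeatureTensor | np.ndarray) -> int:
    return int(classify(model, feats) >= 0.5)


def _epoch_eval(model: TrainedModel, data: list[tuple[np.ndarray, int]]) -> float:
    correct = 0
    for x, y in data:
        logits = model.network.forward(x, train=False)
        correct += int(np.argmax(logits)) == y
    return correct / len(data)


def train(
    model: TrainedModel,
    dataset: Iterable[tuple[FeatureTensor | np.ndarray, int | str]],
    val_set: Iterable[tuple[FeatureTensor | np.ndarray, int | str]] | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train in place by minibatch Adam on softmax cross-entropy.

    Gradients are averaged over each minibatch of variable-length sequences.
    With a validation set, training early-stops when validation accuracy has
    not improved for ``early_stop_patience`` epochs and the best-validation
    weights are restored. Deterministic given the config seed.
    """
    cfg = model.config
    data = [(_as_matrix(f), _as_label_index(l)) for f, l in dataset]
    if not data:
        raise EmptyInputError("empty training set")
    if len({y for _, y in data}) < 2:
        raise ValidationError("training set contains a single class")
    for x, _ in data:
        if x.shape[0] < model.min_length:
            raise TooShortError(
                f"training sequence with {x.shape[0]} rows; variant needs "
                f">= {model.min_length}"
            )
    val = (
        [(_as_matrix(f), _as_label_index(l)) for f, l in val_set]
        if val_set is not None
        else None
    )

    opt = Adam(lr=cfg.learning_rate)
    order_rng = np.random.default_rng((cfg.seed, 0xBA7C4))
    best_acc, best_params, since_best = -1.0, None, 0

    for epoch in range(cfg.max_epochs):
        idx = order_rng.permutation(len(data))
        total_loss, n_hit = 0.0, 0
        for start in range(0, len(idx), cfg.batch_size):
            batch = idx[start : start + cfg.batch_size]
            model.network.zero_grad()
            for i in batch:
                x, y = data[i]
                logits = model.network.forward(x, train=True)
                loss, dlogits = softmax_xent(logits, y)
                total_loss += loss
                n_hit += int(np.argmax(logits)) == y
                model.network.backward(dlogits)
            grads = {k: v / len(batch) for k, v in model.network.named_grads().items()}
            opt.step(model.network.named_params(), grads)
        record = {
            "epoch": epoch,
            "loss": total_loss / len(data),
            "accuracy": n_hit / len(data),
        }
        if val is not None:
            va = _epoch_eval(model, val)
            record["val_accuracy"] = va
            if va > best_acc:
                best_acc, since_best = va, 0
                best_params = {
                    k: v.copy() for k, v in model.network.named_params().items()
                }
            else:
                since_best += 1
        model.training_history.append(record)
        if verbose:
            print(f"epoch {epoch}: {record}")
        if val is not None and since_best >= cfg.early_stop_patience:
            break
    if best_params is not None:
        params = model.network.named_params()
        for k, v in best_params.items():
            params[k][...] = v
    return model


def evaluate(
    model: TrainedModel,
    dataset: Iterable[tuple[FeatureTensor | np.ndarray, int | str]],
) -> EvalReport:
    """Confusion-matrix metrics of the model on a labeled dataset."""
    data = [(_as_matrix(f), _as_label_index(l)) for f, l in dataset]
    if not data:
        raise EmptyInputError("empty evaluation set")
    y_true = [y for _, y in data]
    y_pred = [predict_label(model, x) for x, _ in data]
    return EvalReport.from_predictions(y_true, y_pred)


def subject_split(
    n_items: int,
    groups: Sequence[int],
    test_size: float = 0.25,
    val_size: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-wise train/val/test indices: no subject spans two splits."""
    idx = np.arange(n_items)
    groups = np.asarray(groups)
    gss = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    trainval, test = next(gss.split(idx, groups=groups))
    gss2 = GroupShuffleSplit(
        n_splits=1, test_size=val_size / (1 - test_size), random_state=seed + 1
    )
    tr, va = next(gss2.split(trainval, groups=groups[trainval]))
    return trainval[tr], trainval[va], test


def grid_search(
    train_set: list[tuple[FeatureTensor | np.ndarray, int | str]],
    val_set: list[tuple[FeatureTensor | np.ndarray, int | str]],
    grid: dict[str, list],
    base: ModelConfig | None = None,
) -> tuple[ModelConfig, float, list[dict]]:
    """Exhaustive hyperparameter search maximizing validation accuracy.

    Returns the best config, its validation accuracy, and the full result
    table (one row per combination). Ties break to the earlier combination.
    """
    if not grid:
        raise ValidationError("empty grid")
    base = base or ModelConfig()
    keys = sorted(grid)
    table: list[dict] = []
    best: tuple[float, ModelConfig] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        model = train(build_model(cfg), train_set, val_set)
        acc = evaluate(model, val_set).accuracy
        table.append({**dict(zip(keys, combo)), "val_accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, cfg)
    return best[1], best[0], table


def format_report_table(rows: dict[str, dict[str, float]]) -> str:
    """Render a variant-by-split accuracy grid (model comparison table)."""
    cols = ("train", "val", "test")
    out = io.StringIO()
    out.write(f"{'Model':<20}" + "".join(f"{c + ' acc':>12}" for c in cols) + "\n")
    for name, row in rows.items():
        out.write(
            f"{name:<20}"
            + "".join(
                f"{row[c]:>12.4f}" if c in row and row[c] == row[c] else f"{'—':>12}"
                for c in cols
            )
            + "\n"
        )
    return out.getvalue()


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Weights + config + channel order in one .npz archive."""
    meta = json.dumps(
        {"config": asdict(model.config), "channel_order": list(model.channel_order)}
    )
    np.savez(
        path,
        __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
        **model.network.named_params(),
    )


def load_checkpoint(
    path: str | Path, expect_channel_order: Sequence[str] | None = None
) -> TrainedModel:
    """Rebuild a model from a checkpoint; verifies the feature channel order."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        weights = {k: archive[k] for k in archive.files if k != "__meta__"}
    order = tuple(meta["channel_order"])
    expected = tuple(expect_channel_order) if expect_channel_order else CHANNEL_ORDER
    if order != expected:
        raise SchemaError(
            "checkpoint channel order does not match the preprocessing "
            f"channel order: {order} vs {expected}"
        )
    cfg_dict = meta["config"]
    cfg_dict["conv_kernel_depths"] = tuple(cfg_dict["conv_kernel_depths"])
    cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
    model = build_model(ModelConfig(**cfg_dict))
    params = model.network.named_params()
    if set(params) != set(weights):
        raise SchemaError("checkpoint parameter names do not match the architecture")
    for k in params:
        params[k][...] = weights[k]
    model.channel_order = order
    return model
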