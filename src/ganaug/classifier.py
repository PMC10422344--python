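"""The modulated VGG-derived CNN and its vote-counting prediction rule.

The network is a slimmed VGG-style stack fixed at seven convolutional layers,
four max-pooling layers, four rectifier activations, one fully connected
layer, dropout after every convolutional block, and a sigmoid head for binary
(malignant/benign) output or a normalised-exponential head for the three
tumor classes.  Four stride-2 pools reduce the spatial side by 16, so the
input resolution must be divisible by 16.

Prediction can optionally run the vote-counting procedure: score several
stochastically augmented views (flips, small shifts) of an image, count views
above the threshold against views below it, and call the image malignant only
when the above-threshold counter strictly exceeds the other — a tie counts as
benign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import load_image, resize_image
from .errors import ConfigError, DataError, DivergenceError, UsageError

CONV_LAYERS = 7
POOL_LAYERS = 4
RELU_LAYERS = 4
FC_LAYERS = 1


@dataclass
class ClassifierConfig:
    resolution: int = 32
    conv_layers: int = CONV_LAYERS
    maxpool_layers: int = POOL_LAYERS
    fc_layers: int = FC_LAYERS
    relu_layers: int = RELU_LAYERS
    dropout: float = 0.25
    mode: str = "multiclass"              # or "binary-sigmoid"
    n_classes: int = 3
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("binary-sigmoid", "multiclass"):
            raise ConfigError(f"unknown output mode {self.mode!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout rate must lie in [0, 1)")
        if self.resolution % (2 ** self.maxpool_layers) != 0:
            raise ConfigError(
                f"resolution {self.resolution} not divisible by "
                f"2^{self.maxpool_layers}")
        if (self.conv_layers, self.maxpool_layers, self.fc_layers,
                self.relu_layers) != (CONV_LAYERS, POOL_LAYERS, FC_LAYERS,
                                      RELU_LAYERS):
            raise ConfigError("the modulated architecture is fixed at "
                              "7 conv / 4 pool / 1 fc / 4 relu layers")


def build_modulated_cnn(config: ClassifierConfig) -> list[dict]:
    """Ordered layer specification of the modulated CNN.

    Four conv-relu-pool-dropout blocks, then three further 3x3 convolutions
    (each followed by dropout) on the 16x-reduced feature map, one fully
    connected layer, and the output head.
    """
    widths = [8, 16, 32, 32]
    spec: list[dict] = []
    c = 1
    for w in widths:
        spec += [{"layer": "conv", "in": c, "out": w, "kernel": 3},
                 {"layer": "relu"},
                 {"layer": "maxpool", "size": 2},
                 {"layer": "dropout", "rate": config.dropout}]
        c = w
    for _ in range(3):
        spec += [{"layer": "conv", "in": c, "out": c, "kernel": 3},
                 {"layer": "dropout", "rate": config.dropout}]
    side = config.resolution // (2 ** config.maxpool_layers)
    n_out = 1 if config.mode == "binary-sigmoid" else config.n_classes
    spec += [{"layer": "flatten"},
             {"layer": "dense", "in": c * side * side, "out": n_out}]
    spec.append({"layer": "sigmoid"} if config.mode == "binary-sigmoid"
                else {"layer": "softmax"})
    counts = spec_counts(spec)
    assert counts == {"conv": CONV_LAYERS, "maxpool": POOL_LAYERS,
                      "relu": RELU_LAYERS, "dense": FC_LAYERS}, counts
    return spec


def spec_counts(spec: list[dict]) -> dict[str, int]:
    out = {"conv": 0, "maxpool": 0, "relu": 0, "dense": 0}
    for s in spec:
        if s["layer"] in out:
            out[s["layer"]] += 1
    return out


def _instantiate(spec: list[dict], rng) -> nn.Sequential:
    """Build the network *without* the output squashing; training operates on
    logits and the squashing is applied at prediction time."""
    layers: list[nn.Layer] = []
    for s in spec:
        kind = s["layer"]
        if kind == "conv":
            layers.append(nn.Conv2d(s["in"], s["out"], s["kernel"], rng))
        elif kind == "relu":
            layers.append(nn.ReLU())
        elif kind == "maxpool":
            layers.append(nn.MaxPool2())
        elif kind == "dropout":
            layers.append(nn.Dropout(s["rate"], rng))
        elif kind == "flatten":
            layers.append(nn.Flatten())
        elif kind == "dense":
            layers.append(nn.Dense(s["in"], s["out"], rng))
        elif kind in ("sigmoid", "softmax"):
            pass  # applied functionally on logits
        else:  # pragma: no cover
            raise ConfigError(f"unknown layer kind {kind!r}")
    return nn.Sequential(layers)


@dataclass
class TrainedClassifier:
    config: ClassifierConfig
    spec: list[dict]
    net: nn.Sequential
    label_map: list[str]
    log: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})


def _load_records(records, resolution: int):
    # fixed gray-level scaling: per-image minmax would erase absolute
    # intensity differences that carry class information
    imgs = np.stack([
        resize_image(load_image(r.path) / 255.0, resolution)
        for r in records])[:, None, :, :]
    return imgs, [r.label for r in records]


def train_classifier(config: ClassifierConfig, train_records,
                     val_records=None) -> TrainedClassifier:
    """Train on manifest records (path/label); minimises cross-entropy."""
    if not train_records:
        raise DataError("no training records")
    x, labels = _load_records(train_records, config.resolution)
    label_map = sorted(set(labels))
    if config.mode == "binary-sigmoid" and len(label_map) != 2:
        raise DataError(f"binary mode needs exactly 2 classes, got {label_map}")
    if config.mode == "multiclass" and len(label_map) != config.n_classes:
        config = ClassifierConfig(**{**config.__dict__,
                                     "n_classes": len(label_map)})
    y = np.array([label_map.index(l) for l in labels])
    if val_records:
        xv, lv = _load_records(val_records, config.resolution)
        missing = set(lv) - set(label_map)
        if missing:
            raise DataError(f"validation classes missing from train: {missing}")
        yv = np.array([label_map.index(l) for l in lv])
    else:
        xv = yv = None

    rng = np.random.default_rng(config.seed)
    spec = build_modulated_cnn(config)
    net = _instantiate(spec, rng)
    params, grads = nn.collect(net)
    opt = nn.Adam(params, grads, lr=config.learning_rate, beta1=0.9)
    model = TrainedClassifier(config, spec, net, label_map)

    n = x.shape[0]
    b = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, b):
            idx = order[start:start + b]
            logits = net.forward(x[idx], train=True)
            loss, dl = _loss(config.mode, logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(dl)
            opt.step()
            losses.append(loss)
        model.log["train_loss"].append(float(np.mean(losses)))
        if xv is not None:
            vloss, _ = _loss(config.mode, net.forward(xv, train=False), yv)
            model.log["val_loss"].append(float(vloss))
    return model


def _loss(mode: str, logits, y):
    if mode == "binary-sigmoid":
        loss, dl = nn.bce_with_logits(logits[:, 0], y.astype(float))
        return loss, dl[:, None]
    return nn.softmax_cross_entropy(logits, y)


def predict_scores(model: TrainedClassifier, images: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout off) on (n, R, R) images in [0,1].

    Binary mode returns (n,) sigmoid scores; multiclass returns (n, K) rows
    summing to 1.
    """
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1] != model.config.resolution or x.shape[2] != model.config.resolution:
        raise UsageError(f"images must be {model.config.resolution}px squares, "
                         f"got {x.shape[1:]}")
    logits = model.net.forward(x[:, None], train=False)
    if model.config.mode == "binary-sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(logits[:, 0], -60, 60)))
    return nn.softmax(logits)


def predict_labels(model: TrainedClassifier, images: np.ndarray,
                   threshold: float = 0.5) -> list[str]:
    scores = predict_scores(model, images)
    if model.config.mode == "binary-sigmoid":
        return [model.label_map[int(s > threshold)] for s in scores]
    return [model.label_map[i] for i in scores.argmax(axis=1)]


def predict_records(model: TrainedClassifier, records):
    """Manifest-record prediction helper: returns (y_true, y_pred)."""
    imgs, labels = _load_records(records, model.config.resolution)
    return labels, predict_labels(model, imgs[:, 0])


# ---------------------------------------------------------------------------
# Vote counting
# ---------------------------------------------------------------------------


def vote_from_scores(scores, threshold: float = 0.5) -> str:
    """Tally per-view malignancy scores; Malignant only on a strict majority.

    Each score above the threshold increments the right (malignant) counter,
    otherwise the left (benign) counter; ties return Benign because the
    decision requires the right counter to strictly exceed the left one.
    """
    scores = list(scores)
    if not scores:
        raise UsageError("need at least one view score")
    right = sum(1 for s in scores if s > threshold)
    left = len(scores) - right
    return "Malignant" if right > left else "Benign"


def _augment_views(img: np.ndarray, n_views: int, rng) -> np.ndarray:
    """Stochastic views: the image itself, then random flips and <=2px shifts."""
    views = [img]
    for _ in range(n_views - 1):
        v = img
        if rng.random() < 0.5:
            v = v[:, ::-1]
        dy, dx = rng.integers(-2, 3, size=2)
        v = np.roll(np.roll(v, dy, axis=0), dx, axis=1)
        views.append(v)
    return np.stack(views)


def vote_classify(model: TrainedClassifier, image: np.ndarray,
                  n_views: int = 5, threshold: float = 0.5,
                  seed: int = 0) -> str:
    """Classify one image as Malignant/Benign by vote counting over views."""
    if n_views < 1:
        raise UsageError("n_views must be >= 1")
    if model.config.mode != "binary-sigmoid":
        raise UsageError("vote counting applies to the binary-sigmoid head")
    rng = np.random.default_rng(seed)
    views = _augment_views(np.asarray(image, dtype=float), n_views, rng)
    scores = predict_scores(model, views)
    return vote_from_scores(scores, threshold)
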