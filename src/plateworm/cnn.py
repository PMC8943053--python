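"""Worm / non-worm convolutional classifier.

A shallow VGG-style network filters tracked objects: eight 3x3 stride-1
convolution layers (each followed by ReLU), a 2x2 max pool after every two
convolutions (80 -> 40 -> 20 -> 10 -> 5 spatial size), batch normalisation
after the third and seventh convolutions, dropout before a single fully
connected layer with two output logits.  The default channel plan lands at
about 1.77 million trainable parameters; a ``compact`` preset with the
same topology but narrower channels is provided for quick training on
synthetic data.

Training uses cross-entropy loss and Adam, with an 80/10/10
train/validation/test split stratified by class; the weights with the best
validation accuracy are retained and metrics are reported on the held-out
test split only.

At inference a tracked object is scored on one ROI per second of track
time; the object is a valid worm iff the median worm probability is
strictly greater than 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

from . import nn
from .tracking import Track, extract_roi

DEFAULT_CHANNELS = (32, 64, 64, 128, 128, 256, 256, 256)
COMPACT_CHANNELS = (8, 8, 16, 16, 32, 32, 32, 32)


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters.

    ``conv_channels`` must have exactly 8 entries; batch norm follows
    convolutions 3 and 7 (1-based), a pool follows every second convolution.
    """

    conv_channels: tuple = DEFAULT_CHANNELS
    input_size: int = 80
    dropout: float = 0.5
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 64
    patience: int = 5  # early stopping on validation accuracy
    augment: bool = True  # random flips / right-angle rotations while training
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_channels) != 8:
            raise ValueError("conv_channels must have exactly 8 entries")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16 (four 2x2 pools)")

    @classmethod
    def compact(cls, **kw) -> "CnnConfig":
        """Narrow-channel preset for fast CPU training on synthetic ROIs."""
        kw.setdefault("conv_channels", COMPACT_CHANNELS)
        kw.setdefault("epochs", 12)
        kw.setdefault("patience", 5)
        return cls(**kw)


def preprocess_roi(image: np.ndarray) -> np.ndarray:
    """Normalise a masked ROI for the classifier.

    Masked (zero) background pixels are shifted to the 95th percentile of
    the unmasked grey values (linear-interpolation percentile convention),
    then the image is min-max scaled to [0, 1].  A constant image after
    the fill maps to all zeros; an all-zero input is an error.
    """
    img = np.asarray(image, dtype=float)
    nonzero = img[img > 0]
    if nonzero.size == 0:
        raise ValueError("ROI has no unmasked pixels")
    fill = np.percentile(nonzero, 95)
    out = img.copy()
    out[img == 0] = fill
    lo, hi = out.min(), out.max()
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def build_model(config: CnnConfig) -> nn.Sequential:
    """Assemble the layer stack; ``model.param_count()`` reports trainable size."""
    rng = np.random.default_rng(config.seed)
    ch = config.conv_channels
    layers: list[nn.Layer] = []
    c_in = 1
    for i in range(8):
        layers.append(nn.Conv2d(c_in, ch[i], rng))
        layers.append(nn.ReLU())
        if i in (2, 6):  # after conv 3 and conv 7 (1-based)
            layers.append(nn.BatchNorm2d(ch[i]))
        if i % 2 == 1:
            layers.append(nn.MaxPool2d())
        c_in = ch[i]
    layers.append(nn.Dropout(config.dropout, rng))
    layers.append(nn.Flatten())
    spatial = config.input_size // 16
    layers.append(nn.Linear(spatial * spatial * ch[-1], 2, rng))
    return nn.Sequential(layers)


def expected_param_count(config: CnnConfig) -> int:
    """Closed-form trainable-parameter count for a config (layer arithmetic)."""
    ch, c_in, total = config.conv_channels, 1, 0
    for i in range(8):
        total += 9 * c_in * ch[i] + ch[i]
        if i in (2, 6):
            total += 2 * ch[i]
        c_in = ch[i]
    spatial = config.input_size // 16
    total += spatial * spatial * ch[-1] * 2 + 2
    return total


@dataclass
class TrainedClassifier:
    model: nn.Sequential
    config: CnnConfig
    history: dict = field(default_factory=dict)
    test_accuracy: float = float("nan")
    test_f1: float = float("nan")
    split_sizes: tuple[int, int, int] = (0, 0, 0)

    def predict_proba(self, images: np.ndarray, batch_size: int = 256,
                      preprocessed: bool = False) -> np.ndarray:
        """Worm-class probabilities, shape (n,). Accepts raw masked ROIs."""
        x = images if preprocessed else np.stack([preprocess_roi(im) for im in images])
        x = x.astype(np.float32)[:, None, :, :]
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.model.forward(x[i:i + batch_size], train=False)
            probs.append(nn.softmax(logits)[:, 1])
        return np.concatenate(probs)


def split_indices(labels: np.ndarray, seed: int,
                  fractions=(0.8, 0.1, 0.1)) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test index split."""
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_tr, n_va = int(round(fractions[0] * n)), int(round(fractions[1] * n))
        tr.append(idx[:n_tr])
        va.append(idx[n_tr:n_tr + n_va])
        te.append(idx[n_tr + n_va:])
    return (np.sort(np.concatenate(tr)), np.sort(np.concatenate(va)),
            np.sort(np.concatenate(te)))


def train_classifier(images: np.ndarray, labels: np.ndarray,
                     config: CnnConfig) -> TrainedClassifier:
    """Train on a labelled ROI set; report metrics on the held-out 10% only."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two classes")
    x = np.stack([preprocess_roi(im) for im in images]).astype(np.float32)[:, None]
    itr, iva, ite = split_indices(labels, config.seed)
    model = build_model(config)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    def accuracy(idx):
        preds = []
        for i in range(0, len(idx), 256):
            logits = model.forward(x[idx[i:i + 256]], train=False)
            preds.append(logits.argmax(axis=1))
        return float(np.mean(np.concatenate(preds) == labels[idx]))

    best_val, best_weights, since_best = -1.0, model.get_weights(), 0
    history = {"train_loss": [], "val_accuracy": []}
    for epoch in range(config.epochs):
        order = rng.permutation(itr)
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = order[i:i + config.batch_size]
            xb = x[batch]
            if config.augment:
                # orientation is arbitrary for plate ROIs: flips and
                # right-angle rotations preserve the label
                if rng.random() < 0.5:
                    xb = xb[:, :, ::-1, :]
                if rng.random() < 0.5:
                    xb = xb[:, :, :, ::-1]
                k = int(rng.integers(4))
                if k:
                    xb = np.rot90(xb, k, axes=(2, 3))
                xb = np.ascontiguousarray(xb)
            logits = model.forward(xb, train=True)
            loss, grad = nn.cross_entropy(logits, labels[batch])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_acc = accuracy(iva)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_val:
            best_val, best_weights, since_best = val_acc, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_weights(best_weights)

    clf = TrainedClassifier(model=model, config=config, history=history,
                            split_sizes=(len(itr), len(iva), len(ite)))
    preds = (clf.predict_proba(x[ite, 0], preprocessed=True) > 0.5).astype(int)
    clf.test_accuracy = float(np.mean(preds == labels[ite]))
    clf.test_f1 = float(f1_score(labels[ite], preds))
    return clf


def filter_tracks(classifier: TrainedClassifier, tracks: list[Track],
                  frames, frame_rate: float | None = None,
                  roi_size: int = 80, halo: float = 5.0) -> list[Track]:
    """Score tracks and set ``is_worm`` verdicts in place.

    ``frames`` may be a (T, H, W) array or a :class:`~plateworm.io.FrameStore`
    (whose frame rate is used unless given explicitly).  One ROI per whole
    second of track duration is scored (the first frame of each second —
    deterministic sampling phase); tracks shorter than one second use every
    frame.  The verdict is worm iff the median worm probability is
    strictly greater than 0.5.
    """
    if hasattr(frames, "frames"):  # FrameStore
        frame_rate = frames.frame_rate if frame_rate is None else frame_rate
        frames = frames.frames
    if frame_rate is None:
        raise ValueError("frame_rate required when passing a bare frame array")
    step = max(1, int(round(frame_rate)))
    for t in tracks:
        n = len(t.objects)
        sample_ids = list(range(0, n, step)) if n >= step else list(range(n))
        rois = [extract_roi(frames[t.objects[i].frame_number], t.objects[i],
                            size=roi_size, halo=halo) for i in sample_ids]
        probs = classifier.predict_proba(np.stack(rois))
        t.worm_prob_median = float(np.median(probs))
        t.is_worm = bool(t.worm_prob_median > 0.5)
    return tracks
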