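"""The convolutional landscape-model classifier.

Architecture (fixed): conv 3x1 (32 filters) -> max-pool 3x1 -> conv 3x1
(64 filters) -> max-pool 3x1 -> flatten -> dense 100 -> dense 40 -> softmax
output with one unit per candidate model.  Hidden activations are ReLU;
training uses Adam, categorical cross-entropy, mini-batches of 100 and
exactly ten epochs.  Kernels span 3 rows (sequences) x 1 column (SNP), so
convolutions compare each sequence with its neighbours within the
deme-blocked image.

The number of filters (32/64), stride-1 valid convolutions and pool stride
equal to the pool window are recorded here as explicit defaults so the
architecture is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import SNPImage
from .nn import Adam, Conv3x1, Dense, Flatten, MaxPool3x1, ReLU, Sequential, softmax, softmax_cross_entropy

__all__ = [
    "ClassifierSpec",
    "CNNClassifier",
    "EvaluationReport",
    "CalibrationReport",
    "split_dataset",
    "build_classifier",
    "train_classifier",
    "evaluate_classifier",
    "calibration_report",
    "predict_empirical",
]

#: Minimal admissible image height: two (conv 3x1 valid, pool 3x1 stride 3)
#: stages need 17 input rows (17 -> 15 -> 5 -> 3 -> 1).
MIN_HEIGHT = 17


@dataclass(frozen=True)
class ClassifierSpec:
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: tuple[int, int] = (3, 1)
    pool: tuple[int, int] = (3, 1)
    dense1: int = 100
    dense2: int = 40
    batch_size: int = 100
    epochs: int = 10
    adam_lr: float = 1e-3


#: Filter counts for the reduced-scale experiments: everything about the
#: architecture is fixed except the filter counts, which scale
#: down so a full train/evaluate cycle runs on one CPU in seconds.
REDUCED_SPEC = ClassifierSpec(conv1_filters=8, conv2_filters=16)


@dataclass
class EvaluationReport:
    """Confusion matrix (row percentages), overall accuracy (%), and
    per-model precision/recall."""

    labels: list[int]
    counts: np.ndarray              # raw confusion counts, rows = true
    confusion_percent: np.ndarray   # rows sum to 100
    overall_accuracy: float         # percent
    precision: np.ndarray
    recall: np.ndarray


@dataclass
class CalibrationReport:
    """Five 20%-wide confidence bins over the predicted-class probability."""

    bin_edges: np.ndarray           # [0, .2, .4, .6, .8, 1]
    counts: np.ndarray              # predictions per bin
    accuracies: np.ndarray          # empirical accuracy per bin (nan if empty)


class CNNClassifier:
    """A trainable CNN over equally shaped SNP images."""

    def __init__(self, input_shape: tuple[int, int], n_models: int,
                 spec: ClassifierSpec = ClassifierSpec(), dtype=np.float32):
        h, w = input_shape
        if h < MIN_HEIGHT:
            raise ValueError(
                f"input height {h} too small for two 3x1 conv+pool stages; "
                f"minimal admissible shape is ({MIN_HEIGHT}, 1)"
            )
        if n_models < 2:
            raise ValueError("need at least two candidate models")
        self.input_shape = (h, w)
        self.n_models = n_models
        self.spec = spec
        self.dtype = dtype
        h4 = ((h - 2) // 3 - 2) // 3
        self._flat = h4 * w * spec.conv2_filters
        self.net: Sequential | None = None
        self.loss_trace: list[float] = []

    # -- construction -----------------------------------------------------
    def init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        s, dt = self.spec, self.dtype
        self.net = Sequential([
            Conv3x1(1, s.conv1_filters, rng, dt), ReLU(), MaxPool3x1(),
            Conv3x1(s.conv1_filters, s.conv2_filters, rng, dt), ReLU(), MaxPool3x1(),
            Flatten(),
            Dense(self._flat, s.dense1, rng, dt), ReLU(),
            Dense(s.dense1, s.dense2, rng, dt), ReLU(),
            Dense(s.dense2, self.n_models, rng, dt, relu_fan=False),
        ])

    def architecture(self) -> list[str]:
        """Layer-by-layer description for introspection."""
        s = self.spec
        return [
            f"conv2d 3x1 valid stride1 filters={s.conv1_filters} relu",
            "maxpool2d 3x1 stride3x1",
            f"conv2d 3x1 valid stride1 filters={s.conv2_filters} relu",
            "maxpool2d 3x1 stride3x1",
            "flatten",
            f"dense {s.dense1} relu",
            f"dense {s.dense2} relu",
            f"dense {self.n_models} softmax",
        ]

    # -- inference --------------------------------------------------------
    def _to_batch(self, pixels: np.ndarray) -> np.ndarray:
        x = np.asarray(pixels, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"image shape {x.shape[1:]} does not match the training shape "
                f"{self.input_shape}; re-encode with the same design"
            )
        return x[..., None]

    def predict_proba(self, pixels: np.ndarray, batch: int = 200) -> np.ndarray:
        if self.net is None:
            self.init_weights(seed=0)
        x = self._to_batch(pixels)
        out = []
        for i in range(0, x.shape[0], batch):
            logits = self.net.forward(x[i:i + batch])
            out.append(softmax(logits.astype(np.float64)))
        return np.concatenate(out)

    # -- training ---------------------------------------------------------
    def fit(self, pixels: np.ndarray, labels: np.ndarray, seed: int) -> list[float]:
        """Train for exactly ``spec.epochs`` epochs; weights are
        (re)initialized from ``seed`` so a fit is fully determined by its
        inputs and seed.  Returns the per-epoch mean loss trace."""
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size < 2:
            raise ValueError("training set covers a single class; cannot train")
        if labels.min() < 0 or labels.max() >= self.n_models:
            raise ValueError("labels must be in [0, n_models)")
        ss = np.random.SeedSequence(seed)
        init_seed, shuffle_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        self.init_weights(init_seed)
        rng = np.random.default_rng(shuffle_seed)
        x = self._to_batch(pixels)
        opt = Adam(self.net.params, lr=self.spec.adam_lr)
        n = x.shape[0]
        self.loss_trace = []
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, self.spec.batch_size):
                idx = order[i:i + self.spec.batch_size]
                logits = self.net.forward(x[idx])
                loss, dlogits, _ = softmax_cross_entropy(logits, labels[idx])
                self.net.backward(dlogits)
                opt.step(self.net.grads)
                losses.append(loss)
            self.loss_trace.append(float(np.mean(losses)))
        return self.loss_trace

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        if self.net is None:
            raise ValueError("nothing to save: classifier not initialized")
        np.savez_compressed(
            path,
            input_shape=np.array(self.input_shape),
            n_models=self.n_models,
            **{f"p{i}": p for i, p in enumerate(self.net.params)},
        )

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        with np.load(path) as data:
            clf = cls(tuple(data["input_shape"]), int(data["n_models"]))
            clf.init_weights(seed=0)
            for i, p in enumerate(clf.net.params):
                p[...] = data[f"p{i}"]
        return clf


# -- module-level operations ----------------------------------------------

def _stack(images: Sequence[SNPImage]):
    pixels = np.stack([im.pixels for im in images])
    labels = np.array([im.label for im in images])
    return pixels, labels


def split_dataset(
    images: Sequence[SNPImage], train_fraction: float = 0.8,
    rng: int | np.random.Generator = 0,
):
    """Stratified, disjoint, exhaustive train/test split of a labeled corpus.

    Requires equal example counts per label; per-label train count is
    ``round(train_fraction * per-label total)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    labels = np.array([im.label for im in images])
    if any(l is None for l in labels):
        raise ValueError("all images must be labeled for splitting")
    uniq, counts = np.unique(labels, return_counts=True)
    if not np.all(counts == counts[0]):
        raise ValueError(f"unbalanced labels: counts {dict(zip(uniq, counts))}")
    n_train = int(round(train_fraction * counts[0]))
    train, test = [], []
    for lab in uniq:
        idx = np.where(labels == lab)[0]
        idx = idx[rng.permutation(idx.size)]
        train.extend(int(i) for i in idx[:n_train])
        test.extend(int(i) for i in idx[n_train:])
    return [images[i] for i in sorted(train)], [images[i] for i in sorted(test)]


def build_classifier(input_shape: tuple[int, int], n_models: int,
                     spec: ClassifierSpec = ClassifierSpec()) -> CNNClassifier:
    return CNNClassifier(input_shape, n_models, spec=spec)


def train_classifier(classifier: CNNClassifier, train_images: Sequence[SNPImage],
                     seed: int) -> tuple[CNNClassifier, list[float]]:
    pixels, labels = _stack(train_images)
    trace = classifier.fit(pixels, labels.astype(int), seed)
    return classifier, trace


def evaluate_classifier(trained: CNNClassifier, test_images: Sequence[SNPImage]) -> EvaluationReport:
    pixels, labels = _stack(test_images)
    labels = labels.astype(int)
    probs = trained.predict_proba(pixels)
    pred = probs.argmax(axis=1)
    k = trained.n_models
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (labels, pred), 1)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion_percent = 100.0 * counts / row_tot
        precision = np.diag(counts) / counts.sum(axis=0)
        recall = np.diag(counts) / counts.sum(axis=1)
    accuracy = 100.0 * np.trace(counts) / counts.sum()
    return EvaluationReport(
        labels=list(range(k)), counts=counts, confusion_percent=confusion_percent,
        overall_accuracy=float(accuracy), precision=precision, recall=recall,
    )


def calibration_report(trained: CNNClassifier, test_images: Sequence[SNPImage]) -> CalibrationReport:
    pixels, labels = _stack(test_images)
    probs = trained.predict_proba(pixels)
    return calibration_from_probs(probs, labels.astype(int))


def calibration_from_probs(probs: np.ndarray, labels: np.ndarray) -> CalibrationReport:
    """Bin the predicted-class probability into five 20%-wide classes and
    report the count and empirical accuracy per bin."""
    top = probs.max(axis=1)
    pred = probs.argmax(axis=1)
    correct = pred == labels
    edges = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    which = np.clip(np.digitize(top, edges[1:-1], right=False), 0, 4)
    counts = np.bincount(which, minlength=5)
    acc = np.full(5, np.nan)
    for b in range(5):
        if counts[b] > 0:
            acc[b] = float(correct[which == b].mean())
    return CalibrationReport(bin_edges=edges, counts=counts, accuracies=acc)


def predict_empirical(trained: CNNClassifier, image: SNPImage) -> np.ndarray:
    """Per-model probability vector for one (empirical) image."""
    return trained.predict_proba(image.pixels)[0]
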