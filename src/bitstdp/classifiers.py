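"""Output-layer classifiers over feature-extraction spikes.

Two readouts, trading accuracy against on-line trainability:

* :class:`SimpleClassifier` -- a teacher-driven STDP classifier with integer
  weights.  Post-synaptic spikes are replaced by a supervision event naming
  the correct class; weights from recently active feature neurons to that
  class are potentiated, then the class column is renormalized so its weight
  sum stays at a fixed budget.  Trains on-line, sample by sample.
* Histogram + softmax -- per-sample normalized spike-count histograms of the
  feature layer are collected (:func:`histogram_features`), a linear softmax
  classifier is trained in the frame domain by mini-batch SGD
  (:func:`train_softmax_sgd`), and the result is converted back to a spiking
  readout (:func:`convert_to_snn`) by scaling the weights by a constant ``k``
  and setting the LIF thresholds to ``k``; :func:`snn_classify` then reads out
  the class as the output neuron with the highest spike count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .aer_core import EventStream
from .stdp import PreBuffer

__all__ = [
    "SimpleClassifier",
    "HistogramSample",
    "histogram_features",
    "train_softmax_sgd",
    "SnnClassifier",
    "convert_to_snn",
    "snn_classify",
]


def _renormalize_column(col: np.ndarray, target: int) -> np.ndarray:
    """Rescale a non-negative integer column so it sums exactly to target.

    Largest-remainder rounding: scale, floor, then hand out the remaining
    units to the entries with the largest fractional parts (ties to lower
    index).  Deterministic.
    """
    total = int(col.sum())
    if total == 0 or total == target:
        return col
    scaled = col.astype(np.float64) * (target / total)
    out = np.floor(scaled).astype(np.int64)
    short = target - int(out.sum())
    if short > 0:
        frac = scaled - np.floor(scaled)
        order = np.lexsort((np.arange(len(col)), -frac))
        out[order[:short]] += 1
    return out


class SimpleClassifier:
    """Teacher-driven integer-weight STDP classifier.

    Weights are ``n_features x n_classes`` non-negative integers at a given
    bit resolution; each class column's sum is held at ``w_sum_target`` by
    renormalization after every update, so classes compete for a fixed weight
    budget.  The pre-buffer collects recent feature-layer spike addresses;
    the teacher event at sample end potentiates the buffered synapses of the
    correct class.
    """

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        w_sum_target: int = 256,
        buffer_capacity: int = 64,
        learn_rate: int = 4,
        n_bits: int = 8,
        rng: Optional[np.random.Generator] = None,
    ):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if learn_rate < 1:
            raise ValueError("learn_rate must be a positive integer")
        self.n_features = n_features
        self.n_classes = n_classes
        self.w_sum_target = int(w_sum_target)
        self.learn_rate = int(learn_rate)
        self.w_max = 2**n_bits - 1
        self.pre_buffer = PreBuffer(buffer_capacity)
        rng = rng or np.random.default_rng()
        # random non-negative start, each column normalized to the budget
        raw = rng.integers(0, 8, size=(n_features, n_classes)).astype(np.int64)
        self.weights = np.stack(
            [_renormalize_column(raw[:, j], self.w_sum_target) for j in range(n_classes)],
            axis=1,
        )

    def observe(self, feature_address: int) -> None:
        """Record one feature-layer spike in the pre-buffer."""
        self.pre_buffer.append(feature_address)

    def update(self, teacher_class: int) -> None:
        """Apply the teacher event: potentiate buffered synapses, renormalize.

        An empty buffer (no feature activity since the last flush) is a no-op.
        The buffer is flushed afterwards so each sample supervises once.
        """
        buffered = self.pre_buffer.recent()
        if not buffered:
            return
        col = self.weights[:, teacher_class]
        for addr in buffered:
            col[addr] = min(col[addr] + self.learn_rate, self.w_max)
        self.weights[:, teacher_class] = _renormalize_column(col, self.w_sum_target)
        self.pre_buffer.flush()

    def predict(self, feature_counts: np.ndarray) -> int:
        """Class with the highest weighted spike count (ties: lowest index)."""
        scores = np.asarray(feature_counts, dtype=np.float64) @ self.weights
        return int(np.argmax(scores))


@dataclass(frozen=True)
class HistogramSample:
    """L1-normalized spike-count vector over feature neurons, with label."""

    features: np.ndarray
    label: int

    def __post_init__(self):
        f = np.asarray(self.features, dtype=np.float64)
        if f.min() < 0:
            raise ValueError("histogram entries must be non-negative")
        total = f.sum()
        if total > 0 and not np.isclose(total, 1.0):
            raise ValueError("non-empty histograms must sum to 1")
        object.__setattr__(self, "features", f)


def histogram_features(events: EventStream, n_features: int, label: int = -1) -> HistogramSample:
    """Normalized spike-count histogram of a feature-layer event stream.

    Counting is order-free; a silent stream yields the all-zero vector.
    """
    if len(events) and events.addresses.max() >= n_features:
        raise ValueError("event address outside the feature space")
    counts = np.bincount(events.addresses, minlength=n_features).astype(np.float64)
    total = counts.sum()
    if total > 0:
        counts /= total
    return HistogramSample(features=counts, label=label)


def counts_to_histogram(counts: np.ndarray, label: int = -1) -> HistogramSample:
    """Histogram sample straight from a spike-count vector."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    return HistogramSample(counts / total if total > 0 else counts, label)


def train_softmax_sgd(
    dataset: Sequence[HistogramSample],
    n_classes: Optional[int] = None,
    epochs: int = 200,
    batch_size: int = 16,
    learning_rate: float = 0.5,
    l2: float = 1e-4,
    seed: int = 0,
) -> np.ndarray:
    """Train a linear softmax classifier by mini-batch SGD.

    Minimizes the cross-entropy of ``softmax(X W)`` (no intercept, so the
    weight matrix alone defines the readout and converts cleanly to spiking
    neurons).  Returns the ``n_features x n_classes`` weight matrix;
    reproducible per seed.
    """
    X = np.stack([s.features for s in dataset])
    y = np.asarray([s.label for s in dataset], dtype=np.int64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("softmax training needs at least 2 classes present")
    k = int(n_classes) if n_classes is not None else int(classes.max()) + 1
    n, d = X.shape
    rng = np.random.default_rng(seed)
    W = 0.01 * rng.standard_normal((d, k))
    onehot = np.eye(k)[y]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, tb = X[idx], onehot[idx]
            logits = xb @ W
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            grad = xb.T @ (p - tb) / len(idx) + l2 * W
            W -= learning_rate * grad
    return W


@dataclass
class SnnClassifier:
    """Spiking readout converted from a frame-domain linear classifier.

    Integer weights ``round(k * W)`` feed leak-free LIF output neurons with
    threshold ``k``; the predicted class is the neuron with the highest output
    spike count.  ``default_class`` is returned (with a warning) when the
    input carries no events.
    """

    weights: np.ndarray  # integer, n_features x n_classes
    threshold: int
    default_class: int = 0

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]


def convert_to_snn(weights: np.ndarray, k: float, default_class: int = 0) -> SnnClassifier:
    """Convert frame-domain softmax weights to a spiking classifier.

    Negative weights cannot drive the non-negative LIF states, so the global
    minimum weight is subtracted from every entry first.  Because the offset
    is identical for all classes (and per-sample input mass is class
    independent), the frame-domain argmax is preserved; weights are then
    scaled by ``k`` and rounded, and every output threshold is set to ``k``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    W = np.asarray(weights, dtype=np.float64)
    lo = W.min()
    if lo < 0:
        W = W - lo
    return SnnClassifier(
        weights=np.rint(k * W).astype(np.int64),
        threshold=int(round(k)),
        default_class=default_class,
    )


def snn_classify(clf: SnnClassifier, events: EventStream) -> int:
    """Run events through the spiking output layer; argmax spike count.

    Output neurons integrate the (integer) weight of each incoming feature
    event and emit a spike whenever their state reaches the threshold ``k``,
    consuming ``k`` state units per spike (states stay non-negative; residual
    charge below threshold is retained).  Ties break to the lowest index.
    """
    if len(events) == 0:
        warnings.warn("no input events; returning the default class", stacklevel=2)
        return clf.default_class
    if events.addresses.max() >= clf.weights.shape[0]:
        raise ValueError("event address outside the classifier feature space")
    # Leak-free integration with threshold subtraction commutes event-wise,
    # so the spike count per neuron is the integer quotient of the total
    # accumulated charge.
    charge = np.zeros(clf.n_classes, dtype=np.int64)
    counts = np.bincount(events.addresses, minlength=clf.weights.shape[0])
    charge = counts @ clf.weights
    spikes = charge // clf.threshold
    return int(np.argmax(spikes))
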