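"""End-to-end experiment runners.

* Orientation selectivity: a 32 x 32 input layer fully connected to four
  1-bit-synapse neurons develops orientation-tuned receptive fields from
  Poisson-encoded oriented bars, through stochastic STDP with winner-take-all
  competition, homeostatic threshold growth and weight normalization.  After
  training, plasticity / threshold adaptation / lateral inhibition are
  disabled and tuning curves are measured with bars rotated in 10-degree
  steps.
* Feature-extraction pipeline: an FE layer trained by one unsupervised pass
  of stochastic STDP (or set to fixed random bits with the same per-neuron
  active-synapse budget, the control condition), followed by a trainable
  classifier; reports train/test accuracy with binomial confidence
  intervals.  A small grid search utility selects hyperparameters on a
  validation split and spends the test set exactly once.

The population engine (:class:`FeatureExtractionLayer`) is the event-driven
core shared by both: fully connected 1-bit weights, per-neuron dual counters
and thresholds, lazy piece-wise-linear leak, WTA lateral inhibition, and the
stochastic STDP update on each learning trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .aer_core import EventStream, subsample_addresses
from .classifiers import SimpleClassifier, counts_to_histogram, train_softmax_sgd
from .neuron import LeakSchedule, NeuronConfig, fit_leak_schedule
from .stdp import BinaryWeights, PreBuffer, StdpConfig, apply_binary_stdp, wta_resolve
from . import stimuli
from .stimuli import EncodingConfig, SampleSequence

__all__ = [
    "FeatureExtractionLayer",
    "OrientationConfig",
    "TrainedNetwork",
    "run_orientation_training",
    "TuningCurve",
    "measure_tuning",
    "preferred_orientations",
    "PipelineConfig",
    "make_symbol_dataset",
    "run_fe_pipeline",
    "compare_fe_modes",
    "hyperparam_search",
    "confidence_interval",
]


class FeatureExtractionLayer:
    """A fully connected population of 1-bit-synapse LIF neurons.

    Every input event addresses one synapse row, so all neurons see the event
    simultaneously; leak is applied lazily over the gap since the previous
    event.  In learning mode the layer runs winner-take-all (one output spike
    per input event at most, all other members reset), homeostatic threshold
    growth and the stochastic STDP update; in inference mode neurons fire
    independently with frozen thresholds and no plasticity.
    """

    def __init__(
        self,
        n_inputs: int,
        n_neurons: int,
        neuron_config: NeuronConfig,
        stdp_config: StdpConfig,
        w_sum: int,
        leak_schedule: Optional[LeakSchedule] = None,
        rng: Optional[np.random.Generator] = None,
        weights: Optional[BinaryWeights] = None,
        wta_policy: Literal["lowest", "random"] = "lowest",
    ):
        self.n_inputs = n_inputs
        self.n_neurons = n_neurons
        self.neuron_config = neuron_config
        self.stdp_config = stdp_config
        self.leak_schedule = leak_schedule
        self.wta_policy = wta_policy
        self.rng = rng or np.random.default_rng()
        self.weights = weights if weights is not None else BinaryWeights.random(
            n_inputs, n_neurons, w_sum, self.rng
        )
        self.buffer = PreBuffer(stdp_config.buffer_size)
        self.firing_thresholds = np.full(n_neurons, neuron_config.x_th_init, dtype=np.int64)
        self.stdp_thresholds = np.full(
            n_neurons, neuron_config.stdp_threshold_init, dtype=np.int64
        )
        self.reset_state(0)

    def reset_state(self, t0: int = 0) -> None:
        """Zero all counters (thresholds untouched) and restart the clock."""
        self.firing_counters = np.zeros(self.n_neurons, dtype=np.int64)
        self.learning_counters = np.zeros(self.n_neurons, dtype=np.int64)
        self._last_t = int(t0)
        self._leak_carry = 0.0

    # -- internal helpers ---------------------------------------------------

    def _leak(self, now: int) -> None:
        gap = now - self._last_t
        if gap <= 0 or self.leak_schedule is None:
            self._last_t = now
            return
        sched = self.leak_schedule
        bps = sched.halving_points_us
        if bps and gap <= bps[0]:  # fast path: single-segment gap
            amount = sched.initial_decrement / sched.tick_us * gap + self._leak_carry
        else:
            amount = sched.decay_amount(gap) + self._leak_carry
        dec = int(amount)
        self._leak_carry = amount - dec
        if dec:
            np.maximum(self.firing_counters - dec, 0, out=self.firing_counters)
            np.maximum(self.learning_counters - dec, 0, out=self.learning_counters)
        self._last_t = now

    # -- public API ---------------------------------------------------------

    def train_on_stream(self, stream: EventStream) -> List[Tuple[int, int]]:
        """Process events with plasticity, WTA and homeostasis enabled.

        Returns the (time, neuron) output spikes of the winners.  With a
        single threshold (software mode) the STDP update fires on every
        output spike of the WTA winner; in dual-threshold mode firing and
        learning run on separate counters and thresholds, each with its own
        WTA reset.
        """
        cfg = self.neuron_config
        scfg = self.stdp_config
        bits = self.weights.bits
        fc = self.firing_counters
        lc = self.learning_counters
        fth = self.firing_thresholds
        sth = self.stdp_thresholds
        dual = cfg.dual_threshold
        spikes: List[Tuple[int, int]] = []
        for t, a in zip(stream.timestamps.tolist(), stream.addresses.tolist()):
            self._leak(t)
            self.buffer.append(a)
            w = bits[a]
            fc += w
            lc += w
            fired = np.flatnonzero(fc >= fth)
            if fired.size:
                winner = wta_resolve(fired, self.wta_policy, self.rng)
                spikes.append((t, winner))
                fth[winner] = min(fth[winner] + cfg.th_increment, cfg.x_th_max)
                fc[:] = 0  # winner reset + lateral inhibition
                if not dual:
                    lc[:] = 0
                    self._leak_carry = 0.0
                    apply_binary_stdp(self.weights, winner, self.buffer, scfg, self.rng)
            if dual:
                triggers = np.flatnonzero(lc >= sth)
                if triggers.size:
                    learner = wta_resolve(triggers, self.wta_policy, self.rng)
                    sth[learner] += cfg.stdp_th_increment
                    lc[:] = 0
                    apply_binary_stdp(self.weights, learner, self.buffer, scfg, self.rng)
        return spikes

    def infer_on_stream(
        self, stream: EventStream, record_spikes: bool = False
    ):
        """Process events with plasticity, adaptation and WTA all disabled.

        Thresholds are frozen at their current values; each neuron fires and
        resets independently.  Returns the per-neuron spike counts, or
        ``(counts, [(t, neuron), ...])`` when ``record_spikes`` is set.
        """
        bits = self.weights.bits
        fc = self.firing_counters
        fth = self.firing_thresholds
        counts = np.zeros(self.n_neurons, dtype=np.int64)
        spikes: List[Tuple[int, int]] = []
        for t, a in zip(stream.timestamps.tolist(), stream.addresses.tolist()):
            self._leak(t)
            fc += bits[a]
            fired = fc >= fth
            if fired.any():
                counts[fired] += 1
                fc[fired] = 0
                if record_spikes:
                    spikes.extend((t, int(j)) for j in np.flatnonzero(fired))
        if record_spikes:
            return counts, spikes
        return counts


# ---------------------------------------------------------------------------
# Orientation selectivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationConfig:
    """Study conditions of the orientation-selectivity experiment.

    Defaults: 4 neurons over a 32 x 32 input, initial threshold 10 capped at
    100, STDP buffer of 250 events, 80% potentiation probability, 180 active
    synapses per neuron, 400 epochs of 4 bar orientations 45 degrees apart.
    Encoding (not pinned down by the protocol itself): 1000 spikes per sample
    at a constant 100 k events/s population rate, inter-symbol time 100 ms so
    the 12 ms leak returns every neuron to rest between samples.
    """

    orientations: Tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    epochs: int = 400
    size: int = 32
    n_neurons: int = 4
    w_sum: int = 180
    neuron: NeuronConfig = field(default_factory=lambda: NeuronConfig(
        x_th_init=10, x_th_max=100, th_increment=1))
    stdp: StdpConfig = field(default_factory=lambda: StdpConfig(
        p_ltp=0.8, buffer_size=250, normalization="deterministic", flush=True))
    encoding: EncodingConfig = field(default_factory=lambda: EncodingConfig(
        total_rate=100_000.0, total_spikes=1000, ist_us=100_000))
    tau_leak_us: float = 12_000.0


@dataclass
class TrainedNetwork:
    """Frozen outcome of a feature-extraction training run."""

    weights: BinaryWeights
    firing_thresholds: np.ndarray
    leak_schedule: Optional[LeakSchedule]
    neuron_config: NeuronConfig
    n_output_spikes: int = 0


def run_orientation_training(
    config: OrientationConfig = OrientationConfig(), seed: int = 0
) -> TrainedNetwork:
    """Train the 4-neuron population on randomly ordered oriented bars.

    Deterministic per seed (one generator drives encoding, initial weights
    and the stochastic STDP draws).  Returns the final 1-bit receptive fields
    and per-neuron thresholds.
    """
    rng = np.random.default_rng(seed)
    schedule = fit_leak_schedule(config.tau_leak_us, initial_state=config.neuron.x_th_max)
    layer = FeatureExtractionLayer(
        n_inputs=config.size * config.size,
        n_neurons=config.n_neurons,
        neuron_config=config.neuron,
        stdp_config=config.stdp,
        w_sum=config.w_sum,
        leak_schedule=schedule,
        rng=rng,
    )
    seq = stimuli.bar_sequence(
        list(config.orientations), config.epochs, config.encoding, rng, size=config.size
    )
    spikes = layer.train_on_stream(seq.stream)
    return TrainedNetwork(
        weights=layer.weights,
        firing_thresholds=layer.firing_thresholds.copy(),
        leak_schedule=schedule,
        neuron_config=config.neuron,
        n_output_spikes=len(spikes),
    )


@dataclass
class TuningCurve:
    """Firing rate of each neuron as a function of bar orientation."""

    angles_deg: np.ndarray
    rates_hz: np.ndarray  # (n_angles, n_neurons)

    def peak_angle(self, neuron: int) -> float:
        return float(self.angles_deg[int(np.argmax(self.rates_hz[:, neuron]))])


def measure_tuning(
    network: TrainedNetwork,
    angles_deg: Sequence[float] = tuple(range(0, 181, 10)),
    encoding: EncodingConfig = EncodingConfig(total_rate=100_000.0, total_spikes=3000,
                                              ist_us=100_000),
    seed: int = 1,
    repeats: int = 3,
) -> TuningCurve:
    """Post-learning tuning curves over rotated bars.

    Plasticity, threshold adaptation and lateral inhibition are off;
    thresholds stay at their final training values.  Each angle is presented
    ``repeats`` times with fresh Poisson draws and the firing rate is
    spikes per second of stimulus.
    """
    rng = np.random.default_rng(seed)
    n_inputs = network.weights.n_pre
    size = int(round(n_inputs**0.5))
    layer = FeatureExtractionLayer(
        n_inputs=n_inputs,
        n_neurons=network.weights.n_post,
        neuron_config=network.neuron_config,
        stdp_config=StdpConfig(),  # unused in inference
        w_sum=network.weights.w_sum_target,
        leak_schedule=network.leak_schedule,
        rng=rng,
        weights=network.weights,
    )
    layer.firing_thresholds = network.firing_thresholds.copy()
    duration_s = encoding.sample_duration_us / 1e6
    rates = np.zeros((len(angles_deg), layer.n_neurons))
    for i, angle in enumerate(angles_deg):
        counts = np.zeros(layer.n_neurons, dtype=np.int64)
        for _ in range(repeats):
            img = stimuli.oriented_bar_image(angle, size=size, rng=rng)
            ev = stimuli.poisson_encode(img, encoding, rng)
            layer.reset_state(0)
            counts += layer.infer_on_stream(ev)
        rates[i] = counts / (repeats * duration_s)
    return TuningCurve(np.asarray(angles_deg, dtype=float), rates)


def preferred_orientations(
    curve: TuningCurve, trained: Sequence[float] = (0.0, 45.0, 90.0, 135.0)
) -> np.ndarray:
    """Map each neuron's tuning-curve peak to the nearest trained orientation.

    Orientation is a 180-degree circular quantity (a bar at 0 and at 180 are
    the same stimulus).
    """
    trained = np.asarray(trained, dtype=float)
    prefs = np.empty(curve.rates_hz.shape[1])
    for j in range(curve.rates_hz.shape[1]):
        peak = curve.peak_angle(j) % 180.0
        d = np.abs(trained - peak)
        d = np.minimum(d, 180.0 - d)
        prefs[j] = trained[int(np.argmin(d))]
    return prefs


# ---------------------------------------------------------------------------
# Feature-extraction + classifier pipeline (synthetic moving symbols)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions of the synthetic 4-class moving-symbol pipeline.

    The visual field is 128 x 128 subsampled by 4 to a 32 x 32 input (1024
    synapses per neuron), matching the event-camera processing chain.  STDP
    parameters follow the on-line hardware configuration: 100 active synapses
    per neuron, 90-event buffer, 30% potentiation probability.  The hidden
    layer is deliberately small (16 neurons): a better feature extractor
    shows its worth against random projections precisely when the hidden
    layer is small and the classifier simple.  The homeostatic threshold cap
    is set far above the working range so per-neuron threshold growth, not
    the cap, equalizes activity; the leak schedule is fitted to a typical
    working state of 200 counter units.
    """

    n_fe: int = 16
    n_classes: int = 4
    field_size: Tuple[int, int] = (128, 128)
    subsample_factor: int = 4
    glyph_scale: int = 6
    w_sum: int = 100
    neuron: NeuronConfig = field(default_factory=lambda: NeuronConfig(
        x_th_init=10, x_th_max=2000, th_increment=1))
    stdp: StdpConfig = field(default_factory=lambda: StdpConfig(
        p_ltp=0.3, buffer_size=90, normalization="deterministic", flush=True))
    tau_leak_us: float = 100_000.0
    leak_fit_state: float = 200.0
    event_rate: float = 10_000.0
    sample_duration_us: int = 500_000
    random_activity_target: float = 100.0  # spikes/sample for standalone random mode
    clf_w_sum_per_feature: int = 32
    clf_buffer: int = 128
    clf_learn_rate: int = 8
    clf_n_bits: int = 16

    @property
    def n_inputs(self) -> int:
        r, c = self.field_size
        f = self.subsample_factor
        return (r // f) * (c // f)

    @property
    def clf_w_sum(self) -> int:
        return self.clf_w_sum_per_feature * self.n_fe


def make_symbol_dataset(
    n_train: int,
    n_test: int,
    rng: np.random.Generator,
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[List[Tuple[EventStream, int]], List[Tuple[EventStream, int]]]:
    """Synthetic DVS-like dataset: each sample is one glyph pass.

    Classes are the four poker suits; samples are moving-symbol streams
    subsampled to the network input resolution, in shuffled order balanced
    across classes.
    """
    def make(n: int) -> List[Tuple[EventStream, int]]:
        samples = []
        for i in range(n):
            label = i % config.n_classes
            ev = stimuli.moving_symbol_stream(
                stimuli.GLYPH_NAMES[label],
                event_rate=config.event_rate,
                duration_us=config.sample_duration_us,
                rng=rng,
                field=config.field_size,
                scale=config.glyph_scale,
            )
            ev = subsample_addresses(ev, config.subsample_factor)
            samples.append((ev, label))
        order = rng.permutation(n)
        return [samples[k] for k in order]

    return make(n_train), make(n_test)


def _fe_counts(layer: FeatureExtractionLayer, dataset) -> np.ndarray:
    out = np.zeros((len(dataset), layer.n_neurons), dtype=np.int64)
    for i, (ev, _label) in enumerate(dataset):
        layer.reset_state(0)
        out[i] = layer.infer_on_stream(ev)
    return out


def _calibrate_threshold(
    layer: FeatureExtractionLayer, dataset, target_mean_spikes: float
) -> int:
    """Pick the uniform inference threshold whose mean activity on the
    calibration samples comes closest to the target (the automatic
    inference-threshold adjustment applied to fixed-random receptive
    fields).  Activity is monotone decreasing in the threshold, so a
    bisection over a wide range suffices."""
    lo, hi = 2, 4000
    best_th, best_gap = lo, float("inf")
    for _ in range(12):
        mid = (lo + hi) // 2
        layer.firing_thresholds[:] = mid
        mean_spikes = _fe_counts(layer, dataset).sum(axis=1).mean()
        gap = abs(mean_spikes - target_mean_spikes)
        if gap < best_gap:
            best_th, best_gap = mid, gap
        if mean_spikes > target_mean_spikes:
            lo = mid + 1
        else:
            hi = mid - 1
        if lo > hi:
            break
    layer.firing_thresholds[:] = best_th
    return best_th


def run_fe_pipeline(
    config: PipelineConfig,
    train_set,
    test_set,
    fe_mode: Literal["stdp", "random"] = "stdp",
    classifier: Literal["simple", "softmax"] = "simple",
    seed: int = 0,
    activity_target: Optional[float] = None,
) -> Dict:
    """Train the FE layer (one unsupervised STDP pass, or fixed random bits
    with the same W_sum budget), freeze it, train the classifier, and report
    train/test accuracy with 99% binomial confidence intervals.

    No weight or threshold changes happen during evaluation.  In STDP mode
    the learned per-neuron thresholds are the inference operating point; in
    random mode a uniform inference threshold is calibrated on a slice of the
    training set to ``activity_target`` mean spikes per sample (defaulting to
    the config's ``random_activity_target``) -- pass the STDP run's measured
    activity for an activity-matched paired comparison.
    """
    if not train_set or not test_set:
        raise ValueError("train and test sets must be non-empty")
    if len({label for _, label in train_set}) < 2:
        raise ValueError("training set must contain at least 2 classes")
    rng = np.random.default_rng(seed)
    schedule = fit_leak_schedule(config.tau_leak_us, initial_state=config.leak_fit_state)
    layer = FeatureExtractionLayer(
        n_inputs=config.n_inputs,
        n_neurons=config.n_fe,
        neuron_config=config.neuron,
        stdp_config=config.stdp,
        w_sum=config.w_sum,
        leak_schedule=schedule,
        rng=rng,
    )
    if fe_mode == "stdp":
        for ev, _label in train_set:  # one pass, unsupervised
            layer.reset_state(0)
            layer.train_on_stream(ev)
        # freeze: thresholds stay at their final learned values
    elif fe_mode == "random":
        calib = train_set[: max(10, len(train_set) // 16)]
        target = activity_target if activity_target is not None \
            else config.random_activity_target
        _calibrate_threshold(layer, calib, target_mean_spikes=target)
    else:
        raise ValueError(f"unknown fe_mode {fe_mode!r}")

    train_counts = _fe_counts(layer, train_set)
    test_counts = _fe_counts(layer, test_set)
    train_labels = np.asarray([label for _, label in train_set])
    test_labels = np.asarray([label for _, label in test_set])

    if classifier == "simple":
        clf = SimpleClassifier(
            n_features=config.n_fe,
            n_classes=config.n_classes,
            w_sum_target=config.clf_w_sum,
            buffer_capacity=config.clf_buffer,
            learn_rate=config.clf_learn_rate,
            n_bits=config.clf_n_bits,
            rng=rng,
        )
        # teacher events fire periodically during the sample (every time the
        # classifier's pre-buffer fills) and once at sample end
        for ev, label in train_set:
            layer.reset_state(0)
            _counts, spikes = layer.infer_on_stream(ev, record_spikes=True)
            for k, (_t, j) in enumerate(spikes):
                clf.observe(j)
                if (k + 1) % config.clf_buffer == 0:
                    clf.update(label)
            clf.update(label)
        train_pred = np.array([clf.predict(c) for c in train_counts])
        test_pred = np.array([clf.predict(c) for c in test_counts])
    elif classifier == "softmax":
        hist = [counts_to_histogram(c, int(y)) for c, y in zip(train_counts, train_labels)]
        W = train_softmax_sgd(hist, n_classes=config.n_classes, seed=seed)
        train_pred = np.argmax(train_counts @ W, axis=1)
        test_pred = np.argmax(test_counts @ W, axis=1)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    train_acc = float((train_pred == train_labels).mean())
    test_acc = float((test_pred == test_labels).mean())
    ci = confidence_interval(1.0 - test_acc, len(test_set), 0.99)
    return {
        "fe_mode": fe_mode,
        "classifier": classifier,
        "train_accuracy": train_acc,
        "test_accuracy": test_acc,
        "test_error_ci99": ci,
        "mean_test_fe_spikes": float(test_counts.sum(axis=1).mean()),
        "final_thresholds": layer.firing_thresholds.copy(),
        "weights": layer.weights,
    }


def compare_fe_modes(
    config: PipelineConfig,
    train_set,
    test_set,
    classifier: Literal["simple", "softmax"] = "simple",
    seed: int = 0,
) -> Dict:
    """Paired STDP-vs-random comparison under the activity-matching protocol.

    The STDP run goes first; the random baseline's uniform inference
    threshold is then calibrated so its mean spikes per sample match the
    STDP network's measured test activity, removing operating-point
    differences from the comparison.
    """
    stdp_report = run_fe_pipeline(config, train_set, test_set, "stdp", classifier, seed)
    random_report = run_fe_pipeline(
        config, train_set, test_set, "random", classifier, seed,
        activity_target=stdp_report["mean_test_fe_spikes"],
    )
    return {"stdp": stdp_report, "random": random_report}


def hyperparam_search(
    grid: Sequence[Dict],
    base_config: PipelineConfig,
    train_set,
    val_set,
    test_set,
    fe_mode: Literal["stdp", "random"] = "stdp",
    classifier: Literal["simple", "softmax"] = "simple",
    seed: int = 0,
) -> Dict:
    """Grid search on the validation split; the winner is retrained on
    train+validation and the test set is evaluated exactly once.

    Each grid point is a dict of :class:`PipelineConfig` field overrides
    (nested ``stdp``/``neuron`` overrides are dicts of their fields).
    Returns the winning config, all validation scores, and the single test
    report (``n_test_evaluations`` documents the leakage guard).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    val_scores = []
    for overrides in grid:
        cfg = _apply_overrides(base_config, overrides)
        report = run_fe_pipeline(cfg, train_set, val_set, fe_mode, classifier, seed)
        val_scores.append(report["test_accuracy"])  # accuracy on the val split
    best_idx = int(np.argmax(val_scores))
    best_cfg = _apply_overrides(base_config, grid[best_idx])
    final = run_fe_pipeline(
        best_cfg, list(train_set) + list(val_set), test_set, fe_mode, classifier, seed
    )
    return {
        "best_overrides": grid[best_idx],
        "validation_scores": val_scores,
        "test_report": final,
        "n_test_evaluations": 1,
    }


def _apply_overrides(config: PipelineConfig, overrides: Dict) -> PipelineConfig:
    kwargs = {}
    for key, value in overrides.items():
        if key == "stdp":
            kwargs["stdp"] = replace(config.stdp, **value)
        elif key == "neuron":
            kwargs["neuron"] = replace(config.neuron, **value)
        else:
            kwargs[key] = value
    return replace(config, **kwargs)


def confidence_interval(
    error_rate: float,
    n_test: int,
    confidence: float = 0.99,
    z_star: Optional[float] = None,
) -> Tuple[float, float]:
    """Binomial confidence interval of the mean test error.

    ``error_rate +/- z* sqrt(error_rate (1 - error_rate) / n_test)``; at the
    0.99 level the conventional ``z* = 2.578`` is used, other levels take the
    normal quantile.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if z_star is None:
        z_star = 2.578 if abs(confidence - 0.99) < 1e-9 else float(
            stats.norm.ppf(0.5 + confidence / 2.0)
        )
    half = z_star * float(np.sqrt(error_rate * (1.0 - error_rate) / n_test))
    return (error_rate - half, error_rate + half)
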