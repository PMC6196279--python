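# Methods

This note documents the models, numerical choices and known limitations of
`bitstdp`, in the spirit of a simulator methods appendix. Everything stated
here is computed by the shipped tests or scripts; nothing is asserted beyond
what the code reproduces.

## Neuron model

Neurons are linear-leak integrate-and-fire units with *non-negative integer*
state, instantaneous 1-bit synapses, and reset-to-zero on firing. Each
neuron carries two counters — a firing counter for inference and a learning
counter for STDP triggers — with separate thresholds. In software mode
(`dual_threshold = False`) the two are coupled: the STDP trigger mirrors the
output spike, which matches off-line, layer-by-layer training. Hardware-
emulation mode decouples them, as required when all layers learn on-line
simultaneously: the firing threshold keeps activity high for downstream
layers while the STDP threshold (incremented by one per learning event)
slows plasticity as a neuron specializes.

### Leak

The exponential leak `S0 * exp(-t/tau)` is approximated by a piece-wise-
linear schedule: a fixed decrement per microsecond tick, halved at
breakpoints `h, 2h, ..., nh` with `h = tau * ln 2` (`fit_leak_schedule`,
default 6 halvings). Within each halving interval the schedule follows the
chord of the exponential, so the worst-case deviation is about 4.3 % of the
running state; the shipped tolerance constant (5 units on a 100-unit state,
`LEAK_FIT_TOLERANCE`) is verified against the closed-form exponential on a
0.5 ms grid over 60 ms at `tau = 12 ms`. After the final breakpoint the last
decrement continues indefinitely, so every neuron reaches its resting state
in bounded time — this implements the between-sample reset when samples are
separated by an inter-symbol time (IST) of at least the full drain time.

Leak is evaluated lazily, only when an event touches the neuron, as a
function of the *gap* since the neuron's last update. Consequences worth
knowing: under dense input the gap rarely leaves the first (fastest) segment,
so the effective leak rate is the initial one; the integer part of the
accumulated decrement is applied and the fraction carried forward. This is
an approximation of a clocked hardware leak, chosen for O(events) cost; it
is exact for isolated decays from a fresh state, which is the regime the
fitting oracle checks.

## The stochastic 1-bit STDP rule

The rule is order-based ("undiscriminating depressing"): only a bounded
circular pre-buffer of recent input addresses is kept. On a learning
trigger for neuron `j`:

1. **LTP** — up to `number_of_potentiation` most recent buffered addresses
   are set to 1 with probability `P_LTP` each. Duplicates in the buffer draw
   independently; potentiation is idempotent, so duplicates cost attempts
   but not correctness (mirroring the hardware circular buffer).
2. **LTD / normalization** — with *deterministic* normalization, exactly
   `popcount - W_sum` active bits are cleared, chosen uniformly at random
   among active synapses **not** in the buffer (the recently active synapses
   are the ones the rule rewards); if too few unprotected bits exist the
   update falls back to buffered ones and logs a warning. With *stochastic*
   normalization every eligible active bit is cleared with the 10-bit
   probability `floor(1024 * dW / W_actual) / 1024`, the exact integer
   arithmetic of the hardware divider; the popcount then wanders around
   `W_sum` instead of sitting on it. The expectation of cleared bits equals
   `dW` up to the 10-bit quantization (at most `W_actual/1024` bits), which
   is why the acceptance check on the depression mean carries that bound in
   addition to the binomial 3-sigma term.
3. **Flushing** — the pre-buffer is emptied (default on), so each learning
   event consumes only the history that caused it. The hardware does this
   unconditionally; the flag exists because soft-inhibition variants may
   want it off.

Buffered-synapse protection from same-update LTD is on by default and can be
dropped (`protect_buffered = False`) to mirror the hardware LTD pass, which
rescans the entire weight row.

WTA lateral inhibition allows one output spike per input event during
learning; losers have both counters reset. The tie-break is lowest-index by
default (deterministic), with a seeded-random alternative. Probabilities are
floats in software and 10-bit integers against a 16-bit LFSR
(`hw_model.LfsrRandom`) in hardware-emulation paths; the two are verified to
be statistically indistinguishable on the 0–1024 grid.

## Classifiers

**Simple teacher-STDP classifier.** Integer weights (default 16-bit) from
feature neurons to class neurons; a pre-buffer collects recent feature
spikes, and a teacher event potentiates the buffered synapses of the correct
class by `learn_rate`, after which the class column is renormalized to its
weight budget by largest-remainder integer rescaling (deterministic, exact).
The per-class budget scales with the feature count (32 units per feature by
default) so renormalization does not quantize the weights away. During
pipeline training the teacher fires every time the classifier buffer fills
and once at sample end; prediction is the argmax of the weighted spike
counts. This classifier is deliberately weak — it exists to probe feature
quality, not to maximize accuracy.

**Histogram + softmax + spiking conversion.** Per-sample L1-normalized
spike-count histograms feed a linear softmax trained by mini-batch SGD
(hand-rolled in numpy: no intercept, so the weight matrix alone defines the
readout; deterministic per seed; cross-checked against scikit-learn's
logistic regression in the tests). Conversion to spiking form subtracts the
*global* minimum weight (a per-class offset would bias the readout, since
adding `delta_c` to class `c`'s column shifts its score by `delta_c` times
the input mass, which is class-independent only if the offset is), scales by
`k`, rounds, and sets all output thresholds to `k`. Output neurons integrate
without leak and consume `k` units of charge per spike while retaining
sub-threshold residuals, so the spike count is exactly the integer quotient
of the accumulated charge — at high input event counts the spiking argmax
reproduces the frame-domain argmax (>= 95 % agreement on 200 synthetic
samples at `k = 1000` in the acceptance suite).

## Synthetic stimuli

* **Oriented bars** — 8 x 24 px bars in a 32 x 32 frame, rasterized
  analytically (a pixel belongs to the bar if its center falls inside the
  rotated rectangle), intensities uniform on [0.8, 1.0], background 0. At
  0 degrees the count is exactly 192 pixels; oblique angles deviate slightly
  by nearest-neighbor rasterization.
* **Poisson rate coding** — pixel `i` fires at `total_rate * I_i / sum(I)`,
  keeping the population rate constant across images. In exact-count mode
  the conditional property of the Poisson process is used (categorical
  pixels, uniform times), so a sample has exactly `total_spikes` events.
* **Moving-symbol surrogate** — a DVS-like stand-in: events are drawn from
  the *edge* pixels of a poker-suit glyph as it follows a smooth random
  Lissajous path, with instantaneous event rate proportional to path speed
  (a stationary object emits nothing). The path emulates a hand-held symbol
  wobbled slowly in front of the sensor: roughly centered, drifting at most
  ~15 px, one to two oscillation cycles per 0.5 s sample. What it does *not*
  emulate: sensor noise, ON/OFF polarity statistics, contrast-dependent
  event rates, occlusions, or scale changes. Passing tests on this surrogate
  therefore demonstrate that the learning machinery extracts and exploits
  spatial structure from motion-driven edge events, not that any particular
  accuracy would transfer to real event-camera recordings.

All generators are pure functions of the supplied numpy `Generator`.

## Experiments and study conditions

**Orientation selectivity.** 4 neurons, 1024 inputs, initial threshold 10,
cap 100, buffer 250, `P_LTP = 0.8`, `W_sum = 180`, 400 epochs of the four
orientations (0/45/90/135 degrees) in random order, deterministic
normalization. The encoding is not pinned down by the protocol, so the
package fixes it once: 1000 spikes per sample at a constant 100 k events/s
population rate (10 ms per sample), IST 100 ms, leak `tau = 12 ms` — the IST
exceeds the full drain time, so states reset between samples. Note that
`W_sum = 180` is slightly below the 192 bar pixels, leaving the rule a
12-synapse slack. Tuning curves are measured at 10-degree steps (0–180,
with 0 and 180 identified) from 3 x 3000-spike presentations per angle, with
plasticity, threshold adaptation and inhibition disabled and thresholds
frozen at their final values. Preferred orientation is the circular nearest
trained orientation of the tuning-curve argmax.

**Moving-symbol pipeline.** 128 x 128 field subsampled by 4 to a 32 x 32
input; `W_sum = 100`, buffer 90, `P_LTP = 0.3` (the on-line hardware
configuration); one unsupervised STDP pass over 160 training samples, then a
frozen-feature classifier pass, 48 test samples (40/12 per class). Two
deliberate design choices:

* The hidden layer is small (16 neurons) and the classifier is the simple
  one. A sufficiently large random hidden layer followed by a strong
  classifier is already an excellent pattern recognizer, so the value of a
  *trained* feature layer shows precisely where that regime breaks down —
  few neurons, weak classifier. With large hidden layers the random
  baseline's spike counts approach information-preserving random projections
  of the input histogram and the contrast narrows or inverts; 16 neurons is
  the regime this experiment is about.
* The homeostatic cap is set far above the working range (2000), so
  per-neuron threshold growth — not the cap — equalizes activity. Capping at
  a few tens of units in this dense-event regime saturates every threshold
  immediately, disabling competition and collapsing the receptive fields.
* Inference operating points are activity-matched: the STDP network is read
  out at its learned thresholds; the random baseline's uniform threshold is
  calibrated (bisection on a training slice) to the STDP network's mean
  spikes per sample. Comparing at mismatched activity levels confounds
  feature quality with operating point.

The contrast is evaluated as mean test accuracy over five seeded
dataset/training replicates; it is directional (trained features beat
random ones), with both arms well above 4-class chance.

**Hyperparameter search** scores each grid point on a validation split and
spends the test split exactly once, on the winner retrained on
train+validation — the call pattern is asserted in the tests.

## Numerical and degenerate-input conventions

* Timestamps are integer microseconds; ties keep input order everywhere.
* Pixel flattening is row-major, 0-based.
* Event-count slicing drops the trailing remainder, keeping slice statistics
  uniform.
* Ties in argmax readouts break to the lowest index; a silent input stream
  yields the configured default class plus a warning.
* Histograms of silent streams are all-zero (not renormalized).
* `confidence_interval` uses the conventional `z* = 2.578` at the 0.99 level
  (the value used in the experimental protocol) and the exact normal
  quantile otherwise.
* Seeds: every experiment entry point takes one integer seed; all
  randomness (weights, stimuli, STDP draws, SGD shuffling) derives from it.

## Known limitations

* The event engine is a per-event Python loop over numpy state vectors —
  adequate up to a few hundred neurons and a few million events, not a
  large-scale simulator.
* Dual-threshold on-line mode is implemented but the shipped experiments use
  the software (single-threshold, sequential-layer) protocol.
* The cycle-cost model covers steady-state accounting and a lockout flag for
  events arriving mid-update; it does not model bus arbitration latencies or
  register-transfer-level behavior.
* DVS polarity is merged into a single address space by default (the readers
  keep the polarity column; the feature-extraction layer ignores it).
* In the "2090 + buffer size" saturation expression, buffer capacity and the
  number of potentiations coincide; the model takes the number of
  potentiations when they differ.
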