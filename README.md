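# bitstdp

Event-driven spiking neural networks with **1-bit synaptic weights** learned
by **stochastic, order-based STDP**.

Hardware implementations of spike-timing-dependent plasticity usually founder
on weight precision: conventional STDP accumulates tiny graded updates, so
every synapse needs a wide word of memory and arithmetic. This package
implements and studies the alternative: synapses that are a single bit, with
plasticity expressed as *probabilistic* bit flips, plus the stabilization
mechanisms that make such learning converge — per-neuron weight budgets,
homeostatic threshold adaptation, winner-take-all lateral inhibition, bounded
pre-synaptic event buffers with list flushing, and separate learning/inference
thresholds. It is written for computational-neuroscience and neuromorphic-
engineering work: everything is event-driven (address-event representation,
integer-microsecond timestamps), deterministic per seed, and mirrors the
behavior of a compact FPGA neural core down to its clock-cycle budget.

## The model

**Neuron.** Linear-leak integrate-and-fire with non-negative integer state.
An input event through an active synapse (`w = 1`) increments the state; the
neuron fires when the state reaches its threshold `x_th` and resets to zero.
The exponential leak `exp(-t/tau)` is approximated by a piece-wise-linear
decay whose per-tick decrement halves at fitted breakpoints (a bit-shift in
hardware), applied lazily when events arrive.

**Learning rule.** Order-based "undiscriminating depressing" STDP: a bounded
circular buffer keeps the addresses of the most recent pre-synaptic events.
When a neuron produces a learning trigger,

* *LTP*: each buffered synapse is set to 1 with probability `P_LTP`;
* *LTD*: the remaining active synapses are depressed so the per-neuron count
  of active synapses returns to the budget `W_sum` — either exactly
  (deterministic normalization) or stochastically with the 10-bit hardware
  probability

  ```
  P_LTD = floor(1024 * dW / W_actual),   dW = W_actual - W_sum
  ```

  compared against a 16-bit LFSR sample;
* during learning each input event may produce at most one output spike
  (WTA); every other neuron in the population is reset, each spike raises the
  winner's threshold by 1 up to `x_th_max` (homeostasis), and the pre-buffer
  is flushed.

**Readouts.** A simple on-line classifier (teacher-driven integer-weight STDP
with per-class weight budgets) and a high-performance one: per-sample
normalized spike-count histograms, a softmax trained by mini-batch SGD, then
conversion to spiking neurons by scaling the weights by `k` and setting the
LIF thresholds to `k`. Test errors carry binomial confidence intervals
`mu ± z* sqrt(mu(1-mu)/N_T)` with `z* = 2.578` at the 0.99 level.

**Hardware model.** Closed-form cycle accounting of the shared STDP unit
(`7 + n_pot` cycles for LTP, `1024+3+25+1024+7 = 2083` for LTD), its
saturation throughput, the maximal 16-bit LFSR, and the resource-scaling law
`R ~ N_h * n_b` that trades bit resolution against hidden-layer size.

## Worked example

Train the four-neuron orientation-selectivity network (32 x 32 Poisson-coded
oriented bars, `W_sum = 180`, `P_LTP = 80%`, buffer 250, thresholds 10 to
100, 400 epochs) and measure its tuning curves:

```python
from bitstdp import experiments

net = experiments.run_orientation_training(seed=1)
print(net.weights.popcount())        # [180 180 180 180]
print(net.firing_thresholds)         # [100 100 100 100]

curve = experiments.measure_tuning(net, seed=2)
print(experiments.preferred_orientations(curve))   # e.g. [135.  45.  90.   0.]
```

Every neuron ends with exactly 180 active synapses (the deterministic weight
budget), every threshold has climbed to its 100-unit cap, and the four
tuning-curve peaks — measured in 10-degree steps with plasticity, adaptation
and inhibition disabled — cover all four trained orientations: each neuron
has become an orientation detector.

The hardware cost of one STDP update at a 90-event buffer:

```text
$ bitstdp hwcost --num-potentiation 90
{ "num_potentiation": 90, "ltp_cycles": 97, "ltd_cycles": 2083,
  "total_cycles": 2180, "saturation_eps": 45871.56 }
```

i.e. 2180 clock cycles per learning event, so at 100 MHz the shared STDP unit
saturates near 45.9 k learning events per second.

Other entry points: `bitstdp orientation train|tune`, `bitstdp pipeline run
--fe stdp|random` (the synthetic moving-symbol task with the STDP-trained
versus fixed-random feature layer), and `experiments.hyperparam_search` for
validation-based parameter selection.

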