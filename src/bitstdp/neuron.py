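"""Binary-synapse linear-leak integrate-and-fire neuron.

The neuron model is deliberately minimal, mirroring what fits in a few dozen
FPGA slices: a non-negative integer state (counter) that is incremented by one
whenever an input event arrives through an active (value-1) synapse, compared
against an integer threshold, and reset to zero when the threshold is crossed.
Two refinements support on-line learning:

* **Dual counters / dual thresholds.** A *firing* counter drives inference
  spikes and a *learning* counter drives STDP triggers.  In software mode the
  two are coupled (single threshold); hardware mode decouples them so firing
  activity stays high while plasticity slows down as the neuron specializes.
* **Homeostatic threshold growth.** Each output spike raises the firing
  threshold (by ``th_increment``, capped at ``x_th_max``); each STDP trigger
  raises the STDP threshold by one.  This hands firing opportunities to
  less-specialized neurons in the population.

Leak is the piece-wise-linear "bit-shift" approximation of an exponential
decay: a fixed decrement per tick whose magnitude is halved at configured
elapsed-time breakpoints.  Evaluation is lazy -- leak is only applied when an
event touches the neuron -- and the decrement schedule is data, not code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "LeakSchedule",
    "fit_leak_schedule",
    "NeuronConfig",
    "NeuronState",
    "apply_leak",
    "process_input_event",
    "inhibit",
    "LEAK_FIT_TOLERANCE",
]

#: Max absolute deviation (state units) accepted between the default fitted
#: schedule and exact exponential decay of an initial state of 100 units,
#: sampled on a 0.5 ms grid over 60 ms.  The chord of each halving interval
#: overshoots the convex exponential by at most ~4.3% of the running state.
LEAK_FIT_TOLERANCE = 5.0


@dataclass(frozen=True)
class LeakSchedule:
    """Piece-wise-linear decay: a per-tick decrement halved at breakpoints.

    Parameters
    ----------
    initial_decrement:
        State units subtracted per ``tick_us`` in the first segment (> 0).
    tick_us:
        Tick duration in microseconds.
    halving_points_us:
        Strictly increasing elapsed-time breakpoints; at the k-th breakpoint
        the decrement becomes ``initial_decrement / 2**k``.  After the last
        breakpoint the final decrement applies indefinitely, so any state
        eventually reaches zero.
    target_tau_us:
        Documentation-only: the exponential time constant the schedule was
        fitted to, if any.
    """

    initial_decrement: float
    tick_us: float
    halving_points_us: Tuple[float, ...] = ()
    target_tau_us: Optional[float] = None

    def __post_init__(self):
        if self.initial_decrement <= 0 or self.tick_us <= 0:
            raise ValueError("initial_decrement and tick_us must be positive")
        pts = tuple(float(p) for p in self.halving_points_us)
        if any(b <= a for a, b in zip(pts, pts[1:])) or (pts and pts[0] <= 0):
            raise ValueError("halving points must be strictly increasing and positive")
        object.__setattr__(self, "halving_points_us", pts)

    def decay_amount(self, elapsed_us: float) -> float:
        """Total state decrement accumulated over ``elapsed_us`` of silence."""
        if elapsed_us <= 0:
            return 0.0
        rate = self.initial_decrement / self.tick_us  # units per microsecond
        total = 0.0
        prev = 0.0
        for bp in self.halving_points_us:
            if elapsed_us <= bp:
                return total + rate * (elapsed_us - prev)
            total += rate * (bp - prev)
            prev = bp
            rate /= 2.0
        return total + rate * (elapsed_us - prev)

    def to_pairs(self) -> list:
        """Serialize as ``[(breakpoint_us, decrement_per_tick), ...]`` pairs."""
        pairs = [(0.0, self.initial_decrement)]
        for k, bp in enumerate(self.halving_points_us, start=1):
            pairs.append((bp, self.initial_decrement / 2.0**k))
        return pairs

    @classmethod
    def from_pairs(cls, pairs, tick_us: float, target_tau_us=None) -> "LeakSchedule":
        pairs = sorted(pairs)
        first = pairs[0][1]
        return cls(
            initial_decrement=first,
            tick_us=tick_us,
            halving_points_us=tuple(bp for bp, _ in pairs[1:]),
            target_tau_us=target_tau_us,
        )


def fit_leak_schedule(
    tau_us: float,
    initial_state: float = 100.0,
    n_halvings: int = 6,
    tick_us: float = 1.0,
) -> LeakSchedule:
    """Fit a halving schedule to exponential decay ``S0 * exp(-t/tau)``.

    The exponential halves every ``h = tau * ln 2``; the fitted schedule drains
    half the remaining state per interval of length ``h`` with a linear chord,
    halving the decrement at ``h, 2h, ..., n_halvings*h``.  The chord stays
    within ~4.3% of ``S0`` of the exact curve (see :data:`LEAK_FIT_TOLERANCE`).
    """
    if tau_us <= 0 or initial_state <= 0:
        raise ValueError("tau_us and initial_state must be positive")
    h = tau_us * math.log(2.0)
    rate0 = initial_state / (2.0 * h)  # units per microsecond in first segment
    return LeakSchedule(
        initial_decrement=rate0 * tick_us,
        tick_us=tick_us,
        halving_points_us=tuple(h * k for k in range(1, n_halvings + 1)),
        target_tau_us=tau_us,
    )


@dataclass(frozen=True)
class NeuronConfig:
    """Static neuron parameters.

    ``dual_threshold=False`` (software mode) makes the STDP trigger mirror the
    firing event; ``True`` (hardware-emulation mode) maintains the separate
    learning counter with its own threshold that grows by one per STDP event.
    """

    x_th_init: int = 10
    x_th_max: int = 100
    th_increment: int = 1
    dual_threshold: bool = False
    stdp_th_init: Optional[int] = None
    stdp_th_increment: int = 1

    def __post_init__(self):
        if not (0 < self.x_th_init <= self.x_th_max):
            raise ValueError("require 0 < x_th_init <= x_th_max")
        if self.th_increment < 0 or self.stdp_th_increment < 0:
            raise ValueError("threshold increments must be >= 0")

    @property
    def stdp_threshold_init(self) -> int:
        return self.x_th_init if self.stdp_th_init is None else self.stdp_th_init


@dataclass
class NeuronState:
    """Mutable per-neuron dynamic state (all counters clamped at zero)."""

    firing_counter: int = 0
    learning_counter: int = 0
    firing_threshold: int = 10
    stdp_threshold: int = 10
    last_update: int = 0
    leak_carry: float = 0.0  # sub-unit leak owed from previous gaps

    @classmethod
    def from_config(cls, config: NeuronConfig, t0: int = 0) -> "NeuronState":
        return cls(
            firing_threshold=config.x_th_init,
            stdp_threshold=config.stdp_threshold_init,
            last_update=t0,
        )


def apply_leak(state: NeuronState, now: int, schedule: Optional[LeakSchedule]) -> NeuronState:
    """Lazily apply the piece-wise-linear leak for the gap since last update.

    Both counters decrease by the integer part of the accumulated decrement
    (fractional remainder carried forward) and clamp at zero.  ``now`` must not
    precede the last update.
    """
    if now < state.last_update:
        raise ValueError(
            f"temporal ordering violated: now={now} < last_update={state.last_update}"
        )
    if schedule is not None and now > state.last_update:
        amount = schedule.decay_amount(now - state.last_update) + state.leak_carry
        dec = int(amount)
        state.leak_carry = amount - dec
        if dec:
            state.firing_counter = max(0, state.firing_counter - dec)
            state.learning_counter = max(0, state.learning_counter - dec)
            if state.firing_counter == 0 and state.learning_counter == 0:
                state.leak_carry = 0.0
    state.last_update = now
    return state


def process_input_event(
    state: NeuronState,
    weight: int,
    now: int,
    config: NeuronConfig,
    schedule: Optional[LeakSchedule] = None,
) -> Tuple[NeuronState, bool, bool]:
    """Integrate one input event through a 1-bit synapse.

    Leak is applied first.  An active synapse (weight 1) increments both
    counters.  A counter that reaches its threshold resets to zero; on firing
    the firing threshold grows by ``th_increment`` (capped at ``x_th_max``),
    on an STDP trigger the STDP threshold grows by ``stdp_th_increment``.
    With ``dual_threshold`` off the STDP trigger simply mirrors the fire.

    Returns ``(state, fired, stdp_triggered)``.
    """
    if weight not in (0, 1):
        raise ValueError(f"weight must be 0 or 1, got {weight}")
    apply_leak(state, now, schedule)
    if weight == 0:
        return state, False, False
    state.firing_counter += 1
    state.learning_counter += 1
    fired = state.firing_counter >= state.firing_threshold
    if fired:
        state.firing_counter = 0
        state.firing_threshold = min(
            state.firing_threshold + config.th_increment, config.x_th_max
        )
    if config.dual_threshold:
        stdp_triggered = state.learning_counter >= state.stdp_threshold
        if stdp_triggered:
            state.learning_counter = 0
            state.stdp_threshold += config.stdp_th_increment
    else:
        stdp_triggered = fired
        if fired:
            state.learning_counter = 0
    return state, fired, stdp_triggered


def inhibit(state: NeuronState) -> NeuronState:
    """Lateral-inhibition reset: zero both counters, thresholds untouched."""
    state.firing_counter = 0
    state.learning_counter = 0
    state.leak_carry = 0.0
    return state
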