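"""Event-list STDP engine and the stochastic 1-bit ("undiscriminating
depressing") learning rule.

Two layers of machinery live here:

1. A generic bounded event-list STDP engine (:class:`EventListStdpEngine`)
   with the usual kernel zoo -- classic / rectangular / narrow-potentiation /
   symmetric shapes, in either *time-based* form (kernel of the spike-time
   difference, microseconds) or *order-based* form (kernel of the rank
   difference in a bounded list; timestamps are irrelevant, only ordering
   matters, so learning self-adapts to the input dynamics).

2. The 1-bit stochastic rule used for feature extraction: only a bounded
   pre-synaptic address buffer is kept, and whenever a neuron produces an
   STDP trigger its recently-active synapses are *potentiated* to 1 with
   probability ``p_ltp``, while its remaining active synapses are *depressed*
   to 0 -- either deterministically (restoring the per-neuron active-synapse
   budget ``W_sum`` exactly) or stochastically with the normalized 10-bit
   depression probability

       ``P_LTD = floor(1024 * (actual_active - expected_active) / actual_active)``

   compared against a pseudo-random draw (:func:`ltd_probability_1024`).
   Winner-take-all lateral inhibition and optional pre-list flushing complete
   the rule.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "StdpKernel",
    "kernel_eval",
    "EventListStdpEngine",
    "WeightUpdate",
    "PreBuffer",
    "BinaryWeights",
    "StdpConfig",
    "stochastic_bit_update",
    "ltd_probability_1024",
    "apply_binary_stdp",
    "wta_resolve",
]

logger = logging.getLogger(__name__)

KernelShape = Literal[
    "classic",
    "rectangular",
    "narrow-potentiation",
    "symmetric-hebbian",
    "symmetric-narrow",
]


@dataclass(frozen=True)
class StdpKernel:
    """An STDP learning function xi(delta).

    ``delta`` is ``t_post - t_pre`` in microseconds (time mode) or the rank
    difference in the event lists (order mode); positive delta means the
    pre-synaptic spike preceded the post-synaptic one.  In stochastic 1-bit
    mode ``a_plus``/``a_minus`` are probabilities and must lie in [0, 1].

    Windows: updates vanish outside ``(-t_min, +t_max]`` (use ``inf`` for the
    unbounded "undiscriminating" variants).  ``t_p`` is the narrow potentiation
    window; ``tau_plus``/``tau_minus`` set the e-folding of the classic shape.
    """

    mode: Literal["time", "order"] = "order"
    shape: KernelShape = "narrow-potentiation"
    a_plus: float = 1.0
    a_minus: float = 1.0
    t_p: float = 1.0
    t_max: float = float("inf")
    t_min: float = float("inf")
    tau_plus: Optional[float] = None
    tau_minus: Optional[float] = None
    stochastic: bool = False

    def __post_init__(self):
        if self.t_max < 0 or self.t_min < 0 or self.t_p < 0:
            raise ValueError("kernel windows must be non-negative")
        if self.stochastic and not (abs(self.a_plus) <= 1 and abs(self.a_minus) <= 1):
            raise ValueError("stochastic-mode magnitudes must lie in [-1, 1]")


def kernel_eval(kernel: StdpKernel, delta: float) -> float:
    """Evaluate xi(delta); zero outside the kernel windows.

    Sign convention: positive return values request potentiation, negative
    ones depression.
    """
    if delta > kernel.t_max or delta < -kernel.t_min:
        return 0.0
    shape = kernel.shape
    if shape == "classic":
        tp = kernel.tau_plus if kernel.tau_plus is not None else kernel.t_max / 4.0
        tm = kernel.tau_minus if kernel.tau_minus is not None else kernel.t_min / 4.0
        if delta > 0:
            return kernel.a_plus * float(np.exp(-delta / tp))
        if delta < 0:
            return -kernel.a_minus * float(np.exp(delta / tm))
        return 0.0
    if shape == "rectangular":
        if delta > 0:
            return kernel.a_plus
        if delta < 0:
            return -kernel.a_minus
        return 0.0
    if shape == "narrow-potentiation":
        if 0 < delta <= kernel.t_p:
            return kernel.a_plus
        if delta != 0:
            return -kernel.a_minus
        return 0.0
    if shape == "symmetric-hebbian":
        if abs(delta) <= kernel.t_p:
            return kernel.a_plus
        return 0.0
    if shape == "symmetric-narrow":
        if abs(delta) <= kernel.t_p:
            return kernel.a_plus
        return -kernel.a_minus
    raise ValueError(f"unknown kernel shape {shape!r}")


@dataclass(frozen=True)
class WeightUpdate:
    """A signed weight-update command emitted by the engine."""

    pre: int
    post: int
    value: float


class EventListStdpEngine:
    """Population-level bounded pre/post event lists driving kernel updates.

    In time mode entries expire once older than ``t_max`` (pre list) or
    ``t_min`` (post list); in order mode the lists are bounded FIFOs of
    ``n_max`` / ``n_min`` entries.  Each incoming event is stored in its own
    list and matched against the opposite list, emitting one
    :class:`WeightUpdate` per match (or only the most recent match when
    ``most_recent_only`` is set).
    """

    def __init__(
        self,
        kernel: StdpKernel,
        n_max: Optional[int] = None,
        n_min: Optional[int] = None,
        most_recent_only: bool = False,
    ):
        self.kernel = kernel
        self.n_max = n_max
        self.n_min = n_min
        self.most_recent_only = most_recent_only
        self.pre_list: deque = deque(maxlen=n_max)
        self.post_list: deque = deque(maxlen=n_min)

    def _expire(self, now: float) -> None:
        if self.kernel.mode != "time":
            return
        while self.pre_list and now - self.pre_list[0][0] > self.kernel.t_max:
            self.pre_list.popleft()
        while self.post_list and now - self.post_list[0][0] > self.kernel.t_min:
            self.post_list.popleft()

    def on_pre_event(self, pre_address: int, now: float) -> List[WeightUpdate]:
        self._expire(now)
        updates = []
        matches = [self.post_list[-1]] if (self.most_recent_only and self.post_list) \
            else list(self.post_list)
        for rank, (t_post, j) in enumerate(reversed(matches), start=1):
            delta = (t_post - now) if self.kernel.mode == "time" else -rank
            v = kernel_eval(self.kernel, delta)
            if v != 0.0:
                updates.append(WeightUpdate(pre=pre_address, post=j, value=v))
        self.pre_list.append((now, pre_address))
        return updates

    def on_post_event(self, post_address: int, now: float) -> List[WeightUpdate]:
        self._expire(now)
        updates = []
        matches = [self.pre_list[-1]] if (self.most_recent_only and self.pre_list) \
            else list(self.pre_list)
        for rank, (t_pre, i) in enumerate(reversed(matches), start=1):
            delta = (now - t_pre) if self.kernel.mode == "time" else rank
            v = kernel_eval(self.kernel, delta)
            if v != 0.0:
                updates.append(WeightUpdate(pre=i, post=post_address, value=v))
        self.post_list.append((now, post_address))
        return updates


class PreBuffer:
    """Bounded circular FIFO of recent pre-synaptic addresses (order mode).

    Duplicates are allowed, as in the hardware circular buffer; potentiation
    is idempotent so duplicates cost attempts, not correctness.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._entries: deque = deque(maxlen=capacity)

    def append(self, address: int) -> None:
        self._entries.append(address)

    def recent(self, n: Optional[int] = None) -> List[int]:
        """The last ``n`` addresses, most recent last (all if n is None)."""
        if n is None or n >= len(self._entries):
            return list(self._entries)
        return list(self._entries)[-n:]

    def flush(self) -> None:
        self._entries.clear()

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)


class BinaryWeights:
    """A pre x post bit matrix with a per-neuron active-synapse budget W_sum."""

    def __init__(self, bits: np.ndarray, w_sum_target: int):
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.ndim != 2:
            raise ValueError("bits must be a 2-D (pre x post) matrix")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("weights must be 0 or 1")
        if not 0 <= w_sum_target <= bits.shape[0]:
            raise ValueError("w_sum_target must lie in [0, n_pre]")
        self.bits = bits
        self.w_sum_target = int(w_sum_target)

    @property
    def n_pre(self) -> int:
        return self.bits.shape[0]

    @property
    def n_post(self) -> int:
        return self.bits.shape[1]

    def popcount(self, neuron_index: Optional[int] = None):
        """Number of active synapses, per neuron or for one neuron."""
        if neuron_index is None:
            return self.bits.sum(axis=0).astype(int)
        return int(self.bits[:, neuron_index].sum())

    @classmethod
    def random(
        cls,
        n_pre: int,
        n_post: int,
        w_sum: int,
        rng: np.random.Generator,
        exact: bool = True,
    ) -> "BinaryWeights":
        """Random initial bits; ``exact=True`` places exactly ``w_sum`` ones
        per neuron (the fixed-W_sum random baseline), otherwise Bernoulli
        bits with mean ``w_sum / n_pre``."""
        bits = np.zeros((n_pre, n_post), dtype=np.uint8)
        if exact:
            for j in range(n_post):
                idx = rng.choice(n_pre, size=w_sum, replace=False)
                bits[idx, j] = 1
        else:
            bits[:] = (rng.random((n_pre, n_post)) < w_sum / n_pre).astype(np.uint8)
        return cls(bits, w_sum)

    def save_text(self, path, seed: Optional[int] = None) -> None:
        """Plain-text export: header comments plus one 0/1 row per pre line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# binary weights {self.n_pre}x{self.n_post} "
                     f"w_sum={self.w_sum_target} seed={seed}\n")
            for row in self.bits:
                fh.write("".join(map(str, row)) + "\n")

    @classmethod
    def load_text(cls, path) -> "BinaryWeights":
        w_sum = 0
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line.split():
                        if tok.startswith("w_sum="):
                            w_sum = int(tok.split("=", 1)[1])
                    continue
                if line:
                    rows.append([int(ch) for ch in line])
        return cls(np.asarray(rows, dtype=np.uint8), w_sum)


@dataclass(frozen=True)
class StdpConfig:
    """Parameters of the stochastic 1-bit rule.

    ``number_of_potentiation`` bounds how many of the most recent buffered
    addresses take part in LTP (defaults to the full buffer; must not exceed
    ``buffer_size``).  ``protect_buffered`` shields the just-potentiated
    synapses from same-update LTD (software rule); hardware emulation rescans
    the full weight row and drops the protection.
    """

    p_ltp: float = 0.8
    buffer_size: int = 250
    number_of_potentiation: Optional[int] = None
    normalization: Literal["deterministic", "stochastic"] = "deterministic"
    flush: bool = True
    protect_buffered: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.p_ltp <= 1.0:
            raise ValueError("p_ltp must lie in [0, 1]")
        if self.buffer_size < 1:
            raise ValueError("buffer_size must be >= 1")
        n_pot = self.number_of_potentiation
        if n_pot is not None and not (0 <= n_pot <= self.buffer_size):
            raise ValueError("number_of_potentiation must lie in [0, buffer_size]")

    @property
    def n_potentiation(self) -> int:
        return self.buffer_size if self.number_of_potentiation is None \
            else self.number_of_potentiation


def stochastic_bit_update(w: int, p: float, u: float) -> int:
    """One stochastic 1-bit weight update.

    A positive probability ``p`` sets the bit to 1 when the uniform draw
    ``u <= p``; a negative one clears it when ``u <= |p|``; otherwise the bit
    is unchanged.  Idempotent on already-set targets.
    """
    if not -1.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [-1, 1], got {p}")
    if w not in (0, 1):
        raise ValueError("w must be 0 or 1")
    if p > 0 and u <= p:
        return 1
    if p < 0 and u <= -p:
        return 0
    return w


def ltd_probability_1024(actual_active: int, expected_active: int) -> int:
    """Normalized 10-bit LTD probability ``floor(1024 * dW / actual)``.

    ``actual_active`` is the neuron's current number of active weights and
    ``expected_active`` its budget W_sum.  When no depression is needed
    (actual <= expected, or no active weights) the probability is 0; the
    result is clamped to the 10-bit range compared against the hardware LFSR.
    """
    if actual_active < 0 or expected_active < 0:
        raise ValueError("counts must be non-negative")
    if actual_active <= expected_active or actual_active == 0:
        return 0
    return min(1024, (1024 * (actual_active - expected_active)) // actual_active)


def apply_binary_stdp(
    weights: BinaryWeights,
    neuron_index: int,
    buffer: PreBuffer,
    config: StdpConfig,
    rng: np.random.Generator,
) -> BinaryWeights:
    """One full stochastic-STDP update of a single neuron's weight column.

    Phase 1 (LTP): each of the up-to-``number_of_potentiation`` most recent
    buffered pre-addresses is potentiated to 1 with probability ``p_ltp``.
    Phase 2 (LTD): deterministic normalization flips exactly
    ``popcount - W_sum`` randomly chosen active bits back to 0 (preferring
    non-buffered synapses when ``protect_buffered``); stochastic normalization
    depresses every eligible active bit with probability
    ``ltd_probability_1024 / 1024``.  Phase 3: optional pre-list flush.

    The weights object is modified in place and returned.
    """
    col = weights.bits[:, neuron_index]
    recent = buffer.recent(config.n_potentiation)
    buffered = np.unique(np.asarray(recent, dtype=np.int64)) if recent else \
        np.empty(0, dtype=np.int64)

    # Phase 1: LTP over the recent pre-addresses (duplicates draw separately).
    if recent:
        draws = rng.random(len(recent))
        for addr, u in zip(recent, draws):
            if u <= config.p_ltp:
                col[addr] = 1

    # Phase 2: LTD / normalization.
    popcount = int(col.sum())
    target = weights.w_sum_target
    if config.normalization == "deterministic":
        excess = popcount - target
        if excess > 0:
            active = np.flatnonzero(col == 1)
            if config.protect_buffered:
                eligible = np.setdiff1d(active, buffered, assume_unique=False)
            else:
                eligible = active
            if eligible.size < excess:
                logger.warning(
                    "neuron %d: only %d depressible non-buffered synapses for "
                    "excess %d; falling back to buffered ones",
                    neuron_index, eligible.size, excess,
                )
                extra = np.setdiff1d(active, eligible)
                victims = np.concatenate([
                    eligible,
                    rng.choice(extra, size=excess - eligible.size, replace=False),
                ])
            else:
                victims = rng.choice(eligible, size=excess, replace=False)
            col[victims] = 0
    elif config.normalization == "stochastic":
        p1024 = ltd_probability_1024(popcount, target)
        if p1024 > 0:
            active = np.flatnonzero(col == 1)
            if config.protect_buffered and buffered.size:
                active = np.setdiff1d(active, buffered)
            if active.size:
                u = rng.random(active.size)
                col[active[u <= p1024 / 1024.0]] = 0
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")

    # Phase 3: pre-list flushing.
    if config.flush:
        buffer.flush()
    return weights


def wta_resolve(
    candidates: Sequence[int],
    policy: Literal["lowest", "random"] = "lowest",
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Winner-take-all tie-break among simultaneously firing neurons.

    Exactly one winner is returned; the caller is responsible for inhibiting
    the rest of the population.
    """
    if len(candidates) == 0:
        raise ValueError("wta_resolve requires a non-empty candidate list")
    if len(candidates) == 1:
        return int(candidates[0])
    if policy == "lowest":
        return int(min(candidates))
    if policy == "random":
        if rng is None:
            raise ValueError("random WTA policy requires an rng")
        return int(rng.choice(np.asarray(candidates)))
    raise ValueError(f"unknown WTA policy {policy!r}")
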