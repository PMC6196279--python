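"""Behavioral model of the FPGA neuron block's STDP unit.

Closed-form clock-cycle accounting of the shared STDP unit (circular pre
buffer, LTP processor, LTD processor with a slow serial divider), the 16-bit
LFSR that supplies 10-bit pseudo-random numbers for the stochastic weight
updates, the saturation throughput of the unit during learning, and the
resource-scaling model trading bit resolution against hidden-layer size.

The canonical configuration is a 1024-synapse neuron: reading the circular
buffer or the synaptic memory each costs 3 pipeline cycles, one extra cycle
pads the write-data pipeline (so LTP costs ``7 + number_of_potentiation``
cycles), and the serial divider that computes the normalized LTD probability
costs 25 cycles (LTD total ``1024+3+25+1024+7 = 2083``).  While an STDP
update is running, further STDP trigger events are ignored (lockout), so the
unit saturates at ``clock / total_cycles`` STDP events per second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "CycleCostModel",
    "ltp_cycles",
    "ltd_cycles",
    "stdp_total_cycles",
    "saturation_rate",
    "Lfsr16",
    "lfsr_next",
    "LfsrRandom",
    "resource_model",
]


@dataclass(frozen=True)
class CycleCostModel:
    """Steady-state clock-cycle parameters of the STDP unit."""

    synapse_count: int = 1024
    buffer_read_latency: int = 3
    weight_read_latency: int = 3
    pipeline_pad: int = 1
    divider_latency: int = 25
    clock_hz: float = 100e6

    def __post_init__(self):
        for name in ("synapse_count", "buffer_read_latency", "weight_read_latency",
                     "pipeline_pad", "divider_latency"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def ltp_overhead(self) -> int:
        """Pipeline overhead of the LTP pass (7 cycles at defaults)."""
        return self.buffer_read_latency + self.weight_read_latency + self.pipeline_pad


def ltp_cycles(num_potentiation: int, model: Optional[CycleCostModel] = None) -> int:
    """LTP pass: pipeline overhead plus one cycle per potentiation attempt."""
    model = model or CycleCostModel()
    if not 0 <= num_potentiation <= model.synapse_count:
        raise ValueError(
            f"num_potentiation must lie in [0, {model.synapse_count}]"
        )
    return model.ltp_overhead + num_potentiation


def ltd_cycles(model: Optional[CycleCostModel] = None) -> int:
    """LTD pass: read all weights, divide, then depress all weights.

    ``(S + weight_read) + divider + (S + ltp_overhead)`` cycles; 2083 at the
    1024-synapse defaults.
    """
    model = model or CycleCostModel()
    s = model.synapse_count
    return (s + model.weight_read_latency) + model.divider_latency + (s + model.ltp_overhead)


def stdp_total_cycles(num_potentiation: int, model: Optional[CycleCostModel] = None) -> int:
    """Full STDP update cost (LTP then LTD) in clock cycles."""
    model = model or CycleCostModel()
    return ltp_cycles(num_potentiation, model) + ltd_cycles(model)


def saturation_rate(model: Optional[CycleCostModel] = None, num_potentiation: int = 90) -> float:
    """STDP-trigger rate (events/s) at which the unit saturates.

    Trigger events arriving while an update is in flight are ignored, so the
    sustainable rate is one update per ``stdp_total_cycles`` clock periods.
    """
    model = model or CycleCostModel()
    return model.clock_hz / stdp_total_cycles(num_potentiation, model)


# ---------------------------------------------------------------------------
# 16-bit LFSR pseudo-random number generator
# ---------------------------------------------------------------------------

#: Maximal-length Fibonacci taps for x^16 + x^15 + x^13 + x^4 + 1.
DEFAULT_TAPS: Tuple[int, ...] = (16, 15, 13, 4)


@dataclass(frozen=True)
class Lfsr16:
    """16-bit Fibonacci linear-feedback shift register state.

    With maximal taps the orbit visits every nonzero 16-bit state exactly once
    (period 65535); the all-zero state is absorbing and therefore rejected.
    """

    state: int = 0xACE1
    taps: Tuple[int, ...] = DEFAULT_TAPS

    def __post_init__(self):
        if not 0 < self.state <= 0xFFFF:
            raise ValueError("LFSR state must be a nonzero 16-bit integer")


def lfsr_next(lfsr: Lfsr16) -> Tuple[Lfsr16, int]:
    """Advance the LFSR one step; return the new state and its low 10 bits.

    The 10-bit sample is the value compared against 10-bit probabilities
    (accept when ``sample < probability_1024``).
    """
    s = lfsr.state
    bit = 0
    for tap in lfsr.taps:
        bit ^= s >> (tap - 1)
    bit &= 1
    s = ((s << 1) | bit) & 0xFFFF
    nxt = Lfsr16(state=s, taps=lfsr.taps)
    return nxt, s & 0x3FF


class LfsrRandom:
    """Adapter exposing the LFSR through a float ``random()`` interface.

    Draws are quantized to the 10-bit grid ``sample / 1024`` in [0, 1), so a
    comparison ``u <= p`` with ``p = k/1024`` accepts exactly when
    ``sample < k`` -- the hardware comparison.  Suitable wherever the
    stochastic update path only needs uniform draws.
    """

    def __init__(self, seed: int = 0xACE1, taps: Tuple[int, ...] = DEFAULT_TAPS):
        seed = int(seed) & 0xFFFF
        if seed == 0:
            seed = 0xACE1
        self._lfsr = Lfsr16(state=seed, taps=taps)

    def random(self, size=None):
        if size is None:
            self._lfsr, sample = lfsr_next(self._lfsr)
            # map to [0,1) mid-grid so that u <= k/1024 iff sample < k
            return (sample + 0.5) / 1024.0
        out = np.empty(int(size), dtype=np.float64)
        for i in range(int(size)):
            self._lfsr, sample = lfsr_next(self._lfsr)
            out[i] = (sample + 0.5) / 1024.0
        return out


# ---------------------------------------------------------------------------
# Resource scaling: bit resolution vs hidden-layer size
# ---------------------------------------------------------------------------

def resource_model(
    n_inputs: int,
    n_hidden: int,
    n_bits: int,
    alphas: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Dict[str, float]:
    """Hardware resources of a fully connected hidden layer.

    ``R_syn = a_syn * N_i * N_h * n_b`` (synaptic memory),
    ``R_h = a_h * N_h * n_b`` (neuron logic), ``R_ov = a_ov * n_b`` (shared
    overhead).  For fixed inputs, keeping ``N_h * n_b`` constant keeps
    ``R_syn + R_h`` constant -- e.g. 256 one-bit neurons cost the same as 32
    eight-bit ones.
    """
    if min(n_inputs, n_hidden, n_bits) < 1:
        raise ValueError("n_inputs, n_hidden and n_bits must be positive")
    a_syn, a_h, a_ov = alphas
    r_syn = a_syn * n_inputs * n_hidden * n_bits
    r_h = a_h * n_hidden * n_bits
    r_ov = a_ov * n_bits
    return {
        "R_syn": r_syn,
        "R_h": r_h,
        "R_ov": r_ov,
        "total_core": r_syn + r_h,
        "total": r_syn + r_h + r_ov,
    }
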