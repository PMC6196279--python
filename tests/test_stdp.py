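import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bitstdp.stdp import (
    BinaryWeights,
    EventListStdpEngine,
    PreBuffer,
    StdpConfig,
    StdpKernel,
    apply_binary_stdp,
    kernel_eval,
    ltd_probability_1024,
    stochastic_bit_update,
    wta_resolve,
)


class TestKernels:
    def test_narrow_potentiation_windows(self):
        k = StdpKernel(shape="narrow-potentiation", a_plus=0.8, a_minus=0.3, t_p=5)
        assert kernel_eval(k, 3) == 0.8       # within the narrow window
        assert kernel_eval(k, 5) == 0.8
        assert kernel_eval(k, 6) == -0.3      # beyond it: depression
        assert kernel_eval(k, -2) == -0.3     # undiscriminating on the negative side

    def test_symmetric_hebbian_is_even(self):
        k = StdpKernel(shape="symmetric-hebbian", a_plus=0.5, t_p=4, t_max=20, t_min=20)
        for d in range(-20, 21):
            assert kernel_eval(k, d) == kernel_eval(k, -d)

    def test_zero_outside_windows(self):
        k = StdpKernel(shape="rectangular", a_plus=1, a_minus=1, t_max=10, t_min=5)
        assert kernel_eval(k, 11) == 0.0
        assert kernel_eval(k, -6) == 0.0

    def test_rectangular_area_ratio(self):
        """Numeric integration oracle: the ratio of the areas under the
        positive and negative branches equals (A+ t_max)/(A- t_min)."""
        k = StdpKernel(mode="time", shape="rectangular", a_plus=0.7, a_minus=0.2,
                       t_max=30.0, t_min=12.0)
        grid = np.linspace(-12.0, 30.0, 100_001)
        vals = np.array([kernel_eval(k, d) for d in grid])
        dx = grid[1] - grid[0]
        pos = vals[vals > 0].sum() * dx
        neg = -vals[vals < 0].sum() * dx
        assert pos / neg == pytest.approx((0.7 * 30.0) / (0.2 * 12.0), rel=1e-3)

    def test_stochastic_magnitude_validation(self):
        with pytest.raises(ValueError):
            StdpKernel(a_plus=1.5, stochastic=True)


class TestEventListEngine:
    def test_empty_opposite_list_no_updates(self):
        eng = EventListStdpEngine(StdpKernel(mode="order"), n_max=8, n_min=8)
        assert eng.on_pre_event(3, 100) == []
        assert eng.on_post_event(0, 50) != []  # pre list now holds one entry

    def test_order_mode_invariant_to_time_scaling(self):
        """Multiplying all timestamps by 10 leaves the update sequence of the
        order-based rule unchanged."""
        kernel = StdpKernel(mode="order", shape="narrow-potentiation", t_p=2,
                            a_plus=0.5, a_minus=0.5)

        def run(scale):
            eng = EventListStdpEngine(kernel, n_max=4, n_min=4)
            out = []
            for kind, addr, t in [("pre", 0, 1), ("pre", 1, 2), ("post", 0, 3),
                                  ("pre", 2, 5), ("post", 1, 8)]:
                fn = eng.on_pre_event if kind == "pre" else eng.on_post_event
                out.extend(fn(addr, t * scale))
            return [(u.pre, u.post, u.value) for u in out]

        assert run(1) == run(10)

    def test_time_mode_expiry(self):
        kernel = StdpKernel(mode="time", shape="rectangular", a_plus=1, a_minus=1,
                            t_max=100, t_min=100)
        eng = EventListStdpEngine(kernel)
        eng.on_pre_event(0, 0)
        assert eng.on_post_event(0, 101) == []  # pre entry expired
        eng2 = EventListStdpEngine(kernel)
        eng2.on_pre_event(0, 0)
        assert len(eng2.on_post_event(0, 100)) == 1

    def test_bounded_order_lists_evict_oldest(self):
        eng = EventListStdpEngine(StdpKernel(mode="order"), n_max=2, n_min=2)
        for i in range(5):
            eng.on_pre_event(i, i)
        assert [a for _t, a in eng.pre_list] == [3, 4]


class TestStochasticBitUpdate:
    @pytest.mark.parametrize("w,p,u,expected", [
        (0, 0.8, 0.5, 1),    # draw below positive probability: set
        (1, -0.25, 0.5, 1),  # draw above |p|: unchanged
        (1, 0.8, 0.5, 1),    # idempotent on already-set target
        (1, -0.25, 0.1, 0),  # draw below |p|: clear
        (0, -0.9, 0.1, 0),   # idempotent on already-clear target
        (0, 0.0, 0.0, 0),    # zero probability never changes
    ])
    def test_rule_cases(self, w, p, u, expected):
        assert stochastic_bit_update(w, p, u) == expected

    def test_probability_out_of_range(self):
        with pytest.raises(ValueError):
            stochastic_bit_update(0, 1.5, 0.5)

    def test_set_fraction_matches_binomial(self, rng):
        """Binomial oracle: over 1e5 seeded draws at p=+0.3 the set fraction
        lies within 3 sigma of 0.3."""
        n, p = 100_000, 0.3
        u = rng.random(n)
        frac = np.mean([stochastic_bit_update(0, p, ui) for ui in u])
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestLtdProbability:
    @pytest.mark.parametrize("actual,expected,result", [
        (180, 180, 0),        # no excess: no depression
        (200, 180, 102),      # floor(1024 * 20 / 200)
        (7, 0, 1024),         # expected 0: certain depression
        (150, 180, 0),        # below budget: signals no depression
        (0, 0, 0),
    ])
    def test_values(self, actual, expected, result):
        assert ltd_probability_1024(actual, expected) == result

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ltd_probability_1024(-1, 0)


# ---------------------------------------------------------------------------
# apply_binary_stdp against an independent brute-force reference
# ---------------------------------------------------------------------------

class ScriptedRng:
    """Deterministic stand-in for a Generator: uniform draws come from a
    queue; choice() picks the lowest eligible addresses."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, size=None):
        if size is None:
            return self.draws.pop(0)
        out = np.array([self.draws.pop(0) for _ in range(int(size))])
        return out

    def choice(self, arr, size, replace=False):
        return np.sort(np.asarray(arr))[: int(size)]


def reference_binary_stdp(bits, col_j, recent, w_sum, p_ltp, normalization, draws,
                          protect=True):
    """Plain-loop reference of the stochastic 1-bit update rule.

    Draw protocol: one uniform per buffered entry (oldest first as stored in
    the buffer slice), then in stochastic mode one uniform per eligible
    active address in ascending order.  Deterministic victims are the lowest
    eligible addresses.  Operates on a plain list of ints; independent of the
    implementation under test.
    """
    col = list(bits)
    queue = list(draws)
    for addr in recent:
        u = queue.pop(0)
        if u <= p_ltp:
            col[addr] = 1
    active = [i for i, b in enumerate(col) if b == 1]
    excess = sum(col) - w_sum
    buffered = set(recent)
    if normalization == "deterministic":
        if excess > 0:
            eligible = [i for i in active if not (protect and i in buffered)]
            if len(eligible) < excess:
                spill = sorted(set(active) - set(eligible))[: excess - len(eligible)]
                victims = eligible + spill
            else:
                victims = sorted(eligible)[:excess]
            for i in victims:
                col[i] = 0
    else:
        p1024 = 0
        if sum(col) > w_sum and sum(col) > 0:
            p1024 = min(1024, (1024 * (sum(col) - w_sum)) // sum(col))
        eligible = [i for i in active if not (protect and i in buffered)]
        for i in eligible:
            u = queue.pop(0)
            if p1024 > 0 and u <= p1024 / 1024.0:
                col[i] = 0
    return col


class TestApplyBinaryStdp:
    def test_fixed_point_when_buffer_already_set(self, rng):
        bits = np.zeros((8, 1), dtype=np.uint8)
        bits[[0, 1, 2], 0] = 1
        w = BinaryWeights(bits.copy(), w_sum_target=3)
        buf = PreBuffer(4)
        for a in (0, 1, 2):
            buf.append(a)
        cfg = StdpConfig(p_ltp=1.0, buffer_size=4, normalization="deterministic")
        apply_binary_stdp(w, 0, buf, cfg, rng)
        assert np.array_equal(w.bits, bits)

    def test_certain_ltp_counting_argument(self, rng):
        """With p_ltp=1 and deterministic normalization, z zero-bits in the
        buffer force exactly z depressions elsewhere and the popcount returns
        to W_sum (16-synapse toy, checked for several starts)."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            w = BinaryWeights.random(16, 1, w_sum=6, rng=r)
            buffered = r.choice(16, size=4, replace=False)
            z = int((w.bits[buffered, 0] == 0).sum())
            outside_before = set(np.flatnonzero(w.bits[:, 0])) - set(buffered.tolist())
            buf = PreBuffer(8)
            for a in buffered:
                buf.append(int(a))
            cfg = StdpConfig(p_ltp=1.0, buffer_size=8, normalization="deterministic")
            apply_binary_stdp(w, 0, buf, cfg, r)
            assert w.popcount(0) == 6
            outside_after = set(np.flatnonzero(w.bits[:, 0])) - set(buffered.tolist())
            assert len(outside_before) - len(outside_after) == z

    def test_stochastic_mean_depressions_equals_excess(self):
        """Expectation of the 10-bit rule: depressing each of `actual` active
        bits with probability floor(1024 dW/actual)/1024 removes ~dW bits on
        average (within 3 sigma plus the 10-bit quantization bound)."""
        trials = 2000
        actual, target = 100, 50
        rng = np.random.default_rng(99)
        cfg = StdpConfig(p_ltp=0.5, buffer_size=4, normalization="stochastic",
                         protect_buffered=False)
        dW = actual - target
        p = ((1024 * dW) // actual) / 1024.0
        depressions = np.empty(trials)
        for t in range(trials):
            bits = np.zeros((128, 1), dtype=np.uint8)
            bits[:actual] = 1
            w = BinaryWeights(bits, w_sum_target=target)
            apply_binary_stdp(w, 0, PreBuffer(4), cfg, rng)
            depressions[t] = actual - w.popcount(0)
        sigma = np.sqrt(actual * p * (1 - p) / trials)
        assert abs(depressions.mean() - dW) <= 3 * sigma + actual / 1024.0

    def test_flush_empties_buffer(self, rng):
        w = BinaryWeights.random(8, 1, 3, rng)
        buf = PreBuffer(4)
        buf.append(0)
        apply_binary_stdp(w, 0, buf, StdpConfig(buffer_size=4, flush=True), rng)
        assert len(buf) == 0
        buf.append(1)
        apply_binary_stdp(w, 0, buf, StdpConfig(buffer_size=4, flush=False), rng)
        assert len(buf) == 1

    def test_fallback_when_all_ones_buffered(self, rng, caplog):
        # every active synapse is protected: the update must fall back to
        # depressing buffered bits to restore the budget
        bits = np.zeros((6, 1), dtype=np.uint8)
        bits[:4, 0] = 1
        w = BinaryWeights(bits, w_sum_target=2)
        buf = PreBuffer(6)
        for a in range(4):
            buf.append(a)
        cfg = StdpConfig(p_ltp=0.0, buffer_size=6, normalization="deterministic")
        with caplog.at_level("WARNING"):
            apply_binary_stdp(w, 0, buf, cfg, rng)
        assert w.popcount(0) == 2
        assert any("falling back" in r.message for r in caplog.records)

    @pytest.mark.parametrize("normalization", ["deterministic", "stochastic"])
    def test_matches_brute_force_reference_4x2(self, normalization):
        """Exhaustive oracle: on a 4-pre x 2-post toy, enumerate scripted RNG
        draw combinations and compare the final bit state with the loop
        reference, state for state."""
        grid = (0.1, 0.6, 0.95)
        start_bits = [(1, 0, 1, 0), (1, 1, 0, 0), (0, 1, 1, 1)]
        for bits0, recent, j in itertools.product(
            start_bits, [(0,), (2, 3), (1, 1, 2)], (0, 1)
        ):
            n_draws = len(recent) + 4  # enough for LTP plus stochastic LTD
            for draws in itertools.product(grid, repeat=min(n_draws, 5)):
                draws = list(draws) + [0.5] * (n_draws - len(draws))
                bits = np.zeros((4, 2), dtype=np.uint8)
                bits[:, j] = bits0
                w = BinaryWeights(bits, w_sum_target=2)
                buf = PreBuffer(4)
                for a in recent:
                    buf.append(a)
                cfg = StdpConfig(p_ltp=0.6, buffer_size=4,
                                 normalization=normalization, flush=False)
                apply_binary_stdp(w, j, buf, cfg, ScriptedRng(list(draws)))
                expected = reference_binary_stdp(
                    list(bits0), j, list(recent), 2, 0.6, normalization, list(draws)
                )
                assert w.bits[:, j].tolist() == expected, (
                    bits0, recent, j, draws, normalization
                )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_updates=st.integers(1, 8))
def test_bit_domain_invariants_under_random_updates(seed, n_updates):
    """Randomized operation sequences keep weights in {0,1} and, with
    deterministic normalization, every neuron's popcount at W_sum."""
    rng = np.random.default_rng(seed)
    w = BinaryWeights.random(32, 3, w_sum=10, rng=rng)
    buf = PreBuffer(8)
    cfg = StdpConfig(p_ltp=0.7, buffer_size=8, normalization="deterministic")
    for _ in range(n_updates):
        for _ in range(int(rng.integers(1, 8))):
            buf.append(int(rng.integers(0, 32)))
        j = int(rng.integers(0, 3))
        apply_binary_stdp(w, j, buf, cfg, rng)
        assert np.isin(w.bits, (0, 1)).all()
        assert w.popcount(j) == 10
        assert len(buf) == 0  # flushed


def test_stochastic_popcount_drifts_back_to_budget():
    """With stochastic normalization the popcount above W_sum is pushed back
    down on average (supermartingale behavior over repeated updates)."""
    rng = np.random.default_rng(5)
    excursions = []
    for _ in range(200):
        bits = np.zeros((64, 1), dtype=np.uint8)
        bits[:40, 0] = 1  # 20 above the budget
        w = BinaryWeights(bits, w_sum_target=20)
        cfg = StdpConfig(p_ltp=0.0, buffer_size=4, normalization="stochastic",
                         protect_buffered=False)
        apply_binary_stdp(w, 0, PreBuffer(4), cfg, rng)
        excursions.append(w.popcount(0))
    assert np.mean(excursions) < 40
    assert np.mean(excursions) == pytest.approx(20, abs=3)


class TestWta:
    def test_single_candidate(self):
        assert wta_resolve([7]) == 7

    def test_lowest_index_policy(self):
        assert wta_resolve([5, 2, 9]) == 2

    def test_seeded_random_reproducible(self):
        winners = [wta_resolve([3, 1, 4], "random", np.random.default_rng(11))
                   for _ in range(3)]
        assert winners[0] == winners[1] == winners[2]
        assert winners[0] in (3, 1, 4)

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            wta_resolve([])


class TestBuffersAndWeights:
    def test_prebuffer_capacity_and_recent_order(self):
        buf = PreBuffer(3)
        for a in (1, 2, 3, 4):
            buf.append(a)
        assert len(buf) == 3
        assert buf.recent() == [2, 3, 4]
        assert buf.recent(2) == [3, 4]
        buf.flush()
        assert len(buf) == 0

    def test_weights_text_round_trip(self, tmp_path, rng):
        w = BinaryWeights.random(16, 4, 5, rng)
        path = tmp_path / "w.txt"
        w.save_text(path, seed=42)
        back = BinaryWeights.load_text(path)
        assert np.array_equal(back.bits, w.bits)
        assert back.w_sum_target == 5

    def test_exact_random_init_popcounts(self, rng):
        w = BinaryWeights.random(100, 7, 33, rng, exact=True)
        assert (w.popcount() == 33).all()

    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError):
            BinaryWeights(np.full((2, 2), 2), 1)
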