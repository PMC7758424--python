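import numpy as np
import pytest
from hypothesis import given, strategies as st

from memdec import AssociationSet, MemoryConfig, ScenarioError
from memdec.memory_net import (
    encode_attractors,
    encode_episodic_chain,
    add_association,
    init_state,
    pattern_visits,
    readout,
    reset,
    step,
)


def block_patterns(n_blocks, block=2):
    """Orthogonal one-hot-block patterns of width ``block``."""
    F = n_blocks * block
    return [np.repeat(np.eye(n_blocks)[k], block) for k in range(n_blocks)], F


def make_assoc(n, w_sem=None, w_epi=None):
    z = np.zeros((n, n))
    return AssociationSet(
        semantic_weights=z if w_sem is None else w_sem,
        episodic_weights=z if w_epi is None else w_epi,
    )


def run(state, assoc, cfg, steps, inp=None, record=False):
    n = assoc.n
    inp = np.zeros(n) if inp is None else inp
    trace = []
    for _ in range(steps):
        step(state, inp, assoc, cfg)
        if record:
            trace.append(readout(state, cfg).copy())
    return np.asarray(trace) if record else state


class TestAttractors:
    def test_single_pattern_is_persistent_fixed_point(self):
        pats, F = block_patterns(2)
        assoc = make_assoc(F, w_sem=encode_attractors(pats, strength=0.4))
        cfg = MemoryConfig(leak=0.2)
        state = init_state(F, cfg)
        state.x = 2.0 * pats[0]
        state.hist[:] = readout(state, cfg)
        trace = run(state, assoc, cfg, 100, record=True)
        assert np.allclose(trace[-1], pats[0], atol=1e-6)
        assert np.all(np.abs(trace - pats[0]) < 1e-6)

    def test_empty_pattern_list_gives_zero_matrix_and_decay(self):
        w = encode_attractors([], n=3)
        assert np.array_equal(w, np.zeros((3, 3)))
        cfg = MemoryConfig(leak=0.2)
        state = init_state(3, cfg)
        state.x = np.array([1.0, 0.5, 0.0])
        state.hist[:] = readout(state, cfg)
        run(state, make_assoc(3), cfg, 200)
        assert np.all(state.x < 1e-6)

    def test_two_orthogonal_patterns_both_fixed_points(self):
        pats, F = block_patterns(3)
        assoc = make_assoc(F, w_sem=encode_attractors(pats[:2], strength=0.4))
        cfg = MemoryConfig(leak=0.2)
        for p in pats[:2]:
            state = init_state(F, cfg)
            state.x = 2.0 * p
            state.hist[:] = readout(state, cfg)
            run(state, assoc, cfg, 100)
            assert np.allclose(readout(state, cfg), p, atol=1e-6)

    def test_inconsistent_pattern_lengths_rejected(self):
        with pytest.raises(ScenarioError):
            encode_attractors([np.ones(3), np.ones(4)])

    def test_attractor_persists_1000_steps_without_depression(self):
        pats, F = block_patterns(2)
        assoc = make_assoc(F, w_sem=encode_attractors(pats, strength=0.4))
        cfg = MemoryConfig()  # no leak, no depression
        state = init_state(F, cfg)
        state.x = pats[0].copy()
        state.hist[:] = readout(state, cfg)
        run(state, assoc, cfg, 1000)
        assert np.allclose(readout(state, cfg), pats[0])


class TestStepDynamics:
    def test_zero_everything_stays_zero(self):
        cfg = MemoryConfig()
        state = init_state(4, cfg)
        run(state, make_assoc(4), cfg, 50)
        assert np.array_equal(state.x, np.zeros(4))

    def test_constant_input_integrates_as_ramp(self):
        # no weights, no leak: x(t) = sum of dt * I, a pure cumulative integral
        cfg = MemoryConfig(dt=0.5)
        state = init_state(3, cfg)
        I = np.array([0.02, 0.0, -0.01])
        run(state, make_assoc(3), cfg, 40, inp=I)
        assert np.allclose(state.x, 40 * 0.5 * I)

    def test_latching_visits_a_then_b(self):
        pats, F = block_patterns(2)
        A, B = pats
        w = encode_attractors(pats, strength=0.4)
        add_association(w, A, B, 0.1)
        assoc = make_assoc(F, w_sem=w)
        cfg = MemoryConfig(leak=0.2, depression_gain=0.05,
                           depression_recovery=0.001)
        state = init_state(F, cfg)
        state.x = 2.0 * A
        state.hist[:] = readout(state, cfg)
        trace = run(state, assoc, cfg, 400, record=True)
        visits = pattern_visits(trace, pats)
        assert visits == [0, 1]
        # A's attractor has collapsed by the end
        assert trace[-1][A > 0].mean() < 0.5

    def test_nonfinite_state_raises_with_context(self):
        cfg = MemoryConfig()
        state = init_state(2, cfg)
        from memdec import NumericalError

        with pytest.raises(NumericalError):
            run(state, make_assoc(2), cfg, 5, inp=np.array([np.inf, 0.0]))

    def test_dimension_mismatch_rejected(self):
        cfg = MemoryConfig()
        state = init_state(3, cfg)
        with pytest.raises(ScenarioError):
            step(state, np.zeros(2), make_assoc(3), cfg)


class TestEpisodicChains:
    def _chain_net(self, L, tau_slow=10, block=2):
        pats, F = block_patterns(L, block=block)
        assoc = AssociationSet(
            semantic_weights=encode_attractors(pats, strength=0.4),
            episodic_weights=encode_episodic_chain(pats, strength=0.5),
        )
        cfg = MemoryConfig(leak=0.2, tau_slow=tau_slow, input_gain=1.0)
        state = init_state(F, cfg)
        return pats, assoc, cfg, state

    def test_successor_active_after_tau_slow_plus_settling(self):
        pats, assoc, cfg, state = self._chain_net(2)
        trace = run(state, assoc, cfg, cfg.tau_slow + 15, inp=pats[0], record=True)
        assert trace[-1][pats[1] > 0].mean() > 0.9
        # and not before the delay has elapsed
        assert trace[cfg.tau_slow - 1][pats[1] > 0].mean() < 0.5

    def test_chain_visits_every_pattern_in_order(self):
        L = 4
        pats, assoc, cfg, state = self._chain_net(L)
        trace = run(state, assoc, cfg, L * (cfg.tau_slow + 10), inp=pats[0], record=True)
        assert pattern_visits(trace, pats) == list(range(L))

    def test_reversed_chain_replays_in_reverse(self):
        pats, F = block_patterns(3)
        assoc = AssociationSet(
            semantic_weights=encode_attractors(pats, strength=0.4),
            episodic_weights=encode_episodic_chain(pats[::-1], strength=0.5),
        )
        cfg = MemoryConfig(leak=0.2, tau_slow=10, input_gain=1.0)
        state = init_state(F, cfg)
        trace = run(state, assoc, cfg, 80, inp=pats[2], record=True)
        assert pattern_visits(trace, pats) == [2, 1, 0]

    def test_too_short_chain_rejected(self):
        with pytest.raises(ScenarioError):
            encode_episodic_chain([np.ones(3)])


class TestDelayBufferEquivalence:
    def test_episodic_at_fast_latency_equals_semantic_matrix(self, rng):
        """With tau_slow == tau_fast, a weight matrix behaves identically
        whether it is routed through the semantic or the episodic pathway."""
        n = 5
        w = rng.normal(scale=0.1, size=(n, n))
        cfg = MemoryConfig(tau_fast=3, tau_slow=3, leak=0.1)
        a_sem = make_assoc(n, w_sem=w.copy())
        a_epi = AssociationSet(semantic_weights=np.zeros((n, n)), episodic_weights=w.copy())
        s1, s2 = init_state(n, cfg), init_state(n, cfg)
        inp = rng.random(n) * 0.1
        for _ in range(60):
            step(s1, inp, a_sem, cfg)
            step(s2, inp, a_epi, cfg)
            assert np.array_equal(s1.x, s2.x)

    def test_split_matrices_equal_merged_matrix(self, rng):
        n = 4
        w1 = rng.normal(scale=0.1, size=(n, n))
        w2 = rng.normal(scale=0.1, size=(n, n))
        cfg = MemoryConfig(tau_fast=2, tau_slow=2, leak=0.1)
        split = AssociationSet(semantic_weights=w1, episodic_weights=w2)
        merged = make_assoc(n, w_sem=w1 + w2)
        s1, s2 = init_state(n, cfg), init_state(n, cfg)
        inp = rng.random(n) * 0.1
        for _ in range(60):
            step(s1, inp, split, cfg)
            step(s2, inp, merged, cfg)
            np.testing.assert_allclose(s1.x, s2.x, atol=1e-13)


class TestReadoutAndReset:
    def test_readout_of_zero_state_is_zero(self):
        cfg = MemoryConfig()
        assert np.array_equal(readout(init_state(3, cfg), cfg), np.zeros(3))

    @given(st.lists(st.floats(-3, 3), min_size=4, max_size=4),
           st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_readout_monotone_in_state(self, xs, bump):
        cfg = MemoryConfig()
        s1, s2 = init_state(4, cfg), init_state(4, cfg)
        s1.x = np.array(xs)
        s2.x = s1.x + np.array(bump)
        assert np.all(readout(s2, cfg) >= readout(s1, cfg))

    def test_reset_clears_activity_but_not_depression(self):
        pats, F = block_patterns(2)
        assoc = make_assoc(F, w_sem=encode_attractors(pats, strength=0.4))
        cfg = MemoryConfig(leak=0.2, depression_gain=0.05)
        state = init_state(F, cfg)
        run(state, assoc, cfg, 30, inp=pats[0])
        d_before = state.d_sem.copy()
        assert d_before.any()
        reset(state)
        assert np.array_equal(state.x, np.zeros(F))
        assert np.array_equal(state.hist, np.zeros_like(state.hist))
        assert np.array_equal(state.d_sem, d_before)
        run(state, assoc, cfg, 10)
        assert np.array_equal(state.x, np.zeros(F))  # stays quiescent

    def test_reset_then_present_pattern_reenters_attractor(self):
        pats, F = block_patterns(2)
        assoc = make_assoc(F, w_sem=encode_attractors(pats, strength=0.4))
        cfg = MemoryConfig(leak=0.2, input_gain=1.0)
        state = init_state(F, cfg)
        run(state, assoc, cfg, 40, inp=pats[0])
        reset(state)
        run(state, assoc, cfg, 40, inp=pats[1])
        assert np.allclose(readout(state, cfg), pats[1], atol=1e-3)


class TestDepressionBounds:
    @given(st.floats(0.0, 2.0), st.floats(0.0, 1.0), st.integers(1, 200))
    def test_depression_stays_in_unit_interval(self, gain, recovery, steps):
        pats, F = block_patterns(2)
        assoc = make_assoc(F, w_sem=encode_attractors(pats, strength=0.5))
        cfg = MemoryConfig(leak=0.1, depression_gain=gain,
                           depression_recovery=recovery)
        state = init_state(F, cfg)
        run(state, assoc, cfg, steps, inp=pats[0])
        assert np.all(state.d_sem >= 0.0) and np.all(state.d_sem <= 1.0)
        assert np.all(state.d_epi >= 0.0) and np.all(state.d_epi <= 1.0)
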