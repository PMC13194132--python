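"""Traced-current synapses: closed forms, delays, and path equivalence."""

import numpy as np
import pytest

from snnkit import Blueprint, NodeSpec, build_model
from snnkit.synapses import (
    SynapseParams, init_weights, init_delays, synapse_init, synapse_step,
    delayed_arrivals,
)


class TestInitWeights:
    def test_density_zero_gives_empty_mask(self):
        W, mask = init_weights((20, 20), 0.0, 1.0, 1, seed=0)
        assert mask.sum() == 0
        assert np.all(W == 0)

    def test_full_density_zero_magnitude(self):
        W, mask = init_weights((10, 10), 1.0, 0.0, 1, seed=0)
        assert mask.all()
        assert np.all(W == 0)

    def test_realized_density_within_binomial_bound(self):
        shape, density = (256, 256), 0.1
        W, mask = init_weights(shape, density, 1.0, 1, seed=42)
        n = shape[0] * shape[1]
        sigma = np.sqrt(n * density * (1 - density))
        assert abs(mask.sum() - n * density) < 3 * sigma

    def test_inhibitory_weights_nonpositive(self):
        W, _ = init_weights((30, 30), 0.5, 2.0, -1, seed=3)
        assert np.all(W <= 0)

    def test_self_connections_excluded(self):
        _, mask = init_weights((15, 15), 1.0, 1.0, 1, seed=0, exclude_self=True)
        assert not np.any(np.diag(mask))

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            init_weights((4, 4), 1.5, 1.0, 1, seed=0)


class TestSynapseStep:
    def test_silence_in_silence_out(self):
        params = SynapseParams(density=1.0)
        state = synapse_init(4, 3, params, seed=0)
        for _ in range(50):
            state, out = synapse_step(state, np.zeros(4, dtype=np.uint8), params, 1.0)
            assert np.all(out == 0)

    def test_single_spike_matches_closed_form(self):
        # current jumps by w at t0 + d, then decays as w exp(-(t-t0-d)/tau_s)
        params = SynapseParams(tau_s=5.0, density=1.0)
        state = synapse_init(1, 1, params, seed=1)
        state.W[:] = 0.7
        state.delays[:] = 4
        t0_step = 3
        trace = []
        for k in range(40):
            pre = np.array([1 if k == t0_step else 0], dtype=np.uint8)
            state, out = synapse_step(state, pre, params, 1.0)
            trace.append(out[0])
        trace = np.array(trace)
        arrival = t0_step + 4
        assert np.all(trace[:arrival] == 0)
        t = np.arange(len(trace) - arrival)
        assert np.allclose(trace[arrival:], 0.7 * np.exp(-t / 5.0), atol=1e-12)

    def test_zero_weights_give_zero_output(self, rng):
        params = SynapseParams(density=1.0, w_max=0.0)
        state = synapse_init(6, 5, params, seed=2)
        for _ in range(30):
            state, out = synapse_step(state, (rng.random(6) < 0.4).astype(np.uint8),
                                      params, 1.0)
            assert np.all(out == 0)

    def test_superposition_of_two_trains(self, rng):
        params = SynapseParams(tau_s=4.0, density=1.0)
        train1 = (rng.random((60, 5)) < 0.2).astype(np.uint8)
        train2 = (rng.random((60, 5)) < 0.2).astype(np.uint8)
        both = np.clip(train1 + train2, 0, 1)
        # use disjoint trains so (train1 + train2) stays binary
        train2[both < train1 + train2] = 0
        outputs = []
        for train in (train1, train2, np.clip(train1 + train2, 0, 1)):
            state = synapse_init(5, 4, params, seed=7)
            acc = []
            for row in train:
                state, out = synapse_step(state, row, params, 1.0)
                acc.append(out)
            outputs.append(np.array(acc))
        assert np.allclose(outputs[0] + outputs[1], outputs[2], atol=1e-9)

    def test_cross_correlation_recovers_every_delay(self, rng):
        params = SynapseParams(tau_s=3.0, density=1.0, d_max_steps=6)
        n_pre, n_post = 4, 3
        state = synapse_init(n_pre, n_post, params, seed=5)
        raster = (rng.random((200, n_pre)) < 0.05).astype(np.uint8)
        arrivals = []
        for row in raster:
            state, _ = synapse_step(state, row, params, 1.0)
            arrivals.append(delayed_arrivals(state))
        arrivals = np.array(arrivals)  # (T, n_pre, n_post)
        for j in range(n_pre):
            spikes = np.flatnonzero(raster[:, j])
            for i in range(n_post):
                hits = np.flatnonzero(arrivals[:, j, i])
                lags = {h - s for h in hits for s in spikes if h >= s}
                assert state.delays[j, i] in lags
                # every arrival is exactly one delayed spike
                assert len(hits) == len([s for s in spikes if s + state.delays[j, i] < 200])


class TestComponentEquivalence:
    def test_component_matches_dense_reference(self, rng):
        """Event-driven component output equals the dense functional path."""
        bp = Blueprint(nodes={"syn": NodeSpec(kind="traced_synapse", params={
            "n_pre": 12, "n_post": 9, "density": 0.6, "w_max": 1.2,
            "tau_s": 4.0, "d_max_ms": 6.0})}, metadata={"dt": "1.0"})
        model = build_model(bp, seed=21)
        comp = model.component("syn")
        params = SynapseParams(tau_s=4.0, w_max=1.2, density=0.6, d_max_steps=6)
        state = synapse_init(12, 9, params, seed=99)
        state.W, state.mask, state.delays = comp.W.copy(), comp.mask.copy(), comp.delays.copy()
        for k in range(300):
            pre = (rng.random(12) < 0.15).astype(np.uint8)
            out_comp = comp.step({"spikes": pre})["current"]
            state, out_dense = synapse_step(state, pre, params, 1.0)
            assert np.allclose(out_comp, out_dense, atol=1e-9), f"step {k}"

    def test_delay_exceeding_buffer_raises_at_build(self):
        bp = Blueprint(nodes={"syn": NodeSpec(kind="traced_synapse", params={
            "n_pre": 2, "n_post": 2, "d_max_ms": 0.1})}, metadata={"dt": "1.0"})
        with pytest.raises(Exception, match="delay"):
            build_model(bp)


class TestPlasticComponentEquivalence:
    def test_component_with_stdp_matches_dense_replay(self, rng):
        """The event-driven modulated update equals a dense per-connection
        replay of the same spike and modulation sequence (away from the
        weight bounds, where update order cannot matter)."""
        n_pre, n_post, steps = 10, 8, 400
        eta, alpha, beta, gamma, delta = 0.001, -0.1, 1.0, 1.0, -0.1
        tau_pre = tau_post = 20.0
        decay_pre = decay_post = np.exp(-1.0 / 20.0)
        bp = Blueprint(nodes={"syn": NodeSpec(kind="traced_synapse", params={
            "n_pre": n_pre, "n_post": n_post, "density": 0.7, "w_max": 5.0,
            "tau_s": 4.0, "d_max_ms": 5.0, "plastic": True,
            "plasticity": {"eta": eta, "alpha": alpha, "beta": beta,
                           "gamma": gamma, "delta": delta, "tau_pre": tau_pre,
                           "tau_post": tau_post, "w_min": 0.0, "w_max": 5.0}})},
            metadata={"dt": "1.0"})
        model = build_model(bp, seed=31)
        comp = model.component("syn")
        comp.W[comp.mask] = np.clip(comp.W[comp.mask], 1.0, 4.0)  # keep off bounds
        W = comp.W.copy()
        mask, delays = comp.mask.copy(), comp.delays.copy()
        L = int(delays.max()) + 2
        hist = np.zeros((L, n_pre))
        head = 0
        I = np.zeros((n_pre, n_post))
        x_pre = np.zeros((n_pre, n_post))
        x_post_unit = np.zeros(n_post)
        jj = np.arange(n_pre)[:, None]

        for k in range(steps):
            pre = (rng.random(n_pre) < 0.15).astype(np.uint8)
            post = (rng.random(n_post) < 0.15).astype(np.uint8)
            m3 = float(rng.uniform(-0.5, 0.5))
            comp.modulation = m3
            out_comp = comp.step({"spikes": pre, "post_spikes": post})["current"]

            head = (head + 1) % L
            hist[head] = pre
            arrivals = hist[(head - delays) % L, jj]
            xpre_use = x_pre * decay_pre
            xpost_use = x_post_unit * decay_post
            I = I * np.exp(-1.0 / 4.0) + W * (arrivals * mask)
            dW = eta * m3 * (post[None, :] * (alpha + beta * xpre_use)
                             + arrivals * (gamma + delta * xpost_use[None, :]))
            W = np.where(mask, np.clip(W + dW, 0.0, 5.0), 0.0)
            x_pre = xpre_use + arrivals
            x_post_unit = xpost_use + post

            assert np.allclose(out_comp, I.sum(axis=0), atol=1e-9), f"step {k}"
        assert np.max(np.abs(comp.W - W)) < 1e-9
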