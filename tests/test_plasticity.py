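"""Three-factor STDP: closed forms, gating, bounds, scalar-oracle equivalence."""

import numpy as np
import pytest

from snnkit.plasticity import (
    EligibilityTraces, PlasticityParams, stdp_update, structural_update,
    traces_init, update_traces,
)


class TestTraces:
    def test_decay_monotone_without_spikes(self):
        params = PlasticityParams(tau_pre=15.0, tau_post=25.0)
        tr = traces_init((3, 2))
        tr.x_pre += 1.0
        tr.x_post += 1.0
        prev = tr
        for _ in range(50):
            cur = update_traces(prev, np.zeros(3), np.zeros(2), params, 1.0)
            assert np.all(cur.x_pre < prev.x_pre)
            assert np.all(cur.x_post < prev.x_post)
            prev = cur
        assert np.all(prev.x_pre < 0.05)

    def test_single_spike_exponential(self):
        params = PlasticityParams(tau_pre=20.0, tau_post=20.0)
        tr = traces_init((1, 1))
        tr = update_traces(tr, np.ones(1), np.zeros(1), params, 1.0)
        values = [tr.x_pre[0, 0]]
        for _ in range(30):
            tr = update_traces(tr, np.zeros(1), np.zeros(1), params, 1.0)
            values.append(tr.x_pre[0, 0])
        t = np.arange(31)
        assert np.allclose(values, np.exp(-t / 20.0), atol=1e-12)

    def test_two_spikes_superpose(self):
        params = PlasticityParams(tau_pre=20.0)
        gap = 7
        tr = traces_init((1, 1))
        tr = update_traces(tr, np.ones(1), np.zeros(1), params, 1.0)
        for _ in range(gap):
            tr = update_traces(tr, np.zeros(1), np.zeros(1), params, 1.0)
        tr = update_traces(tr, np.ones(1), np.zeros(1), params, 1.0)
        assert np.isclose(tr.x_pre[0, 0], 1.0 + np.exp(-(gap + 1) / 20.0), atol=1e-12)


class TestStdpUpdate:
    def test_zero_modulation_freezes_weights_exactly(self, rng):
        params = PlasticityParams(eta=0.3)
        W = rng.uniform(0, 1, (5, 4))
        tr = traces_init((5, 4))
        tr.x_pre += rng.random((5, 4))
        W2 = stdp_update(W, tr, np.ones(5), np.ones(4), 0.0, params, 1.0)
        assert np.array_equal(W, W2)

    def test_no_spikes_freezes_weights_exactly(self, rng):
        params = PlasticityParams(eta=0.3)
        W = rng.uniform(0, 1, (5, 4))
        tr = traces_init((5, 4))
        tr.x_pre += 0.4
        tr.x_post += 0.2
        W2 = stdp_update(W, tr, np.zeros(5), np.zeros(4), 0.7, params, 1.0)
        assert np.allclose(W, W2)

    def test_coincident_pair_matches_hand_formula(self):
        params = PlasticityParams(eta=0.5, alpha=-0.1, beta=1.0, gamma=1.0,
                                  delta=-0.1, w_max=10.0)
        tr = traces_init((1, 1))
        tr.x_pre[0, 0], tr.x_post[0, 0] = 0.6, 0.3
        W = np.array([[1.0]])
        m3, dt = 0.25, 1.0
        W2 = stdp_update(W, tr, np.ones(1), np.ones(1), m3, params, dt)
        expected = 1.0 + 0.5 * m3 * ((-0.1 + 1.0 * 0.6) + (1.0 + -0.1 * 0.3)) * dt
        assert np.isclose(W2[0, 0], expected, atol=1e-15)

    def test_vectorized_equals_scalar_replay_oracle(self, rng):
        """Per-connection scalar reimplementation over a replayed raster."""
        n_pre, n_post, steps = 10, 10, 1000
        params = PlasticityParams(eta=0.05, alpha=-0.1, beta=1.0, gamma=1.0,
                                  delta=-0.1, tau_pre=20.0, tau_post=20.0,
                                  w_max=2.0)
        mask = rng.random((n_pre, n_post)) < 0.7
        W = rng.uniform(0, 1, (n_pre, n_post)) * mask
        pre = (rng.random((steps, n_pre)) < 0.08).astype(float)
        post = (rng.random((steps, n_post)) < 0.08).astype(float)
        m3 = rng.uniform(-0.3, 0.3, steps)

        # vectorized path
        Wv = W.copy()
        tr = traces_init((n_pre, n_post))
        for k in range(steps):
            decayed = EligibilityTraces(tr.x_pre * np.exp(-1.0 / 20.0),
                                        tr.x_post * np.exp(-1.0 / 20.0))
            Wv = stdp_update(Wv, decayed, pre[k], post[k], m3[k], params, 1.0, mask=mask)
            tr = update_traces(tr, pre[k], post[k], params, 1.0)

        # scalar oracle
        Ws = W.copy()
        for j in range(n_pre):
            for i in range(n_post):
                if not mask[j, i]:
                    continue
                xp = xq = 0.0
                w = W[j, i]
                for k in range(steps):
                    xp *= np.exp(-1.0 / 20.0)
                    xq *= np.exp(-1.0 / 20.0)
                    dw = 0.05 * m3[k] * (post[k, i] * (-0.1 + 1.0 * xp)
                                         + pre[k, j] * (1.0 + -0.1 * xq))
                    w = min(max(w + dw, 0.0), 2.0)
                    xp += pre[k, j]
                    xq += post[k, i]
                Ws[j, i] = w
        assert np.max(np.abs(Wv - Ws)) <= 1e-6

    def test_bounds_hold_on_random_trajectories(self, rng):
        params = PlasticityParams(eta=2.0, w_min=0.0, w_max=1.0)
        W = rng.uniform(0, 1, (6, 6))
        tr = traces_init((6, 6))
        for k in range(300):
            pre = (rng.random(6) < 0.3).astype(float)
            post = (rng.random(6) < 0.3).astype(float)
            decayed = EligibilityTraces(tr.x_pre * np.exp(-0.05), tr.x_post * np.exp(-0.05))
            W = stdp_update(W, decayed, pre, post, rng.uniform(-1, 1), params, 1.0)
            tr = update_traces(tr, pre, post, params, 1.0)
            assert np.all(W >= 0.0) and np.all(W <= 1.0)

    def test_negative_modulation_depresses_active_population(self, rng):
        """Excitatory weights onto a spiking population shrink (in sum) while
        it receives a negative third factor."""
        params = PlasticityParams(eta=0.2, w_max=2.0)
        W = rng.uniform(0.5, 1.5, (8, 8))
        tr = traces_init((8, 8))
        total = [W.sum()]
        for k in range(100):
            pre = (rng.random(8) < 0.3).astype(float)
            post = (rng.random(8) < 0.3).astype(float)
            decayed = EligibilityTraces(tr.x_pre * np.exp(-0.05), tr.x_post * np.exp(-0.05))
            W = stdp_update(W, decayed, pre, post, -0.4, params, 1.0)
            tr = update_traces(tr, pre, post, params, 1.0)
            total.append(W.sum())
        assert total[-1] < total[0]  # net depression over the delivery window


class TestStructural:
    def test_identity_when_disabled(self, rng):
        params = PlasticityParams(prune_eps=0.0, growth_prob=0.0)
        W = rng.uniform(0, 1, (5, 5))
        mask = rng.random((5, 5)) < 0.5
        W2, mask2 = structural_update(W, mask, params, seed=1, step=0)
        assert np.array_equal(W, W2) and np.array_equal(mask, mask2)

    def test_prune_everything_below_threshold(self, rng):
        params = PlasticityParams(prune_eps=10.0, growth_prob=0.0)
        W = rng.uniform(0, 1, (5, 5))
        mask = np.ones((5, 5), dtype=bool)
        W2, mask2 = structural_update(W, mask, params, seed=1, step=0)
        assert mask2.sum() == 0 and np.all(W2 == 0)

    def test_growth_count_within_binomial_bound(self):
        p = 0.05
        params = PlasticityParams(growth_prob=p, growth_w=0.3)
        W = np.zeros((100, 100))
        mask = np.zeros((100, 100), dtype=bool)
        _, mask2 = structural_update(W, mask, params, seed=3, step=0)
        expected, sigma = 1e4 * p, np.sqrt(1e4 * p * (1 - p))
        assert abs(mask2.sum() - expected) < 3 * sigma

    def test_growth_respects_sign(self):
        params = PlasticityParams(growth_prob=0.5, growth_w=0.4)
        W = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        W2, mask2 = structural_update(W, mask, params, seed=4, step=1, sign=-1)
        assert np.all(W2[mask2] == -0.4)

    def test_deterministic_under_seed_and_step(self):
        params = PlasticityParams(growth_prob=0.1, growth_w=0.1)
        W = np.zeros((30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        a = structural_update(W, mask, params, seed=8, step=5)
        b = structural_update(W, mask, params, seed=8, step=5)
        assert np.array_equal(a[1], b[1])
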