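"""Three-factor quadruplet STDP with eligibility traces and structural turnover.

The weight update for connection (j -> i), j presynaptic, is::

    dw_ji/dt = eta * M3rd(t) * ( S_post_i(t) * [alpha + beta  * x_pre_ji(t)]
                               + S_pre_j(t - d_ji) * [gamma + delta * x_post_ji(t)] )

applied as a forward-Euler per-step increment (* dt) and clipped to the
weight bounds with sign preservation (excitatory weights stay >= 0,
inhibitory <= 0).  ``M3rd`` is the modulatory third factor: a reward-linked
scalar at episode ends and a small background constant otherwise; with
``M3rd == 0`` the weights are exactly frozen.

Eligibility traces are exponential with unit increments: the pre trace of a
connection is driven by the *delayed* presynaptic spike (the one the
synapse actually sees), the post trace by the postsynaptic spike.  The
update at step t uses trace values after decay but *before* the current
step's spike increments, so a spike never pairs with itself.

Structural turnover deletes connections whose magnitude falls below
``prune_eps`` and adds absent connections with probability ``growth_prob``
per step at magnitude ``growth_w`` with the population's sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams", "EligibilityTraces", "traces_init",
    "update_traces", "stdp_update", "structural_update",
]


@dataclass(frozen=True)
class PlasticityParams:
    eta: float = 0.5            # learning rate
    alpha: float | np.ndarray = -0.1   # post-spike constant term
    beta: float | np.ndarray = 1.0     # post-spike pre-trace coefficient
    gamma: float | np.ndarray = 1.0    # pre-spike constant term
    delta: float | np.ndarray = -0.1   # pre-spike post-trace coefficient
    tau_pre: float = 20.0       # pre eligibility-trace time constant (ms)
    tau_post: float = 20.0      # post eligibility-trace time constant (ms)
    w_min: float = 0.0          # weight-magnitude lower bound
    w_max: float = 1.0          # weight-magnitude upper bound
    prune_eps: float = 0.0      # delete connections with |w| below this
    growth_prob: float = 0.0    # per-step probability of adding an absent connection
    growth_w: float = 0.0       # magnitude of a newly added weight

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if not (self.tau_pre > 0 and self.tau_post > 0):
            raise ValueError("trace time constants must be positive")
        if self.prune_eps < 0:
            raise ValueError("prune_eps must be nonnegative")
        if not 0.0 <= self.growth_prob <= 1.0:
            raise ValueError("growth_prob must be in [0,1]")


@dataclass
class EligibilityTraces:
    x_pre: np.ndarray   # (n_pre, n_post) presynaptic trace per connection
    x_post: np.ndarray  # (n_pre, n_post) postsynaptic trace per connection


def traces_init(shape: tuple[int, int], dtype=np.float64) -> EligibilityTraces:
    return EligibilityTraces(np.zeros(shape, dtype=dtype), np.zeros(shape, dtype=dtype))


def update_traces(traces: EligibilityTraces, pre_spikes_delayed: np.ndarray,
                  post_spikes: np.ndarray, params: PlasticityParams,
                  dt: float) -> EligibilityTraces:
    """Decay both traces and add unit increments on the triggering spikes.

    ``pre_spikes_delayed`` is the (n_pre, n_post) delayed-arrival indicator
    (or an (n_pre,) vector broadcast across postsynaptic units when the
    caller uses a uniform delay); ``post_spikes`` is the (n_post,) spike
    vector.
    """
    pre = np.asarray(pre_spikes_delayed, dtype=traces.x_pre.dtype)
    if pre.ndim == 1:
        pre = pre[:, None] * np.ones((1, traces.x_pre.shape[1]), dtype=pre.dtype)
    post = np.asarray(post_spikes, dtype=traces.x_post.dtype)
    x_pre = traces.x_pre * np.exp(-dt / params.tau_pre) + pre
    x_post = traces.x_post * np.exp(-dt / params.tau_post) + post[None, :]
    return EligibilityTraces(x_pre=x_pre, x_post=x_post)


def _clip_signed(W: np.ndarray, mask: np.ndarray, sign: int,
                 params: PlasticityParams) -> np.ndarray:
    lo, hi = params.w_min, params.w_max
    if sign >= 0:
        W = np.clip(W, lo, hi)
    else:
        W = np.clip(W, -hi, -lo)
    return np.where(mask, W, 0.0)


def stdp_update(W: np.ndarray, traces: EligibilityTraces,
                pre_spikes_delayed: np.ndarray, post_spikes: np.ndarray,
                m3rd: float, params: PlasticityParams, dt: float,
                mask: np.ndarray | None = None, sign: int = 1) -> np.ndarray:
    """One modulated weight update; only masked connections change.

    The trace values passed in must be the pre-increment values of the
    current step (see module docstring); the caller owns that ordering.
    """
    if mask is None:
        mask = np.ones_like(W, dtype=bool)
    if m3rd == 0.0 or params.eta == 0.0:
        return W.copy()
    pre = np.asarray(pre_spikes_delayed, dtype=W.dtype)
    if pre.ndim == 1:
        pre = np.broadcast_to(pre[:, None], W.shape)
    post = np.asarray(post_spikes, dtype=W.dtype)
    dw = params.eta * m3rd * (
        post[None, :] * (params.alpha + params.beta * traces.x_pre)
        + pre * (params.gamma + params.delta * traces.x_post)
    ) * dt
    if not np.all(np.isfinite(dw)):
        bad = np.argwhere(~np.isfinite(dw))[0]
        raise FloatingPointError(f"non-finite weight update at connection {tuple(bad)}")
    return _clip_signed(W + np.where(mask, dw, 0.0), mask, sign, params)


def structural_update(W: np.ndarray, mask: np.ndarray, params: PlasticityParams,
                      seed: int, step: int, sign: int = 1,
                      exclude_self: bool = False,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Prune near-zero connections and stochastically add absent ones.

    Deterministic under (seed, step); alternatively an explicit generator
    can be supplied by stateful callers.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, step]))
    mask = mask.copy()
    W = W.copy()
    if params.prune_eps > 0:
        doomed = mask & (np.abs(W) < params.prune_eps)
        mask[doomed] = False
        W[doomed] = 0.0
    if params.growth_prob > 0:
        absent = ~mask
        if exclude_self and W.shape[0] == W.shape[1]:
            absent = absent & ~np.eye(W.shape[0], dtype=bool)
        born = absent & (rng.random(W.shape) < params.growth_prob)
        mask[born] = True
        W[born] = sign * params.growth_w
    return W, mask
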