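"""Traced-current synapses with per-connection integer-step delays.

Each connection (j -> i) carries a current obeying::

    tau_s dI_ji/dt = -I_ji ;  I_ji += w_ji  when the presynaptic spike
                              emitted at t - d_ji arrives

(the decay is exponential-Euler exact: I *= exp(-dt/tau_s) per step).
Inhibition is carried by negative weights; excitatory (inhibitory)
weights never change sign (Dale-like clipping).  The postsynaptic drive
is the per-unit sum over presynaptic partners.

Two implementations share these semantics:

* a dense functional reference (:func:`synapse_step`) holding the full
  (n_pre, n_post) current matrix — the contract used by unit tests and
  oracles;
* :class:`TracedSynapse`, the model component, which exploits spike
  sparsity: per-postsynaptic summed currents, a ring buffer of presynaptic
  spike history, per-neuron eligibility-trace rings, and an event-driven
  kernel (numba-compiled when available) that also applies the modulated
  three-factor STDP update.  Both paths agree to float tolerance
  (equivalence-tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Component, ConfigurationError, register_component
from .plasticity import PlasticityParams

try:  # pragma: no cover - exercised indirectly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SynapseParams", "SynapseState", "init_weights", "init_delays",
    "synapse_init", "synapse_step", "TracedSynapse",
]


# ---------------------------------------------------------------------------
# Initializers
# ---------------------------------------------------------------------------

def init_weights(shape: tuple[int, int], density: float, w_max: float,
                 sign: int, seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 exclude_self: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Sparse uniform initialization.

    Each potential connection is present independently with probability
    ``density``; present weights are Uniform(0, w_max) * sign.  Self
    connections within a square pool can be excluded.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0,1], got {density}")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(shape) < density
    if exclude_self and shape[0] == shape[1]:
        np.fill_diagonal(mask, False)
    W = rng.uniform(0.0, w_max, size=shape) * np.sign(sign)
    W = np.where(mask, W, 0.0)
    return W, mask


def init_delays(shape: tuple[int, int], d_max_steps: int,
                rng: np.random.Generator) -> np.ndarray:
    """Integer delays uniform in [1, d_max] steps, per connection."""
    if d_max_steps < 1:
        raise ValueError("d_max_steps must be >= 1 (delays are at least one step)")
    return rng.integers(1, d_max_steps + 1, size=shape, dtype=np.int32)


# ---------------------------------------------------------------------------
# Dense functional reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseParams:
    tau_s: float = 5.0       # synaptic time constant (ms)
    w_min: float = 0.0       # weight-magnitude lower bound
    w_max: float = 1.0       # weight-magnitude upper bound
    density: float = 0.1     # initial connection probability
    sign: int = 1            # +1 excitatory, -1 inhibitory
    d_max_steps: int = 10    # maximum delay in steps

    def __post_init__(self) -> None:
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class SynapseState:
    W: np.ndarray        # (n_pre, n_post) signed weights, zero off-mask
    mask: np.ndarray     # (n_pre, n_post) bool connectivity
    delays: np.ndarray   # (n_pre, n_post) int steps, in [1, d_max]
    I: np.ndarray        # (n_pre, n_post) per-connection traced current
    hist: np.ndarray     # (L, n_pre) circular presynaptic spike history
    head: int            # ring position of the current step


def synapse_init(n_pre: int, n_post: int, params: SynapseParams, seed: int = 0,
                 exclude_self: bool = False) -> SynapseState:
    rng = np.random.default_rng(seed)
    W, mask = init_weights((n_pre, n_post), params.density, params.w_max,
                           params.sign, rng=rng, exclude_self=exclude_self)
    delays = init_delays((n_pre, n_post), params.d_max_steps, rng)
    L = params.d_max_steps + 2
    return SynapseState(W=W, mask=mask, delays=delays,
                        I=np.zeros((n_pre, n_post)),
                        hist=np.zeros((L, n_pre), dtype=np.uint8), head=0)


def delayed_arrivals(state: SynapseState) -> np.ndarray:
    """(n_pre, n_post) indicator of delayed presynaptic spikes arriving now."""
    L = state.hist.shape[0]
    rows = (state.head - state.delays) % L
    return state.hist[rows, np.arange(state.W.shape[0])[:, None]]


def synapse_step(state: SynapseState, presyn_spikes: np.ndarray,
                 params: SynapseParams, dt: float
                 ) -> tuple[SynapseState, np.ndarray]:
    """Dense reference step; returns (new state, summed current per post unit)."""
    n_pre = state.W.shape[0]
    pre = np.asarray(presyn_spikes)
    if pre.shape != (n_pre,):
        raise ValueError(f"presyn_spikes must have shape ({n_pre},)")
    if int(state.delays.max(initial=1)) >= state.hist.shape[0]:
        raise ConfigurationError("a delay exceeds the spike-history buffer")
    L = state.hist.shape[0]
    head = (state.head + 1) % L
    hist = state.hist.copy()
    hist[head] = pre.astype(np.uint8)
    tmp = SynapseState(state.W, state.mask, state.delays, state.I, hist, head)
    arr = delayed_arrivals(tmp)
    I = state.I * np.exp(-dt / params.tau_s) + state.W * (arr * state.mask)
    out = I.sum(axis=0)
    return SynapseState(W=state.W, mask=state.mask, delays=state.delays,
                        I=I, hist=hist, head=head), out


# ---------------------------------------------------------------------------
# Event-driven kernels
# ---------------------------------------------------------------------------

def _arrival_update(hist, head, d_max, csr_i, ptr, W, mask, I_post,
                    xpost_use, eta_m_dt, gamma, delta, lo, hi):
    """Process all delayed spike arrivals this step: current increments and,
    when eta_m_dt != 0, the pre-spike STDP term."""
    L = hist.shape[0]
    n_pre = hist.shape[1]
    plastic = eta_m_dt != 0.0
    for d in range(1, d_max + 1):
        slot = (head - d) % L
        for j in range(n_pre):
            if hist[slot, j]:
                for idx in range(ptr[j, d - 1], ptr[j, d]):
                    i = csr_i[j, idx]
                    if mask[j, i]:
                        I_post[i] += W[j, i]
                        if plastic:
                            w = W[j, i] + eta_m_dt * (gamma + delta * xpost_use[i])
                            if w < lo:
                                w = lo
                            elif w > hi:
                                w = hi
                            W[j, i] = w


def _postspike_update(post, W, mask, delays, xpre_ring, head, decay_pre,
                      eta_m_dt, alpha, beta, lo, hi):
    """Post-spike STDP term: for every postsynaptic spike, pair with the
    delayed presynaptic eligibility trace of each incoming connection."""
    L = xpre_ring.shape[0]
    n_pre, n_post = W.shape
    for i in range(n_post):
        if post[i]:
            for j in range(n_pre):
                if mask[j, i]:
                    xpre = decay_pre * xpre_ring[(head - 1 - delays[j, i]) % L, j]
                    w = W[j, i] + eta_m_dt * (alpha + beta * xpre)
                    if w < lo:
                        w = lo
                    elif w > hi:
                        w = hi
                    W[j, i] = w


if _HAVE_NUMBA:
    _arrival_update = numba.njit(cache=False)(_arrival_update)
    _postspike_update = numba.njit(cache=False)(_postspike_update)


# ---------------------------------------------------------------------------
# Component
# ---------------------------------------------------------------------------

@register_component
class TracedSynapse(Component):
    """Delayed traced-current synapse bundle with optional modulated STDP.

    Ports: in ``spikes`` (n_pre), plus ``post_spikes`` (n_post) when
    plastic — fed by a back edge from the postsynaptic pool, hence lagged
    by one tick; out ``current`` (n_post summed drive).

    The scalar attribute :attr:`modulation` is the third factor applied on
    the next step; with ``modulation == 0`` weights (and structural
    turnover) are exactly frozen.
    """

    kind = "traced_synapse"

    def configure(self, params: dict) -> None:
        self.n_pre = int(params["n_pre"])
        self.n_post = int(params["n_post"])
        self.params = SynapseParams(
            tau_s=float(params.get("tau_s", 5.0)),
            w_min=float(params.get("w_min", 0.0)),
            w_max=float(params.get("w_max", 1.0)),
            density=float(params.get("density", 0.1)),
            sign=int(params.get("sign", 1)),
            d_max_steps=int(round(float(params.get("d_max_ms", 10.0)) / self.dt)),
        )
        if self.params.d_max_steps < 1:
            raise ConfigurationError(
                f"component {self.node_id!r}: max delay must be at least one step (dt)")
        self.exclude_self = bool(params.get("exclude_self", False))
        self.plastic = bool(params.get("plastic", False))
        self.plasticity = PlasticityParams(**params.get("plasticity", {})) if self.plastic else None
        if self.plastic:
            for name in ("alpha", "beta", "gamma", "delta"):
                if isinstance(getattr(self.plasticity, name), np.ndarray):
                    raise ConfigurationError(
                        "TracedSynapse supports scalar STDP coefficients; "
                        "use the functional API for per-connection arrays")
        self.modulation = 0.0
        self.in_ports = {"spikes": self.n_pre}
        if self.plastic:
            self.in_ports["post_spikes"] = self.n_post
        self.out_ports = {"current": self.n_post}
        self._init_state()

    def _init_state(self) -> None:
        p = self.params
        self.W, self.mask = init_weights(
            (self.n_pre, self.n_post), p.density, p.w_max, p.sign,
            rng=self.rng, exclude_self=self.exclude_self)
        self.delays = init_delays((self.n_pre, self.n_post), p.d_max_steps, self.rng)
        self.L = p.d_max_steps + 2
        self.hist = np.zeros((self.L, self.n_pre), dtype=np.uint8)
        self.head = 0
        self.I_post = np.zeros(self.n_post)
        # per-neuron eligibility-trace rings (exact per-connection traces
        # are recovered by delayed lookup; see plasticity module docstring)
        self.xpre_ring = np.zeros((self.L, self.n_pre))
        self.xpost = np.zeros(self.n_post)
        # delay-grouped CSR layout: for presyn j, post targets sorted by
        # delay; ptr[j, d] = end offset of delay-d group
        order = np.argsort(self.delays, axis=1, kind="stable").astype(np.int32)
        self.csr_i = order
        sorted_d = np.take_along_axis(self.delays, order, axis=1)
        self.ptr = np.zeros((self.n_pre, p.d_max_steps + 1), dtype=np.int64)
        for j in range(self.n_pre):
            self.ptr[j, 1:] = np.searchsorted(sorted_d[j], np.arange(1, p.d_max_steps + 1), side="right")
        self._decay_s = float(np.exp(-self.dt / p.tau_s))
        if self.plastic:
            self._decay_pre = float(np.exp(-self.dt / self.plasticity.tau_pre))
            self._decay_post = float(np.exp(-self.dt / self.plasticity.tau_post))
        sign = p.sign
        self._lo = p.w_min if sign > 0 else -p.w_max
        self._hi = p.w_max if sign > 0 else -p.w_min

    # -- stepping ---------------------------------------------------------
    def step(self, inputs: dict) -> dict:
        pre = np.asarray(inputs["spikes"])
        if pre.shape != (self.n_pre,):
            raise ValueError(
                f"component {self.node_id!r} port 'spikes' expects shape ({self.n_pre},), got {pre.shape}")
        post = None
        if self.plastic:
            post = np.asarray(inputs["post_spikes"]).astype(np.uint8)
        self.head = (self.head + 1) % self.L
        self.hist[self.head] = (pre > 0)
        if self.plastic:
            self.xpre_ring[self.head] = self._decay_pre * self.xpre_ring[self.head - 1 if self.head else self.L - 1] + self.hist[self.head]
            xpost_use = self.xpost * self._decay_post
        else:
            xpost_use = self.xpost  # unused
        self.I_post *= self._decay_s
        pl = self.plasticity
        eta_m_dt = (pl.eta * self.modulation * self.dt) if (self.plastic and pl is not None) else 0.0
        _arrival_update(self.hist, self.head, self.params.d_max_steps,
                        self.csr_i, self.ptr, self.W, self.mask, self.I_post,
                        xpost_use, eta_m_dt,
                        float(pl.gamma) if pl else 0.0,
                        float(pl.delta) if pl else 0.0,
                        self._lo, self._hi)
        if eta_m_dt != 0.0 and post is not None and post.any():
            _postspike_update(post, self.W, self.mask, self.delays,
                              self.xpre_ring, self.head, self._decay_pre,
                              eta_m_dt, float(pl.alpha), float(pl.beta),
                              self._lo, self._hi)
        if self.plastic:
            self.xpost = xpost_use + post
        return {"current": self.I_post.copy()}

    # -- structural turnover ---------------------------------------------
    def structural_step(self) -> None:
        """Prune/grow connections; gated by nonzero modulation (frozen
        networks are structurally static)."""
        if not self.plastic or self.modulation == 0.0:
            return
        pl = self.plasticity
        if pl.prune_eps <= 0 and pl.growth_prob <= 0:
            return
        if pl.prune_eps > 0:
            doomed = self.mask & (np.abs(self.W) < pl.prune_eps)
            self.mask[doomed] = False
            self.W[doomed] = 0.0
        if pl.growth_prob > 0:
            absent = ~self.mask
            if self.exclude_self and self.n_pre == self.n_post:
                absent &= ~np.eye(self.n_pre, dtype=bool)
            born = absent & (self.rng.random(self.W.shape) < pl.growth_prob)
            self.mask[born] = True
            self.W[born] = self.params.sign * pl.growth_w

    # -- persistence ------------------------------------------------------
    def get_weights(self) -> dict:
        return {"W": self.W.copy(), "mask": self.mask.copy(), "delays": self.delays.copy()}

    def set_weights(self, payload: dict) -> None:
        if payload["W"].shape != self.W.shape:
            raise ConfigurationError(
                f"component {self.node_id!r}: weight shape {payload['W'].shape} "
                f"does not match {self.W.shape}")
        self.W = np.asarray(payload["W"], dtype=float).copy()
        self.mask = np.asarray(payload["mask"], dtype=bool).copy()
        self.delays = np.asarray(payload["delays"], dtype=np.int32).copy()
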