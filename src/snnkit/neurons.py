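"""Soma models: LIF with threshold adaptation and refractoriness, AdEx, HH.

All models are integrated at a fixed step ``dt`` (ms) with a mixture of
forward Euler (input / nonlinear terms) and exponential Euler (linear leak
and relaxation terms, exact on the homogeneous part).

LIF dynamics (per unit i)::

    tau_m  dv/dt     = -(v - v_rest) + R * sum_j I_ij      (while non-refractory)
    tau_m  dv/dt     = -(v - v_rest)                        (refractory: input gated off)
    tau_th dtheta/dt = -(theta - theta_base)                (+ a on each spike)
    S = 1  iff  v > theta  (evaluated after the integration update)

A spike resets ``v`` to ``v_reset`` and sets the refractory variable
``r <- -r_spike``; ``r`` otherwise relaxes upward at unit rate and the unit
is non-refractory iff ``r > 0``.  ``r`` is clamped at ``r_spike`` from above.

Units: time ms, potentials mV.  LIF currents are in units of mV/R (R is a
dimensionless input scaling).  AdEx uses pF/nS/mV/ms/pA; HH uses the
classic squid-axon set (uF/cm^2, mS/cm^2, mV, ms, uA/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Component, register_component

__all__ = [
    "LIFParams", "LIFState", "lif_init", "lif_step",
    "AdExParams", "AdExState", "adex_init", "adex_step",
    "HHParams", "HHState", "hh_init", "hh_step",
    "LIFPool", "AdExPool", "HHPool",
]


# ---------------------------------------------------------------------------
# LIF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LIFParams:
    tau_m: float = 20.0      # membrane time constant (ms)
    v_rest: float = -65.0    # rest potential (mV)
    R: float = 1.0           # membrane resistance (input scaling)
    theta_base: float = -50.0  # base threshold (mV)
    a: float = 2.0           # threshold increment per spike (mV)
    tau_th: float = 50.0     # threshold time constant (ms)
    r_spike: float = 5.0     # refractory duration (ms)
    v_reset: float = -65.0   # post-spike reset potential (mV)

    def __post_init__(self) -> None:
        if not (self.tau_m > 0 and self.tau_th > 0 and self.r_spike > 0):
            raise ValueError("tau_m, tau_th and r_spike must be positive")
        if not self.theta_base > self.v_rest:
            raise ValueError("theta_base must exceed v_rest")


@dataclass
class LIFState:
    v: np.ndarray      # membrane potential (mV)
    theta: np.ndarray  # adaptive threshold (mV)
    r: np.ndarray      # refractory variable (ms); non-refractory iff r > 0
    S: np.ndarray      # spike indicator {0,1}


def lif_init(n: int, params: LIFParams, dtype=np.float32) -> LIFState:
    return LIFState(
        v=np.full(n, params.v_rest, dtype=dtype),
        theta=np.full(n, params.theta_base, dtype=dtype),
        r=np.full(n, params.r_spike, dtype=dtype),
        S=np.zeros(n, dtype=np.uint8),
    )


def lif_step(state: LIFState, input_current: np.ndarray, params: LIFParams,
             dt: float) -> LIFState:
    """One integration step: exponential-Euler leak, forward-Euler input.

    The spike test ``v > theta`` is evaluated after the update, with the
    threshold already decayed for this step.
    """
    p = params
    dtype = state.v.dtype
    decay_m = dtype.type(np.exp(-dt / p.tau_m))
    decay_th = dtype.type(np.exp(-dt / p.tau_th))
    gate = state.r > 0
    drive = dtype.type(dt / p.tau_m * p.R) * np.asarray(input_current, dtype=dtype)
    v = dtype.type(p.v_rest) + (state.v - dtype.type(p.v_rest)) * decay_m
    v = v + np.where(gate, drive, dtype.type(0))
    theta = dtype.type(p.theta_base) + (state.theta - dtype.type(p.theta_base)) * decay_th
    S = v > theta
    v = np.where(S, dtype.type(p.v_reset), v)
    theta = theta + dtype.type(p.a) * S.astype(dtype)
    r = np.where(S, dtype.type(-p.r_spike),
                 np.minimum(state.r + dtype.type(dt), dtype.type(p.r_spike)))
    return LIFState(v=v, theta=theta, r=r, S=S.astype(np.uint8))


# ---------------------------------------------------------------------------
# AdEx (regular-spiking parameter set)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdExParams:
    C: float = 281.0        # membrane capacitance (pF)
    g_L: float = 30.0       # leak conductance (nS)
    E_L: float = -70.6      # leak reversal (mV)
    V_T: float = -50.4      # spike-initiation threshold (mV)
    delta_T: float = 2.0    # slope factor (mV)
    tau_w: float = 144.0    # adaptation time constant (ms)
    a: float = 4.0          # subthreshold adaptation coupling (nS)
    b: float = 80.5         # spike-triggered adaptation increment (pA)
    v_reset: float = -70.6  # reset potential (mV)
    v_cut: float = -40.4    # numerical spike cutoff, V_T + 5*delta_T (mV)


@dataclass
class AdExState:
    v: np.ndarray  # membrane potential (mV)
    w: np.ndarray  # adaptation current (pA)
    S: np.ndarray  # spike indicator {0,1}


def adex_init(n: int, params: AdExParams, dtype=np.float32) -> AdExState:
    return AdExState(
        v=np.full(n, params.E_L, dtype=dtype),
        w=np.zeros(n, dtype=dtype),
        S=np.zeros(n, dtype=np.uint8),
    )


def adex_step(state: AdExState, input_current: np.ndarray, params: AdExParams,
              dt: float) -> AdExState:
    """Forward-Euler AdEx update with a clamped exponential term.

    The exponent argument is clipped at the cutoff so a single step cannot
    overflow; ``v`` is clipped at ``v_cut`` before the reset test.
    """
    p = params
    v, w = state.v.astype(np.float64), state.w.astype(np.float64)
    I = np.asarray(input_current, dtype=np.float64)
    arg = np.minimum((v - p.V_T) / p.delta_T, (p.v_cut - p.V_T) / p.delta_T + 5.0)
    dv = (-p.g_L * (v - p.E_L) + p.g_L * p.delta_T * np.exp(arg) - w + I) / p.C
    dw = (p.a * (v - p.E_L) - w) / p.tau_w
    v = np.minimum(v + dt * dv, p.v_cut)
    w = w + dt * dw
    S = v >= p.v_cut
    v = np.where(S, p.v_reset, v)
    w = w + p.b * S
    dtype = state.v.dtype
    return AdExState(v=v.astype(dtype), w=w.astype(dtype), S=S.astype(np.uint8))


# ---------------------------------------------------------------------------
# Hodgkin-Huxley (classic squid-axon set)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HHParams:
    C: float = 1.0        # uF/cm^2
    g_Na: float = 120.0   # mS/cm^2
    g_K: float = 36.0
    g_L: float = 0.3
    E_Na: float = 50.0    # mV
    E_K: float = -77.0
    E_L: float = -54.4
    spike_thresh: float = 0.0  # upward-crossing detection level (mV)


@dataclass
class HHState:
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    S: np.ndarray


def _exprel(x: np.ndarray) -> np.ndarray:
    # x / (1 - exp(-x)), stable near x = 0
    out = np.where(np.abs(x) < 1e-7, 1.0 + x / 2.0, x / (-np.expm1(-np.where(np.abs(x) < 1e-7, 1.0, x))))
    return out


def hh_rates(v: np.ndarray) -> tuple[np.ndarray, ...]:
    """Standard alpha/beta rate functions (1/ms), singularities removed."""
    v = np.asarray(v, dtype=np.float64)
    alpha_m = _exprel((v + 40.0) / 10.0)          # 0.1(v+40)/(1-exp(-(v+40)/10))
    beta_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    alpha_n = 0.1 * _exprel((v + 55.0) / 10.0)    # 0.01(v+55)/(1-exp(-(v+55)/10))
    beta_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def hh_equilibrium(params: HHParams = HHParams(), v0: float = -65.0,
                   tol: float = 1e-12, max_iter: int = 200) -> tuple[float, float, float, float]:
    """Resting equilibrium found by fixed-point iteration on (v, gates)."""
    v = v0
    for _ in range(max_iter):
        am, bm, ah, bh, an, bn = (float(x[0]) for x in hh_rates(np.array([v])))
        m, h, n = am / (am + bm), ah / (ah + bh), an / (an + bn)
        g = params.g_Na * m**3 * h + params.g_K * n**4 + params.g_L
        v_new = (params.g_Na * m**3 * h * params.E_Na + params.g_K * n**4 * params.E_K
                 + params.g_L * params.E_L) / g
        if abs(v_new - v) < tol:
            v = v_new
            break
        v = 0.5 * (v + v_new)
    am, bm, ah, bh, an, bn = (float(x[0]) for x in hh_rates(np.array([v])))
    return v, am / (am + bm), ah / (ah + bh), an / (an + bn)


def hh_init(n: int, params: HHParams = HHParams(), dtype=np.float32) -> HHState:
    v0, m0, h0, n0 = hh_equilibrium(params)
    return HHState(
        v=np.full(n, v0, dtype=dtype), m=np.full(n, m0, dtype=dtype),
        h=np.full(n, h0, dtype=dtype), n=np.full(n, n0, dtype=dtype),
        S=np.zeros(n, dtype=np.uint8),
    )


def hh_step(state: HHState, input_current: np.ndarray, params: HHParams,
            dt: float) -> HHState:
    """Exponential-Euler gating update, forward-Euler voltage update.

    A spike is an upward crossing of ``spike_thresh`` (0 mV); gating
    variables stay in [0,1] by construction of the exponential-Euler map
    and are clipped defensively.
    """
    p = params
    v = state.v.astype(np.float64)
    m, h, n = (state.m.astype(np.float64), state.h.astype(np.float64),
               state.n.astype(np.float64))
    I = np.asarray(input_current, dtype=np.float64)
    am, bm, ah, bh, an, bn = hh_rates(v)
    for gate, alpha, beta in ((0, am, bm), (1, ah, bh), (2, an, bn)):
        tau = 1.0 / (alpha + beta)
        inf = alpha * tau
        val = inf + ((m, h, n)[gate] - inf) * np.exp(-dt / tau)
        if gate == 0:
            m = val
        elif gate == 1:
            h = val
        else:
            n = val
    I_ion = (p.g_Na * m**3 * h * (v - p.E_Na) + p.g_K * n**4 * (v - p.E_K)
             + p.g_L * (v - p.E_L))
    v_new = v + dt * (I - I_ion) / p.C
    S = (v_new > p.spike_thresh) & (v <= p.spike_thresh)
    dtype = state.v.dtype
    return HHState(
        v=v_new.astype(dtype),
        m=np.clip(m, 0.0, 1.0).astype(dtype),
        h=np.clip(h, 0.0, 1.0).astype(dtype),
        n=np.clip(n, 0.0, 1.0).astype(dtype),
        S=S.astype(np.uint8),
    )


# ---------------------------------------------------------------------------
# Pool components
# ---------------------------------------------------------------------------

try:
    import numba as _numba

    @_numba.njit(cache=False)
    def _lif_kernel(v, theta, r, S, I, decay_m, decay_th, v_rest, theta_base,
                    a, v_reset, r_spike, drive_coef, dt):  # pragma: no cover - numba
        for i in range(v.shape[0]):
            vi = v_rest + (v[i] - v_rest) * decay_m
            if r[i] > 0:
                vi += drive_coef * I[i]
            th = theta_base + (theta[i] - theta_base) * decay_th
            if vi > th:
                S[i] = 1
                v[i] = v_reset
                theta[i] = th + a
                r[i] = -r_spike
            else:
                S[i] = 0
                v[i] = vi
                theta[i] = th
                ri = r[i] + dt
                r[i] = ri if ri < r_spike else r_spike

    _HAVE_LIF_KERNEL = True
except Exception:  # pragma: no cover
    _HAVE_LIF_KERNEL = False


class _SomaPool(Component):
    """Common scaffolding: in-port 'current' (n,), out-port 'spikes' (n,)."""

    param_cls: type = None
    check_every: int = 100

    def configure(self, params: dict) -> None:
        params = dict(params)
        self.n = int(params.pop("n"))
        self.params = self.param_cls(**params)
        self.in_ports = {"current": self.n}
        self.out_ports = {"spikes": self.n}
        self._step_count = 0
        self.reset()

    def reset(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def step(self, inputs: dict) -> dict:
        I = inputs["current"]
        if np.shape(I) != (self.n,):
            raise ValueError(f"component {self.node_id!r} port 'current' expects shape ({self.n},), got {np.shape(I)}")
        self.state = self._advance(I)
        self._step_count += 1
        if self._step_count % self.check_every == 0:
            self.check_finite(self.state.v, self._step_count, "membrane potential")
        S = self.state.S
        # in-place kernels reuse the spike buffer; hand out a copy so
        # previous-tick readers (back edges) stay valid
        if getattr(self, "_use_kernel", False):
            S = S.copy()
        return {"spikes": S}


@register_component
class LIFPool(_SomaPool):
    """LIF pool; uses an in-place compiled kernel in float64 when available,
    falling back to the vectorized functional step (same semantics,
    equivalence-tested)."""

    kind = "lif_pool"
    param_cls = LIFParams

    def reset(self) -> None:
        use_kernel = _HAVE_LIF_KERNEL and self.dtype == np.float32
        # kernel path holds state in float64 for in-place speed; outputs match
        self.state = lif_init(self.n, self.params, dtype=np.float64 if use_kernel else self.dtype)
        self._use_kernel = use_kernel
        p = self.params
        self._consts = (float(np.exp(-self.dt / p.tau_m)), float(np.exp(-self.dt / p.tau_th)),
                        p.v_rest, p.theta_base, p.a, p.v_reset, p.r_spike,
                        self.dt / p.tau_m * p.R, self.dt)

    def _advance(self, I: np.ndarray) -> LIFState:
        if self._use_kernel:
            s = self.state
            _lif_kernel(s.v, s.theta, s.r, s.S, np.asarray(I, dtype=np.float64),
                        *self._consts)
            return s
        return lif_step(self.state, I, self.params, self.dt)


@register_component
class AdExPool(_SomaPool):
    kind = "adex_pool"
    param_cls = AdExParams

    def reset(self) -> None:
        self.state = adex_init(self.n, self.params, dtype=self.dtype)

    def _advance(self, I: np.ndarray) -> AdExState:
        return adex_step(self.state, I, self.params, self.dt)


@register_component
class HHPool(_SomaPool):
    kind = "hh_pool"
    param_cls = HHParams

    def reset(self) -> None:
        self.state = hh_init(self.n, self.params, dtype=self.dtype)

    def _advance(self, I: np.ndarray) -> HHState:
        return hh_step(self.state, I, self.params, self.dt)
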