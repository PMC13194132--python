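"""I/O boundary: population spike encoder and saturable-trace decoder.

The *topological spiker* maps each scalar observation dimension onto a row
of units with Gaussian tuning curves whose centers tile the value range —
a grid-cell-like code.  Distances respect the declared topology: a ``line``
clips values to the range; a ``circle`` glues the borders (wrap-around
distance), so the two range endpoints produce identical spike statistics.
Unit i fires a Bernoulli spike each millisecond with probability
``rate_max * exp(-dist(value, c_i)^2 / (2 sigma^2))``.

The *trace integrator* is k saturable, exponentially decaying traces in
[0, 1], each fed exclusively by one spike population::

    y *= exp(-dt / tau_out);  y += (1 - y) * (1 - exp(-c * spike_count))

The greedy policy picks the argmax trace at the interaction step, ties
broken toward the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Component, ConfigurationError, register_component

__all__ = [
    "SpikerConfig", "tuning_probabilities", "encode",
    "IntegratorState", "integrator_init", "integrate", "select_action",
    "TopologicalSpiker", "TraceIntegrator",
]


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikerConfig:
    n_units: int = 32                       # units per input dimension
    value_range: tuple = ((-1.0, 1.0),)     # (lo, hi) per dimension
    topology: tuple = ("line",)             # 'line' | 'circle' per dimension
    sigma: float = 0.1                      # tuning width, fraction of range
    rate_max: float = 0.5                   # peak spike probability per ms

    def __post_init__(self) -> None:
        if not 0.0 < self.rate_max <= 1.0:
            raise ValueError("rate_max must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for lo, hi in self.value_range:
            if not lo < hi:
                raise ValueError(f"value range must satisfy lo < hi, got ({lo}, {hi})")
        for topo in self.topology:
            if topo not in ("line", "circle"):
                raise ValueError(f"unknown topology {topo!r}")
        if len(self.topology) != len(self.value_range):
            raise ValueError("topology and value_range must have equal length")

    @property
    def n_dims(self) -> int:
        return len(self.value_range)

    @property
    def n_total(self) -> int:
        return self.n_dims * self.n_units


def _centers(cfg: SpikerConfig, dim: int) -> np.ndarray:
    lo, hi = cfg.value_range[dim]
    if cfg.topology[dim] == "circle":
        # endpoint excluded: lo and hi are the same glued point
        return lo + (hi - lo) * np.arange(cfg.n_units) / cfg.n_units
    return np.linspace(lo, hi, cfg.n_units)


def tuning_probabilities(value: np.ndarray, cfg: SpikerConfig) -> np.ndarray:
    """Per-unit firing probability (per ms) for an observation vector."""
    value = np.atleast_1d(np.asarray(value, dtype=float))
    if value.shape != (cfg.n_dims,):
        raise ValueError(f"expected {cfg.n_dims} observation values, got shape {value.shape}")
    if not np.all(np.isfinite(value)):
        raise ValueError("observation contains non-finite values")
    probs = np.empty((cfg.n_dims, cfg.n_units))
    for d in range(cfg.n_dims):
        lo, hi = cfg.value_range[d]
        span = hi - lo
        sig = cfg.sigma * span
        c = _centers(cfg, d)
        if cfg.topology[d] == "circle":
            delta = np.abs(((value[d] - c) + span / 2) % span - span / 2)
        else:
            delta = np.abs(np.clip(value[d], lo, hi) - c)
        probs[d] = cfg.rate_max * np.exp(-delta**2 / (2.0 * sig**2))
    return probs.ravel()


def encode(value: np.ndarray, cfg: SpikerConfig,
           rng: np.random.Generator) -> np.ndarray:
    """One millisecond of Bernoulli spikes for the given observation."""
    p = tuning_probabilities(value, cfg)
    return (rng.random(p.shape) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# Decoder
# ---------------------------------------------------------------------------

@dataclass
class IntegratorState:
    y: np.ndarray          # k traces in [0, 1]
    tau_out: float = 50.0  # trace time constant (ms)
    gain: float = 0.3      # saturating-increment gain per spike


def integrator_init(k: int = 2, tau_out: float = 50.0, gain: float = 0.3) -> IntegratorState:
    return IntegratorState(y=np.zeros(k), tau_out=tau_out, gain=gain)


def integrate(state: IntegratorState, pool_spike_counts: np.ndarray,
              dt: float) -> IntegratorState:
    counts = np.asarray(pool_spike_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    y = state.y * np.exp(-dt / state.tau_out)
    y = y + (1.0 - y) * (1.0 - np.exp(-state.gain * counts))
    return IntegratorState(y=y, tau_out=state.tau_out, gain=state.gain)


def select_action(state: IntegratorState) -> int:
    """Greedy action: argmax trace, lowest index on ties."""
    return int(np.argmax(state.y))


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

@register_component
class TopologicalSpiker(Component):
    """Encoder component: in-port 'value' (n_dims), out-port 'spikes'.

    The firing-probability profile is refreshed from the input every step
    and spikes are redrawn every millisecond from the component's stream.
    """

    kind = "topological_spiker"

    def configure(self, params: dict) -> None:
        self.config = SpikerConfig(
            n_units=int(params.get("n_units", 32)),
            value_range=tuple(tuple(r) for r in params["value_range"]),
            topology=tuple(params.get("topology", ["line"] * len(params["value_range"]))),
            sigma=float(params.get("sigma", 0.1)),
            rate_max=float(params.get("rate_max", 0.5)),
        )
        self.in_ports = {"value": self.config.n_dims}
        self.out_ports = {"spikes": self.config.n_total}
        self._cached_value: np.ndarray | None = None
        self._cached_probs: np.ndarray | None = None

    def step(self, inputs: dict) -> dict:
        value = np.asarray(inputs["value"], dtype=float)
        if self._cached_value is None or not np.array_equal(value, self._cached_value):
            self._cached_probs = tuning_probabilities(value, self.config)
            self._cached_value = value.copy()
        spikes = (self.rng.random(self._cached_probs.shape) < self._cached_probs)
        return {"spikes": spikes.astype(np.uint8)}


@register_component
class TraceIntegrator(Component):
    """Decoder component: one in-port of spikes per trace, out-port 'traces'."""

    kind = "trace_integrator"

    def configure(self, params: dict) -> None:
        self.k = int(params.get("k", 2))
        if self.k < 1:
            raise ConfigurationError("integrator needs at least one trace")
        sizes = params["pool_sizes"]
        if len(sizes) != self.k:
            raise ConfigurationError("pool_sizes must list one population size per trace")
        self.state = integrator_init(self.k, float(params.get("tau_out", 50.0)),
                                     float(params.get("gain", 0.3)))
        self.in_ports = {f"spikes{i}": int(sizes[i]) for i in range(self.k)}
        self.out_ports = {"traces": self.k}

    def step(self, inputs: dict) -> dict:
        counts = np.array([np.sum(inputs[f"spikes{i}"]) for i in range(self.k)], dtype=float)
        self.state = integrate(self.state, counts, self.dt)
        return {"traces": self.state.y.astype(self.dtype)}
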