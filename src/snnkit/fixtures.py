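"""Seeded synthetic generators used by the test suite and the CLI.

Everything here is deterministic under its seed: OU current traces,
Poisson and periodic spike trains, and random spike rasters.
"""

from __future__ import annotations

import numpy as np

from .metrics import OUParams, SpikeTrain, ou_current

__all__ = ["make_fixture", "poisson_train", "periodic_train", "random_raster"]


def poisson_train(rate_hz: float, duration_ms: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson spike train with the stated rate."""
    rng = np.random.default_rng(seed)
    rate_per_ms = rate_hz / 1000.0
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_per_ms) if rate_per_ms > 0 else np.inf
        if t >= duration_ms:
            break
        times.append(t)
    return SpikeTrain(times=np.array(times), T=duration_ms)


def periodic_train(period_ms: float, duration_ms: float, phase_ms: float = 0.0) -> SpikeTrain:
    """Regular train: spikes at phase, phase + p, ... within [0, T]."""
    if period_ms <= 0:
        raise ValueError("period must be positive")
    times = np.arange(phase_ms, duration_ms, period_ms)
    times = times[(times >= 0) & (times < duration_ms)]
    return SpikeTrain(times=times, T=duration_ms)


def random_raster(n_units: int, n_steps: int, p_spike: float, seed: int) -> np.ndarray:
    """(n_steps, n_units) Bernoulli raster."""
    rng = np.random.default_rng(seed)
    return (rng.random((n_steps, n_units)) < p_spike).astype(np.uint8)


def make_fixture(kind: str, params: dict, seed: int):
    """Dispatch by kind: ou_trace | poisson_train | periodic_train | random_raster."""
    if kind == "ou_trace":
        ou = OUParams(mean=params.get("mean", 0.0), sigma=params.get("sigma", 1.0),
                      tau_ou=params.get("tau_ou", 5.0), dt=params.get("dt", 0.1),
                      seed=seed)
        return ou_current(ou, int(params["n_steps"]))
    if kind == "poisson_train":
        return poisson_train(params["rate_hz"], params["duration_ms"], seed)
    if kind == "periodic_train":
        return periodic_train(params["period_ms"], params["duration_ms"],
                              params.get("phase_ms", 0.0))
    if kind == "random_raster":
        return random_raster(params["n_units"], params["n_steps"],
                             params["p_spike"], seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
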