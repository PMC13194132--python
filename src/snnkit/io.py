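"""Small text/binary exchange helpers for rasters and spike trains.

Rasters travel as two-column CSV (unit_id, time_ms); spike trains as
one-column CSV with the duration in the header; weight payloads as
compressed ``.npz`` with a small header (shape, dt, seed) — see
:meth:`snnkit.training.CartpoleAgent.save_weights`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import SpikeTrain

__all__ = ["raster_to_csv", "raster_from_csv", "spike_train_to_csv",
           "spike_train_from_csv"]


def raster_to_csv(path, spikes: np.ndarray, dt: float) -> None:
    """Write a (n_steps, n_units) binary raster as (unit_id, time_ms) rows."""
    steps, units = np.nonzero(np.asarray(spikes))
    frame = pd.DataFrame({"unit_id": units, "time_ms": (steps + 1) * dt})
    frame.sort_values(["unit_id", "time_ms"]).to_csv(path, index=False)


def raster_from_csv(path, n_units: int, n_steps: int, dt: float) -> np.ndarray:
    frame = pd.read_csv(path)
    raster = np.zeros((n_steps, n_units), dtype=np.uint8)
    steps = np.round(frame.time_ms.to_numpy() / dt).astype(int) - 1
    raster[steps, frame.unit_id.to_numpy()] = 1
    return raster


def spike_train_to_csv(path, train: SpikeTrain) -> None:
    header = f"time_ms (T={train.T!r})"
    np.savetxt(path, train.times, header=header, comments="# ")


def spike_train_from_csv(path) -> SpikeTrain:
    text = Path(path).read_text().splitlines()
    if not text or "T=" not in text[0]:
        raise ValueError(f"{path}: missing duration header")
    T = float(text[0].split("T=")[1].rstrip(")"))
    times = np.loadtxt(path, ndmin=1)
    return SpikeTrain(times=times, T=T)
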