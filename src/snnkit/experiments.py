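"""Canonical end-to-end protocols: agent training/evaluation and fidelity.

These are the study procedures the package reproduces, wired to the
recorded working parameter set (the defaults of
:func:`snnkit.training.cartpole_blueprint` and
:class:`snnkit.training.ModulationState`):

* :func:`train_and_test_agent` — train one mutual-inhibition agent online
  with sparse terminal reward for at most ``max_episodes`` (stopping once
  it strings together ``cap_streak`` maximum-length episodes), freeze all
  plasticity, and evaluate frozen test episodes.
* :func:`learning_speed_trial` — across several seeds, the training-episode
  index at which each seed first reaches a maximum-length (cap) episode.
* :func:`fidelity_fraction` — fraction of OU-driven trials whose
  record-vs-reference spike-train distances fall below the
  record-vs-shuffled baseline, per soma model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics
from .training import (
    CartpoleAgent, ModulationState, TrainConfig, cartpole_blueprint,
    evaluate_frozen, train,
)

__all__ = [
    "AgentRunResult", "train_and_test_agent", "learning_speed_trial",
    "fidelity_fraction", "SOMA_DT_MS",
]

# step sizes of record for the fidelity harness
SOMA_DT_MS = {"lif": 0.1, "adex": 0.1, "hh": 0.05}


@dataclass
class AgentRunResult:
    seed: int
    train_lengths: list[int]
    test_lengths: list[int]
    first_cap_episode: int  # -1 if the cap was never reached in training

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_lengths)) if self.test_lengths else 0.0


def train_and_test_agent(seed: int, max_episodes: int = 300,
                         test_episodes: int = 50, cap_streak: int = 3,
                         n_max: int = 500) -> AgentRunResult:
    """The single-agent protocol: online training then frozen evaluation."""
    blueprint = cartpole_blueprint()
    agent = CartpoleAgent(blueprint, seed=seed)
    mod = ModulationState(N_max=n_max)
    config = TrainConfig(episodes_train=max_episodes, seed=seed, n_max=n_max,
                         early_stop_cap_streak=cap_streak)
    result = train(config, agent=agent, mod=mod)
    lengths = result.lengths
    test = evaluate_frozen(agent, episodes=test_episodes,
                           seed=seed + 424243, config=config)
    arr = np.asarray(lengths)
    first = int(np.argmax(arr >= n_max)) if np.any(arr >= n_max) else -1
    return AgentRunResult(seed=seed, train_lengths=lengths, test_lengths=test,
                          first_cap_episode=first)


def learning_speed_trial(seeds: list[int], max_episodes: int = 120,
                         n_max: int = 500) -> dict[int, int]:
    """Per-seed index of the first maximum-length training episode (-1 if
    never reached); each seed stops as soon as it gets there."""
    out: dict[int, int] = {}
    for seed in seeds:
        agent = CartpoleAgent(cartpole_blueprint(), seed=seed)
        mod = ModulationState(N_max=n_max)
        config = TrainConfig(episodes_train=max_episodes, seed=seed, n_max=n_max,
                             early_stop_cap_streak=1)
        result = train(config, agent=agent, mod=mod)
        arr = np.asarray(result.lengths)
        out[seed] = int(np.argmax(arr >= n_max)) if np.any(arr >= n_max) else -1
    return out


def fidelity_fraction(soma_kind: str, seed: int = 0, n_trials: int = 100,
                      duration_ms: float = 1000.0) -> dict[str, float]:
    """Fraction of trials with record-vs-reference distances strictly below
    the record-vs-shuffled baseline (ISI- and SPIKE-distance jointly and
    separately), plus median distances."""
    df = metrics.fidelity_report(soma_kind, dt_record=SOMA_DT_MS[soma_kind],
                                 n_trials=n_trials, duration_ms=duration_ms,
                                 seed=seed)
    ok = df.dropna()
    if len(ok) == 0:
        raise RuntimeError(f"no valid trials for soma {soma_kind!r}")
    both = (ok.isi_d < ok.isi_d_shuffled) & (ok.spike_d < ok.spike_d_shuffled)
    return {
        "n_valid": int(len(ok)),
        "fraction_both_below": float(both.mean()),
        "fraction_isi_below": float((ok.isi_d < ok.isi_d_shuffled).mean()),
        "fraction_spike_below": float((ok.spike_d < ok.spike_d_shuffled).mean()),
        "median_isi_d": float(ok.isi_d.median()),
        "median_spike_d": float(ok.spike_d.median()),
    }
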