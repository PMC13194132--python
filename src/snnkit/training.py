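"""Online sparse-reward training of the two-population cartpole agent.

The agent (mutual-inhibition architecture): a topological spiker encodes
the four cartpole observations; two motor populations of 256 excitatory
LIF units ("left", "right"), each with a 64-unit inhibitory partner pool
that suppresses the *opposite* motor; a two-trace exponential integrator
reads the excitatory spikes and a greedy policy picks the action.  The
spiker-to-motor synapses are plastic under the three-factor STDP rule.

The network runs 50 simulated ms per environment step with the input held
fixed (the interaction step).  The reward is sparse: during an episode
every plasticity update uses the small background factor lambda; only
when the episode ends in failure (pole fell, or cart out of bounds) is a
reward-linked modulation delivered, during ONE extra interaction step
driven by the final observation::

    R_step  = -1 on failure (0 on truncation at the episode cap)
    M_3rd(t) = (N_ema / N_max) * R_step * exp(-tau_R * (t - t_step))   if R_step != 0
             = lambda                                                  otherwise

``N_ema`` is an exponential moving average of episode lengths, updated
once per episode after the extra step.  The modulation is delivered
independently per motor: the motor whose action is being suppressed (the
action chosen last, which drove the failure) receives M_3rd; the other
motor receives -xi * M_3rd (a small opposite-sign factor that promotes
synaptic growth and stabilizes the agent).

Freezing (evaluation) forces all modulation to zero, which makes weight
and structural updates exact no-ops: the frozen trajectory is bit-identical
to a run with M_3rd == 0 throughout.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .cartpole import LEFT, RIGHT, CartpoleEnv, CartpoleParams
from .core import Blueprint, EdgeSpec, NodeSpec, ModelInstance, build_model
from .interfaces import select_action, IntegratorState

__all__ = [
    "ModulationState", "TrainConfig", "compute_rstep", "compute_m3rd",
    "deliver_modulation", "cartpole_blueprint", "CartpoleAgent",
    "run_episode", "train", "evaluate_frozen", "TrainResult",
]


# ---------------------------------------------------------------------------
# Modulation
# ---------------------------------------------------------------------------

@dataclass
class ModulationState:
    N_max: int = 500          # episode cap of the environment
    N_ema: float = 0.0        # EMA of episode lengths (env steps)
    t_step: float = 0.0       # time of the last interaction step (ms)
    R_step: int = 0           # {-1, 0}
    lambda_bg: float = 5e-5   # background modulation constant
    xi: float = 0.3           # opposite-motor gain
    tau_R: float = 0.02       # modulation decay constant (1/ms)
    ema_coef: float = 0.05    # EMA update coefficient
    episodes_seen: int = 0

    def update_ema(self, episode_length: int) -> None:
        if self.episodes_seen == 0:
            self.N_ema = float(episode_length)
        else:
            self.N_ema = (1.0 - self.ema_coef) * self.N_ema + self.ema_coef * episode_length
        self.episodes_seen += 1


def compute_rstep(pole_fell: bool, oob: bool) -> int:
    """-1 if the episode failed (pole fell or cart out of bounds), else 0.

    Truncation at the episode cap is not a failure."""
    return -1 if (pole_fell or oob) else 0


def compute_m3rd(mod: ModulationState, t: float) -> float:
    """The third factor at time t (ms): the reward branch when R_step != 0,
    otherwise the background constant lambda."""
    if mod.R_step != 0:
        return (mod.N_ema / mod.N_max) * mod.R_step * math.exp(-mod.tau_R * (t - mod.t_step))
    return mod.lambda_bg


def deliver_modulation(m3rd: float, chosen_action: int,
                       mod: ModulationState) -> dict[int, float]:
    """Per-motor modulation map.

    On failure the suppressed motor (the one whose action was chosen last)
    receives m3rd; the other receives -xi * m3rd.  Outside reward events
    both motors receive the background constant."""
    if mod.R_step == 0:
        return {LEFT: mod.lambda_bg, RIGHT: mod.lambda_bg}
    other = RIGHT if chosen_action == LEFT else LEFT
    return {chosen_action: m3rd, other: -mod.xi * m3rd}


# ---------------------------------------------------------------------------
# Agent blueprint
# ---------------------------------------------------------------------------

def cartpole_blueprint(
    n_exc: int = 256,
    n_inh: int = 64,
    n_encoder_units: int = 32,
    dt_ms: float = 1.0,
    rate_max: float = 0.5,
    sigma: float = 0.1,
    w_max_in: float = 1.5,
    w_min_in: float = 0.3,
    density_in: float = 0.25,
    w_max_ei: float = 6.0,
    density_ei: float = 0.4,
    w_max_ie: float = 3.0,
    density_ie: float = 0.4,
    tau_s: float = 5.0,
    d_max_ms: float = 10.0,
    tau_out: float = 50.0,
    gain: float = 0.02,
    e_theta_a: float = 2.0,
    e_tau_th: float = 50.0,
    eta: float = 0.075,
    alpha: float = -0.1,
    beta: float = 1.0,
    gamma: float = 0.0,
    delta: float = -0.1,
    tau_pre: float = 300.0,
    tau_post: float = 300.0,
    prune_eps: float = 0.0,
    growth_prob: float = 0.0,
    growth_w: float = 0.0,
) -> Blueprint:
    """Blueprint of the mutual-inhibition cartpole agent.

    Observation encoding ranges span the environment's termination bounds:
    cart position +-2.4 m, pole angle +-12 deg, both velocities clipped to
    +-3 (m/s, rad/s).  All four dimensions are encoded on line segments.
    """
    angle = 12.0 * math.pi / 180.0
    spiker = NodeSpec(kind="topological_spiker", params={
        "n_units": n_encoder_units,
        "value_range": [[-2.4, 2.4], [-3.0, 3.0], [-angle, angle], [-3.0, 3.0]],
        "topology": ["line", "line", "line", "line"],
        "sigma": sigma, "rate_max": rate_max,
    })
    n_in = 4 * n_encoder_units
    plasticity = {
        "eta": eta, "alpha": alpha, "beta": beta, "gamma": gamma, "delta": delta,
        "tau_pre": tau_pre, "tau_post": tau_post, "w_min": w_min_in, "w_max": w_max_in,
        "prune_eps": prune_eps, "growth_prob": growth_prob, "growth_w": growth_w,
    }
    nodes = {"spiker": spiker}
    edges: list[EdgeSpec] = []
    for side in ("left", "right"):
        other = "right" if side == "left" else "left"
        nodes[f"e_{side}"] = NodeSpec(kind="lif_pool", params={
            "n": n_exc, "a": e_theta_a, "tau_th": e_tau_th})
        # fast-spiking inhibitory partners: no threshold adaptation,
        # short refractory period
        nodes[f"i_{side}"] = NodeSpec(kind="lif_pool", params={
            "n": n_inh, "a": 0.0, "r_spike": 2.0})
        nodes[f"syn_in_{side}"] = NodeSpec(kind="traced_synapse", params={
            "n_pre": n_in, "n_post": n_exc, "sign": 1, "density": density_in,
            "w_max": w_max_in, "w_min": w_min_in, "tau_s": tau_s, "d_max_ms": d_max_ms,
            "plastic": True, "plasticity": plasticity,
        })
        nodes[f"syn_ei_{side}"] = NodeSpec(kind="traced_synapse", params={
            "n_pre": n_exc, "n_post": n_inh, "sign": 1, "density": density_ei,
            "w_max": w_max_ei, "tau_s": tau_s, "d_max_ms": d_max_ms,
        })
        # inhibitory pool of `side` suppresses the *other* motor
        nodes[f"syn_cross_{side}"] = NodeSpec(kind="traced_synapse", params={
            "n_pre": n_inh, "n_post": n_exc, "sign": -1, "density": density_ie,
            "w_max": w_max_ie, "tau_s": tau_s, "d_max_ms": d_max_ms,
        })
        edges += [
            EdgeSpec(source="spiker", source_port="spikes",
                     target=f"syn_in_{side}", target_port="spikes"),
            EdgeSpec(source=f"syn_in_{side}", source_port="current",
                     target=f"e_{side}", target_port="current"),
            EdgeSpec(source=f"e_{side}", source_port="spikes",
                     target=f"syn_in_{side}", target_port="post_spikes"),
            EdgeSpec(source=f"e_{side}", source_port="spikes",
                     target=f"syn_ei_{side}", target_port="spikes"),
            EdgeSpec(source=f"syn_ei_{side}", source_port="current",
                     target=f"i_{side}", target_port="current"),
            EdgeSpec(source=f"i_{side}", source_port="spikes",
                     target=f"syn_cross_{side}", target_port="spikes"),
            EdgeSpec(source=f"syn_cross_{side}", source_port="current",
                     target=f"e_{other}", target_port="current"),
        ]
    nodes["integ"] = NodeSpec(kind="trace_integrator", params={
        "k": 2, "pool_sizes": [n_exc, n_exc], "tau_out": tau_out, "gain": gain})
    edges += [
        EdgeSpec(source="e_left", source_port="spikes", target="integ", target_port="spikes0"),
        EdgeSpec(source="e_right", source_port="spikes", target="integ", target_port="spikes1"),
    ]
    return Blueprint(nodes=nodes, edges=edges,
                     metadata={"dt": repr(dt_ms), "description": "mutual-inhibition cartpole agent"})


# ---------------------------------------------------------------------------
# Agent
# ---------------------------------------------------------------------------

class CartpoleAgent:
    """Executable agent: built model plus the motor-synapse handles."""

    def __init__(self, blueprint: Blueprint | None = None, seed: int = 0,
                 precision: str = "float32") -> None:
        self.blueprint = blueprint if blueprint is not None else cartpole_blueprint()
        self.model: ModelInstance = build_model(self.blueprint, precision=precision, seed=seed)
        self.seed = seed
        self.motor_syn = {LEFT: self.model.component("syn_in_left"),
                          RIGHT: self.model.component("syn_in_right")}
        self.dt = self.model.clock.dt

    # -- modulation handles ----------------------------------------------
    def set_modulation(self, per_motor: dict[int, float]) -> None:
        for motor, value in per_motor.items():
            self.motor_syn[motor].modulation = value

    def structural_step(self) -> None:
        for syn in self.motor_syn.values():
            syn.structural_step()

    # -- network interaction ---------------------------------------------
    def interact(self, observation: np.ndarray, n_steps: int,
                 modulation_fn=None) -> np.ndarray:
        """Hold ``observation`` for ``n_steps`` network steps.

        ``modulation_fn(t_ms) -> {motor: value}`` resolves the per-motor
        modulation each millisecond; returns the integrator traces at the
        end of the window."""
        obs = np.asarray(observation, dtype=float)
        traces = None
        for _ in range(n_steps):
            if modulation_fn is not None:
                self.set_modulation(modulation_fn(self.model.clock.t))
            out = self.model.step({("spiker", "value"): obs})
            traces = out[("integ", "traces")]
        return np.asarray(traces, dtype=float)

    def act(self, traces: np.ndarray) -> int:
        return select_action(IntegratorState(y=np.asarray(traces, dtype=float)))

    # -- weights ----------------------------------------------------------
    def weight_payload(self) -> dict[str, np.ndarray]:
        payload: dict[str, np.ndarray] = {}
        for name, syn in (("left", self.motor_syn[LEFT]), ("right", self.motor_syn[RIGHT])):
            w = syn.get_weights()
            payload[f"{name}_W"] = w["W"]
            payload[f"{name}_mask"] = w["mask"]
            payload[f"{name}_delays"] = w["delays"]
        return payload

    def load_weight_payload(self, payload: dict[str, np.ndarray]) -> None:
        for name, motor in (("left", LEFT), ("right", RIGHT)):
            self.motor_syn[motor].set_weights({
                "W": payload[f"{name}_W"], "mask": payload[f"{name}_mask"],
                "delays": payload[f"{name}_delays"]})

    def weight_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for key in sorted(self.weight_payload()):
            h.update(np.ascontiguousarray(self.weight_payload()[key]).tobytes())
        return h.hexdigest()

    def save_weights(self, path) -> None:
        np.savez_compressed(path, seed=np.int64(self.seed), dt=np.float64(self.dt),
                            **self.weight_payload())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_weight_payload({k: data[k] for k in data.files if k not in ("seed", "dt")})


# ---------------------------------------------------------------------------
# Episode loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    interaction_ms: float = 50.0
    episodes_train: int = 300
    episodes_test: int = 50
    seed: int = 0
    n_max: int = 500
    precision: str = "float32"
    early_stop_cap_streak: int | None = 3   # stop after this many consecutive max-length episodes
    restore_best: bool = True               # end training on the best checkpoint seen
    snapshot_every: int | None = None
    structural_every_interaction: bool = True

    def __post_init__(self) -> None:
        pass


@dataclass
class EpisodeRecord:
    episode: int
    length: int
    reward_event: int  # R_step delivered at the end (-1 failure, 0 cap)
    n_ema: float


@dataclass
class TrainResult:
    episodes: list[EpisodeRecord]
    agent: CartpoleAgent
    mod: ModulationState

    @property
    def lengths(self) -> list[int]:
        return [e.length for e in self.episodes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.episodes])


def run_episode(agent: CartpoleAgent, env: CartpoleEnv, mod: ModulationState,
                config: TrainConfig, frozen: bool = False,
                modulation_log: list | None = None,
                modulation_override: float | None = None) -> int:
    """One online episode; returns its length in environment steps.

    With ``frozen`` all modulation is forced to zero (weights untouched,
    structural turnover off).  ``modulation_override`` pins every modulation
    value (background and terminal alike) to a constant while leaving the
    plasticity machinery running — overriding with 0.0 reproduces the
    frozen trajectory exactly."""
    n_steps = int(round(config.interaction_ms / agent.dt))
    state = env.reset()
    mod.R_step = 0
    action = LEFT

    def background(_t: float) -> dict[int, float]:
        if frozen:
            value = 0.0
        elif modulation_override is not None:
            value = modulation_override
        else:
            value = mod.lambda_bg
        if modulation_log is not None:
            modulation_log.append(value)
        return {LEFT: value, RIGHT: value}

    while True:
        traces = agent.interact(state.observation, n_steps, modulation_fn=background)
        if not frozen and config.structural_every_interaction:
            agent.structural_step()
        action = agent.act(traces)
        state = env.step(action)
        if state.terminated:
            break

    # extra interaction with the final observation and the decaying
    # failure modulation (background-only if the episode merely truncated)
    mod.R_step = compute_rstep(state.pole_fell, state.oob)
    mod.t_step = agent.model.clock.t

    def terminal(t: float) -> dict[int, float]:
        if frozen:
            return {LEFT: 0.0, RIGHT: 0.0}
        if modulation_override is not None:
            return {LEFT: modulation_override, RIGHT: modulation_override}
        m3 = compute_m3rd(mod, t)
        return deliver_modulation(m3, action, mod)

    agent.interact(state.observation, n_steps, modulation_fn=terminal)
    if not frozen and config.structural_every_interaction:
        agent.structural_step()
    mod.R_step = 0
    length = state.step_count
    mod.update_ema(length)
    return length


def train(config: TrainConfig, blueprint: Blueprint | None = None,
          agent: CartpoleAgent | None = None,
          mod: ModulationState | None = None,
          start_episode: int = 0,
          progress=None) -> TrainResult:
    """Full online training run (optionally resuming an existing agent).

    With ``restore_best`` the agent's plastic weights are checkpointed
    whenever the rolling three-episode length sum reaches a new maximum
    and restored at the end, so the returned agent carries the best
    policy encountered rather than whatever the final failure left behind
    (online learning keeps adapting — including unlearning — after every
    episode)."""
    if agent is None:
        agent = CartpoleAgent(blueprint=blueprint, seed=config.seed,
                              precision=config.precision)
    if mod is None:
        mod = ModulationState(N_max=config.n_max)
    env = CartpoleEnv(CartpoleParams(n_max=config.n_max), seed=config.seed + 1_000_003)
    records: list[EpisodeRecord] = []
    streak = 0
    best_score, best_payload = None, None
    for ep in range(start_episode, config.episodes_train):
        length = run_episode(agent, env, mod, config)
        records.append(EpisodeRecord(episode=ep, length=length,
                                     reward_event=-1 if length < config.n_max else 0,
                                     n_ema=mod.N_ema))
        if progress is not None:
            progress(records[-1])
        if config.restore_best:
            window = [r.length for r in records[-3:]]
            # consistency first (worst of the window), then total length
            score = (min(window), sum(window)) if len(window) == 3 else (0, sum(window))
            if best_payload is None or score > best_score:
                best_score = score
                best_payload = agent.weight_payload()
        streak = streak + 1 if length >= config.n_max else 0
        if (config.early_stop_cap_streak is not None
                and streak >= config.early_stop_cap_streak):
            break
    if config.restore_best and best_payload is not None:
        agent.load_weight_payload(best_payload)
    return TrainResult(episodes=records, agent=agent, mod=mod)


def evaluate_frozen(agent: CartpoleAgent, episodes: int, seed: int,
                    config: TrainConfig | None = None) -> list[int]:
    """Frozen evaluation: modulation forced to zero; weights bit-identical
    before and after."""
    config = config or TrainConfig()
    env = CartpoleEnv(CartpoleParams(n_max=config.n_max), seed=seed)
    mod = ModulationState(N_max=config.n_max)
    agent.set_modulation({LEFT: 0.0, RIGHT: 0.0})
    lengths = []
    for _ in range(episodes):
        lengths.append(run_episode(agent, env, mod, config, frozen=True))
    return lengths
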