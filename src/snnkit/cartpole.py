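"""Self-contained cartpole dynamics with v0/v1 episode caps.

The classic pole-on-a-cart control task: a rigid pole is hinged on a cart
that can be pushed left or right with a fixed force.  The community
standard parameterization is used (gravity 9.8 m/s^2, cart 1.0 kg, pole
0.1 kg with half-length 0.5 m, force 10 N, step 0.02 s, termination at
|phi| > 12 deg or |x| > 2.4 m), with episode caps of 200 (v0) or 500 (v1)
steps.  Integration is semi-implicit Euler (velocities updated first).

The termination flags distinguish the failure modes the reward-modulation
signal consumes: ``pole_fell`` (angle limit), ``oob`` (cart out of
bounds) and ``truncated`` (episode cap reached without failure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CartpoleParams", "CartpoleState", "env_reset", "env_step", "CartpoleEnv"]

LEFT, RIGHT = 0, 1


@dataclass(frozen=True)
class CartpoleParams:
    gravity: float = 9.8          # m/s^2
    cart_mass: float = 1.0        # kg
    pole_mass: float = 0.1        # kg
    half_length: float = 0.5      # m
    force_mag: float = 10.0       # N
    env_dt: float = 0.02          # s per environment step
    angle_limit: float = 12.0 * math.pi / 180.0  # rad
    position_limit: float = 2.4   # m
    n_max: int = 500              # episode cap: 200 (v0) or 500 (v1)

    def __post_init__(self) -> None:
        for name in ("gravity", "cart_mass", "pole_mass", "half_length",
                     "force_mag", "env_dt", "angle_limit", "position_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_max not in (200, 500):
            raise ValueError("n_max must be 200 (v0) or 500 (v1)")


@dataclass
class CartpoleState:
    x: float = 0.0        # cart position (m)
    x_dot: float = 0.0    # cart velocity (m/s)
    phi: float = 0.0      # pole angle (rad), 0 = upright
    phi_dot: float = 0.0  # angular velocity (rad/s)
    step_count: int = 0
    pole_fell: bool = False
    oob: bool = False
    truncated: bool = False

    @property
    def terminated(self) -> bool:
        return self.pole_fell or self.oob or self.truncated

    @property
    def observation(self) -> np.ndarray:
        return np.array([self.x, self.x_dot, self.phi, self.phi_dot])


def env_reset(seed: int | None = None,
              rng: np.random.Generator | None = None) -> CartpoleState:
    """All four state variables drawn Uniform(-0.05, 0.05); flags clear."""
    if rng is None:
        rng = np.random.default_rng(seed)
    x, x_dot, phi, phi_dot = rng.uniform(-0.05, 0.05, size=4)
    return CartpoleState(x=x, x_dot=x_dot, phi=phi, phi_dot=phi_dot)


def _accelerations(x_dot: float, phi: float, phi_dot: float, force: float,
                   p: CartpoleParams) -> tuple[float, float]:
    total_mass = p.cart_mass + p.pole_mass
    pole_ml = p.pole_mass * p.half_length
    sin_phi, cos_phi = math.sin(phi), math.cos(phi)
    temp = (force + pole_ml * phi_dot**2 * sin_phi) / total_mass
    phi_acc = (p.gravity * sin_phi - cos_phi * temp) / (
        p.half_length * (4.0 / 3.0 - p.pole_mass * cos_phi**2 / total_mass))
    x_acc = temp - pole_ml * phi_acc * cos_phi / total_mass
    return x_acc, phi_acc


def env_step(state: CartpoleState, action: int,
             params: CartpoleParams = CartpoleParams()) -> CartpoleState:
    """Apply one push and integrate one environment step.

    Raises if the episode already terminated (flags must be honoured).
    """
    if state.terminated:
        raise RuntimeError("env_step called on a terminated episode; reset first")
    if action not in (LEFT, RIGHT):
        raise ValueError(f"action must be {LEFT} (left) or {RIGHT} (right)")
    force = params.force_mag if action == RIGHT else -params.force_mag
    x_acc, phi_acc = _accelerations(state.x_dot, state.phi, state.phi_dot,
                                    force, params)
    tau = params.env_dt
    x_dot = state.x_dot + tau * x_acc
    phi_dot = state.phi_dot + tau * phi_acc
    x = state.x + tau * x_dot
    phi = state.phi + tau * phi_dot
    count = state.step_count + 1
    pole_fell = abs(phi) > params.angle_limit
    oob = abs(x) > params.position_limit
    truncated = (not pole_fell) and (not oob) and count >= params.n_max
    return CartpoleState(x=x, x_dot=x_dot, phi=phi, phi_dot=phi_dot,
                         step_count=count, pole_fell=pole_fell, oob=oob,
                         truncated=truncated)


class CartpoleEnv:
    """Thin stateful wrapper around the pure-function dynamics."""

    def __init__(self, params: CartpoleParams = CartpoleParams(),
                 seed: int | None = None) -> None:
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.state = env_reset(rng=self.rng)

    def reset(self) -> CartpoleState:
        self.state = env_reset(rng=self.rng)
        return self.state

    def step(self, action: int) -> CartpoleState:
        self.state = env_step(self.state, action, self.params)
        return self.state
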