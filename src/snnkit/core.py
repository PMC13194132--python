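"""Simulation clock, blueprints, and blueprint-driven model assembly.

A model is a directed graph of self-contained stateful components.  The
:class:`Blueprint` is a declarative, serializable description of that graph
(nodes = component kind + parameters, edges = port-to-port connections),
kept separate from the executable :class:`ModelInstance` built from it.

Execution semantics
-------------------
Components are stepped once per tick in a fixed, deterministic order:
topological order of the blueprint graph, with cycles broken by one-step
delayed edges.  An edge whose source has already been stepped in the
current tick delivers the fresh output; an edge whose source comes later
in the order (a back edge closing a cycle) delivers the previous tick's
output.  This is the standard synchronous-update convention and makes
recurrent/inhibitory loops well defined.

Multiple edges targeting the same input port are summed elementwise
(currents superpose; spike vectors from distinct sources add as counts).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import Any

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError as _PydanticValidationError

BLUEPRINT_SCHEMA_VERSION = "1"


class ConfigurationError(ValueError):
    """A blueprint references an unknown component kind or invalid parameter."""


class BlueprintValidationError(ValueError):
    """A blueprint violates a structural invariant (dangling edges, duplicate ids...)."""


class NumericalInstabilityError(FloatingPointError):
    """A component state became non-finite during stepping."""


# ---------------------------------------------------------------------------
# Blueprint
# ---------------------------------------------------------------------------

class NodeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str
    params: dict[str, Any] = Field(default_factory=dict)


class EdgeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    source: str  # node id
    source_port: str
    target: str  # node id
    target_port: str

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.source, self.source_port, self.target, self.target_port)


class Blueprint(BaseModel):
    """Declarative component graph: nodes, port-to-port edges, metadata."""

    model_config = ConfigDict(extra="forbid")
    version: str = BLUEPRINT_SCHEMA_VERSION
    nodes: dict[str, NodeSpec] = Field(default_factory=dict)
    edges: list[EdgeSpec] = Field(default_factory=list)
    metadata: dict[str, str] = Field(default_factory=dict)


def serialize_blueprint(bp: Blueprint) -> str:
    """Canonical structured-text form: sorted keys, sorted edges, fixed floats.

    ``serialize(deserialize(text))`` is byte-identical to ``text`` for text
    already in canonical form.
    """
    payload = bp.model_dump(mode="json")
    payload["edges"] = sorted(payload["edges"], key=lambda e: (e["source"], e["source_port"], e["target"], e["target_port"]))
    return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def deserialize_blueprint(text: str) -> Blueprint:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BlueprintValidationError(f"malformed blueprint text at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(payload, dict):
        raise BlueprintValidationError("blueprint text must encode a mapping")
    version = payload.get("version", None)
    if version != BLUEPRINT_SCHEMA_VERSION:
        raise BlueprintValidationError(
            f"unsupported blueprint schema version {version!r}; this build reads version {BLUEPRINT_SCHEMA_VERSION!r}"
        )
    try:
        return Blueprint.model_validate(payload)
    except _PydanticValidationError as exc:
        raise BlueprintValidationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Clock
# ---------------------------------------------------------------------------

@dataclass
class SimulationClock:
    """Integer step accounting; ``t`` is always derived as ``step_index * dt``."""

    dt: float
    step_index: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")

    @property
    def t(self) -> float:
        return self.step_index * self.dt

    def advance(self) -> None:
        self.step_index += 1


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

def component_rng(global_seed: int, node_id: str) -> np.random.Generator:
    """Named counter-based stream per component, derived from (seed, node id).

    Independent of build order: the stream key mixes the global seed with a
    stable hash of the node id.
    """
    key = zlib.crc32(node_id.encode("utf-8"))
    return np.random.Generator(np.random.Philox(key=np.array([global_seed, key], dtype=np.uint64)))


class Component:
    """Base class: a named stateful unit with typed input/output ports.

    Subclasses declare ``in_ports`` / ``out_ports`` as ``{name: size}`` maps
    and implement :meth:`step`, which consumes one array per input port and
    returns one array per output port.
    """

    kind: str = "abstract"

    def __init__(self, node_id: str, params: dict[str, Any], dt: float,
                 dtype: np.dtype, rng: np.random.Generator) -> None:
        self.node_id = node_id
        self.dt = dt
        self.dtype = np.dtype(dtype)
        self.rng = rng
        self.in_ports: dict[str, int] = {}
        self.out_ports: dict[str, int] = {}
        self.configure(params)

    def configure(self, params: dict[str, Any]) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def step(self, inputs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def check_finite(self, arr: np.ndarray, step_index: int, what: str) -> None:
        if not np.all(np.isfinite(arr)):
            raise NumericalInstabilityError(
                f"component {self.node_id!r}: non-finite {what} at step {step_index}"
            )


_REGISTRY: dict[str, type[Component]] = {}


def register_component(cls: type[Component]) -> type[Component]:
    _REGISTRY[cls.kind] = cls
    return cls


def registered_kinds() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# Model building and stepping
# ---------------------------------------------------------------------------

def _execution_order(bp: Blueprint) -> list[str]:
    """Topological order; cycles broken deterministically.

    Iterative Kahn's algorithm with lexicographic tie-break.  When no node
    has zero remaining in-degree (a cycle), the lexicographically smallest
    remaining node is released, which turns its unresolved incoming edges
    into one-step-delayed back edges.
    """
    nodes = sorted(bp.nodes)
    indeg = {n: 0 for n in nodes}
    succ: dict[str, set[str]] = {n: set() for n in nodes}
    for e in bp.edges:
        if e.target not in succ[e.source]:
            succ[e.source].add(e.target)
            indeg[e.target] += 1
    order: list[str] = []
    remaining = set(nodes)
    while remaining:
        ready = sorted(n for n in remaining if indeg[n] == 0)
        pick = ready[0] if ready else sorted(remaining)[0]
        order.append(pick)
        remaining.discard(pick)
        for m in succ[pick]:
            if m in remaining:
                indeg[m] -= 1
    return order


def validate_blueprint(bp: Blueprint) -> None:
    """Structural validation: known kinds, no dangling edges, ports exist later at build."""
    dangling = [e.as_tuple() for e in bp.edges if e.source not in bp.nodes or e.target not in bp.nodes]
    if dangling:
        raise BlueprintValidationError(f"edges reference missing nodes: {dangling}")
    unknown = {nid: spec.kind for nid, spec in bp.nodes.items() if spec.kind not in _REGISTRY}
    if unknown:
        names = ", ".join(f"node {nid!r} has unknown kind {k!r}" for nid, k in unknown.items())
        raise ConfigurationError(names)


class ModelInstance:
    """Executable model: ordered components, clock, per-component RNG streams."""

    def __init__(self, blueprint: Blueprint, components: dict[str, Component],
                 order: list[str], dt: float, dtype: np.dtype, seed: int) -> None:
        self.blueprint = blueprint
        self.components = components
        self.order = order
        self.clock = SimulationClock(dt=dt)
        self.dtype = np.dtype(dtype)
        self.seed = seed
        # (node, port) -> list of (source node, source port)
        self._in_edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
        consumed: set[tuple[str, str]] = set()
        for e in blueprint.edges:
            self._in_edges.setdefault((e.target, e.target_port), []).append((e.source, e.source_port))
            consumed.add((e.source, e.source_port))
        # external inputs: declared in-ports with no incoming edge
        self.external_in_ports: dict[tuple[str, str], int] = {}
        for nid, comp in components.items():
            for port, size in comp.in_ports.items():
                if (nid, port) not in self._in_edges:
                    self.external_in_ports[(nid, port)] = size
        # sink outputs: declared out-ports never consumed by an edge
        self.sink_out_ports: dict[tuple[str, str], int] = {}
        for nid, comp in components.items():
            for port, size in comp.out_ports.items():
                if (nid, port) not in consumed:
                    self.sink_out_ports[(nid, port)] = size
        self._prev: dict[tuple[str, str], np.ndarray] = {
            (nid, port): np.zeros(size, dtype=self.dtype)
            for nid, comp in components.items() for port, size in comp.out_ports.items()
        }
        # static wiring plan: per node, (port, external key or None, source keys)
        self._plan: list[tuple[Component, list[tuple[str, tuple[str, str] | None, list[tuple[str, str]], int]]]] = []
        for nid in order:
            comp = components[nid]
            entries = []
            for port, size in comp.in_ports.items():
                key = (nid, port)
                if key in self.external_in_ports:
                    entries.append((port, key, [], size))
                else:
                    entries.append((port, None, list(self._in_edges[key]), size))
            self._plan.append((comp, entries))

    # -- stepping ---------------------------------------------------------
    def step(self, external_inputs: dict[tuple[str, str], np.ndarray] | None = None
             ) -> dict[tuple[str, str], np.ndarray]:
        """Advance the clock by one dt, stepping every component exactly once."""
        external_inputs = external_inputs or {}
        for key, arr in external_inputs.items():
            if key not in self.external_in_ports:
                raise BlueprintValidationError(f"no external input port {key}")
            expected = self.external_in_ports[key]
            if np.shape(arr) != (expected,):
                raise BlueprintValidationError(
                    f"port {key} expects shape ({expected},), got {np.shape(arr)}")
        missing = [k for k in self.external_in_ports if k not in external_inputs]
        if missing:
            raise BlueprintValidationError(f"external inputs missing for ports: {missing}")

        fresh: dict[tuple[str, str], np.ndarray] = {}
        prev = self._prev
        for comp, entries in self._plan:
            inputs: dict[str, np.ndarray] = {}
            for port, ext_key, srcs, size in entries:
                if ext_key is not None:
                    inputs[port] = np.asarray(external_inputs[ext_key])
                elif len(srcs) == 1:
                    src = srcs[0]
                    val = fresh.get(src)
                    # components treat inputs as read-only, so no copy
                    inputs[port] = val if val is not None else prev[src]
                elif srcs:
                    acc = None
                    for src in srcs:
                        val = fresh.get(src)
                        if val is None:
                            val = prev[src]
                        acc = val.astype(np.float64) if acc is None else acc + val
                    inputs[port] = acc
                else:
                    inputs[port] = np.zeros(size, dtype=self.dtype)
            outputs = comp.step(inputs)
            nid = comp.node_id
            for port in comp.out_ports:
                fresh[(nid, port)] = np.asarray(outputs[port])
        self._prev.update(fresh)
        self.clock.advance()
        return {key: self._prev[key] for key in self.sink_out_ports}

    # -- conveniences -----------------------------------------------------
    def component(self, node_id: str) -> Component:
        return self.components[node_id]

    def components_of_kind(self, kind: str) -> list[Component]:
        return [self.components[n] for n in self.order if self.components[n].kind == kind]


def build_model(blueprint: Blueprint, precision: str = "float32", seed: int = 0) -> ModelInstance:
    """Instantiate a blueprint into a deterministic executable model.

    Two calls with identical (blueprint, precision, seed) produce
    bit-identical instances: every component draws its initial state from
    its own named stream derived from (seed, node id).
    """
    if precision not in ("float16", "float32", "float64"):
        raise ConfigurationError(f"unsupported precision {precision!r}")
    validate_blueprint(blueprint)
    dtype = np.dtype(precision)
    dt = float(blueprint.metadata.get("dt", "1.0"))
    components: dict[str, Component] = {}
    for nid in sorted(blueprint.nodes):
        spec = blueprint.nodes[nid]
        cls = _REGISTRY[spec.kind]
        try:
            components[nid] = cls(nid, dict(spec.params), dt, dtype, component_rng(seed, nid))
        except (TypeError, KeyError, ValueError) as exc:
            if isinstance(exc, (ConfigurationError, BlueprintValidationError)):
                raise
            raise ConfigurationError(f"node {nid!r} (kind {spec.kind!r}): {exc}") from exc
    # port-level edge validation
    bad = []
    for e in blueprint.edges:
        if e.source_port not in components[e.source].out_ports:
            bad.append(e.as_tuple())
        elif e.target_port not in components[e.target].in_ports:
            bad.append(e.as_tuple())
        elif components[e.source].out_ports[e.source_port] != components[e.target].in_ports[e.target_port]:
            bad.append(e.as_tuple())
    if bad:
        raise BlueprintValidationError(f"edges with unknown ports or mismatched sizes: {bad}")
    order = _execution_order(blueprint)
    return ModelInstance(blueprint, components, order, dt, dtype, seed)
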