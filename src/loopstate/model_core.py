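"""Domain types and dynamics of the six-variable feedback-loop model.

The model couples six functional agents — AMPK (``a``), PFK3 (``k``),
APC-Cdh1 (``c``), OXPHOS (``m``), PPP (``p``) and glutamate (``g``) — through
monotone Hill-type activation/inhibition terms, driven by a constant
exogenous input ``u`` (mutant SOD1 acting on OXPHOS).  Each agent obeys

    tau_i * dx_i/dt + x_i = sum of incoming response terms,

so every variable decays linearly and is produced by a bounded, monotone
function of its regulators.  The strength of the single edge shared by all
feedback loops (PFK3 -| PPP, label ``h5``) carries a multiplier ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NODE_ORDER",
    "NODE_NAMES",
    "Edge",
    "SignedNetwork",
    "ResponseFunction",
    "ModelParameterization",
    "hill_activation",
    "hill_inhibition",
    "validate_state",
    "rhs",
    "jacobian",
    "production_bounds",
    "als_network",
]

#: Canonical variable order used for every vector, matrix and table:
#: (AMPK, PFK3, APC-Cdh1, OXPHOS, PPP, GLUTAMATE).
NODE_ORDER: tuple[str, ...] = ("a", "k", "c", "m", "p", "g")

NODE_NAMES: dict[str, str] = {
    "a": "AMPK",
    "k": "PFK3",
    "c": "APC_Cdh1",
    "m": "OXPHOS",
    "p": "PPP",
    "g": "GLUTAMATE",
}


@dataclass(frozen=True)
class Edge:
    """A signed directed interaction, identified by its function label."""

    label: str
    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"edge {self.label}: sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class SignedNetwork:
    """Signed interaction graph with one designated exogenous input node.

    ``edges`` are the internal agent-to-agent interactions; ``input_edges``
    are driven by the constant input ``input_node`` and do not contribute to
    the state dimension.
    """

    node_ids: tuple[str, ...]
    edges: tuple[Edge, ...]
    input_node: str
    input_edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node labels must be unique")
        if self.input_node in self.node_ids:
            raise ValueError("input node must be distinct from state nodes")
        seen: set[tuple[str, str]] = set()
        labels: set[str] = set()
        for e in list(self.edges) + list(self.input_edges):
            if e.label in labels:
                raise ValueError(f"duplicate edge label {e.label!r}")
            labels.add(e.label)
            if e.target not in self.node_ids:
                raise ValueError(f"edge {e.label}: unknown target node {e.target!r}")
            if (e.source, e.target) in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add((e.source, e.target))
        for e in self.edges:
            if e.source not in self.node_ids:
                raise ValueError(f"edge {e.label}: unknown source node {e.source!r}")
        for e in self.input_edges:
            if e.source != self.input_node:
                raise ValueError(f"input edge {e.label}: source must be {self.input_node!r}")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node: str) -> int:
        return self.node_ids.index(node)

    def edge_by_label(self, label: str) -> Edge:
        for e in list(self.edges) + list(self.input_edges):
            if e.label == label:
                return e
        valid = [e.label for e in list(self.edges) + list(self.input_edges)]
        raise KeyError(f"unknown edge label {label!r}; valid labels: {valid}")

    def incoming(self, node: str) -> list[Edge]:
        return [e for e in self.edges if e.target == node]


def als_network() -> SignedNetwork:
    """The built-in six-agent network (nine edges counting the input edge).

    Internal edges: f1 a->k (+), f2 p->m (+), h1 g-|m, h2 g-|c, h3 p-|g,
    h4 c-|k, h5 k-|p, h6 m-|a; input edge h7 u-|m.
    """
    edges = (
        Edge("f1", "a", "k", +1),
        Edge("f2", "p", "m", +1),
        Edge("h1", "g", "m", -1),
        Edge("h2", "g", "c", -1),
        Edge("h3", "p", "g", -1),
        Edge("h4", "c", "k", -1),
        Edge("h5", "k", "p", -1),
        Edge("h6", "m", "a", -1),
    )
    input_edges = (Edge("h7", "u", "m", -1),)
    return SignedNetwork(NODE_ORDER, edges, "u", input_edges)


@dataclass(frozen=True)
class ResponseFunction:
    """Hill-type monotone response.

    * activation:  f(x) = scale * x**n / (1 + saturation * x**n)
    * inhibition:  h(x) = scale / (1 + saturation * x**n)

    ``scale`` plays the role of alpha (activation) or gamma (inhibition);
    ``saturation`` of beta or delta; ``hill`` is the Hill exponent, renamed
    from the conventional symbol to avoid clashing with the PPP variable.
    Exponents below 1 give an unbounded derivative at 0 and are only
    permitted with ``allow_shallow=True``.
    """

    kind: str
    scale: float
    saturation: float
    hill: float
    allow_shallow: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "inhibition"):
            raise ValueError(f"kind must be 'activation' or 'inhibition', got {self.kind!r}")
        for name in ("scale", "saturation", "hill"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")
        if self.hill < 1 and not self.allow_shallow:
            raise ValueError(
                f"hill exponent {self.hill} < 1 gives an unbounded derivative at 0; "
                "pass allow_shallow=True to permit it"
            )

    @property
    def sign(self) -> int:
        return +1 if self.kind == "activation" else -1

    def __call__(self, x: float) -> float:
        x = _check_nonneg(x)
        xn = x**self.hill
        if self.kind == "activation":
            return self.scale * xn / (1.0 + self.saturation * xn)
        return self.scale / (1.0 + self.saturation * xn)

    def derivative(self, x: float) -> float:
        x = _check_nonneg(x)
        n = self.hill
        if x == 0.0:
            if n > 1:
                return 0.0
            if n == 1:
                slope = self.scale if self.kind == "activation" else -self.scale * self.saturation
                return float(slope)
            return np.inf if self.kind == "activation" else -np.inf
        xn = x**n
        denom = (1.0 + self.saturation * xn) ** 2
        if self.kind == "activation":
            return self.scale * n * x ** (n - 1) / denom
        return -self.scale * self.saturation * n * x ** (n - 1) / denom

    @property
    def supremum(self) -> float:
        """Least upper bound of the response on [0, inf)."""
        if self.kind == "activation":
            return self.scale / self.saturation
        return self.scale


def _check_nonneg(x: float) -> float:
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise ValueError(f"activity must be finite and >= 0, got {x}")
    return x


def hill_activation(x: float, fn: ResponseFunction) -> float:
    """Evaluate an activation response; strictly increasing, bounded by scale/saturation."""
    if fn.kind != "activation":
        raise ValueError("hill_activation requires an activation ResponseFunction")
    return fn(x)


def hill_inhibition(x: float, fn: ResponseFunction) -> float:
    """Evaluate an inhibition response; strictly decreasing from scale toward 0."""
    if fn.kind != "inhibition":
        raise ValueError("hill_inhibition requires an inhibition ResponseFunction")
    return fn(x)


@dataclass(frozen=True)
class ModelParameterization:
    """A fully specified model instance.

    ``responses`` maps every edge label (internal and input) to its
    ResponseFunction; ``mu`` multiplies the response of ``mu_edge`` (the
    shared PFK3 -| PPP interaction by default); ``input_level`` is the
    constant value of the exogenous input.
    """

    network: SignedNetwork
    tau: Mapping[str, float]
    responses: Mapping[str, ResponseFunction]
    mu: float = 1.0
    input_level: float = 0.0
    mu_edge: str = "h5"
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.network.node_ids:
            t = self.tau.get(node)
            if t is None:
                raise ValueError(f"missing time constant for node {node!r}")
            if not (np.isfinite(t) and t > 0):
                raise ValueError(f"tau[{node}] must be strictly positive, got {t}")
        for e in list(self.network.edges) + list(self.network.input_edges):
            fn = self.responses.get(e.label)
            if fn is None:
                raise ValueError(f"missing response function for edge {e.label!r}")
            if fn.sign != e.sign:
                raise ValueError(
                    f"edge {e.label}: kind {fn.kind!r} contradicts edge sign {e.sign:+d}"
                )
        if not (np.isfinite(self.mu) and self.mu >= 0):
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not (np.isfinite(self.input_level) and self.input_level >= 0):
            raise ValueError(f"input level must be >= 0, got {self.input_level}")

    def edge_gain(self, label: str) -> float:
        """Multiplier applied to the edge's response (mu on the key edge, else 1)."""
        return self.mu if label == self.mu_edge else 1.0

    def with_mu(self, mu: float) -> "ModelParameterization":
        return replace(self, mu=float(mu))

    def with_input(self, u: float) -> "ModelParameterization":
        return replace(self, input_level=float(u))

    def tau_vector(self) -> np.ndarray:
        return np.array([self.tau[n] for n in self.network.node_ids], dtype=float)


def validate_state(state: Sequence[float], network: SignedNetwork) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (network.n,):
        raise ValueError(f"state must have shape ({network.n},), got {x.shape}")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("state must be finite and nonnegative")
    return x


def _production(x: np.ndarray, params: ModelParameterization) -> np.ndarray:
    net = params.network
    prod = np.zeros(net.n)
    for e in net.edges:
        prod[net.index(e.target)] += params.edge_gain(e.label) * params.responses[e.label](
            x[net.index(e.source)]
        )
    for e in net.input_edges:
        prod[net.index(e.target)] += params.edge_gain(e.label) * params.responses[e.label](
            params.input_level
        )
    return prod


def rhs(state: Sequence[float], params: ModelParameterization) -> np.ndarray:
    """Time derivative: dx_i/dt = (production_i(x, u) - x_i) / tau_i."""
    x = validate_state(state, params.network)
    return (_production(x, params) - x) / params.tau_vector()


def rhs_unscaled(state: Sequence[float], params: ModelParameterization) -> np.ndarray:
    """production(x) - x; shares roots with `rhs` (tau-free equilibrium residual)."""
    x = validate_state(state, params.network)
    return _production(x, params) - x


def jacobian(state: Sequence[float], params: ModelParameterization) -> np.ndarray:
    """Analytic Jacobian of `rhs` at the given state."""
    x = validate_state(state, params.network)
    net = params.network
    tau = params.tau_vector()
    J = np.diag(-1.0 / tau)
    for e in net.edges:
        i, j = net.index(e.target), net.index(e.source)
        J[i, j] += params.edge_gain(e.label) * params.responses[e.label].derivative(x[j]) / tau[i]
    return J


def jacobian_unscaled(state: Sequence[float], params: ModelParameterization) -> np.ndarray:
    """Jacobian of `rhs_unscaled` (production Jacobian minus identity)."""
    x = validate_state(state, params.network)
    net = params.network
    J = -np.eye(net.n)
    for e in net.edges:
        i, j = net.index(e.target), net.index(e.source)
        J[i, j] += params.edge_gain(e.label) * params.responses[e.label].derivative(x[j])
    return J


def production_bounds(params: ModelParameterization) -> np.ndarray:
    """Per-variable upper bound on steady states: sum of incoming suprema.

    Every response term is bounded by its supremum, so at any equilibrium
    x_i = production_i <= bound_i.  Input terms contribute their value at the
    current input level's worst case (the supremum).
    """
    net = params.network
    ub = np.zeros(net.n)
    for e in list(net.edges) + list(net.input_edges):
        ub[net.index(e.target)] += params.edge_gain(e.label) * params.responses[e.label].supremum
    return ub


def unit_parameterization(
    hill: float = 4.0,
    u: float = 0.0,
    mu: float = 1.0,
    network: SignedNetwork | None = None,
) -> ModelParameterization:
    """All scales, saturations and time constants 1, common Hill exponent."""
    net = network if network is not None else als_network()
    responses = {}
    for e in list(net.edges) + list(net.input_edges):
        kind = "activation" if e.sign > 0 else "inhibition"
        responses[e.label] = ResponseFunction(kind, 1.0, 1.0, hill)
    tau = {n: 1.0 for n in net.node_ids}
    return ModelParameterization(net, tau, responses, mu=mu, input_level=u)
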