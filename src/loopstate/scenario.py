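"""Random parameterization sampling and bistable-regime search.

No measured kinetic parameters exist for this model, so analyses run on
synthetic instances: log-uniform draws over order-unity ranges, with steep
Hill exponents as the known lever for bistability.  The shipped reference
fixture is the unit parameterization (all scales, saturations and time
constants 1, Hill exponent 4) at input level u = 2, whose mu-sweep shows a
clean 1 -> 3 -> 1 fold pair; its values are pinned as literals and never
regenerated at import time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from loopstate.bifurcation import sweep_mu
from loopstate.model_core import (
    ModelParameterization,
    ResponseFunction,
    SignedNetwork,
    als_network,
    unit_parameterization,
)

__all__ = [
    "ParameterRanges",
    "sample_parameterization",
    "search_bistable",
    "reference_parameterization",
    "reference_bistable_pair",
    "REFERENCE_MU",
    "REFERENCE_WINDOW",
]

#: Fixture mu sitting mid-window (geometrically) between the two folds.
REFERENCE_MU = 1.3
#: Fold locations of the fixture's mu-sweep, to grid/bisection resolution.
REFERENCE_WINDOW = (1.0217, 1.6426)

# Stable states of the fixture at mu = REFERENCE_MU, pinned at fixture
# creation (Newton-polished to residual < 1e-13); order (a, k, c, m, p, g).
_REFERENCE_HEALTHY = (
    0.09900415067076158,
    0.5095872100535302,
    0.9905526257248908,
    1.73687013223156,
    1.2178747502055258,
    0.3125060229050954,
)
_REFERENCE_PATHOLOGICAL = (
    0.8996792077817436,
    1.3326781643847159,
    0.5095424721767939,
    0.5778642366688157,
    0.3129297946273758,
    0.990501764919743,
)


@dataclass(frozen=True)
class ParameterRanges:
    """Log-uniform sampling bounds (low, high) plus discrete Hill choices."""

    alpha: tuple[float, float] = (0.25, 4.0)
    beta: tuple[float, float] = (0.25, 4.0)
    gamma: tuple[float, float] = (0.25, 4.0)
    delta: tuple[float, float] = (0.25, 4.0)
    tau: tuple[float, float] = (0.5, 2.0)
    hill_choices: tuple[float, ...] = (2.0, 4.0)
    u: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "tau"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} bounds must satisfy 0 < low <= high")
        lo, hi = self.u
        if not (0 <= lo <= hi):
            raise ValueError("u bounds must satisfy 0 <= low <= high")
        if not self.hill_choices or any(h <= 0 for h in self.hill_choices):
            raise ValueError("hill_choices must be positive and nonempty")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameterization(
    ranges: ParameterRanges,
    seed: int,
    network: SignedNetwork | None = None,
) -> ModelParameterization:
    """One random instance; deterministic under (ranges, seed)."""
    rng = np.random.default_rng(seed)
    net = network if network is not None else als_network()
    responses = {}
    for e in list(net.edges) + list(net.input_edges):
        hill = float(rng.choice(ranges.hill_choices))
        if e.sign > 0:
            scale = _loguniform(rng, *ranges.alpha)
            sat = _loguniform(rng, *ranges.beta)
            responses[e.label] = ResponseFunction("activation", scale, sat, hill)
        else:
            scale = _loguniform(rng, *ranges.gamma)
            sat = _loguniform(rng, *ranges.delta)
            responses[e.label] = ResponseFunction("inhibition", scale, sat, hill)
    tau = {n: _loguniform(rng, *ranges.tau) for n in net.node_ids}
    u = float(rng.uniform(*ranges.u))
    return ModelParameterization(
        net,
        tau,
        responses,
        mu=1.0,
        input_level=u,
        provenance={"seed": int(seed), "ranges_hash": ranges.content_hash()},
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def search_bistable(
    ranges: ParameterRanges,
    n_samples: int,
    seed: int = 0,
    mu_grid=None,
    max_hits: int | None = None,
) -> tuple[list[tuple[ModelParameterization, tuple[float, float]]], dict]:
    """Sample instances and keep those whose coarse mu-sweep is bistable.

    Returns (hits, report): each hit is (params, bistable_window); the
    report carries the hit rate and per-sample outcomes.  An empty hit list
    is a valid result, not an error.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mu_grid is None:
        mu_grid = np.logspace(-2, 2, 17)
    seeds = _child_seeds(seed, n_samples)
    hits: list[tuple[ModelParameterization, tuple[float, float]]] = []
    outcomes = []
    n_tried = 0
    for i in range(n_samples):
        n_tried += 1
        params = sample_parameterization(ranges, int(seeds[i]))
        diagram = sweep_mu(
            params,
            mu_grid,
            seed=int(seeds[i]),
            cold_every=4,
            n_starts=16,
            bisect_tol_frac=0.05,
            max_refine=2,
        )
        bistable = diagram.bistable_window is not None and np.any(diagram.stable_counts() >= 2)
        outcomes.append(bool(bistable))
        if bistable:
            hits.append((params, diagram.bistable_window))
            if max_hits is not None and len(hits) >= max_hits:
                break
    report = {
        "n_samples": n_tried,
        "n_hits": len(hits),
        "hit_rate": len(hits) / n_tried,
        "seed": int(seed),
        "ranges_hash": ranges.content_hash(),
        "outcomes": outcomes,
    }
    return hits, report


def reference_parameterization(mu: float = REFERENCE_MU) -> ModelParameterization:
    """The pinned bistable fixture: unit parameters, Hill exponent 4, u = 2.

    Its mu-sweep over [1e-2, 1e2] follows the 1 -> 3 -> 1 pattern with
    folds near REFERENCE_WINDOW; at mu = REFERENCE_MU it has two stable
    equilibria and one unstable.
    """
    p = unit_parameterization(hill=4.0, u=2.0, mu=mu)
    return ModelParameterization(
        p.network,
        p.tau,
        p.responses,
        mu=p.mu,
        input_level=p.input_level,
        provenance={"fixture": "unit-hill4-u2", "window": REFERENCE_WINDOW},
    )


def reference_bistable_pair() -> tuple[np.ndarray, np.ndarray]:
    """(healthy, pathological) stable states of the fixture at mu = REFERENCE_MU."""
    return np.array(_REFERENCE_HEALTHY), np.array(_REFERENCE_PATHOLOGICAL)
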