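"""Bifurcation analysis along the key-interaction strength mu.

The single interaction shared by all feedback loops (PFK3 -| PPP, edge
``h5``) carries a strength multiplier mu.  Sweeping mu produces the
fold-pair / bistable-window picture: equilibrium counts follow 1 -> 3 -> 1,
folds are located by bisection on the stable count, and sweeping mu up then
down exhibits hysteresis.  At mu = 0 the system has a unique equilibrium
with a closed-form expression obtained by forward substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from loopstate.dynamics import (
    Equilibrium,
    _classify_stability,
    _dedup,
    find_equilibria,
    simulate,
    steady_state_from,
)
from loopstate.model_core import ModelParameterization, SignedNetwork

__all__ = [
    "BifurcationDiagram",
    "knockout_equilibrium_closed_form",
    "knockout_edge",
    "sweep_mu",
    "hysteresis_run",
]


@dataclass(frozen=True, eq=False)
class BifurcationDiagram:
    parameter: str
    grid: np.ndarray
    equilibria: tuple[tuple[Equilibrium, ...], ...]  # per grid point, sorted by m
    branches: tuple[tuple[tuple[float, Equilibrium], ...], ...]
    fold_points: tuple[float, ...]
    bistable_window: tuple[float, float] | None
    meta: dict = field(default_factory=dict)

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(e.stable for e in eqs) for eqs in self.equilibria])

    def total_counts(self) -> np.ndarray:
        return np.array([len(eqs) for eqs in self.equilibria])


def knockout_equilibrium_closed_form(params: ModelParameterization) -> Equilibrium:
    """Unique steady state when the shared PFK3 -| PPP interaction is off.

    With the key edge silenced the dependency graph is acyclic and the
    steady state follows by forward substitution:

        p = 0, g = h3(0), c = h2(g), m = h7(u) + h1(g) + f2(0),
        a = h6(m), k = f1(a) + h4(c).

    Requires mu = 0 (precondition error otherwise) and the built-in edge
    labels.
    """
    if params.mu != 0.0:
        raise ValueError(f"closed form requires mu = 0, got mu = {params.mu}")
    r = params.responses
    u = params.input_level
    p = 0.0
    g = r["h3"](p)
    c = r["h2"](g)
    m = r["h7"](u) + r["h1"](g) + r["f2"](p)
    a = r["h6"](m)
    k = r["f1"](a) + r["h4"](c)
    net = params.network
    state = np.zeros(net.n)
    for node, val in (("a", a), ("k", k), ("c", c), ("m", m), ("p", p), ("g", g)):
        state[net.index(node)] = val
    return _classify_stability(params, state)


def knockout_edge(params: ModelParameterization, edge_label: str) -> ModelParameterization:
    """Parameterization with one interaction removed (response identically 0)."""
    net = params.network
    edge = net.edge_by_label(edge_label)  # raises with the valid-label list
    new_net = SignedNetwork(
        net.node_ids,
        tuple(e for e in net.edges if e.label != edge_label),
        net.input_node,
        tuple(e for e in net.input_edges if e.label != edge_label),
    )
    new_responses = {k: v for k, v in params.responses.items() if k != edge_label}
    return ModelParameterization(
        new_net,
        dict(params.tau),
        new_responses,
        mu=params.mu,
        input_level=params.input_level,
        mu_edge=params.mu_edge,
        provenance=dict(params.provenance) | {"knockout": edge_label},
    )


def _equilibria_at(
    params: ModelParameterization,
    mu: float,
    warm: list[np.ndarray],
    seed: int,
    cold: bool,
    n_starts: int,
) -> list[Equilibrium]:
    p = params.with_mu(mu)
    sols: list[np.ndarray] = []
    for x0 in warm:
        x = steady_state_from(p, x0)
        if x is not None:
            sols.append(x)
    if cold or not sols:
        for e in find_equilibria(p, n_starts=n_starts, seed=seed, include_simulations=False):
            sols.append(e.state)
    reps = _dedup(sols)
    eqs = [_classify_stability(p, x) for x in reps]
    eqs.sort(key=lambda e: e.value("m", p.network))
    return eqs


def _assemble_branches(points: list[tuple[float, list[Equilibrium]]]):
    """Nearest-neighbour continuation of equilibria into branches."""
    branches: list[list[tuple[float, Equilibrium]]] = []
    open_tips: list[int] = []
    for mu, eqs in points:
        used = set()
        new_tips = []
        for e in eqs:
            best, best_d = None, np.inf
            for bi in open_tips:
                if bi in used:
                    continue
                prev = branches[bi][-1][1]
                d = float(np.max(np.abs(prev.state - e.state)))
                if d < best_d:
                    best, best_d = bi, d
            scale = 1.0 + float(np.max(np.abs(e.state)))
            if best is not None and best_d < 0.5 * scale:
                branches[best].append((mu, e))
                used.add(best)
                new_tips.append(best)
            else:
                branches.append([(mu, e)])
                new_tips.append(len(branches) - 1)
        open_tips = new_tips
    return tuple(tuple(b) for b in branches)


def sweep_mu(
    params: ModelParameterization,
    mu_grid,
    seed: int = 0,
    cold_every: int = 5,
    n_starts: int = 32,
    bisect_tol_frac: float = 1e-3,
    max_refine: int = 8,
) -> BifurcationDiagram:
    """Equilibrium continuation along an increasing mu grid.

    Warm-started Newton continues every known solution from the previous
    grid point; periodic cold multistarts catch branches that appear away
    from the continued ones.  Fold points are located by bisection on the
    stable-equilibrium count; auto-refinement inserts grid points when the
    count changes by more than one fold at a time.
    """
    grid = np.asarray(mu_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("mu_grid must be a strictly increasing 1-D grid")
    points: list[tuple[float, list[Equilibrium]]] = []
    warm: list[np.ndarray] = []
    for idx, mu in enumerate(grid):
        eqs = _equilibria_at(
            params, mu, warm, seed + idx, cold=(idx % cold_every == 0), n_starts=n_starts
        )
        points.append((float(mu), eqs))
        warm = [e.state for e in eqs]

    # refine intervals where the count jumps by more than one fold (|d stable| > 1)
    refined = True
    depth = 0
    while refined and depth < max_refine:
        refined = False
        depth += 1
        i = 0
        while i < len(points) - 1:
            (mu0, e0), (mu1, e1) = points[i], points[i + 1]
            if abs(sum(e.stable for e in e1) - sum(e.stable for e in e0)) > 1 and (
                mu1 - mu0
            ) > bisect_tol_frac * mu0:
                mid = 0.5 * (mu0 + mu1)
                eqs = _equilibria_at(
                    params, mid, [e.state for e in e0], seed, cold=True, n_starts=n_starts
                )
                points.insert(i + 1, (mid, eqs))
                refined = True
            i += 1

    # folds: bisection on stable-count change between adjacent points
    folds: list[float] = []
    boundary_folds: list[str] = []
    for i in range(len(points) - 1):
        (mu0, e0), (mu1, e1) = points[i], points[i + 1]
        c0, c1 = sum(e.stable for e in e0), sum(e.stable for e in e1)
        if c0 == c1:
            continue
        lo, hi = mu0, mu1
        warm_lo = [e.state for e in e0]
        while (hi - lo) > bisect_tol_frac * max(lo, 1e-12):
            mid = 0.5 * (lo + hi)
            eqs = _equilibria_at(params, mid, warm_lo, seed, cold=True, n_starts=n_starts)
            if sum(e.stable for e in eqs) == c0:
                lo = mid
                warm_lo = [e.state for e in eqs]
            else:
                hi = mid
        folds.append(0.5 * (lo + hi))
    counts = [sum(e.stable for e in eqs) for _, eqs in points]
    window = None
    if any(c >= 2 for c in counts):
        in_win = [mu for (mu, eqs), c in zip(points, counts) if c >= 2]
        lo = min([f for f in folds if f <= min(in_win)] or [grid[0]])
        hi = max([f for f in folds if f >= max(in_win)] or [grid[-1]])
        window = (lo, hi)
        if counts[0] >= 2:
            boundary_folds.append("lower boundary inside window")
        if counts[-1] >= 2:
            boundary_folds.append("upper boundary inside window")
    return BifurcationDiagram(
        parameter="mu",
        grid=np.array([mu for mu, _ in points]),
        equilibria=tuple(tuple(eqs) for _, eqs in points),
        branches=_assemble_branches(points),
        fold_points=tuple(folds),
        bistable_window=window,
        meta={
            "seed": seed,
            "bisect_tol_frac": bisect_tol_frac,
            "boundary_flags": boundary_folds,
            "refine_depth": depth,
        },
    )


def hysteresis_run(
    params: ModelParameterization,
    mu_path,
    seed: int = 0,
    t_relax: float = 400.0,
) -> list[tuple[float, np.ndarray]]:
    """Quasi-static sweep: relax to steady state at each mu, warm-starting
    from the previous attained state (simulation then Newton polish)."""
    path: list[tuple[float, np.ndarray]] = []
    state: np.ndarray | None = None
    for mu in np.asarray(mu_path, dtype=float):
        p = params.with_mu(float(mu))
        if state is None:
            eqs = find_equilibria(p, n_starts=32, seed=seed)
            stable = [e for e in eqs if e.stable]
            state = stable[0].state if stable else np.zeros(p.network.n)
        else:
            traj = simulate(p, np.clip(state, 0.0, None), t_end=t_relax, n_points=2)
            polished = steady_state_from(p, traj.final_state)
            state = polished if polished is not None else traj.final_state
        path.append((float(mu), state.copy()))
    return path
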