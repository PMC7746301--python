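"""Numerical dynamics: simulation, equilibrium finding and classification.

Equilibria solve production(x) = x.  Because every production term is
bounded, all equilibria lie in the box [0, production_bounds]; the finder
combines quasi-random multistart Newton over that box with the endpoints of
long simulations, deduplicates at tolerance, and classifies stability from
the Jacobian spectrum.  Health labels are relative: among coexisting stable
states the high-OXPHOS one is "healthy", and the full six-coordinate
ordering (m, p, c high / a, k, g low at the healthy state) is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from loopstate.model_core import (
    ModelParameterization,
    jacobian,
    production_bounds,
    rhs,
    validate_state,
)

__all__ = [
    "Equilibrium",
    "Trajectory",
    "simulate",
    "find_equilibria",
    "classify_health",
    "verify_influence_numerically",
    "steady_state_from",
]

DEDUP_RTOL = 1e-6
DEDUP_ATOL = 1e-9
STABILITY_MARGIN = 1e-8
RESIDUAL_TOL = 1e-9

#: Coordinates that are high at the healthy state; the rest are low.
HEALTHY_HIGH = ("m", "p", "c")
HEALTHY_LOW = ("a", "k", "g")


@dataclass(frozen=True, eq=False)
class Equilibrium:
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    residual: float
    label: str = "unclassified"

    @property
    def dominant_eigenvalue(self) -> complex:
        return self.eigenvalues[int(np.argmax(self.eigenvalues.real))]

    def value(self, node: str, network) -> float:
        return float(self.state[network.index(node)])

    def relabeled(self, label: str) -> "Equilibrium":
        return replace(self, label=label)


@dataclass(frozen=True, eq=False)
class Trajectory:
    t: np.ndarray
    states: np.ndarray  # shape (len(t), n)
    x0: np.ndarray
    params: ModelParameterization
    meta: dict = field(default_factory=dict)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def final_residual(self) -> float:
        return float(np.max(np.abs(rhs(np.clip(self.final_state, 0.0, None), self.params))))


# ---------------------------------------------------------------------------
# Residual in a form safe for root finders that step outside the orthant


def _clipped_production(x: np.ndarray, params: ModelParameterization) -> np.ndarray:
    net = params.network
    xc = np.clip(x, 0.0, None)
    prod = np.zeros(net.n)
    for e in net.edges:
        prod[net.index(e.target)] += params.edge_gain(e.label) * params.responses[e.label](
            xc[net.index(e.source)]
        )
    for e in net.input_edges:
        prod[net.index(e.target)] += params.edge_gain(e.label) * params.responses[e.label](
            params.input_level
        )
    return prod


def _residual(x: np.ndarray, params: ModelParameterization, forcing: np.ndarray | None = None):
    r = _clipped_production(x, params) - x
    if forcing is not None:
        r = r + forcing
    return r


def _residual_jac(x: np.ndarray, params: ModelParameterization, forcing=None) -> np.ndarray:
    net = params.network
    xc = np.clip(x, 0.0, None)
    J = -np.eye(net.n)
    for e in net.edges:
        i, j = net.index(e.target), net.index(e.source)
        if x[j] >= 0:
            J[i, j] += params.edge_gain(e.label) * params.responses[e.label].derivative(xc[j])
    return J


def _polish(x: np.ndarray, params: ModelParameterization, forcing=None) -> np.ndarray | None:
    """A few damped Newton steps to push the residual to machine level."""
    x = x.copy()
    for _ in range(30):
        r = _residual(x, params, forcing)
        if np.max(np.abs(r)) < 1e-13:
            break
        try:
            step = np.linalg.solve(_residual_jac(x, params, forcing), -r)
        except np.linalg.LinAlgError:
            return None
        x = x + step
    x[np.abs(x) < 1e-12] = 0.0
    if np.any(x < 0):
        return None
    if np.max(np.abs(_residual(x, params, forcing))) > RESIDUAL_TOL:
        return None
    return x


def _solve_from(x0: np.ndarray, params: ModelParameterization, forcing=None) -> np.ndarray | None:
    sol = optimize.root(
        _residual,
        x0,
        args=(params, forcing),
        jac=_residual_jac,
        method="hybr",
        options={"xtol": 1e-12},
    )
    if not sol.success:
        return None
    return _polish(sol.x, params, forcing)


def steady_state_from(
    params: ModelParameterization, x0: Sequence[float], forcing: np.ndarray | None = None
) -> np.ndarray | None:
    """Warm-started Newton solve for a steady state near x0 (continuation step)."""
    return _solve_from(np.asarray(x0, dtype=float), params, forcing)


# ---------------------------------------------------------------------------
# Simulation


def simulate(
    params: ModelParameterization,
    x0: Sequence[float],
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 200,
) -> Trajectory:
    """Integrate the ODE with a stiff-capable adaptive method."""
    x0 = validate_state(x0, params.network)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, x: rhs(np.clip(x, 0.0, None), params),
        (0.0, t_end),
        x0,
        method="LSODA",
        jac=lambda t, x: jacobian(np.clip(x, 0.0, None), params),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    meta = {"method": "LSODA", "rtol": rtol, "atol": atol, "success": bool(sol.success)}
    if not sol.success:
        meta["message"] = sol.message
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(sol.t, states, x0, params, meta)


# ---------------------------------------------------------------------------
# Equilibria


def _classify_stability(params: ModelParameterization, x: np.ndarray) -> Equilibrium:
    J = jacobian(x, params)
    eig = np.linalg.eigvals(J)
    max_re = float(np.max(eig.real))
    marginal = abs(max_re) <= STABILITY_MARGIN
    stable = max_re < -STABILITY_MARGIN
    res = float(np.max(np.abs(rhs(x, params))))
    return Equilibrium(state=x, eigenvalues=eig, stable=stable, marginal=marginal, residual=res)


def _dedup(solutions: list[np.ndarray], rtol: float = DEDUP_RTOL, atol: float = DEDUP_ATOL):
    reps: list[np.ndarray] = []
    for x in solutions:
        if not any(np.allclose(x, r, rtol=rtol, atol=atol) for r in reps):
            reps.append(x)
    return reps


def find_equilibria(
    params: ModelParameterization,
    n_starts: int = 48,
    seed: int = 0,
    include_simulations: bool = True,
    dedup_rtol: float = DEDUP_RTOL,
) -> list[Equilibrium]:
    """Multistart search for all equilibria, with stability classification.

    Starts are Sobol points in the box bounded by each variable's maximal
    production (plus 10% headroom), the box corners, and — optionally — the
    endpoints of long simulations from a few spread-out initial conditions.
    Results are deduplicated and sorted by the OXPHOS coordinate.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    net = params.network
    ub = production_bounds(params) * 1.1 + 1e-6
    sampler = qmc.Sobol(d=net.n, scramble=True, seed=seed)
    m = max(1, int(np.ceil(np.log2(n_starts))))
    starts = [qmc.scale(row[None, :], np.zeros(net.n), ub)[0] for row in sampler.random_base2(m)][
        :n_starts
    ]
    starts.append(np.zeros(net.n))
    starts.append(ub.copy())
    if include_simulations:
        for x0 in (np.zeros(net.n), ub / 2, ub):
            traj = simulate(params, x0, t_end=200.0, n_points=2)
            starts.append(np.clip(traj.final_state, 0.0, None))
    sols = []
    for x0 in starts:
        x = _solve_from(np.asarray(x0, dtype=float), params)
        if x is not None:
            sols.append(x)
    reps = _dedup(sols, rtol=dedup_rtol)
    eqs = [_classify_stability(params, x) for x in reps]
    eqs.sort(key=lambda e: e.value("m", net) if "m" in net.node_ids else float(e.state[0]))
    return eqs


# ---------------------------------------------------------------------------
# Health labels


def _ordering_consistent(healthy: np.ndarray, patho: np.ndarray, network) -> bool:
    hi = all(healthy[network.index(n)] > patho[network.index(n)] for n in HEALTHY_HIGH)
    lo = all(healthy[network.index(n)] < patho[network.index(n)] for n in HEALTHY_LOW)
    return hi and lo


def classify_health(
    equilibria: list[Equilibrium],
    network,
    reference_states: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-9,
) -> list[Equilibrium]:
    """Label stable equilibria healthy/pathological by the OXPHOS ordering.

    With two stable states, the higher-m one is healthy — but only if the
    full six-coordinate ordering is consistent (m, p, c larger and a, k, g
    smaller at the healthy state); otherwise both stay unclassified.  A
    single stable state is compared coordinate-wise against the midpoint of
    ``reference_states`` (a bistable pair, e.g. from the reference fixture).
    """
    stable = [e for e in equilibria if e.stable]
    if not stable:
        return list(equilibria)
    out = list(equilibria)

    def _set(e: Equilibrium, label: str) -> None:
        idx = next(i for i, other in enumerate(out) if other is e)
        out[idx] = e.relabeled(label)

    if len(stable) >= 2:
        ordered = sorted(stable, key=lambda e: e.value("m", network))
        lo, hi = ordered[0], ordered[-1]
        if abs(hi.value("m", network) - lo.value("m", network)) < tol:
            return out
        if _ordering_consistent(hi.state, lo.state, network):
            _set(hi, "healthy")
            _set(lo, "pathological")
        return out

    if reference_states is None:
        from loopstate.scenario import reference_bistable_pair  # lazy: avoids import cycle

        reference_states = reference_bistable_pair()
    mid = (np.asarray(reference_states[0]) + np.asarray(reference_states[1])) / 2.0
    e = stable[0]
    # OXPHOS is the discriminating coordinate for a lone equilibrium: other
    # coordinates can be structurally pinned (a knockout forces p = 0
    # regardless of health), so a full-ordering comparison would never label.
    m_idx = network.index("m")
    gap = e.state[m_idx] - mid[m_idx]
    if abs(gap) < tol:
        return out
    _set(e, "healthy" if gap > 0 else "pathological")
    return out


# ---------------------------------------------------------------------------
# Numerical verification of structural influence predictions


def verify_influence_numerically(
    params: ModelParameterization,
    equilibrium: Equilibrium,
    epsilon: float = 1e-3,
    epsilon_min: float = 1e-8,
    zero_tol_factor: float = 1e-6,
) -> dict:
    """Perturbation test of the structural influence predictions.

    For each node j, adds a persistent input epsilon to equation j,
    recomputes the steady state by warm-started Newton continuation, and
    compares the sign of every shift with the symbolic influence matrix;
    the input-perturbation column is checked against the input-output
    influence vector.  If continuation leaves the neighbourhood of the
    starting equilibrium (basin escape near a fold), epsilon is halved;
    at epsilon_min the column is marked untestable, never a disagreement.
    """
    from loopstate.structural_analysis import (
        input_output_influence,
        input_sign_vector,
        interaction_matrix,
        structural_influence_matrix,
    )

    if not equilibrium.stable:
        raise ValueError("influence verification requires a stable equilibrium")
    net = params.network
    S = interaction_matrix(net)
    infl, _ = structural_influence_matrix(S)
    io_infl = input_output_influence(S, input_sign_vector(net))
    x_star = equilibrium.state

    def _perturbed_state(forcing: np.ndarray | None, new_params: ModelParameterization):
        eps = 1.0
        scale_forcing = forcing
        while True:
            x = steady_state_from(new_params, x_star, forcing=scale_forcing)
            if x is not None:
                Ju = _residual_jac(x_star, params)
                pred = np.linalg.solve(
                    -Ju, scale_forcing if scale_forcing is not None else np.zeros(net.n)
                )
                moved = np.max(np.abs(x - x_star))
                allowance = 10.0 * (np.max(np.abs(pred)) + 1e-12)
                if forcing is None or moved <= allowance:
                    return x, eps
            if forcing is None:
                return None, eps
            eps /= 2.0
            scale_forcing = forcing * eps
            if np.max(np.abs(scale_forcing)) < epsilon_min:
                return None, eps

    entries: dict[tuple[str, str], str] = {}
    n_agree = n_disagree = n_untestable = 0
    for j, node_j in enumerate(net.node_ids):
        forcing = np.zeros(net.n)
        forcing[j] = epsilon
        x_new, _ = _perturbed_state(forcing, params)
        if x_new is None:
            for node_i in net.node_ids:
                entries[(node_i, node_j)] = "untestable"
                n_untestable += 1
            continue
        delta = x_new - x_star
        thresh = zero_tol_factor * epsilon
        for i, node_i in enumerate(net.node_ids):
            predicted = infl.entries[i][j]
            if predicted == "?":
                entries[(node_i, node_j)] = "untestable"
                n_untestable += 1
                continue
            if predicted == "0":
                ok = abs(delta[i]) < thresh
            elif abs(delta[i]) < thresh:
                entries[(node_i, node_j)] = "untestable"
                n_untestable += 1
                continue
            else:
                ok = (delta[i] > 0) == (predicted == "+")
            ok = bool(ok)
            entries[(node_i, node_j)] = "agree" if ok else "disagree"
            n_agree += int(ok)
            n_disagree += int(not ok)

    # input perturbation: bump u and re-solve
    u_entries: dict[str, str] = {}
    du = max(epsilon, 1e-6 * (1.0 + params.input_level))
    x_u = steady_state_from(params.with_input(params.input_level + du), x_star)
    if x_u is None:
        u_entries = {n: "untestable" for n in net.node_ids}
    else:
        delta_u = x_u - x_star
        for i, node_i in enumerate(net.node_ids):
            predicted = io_infl.entries[i][0]
            if predicted in ("?",):
                u_entries[node_i] = "untestable"
            elif predicted == "0":
                u_entries[node_i] = "agree" if abs(delta_u[i]) < zero_tol_factor * du else "disagree"
            elif abs(delta_u[i]) < 1e-12:
                u_entries[node_i] = "untestable"
            else:
                u_entries[node_i] = (
                    "agree" if (delta_u[i] > 0) == (predicted == "+") else "disagree"
                )
    return {
        "entries": entries,
        "input_entries": u_entries,
        "n_agree": n_agree,
        "n_disagree": n_disagree,
        "n_untestable": n_untestable,
        "input_disagreements": [n for n, v in u_entries.items() if v == "disagree"],
        "epsilon": epsilon,
    }
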