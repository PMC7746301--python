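"""Parameter-free qualitative analysis of signed interaction networks.

Everything here operates on sign patterns only: the interaction matrix S
(signs of the Jacobian), the input sign vector, simple-cycle enumeration
with loop signs, candidate-multistationarity, monotone-gauge detection
(diagonal +/-1 similarity making the off-diagonal pattern Metzler), and the
structural influence matrix — the sign pattern of adj(-J) over *all*
magnitude assignments consistent with S, computed symbolically and
cross-checkable against a Monte-Carlo determinant oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import sympy as sp

__all__ = [
    "SignMatrix",
    "FeedbackLoop",
    "Gauge",
    "interaction_matrix",
    "input_sign_vector",
    "enumerate_feedback_loops",
    "is_candidate_multistationary",
    "find_monotone_gauge",
    "all_feasible_gauges",
    "structural_influence_matrix",
    "influence_via_gauge",
    "input_output_influence",
    "monte_carlo_influence_signs",
    "random_jacobian_realization",
    "is_irreducible",
]

_SIGN_CHARS = ("+", "-", "0", "?")
_INT_TO_CHAR = {1: "+", -1: "-", 0: "0"}
_CHAR_TO_INT = {"+": 1, "-": -1, "0": 0}


@dataclass(frozen=True)
class SignMatrix:
    """A labeled matrix over the alphabet {+, -, 0, ?}."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    entries: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.entries) != len(self.row_labels):
            raise ValueError("row count does not match row labels")
        for row in self.entries:
            if len(row) != len(self.col_labels):
                raise ValueError("column count does not match column labels")
            for ch in row:
                if ch not in _SIGN_CHARS:
                    raise ValueError(f"invalid sign character {ch!r}")

    @classmethod
    def from_ints(
        cls,
        mat: Sequence[Sequence[int]],
        row_labels: Sequence[str],
        col_labels: Sequence[str] | None = None,
    ) -> "SignMatrix":
        cols = tuple(col_labels) if col_labels is not None else tuple(row_labels)
        entries = tuple(tuple(_INT_TO_CHAR[int(v)] for v in row) for row in mat)
        return cls(tuple(row_labels), cols, entries)

    def __getitem__(self, key: tuple[str, str]) -> str:
        i = self.row_labels.index(key[0])
        j = self.col_labels.index(key[1])
        return self.entries[i][j]

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    @property
    def has_unknown(self) -> bool:
        return any("?" in row for row in self.entries)

    def to_ints(self) -> np.ndarray:
        """Integer matrix; raises if any entry is '?'."""
        if self.has_unknown:
            raise ValueError("matrix contains '?' entries")
        return np.array([[_CHAR_TO_INT[ch] for ch in row] for row in self.entries], dtype=int)

    def format_table(self, names: dict[str, str] | None = None, title: str = "") -> str:
        """Plain-text rendering with labeled rows/columns."""
        names = names or {}
        cols = [names.get(c, c) for c in self.col_labels]
        rows = [names.get(r, r) for r in self.row_labels]
        width = max(len(s) for s in cols + rows + [title]) + 2
        lines = [title.ljust(width) + "".join(c.rjust(width) for c in cols)]
        for r, row in zip(rows, self.entries):
            lines.append(r.ljust(width) + "".join(ch.rjust(width) for ch in row))
        return "\n".join(lines)


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with its edge signs."""

    node_sequence: tuple[str, ...]
    edge_signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.node_sequence)) != len(self.node_sequence):
            raise ValueError("loop nodes must be distinct")
        if len(self.edge_signs) != len(self.node_sequence):
            raise ValueError("one edge sign per step required")

    @property
    def n_negative(self) -> int:
        return sum(1 for s in self.edge_signs if s < 0)

    @property
    def overall_sign(self) -> int:
        return int(np.prod(self.edge_signs))

    @property
    def is_positive(self) -> bool:
        return self.overall_sign == +1

    def __len__(self) -> int:
        return len(self.node_sequence)


@dataclass(frozen=True)
class Gauge:
    """Diagonal +/-1 change of variables D, acting on a sign pattern as D S D."""

    flips: dict[str, int]

    def __post_init__(self) -> None:
        for node, v in self.flips.items():
            if v not in (+1, -1):
                raise ValueError(f"flip for {node!r} must be +/-1")

    def flipped_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, v in sorted(self.flips.items()) if v < 0)

    def apply(self, S: SignMatrix) -> SignMatrix:
        """Gauged pattern: entry (i,j) -> flips[i] * entry * flips[j]."""
        out = []
        for i, ri in enumerate(S.row_labels):
            row = []
            for j, cj in enumerate(S.col_labels):
                ch = S.entries[i][j]
                if ch in ("0", "?"):
                    row.append(ch)
                else:
                    v = _CHAR_TO_INT[ch] * self.flips[ri] * self.flips[cj]
                    row.append(_INT_TO_CHAR[v])
            out.append(tuple(row))
        return SignMatrix(S.row_labels, S.col_labels, tuple(out))

    def negate(self) -> "Gauge":
        return Gauge({n: -v for n, v in self.flips.items()})


# ---------------------------------------------------------------------------
# Sign matrices of a network


def interaction_matrix(network) -> SignMatrix:
    """Sign pattern of the Jacobian: entry (i, j) is the direct effect of j on i.

    Diagonal entries are '-' (linear self-degradation); off-diagonal entries
    are the network's edge signs.
    """
    n = network.n
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        mat[i][i] = -1
    for e in network.edges:
        i, j = network.index(e.target), network.index(e.source)
        if i == j:
            continue  # self-loop folds into degradation sign
        mat[i][j] = e.sign
    return SignMatrix.from_ints(mat, network.node_ids)


def input_sign_vector(network) -> SignMatrix:
    """n x 1 column of signs of d(dx_i/dt)/du."""
    col = [[0] for _ in network.node_ids]
    for e in network.input_edges:
        col[network.index(e.target)][0] = e.sign
    return SignMatrix.from_ints(col, network.node_ids, (network.input_node,))


# ---------------------------------------------------------------------------
# Loops


def _support_digraph(S: SignMatrix) -> nx.DiGraph:
    """Directed graph on the off-diagonal support; edge j->i when S[i][j] != 0."""
    G = nx.DiGraph()
    G.add_nodes_from(S.row_labels)
    for i, ri in enumerate(S.row_labels):
        for j, cj in enumerate(S.col_labels):
            if i == j:
                continue
            ch = S.entries[i][j]
            if ch in ("+", "-"):
                G.add_edge(cj, ri, sign=_CHAR_TO_INT[ch])
    return G


def enumerate_feedback_loops(S: SignMatrix) -> list[FeedbackLoop]:
    """All simple directed cycles of length >= 2, in canonical order.

    Each cycle is rotated to start at its lexicographically smallest node;
    the list is sorted by length, then lexicographically.  Diagonal
    self-degradation terms are not loops.
    """
    if not S.is_square:
        raise ValueError("loop enumeration requires a square sign matrix")
    G = _support_digraph(S)
    loops = []
    for cyc in nx.simple_cycles(G):
        if len(cyc) < 2:
            continue
        k = min(range(len(cyc)), key=lambda i: cyc[i])
        seq = tuple(cyc[k:] + cyc[:k])
        signs = tuple(
            G.edges[seq[i], seq[(i + 1) % len(seq)]]["sign"] for i in range(len(seq))
        )
        loops.append(FeedbackLoop(seq, signs))
    loops.sort(key=lambda L: (len(L), L.node_sequence))
    return loops


def is_candidate_multistationary(loops: Iterable[FeedbackLoop]) -> tuple[bool, dict]:
    """True iff there is at least one loop and every loop is positive.

    All-positive loops make multiple equilibria *possible* (a candidate
    property), never a proof.  The report lists any negative loops, or the
    reason for a negative verdict.
    """
    loops = list(loops)
    negative = [L for L in loops if not L.is_positive]
    if not loops:
        return False, {"reason": "no loops", "n_loops": 0, "negative_loops": []}
    if negative:
        return False, {
            "reason": "negative loops present",
            "n_loops": len(loops),
            "negative_loops": [L.node_sequence for L in negative],
        }
    return True, {"reason": "all loops positive", "n_loops": len(loops), "negative_loops": []}


# ---------------------------------------------------------------------------
# Monotone gauge


def _gauge_constraints(S: SignMatrix) -> nx.Graph:
    """Undirected constraint graph: edge (i, j) requires flip_i * flip_j = sign.

    Conflicting signs between the (i, j) and (j, i) entries make the
    constraint unsatisfiable and are recorded as parallel requirements.
    """
    G = nx.Graph()
    G.add_nodes_from(S.row_labels)
    n = len(S.row_labels)
    for i in range(n):
        for j in range(i + 1, n):
            signs = set()
            for a, b in ((i, j), (j, i)):
                ch = S.entries[a][b]
                if ch in ("+", "-"):
                    signs.add(_CHAR_TO_INT[ch])
            if not signs:
                continue
            if len(signs) == 2:
                G.add_edge(S.row_labels[i], S.row_labels[j], sign=0)  # infeasible marker
            else:
                G.add_edge(S.row_labels[i], S.row_labels[j], sign=signs.pop())
    return G


def find_monotone_gauge(S: SignMatrix, canonical_node: str = "m") -> Gauge | None:
    """Flip assignment making every off-diagonal entry nonnegative, if any.

    Solved as 2-coloring of the signed undirected support (linear time).
    The gauge is defined up to global negation per connected component; the
    canonical form sets ``canonical_node`` (when present) to +1 in its
    component and the smallest-label node to +1 elsewhere.
    """
    if not S.is_square:
        raise ValueError("gauge detection requires a square sign matrix")
    G = _gauge_constraints(S)
    flips: dict[str, int] = {}
    for comp in nx.connected_components(G):
        comp = set(comp)
        root = canonical_node if canonical_node in comp else min(comp)
        flips[root] = +1
        stack = [root]
        seen = {root}
        while stack:
            node = stack.pop()
            for nbr in G.neighbors(node):
                s = G.edges[node, nbr]["sign"]
                if s == 0:
                    return None  # (i,j)/(j,i) sign conflict
                want = flips[node] * s
                if nbr in seen:
                    if flips[nbr] != want:
                        return None  # odd negative cycle in the support
                else:
                    flips[nbr] = want
                    seen.add(nbr)
                    stack.append(nbr)
    gauge = Gauge(flips)
    gauged = gauge.apply(S)
    for i, row in enumerate(gauged.entries):  # soundness check, never assumed
        for j, ch in enumerate(row):
            if i != j and ch == "-":
                raise AssertionError("2-coloring produced a non-Metzler gauge")
    return gauge


def all_feasible_gauges(S: SignMatrix) -> list[Gauge]:
    """Brute force over all 2^n flip assignments (verification oracle)."""
    nodes = S.row_labels
    out = []
    for combo in itertools.product((+1, -1), repeat=len(nodes)):
        g = Gauge(dict(zip(nodes, combo)))
        gauged = g.apply(S)
        ok = all(
            ch != "-"
            for i, row in enumerate(gauged.entries)
            for j, ch in enumerate(row)
            if i != j
        )
        if ok:
            out.append(g)
    return out


def is_irreducible(S: SignMatrix) -> bool:
    """Strong connectivity of the off-diagonal support digraph."""
    G = _support_digraph(S)
    return nx.is_strongly_connected(G)


# ---------------------------------------------------------------------------
# Structural influence

#: memo for the (expensive) symbolic adjoint expansion; SignMatrix is hashable
_influence_cache: dict[tuple[SignMatrix, bool], tuple[SignMatrix, dict]] = {}


def _symbolic_neg_jacobian(S: SignMatrix) -> sp.Matrix:
    """-J as a symbolic matrix: diagonal d_i > 0, off-diagonal -s_ij * w_ij."""
    n = len(S.row_labels)
    A = sp.zeros(n, n)
    for i in range(n):
        for j in range(n):
            ch = S.entries[i][j]
            if i == j:
                if ch != "-":
                    raise ValueError("influence analysis requires '-' diagonal (self-degradation)")
                A[i, j] = sp.Symbol(f"d_{i}", positive=True)
            elif ch in ("+", "-"):
                A[i, j] = -_CHAR_TO_INT[ch] * sp.Symbol(f"w_{i}_{j}", positive=True)
    return A


def _poly_sign(expr: sp.Expr) -> str:
    """Sign of a polynomial with positive-symbol variables, from term coefficients."""
    expr = sp.expand(expr)
    if expr == 0:
        return "0"
    terms = expr.args if isinstance(expr, sp.Add) else (expr,)
    signs = set()
    for t in terms:
        coeff = t.as_coeff_Mul()[0]
        signs.add(1 if coeff > 0 else -1)
    if len(signs) == 2:
        return "?"
    return "+" if signs.pop() > 0 else "-"


def structural_influence_matrix(
    S: SignMatrix, assume_stability: bool = True
) -> tuple[SignMatrix, dict]:
    """Parameter-free sign pattern of adj(-J), the steady-state response signs.

    Entry (i, k) is the sign of the steady-state shift of variable i under a
    persistent positive input added to equation k.  Two symbolic stages:

    1. Term expansion: each adjoint entry is a polynomial in the (positive)
       magnitude symbols; if every nonzero term agrees the sign holds for
       *all* magnitude assignments ('0' when the entry vanishes identically,
       '?' when terms conflict).
    2. With ``assume_stability`` (the setting in which the influence matrix
       is meaningful — perturbations around a stable equilibrium), remaining
       '?' entries are resolved by the monotone argument when it applies:
       if a gauge D makes the off-diagonal pattern Metzler and the support
       is irreducible, then for every Hurwitz realization D(-J)D is an
       irreducible nonsingular M-matrix, so adj(-J) re-gauged is entrywise
       positive and entry (i, k) has the definite sign D_ii * D_kk.

    Sampling can refute but never produce a definite sign; stage 2 is a
    theorem, not a heuristic, and is skipped when its hypotheses fail.
    The report flags structurally singular patterns (det(-J) identically 0)
    and records which entries stage 2 resolved.
    """
    if not S.is_square:
        raise ValueError("influence matrix requires a square sign pattern")
    cached = _influence_cache.get((S, assume_stability))
    if cached is not None:
        mat, report = cached
        return mat, {k: (list(v) if isinstance(v, list) else v) for k, v in report.items()}
    A = _symbolic_neg_jacobian(S)
    adj = A.adjugate()
    n = len(S.row_labels)
    entries = [[_poly_sign(adj[i, k]) for k in range(n)] for i in range(n)]
    det_sign = _poly_sign(A.det(method="berkowitz"))
    report: dict = {
        "structurally_singular": det_sign == "0",
        "det_sign": det_sign,
        "resolved_by_monotonicity": [],
        "assume_stability": assume_stability,
    }
    has_unknown = any("?" in row for row in entries)
    if assume_stability and has_unknown:
        gauge = find_monotone_gauge(S)
        if gauge is not None and is_irreducible(S):
            for i, ri in enumerate(S.row_labels):
                for k, ck in enumerate(S.col_labels):
                    if entries[i][k] == "?":
                        resolved = _INT_TO_CHAR[gauge.flips[ri] * gauge.flips[ck]]
                        entries[i][k] = resolved
                        report["resolved_by_monotonicity"].append((ri, ck))
                    elif entries[i][k] in ("+", "-"):
                        # stage-1 signs must not contradict the theorem
                        expect = _INT_TO_CHAR[gauge.flips[ri] * gauge.flips[ck]]
                        if entries[i][k] != expect:
                            raise AssertionError(
                                "term-expansion sign contradicts monotone-gauge theorem"
                            )
    mat = SignMatrix(S.row_labels, S.col_labels, tuple(tuple(r) for r in entries))
    _influence_cache[(S, assume_stability)] = (mat, report)
    return mat, {k: (list(v) if isinstance(v, list) else v) for k, v in report.items()}


def influence_via_gauge(S: SignMatrix) -> SignMatrix:
    """Shortcut: gauged-Metzler + irreducible => all-'+' influence, re-gauged.

    For an irreducible Metzler pattern the adjoint of -J is entrywise
    positive whenever -J is a nonsingular M-matrix (the stable case), so the
    influence matrix is the all-'+' matrix with the gauge's flipped rows and
    columns negated.  Refuses to run when no gauge exists or the support is
    not strongly connected.
    """
    gauge = find_monotone_gauge(S)
    if gauge is None:
        raise ValueError("no monotone gauge exists; use structural_influence_matrix")
    if not is_irreducible(S):
        raise ValueError("support is not irreducible; use structural_influence_matrix")
    mat = [
        [gauge.flips[ri] * gauge.flips[cj] for cj in S.col_labels]
        for ri in S.row_labels
    ]
    return SignMatrix.from_ints(mat, S.row_labels, S.col_labels)


def _sign_combine(values: Iterable[int]) -> str:
    nonzero = {v for v in values if v != 0}
    if not nonzero:
        return "0"
    if len(nonzero) == 2:
        return "?"
    return _INT_TO_CHAR[nonzero.pop()]


def input_output_influence(S: SignMatrix, S_u: SignMatrix) -> SignMatrix:
    """Sign of the steady-state shift of each variable under a persistent
    increase of the input: the influence columns of the input's targets,
    weighted by the input edge signs (conflicting contributions give '?')."""
    infl, _ = structural_influence_matrix(S)
    n = len(S.row_labels)
    out = []
    for i in range(n):
        contribs: list[int] = []
        unknown = False
        for t in range(n):
            s_in = S_u.entries[t][0]
            if s_in not in ("+", "-"):
                continue
            s_infl = infl.entries[i][t]
            if s_infl == "?":
                unknown = True
                break
            contribs.append(_CHAR_TO_INT[s_in] * _CHAR_TO_INT[s_infl])
        out.append(("?",) if unknown else (_sign_combine(contribs),))
    return SignMatrix(S.row_labels, S_u.col_labels, tuple(out))


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def random_jacobian_realization(
    S: SignMatrix, rng: np.random.Generator, low: float = 0.1, high: float = 10.0
) -> np.ndarray:
    """A numeric Jacobian with magnitudes log-uniform in [low, high] and the
    sign pattern S ('?' entries are not allowed)."""
    M = S.to_ints().astype(float)
    n = M.shape[0]
    mags = np.exp(rng.uniform(np.log(low), np.log(high), size=(n, n)))
    return M * mags


def monte_carlo_influence_signs(
    S: SignMatrix,
    n_draws: int = 1000,
    seed: int = 0,
    tol: float = 1e-12,
    require_stable: bool = True,
    max_attempts_factor: int = 200,
) -> SignMatrix:
    """Sampling oracle for the influence signs.

    For each draw, realizes J with random magnitudes and evaluates the sign
    of det([[-J, -C_k], [R_i, 0]]) (equal to the (i, k) adjoint entry) for
    every entry.  Entries with consistent signs across draws get that sign;
    conflicting draws give '?'.  With ``require_stable`` only Hurwitz
    realizations are kept (the influence matrix is defined at stable
    equilibria); draws are rejection-sampled up to a cap.  Sampling can
    only ever *refute* a definite symbolic sign, never certify one.
    """
    rng = np.random.default_rng(seed)
    n = len(S.row_labels)
    observed: list[list[set]] = [[set() for _ in range(n)] for _ in range(n)]
    kept = 0
    attempts = 0
    while kept < n_draws:
        attempts += 1
        if attempts > max_attempts_factor * n_draws:
            if kept == 0:
                raise RuntimeError("no stable realization found for this sign pattern")
            break
        J = random_jacobian_realization(S, rng)
        if require_stable and np.max(np.linalg.eigvals(J).real) >= 0:
            continue
        kept += 1
        negJ = -J
        scale = np.abs(negJ).max()
        for i in range(n):
            for k in range(n):
                B = np.zeros((n + 1, n + 1))
                B[:n, :n] = negJ
                B[:n, n] = 0.0
                B[k, n] = -1.0  # -C_k
                B[n, i] = 1.0  # R_i
                d = np.linalg.det(B)
                if abs(d) < tol * scale**n:
                    observed[i][k].add(0)
                else:
                    observed[i][k].add(1 if d > 0 else -1)
    entries = []
    for i in range(n):
        row = []
        for k in range(n):
            obs = observed[i][k]
            nonzero = {v for v in obs if v != 0}
            if len(nonzero) == 2:
                row.append("?")
            elif not nonzero:
                row.append("0")
            else:
                row.append(_INT_TO_CHAR[nonzero.pop()])
        entries.append(tuple(row))
    return SignMatrix(S.row_labels, S.col_labels, tuple(entries))
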