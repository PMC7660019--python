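"""Admixture graphs: expected f-statistics, fitting and model comparison.

An admixture graph is a rooted DAG of populations: ordinary edges carry a
drift length ``c_e >= 0`` (in f2 units), admixture nodes have exactly two
parents and a mixing proportion ``alpha`` giving the weight of the first
parent.  A lineage sampled in a leaf traverses each edge with a
probability obtained by routing through admixture nodes with weight
``alpha`` / ``1 - alpha``; expected f-statistics are then linear in the
drift lengths::

    E[f2(A,B)]    = sum_e c_e (vA[e] - vB[e])^2
    E[f4(A,B;C,D)] = sum_e c_e (vA[e] - vB[e]) (vC[e] - vD[e])

Fitting minimizes the diagonal weighted least-squares score
``sum_pairs (f2_obs - f2_exp)^2 / se^2`` over all leaf pairs, with
multi-start bounded local optimization.  Goodness of fit is diagnosed by
the worst f4 residual: the quadruple whose observed-minus-expected f4, in
SE units, is largest in magnitude; fitted models with worst ``|Z| < 3``
are conventionally regarded as consistent with the data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .genotype_io import GenotypeError
from .popfreq import BlockSpec, FreqTable

__all__ = [
    "AdmixtureGraph",
    "GraphParams",
    "GraphFitResult",
    "ScenarioSpec",
    "lineage_edge_probabilities",
    "expected_fstats",
    "fit_graph",
    "worst_f4",
    "compare_scenarios",
    "all_quadruple_orderings",
]


class GraphError(ValueError):
    pass


@dataclass
class AdmixtureGraph:
    """A rooted admixture graph.

    ``drift_edges`` maps ordinary (parent, child) edges to default drift
    lengths; ``admixtures`` maps an admixture node to
    ``(parentA, parentB, alpha)`` where ``alpha`` is the default weight of
    ``parentA``.  Admixture in-edges carry no drift; put post-admixture
    drift on the out-edge of the admixture node.
    """

    drift_edges: dict[tuple[str, str], float]
    admixtures: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        for (p, c), d in self.drift_edges.items():
            if d < 0:
                raise GraphError(f"negative drift on edge {p}->{c}")
            g.add_edge(p, c)
        for child, (pa, pb, alpha) in self.admixtures.items():
            if not 0.0 <= alpha <= 1.0:
                raise GraphError(f"alpha for {child} outside [0, 1]: {alpha}")
            if pa == pb:
                raise GraphError(f"admixture node {child} has identical parents")
            g.add_edge(pa, child)
            g.add_edge(pb, child)
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("admixture graph contains a cycle")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise GraphError(f"graph must have exactly one root, found {roots}")
        for n in g.nodes:
            expect = 2 if n in self.admixtures else (0 if n == roots[0] else 1)
            if g.in_degree(n) != expect:
                raise GraphError(
                    f"node {n!r} has in-degree {g.in_degree(n)}, expected {expect}"
                )
        self._dg = g
        self._root = roots[0]

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self._dg.nodes if self._dg.out_degree(n) == 0)

    @property
    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.drift_edges)

    @property
    def admix_nodes(self) -> list[str]:
        return sorted(self.admixtures)

    def default_params(self) -> "GraphParams":
        return GraphParams(
            drift=dict(self.drift_edges),
            alpha={n: a for n, (_, _, a) in self.admixtures.items()},
        )

    def relabel_leaves(self, mapping: dict[str, str]) -> "AdmixtureGraph":
        """Return a copy with leaf names substituted (internal names kept)."""
        leaves = set(self.leaves)
        unknown = set(mapping) - leaves
        if unknown:
            raise GraphError(f"not leaves: {sorted(unknown)}")

        def m(n: str) -> str:
            return mapping.get(n, n)

        return AdmixtureGraph(
            {(m(p), m(c)): d for (p, c), d in self.drift_edges.items()},
            {m(c): (m(pa), m(pb), a) for c, (pa, pb, a) in self.admixtures.items()},
        )

    # -- text format -------------------------------------------------------

    @classmethod
    def from_edge_list(cls, text: str) -> "AdmixtureGraph":
        """Parse a DOT-like edge list.

        Lines are either ``parent child drift`` or
        ``admix child parentA parentB alpha``; ``#`` starts a comment.
        """
        drift: dict[tuple[str, str], float] = {}
        admix: dict[str, tuple[str, str, float]] = {}
        for ln, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "admix":
                if len(parts) != 5:
                    raise GraphError(f"line {ln}: expected 'admix child pA pB alpha'")
                admix[parts[1]] = (parts[2], parts[3], float(parts[4]))
            else:
                if len(parts) != 3:
                    raise GraphError(f"line {ln}: expected 'parent child drift'")
                drift[(parts[0], parts[1])] = float(parts[2])
        return cls(drift, admix)

    def to_edge_list(self) -> str:
        lines = [f"{p}\t{c}\t{d:.6g}" for (p, c), d in sorted(self.drift_edges.items())]
        lines += [
            f"admix\t{c}\t{pa}\t{pb}\t{a:.6g}"
            for c, (pa, pb, a) in sorted(self.admixtures.items())
        ]
        return "\n".join(lines) + "\n"


@dataclass
class GraphParams:
    drift: dict[tuple[str, str], float]
    alpha: dict[str, float]


@dataclass
class GraphFitResult:
    params: GraphParams
    score: float
    converged: bool
    n_restarts_used: int
    worst_f4: tuple[tuple[str, str, str, str], float] | None = None


# ---------------------------------------------------------------------------


def lineage_edge_probabilities(
    graph: AdmixtureGraph, alpha: dict[str, float] | None = None
) -> dict[str, np.ndarray]:
    """Probability that a lineage from each leaf traverses each drift edge.

    Returns, per leaf, a vector over ``graph.edge_list``.  At an admixture
    node the lineage follows the first parent with probability ``alpha``.
    """
    alphas = {n: a for n, (_, _, a) in graph.admixtures.items()}
    if alpha:
        alphas.update(alpha)
    edges = graph.edge_list
    eindex = {e: i for i, e in enumerate(edges)}
    order = list(nx.topological_sort(graph._dg))[::-1]  # children first
    out: dict[str, np.ndarray] = {}
    for leaf in graph.leaves:
        v = np.zeros(len(edges))
        weight = {leaf: 1.0}
        for node in order:
            w = weight.get(node, 0.0)
            if w == 0.0 or node == graph.root:
                continue
            if node in graph.admixtures:
                pa, pb, _ = graph.admixtures[node]
                a = alphas[node]
                weight[pa] = weight.get(pa, 0.0) + a * w
                weight[pb] = weight.get(pb, 0.0) + (1.0 - a) * w
            else:
                (parent,) = graph._dg.predecessors(node)
                v[eindex[(parent, node)]] += w
                weight[parent] = weight.get(parent, 0.0) + w
        out[leaf] = v
    return out


def all_quadruple_orderings(leaves: list[str]) -> list[tuple[str, str, str, str]]:
    """The three distinct f4 orderings of every 4-subset, lexicographically."""
    quads = []
    for a, b, c, d in itertools.combinations(sorted(leaves), 4):
        quads += [(a, b, c, d), (a, c, b, d), (a, d, b, c)]
    return quads


def expected_fstats(
    graph: AdmixtureGraph, params: GraphParams | None = None
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str, str, str], float]]:
    """Expected f2 for all leaf pairs and f4 for all quadruple orderings."""
    params = params or graph.default_params()
    v = lineage_edge_probabilities(graph, params.alpha)
    c = np.array([params.drift[e] for e in graph.edge_list])
    leaves = graph.leaves
    f2 = {
        (a, b): float(np.sum(c * (v[a] - v[b]) ** 2))
        for a, b in itertools.combinations(leaves, 2)
    }
    f4 = {
        (a, b, cc, d): float(np.sum(c * (v[a] - v[b]) * (v[cc] - v[d])))
        for a, b, cc, d in all_quadruple_orderings(leaves)
    }
    return f2, f4


def _lookup_pair(table: dict, a: str, b: str):
    if (a, b) in table:
        return table[(a, b)]
    if (b, a) in table:
        return table[(b, a)]
    raise GenotypeError(f"missing observed statistic for pair ({a}, {b})")


def fit_graph(
    graph: AdmixtureGraph,
    observed_f2: dict[tuple[str, str], tuple[float, float]],
    seed: int = 0,
    n_restarts: int = 10,
    score_tol: float = 1e-10,
    max_drift: float = 2.0,
) -> GraphFitResult:
    """Fit drift lengths and admixture proportions to observed f2 values.

    ``observed_f2`` maps unordered leaf pairs to ``(estimate, se)`` with
    ``se > 0``.  The score is the weighted residual sum of squares; the
    optimizer runs ``n_restarts`` bounded local fits from seeded random
    starting points and keeps the best, stopping early once the score
    falls below ``score_tol``.
    """
    leaves = graph.leaves
    pairs = list(itertools.combinations(leaves, 2))
    obs = np.array([_lookup_pair(observed_f2, a, b)[0] for a, b in pairs])
    se = np.array([_lookup_pair(observed_f2, a, b)[1] for a, b in pairs])
    if np.any(se <= 0):
        raise GenotypeError("observed f2 standard errors must be positive")
    edges = graph.edge_list
    admix = graph.admix_nodes
    n_e, n_a = len(edges), len(admix)

    # with fixed alphas the model is linear in drifts; recompute the
    # lineage-probability design matrix only when alphas move
    def design(alphas: np.ndarray) -> np.ndarray:
        v = lineage_edge_probabilities(graph, dict(zip(admix, alphas)))
        return np.stack([(v[a] - v[b]) ** 2 for a, b in pairs])

    def residuals(x: np.ndarray) -> np.ndarray:
        drifts, alphas = x[:n_e], x[n_e:]
        return (design(alphas) @ drifts - obs) / se

    lb = np.concatenate([np.zeros(n_e), np.zeros(n_a)])
    ub = np.concatenate([np.full(n_e, max_drift), np.ones(n_a)])
    best = None
    best_score = np.inf
    used = 0
    converged = False
    for r in range(n_restarts):
        used = r + 1
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        x0 = np.concatenate(
            [rng.uniform(1e-4, 0.1, n_e), rng.uniform(0.05, 0.95, n_a)]
        )
        try:
            sol = least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        score = float(np.sum(sol.fun**2))
        if score < best_score:
            best_score, best = score, sol
            converged = converged or sol.status > 0
        if best_score < score_tol:
            break
    if best is None:
        raise GenotypeError("all optimizer restarts failed")
    params = GraphParams(
        drift=dict(zip(edges, best.x[:n_e])),
        alpha=dict(zip(admix, best.x[n_e:])),
    )
    return GraphFitResult(params, best_score, converged, used)


def worst_f4(
    graph: AdmixtureGraph,
    params: GraphParams,
    observed_f4: dict[tuple[str, str, str, str], tuple[float, float]],
) -> tuple[tuple[str, str, str, str], float]:
    """The quadruple with the largest |observed - expected| f4 in SE units.

    Ties are broken toward the lexicographically smallest quadruple.
    """
    quads = all_quadruple_orderings(graph.leaves)
    if not quads:
        raise GenotypeError("need at least 4 leaves for f4 residuals")
    _, expected = expected_fstats(graph, params)
    best_quad, best_z = None, 0.0
    for q in quads:  # lexicographic order; strict > keeps the first of ties
        est, se = observed_f4[q]
        if se <= 0:
            raise GenotypeError(f"non-positive SE for f4{q}")
        z = (est - expected[q]) / se
        if abs(z) > abs(best_z) or best_quad is None:
            best_quad, best_z = q, float(z)
    return best_quad, best_z


# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """A demographic scenario: a graph topology over leaf roles plus the
    candidate populations that may fill each role."""

    scenario_id: int
    graph: AdmixtureGraph
    candidates: dict[str, list[str]]

    def __post_init__(self) -> None:
        roles = set(self.candidates)
        if roles != set(self.graph.leaves):
            raise GraphError(
                f"candidate roles {sorted(roles)} do not match graph leaves "
                f"{self.graph.leaves}"
            )
        for role, pops in self.candidates.items():
            if not pops:
                raise GraphError(f"empty candidate list for role {role!r}")

    def assignments(self):
        roles = list(self.candidates)
        for combo in itertools.product(*(self.candidates[r] for r in roles)):
            yield dict(zip(roles, combo))


def _observed_f2_cache(freq, blocks, cache, pops):
    from .fstats import f2_stat

    out = {}
    for a, b in itertools.combinations(sorted(pops), 2):
        if (a, b) not in cache:
            r = f2_stat(freq, blocks, a, b)
            cache[(a, b)] = (r.estimate, r.se)
        out[(a, b)] = cache[(a, b)]
    return out


def _observed_f4_cache(freq, blocks, cache, pops):
    from .fstats import f4_stat

    out = {}
    for q in all_quadruple_orderings(sorted(pops)):
        if q not in cache:
            r = f4_stat(freq, blocks, *q)
            cache[q] = (r.estimate, r.se)
        out[q] = cache[q]
    return out


def compare_scenarios(
    scenarios: list[ScenarioSpec],
    freq: FreqTable,
    blocks: BlockSpec,
    seed: int = 0,
    n_restarts: int = 10,
    compute_worst_f4: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every scenario under every leaf-role assignment and rank by score.

    Returns the per-assignment table (sorted by score) and a per-scenario
    summary with the median score.  Assignments that would use one
    population in two roles are skipped with a warning.
    """
    if len(scenarios) < 2:
        raise GenotypeError("need at least two scenarios to compare")
    f2_cache: dict = {}
    f4_cache: dict = {}
    rows = []
    for spec in scenarios:
        for assignment in spec.assignments():
            pops = list(assignment.values())
            if len(set(pops)) != len(pops):
                warnings.warn(
                    f"scenario {spec.scenario_id}: skipping assignment reusing "
                    f"a population: {assignment}",
                    stacklevel=2,
                )
                continue
            g = spec.graph.relabel_leaves(assignment)
            obs_f2 = _observed_f2_cache(freq, blocks, f2_cache, pops)
            fit = fit_graph(g, obs_f2, seed=seed, n_restarts=n_restarts)
            row = {
                "scenario": spec.scenario_id,
                "assignment": ";".join(f"{r}={p}" for r, p in assignment.items()),
                "score": fit.score,
                "converged": fit.converged,
            }
            if compute_worst_f4:
                obs_f4 = _observed_f4_cache(freq, blocks, f4_cache, pops)
                quad, z = worst_f4(g, fit.params, obs_f4)
                row["worst_f4_quad"] = ",".join(quad)
                row["worst_f4_z"] = z
            rows.append(row)
    table = pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)
    summary = (
        table.groupby("scenario")["score"]
        .median()
        .rename("median_score")
        .reset_index()
        .sort_values("median_score", kind="stable")
        .reset_index(drop=True)
    )
    return table, summary
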