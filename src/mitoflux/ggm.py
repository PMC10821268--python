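"""Decomposable Gaussian graphical models of gene co-expression.

The model-selection procedure: starting from the maximum-likelihood
spanning tree over genes (equivalently, the maximum spanning tree under
edge weight -1/2 log(1 - r^2) with r the Pearson correlation of
log-transformed abundances), edges are added greedily as long as each
addition preserves decomposability (chordality) and reduces the Bayesian
Information Criterion, ending in a graph with locally minimal BIC. The
Gaussian log-likelihood of a decomposable model factorizes over the clique
tree as sum of clique terms minus separator terms, which keeps every step
closed-form.

Downstream of structure learning: branches of the network are extracted by
divisive community detection (edge betweenness, cut at maximal modularity),
each branch becomes a functional node labelled by hypergeometric gene-set
enrichment, node activity is the mean expression of the member genes per
sample, and activities are compared across condition groups with
Kruskal-Wallis tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "DecomposableGraph",
    "ModelScore",
    "FunctionalNode",
    "NodeActivityTable",
    "select_most_variable",
    "max_likelihood_spanning_tree",
    "model_bic",
    "addable_edges",
    "forward_select_edges",
    "detect_branches",
    "enrich_node",
    "node_activity",
    "compare_node_activity",
    "build_network",
]

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Chordal graph machinery
# ---------------------------------------------------------------------------

def _mcs_order(G: nx.Graph) -> list:
    """Maximum-cardinality search visit order; ties broken by smallest
    vertex id so the result is deterministic."""
    weights = {v: 0 for v in G}
    unvisited = set(G)
    order = []
    while unvisited:
        v = min(unvisited, key=lambda u: (-weights[u], u))
        order.append(v)
        unvisited.discard(v)
        for w in G[v]:
            if w in unvisited:
                weights[w] += 1
    return order


class NotChordalError(ValueError):
    pass


class DecomposableGraph:
    """A chordal (decomposable) undirected graph over gene ids with
    clique/separator bookkeeping via a junction tree.

    The constructor verifies chordality by maximum-cardinality search plus
    a perfect-elimination check and raises :class:`NotChordalError`
    otherwise.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._peo = self._check_chordal()
        self._cliques: list | None = None
        self._separators: list | None = None

    def _check_chordal(self) -> list:
        order = _mcs_order(self.graph)
        pos = {v: i for i, v in enumerate(order)}
        peo = list(reversed(order))  # reverse MCS order is a PEO iff chordal
        ppos = {v: i for i, v in enumerate(peo)}
        for v in peo:
            madj = [u for u in self.graph[v] if ppos[u] > ppos[v]]
            for a, b in itertools.combinations(madj, 2):
                if not self.graph.has_edge(a, b):
                    raise NotChordalError(
                        f"graph is not chordal: fill-in needed between "
                        f"{a!r} and {b!r} (eliminating {v!r})"
                    )
        return peo

    # -- basic accessors ---------------------------------------------------
    @property
    def vertices(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "DecomposableGraph":
        return DecomposableGraph(self.graph.copy())

    def with_edge(self, u, v) -> "DecomposableGraph":
        g = self.graph.copy()
        g.add_edge(u, v)
        return DecomposableGraph(g)

    # -- cliques / separators ----------------------------------------------
    def cliques(self) -> list:
        """Maximal cliques, from the perfect elimination ordering."""
        if self._cliques is None:
            ppos = {v: i for i, v in enumerate(self._peo)}
            cands = []
            for v in self._peo:
                c = frozenset([v]) | {u for u in self.graph[v] if ppos[u] > ppos[v]}
                cands.append(c)
            maximal = [
                c for c in cands
                if not any(c < other for other in cands)
            ]
            self._cliques = sorted(set(maximal), key=lambda c: sorted(c))
        return list(self._cliques)

    def separators(self) -> list:
        """Separator multiset from a junction tree (max-weight spanning
        tree of the clique graph under intersection size). Empty separators
        join disconnected components."""
        if self._separators is None:
            cliques = self.cliques()
            k = len(cliques)
            if k <= 1:
                self._separators = []
                return []
            # Prim over the complete clique graph
            in_tree = {0}
            seps = []
            best = {
                j: (len(cliques[0] & cliques[j]), 0) for j in range(1, k)
            }
            while len(in_tree) < k:
                j = max(
                    (j for j in best if j not in in_tree),
                    key=lambda j: (best[j][0], -j),
                )
                w, i = best[j]
                seps.append(cliques[i] & cliques[j])
                in_tree.add(j)
                for l in range(k):
                    if l not in in_tree:
                        wl = len(cliques[j] & cliques[l])
                        if wl > best[l][0]:
                            best[l] = (wl, j)
            self._separators = seps
        return list(self._separators)


# ---------------------------------------------------------------------------
# Gene filtering and tree initialization
# ---------------------------------------------------------------------------

def select_most_variable(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """The k genes with the largest variance of log2(value + 1) across all
    samples, ordered by descending variance then gene id."""
    if not 1 <= k <= expr.n_genes:
        raise ValueError(f"k={k} outside [1, {expr.n_genes}]")
    logv = expr.log2_values()
    var = logv.var(axis=1, ddof=1)
    order = sorted(expr.gene_ids, key=lambda g: (-var[g], g))
    return expr.subset_genes(order[:k])


def _log_data(expr: ExpressionMatrix) -> pd.DataFrame:
    logv = expr.log2_values()
    const = logv.index[logv.var(axis=1, ddof=0) == 0.0]
    if len(const):
        raise ValueError(f"constant gene (zero variance): {const[0]!r}")
    return logv


def max_likelihood_spanning_tree(expr: ExpressionMatrix) -> DecomposableGraph:
    """Maximum-likelihood spanning tree over genes.

    For Gaussian data the log-likelihood gain of joining two genes is
    -n/2 log(1 - r^2), a strictly increasing function of |r|, so the tree
    is the maximum spanning tree under that weight (Chow-Liu). Ties are
    broken lexicographically by gene-id pair.
    """
    if expr.n_samples < 3:
        raise ValueError("need >=3 samples to estimate correlations")
    logv = _log_data(expr)
    genes = list(logv.index)
    R = np.corrcoef(logv.to_numpy())
    if len(genes) == 1:
        g = nx.Graph()
        g.add_node(genes[0])
        return DecomposableGraph(g)
    cand = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        r2 = min(R[i, j] ** 2, 1.0 - 1e-15)
        w = -0.5 * math.log1p(-r2)
        cand.append((-w, genes[i], genes[j]))
    cand.sort()
    # Kruskal with union-find
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    g = nx.Graph()
    g.add_nodes_from(genes)
    for _, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            g.add_edge(a, b)
            if g.number_of_edges() == len(genes) - 1:
                break
    return DecomposableGraph(g)


# ---------------------------------------------------------------------------
# Likelihood and BIC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelScore:
    """Fit summary of a decomposable Gaussian model:
    bic = -2 log_likelihood + df log(n)."""

    log_likelihood: float
    df: int
    n: int

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.df * math.log(self.n)


class _LikelihoodEngine:
    """Caches the MLE covariance of the log2 data and per-subset
    log-determinants for repeated clique evaluations."""

    def __init__(self, expr: ExpressionMatrix):
        logv = _log_data(expr)
        self.genes = list(logv.index)
        self.index = {g: i for i, g in enumerate(self.genes)}
        X = logv.to_numpy()
        self.n = X.shape[1]
        self.cov = np.cov(X, ddof=0) if len(self.genes) > 1 else np.atleast_2d(
            np.var(X, ddof=0)
        )
        self._logdet_cache: dict = {}

    def logdet(self, subset: frozenset) -> float:
        got = self._logdet_cache.get(subset)
        if got is not None:
            return got
        idx = sorted(self.index[g] for g in subset)
        sub = self.cov[np.ix_(idx, idx)]
        sign, val = np.linalg.slogdet(sub)
        # relative test: the correlation-matrix determinant must not vanish
        if sign <= 0 or val - float(np.sum(np.log(np.diag(sub)))) < math.log(1e-12):
            raise ValueError(
                f"singular covariance on clique {sorted(subset)}"
            )
        self._logdet_cache[subset] = val
        return val

    def marginal_loglik(self, subset: frozenset) -> float:
        """Maximized Gaussian log-likelihood of the marginal on ``subset``."""
        if not subset:
            return 0.0
        p = len(subset)
        return -0.5 * self.n * (p * LOG2PI + self.logdet(subset) + p)

    def graph_loglik(self, graph: DecomposableGraph) -> float:
        ll = sum(self.marginal_loglik(c) for c in graph.cliques())
        ll -= sum(self.marginal_loglik(s) for s in graph.separators())
        return ll

    def partial_corr(self, u, v, sep: frozenset) -> float:
        idx = [self.index[u], self.index[v]] + sorted(self.index[g] for g in sep)
        sub = self.cov[np.ix_(idx, idx)]
        P = np.linalg.pinv(sub)
        denom = math.sqrt(abs(P[0, 0] * P[1, 1]))
        if denom == 0:
            return 0.0
        return float(-P[0, 1] / denom)


def model_bic(graph: DecomposableGraph, expr: ExpressionMatrix,
              engine: _LikelihoodEngine | None = None) -> ModelScore:
    """BIC of a decomposable Gaussian model.

    The log-likelihood decomposes clique-wise over a junction tree:
    ll = sum_cliques ll_C - sum_separators ll_S, each term the maximized
    Gaussian log-likelihood of the marginal. Degrees of freedom count one
    mean and one variance per vertex plus one free parameter per edge
    (2p + |E|).
    """
    missing = set(graph.graph.nodes) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"graph vertices not in expression matrix: {sorted(missing)[:5]}")
    if engine is None:
        engine = _LikelihoodEngine(expr.subset_genes(graph.vertices))
    ll = engine.graph_loglik(graph)
    df = 2 * graph.n_vertices + graph.n_edges
    return ModelScore(log_likelihood=ll, df=df, n=engine.n)


# ---------------------------------------------------------------------------
# Edge addition
# ---------------------------------------------------------------------------

def _separates(G: nx.Graph, S: set, u, v) -> bool:
    """True iff removing S disconnects u from v."""
    if u in S or v in S:
        raise ValueError("endpoints cannot be in the separator")
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in G[x]:
            if y == v:
                return False
            if y not in S and y not in seen:
                seen.add(y)
                stack.append(y)
    return True


def _is_addable(G: nx.Graph, u, v) -> bool:
    # For chordal G and u,v non-adjacent: G + uv stays chordal iff u,v lie
    # in different components or N(u) & N(v) separates u from v.
    common = set(G[u]) & set(G[v])
    return _separates(G, common, u, v)


def addable_edges(graph: DecomposableGraph) -> set:
    """All non-edges whose addition keeps the graph chordal.

    Uses the chordal edge-addition criterion: a non-edge (u, v) is addable
    iff the common neighborhood N(u) & N(v) separates u from v (vertices in
    different components are always addable).
    """
    G = graph.graph
    out = set()
    for u, v in itertools.combinations(sorted(G.nodes), 2):
        if not G.has_edge(u, v) and _is_addable(G, u, v):
            out.add((u, v))
    return out


def forward_select_edges(
    tree: DecomposableGraph, expr: ExpressionMatrix
) -> tuple[DecomposableGraph, ModelScore]:
    """Greedy decomposability-preserving edge addition to a local BIC
    minimum.

    At each step every addable non-edge (u, v) is scored by its exact BIC
    change: adding a legal edge creates the clique {u, v} | S with
    S = N(u) & N(v), and changes the log-likelihood by
    -n/2 log(1 - rho^2) where rho is the partial correlation of u and v
    given S, at the cost of one extra parameter (log n of penalty). The
    largest-reduction edge is added (ties broken lexicographically); the
    loop stops when no addable edge reduces BIC.
    """
    engine = _LikelihoodEngine(expr.subset_genes(tree.vertices))
    G = tree.graph.copy()
    logn = math.log(engine.n)
    while True:
        best = None
        for u, v in itertools.combinations(sorted(G.nodes), 2):
            if G.has_edge(u, v):
                continue
            common = frozenset(set(G[u]) & set(G[v]))
            if not _separates(G, common, u, v):
                continue
            rho = engine.partial_corr(u, v, common)
            r2 = min(rho * rho, 1.0 - 1e-12)
            delta_ll = -0.5 * engine.n * math.log1p(-r2)
            delta_bic = -2.0 * delta_ll + logn
            if delta_bic < -1e-9 and (best is None or
                                      (delta_bic, u, v) < best):
                best = (delta_bic, u, v)
        if best is None:
            break
        G.add_edge(best[1], best[2])
    final = DecomposableGraph(G)
    return final, model_bic(final, expr, engine=engine)


# ---------------------------------------------------------------------------
# Branches, functional nodes, activities
# ---------------------------------------------------------------------------

def modularity_density(G: nx.Graph, partition) -> float:
    """Modularity density: sum over communities of
    (2 * internal edges - boundary edges) / community size.

    Unlike Newman-Girvan modularity this criterion has no resolution
    limit, so tightly-knit small modules are not merged just because the
    graph is large. It is parameter-free and deterministic."""
    D = 0.0
    for c in partition:
        nc = len(c)
        if nc == 0:
            continue
        e_in = G.subgraph(c).number_of_edges()
        e_out = sum(1 for u in c for v in G[u] if v not in c)
        D += (2.0 * e_in - e_out) / nc
    return D


def detect_branches(graph: DecomposableGraph, min_size: int = 2) -> list:
    """Partition the network into branches.

    Divisive community detection by repeated removal of the
    highest-betweenness edge; the partition sequence is cut at maximal
    modularity density (the undivided graph is a candidate); communities
    smaller than ``min_size`` are merged into the neighboring community
    they share the most edges with. Deterministic given the graph.
    Returns sorted gene sets.
    """
    G = graph.graph
    if min_size > G.number_of_nodes():
        raise ValueError(
            f"min_size={min_size} exceeds vertex count {G.number_of_nodes()}"
        )
    if not nx.is_connected(G):
        raise ValueError("branch detection requires a connected graph")
    best_part = [set(G.nodes)]
    best_q = modularity_density(G, best_part)
    for part in nx.community.girvan_newman(G):
        q = modularity_density(G, part)
        if q > best_q + 1e-12:
            best_q = q
            best_part = [set(c) for c in part]
    # merge undersized communities into their best-connected neighbor
    parts = [set(c) for c in best_part]
    while len(parts) > 1:
        small = sorted(
            (c for c in parts if len(c) < min_size),
            key=lambda c: (len(c), sorted(c)),
        )
        if not small:
            break
        c = small[0]
        others = [o for o in parts if o is not c]

        def connectivity(o):
            return sum(1 for u in c for v in G[u] if v in o)

        target = max(others, key=lambda o: (connectivity(o), len(o),
                                            tuple(sorted(o))))
        parts.remove(c)
        target |= c
    return sorted((set(p) for p in parts), key=lambda s: sorted(s))


@dataclass(frozen=True)
class FunctionalNode:
    """A branch of the network labelled by its overrepresented function."""

    node_id: int
    genes: frozenset
    label: str = ""
    enrichment_p: float = 1.0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("functional node with no genes")
        if not 0.0 <= self.enrichment_p <= 1.0:
            raise ValueError(f"enrichment_p outside [0,1]: {self.enrichment_p}")


def enrich_node(genes: set, gene_sets: dict, universe: set) -> tuple:
    """Best-label hypergeometric enrichment.

    For each candidate set a one-sided hypergeometric tail p-value of the
    observed overlap is computed, p-values are Benjamini-Hochberg adjusted
    across the candidate sets, and the label with the smallest adjusted p
    is returned (ties lexicographic)."""
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    genes = set(genes) & set(universe)
    if not genes:
        raise ValueError("node genes have no overlap with the universe")
    M, N = len(universe), len(genes)
    labels = sorted(gene_sets)
    raw = []
    for lab in labels:
        s = set(gene_sets[lab]) & set(universe)
        k = len(genes & s)
        raw.append(stats.hypergeom.sf(k - 1, M, len(s), N) if s else 1.0)
    adj = stats.false_discovery_control(raw, method="bh")
    adj = np.minimum(adj, 1.0)
    best = min(range(len(labels)), key=lambda i: (adj[i], labels[i]))
    return labels[best], float(adj[best])


@dataclass
class NodeActivityTable:
    """Mean member-gene expression per (functional node, sample)."""

    activity: pd.DataFrame     # node_id x sample
    groups: pd.Series = field(repr=False)


def node_activity(expr: ExpressionMatrix, nodes: list) -> NodeActivityTable:
    """activity(node, sample) = arithmetic mean of the node's gene values
    in that sample (raw abundance units)."""
    rows = {}
    for node in nodes:
        genes = sorted(node.genes)
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise ValueError(f"node {node.node_id} genes not in matrix: {missing[:5]}")
        rows[node.node_id] = expr.values.loc[genes].mean(axis=0)
    table = pd.DataFrame(rows).T
    table.index.name = "node_id"
    return NodeActivityTable(activity=table, groups=expr.groups)


def compare_node_activity(table: NodeActivityTable) -> pd.DataFrame:
    """Kruskal-Wallis test of node activity across condition groups.

    Returns a frame indexed by node_id with the tie-corrected H statistic
    and its chi-square p-value on (groups - 1) degrees of freedom."""
    labels = [g for g in dict.fromkeys(table.groups)]
    if len(labels) < 2:
        raise ValueError("need >=2 groups to compare")
    for lab in labels:
        if (table.groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has <2 samples")
    out = {}
    for node_id, row in table.activity.iterrows():
        samples = [row[table.groups.index[table.groups == lab]].to_numpy()
                   for lab in labels]
        if np.ptp(np.concatenate(samples)) == 0:
            h, p = 0.0, 1.0  # all ranks tied; scipy refuses this case
        else:
            h, p = stats.kruskal(*samples)
        out[node_id] = {"H": float(h), "p": float(p)}
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def build_network(
    expr: ExpressionMatrix,
    top_k: int | None = None,
    min_branch: int = 2,
    gene_sets: dict | None = None,
):
    """Full structure-learning pass: variable-gene selection, spanning
    tree, BIC forward selection, branch detection and functional-node
    construction (with enrichment labels when gene sets are supplied).

    Returns (graph, score, nodes, activity_table, comparison_frame).
    """
    if top_k is not None:
        expr = select_most_variable(expr, top_k)
    logv = expr.log2_values()
    keep = logv.index[logv.var(axis=1, ddof=0) > 0.0]
    if len(keep) < expr.n_genes:
        expr = expr.subset_genes(list(keep))
    tree = max_likelihood_spanning_tree(expr)
    graph, score = forward_select_edges(tree, expr)
    branches = detect_branches(graph, min_size=min_branch)
    universe = set(expr.gene_ids)
    nodes = []
    for i, genes in enumerate(branches):
        if gene_sets:
            label, p = enrich_node(genes, gene_sets, universe)
        else:
            label, p = f"node_{i}", 1.0
        nodes.append(FunctionalNode(i, frozenset(genes), label, p))
    table = node_activity(expr, nodes)
    comparison = compare_node_activity(table)
    return graph, score, nodes, table, comparison
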