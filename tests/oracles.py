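"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive and shares no code with the paths it
checks: graph enumeration plus direct chordality testing, Gaussian
likelihood through iterative proportional scaling, LP via basic-solution
enumeration, and a window-by-window G4 scanner.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def connected_chordal_graphs(max_nodes: int):
    """All connected chordal graphs with 2..max_nodes vertices, one per
    isomorphism class (from the networkx graph atlas), nodes relabelled to
    strings."""
    for g in nx.graph_atlas_g()[1:]:
        if g.number_of_nodes() < 2 or g.number_of_nodes() > max_nodes:
            continue
        if not nx.is_connected(g) or not nx.is_chordal(g):
            continue
        yield nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})


def brute_force_addable(G: nx.Graph) -> set:
    """Non-edges whose addition keeps the graph chordal, by direct test."""
    out = set()
    for u, v in itertools.combinations(sorted(G.nodes), 2):
        if G.has_edge(u, v):
            continue
        H = G.copy()
        H.add_edge(u, v)
        if nx.is_chordal(H):
            out.add((u, v))
    return out


def ips_loglik(G: nx.Graph, X: np.ndarray) -> float:
    """Maximized Gaussian log-likelihood of the graphical model G evaluated
    directly: fit the graph-constrained MLE covariance by iterative
    proportional scaling over the maximal cliques, then evaluate the joint
    density at the fit. X is gene-by-sample."""
    genes = sorted(G.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    p, n = X.shape
    S = np.cov(X, ddof=0) if p > 1 else np.atleast_2d(np.var(X, ddof=0))
    K = np.diag(1.0 / np.diag(S))
    cliques = [sorted(idx[v] for v in c) for c in nx.find_cliques(G)]
    for _ in range(500):
        K_old = K.copy()
        for c in cliques:
            Sigma = np.linalg.inv(K)
            K[np.ix_(c, c)] += (
                np.linalg.inv(S[np.ix_(c, c)]) - np.linalg.inv(Sigma[np.ix_(c, c)])
            )
        if np.max(np.abs(K - K_old)) < 1e-14:
            break
    sign, logdet_K = np.linalg.slogdet(K)
    assert sign > 0
    trace = float(np.trace(S @ K))
    return -0.5 * n * (p * np.log(2 * np.pi) - logdet_K + trace)


def vertex_enumeration_lp(S: np.ndarray, c: np.ndarray, lb, ub, tol=1e-9):
    """Maximize c.v s.t. S v = 0, lb <= v <= ub by enumerating candidate
    basic solutions: every subset of variables pinned to a bound with the
    rest solved by least squares. Returns (best objective, best v) or
    (None, None) when infeasible."""
    m, n = S.shape
    lb, ub = np.asarray(lb, float), np.asarray(ub, float)
    best, best_v = None, None
    for k in range(n + 1):
        for fixed in itertools.combinations(range(n), k):
            free = [j for j in range(n) if j not in fixed]
            for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
                v = np.zeros(n)
                for j, val in zip(fixed, bounds_choice):
                    v[j] = val
                if free:
                    A = S[:, free]
                    b = -S[:, list(fixed)] @ np.array(bounds_choice) if fixed else np.zeros(m)
                    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v)) > tol:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                obj = float(c @ v)
                if best is None or obj > best:
                    best, best_v = obj, v.copy()
    return best, best_v


def naive_g4_scan(bases: str, circular: bool, window: int, threshold: float):
    """Window-by-window scanner with per-window score recomputation and
    position-set merging; no shared machinery with the fast path. Returns a
    set of (frozenset of 0-based covered positions, strand)."""
    L = len(bases)

    def base_score(i: int) -> int:
        ch = bases[i % L]
        if ch not in "GC":
            return 0
        # walk left and right to measure the run, respecting circularity
        run = 1
        j = i - 1
        while (circular or j >= 0) and bases[j % L] == ch and run < L:
            run += 1
            j -= 1
        j = i + 1
        while (circular or j < L) and bases[j % L] == ch and run < L:
            run += 1
            j += 1
        val = min(run, 4)
        return val if ch == "G" else -val

    starts = range(L) if circular else range(L - window + 1)
    hits = []
    for sign in (1, -1):
        covered: set = set()
        for s in starts:
            mean = sum(base_score(s + k) for k in range(window)) / window
            if sign * mean >= threshold:
                covered |= {(s + k) % L for k in range(window)}
        # split covered positions into maximal (circular) runs
        strand = "+" if sign > 0 else "-"
        if circular and len(covered) == L:
            hits.append((frozenset(covered), strand))
            continue
        for pos in sorted(covered):
            prev = (pos - 1) % L if circular else pos - 1
            if prev in covered:
                continue  # not a run start
            run = [pos]
            cur = pos
            while True:
                nxt = (cur + 1) % L if circular else cur + 1
                if (circular or nxt < L) and nxt in covered and nxt != pos:
                    run.append(nxt)
                    cur = nxt
                else:
                    break
            hits.append((frozenset(run), strand))
    return set(hits)
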