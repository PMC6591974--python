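"""Independent brute-force oracles used to cross-check the production code.

Everything here is written from the defining formulas with plain Python
loops over explicit neighbour sets, deliberately sharing no code with the
package internals.
"""

from __future__ import annotations

import numpy as np


def neighbour_sets(edges: list[tuple[str, str]]) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {}
    for a, b in edges:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    return nbrs


def brute_edge_weight(edges: list[tuple[str, str]], i: str, j: str) -> float:
    """Squared shared-neighbour count over the (degree-1) product."""
    nbrs = neighbour_sets(edges)
    ni, nj = nbrs.get(i, set()), nbrs.get(j, set())
    if len(ni) <= 1 or len(nj) <= 1:
        return 0.0
    common = len(ni & nj)
    return common * common / ((len(ni) - 1) * (len(nj) - 1))


def brute_wp_matrix(
    edges: list[tuple[str, str]], index: list[str]
) -> np.ndarray:
    """Dense symmetric weight matrix over ``index``; non-edges are 0."""
    n = len(index)
    pos = {p: k for k, p in enumerate(index)}
    wp = np.zeros((n, n))
    edge_set = {(min(a, b), max(a, b)) for a, b in edges}
    for a, b in edge_set:
        if a in pos and b in pos:
            w = brute_edge_weight(edges, a, b)
            wp[pos[a], pos[b]] = w
            wp[pos[b], pos[a]] = w
    return wp


def brute_group_association(
    edges: list[tuple[str, str]], index: list[str], p: str, group: set[str]
) -> float:
    wp = brute_wp_matrix(edges, index)
    pos = {q: k for k, q in enumerate(index)}
    return max(wp[pos[x], pos[p]] if x != p else 0.0 for x in group)


def brute_wd_matrix(
    edges: list[tuple[str, str]],
    index: list[str],
    groups: dict[str, set[str]],
    domain_index: list[str],
) -> np.ndarray:
    """Dense symmetric domain-association matrix by direct double loop."""
    m = len(domain_index)
    wd = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            gi = groups[domain_index[a]]
            gj = groups[domain_index[b]]
            total = sum(brute_group_association(edges, index, y, gj) for y in gi)
            total += sum(brute_group_association(edges, index, x, gi) for x in gj)
            wd[a, b] = total / (len(gi) + len(gj))
    return wd


def direct_restart_solve(T: np.ndarray, h0: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form fixed point h = alpha (I - (1-alpha) T^T)^{-1} h0."""
    n = T.shape[0]
    return alpha * np.linalg.solve(np.eye(n) - (1.0 - alpha) * T.T, h0)


def random_instance(rng: np.random.Generator, max_n: int = 20, max_m: int = 8):
    """A random connected-ish PPI edge list plus random annotations, small
    enough for the brute-force oracles."""
    n = int(rng.integers(4, max_n + 1))
    proteins = [f"P{k:02d}" for k in range(n)]
    p_edge = min(1.0, 2.5 / n + 0.15)
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p_edge:
                edges.append((proteins[a], proteins[b]))
    if not edges:
        edges = [(proteins[0], proteins[1])]
    m = int(rng.integers(1, max_m + 1))
    domains = [f"D{k}" for k in range(m)]
    dom_records = set()
    for p in proteins:
        for _ in range(int(rng.integers(0, 3))):
            dom_records.add((p, domains[int(rng.integers(0, m))]))
    # keep at least one membership so the bipartite layer is non-trivial
    dom_records.add((proteins[0], domains[0]))
    compartments = ["nucleus", "cytosol", "golgi", "vacuole"]
    loc_records = {
        (p, compartments[int(rng.integers(0, len(compartments)))])
        for p in proteins
        if rng.random() < 0.8
    }
    counts = {p: int(rng.integers(0, 30)) for p in proteins if rng.random() < 0.9}
    return proteins, edges, sorted(dom_records), sorted(loc_records), counts
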