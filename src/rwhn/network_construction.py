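"""Construction of the three network layers.

The protein layer ``PN`` is the input PPI graph with every edge weighted by
an edge-clustering-coefficient variant: the squared number of shared
neighbours divided by the product of the endpoints' (degree − 1). The
protein-domain layer is the binary incidence of protein → domain membership.
The domain layer ``DN`` is derived from both: two domains are associated to
the extent that the proteins carrying one interact strongly (in ``PN``
weight) with the proteins carrying the other.

Weights are evaluated only on actual PPI edges; every non-edge carries
weight 0, which is what the protein-group association maxima see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io_formats import AnnotationTable, InteractionTable

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightedPPINetwork:
    """Protein layer: symmetric edge weights over a fixed protein index.

    ``weights`` is the symmetric n×n sparse matrix of edge weights (zero
    diagonal, entries in [0, 1]); ``degree`` is the unweighted neighbour
    count per protein.
    """

    protein_index: tuple[str, ...]
    weights: sp.csr_matrix
    degree: np.ndarray

    @property
    def n(self) -> int:
        return len(self.protein_index)

    def index_of(self, protein: str) -> int:
        try:
            return self._lookup[protein]
        except AttributeError:
            object.__setattr__(
                self, "_lookup", {p: i for i, p in enumerate(self.protein_index)}
            )
            return self._lookup[protein]

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index_of(a), self.index_of(b)])


@dataclass(frozen=True)
class ProteinDomainMap:
    """Bipartite protein-domain membership over fixed indices.

    ``incidence`` is the binary n×m matrix; ``protein_group`` maps each
    domain to the set of proteins containing it (every retained domain has at
    least one protein).
    """

    domain_index: tuple[str, ...]
    incidence: sp.csr_matrix
    protein_group: Mapping[str, frozenset[str]]
    domain_sets: Mapping[str, frozenset[str]]

    @property
    def m(self) -> int:
        return len(self.domain_index)


@dataclass(frozen=True)
class DomainNetwork:
    """Domain layer: symmetric m×m association weights, zero diagonal."""

    weights: sp.csr_matrix

    @property
    def m(self) -> int:
        return self.weights.shape[0]


def edge_weight(graph: nx.Graph, i: str, j: str) -> float:
    """Edge-clustering-coefficient weight of the pair (i, j).

    |N_i ∩ N_j|² / ((|N_i|−1)·(|N_j|−1)) when both endpoints have degree
    above 1, else 0. Neighbourhoods are open (the graph has no self-loops).
    """
    if i == j:
        raise ValueError("edge_weight requires two distinct proteins")
    if i not in graph or j not in graph:
        raise KeyError(f"unknown protein in edge_weight: {i!r} or {j!r}")
    di, dj = graph.degree(i), graph.degree(j)
    if di <= 1 or dj <= 1:
        return 0.0
    common = len(set(graph[i]) & set(graph[j]))
    return common * common / ((di - 1) * (dj - 1))


def build_weighted_ppi(interactions: InteractionTable) -> WeightedPPINetwork:
    """Weight every input edge by :func:`edge_weight`; the protein index is
    lexicographic and non-edges have weight 0."""
    graph = nx.Graph()
    graph.add_edges_from(interactions.records)
    index = tuple(sorted(graph.nodes))
    pos = {p: k for k, p in enumerate(index)}
    n = len(index)
    rows, cols, vals = [], [], []
    for a, b in interactions.records:
        w = edge_weight(graph, a, b)
        if w > 0.0:
            ia, ib = pos[a], pos[b]
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [w, w]
    weights = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    degree = np.array([graph.degree(p) for p in index], dtype=np.int64)
    return WeightedPPINetwork(protein_index=index, weights=weights, degree=degree)


def build_protein_domain_map(
    annotations: AnnotationTable, protein_index: Sequence[str]
) -> ProteinDomainMap:
    """Restrict domain annotations to the network's proteins and build the
    incidence; domains left with no retained protein are dropped."""
    if annotations.kind != "domain":
        raise ValueError("build_protein_domain_map needs a domain annotation table")
    keep = set(protein_index)
    retained = [(p, d) for p, d in annotations.records if p in keep]
    skipped = len(annotations.records) - len(retained)
    if skipped:
        logger.warning(
            "dropped %d domain annotations for proteins outside the PPI network", skipped
        )
    domain_index = tuple(sorted({d for _, d in retained}))
    dpos = {d: k for k, d in enumerate(domain_index)}
    ppos = {p: k for k, p in enumerate(protein_index)}
    n, m = len(protein_index), len(domain_index)
    rows = [ppos[p] for p, _ in retained]
    cols = [dpos[d] for _, d in retained]
    incidence = sp.csr_matrix(
        (np.ones(len(retained)), (rows, cols)), shape=(n, m)
    )
    group: dict[str, set[str]] = {d: set() for d in domain_index}
    dsets: dict[str, set[str]] = {}
    for p, d in retained:
        group[d].add(p)
        dsets.setdefault(p, set()).add(d)
    return ProteinDomainMap(
        domain_index=domain_index,
        incidence=incidence,
        protein_group={d: frozenset(s) for d, s in group.items()},
        domain_sets={p: frozenset(s) for p, s in dsets.items()},
    )


def protein_group_association(
    pn: WeightedPPINetwork, p: str, group: Iterable[str]
) -> float:
    """Association of protein ``p`` with a protein group: the maximum PN
    weight between ``p`` and any member (0 for non-adjacent members; ``p``
    itself contributes 0)."""
    members = list(group)
    if not members:
        raise ValueError("protein group must be non-empty")
    return max(pn.weight(x, p) if x != p else 0.0 for x in members)


def domain_weight(
    pn: WeightedPPINetwork, pd: ProteinDomainMap, d_i: str, d_j: str
) -> float:
    """Association weight between two distinct domains: the mean, over both
    protein groups, of each member's association with the opposite group."""
    if d_i == d_j:
        raise ValueError("domain_weight requires two distinct domains")
    gi, gj = pd.protein_group[d_i], pd.protein_group[d_j]
    total = sum(protein_group_association(pn, y, gj) for y in gi)
    total += sum(protein_group_association(pn, x, gi) for x in gj)
    return total / (len(gi) + len(gj))


def build_domain_network(pn: WeightedPPINetwork, pd: ProteinDomainMap) -> DomainNetwork:
    """Evaluate the domain association weight for all domain pairs.

    Vectorised: ``Smax[p, d]`` holds the association of protein p with the
    group of domain d, then the pairwise sums reduce to an incidence product.
    Exactly symmetric by construction.
    """
    n, m = pn.n, pd.m
    if m == 0:
        return DomainNetwork(weights=sp.csr_matrix((0, 0)))
    W = pn.weights.tocsc()
    inc = pd.incidence.tocsc()
    smax = np.zeros((n, m))
    for j in range(m):
        members = inc.indices[inc.indptr[j] : inc.indptr[j + 1]]
        if members.size:
            col = W[:, members].max(axis=1)
            smax[:, j] = np.asarray(col.todense()).ravel()
    # A[i, j] = sum over proteins of domain i of their association with group j
    A = np.asarray(pd.incidence.T @ smax)
    sizes = np.asarray(pd.incidence.sum(axis=0)).ravel()
    denom = sizes[:, None] + sizes[None, :]
    wd = (A + A.T) / denom
    np.fill_diagonal(wd, 0.0)
    return DomainNetwork(weights=sp.csr_matrix(wd))
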