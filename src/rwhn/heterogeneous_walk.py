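"""Random walk with restart on the protein-domain heterogeneous network.

The heterogeneous matrix stacks the weighted protein layer ``M_P``, the
domain layer ``M_D`` and the bipartite incidence ``M_PD``::

    HM = [[ M_P,     M_PD ],
          [ M_PD^T,  M_D  ]]

Each row is turned into a transition distribution. A protein that carries at
least one domain keeps mass (1−β) on its row-normalized PN weights and sends
β across the bipartite links, split uniformly over its domains; a protein
without domains keeps everything in the protein layer. Domain rows behave
symmetrically: (1−β) on row-normalized domain-association weights and β back
to the member proteins, split uniformly (column-normalized incidence).
The convention 0/0 := 0 applies to every normalization, so a row may sum to
less than one (an isolated protein, a domain with no associations). The
missing mass of such deficient rows is redistributed proportionally to the
restart prior — the standard dangling-node repair — which keeps the chain
stochastic without affecting regular rows.

The walk iterates

    h_{i+1} = (1−α) · T^T · h_i + α · h0

from h_0 = h0, where T is the row-stochastic transition matrix and α the
restart probability. The map is an L1 contraction with ratio (1−α), so the
iteration converges geometrically to the unique fixed point
h = α (I − (1−α) T^T)^{-1} h0 for any α in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import (
    AnnotationTable,
    InteractionTable,
    OrthologyTable,
    RankedOutput,
)
from .network_construction import (
    DomainNetwork,
    ProteinDomainMap,
    WeightedPPINetwork,
    build_domain_network,
    build_protein_domain_map,
    build_weighted_ppi,
)
from .priors import PriorVector, build_prior_vector

logger = logging.getLogger(__name__)

#: Walk parameters tuned on yeast (DIP network); see also the Gavin-optimal
#: (alpha=0.3, beta=0.1) and E. coli (alpha=0.2, beta=0.1) presets.
DEFAULT_ALPHA = 0.3
DEFAULT_BETA = 0.2
PRESETS = {
    "dip": (0.3, 0.2),
    "gavin": (0.3, 0.1),
    "ecoli": (0.2, 0.1),
}
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition over n proteins + m domains.

    Stored as the raw sparse block matrix plus each row's deficit; the
    dangling repair (deficit mass sent to the prior) is applied implicitly by
    :meth:`apply`, so regular rows stay sparse.
    """

    raw: sp.csr_matrix
    deficit: np.ndarray
    prior: np.ndarray
    beta: float
    n: int
    m: int

    def apply(self, h: np.ndarray) -> np.ndarray:
        """T^T·h for the repaired matrix T = raw + deficit ⊗ prior."""
        return self.raw.T @ h + self.prior * float(self.deficit @ h)

    def dense(self) -> np.ndarray:
        """Materialize the repaired row-stochastic matrix (diagnostics and
        small-problem checks only)."""
        return self.raw.toarray() + np.outer(self.deficit, self.prior)


@dataclass(frozen=True)
class WalkResult:
    """Converged (or capped) walk state over the n+m nodes."""

    scores: np.ndarray
    alpha: float
    iterations: int
    residuals: tuple[float, ...]
    converged: bool = True
    n: int = 0
    m: int = 0

    @property
    def protein_scores(self) -> np.ndarray:
        return self.scores[: self.n]

    @property
    def domain_scores(self) -> np.ndarray:
        return self.scores[self.n :]


def _row_normalize(matrix: sp.spmatrix) -> sp.csr_matrix:
    """Divide each row by its sum; all-zero rows stay zero (0/0 := 0)."""
    matrix = sp.csr_matrix(matrix, dtype=float)
    sums = np.asarray(matrix.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.diags(inv) @ matrix


def assemble_transition(
    pn: WeightedPPINetwork,
    pd: ProteinDomainMap,
    dn: DomainNetwork,
    beta: float,
    prior: PriorVector,
) -> TransitionModel:
    """Build the repaired row-stochastic transition matrix of the
    heterogeneous network for inter-layer jump probability ``beta``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1]; got {beta}")
    n, m = pn.n, pd.m
    if prior.n != n or prior.m != m:
        raise ValueError("prior vector does not match network dimensions")

    wp_norm = _row_normalize(pn.weights)
    has_domain = np.asarray(pd.incidence.sum(axis=1)).ravel() > 0 if m else np.zeros(n, bool)

    if m == 0:
        raw = wp_norm
    else:
        protein_scale = np.where(has_domain, 1.0 - beta, 1.0)
        pp_block = sp.diags(protein_scale) @ wp_norm
        pd_block = beta * _row_normalize(pd.incidence)

        has_protein = np.asarray(pd.incidence.sum(axis=0)).ravel() > 0
        domain_scale = np.where(has_protein, 1.0 - beta, 1.0)
        dd_block = sp.diags(domain_scale) @ _row_normalize(dn.weights)
        dp_block = beta * _row_normalize(pd.incidence.T)

        raw = sp.bmat([[pp_block, pd_block], [dp_block, dd_block]], format="csr")

    deficit = 1.0 - np.asarray(raw.sum(axis=1)).ravel()
    deficit[np.abs(deficit) < 1e-12] = 0.0
    if np.any(deficit < -1e-9):
        raise AssertionError("transition row exceeds unit mass")
    deficit = np.clip(deficit, 0.0, 1.0)
    return TransitionModel(
        raw=sp.csr_matrix(raw), deficit=deficit, prior=prior.values.copy(),
        beta=beta, n=n, m=m,
    )


def iterate_walk(
    model: TransitionModel,
    prior: PriorVector,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> WalkResult:
    """Power iteration of the restart walk until the L1 change drops below
    ``tol`` (or ``max_iter`` is hit, which flags the result but is not
    fatal)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1]; got {alpha}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    h0 = prior.values
    h = h0.copy()
    residuals: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        h_next = (1.0 - alpha) * model.apply(h) + alpha * h0
        res = float(np.abs(h_next - h).sum())
        residuals.append(res)
        h = h_next
        if res < tol:
            converged = True
            break
    if not converged:
        logger.warning("walk did not converge in %d iterations (L1=%.3g)",
                       max_iter, residuals[-1] if residuals else float("nan"))
    return WalkResult(
        scores=h, alpha=alpha, iterations=iterations,
        residuals=tuple(residuals), converged=converged, n=model.n, m=model.m,
    )


def rank_proteins(result: WalkResult, protein_index: tuple[str, ...]) -> RankedOutput:
    """Rank proteins (domains are diagnostics only) by walk score,
    descending; ties break lexicographically on ID."""
    scores = result.protein_scores
    if len(protein_index) != scores.shape[0]:
        raise ValueError("protein index does not match walk result")
    order = sorted(range(len(protein_index)), key=lambda i: (-scores[i], protein_index[i]))
    rows = tuple(
        (rank, protein_index[i], float(scores[i]))
        for rank, i in enumerate(order, start=1)
    )
    return RankedOutput(rows=rows)


@dataclass(frozen=True)
class PipelineResult:
    """Everything a run produces: the ranking plus intermediate layers and
    the raw walk state (domain scores, residual trace)."""

    ranking: RankedOutput
    pn: WeightedPPINetwork
    pd: ProteinDomainMap
    dn: DomainNetwork
    prior: PriorVector
    model: TransitionModel
    walk: WalkResult
    params: dict = field(default_factory=dict)


def run_pipeline(
    interactions: InteractionTable,
    domain_annotations: AnnotationTable,
    localization: AnnotationTable,
    orthology: OrthologyTable,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PipelineResult:
    """End-to-end run keeping every intermediate (see :func:`run_rwhn` for
    the ranking-only entry point)."""
    pn = build_weighted_ppi(interactions)
    pd = build_protein_domain_map(domain_annotations, pn.protein_index)
    dn = build_domain_network(pn, pd)
    prior = build_prior_vector(pn, pd, localization, orthology)
    model = assemble_transition(pn, pd, dn, beta, prior)
    walk = iterate_walk(model, prior, alpha=alpha, tol=tol, max_iter=max_iter)
    ranking = rank_proteins(walk, pn.protein_index)
    return PipelineResult(
        ranking=ranking, pn=pn, pd=pd, dn=dn, prior=prior, model=model, walk=walk,
        params={"alpha": alpha, "beta": beta, "tol": tol, "max_iter": max_iter,
                "iterations": walk.iterations, "converged": walk.converged},
    )


def run_rwhn(
    interactions: InteractionTable,
    domain_annotations: AnnotationTable,
    localization: AnnotationTable,
    orthology: OrthologyTable,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankedOutput:
    """Rank the network's proteins by essentiality score. Deterministic for
    fixed inputs and parameters."""
    return run_pipeline(
        interactions, domain_annotations, localization, orthology,
        alpha=alpha, beta=beta, tol=tol, max_iter=max_iter,
    ).ranking
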