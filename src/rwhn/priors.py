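"""Restart priors from subcellular localization and orthology conservation.

Essential proteins are enriched in a handful of compartments (chiefly the
nucleus and cytosol) and tend to be conserved across species. Both signals
are turned into [0, 1] scores — a compartment's importance is its annotation
frequency relative to the most populated compartment, a protein's
conservation is its ortholog count relative to the network maximum — and
averaged into the initial score h0 of each protein. A domain inherits the
best initial score among the proteins that carry it. The concatenated
(proteins, domains) vector, rescaled to sum to one, is the restart
distribution of the walk.

Missing annotations contribute score 0: absent evidence gives no boost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import AnnotationTable, OrthologyTable
from .network_construction import ProteinDomainMap, WeightedPPINetwork

logger = logging.getLogger(__name__)

#: The eleven-compartment reference vocabulary for a eukaryotic cell, usable
#: as an optional filter on localization tables. The method itself accepts
#: any compartment vocabulary.
REFERENCE_COMPARTMENTS = (
    "Endoplasmic",
    "Cytoskeleton",
    "Golgi",
    "Cytosol",
    "Vacuole",
    "Mitochondrion",
    "Endosome",
    "Plasma",
    "Nucleus",
    "Peroxisome",
    "Extracellular",
)


@dataclass(frozen=True)
class CompartmentImportance:
    """Per-compartment importance: annotation count over the max count."""

    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.scores:
            vals = list(self.scores.values())
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise ValueError("compartment importances must lie in [0, 1]")
            if abs(max(vals) - 1.0) > 1e-12:
                raise ValueError("maximal compartment importance must be 1")


@dataclass(frozen=True)
class PriorVector:
    """Length-(n+m) restart distribution, proteins first then domains."""

    values: np.ndarray
    n: int
    m: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (self.n + self.m,):
            raise ValueError("prior vector length must be n+m")
        if np.any(v < 0):
            raise ValueError("prior vector must be non-negative")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError("prior vector must sum to 1")

    @property
    def protein_part(self) -> np.ndarray:
        return self.values[: self.n]

    @property
    def domain_part(self) -> np.ndarray:
        return self.values[self.n :]


def compartment_importance(localization: AnnotationTable) -> CompartmentImportance:
    """Importance of each compartment: number of distinct annotated proteins,
    normalized by the most populated compartment."""
    if localization.kind != "localization":
        raise ValueError("compartment_importance needs a localization table")
    counts = {t: len(ps) for t, ps in localization.proteins_by_term().items()}
    if not counts:
        return CompartmentImportance(scores={})
    peak = max(counts.values())
    return CompartmentImportance(scores={t: c / peak for t, c in counts.items()})


def functional_score(
    p: str, localization: AnnotationTable, imp: CompartmentImportance
) -> float:
    """Best importance among the compartments annotated to ``p``; 0 when
    unannotated."""
    terms = localization.terms_by_protein().get(p, frozenset())
    if not terms:
        return 0.0
    return max(imp.scores.get(t, 0.0) for t in terms)


def conservative_score(p: str, orthology: OrthologyTable, peak: int | None = None) -> float:
    """Ortholog count of ``p`` over the maximum count (``peak``); 0 when
    absent or when the maximum is 0. Without an explicit ``peak`` the table's
    own maximum is used."""
    if peak is None:
        peak = max(orthology.records.values(), default=0)
    if peak <= 0:
        return 0.0
    return orthology.count(p) / peak


def filter_compartments(
    localization: AnnotationTable, keep: tuple[str, ...] = REFERENCE_COMPARTMENTS
) -> AnnotationTable:
    """Optionally restrict a localization table to a compartment whitelist."""
    keep_set = set(keep)
    return AnnotationTable(
        kind="localization",
        records=tuple((p, t) for p, t in localization.records if t in keep_set),
    )


def build_prior_vector(
    pn: WeightedPPINetwork,
    pd: ProteinDomainMap,
    localization: AnnotationTable,
    orthology: OrthologyTable,
) -> PriorVector:
    """Assemble the restart distribution h0 over proteins then domains.

    Each protein's raw score is the mean of its functional (localization) and
    conservative (orthology) scores; each domain takes the maximum raw score
    of its member proteins; the full vector is rescaled to sum to one. If
    every raw score is zero the uniform distribution is returned.
    """
    n, m = pn.n, pd.m
    imp = compartment_importance(localization)
    terms_by_protein = localization.terms_by_protein()
    # conservation normalizer runs over proteins of the network only
    peak = max((orthology.count(p) for p in pn.protein_index), default=0)

    raw = np.zeros(n + m)
    for i, p in enumerate(pn.protein_index):
        terms = terms_by_protein.get(p, frozenset())
        s_score = max((imp.scores.get(t, 0.0) for t in terms), default=0.0)
        i_score = orthology.count(p) / peak if peak > 0 else 0.0
        raw[i] = 0.5 * (s_score + i_score)
    ppos = {p: i for i, p in enumerate(pn.protein_index)}
    for j, d in enumerate(pd.domain_index):
        members = pd.protein_group[d]
        raw[n + j] = max(raw[ppos[p]] for p in members)

    total = raw.sum()
    if total <= 0.0:
        logger.warning("all raw prior scores are zero; using the uniform restart")
        raw = np.full(n + m, 1.0 / (n + m))
    else:
        raw = raw / total
    return PriorVector(values=raw, n=n, m=m)
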