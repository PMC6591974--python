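from __future__ import annotations

import pytest

from rwhn import (
    AnnotationTable,
    InteractionTable,
    OrthologyTable,
    build_domain_network,
    build_protein_domain_map,
    build_weighted_ppi,
)

# Hand-computable 4-protein / 2-domain fixture. Degrees: A=2, B=3, C=3, D=2.
# WP(B,C)=1.0 (shared {A,D}); every other edge has weight 0.5.
TOY_EDGES = (("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D"))
TOY_DOMAINS = (("A", "d1"), ("B", "d1"), ("C", "d2"))


@pytest.fixture
def toy_interactions() -> InteractionTable:
    return InteractionTable(records=TOY_EDGES)


@pytest.fixture
def toy_domain_table() -> AnnotationTable:
    return AnnotationTable(kind="domain", records=TOY_DOMAINS)


@pytest.fixture
def toy_localization() -> AnnotationTable:
    return AnnotationTable(
        kind="localization",
        records=(("A", "nucleus"), ("B", "nucleus"), ("C", "cytosol")),
    )


@pytest.fixture
def toy_orthology() -> OrthologyTable:
    return OrthologyTable(records={"A": 4, "B": 2, "C": 1, "D": 0})


@pytest.fixture
def toy_pn(toy_interactions):
    return build_weighted_ppi(toy_interactions)


@pytest.fixture
def toy_pd(toy_pn, toy_domain_table):
    return build_protein_domain_map(toy_domain_table, toy_pn.protein_index)


@pytest.fixture
def toy_dn(toy_pn, toy_pd):
    return build_domain_network(toy_pn, toy_pd)
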