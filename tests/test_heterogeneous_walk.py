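import numpy as np
import pytest

from rwhn import (
    AnnotationTable,
    InteractionTable,
    OrthologyTable,
    PriorVector,
    assemble_transition,
    build_domain_network,
    build_prior_vector,
    build_protein_domain_map,
    build_weighted_ppi,
    iterate_walk,
    rank_proteins,
    run_pipeline,
    run_rwhn,
)
from rwhn.heterogeneous_walk import TransitionModel, WalkResult

from .oracles import direct_restart_solve, random_instance


def _model_from_tables(interactions, dom_table, loc_table, orth_table, beta=0.2):
    pn = build_weighted_ppi(interactions)
    pd_map = build_protein_domain_map(dom_table, pn.protein_index)
    dn = build_domain_network(pn, pd_map)
    prior = build_prior_vector(pn, pd_map, loc_table, orth_table)
    return pn, pd_map, prior, assemble_transition(pn, pd_map, dn, beta, prior)


def _random_model(seed, beta=0.2):
    rng = np.random.default_rng(seed)
    _, edges, dom_records, loc_records, counts = random_instance(rng)
    return _model_from_tables(
        InteractionTable(records=tuple(sorted((min(a, b), max(a, b)) for a, b in edges))),
        AnnotationTable(kind="domain", records=tuple(dom_records)),
        AnnotationTable(kind="localization", records=tuple(sorted(loc_records))),
        OrthologyTable(records=counts),
        beta=beta,
    )


class TestAssembleTransition:
    def test_toy_protein_row(self, toy_pn, toy_pd, toy_dn,
                             toy_localization, toy_orthology):
        prior = build_prior_vector(toy_pn, toy_pd, toy_localization, toy_orthology)
        model = assemble_transition(toy_pn, toy_pd, toy_dn, beta=0.2, prior=prior)
        dense = model.dense()
        idx = {p: i for i, p in enumerate(toy_pn.protein_index)}
        n = toy_pn.n
        row_a = dense[idx["A"]]
        # A's PN neighbours B and C both carry weight 0.5 and A has one domain
        assert row_a[idx["B"]] == pytest.approx(0.4)
        assert row_a[idx["C"]] == pytest.approx(0.4)
        assert row_a[n + toy_pd.domain_index.index("d1")] == pytest.approx(0.2)
        assert row_a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_protein_without_domains_keeps_full_layer_mass(
        self, toy_pn, toy_pd, toy_dn, toy_localization, toy_orthology
    ):
        prior = build_prior_vector(toy_pn, toy_pd, toy_localization, toy_orthology)
        model = assemble_transition(toy_pn, toy_pd, toy_dn, beta=0.2, prior=prior)
        dense = model.dense()
        idx = {p: i for i, p in enumerate(toy_pn.protein_index)}
        row_d = dense[idx["D"]]  # D has no domain: B and C split 0.5/0.5 unscaled
        assert row_d[idx["B"]] == pytest.approx(0.5)
        assert row_d[idx["C"]] == pytest.approx(0.5)
        assert row_d[toy_pn.n :].sum() == pytest.approx(0.0)

    def test_isolated_protein_row_equals_prior(self):
        # X-Y is a separate degree-1 pair, so every weight on it is 0
        inter = InteractionTable(records=(("A", "B"), ("A", "C"), ("B", "C"), ("X", "Y")))
        pn, pd_map, prior, model = _model_from_tables(
            inter,
            AnnotationTable(kind="domain", records=(("A", "d1"),)),
            AnnotationTable(kind="localization", records=(("A", "nuc"), ("X", "nuc"))),
            OrthologyTable(records={"A": 2, "X": 1}),
        )
        dense = model.dense()
        x = pn.index_of("X")
        assert np.allclose(dense[x], prior.values, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_rows_stochastic_after_repair(self, seed):
        *_, model = _random_model(seed)
        dense = model.dense()
        assert np.all(dense >= -1e-15)
        assert np.allclose(dense.sum(axis=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_protein_to_domain_mass_is_zero_or_beta(self, seed):
        beta = 0.35
        pn, pd_map, _, model = _random_model(seed, beta=beta)
        raw = model.raw.toarray()
        pd_mass = raw[: pn.n, pn.n :].sum(axis=1)
        assert all(abs(v) < 1e-12 or abs(v - beta) < 1e-12 for v in pd_mass)

    def test_beta_out_of_range_rejected(self, toy_pn, toy_pd, toy_dn,
                                        toy_localization, toy_orthology):
        prior = build_prior_vector(toy_pn, toy_pd, toy_localization, toy_orthology)
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError):
                assemble_transition(toy_pn, toy_pd, toy_dn, beta=bad, prior=prior)


class TestIterateWalk:
    def test_alpha_one_returns_prior(self, toy_pn, toy_pd, toy_dn,
                                     toy_localization, toy_orthology):
        prior = build_prior_vector(toy_pn, toy_pd, toy_localization, toy_orthology)
        model = assemble_transition(toy_pn, toy_pd, toy_dn, beta=0.2, prior=prior)
        res = iterate_walk(model, prior, alpha=1.0)
        assert res.iterations == 1
        assert np.allclose(res.scores, prior.values, atol=1e-15)

    def test_two_state_symmetric_chain_stays_uniform(self):
        import scipy.sparse as sp

        T = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        prior = PriorVector(values=np.array([0.5, 0.5]), n=2, m=0)
        model = TransitionModel(raw=T, deficit=np.zeros(2), prior=prior.values,
                                beta=0.0, n=2, m=0)
        res = iterate_walk(model, prior, alpha=0.4)
        assert np.allclose(res.scores, 0.5, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("alpha", [0.15, 0.3, 0.7])
    def test_matches_direct_solve(self, seed, alpha):
        _, _, prior, model = _random_model(seed)
        res = iterate_walk(model, prior, alpha=alpha, tol=1e-12, max_iter=5000)
        expected = direct_restart_solve(model.dense(), prior.values, alpha)
        assert np.max(np.abs(res.scores - expected)) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conserved_and_contracting(self, seed):
        alpha = 0.3
        _, _, prior, model = _random_model(seed)
        h = prior.values.copy()
        prev_res = None
        for _ in range(60):
            h_next = (1 - alpha) * model.apply(h) + alpha * prior.values
            assert h_next.sum() == pytest.approx(1.0, abs=1e-10)
            res = np.abs(h_next - h).sum()
            if prev_res is not None and prev_res > 0:
                assert res <= (1 - alpha) * prev_res + 1e-12
            prev_res = res
            h = h_next

    def test_invalid_alpha_rejected(self, toy_pn, toy_pd, toy_dn,
                                    toy_localization, toy_orthology):
        prior = build_prior_vector(toy_pn, toy_pd, toy_localization, toy_orthology)
        model = assemble_transition(toy_pn, toy_pd, toy_dn, beta=0.2, prior=prior)
        for bad in (0.0, -0.2, 1.2):
            with pytest.raises(ValueError):
                iterate_walk(model, prior, alpha=bad)

    def test_non_convergence_flags_result(self, toy_pn, toy_pd, toy_dn,
                                          toy_localization, toy_orthology):
        prior = build_prior_vector(toy_pn, toy_pd, toy_localization, toy_orthology)
        model = assemble_transition(toy_pn, toy_pd, toy_dn, beta=0.2, prior=prior)
        res = iterate_walk(model, prior, alpha=0.05, tol=1e-15, max_iter=3)
        assert not res.converged
        assert res.iterations == 3


class TestRankProteins:
    def test_sorted_descending(self):
        res = WalkResult(scores=np.array([0.3, 0.5, 0.2]), alpha=0.3,
                         iterations=1, residuals=(0.0,), n=3, m=0)
        ranking = rank_proteins(res, ("A", "B", "C"))
        assert ranking.protein_ids == ("B", "A", "C")

    def test_ties_break_lexicographically(self):
        res = WalkResult(scores=np.array([0.4, 0.4]), alpha=0.3,
                         iterations=1, residuals=(0.0,), n=2, m=0)
        assert rank_proteins(res, ("B", "A")).protein_ids == ("A", "B")

    def test_domain_scores_excluded(self):
        res = WalkResult(scores=np.array([0.2, 0.1, 0.7]), alpha=0.3,
                         iterations=1, residuals=(0.0,), n=2, m=1)
        ranking = rank_proteins(res, ("A", "B"))
        assert len(ranking) == 2


class TestPipelineLimits:
    def test_beta_zero_equals_pn_only_walk(self, toy_interactions, toy_domain_table,
                                           toy_localization, toy_orthology):
        """With no inter-layer jumps the protein ranking must match a restart
        walk on the protein layer alone with the protein-restricted prior."""
        result = run_pipeline(
            toy_interactions, toy_domain_table, toy_localization, toy_orthology,
            beta=0.0, tol=1e-14, max_iter=5000,
        )
        pn = result.pn
        # independent PN-only computation
        from .oracles import direct_restart_solve as solve

        wp = pn.weights.toarray()
        sums = wp.sum(axis=1, keepdims=True)
        T = np.divide(wp, sums, out=np.zeros_like(wp), where=sums > 0)
        p_prior = result.prior.protein_part.copy()
        p_prior = p_prior / p_prior.sum()
        deficit = 1.0 - T.sum(axis=1)
        T = T + np.outer(deficit, p_prior)
        expected = solve(T, p_prior, 0.3)
        order_expected = sorted(
            range(pn.n), key=lambda i: (-expected[i], pn.protein_index[i])
        )
        assert result.ranking.protein_ids == tuple(
            pn.protein_index[i] for i in order_expected
        )

    def test_no_domains_reduces_to_weighted_pagerank(self, toy_interactions,
                                                     toy_localization, toy_orthology):
        empty_domains = AnnotationTable(kind="domain", records=())
        result = run_pipeline(
            toy_interactions, empty_domains, toy_localization, toy_orthology
        )
        assert result.pd.m == 0
        assert len(result.ranking) == 4
        assert result.walk.converged

    def test_deterministic_for_fixed_inputs(self, toy_interactions, toy_domain_table,
                                            toy_localization, toy_orthology):
        r1 = run_rwhn(toy_interactions, toy_domain_table, toy_localization, toy_orthology)
        r2 = run_rwhn(toy_interactions, toy_domain_table, toy_localization, toy_orthology)
        assert r1.rows == r2.rows

    def test_permutation_equivariance(self, toy_interactions, toy_domain_table,
                                      toy_localization, toy_orthology):
        relabel = {"A": "W", "B": "Z", "C": "Y", "D": "X"}
        r1 = run_rwhn(toy_interactions, toy_domain_table, toy_localization, toy_orthology)
        r2 = run_rwhn(
            InteractionTable(records=tuple(sorted(
                tuple(sorted((relabel[a], relabel[b]))) for a, b in toy_interactions.records
            ))),
            AnnotationTable(kind="domain", records=tuple(sorted(
                (relabel[p], d) for p, d in toy_domain_table.records))),
            AnnotationTable(kind="localization", records=tuple(sorted(
                (relabel[p], t) for p, t in toy_localization.records))),
            OrthologyTable(records={relabel[p]: c for p, c in (("A", 4), ("B", 2), ("C", 1), ("D", 0))}),
        )
        scores1 = {p: s for _, p, s in r1.rows}
        scores2 = {p: s for _, p, s in r2.rows}
        for p, s in scores1.items():
            assert scores2[relabel[p]] == pytest.approx(s, abs=1e-12)
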