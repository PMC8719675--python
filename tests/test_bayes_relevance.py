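"""Bayesian-network relevance machinery against exact oracles.

The key oracle is exhaustive DAG enumeration: for up to four variables the
structure posterior, edge posteriors and Markov-blanket posteriors can be
computed exactly, and the MCMC estimates must agree.
"""

import math

import numpy as np
import pytest

from gxemig.bayes_relevance import (
    DiscreteDataset, McmcConfig, ch_family_score, enumerate_dags,
    exact_relevance_posterior, family_score, markov_blanket,
    relevance_difference, relevance_posterior, stratified_relevance,
    structure_mcmc, total_score,
)


def polya_sequential_oracle(child_col, parent_cols, arities_child,
                            parent_arities):
    """Dirichlet-multinomial marginal likelihood by sequential prediction.

    Chain-rule/Pólya-urn route: P(x_1..x_n) = ∏_t (count(x_t | config_t)
    + 1) / (n(config_t) + r), an independent path to the same integral the
    closed-form score evaluates.
    """
    counts: dict = {}
    totals: dict = {}
    log_p = 0.0
    for t in range(len(child_col)):
        cfg = tuple(int(c[t]) for c in parent_cols)
        x = int(child_col[t])
        c = counts.get((cfg, x), 0)
        n = totals.get(cfg, 0)
        log_p += math.log((c + 1) / (n + arities_child))
        counts[(cfg, x)] = c + 1
        totals[cfg] = n + 1
    return log_p


class TestChScore:
    def test_hand_value_one_twentieth(self):
        # binary child, no parents, counts (3,1): 1!*3!*1!/5! = 1/20
        assert math.exp(ch_family_score([[3, 1]])) == pytest.approx(1 / 20)

    def test_empty_table_scores_zero(self):
        assert ch_family_score(np.zeros((2, 2))) == 0.0
        assert ch_family_score([[0, 0]]) == 0.0

    def test_matches_polya_urn_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(1, 9))
            parent = rng.integers(0, 2, n)
            child = rng.integers(0, 3, n)
            counts = np.zeros((2, 3))
            for p, c in zip(parent, child):
                counts[p, c] += 1
            assert ch_family_score(counts) == pytest.approx(
                polya_sequential_oracle(child, [parent], 3, [2]), rel=1e-10)

    def test_decomposability_on_random_structures(self):
        rng = np.random.default_rng(11)
        data = np.column_stack([rng.integers(0, 2, 50),
                                rng.integers(0, 3, 50),
                                rng.integers(0, 2, 50)])
        ds = DiscreteDataset(data, ["a", "b", "c"], [2, 3, 2])
        for ps in [(frozenset(), frozenset({0}), frozenset({0, 1})),
                   (frozenset({1}), frozenset(), frozenset()),
                   (frozenset(), frozenset(), frozenset())]:
            total = total_score(ds, ps)
            parts = sum(family_score(ds, v, ps[v]) for v in range(3))
            assert total == pytest.approx(parts, rel=1e-12)

    def test_edge_move_changes_one_family(self):
        rng = np.random.default_rng(13)
        data = np.column_stack([rng.integers(0, 2, 40),
                                rng.integers(0, 2, 40)])
        ds = DiscreteDataset(data, ["a", "b"], [2, 2])
        no_edge = (frozenset(), frozenset())
        with_edge = (frozenset(), frozenset({0}))
        delta = total_score(ds, with_edge) - total_score(ds, no_edge)
        assert delta == pytest.approx(
            family_score(ds, 1, frozenset({0}))
            - family_score(ds, 1, frozenset()), rel=1e-12)


class TestMarkovBlanket:
    def test_parents_only(self):
        # A->T<-B, C->A: MB(T) = {A, B}
        ps = [frozenset({2}), frozenset(), frozenset(),
              frozenset({0, 1})]       # vars A,B,C,T
        assert markov_blanket(ps, 3) == {0, 1}

    def test_child_and_spouse(self):
        # T->D<-E: MB(T) = {D, E}
        ps = [frozenset(), frozenset({0, 2}), frozenset()]   # T,D,E
        assert markov_blanket(ps, 0) == {1, 2}

    def test_empty_graph(self):
        ps = [frozenset()] * 4
        assert markov_blanket(ps, 2) == set()


class TestEnumeration:
    def test_dag_counts(self):
        # labelled-DAG counts: 1, 3, 25, 543
        assert sum(1 for _ in enumerate_dags(2)) == 3
        assert sum(1 for _ in enumerate_dags(3)) == 25
        assert sum(1 for _ in enumerate_dags(4)) == 543

    def test_parent_cap_respected(self):
        capped = list(enumerate_dags(4, max_parents=1))
        assert all(all(len(pa) <= 1 for pa in ps) for ps in capped)
        assert len(capped) < 543


def two_var_dataset(counts_matrix, seed=0):
    """Rows for a 2x2 contingency table."""
    rows = []
    for a in (0, 1):
        for b in (0, 1):
            rows += [[a, b]] * counts_matrix[a][b]
    data = np.array(rows)
    rng = np.random.default_rng(seed)
    return DiscreteDataset(data[rng.permutation(len(data))],
                           ["A", "B"], [2, 2])


class TestStructureMcmc:
    def test_strong_dependence_edge_posterior(self):
        ds = two_var_dataset([[40, 10], [10, 40]])
        exact_mb, exact_edge = exact_relevance_posterior(ds, "B")
        assert exact_mb["A"] > 0.95
        samples = structure_mcmc(
            ds, McmcConfig(burn_in=2000, n_steps=20000, n_chains=2, seed=5),
            "B")
        post = relevance_posterior(samples)
        assert post.pooled["A"] == pytest.approx(exact_mb["A"], abs=0.03)

    def test_independent_variables_match_enumeration(self):
        rng = np.random.default_rng(19)
        data = np.column_stack([rng.integers(0, 2, 300),
                                rng.integers(0, 2, 300)])
        ds = DiscreteDataset(data, ["A", "B"], [2, 2])
        exact_mb, _ = exact_relevance_posterior(ds, "B")
        assert exact_mb["A"] < 0.5
        samples = structure_mcmc(
            ds, McmcConfig(burn_in=2000, n_steps=20000, n_chains=2, seed=7),
            "B")
        post = relevance_posterior(samples)
        assert post.pooled["A"] == pytest.approx(exact_mb["A"], abs=0.03)

    def test_four_variable_posterior_matches_enumeration(self):
        rng = np.random.default_rng(23)
        n = 150
        a = rng.integers(0, 2, n)
        b = (a ^ (rng.random(n) < 0.25)).astype(int)
        c = rng.integers(0, 3, n)
        t = (b ^ (rng.random(n) < 0.3)).astype(int)
        ds = DiscreteDataset(np.column_stack([a, b, c, t]),
                             ["A", "B", "C", "T"], [2, 2, 3, 2])
        exact_mb, _ = exact_relevance_posterior(ds, "T")
        samples = structure_mcmc(
            ds, McmcConfig(burn_in=5000, n_steps=30000, n_chains=4, seed=9),
            "T")
        post = relevance_posterior(samples)
        for v in ("A", "B", "C"):
            assert post.pooled[v] == pytest.approx(exact_mb[v], abs=0.03)

    def test_copy_of_target_fully_relevant(self):
        rng = np.random.default_rng(29)
        t = rng.integers(0, 2, 200)
        noise = rng.integers(0, 2, 200)
        ds = DiscreteDataset(np.column_stack([t, noise, t]),
                             ["copy", "noise", "T"], [2, 2, 2])
        samples = structure_mcmc(
            ds, McmcConfig(burn_in=2000, n_steps=10000, n_chains=2, seed=1),
            "T")
        post = relevance_posterior(samples)
        exact_mb, _ = exact_relevance_posterior(ds, "T")
        assert post.pooled["copy"] > 0.99
        # the independent variable stays near its structure-prior baseline
        # (spouse configurations keep it well above zero but far from 1)
        assert post.pooled["noise"] == pytest.approx(exact_mb["noise"],
                                                     abs=0.03)
        assert post.pooled["noise"] < 0.5

    def test_pooled_equals_chain_weighted_mean(self):
        ds = two_var_dataset([[30, 20], [20, 30]])
        samples = structure_mcmc(
            ds, McmcConfig(burn_in=500, n_steps=5000, n_chains=3, seed=2),
            "B")
        post = relevance_posterior(samples)
        w = samples.n_samples / samples.n_samples.sum()
        assert post.pooled["A"] == pytest.approx(
            float((post.per_chain["A"] * w).sum()), rel=1e-9)
        assert all(0.0 <= v <= 1.0 for v in post.pooled.values())


class TestStratified:
    def test_difference_arithmetic(self):
        dep = {"rs1": 0.929, "rs2": 0.997, "rs3": 0.704}
        ctl = {"rs1": 0.025, "rs2": 0.210, "rs3": 0.047}
        diff = relevance_difference(dep, ctl)
        assert diff == pytest.approx(
            {"rs1": 0.904, "rs2": 0.787, "rs3": 0.657})

    def test_identical_strata_small_difference(self):
        rng = np.random.default_rng(37)
        n = 400
        x = rng.integers(0, 2, n)
        t = (x ^ (rng.random(n) < 0.3)).astype(int)
        strat = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
        # same generating process in both strata
        ds = DiscreteDataset(np.column_stack([x, strat, t]),
                             ["X", "S", "T"], [2, 2, 2])
        res = stratified_relevance(
            ds, "T", "S",
            McmcConfig(burn_in=2000, n_steps=15000, n_chains=2, seed=3))
        assert abs(res["difference"]["X"]) < 0.25

    def test_stratum_specific_effect_detected(self):
        # X influences T only in stratum 1; two extra noise variables keep
        # the per-edge prior mass realistic.
        rng = np.random.default_rng(41)
        n = 1200
        strat = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        n1 = rng.integers(0, 2, n)
        n2 = rng.integers(0, 3, n)
        t = np.where(strat == 1, (x ^ (rng.random(n) < 0.15)).astype(int),
                     rng.integers(0, 2, n))
        ds = DiscreteDataset(np.column_stack([x, n1, n2, strat, t]),
                             ["X", "N1", "N2", "S", "T"], [2, 2, 3, 2, 2])
        res = stratified_relevance(
            ds, "T", "S",
            McmcConfig(burn_in=3000, n_steps=20000, n_chains=2, seed=4))
        assert res["difference"]["X"] > 0.5
        assert res["strata"][1].pooled["X"] > res["strata"][0].pooled["X"]

    def test_single_level_stratum_raises(self):
        ds = two_var_dataset([[30, 20], [20, 30]])
        data = np.column_stack([ds.data, np.zeros(100, dtype=int)])
        ds2 = DiscreteDataset(data, ["A", "B", "S"], [2, 2, 2])
        with pytest.raises(ValueError, match="single level"):
            stratified_relevance(ds2, "B", "S")
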