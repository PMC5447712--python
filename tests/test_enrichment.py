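"""Two-group enrichment mixture and pattern permutation tests."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from cspattern import (
    CSPAssignment,
    CSPCatalog,
    DirichletPrior,
    EnrichmentModel,
    Partition,
    RiskGrouping,
    choose_beta,
    csp_permutation_test,
    enrichment_log_posterior,
    synth,
)
from cspattern.data import attach_states

from .oracles import dirichlet_multinomial_term, mixture_score


def _variant_set(matrix, window_indices, cluster_sizes=None, rng=None):
    """Build a VariantSet on the given windows with chosen LD cluster sizes."""
    import pandas as pd

    rng = rng or np.random.default_rng(0)
    n = len(window_indices)
    if cluster_sizes is None:
        clusters = [f"c{i}" for i in range(n)]
    else:
        clusters = []
        for k, size in enumerate(cluster_sizes):
            clusters += [f"c{k}"] * size
        clusters = clusters[:n]
    rows = []
    for i, w in enumerate(window_indices):
        win = matrix.window(int(w))
        rows.append(
            {
                "variant_id": f"v{i}", "chrom": win.chrom,
                "pos": int(rng.integers(win.start, win.end)),
                "ld_cluster": clusters[i],
                "maf": 0.2, "annotation": "intronic", "label": "risk",
            }
        )
    return attach_states(pd.DataFrame(rows), matrix)


class TestChooseBeta:
    @pytest.mark.parametrize(
        "sizes,expected", [([3, 4], 10.0), ([25, 2], 25.0), ([1], 10.0)]
    )
    def test_rule(self, default_instance, sizes, expected):
        m, _ = default_instance
        vs = _variant_set(m, list(range(sum(sizes))), cluster_sizes=sizes)
        assert choose_beta(vs) == expected

    def test_empty_set_rejected(self, default_instance):
        m, _ = default_instance
        vs = _variant_set(m, [0])
        with pytest.raises(ValueError):
            choose_beta(vs.subset(np.array([], dtype=int)))


class TestMixtureScore:
    @pytest.fixture()
    def toy(self, rng):
        X = rng.integers(1, 4, size=(5, 4))
        pats = [Partition(np.array([0, 0, 1, 1]), 2), Partition(np.zeros(4, dtype=int), 2)]
        cat = CSPCatalog(pats, np.array([30, 70]))
        prior = DirichletPrior(np.array([0.6, 0.9, 1.2]))
        return X, cat, prior

    def test_matches_term_by_term_oracle(self, toy):
        X, cat, prior = toy
        grouping = RiskGrouping(np.array([1, 1, 0, 0, 0], bool), np.array([0, 0, 1, 1, 0]))
        got = enrichment_log_posterior(grouping, X, cat, beta=12.0, prior=prior)
        expected = mixture_score(
            [True, True, False, False, False],
            [0, 0, 1, 1, 0],
            X.tolist(),
            [p.group_of.tolist() for p in cat.patterns],
            2,
            prior.alpha.tolist(),
            12.0,
            cat.frequencies.tolist(),
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_group1_reduces_to_beta_marginal(self, toy):
        X, cat, prior = toy
        grouping = RiskGrouping(np.zeros(5, bool), np.array([0, 1, 1, 0, 1]))
        beta = 10.0
        got = enrichment_log_posterior(grouping, X, cat, beta, prior)
        l2 = 5
        mix = (
            gammaln(1 + beta) + gammaln(l2 + beta)
            - gammaln(beta) - gammaln(l2 + 1 + beta)
        )
        # the l1 = 0 collapse keeps exactly the quoted Beta-marginal term
        direct = mixture_score(
            [False] * 5, [0, 1, 1, 0, 1], X.tolist(),
            [p.group_of.tolist() for p in cat.patterns], 2,
            prior.alpha.tolist(), beta, cat.frequencies.tolist(),
        )
        assert got == pytest.approx(direct, abs=1e-10)
        # assembled independently: Beta marginal + background term + state terms
        z2 = np.bincount([0, 1, 1, 0, 1], minlength=2)
        background = float((z2 * np.log(cat.frequencies)).sum())
        states_part = sum(
            dirichlet_multinomial_term(
                X[j].tolist(), cat.patterns[c].group_of.tolist(), 2, prior.alpha.tolist()
            )
            for j, c in enumerate([0, 1, 1, 0, 1])
        )
        assert got == pytest.approx(mix + background + states_part, abs=1e-10)

    def test_zero_frequency_pattern_in_group2_is_minus_inf(self, toy):
        X, _, prior = toy
        pats = [Partition(np.zeros(4, dtype=int), 2), Partition(np.array([0, 1, 1, 0]), 2)]
        cat = CSPCatalog(pats, np.array([10, 0]))
        grouping = RiskGrouping(np.zeros(5, bool), np.array([1, 0, 0, 0, 0]))
        assert enrichment_log_posterior(grouping, X, cat, 10.0, prior) == -math.inf


class TestFitEnrichment:
    def test_null_variants_mostly_assigned_to_background(self, default_instance, fitted):
        m, truth = default_instance
        fracs = []
        for seed in range(5):
            risk, _ = synth.gen_variants(
                truth, m, enrichment_fold=1.0, n_risk=100, n_null=10, seed=seed
            )
            res = EnrichmentModel(risk, fitted.catalog, beta=10, prior=fitted.prior).fit(
                seed=seed
            )
            fracs.append(res.group1_fraction)
        assert np.mean(fracs) <= 0.10

    def test_planted_enrichment_dominates_group1(self, default_instance, fitted):
        m, truth = default_instance
        risk, _ = synth.gen_variants(
            truth, m, enriched_patterns=(1,), enrichment_fold=10,
            n_risk=100, n_null=10, seed=3,
        )
        res = EnrichmentModel(risk, fitted.catalog, beta=10, prior=fitted.prior).fit(seed=3)
        assert res.group1_fraction > 0.2
        z1, _ = res.grouping.z_counts(fitted.catalog.n_patterns)
        # the planted pattern (split 6|6) should dominate group 1
        planted = truth.patterns[1]
        best = int(np.argmax(z1))
        assert fitted.catalog.patterns[best] == Partition(planted, 5)

    def test_growing_beta_empties_group1(self, default_instance, fitted):
        m, truth = default_instance
        risk, _ = synth.gen_variants(
            truth, m, enriched_patterns=(1,), enrichment_fold=5,
            n_risk=60, n_null=10, seed=5,
        )
        fracs = []
        for beta in (10.0, 1e3, 1e6):
            res = EnrichmentModel(risk, fitted.catalog, beta=beta, prior=fitted.prior).fit(
                seed=5
            )
            fracs.append(res.group1_fraction)
        assert fracs[0] >= fracs[-1]
        assert fracs[-1] == 0.0

    def test_single_variant_goes_to_background(self, default_instance, fitted):
        m, truth = default_instance
        risk, _ = synth.gen_variants(truth, m, n_risk=1, n_null=10, seed=2)
        res = EnrichmentModel(risk, fitted.catalog, beta=10, prior=fitted.prior).fit(seed=2)
        assert res.grouping.l1 == 0

    def test_monotone_score_after_annealing(self, default_instance, fitted):
        m, truth = default_instance
        risk, _ = synth.gen_variants(truth, m, n_risk=80, n_null=10, seed=7)
        res = EnrichmentModel(risk, fitted.catalog, beta="auto", prior=fitted.prior).fit(
            seed=7
        )
        assert np.all(np.diff(res.score_history[50:]) >= -1e-8)


class TestPermutationTest:
    def test_null_draws_give_large_pvalues(self, rng):
        bg = CSPAssignment(rng.integers(0, 4, size=5000))
        risk = bg.M[rng.integers(0, 5000, size=200)]
        rep = csp_permutation_test(risk, bg, n_perm=500, seed=1)
        assert (rep["p_two_sided"] > 0.05).sum() >= 3
        assert rep["p_two_sided"].between(0, 1).all()

    def test_extreme_enrichment_attains_minimal_p(self, rng):
        M_bg = np.zeros(5000, dtype=np.int64)
        M_bg[:50] = 1  # background frequency 1%
        risk = np.ones(50, dtype=np.int64)
        n_perm = 999
        rep = csp_permutation_test(risk, M_bg, n_perm=n_perm, seed=2)
        row = rep.set_index("pattern").loc[1]
        assert row["p_two_sided"] == pytest.approx(2 / (n_perm + 1))
        assert row["direction"] == "enriched"

    def test_single_permutation_bounded(self, rng):
        bg = rng.integers(0, 3, size=100)
        rep = csp_permutation_test(bg[:10], bg, n_perm=1, seed=0)
        assert (rep["p_two_sided"] <= 1).all()

    def test_background_smaller_than_risk_rejected(self):
        with pytest.raises(ValueError):
            csp_permutation_test(np.zeros(10, int), np.zeros(5, int))

    def test_pvalues_roughly_uniform_under_null(self, rng):
        bg = CSPAssignment(rng.integers(0, 2, size=20000))
        pvals = []
        for seed in range(60):
            risk = bg.M[rng.integers(0, 20000, size=100)]
            rep = csp_permutation_test(risk, bg, n_perm=200, seed=seed)
            pvals.append(rep["p_two_sided"].iloc[0])
        # two-sided doubling + discreteness make p slightly conservative;
        # only require no gross anti-conservatism
        assert np.mean(np.array(pvals) <= 0.05) <= 0.12

    def test_cluster_level_permutation_runs(self, rng):
        bg = rng.integers(0, 3, size=1000)
        risk = bg[:20]
        clusters = np.repeat(np.arange(5), 4)
        rep = csp_permutation_test(risk, bg, n_perm=100, seed=0, ld_clusters=clusters)
        assert rep["p_two_sided"].between(0, 1).all()
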