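"""Feature construction, GLM fitting, PR-AUC and split-based evaluation."""

import numpy as np
import pytest

from cspattern import (
    CSPCatalog,
    ComponentMap,
    DirichletPrior,
    Partition,
    VariantPredictionModel,
    allstate_indicators,
    csp_features,
    match_nulls,
    position_log_marginal,
    pr_auc,
    select_best_celltype,
    synth,
    train_glm,
)
from cspattern.prediction import celltype_indicators, evaluate_trait

from .oracles import average_precision


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_matches_rank_by_rank_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert pr_auc(scores, labels) == pytest.approx(
                average_precision(scores.tolist(), labels.tolist()), abs=1e-12
            )

    def test_random_scores_approach_prevalence(self, rng):
        n = 20000
        labels = (rng.random(n) < 0.2).astype(int)
        auc = pr_auc(rng.normal(size=n), labels)
        assert auc == pytest.approx(0.2, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [1, 1])


class TestComponentMap:
    def test_rank_deficient_input_caps_width(self, rng, caplog):
        base = rng.normal(size=(3, 10))
        X = rng.normal(size=(40, 3)) @ base  # rank 3
        with caplog.at_level("WARNING"):
            cmap = ComponentMap.fit(X, n_components=48)
        assert cmap.n_components == 3
        assert "rank" in caplog.text

    def test_projection_is_consistent_between_fit_and_transform(self, rng):
        X = rng.normal(size=(30, 8))
        cmap = ComponentMap.fit(X, n_components=5)
        again = cmap.transform(X)
        assert again.shape == (30, 5)
        assert np.allclose(cmap.transform(X[:1]), again[:1])

    def test_component_variances_match_eigendecomposition(self, rng):
        X = rng.normal(size=(50, 6)) * np.array([3, 2, 1.5, 1, 0.5, 0.2])
        cmap = ComponentMap.fit(X, n_components=6)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (len(X) - 1)))[::-1]
        assert np.all(np.diff(cmap.explained_variance_) <= 1e-12)
        assert np.allclose(cmap.explained_variance_, eigvals[:6], atol=1e-8)
        assert np.allclose(cmap.components_ @ cmap.components_.T, np.eye(6), atol=1e-10)


class TestFeatureBlocks:
    def test_csp_feature_width_and_values(self, rng):
        X = rng.integers(1, 4, size=(5, 4))
        pats = [Partition(np.array([0, 0, 1, 1]), 2), Partition(np.zeros(4, int), 2)]
        cat = CSPCatalog(pats, np.array([1, 1]))
        prior = DirichletPrior(np.array([0.5, 1.0, 1.5]))
        F = csp_features(X, cat, prior)
        assert F.shape == (5, 2)
        for j in range(5):
            for c, p in enumerate(pats):
                assert F[j, c] == pytest.approx(position_log_marginal(X[j], p, prior))

    def test_duplicate_patterns_give_identical_columns(self, rng):
        X = rng.integers(1, 3, size=(4, 3))
        p = Partition(np.array([0, 1, 0]), 2)
        cat = CSPCatalog([p, p], np.array([1, 1]))
        F = csp_features(X, cat, DirichletPrior(np.ones(2)))
        assert np.allclose(F[:, 0], F[:, 1])

    def test_allstate_indicator_arithmetic(self, rng):
        # 25 states x 127 epigenomes -> 3,175 indicator columns, rows sum to N
        X = rng.integers(1, 26, size=(10, 127))
        F = allstate_indicators(X, 25)
        assert F.shape == (10, 3175)
        assert np.all(F.sum(axis=1) == 127)

    def test_unseen_state_collapses_to_reference(self):
        train = np.array([1, 2, 2, 1])
        feats, levels = celltype_indicators(train, 4)
        test, _ = celltype_indicators(np.array([3, 1]), 4, levels)
        assert np.allclose(test[0], 0)  # state 3 unseen in training


class TestTrainGLM:
    def test_constant_features_give_constant_scores(self):
        X = np.zeros((20, 3))
        y = np.array([1] * 5 + [0] * 15)
        glm = train_glm(X, y)
        scores = glm.predict_proba(X)
        assert np.allclose(scores, scores[0])

    def test_separable_feature_preserves_ordering(self):
        x = np.linspace(-2, 2, 30)[:, None]
        y = (x.ravel() > 0).astype(int)
        glm = train_glm(x, y)
        scores = glm.predict_proba(x)
        assert np.all(np.diff(scores) >= -1e-12)

    def test_coefficient_recovery_on_simulated_data(self, rng):
        n = 2000
        X = rng.normal(size=(n, 2))
        beta = np.array([0.8, -1.2])
        logits = -0.3 + X @ beta
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        glm = train_glm(X, y)
        assert glm.backend == "glm"
        est = glm.params[1:]
        se = glm.bse[1:]
        assert np.all(np.abs(est - beta) < 3 * se)


class TestSingleCellType:
    def test_informative_celltype_recovered(self, rng):
        n, N, S = 200, 6, 4
        X = rng.integers(1, S + 1, size=(n, N))
        y = rng.integers(0, 2, size=n)
        X[:, 3] = np.where(y == 1, 4, rng.integers(1, 4, size=n))  # cell type 3 informative
        assert select_best_celltype(X, y, S) == 3

    def test_uninformative_states_stay_near_prevalence(self, rng):
        n, N, S = 300, 4, 3
        X = rng.integers(1, S + 1, size=(n, N))
        y = (rng.random(n) < 0.25).astype(int)
        best = select_best_celltype(X, y, S)
        feats, levels = celltype_indicators(X[:, best], S)
        auc = pr_auc(train_glm(feats, y).predict_proba(feats), y)
        assert auc < 0.45  # in-sample, still close to the 0.25 baseline


class TestMatchNulls:
    def test_pool_copy_matches_exactly(self, default_instance):
        m, truth = default_instance
        risk, _ = synth.gen_variants(truth, m, n_risk=40, n_null=10, seed=0)
        matched = match_nulls(risk, risk, seed=1)
        def hist(vs):
            bins = np.floor(vs.table["maf"].to_numpy() / 0.05).astype(int)
            return sorted(zip(bins, vs.table["annotation"]))
        assert hist(matched) == hist(risk)

    def test_uniform_pool_reproduces_risk_histogram(self, default_instance):
        m, truth = default_instance
        risk, null = synth.gen_variants(truth, m, n_risk=50, n_null=800, seed=3)
        matched = match_nulls(risk, null, seed=3)
        assert len(matched) == len(risk)
        rb = np.floor(risk.table["maf"].to_numpy() / 0.05).astype(int)
        mb = np.floor(matched.table["maf"].to_numpy() / 0.05).astype(int)
        import collections
        assert collections.Counter(zip(rb, risk.table["annotation"])) == collections.Counter(
            zip(mb, matched.table["annotation"])
        )

    def test_empty_cell_falls_back_with_warning(self, default_instance, caplog):
        m, truth = default_instance
        risk, null = synth.gen_variants(truth, m, n_risk=20, n_null=100, seed=4)
        pool = null.subset(np.where(null.table["annotation"] != "coding")[0])
        risk.table.loc[0, "annotation"] = "coding"
        with caplog.at_level("WARNING"):
            matched = match_nulls(risk, pool, seed=0)
        assert len(matched) == len(risk)
        assert "fallback" in caplog.text


class TestEvaluateTrait:
    def test_shuffled_labels_stay_near_prevalence(self, default_instance, fitted, clusters, rng):
        m, truth = default_instance
        risk, null = synth.gen_variants(truth, m, enrichment_fold=1.0,
                                        n_risk=60, n_null=240, seed=9)
        res = evaluate_trait(
            risk, null, "csp+enrichment", m.n_states, catalog=fitted.catalog,
            prior=fitted.prior, clusters=clusters, n_repeats=4, seed=0,
        )
        assert abs(res.mean_auc - 0.2) < 0.12

    def test_same_seed_reproduces_result(self, default_instance, fitted, clusters):
        m, truth = default_instance
        risk, null = synth.gen_variants(truth, m, n_risk=40, n_null=160, seed=5)
        kw = dict(catalog=fitted.catalog, prior=fitted.prior, clusters=clusters,
                  n_repeats=3, seed=21)
        a = evaluate_trait(risk, null, "csp+enrichment", m.n_states, **kw)
        b = evaluate_trait(risk, null, "csp+enrichment", m.n_states, **kw)
        assert np.array_equal(a.aucs, b.aucs)

    def test_too_few_risk_variants_skips_repeats(self, default_instance, fitted, clusters):
        m, truth = default_instance
        risk, null = synth.gen_variants(truth, m, n_risk=6, n_null=40, seed=6)
        res = evaluate_trait(
            risk, null, "csp+enrichment", m.n_states, catalog=fitted.catalog,
            prior=fitted.prior, clusters=clusters, n_repeats=2, seed=0,
        )
        assert len(res.skipped) == 2 and len(res.aucs) == 0

    def test_feature_width_is_patterns_plus_components(self, default_instance, fitted, clusters):
        m, truth = default_instance
        risk, null = synth.gen_variants(truth, m, n_risk=40, n_null=160, seed=8)
        model = VariantPredictionModel(
            risk, null, m.n_states, catalog=fitted.catalog, prior=fitted.prior,
            clusters=clusters,
        )
        rng = np.random.default_rng(0)
        train, test, _ = model._split(rng, 0.5)
        Xtr, Xte, _ = model._features(train, test)
        width = fitted.catalog.n_patterns + min(48, model._zblock[train].shape[1])
        # z block has S*G columns; rank caps the component count at desk scale
        assert Xtr.shape[1] <= width
        assert Xtr.shape[1] == Xte.shape[1]
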