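"""Risk-vs-null variant prediction from pattern likelihoods and state-enrichment
features, with precision-recall evaluation under repeated random splits.

Three feature sets are compared:

``csp+enrichment``
    Per-pattern Dirichlet-multinomial log likelihoods of the variant's state
    vector (C columns) concatenated with the leading principal components of
    the sign-log transformed state-by-cluster z-scores.
``all-states``
    Principal components of the one-hot state indicators over all epigenomes
    (S x N columns before reduction) — the additive, linear baseline.
``single-cell-type``
    Categorical state predictor from one epigenome at a time; the best
    epigenome is chosen on the training half only.

Component maps and cell-type selection are fitted on training halves only and
reused verbatim on test halves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .data import ClusterDefinition, VariantSet
from .model import CSPCatalog, DirichletPrior, partition_loglik
from .zscores import transform_z, variant_zscore_block

logger = logging.getLogger(__name__)

FEATURE_SETS = ("csp+enrichment", "all-states", "single-cell-type")


# ---------------------------------------------------------------------------
# feature construction


def csp_features(
    variant_states: np.ndarray, catalog: CSPCatalog, prior: DirichletPrior
) -> np.ndarray:
    """Per-pattern log likelihood of each variant's state vector: (n, C)."""
    if catalog.n_patterns == 0:
        raise ValueError("empty catalog")
    X = np.asarray(variant_states, dtype=np.int64)
    if X.ndim == 1:
        X = X[None, :]
    return np.column_stack([partition_loglik(X, pat, prior) for pat in catalog.patterns])


def zscore_feature_matrix(
    variants: VariantSet, clusters: ClusterDefinition, n_states: int
) -> np.ndarray:
    """Sign-log transformed, flattened S x G z-scores per variant: (n, S*G)."""
    block = variant_zscore_block(variants, clusters, n_states)
    return transform_z(block).reshape(block.shape[0], -1)


def allstate_indicators(variant_states: np.ndarray, n_states: int) -> np.ndarray:
    """One-hot state indicators over all epigenomes: (n, S*N); rows sum to N."""
    X = np.asarray(variant_states, dtype=np.int64)
    n, N = X.shape
    out = np.zeros((n, n_states * N))
    cols = np.arange(N) * n_states + (X - 1)
    out[np.arange(n)[:, None], cols] = 1.0
    return out


@dataclass
class ComponentMap:
    """Centered principal-component projection learned on training data.

    The identical loadings are applied to test data; inputs are centered but
    not rescaled (the feature blocks are already on a common scale).
    """

    mean_: np.ndarray
    components_: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, n_components: int) -> "ComponentMap":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a component map")
        limit = min(n_components, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=limit, svd_solver="full")
        pca.fit(X)
        ev = pca.explained_variance_
        keep = ev > max(ev.max(), 1.0) * 1e-12 if len(ev) else np.zeros(0, bool)
        width = int(keep.sum())
        if width < n_components:
            logger.warning(
                "component map rank %d below requested %d components", width, n_components
            )
        return cls(pca.mean_, pca.components_[keep], ev[keep])

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T


def enrichment_features(
    variants: VariantSet | np.ndarray,
    clusters: ClusterDefinition | None = None,
    n_states: int | None = None,
    n_components: int = 48,
) -> tuple[np.ndarray, ComponentMap]:
    """Reduced z-score feature block for training variants, plus the fitted map.

    Accepts either a VariantSet (z-scores computed here) or a precomputed
    transformed z-score block.
    """
    if isinstance(variants, VariantSet):
        block = zscore_feature_matrix(variants, clusters, n_states)
    else:
        block = np.asarray(variants, dtype=float)
    cmap = ComponentMap.fit(block, n_components)
    return cmap.transform(block), cmap


def allstate_features(
    variants: VariantSet | np.ndarray,
    n_states: int | None = None,
    n_components: int = 96,
) -> tuple[np.ndarray, ComponentMap]:
    """Reduced one-hot state-indicator block plus the fitted component map."""
    if isinstance(variants, VariantSet):
        block = allstate_indicators(variants.states, n_states)
    else:
        block = np.asarray(variants, dtype=float)
    cmap = ComponentMap.fit(block, n_components)
    return cmap.transform(block), cmap


def celltype_indicators(
    states_column: np.ndarray, n_states: int, levels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Categorical one-hot for a single epigenome's states (reference = first level).

    ``levels`` fixes the training-time category set; states unseen in training
    collapse to the reference level.
    """
    s = np.asarray(states_column, dtype=np.int64)
    if levels is None:
        levels = np.unique(s)
    non_ref = levels[1:]
    out = (s[:, None] == non_ref[None, :]).astype(float)
    return out, levels


# ---------------------------------------------------------------------------
# GLM and evaluation


@dataclass
class FittedGLM:
    """Logistic model with a consistent score interface across backends."""

    params: np.ndarray
    bse: np.ndarray | None
    backend: str
    _predict: object = field(repr=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._predict(np.asarray(X, dtype=float))


def train_glm(features: np.ndarray, labels: np.ndarray, ridge_alpha: float = 1.0) -> FittedGLM:
    """Fit a binomial GLM of risk (1) vs null (0) labels on the feature matrix.

    Uses iteratively reweighted least squares; under complete separation or
    non-convergence it falls back to a weak L2 (ridge) logistic fit.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e4:
            raise ValueError("unstable coefficients (separation suspected)")
        return FittedGLM(
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            backend="glm",
            _predict=lambda Z: np.asarray(
                res.predict(sm.add_constant(Z, has_constant="add"))
            ),
        )
    except Exception as exc:  # separation, singular design, non-convergence
        logger.warning("GLM fit failed (%s); falling back to ridge logistic", exc)
        clf = LogisticRegression(C=1.0 / ridge_alpha, max_iter=2000)
        clf.fit(X, y.astype(int))
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return FittedGLM(
            params=params,
            bse=None,
            backend="ridge",
            _predict=lambda Z: clf.predict_proba(Z)[:, 1],
        )


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, as step-wise average precision."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("PR-AUC needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def single_celltype_model(
    train_states: np.ndarray,
    train_labels: np.ndarray,
    cell_type: int,
    n_states: int,
) -> tuple[FittedGLM, np.ndarray]:
    """Fit the categorical single-epigenome predictor for one cell type."""
    feats, levels = celltype_indicators(train_states[:, cell_type], n_states)
    return train_glm(feats, train_labels), levels


def select_best_celltype(
    train_states: np.ndarray, train_labels: np.ndarray, n_states: int
) -> int:
    """Cell type with the best in-sample PR-AUC on the training half.

    Ties break to the lowest column index.  Selection never sees test data.
    """
    best, best_auc = 0, -np.inf
    for i in range(train_states.shape[1]):
        glm, levels = single_celltype_model(train_states, train_labels, i, n_states)
        feats, _ = celltype_indicators(train_states[:, i], n_states, levels)
        auc = pr_auc(glm.predict_proba(feats), train_labels)
        if auc > best_auc + 1e-12:
            best, best_auc = i, auc
    return best


def match_nulls(
    risk: VariantSet,
    pool: VariantSet,
    maf_bin_width: float = 0.05,
    seed: int = 0,
) -> VariantSet:
    """Sample a null set matching the risk (MAF bin x annotation) histogram.

    Sampling is without replacement within each cell; an occupied cell that is
    empty in the pool falls back to the nearest MAF bin in the same annotation
    category (then to the nearest bin regardless of category), with a warning.
    """
    rng = np.random.default_rng(seed)
    risk_bins = np.floor(risk.table["maf"].to_numpy() / maf_bin_width).astype(int)
    pool_bins = np.floor(pool.table["maf"].to_numpy() / maf_bin_width).astype(int)
    pool_ann = pool.table["annotation"].to_numpy()
    taken = np.zeros(len(pool), dtype=bool)
    chosen: list[int] = []
    cells = pd.DataFrame(
        {"bin": risk_bins, "annotation": risk.table["annotation"].to_numpy()}
    ).value_counts()
    for (b, ann), want in cells.items():
        for _ in range(int(want)):
            avail = np.where((pool_bins == b) & (pool_ann == ann) & ~taken)[0]
            if len(avail) == 0:
                same_ann = np.where((pool_ann == ann) & ~taken)[0]
                fallback = same_ann if len(same_ann) else np.where(~taken)[0]
                if len(fallback) == 0:
                    raise ValueError("null pool exhausted")
                logger.warning(
                    "empty pool cell (bin=%s, annotation=%s); nearest-MAF fallback", b, ann
                )
                avail = fallback[
                    np.abs(pool_bins[fallback] - b) == np.abs(pool_bins[fallback] - b).min()
                ]
            pick = int(rng.choice(avail))
            taken[pick] = True
            chosen.append(pick)
    return pool.subset(np.array(sorted(chosen)))


@dataclass
class EvalResult:
    """Per-repeat PR-AUCs of one trait under one feature set."""

    feature_set: str
    aucs: np.ndarray
    n_repeats: int
    skipped: list[str] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs)) if len(self.aucs) else float("nan")

    def summary(self) -> str:
        return (
            f"EvalResult({self.feature_set}): mean PR-AUC "
            f"{self.mean_auc:.4f} over {len(self.aucs)}/{self.n_repeats} repeats"
            + (f"; skipped: {len(self.skipped)}" if self.skipped else "")
        )


class VariantPredictionModel:
    """Risk-vs-null predictor for one trait, evaluated under repeated splits.

    Parameters
    ----------
    risk, null : VariantSet
        The trait's risk variants (label 1) and matched null variants (label 0).
    catalog, prior : fitted CSP catalog and state prior (``csp+enrichment`` only).
    clusters : ClusterDefinition (``csp+enrichment`` only).
    n_states : int
        Number of chromatin states S.
    feature_set : one of ``csp+enrichment``, ``all-states``, ``single-cell-type``.
    n_enrichment_components, n_allstate_components : PCA widths (defaults 48, 96).
    """

    def __init__(
        self,
        risk: VariantSet,
        null: VariantSet,
        n_states: int,
        feature_set: str = "csp+enrichment",
        catalog: CSPCatalog | None = None,
        prior: DirichletPrior | None = None,
        clusters: ClusterDefinition | None = None,
        n_enrichment_components: int = 48,
        n_allstate_components: int = 96,
    ):
        if feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if feature_set == "csp+enrichment" and (catalog is None or clusters is None):
            raise ValueError("csp+enrichment needs a catalog and a cluster definition")
        self.risk, self.null = risk, null
        self.S = n_states
        self.feature_set = feature_set
        self.catalog = catalog
        self.clusters = clusters
        if prior is None and catalog is not None:
            prior = DirichletPrior.from_proportions(np.full(n_states, 1.0 / n_states))
        self.prior = prior
        self.n_enrich = n_enrichment_components
        self.n_allstate = n_allstate_components
        # precompute split-independent per-variant blocks
        self._states = np.vstack([risk.states, null.states])
        self._labels = np.concatenate([np.ones(len(risk)), np.zeros(len(null))])
        if feature_set == "csp+enrichment":
            self._csp = csp_features(self._states, catalog, self.prior)
            z_risk = zscore_feature_matrix(risk, clusters, n_states)
            z_null = zscore_feature_matrix(null, clusters, n_states)
            self._zblock = np.vstack([z_risk, z_null])
        elif feature_set == "all-states":
            self._onehot = allstate_indicators(self._states, n_states)

    def _split(self, rng: np.random.Generator, split: float):
        def half(n):
            idx = rng.permutation(n)
            cut = int(round(split * n))
            return idx[:cut], idx[cut:]

        r_tr, r_te = half(len(self.risk))
        n_tr, n_te = half(len(self.null))
        train = np.concatenate([r_tr, len(self.risk) + n_tr])
        test = np.concatenate([r_te, len(self.risk) + n_te])
        return train, test, (len(r_tr), len(r_te))

    def _features(self, train: np.ndarray, test: np.ndarray):
        if self.feature_set == "csp+enrichment":
            _, cmap = enrichment_features(self._zblock[train], n_components=self.n_enrich)
            Xtr = np.hstack([self._csp[train], cmap.transform(self._zblock[train])])
            Xte = np.hstack([self._csp[test], cmap.transform(self._zblock[test])])
            return Xtr, Xte, None
        if self.feature_set == "all-states":
            _, cmap = allstate_features(self._onehot[train], n_components=self.n_allstate)
            return cmap.transform(self._onehot[train]), cmap.transform(self._onehot[test]), None
        # single cell type: select on the training half only
        best = select_best_celltype(self._states[train], self._labels[train], self.S)
        feats_tr, levels = celltype_indicators(self._states[train, best], self.S)
        feats_te, _ = celltype_indicators(self._states[test, best], self.S, levels)
        return feats_tr, feats_te, best

    def evaluate(self, n_repeats: int = 10, split: float = 0.5, seed: int = 0) -> EvalResult:
        """Mean test-half PR-AUC over independent 50/50 splits.

        Repeats where either half holds fewer than five risk variants are
        skipped with a reason recorded.
        """
        seeds = np.random.SeedSequence(seed).spawn(n_repeats)
        aucs, skipped = [], []
        for r in range(n_repeats):
            rng = np.random.default_rng(seeds[r])
            train, test, (n_r_tr, n_r_te) = self._split(rng, split)
            if min(n_r_tr, n_r_te) < 5:
                skipped.append(f"repeat {r}: <5 risk variants in a half")
                continue
            Xtr, Xte, _ = self._features(train, test)
            glm = train_glm(Xtr, self._labels[train])
            aucs.append(pr_auc(glm.predict_proba(Xte), self._labels[test]))
        return EvalResult(self.feature_set, np.array(aucs), n_repeats, skipped)


def evaluate_trait(
    risk: VariantSet,
    null: VariantSet,
    feature_set: str,
    n_states: int,
    catalog: CSPCatalog | None = None,
    prior: DirichletPrior | None = None,
    clusters: ClusterDefinition | None = None,
    n_repeats: int = 10,
    split: float = 0.5,
    seed: int = 0,
) -> EvalResult:
    """Convenience wrapper: build a :class:`VariantPredictionModel` and evaluate."""
    model = VariantPredictionModel(
        risk,
        null,
        n_states,
        feature_set=feature_set,
        catalog=catalog,
        prior=prior,
        clusters=clusters,
    )
    return model.evaluate(n_repeats=n_repeats, split=split, seed=seed)
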