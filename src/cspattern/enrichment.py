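"""Risk-variant sub-selection under a two-group mixture, and permutation tests
for pattern enrichment/depletion at disease variants.

The mixture says each risk variant either (group 1) co-occurs with the fitted
patterns at unknown, trait-specific frequencies, or (group 2) follows the
genome background frequencies p_c.  The group fractions carry a Beta(1, beta)
prior with beta >= 10, so the null (everything in group 2) is favored unless
the data say otherwise; the group-1 pattern frequencies carry a Dirichlet(1)
prior and are integrated out.  Inference is annealed iterative conditional
maximization over each variant's group label and pattern index, mirroring the
genome-wide model fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import VariantSet
from .model import (
    CSPAssignment,
    CSPCatalog,
    DirichletPrior,
    _anneal_temperature,
    _pick,
    partition_loglik,
)

logger = logging.getLogger(__name__)


@dataclass
class RiskGrouping:
    """Mixture state of a fitted enrichment model.

    ``in_group1`` flags the pattern-associated variants; ``M`` holds each
    variant's inferred pattern index (0-based into the catalog).
    """

    in_group1: np.ndarray
    M: np.ndarray

    def __post_init__(self):
        self.in_group1 = np.asarray(self.in_group1, dtype=bool)
        self.M = np.asarray(self.M, dtype=np.int64)
        if len(self.in_group1) != len(self.M):
            raise ValueError("group flags and pattern indices differ in length")

    @property
    def l1(self) -> int:
        return int(self.in_group1.sum())

    @property
    def l2(self) -> int:
        return int((~self.in_group1).sum())

    def z_counts(self, n_patterns: int) -> tuple[np.ndarray, np.ndarray]:
        z1 = np.bincount(self.M[self.in_group1], minlength=n_patterns)
        z2 = np.bincount(self.M[~self.in_group1], minlength=n_patterns)
        return z1, z2

    @property
    def group1_fraction(self) -> float:
        return self.l1 / len(self.M) if len(self.M) else 0.0


def choose_beta(variants: VariantSet) -> float:
    """Null-favoring prior weight: max(10, largest LD-cluster size)."""
    if len(variants) == 0:
        raise ValueError("empty variant set")
    return float(max(10, int(variants.ld_cluster_sizes.max())))


def enrichment_log_posterior(
    grouping: RiskGrouping,
    variant_states: np.ndarray,
    catalog: CSPCatalog,
    beta: float,
    prior: DirichletPrior,
) -> float:
    """Joint log score of a grouping under the two-group mixture.

    Beta-marginal term in (l1, l2, beta), Dirichlet(1)-marginal term over the
    group-1 pattern counts, background multinomial term for group 2, plus the
    state log marginal of every variant under its assigned pattern.
    """
    C = catalog.n_patterns
    p = catalog.frequencies
    l1, l2 = grouping.l1, grouping.l2
    z1, z2 = grouping.z_counts(C)
    score = (
        gammaln(1 + beta)
        + gammaln(l1 + 1)
        + gammaln(l2 + beta)
        - gammaln(beta)
        - gammaln(l1 + l2 + 1 + beta)
    )
    score += gammaln(C) - gammaln(l1 + C) + gammaln(z1 + 1).sum()
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    if np.any((z2 > 0) & np.isneginf(logp)):
        logger.warning("group-2 count on a zero-frequency pattern: score is -inf")
        return -math.inf
    score += float(np.where(z2 > 0, z2 * logp, 0.0).sum())
    X = np.asarray(variant_states, dtype=np.int64)
    for c in range(C):
        rows = np.where(grouping.M == c)[0]
        if len(rows):
            score += partition_loglik(X[rows], catalog.patterns[c], prior).sum()
    return float(score)


def fit_enrichment(
    variants: VariantSet | np.ndarray,
    catalog: CSPCatalog,
    beta: float | str = "auto",
    prior: DirichletPrior | None = None,
    n_iter: int = 100,
    anneal_iters: int = 50,
    t0: float = 5.0,
    seed: int = 0,
) -> "EnrichmentResults":
    """Fit the two-group enrichment mixture to a risk-variant set."""
    return EnrichmentModel(variants, catalog, beta=beta, prior=prior).fit(
        n_iter=n_iter, anneal_iters=anneal_iters, t0=t0, seed=seed
    )


class EnrichmentModel:
    """Two-group pattern-enrichment mixture for one trait's risk variants.

    Parameters
    ----------
    variants : VariantSet or (n, N) state array
        Risk variants with their per-epigenome state vectors.
    catalog : CSPCatalog
        Fitted pattern catalog supplying the background frequencies p_c.
    beta : float or "auto"
        Beta(1, beta) prior weight for the null group; "auto" applies
        max(10, largest LD-cluster size).
    prior : DirichletPrior, optional
        State prior; defaults to a flat prior over the states seen at the
        variants (pass the genome-wide prior from the CSP fit in practice).
    """

    def __init__(self, variants, catalog: CSPCatalog, beta="auto", prior=None):
        if isinstance(variants, VariantSet):
            self.variants = variants
            self.X = variants.states
        else:
            self.variants = None
            self.X = np.asarray(variants, dtype=np.int64)
        if self.X.shape[0] == 0:
            raise ValueError("empty variant set")
        if beta == "auto":
            if self.variants is None:
                raise ValueError('beta="auto" needs a VariantSet with LD clusters')
            beta = choose_beta(self.variants)
        if beta < 1:
            raise ValueError("beta must be >= 1 to favor the null")
        self.beta = float(beta)
        self.catalog = catalog
        if prior is None:
            S = int(self.X.max())
            prior = DirichletPrior.from_proportions(np.full(S, 1.0 / S))
        self.prior = prior

    def fit(
        self, n_iter: int = 100, anneal_iters: int = 50, t0: float = 5.0, seed: int = 0
    ) -> "EnrichmentResults":
        rng = np.random.default_rng(seed)
        n = self.X.shape[0]
        C = self.catalog.n_patterns
        beta = self.beta
        with np.errstate(divide="ignore"):
            logp = np.log(self.catalog.frequencies)

        lik = np.column_stack(
            [partition_loglik(self.X, pat, self.prior) for pat in self.catalog.patterns]
        )
        in1 = rng.random(n) < 0.5
        M = rng.integers(0, C, size=n)
        z1, z2 = RiskGrouping(in1, M).z_counts(C)
        l1 = int(in1.sum())

        history: list[float] = []
        converged = False
        for sweep in range(n_iter):
            temp = _anneal_temperature(sweep, anneal_iters, t0)
            changed = 0
            for j in range(n):
                c_old, g_old = M[j], in1[j]
                if g_old:
                    z1[c_old] -= 1
                    l1 -= 1
                else:
                    z2[c_old] -= 1
                l2 = n - 1 - l1
                # candidate scores for (group 1, c) then (group 2, c)
                s1 = lik[j] + math.log(l1 + 1) - math.log(l1 + C) + np.log(z1 + 1)
                s2 = lik[j] + math.log(l2 + beta) + logp
                scores = np.concatenate([s1, s2])
                pick = _pick(scores, temp, rng)
                g_new, c_new = pick < C, pick % C
                if g_new != g_old or c_new != c_old:
                    changed += 1
                M[j] = c_new
                in1[j] = g_new
                if g_new:
                    z1[c_new] += 1
                    l1 += 1
                else:
                    z2[c_new] += 1
            history.append(
                enrichment_log_posterior(
                    RiskGrouping(in1.copy(), M.copy()), self.X, self.catalog, beta, self.prior
                )
            )
            if changed == 0 and temp is None:
                converged = True
                break
        return EnrichmentResults(
            model=self,
            grouping=RiskGrouping(in1, M),
            score_history=np.array(history),
            converged=converged,
        )


@dataclass
class EnrichmentResults:
    """Fitted mixture: which risk variants are pattern-associated, and where."""

    model: EnrichmentModel
    grouping: RiskGrouping
    score_history: np.ndarray
    converged: bool

    @property
    def group1_index(self) -> np.ndarray:
        return np.where(self.grouping.in_group1)[0]

    @property
    def group1_fraction(self) -> float:
        return self.grouping.group1_fraction

    def summary(self) -> str:
        g = self.grouping
        lines = [
            "Pattern-enrichment mixture",
            f"  variants: {len(g.M)}  beta: {self.model.beta:g}",
            f"  group 1 (pattern-associated): {g.l1} ({100 * g.group1_fraction:.1f}%)",
            f"  group 2 (background): {g.l2}",
            f"  final log score: {self.score_history[-1]:.3f}",
        ]
        if g.l1:
            z1, _ = g.z_counts(self.model.catalog.n_patterns)
            top = np.argsort(z1)[::-1]
            lines.append("  top group-1 patterns: " + ", ".join(
                f"{c} (n={z1[c]})" for c in top[:5] if z1[c] > 0
            ))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# permutation test


def csp_permutation_test(
    risk_patterns: np.ndarray,
    background: CSPAssignment | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    ld_clusters: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-sided permutation p-values for per-pattern enrichment/depletion.

    Draws ``n_perm`` sets of ``len(risk_patterns)`` positions (with
    replacement) from the background assignment and compares per-pattern
    co-occurrence counts.  Each tail probability uses the add-one correction
    (r + 1) / (n_perm + 1); the two-sided p doubles the smaller tail, capped
    at 1.  ``signed_log10_p`` is -log10(p) with a negative sign for depletion.

    If ``ld_clusters`` labels each risk variant with its LD cluster, a single
    background position is drawn per cluster and shared by its members, so the
    permutation preserves the dependence structure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    risk_patterns = np.asarray(risk_patterns, dtype=np.int64)
    M_bg = background.M if isinstance(background, CSPAssignment) else np.asarray(background)
    n = len(risk_patterns)
    if len(M_bg) < n:
        raise ValueError("background assignment smaller than the risk set")
    C = int(max(risk_patterns.max(), M_bg.max())) + 1
    rng = np.random.default_rng(seed)

    obs = np.bincount(risk_patterns, minlength=C)
    p_bg = np.bincount(M_bg, minlength=C) / len(M_bg)
    expected = n * p_bg

    if ld_clusters is not None:
        ld_clusters = np.asarray(ld_clusters)
        uniq, inv = np.unique(ld_clusters, return_inverse=True)
        draws_cluster = M_bg[rng.integers(0, len(M_bg), size=(n_perm, len(uniq)))]
        draws = draws_cluster[:, inv]
    else:
        draws = M_bg[rng.integers(0, len(M_bg), size=(n_perm, n))]

    rows = []
    for c in range(C):
        counts_c = (draws == c).sum(axis=1)
        p_ge = ((counts_c >= obs[c]).sum() + 1) / (n_perm + 1)
        p_le = ((counts_c <= obs[c]).sum() + 1) / (n_perm + 1)
        p_two = min(1.0, 2.0 * min(p_ge, p_le))
        direction = np.sign(obs[c] - expected[c])
        rows.append(
            {
                "pattern": c,
                "observed": int(obs[c]),
                "expected": expected[c],
                "p_two_sided": p_two,
                "signed_log10_p": float(direction * -math.log10(p_two)) if p_two < 1 else 0.0,
                "direction": {1.0: "enriched", -1.0: "depleted", 0.0: "none"}[float(direction)],
            }
        )
    return pd.DataFrame(rows)
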