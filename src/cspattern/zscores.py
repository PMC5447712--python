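"""Epigenetic-state enrichment z-scores over fixed epigenome clusters.

At a variant, every epigenome carries one chromatin state; for each state s and
cluster g the count of s inside g is compared with its expectation under the
cluster's share p_g of all epigenomes, normal-approximation standardized with a
+1 variance floor so empty counts give exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClusterDefinition, VariantSet


@dataclass
class ZScoreMatrix:
    """State-by-cluster enrichment scores (S x G), raw or sign-log transformed."""

    values: np.ndarray
    transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("z-score matrix must be finite")

    @property
    def shape(self):
        return self.values.shape

    def transform(self) -> "ZScoreMatrix":
        if self.transformed:
            return self
        return ZScoreMatrix(transform_z(self.values), transformed=True)

    def flatten(self) -> np.ndarray:
        return self.values.ravel()


def state_zscore(n_sg: float, n_s_neg_g: float, p_g: float) -> float:
    """z = (n_sg - n_s * p_g) / sqrt(n_s * p_g * (1 - p_g) + 1), n_s = n_sg + n_s,-g."""
    if not 0 < p_g < 1:
        raise ValueError("p_g must lie strictly between 0 and 1")
    if n_sg < 0 or n_s_neg_g < 0:
        raise ValueError("counts must be non-negative")
    n_s = n_sg + n_s_neg_g
    return float((n_sg - n_s * p_g) / np.sqrt(n_s * p_g * (1 - p_g) + 1))


def transform_z(z):
    """Sign-preserving log shrinkage: sign(z) * log(|z| + 1)."""
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.log(np.abs(z) + 1.0)
    return out if out.ndim else float(out)


def variant_zscores(
    states_at_variant: np.ndarray,
    clusters: ClusterDefinition,
    n_states: int,
    epigenome_ids: list[str],
) -> ZScoreMatrix:
    """S x G raw z-score matrix for one variant's state vector."""
    states_at_variant = np.asarray(states_at_variant, dtype=np.int64)
    member = clusters.membership(epigenome_ids)
    G = clusters.n_clusters
    p_g = clusters.proportions(epigenome_ids)
    # counts[s, g] = number of epigenomes in cluster g carrying state s+1
    counts = np.zeros((n_states, G))
    np.add.at(counts, (states_at_variant - 1, member), 1)
    n_s = counts.sum(axis=1, keepdims=True)
    z = (counts - n_s * p_g) / np.sqrt(n_s * p_g * (1 - p_g) + 1)
    return ZScoreMatrix(z)


def variant_zscore_block(
    variants: VariantSet, clusters: ClusterDefinition, n_states: int
) -> np.ndarray:
    """Stacked raw z matrices for a variant set, shape (n_variants, S, G)."""
    return np.stack(
        [
            variant_zscores(row, clusters, n_states, variants.epigenome_ids).values
            for row in variants.states
        ]
    )


def trait_zscores(
    risk: VariantSet,
    null: VariantSet,
    clusters: ClusterDefinition,
    n_states: int,
    transform: bool = False,
) -> ZScoreMatrix:
    """Trait-level background-subtracted enrichment matrix.

    Mean raw z over the risk variants minus the mean over the null variants,
    entrywise; subtraction happens on the raw scale, with the sign-log
    transform optionally applied afterwards.
    """
    if len(risk) == 0 or len(null) == 0:
        raise ValueError("risk and null sets must be non-empty")
    mean_risk = variant_zscore_block(risk, clusters, n_states).mean(axis=0)
    mean_null = variant_zscore_block(null, clusters, n_states).mean(axis=0)
    out = ZScoreMatrix(mean_risk - mean_null)
    return out.transform() if transform else out
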