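"""Seeded generators for every input the package consumes, with planted ground
truth for parameter-recovery tests.

The state-matrix generator follows the model's own generative story: each
position draws a pattern (an epigenome partition) from fixed frequencies, each
group of the partition draws a state distribution, and group members emit
states i.i.d. from it.  Group distributions are symmetric-Dirichlet draws whose
largest coordinate is swapped onto a per-group dominant state sampled without
replacement across the groups of a position, so different groups of the same
position always favor different states (well-separated groups; without this a
two-group position whose groups happen to share a dominant state is
indistinguishable from a constitutive one and the planted label is
meaningless).

The default desk-scale instance is 12 epigenomes x 2,000 windows x 6 states
with four planted patterns — one constitutive pattern at 70% frequency
(mirroring the dominance of non-cell-type-specific genome observed in real
multi-epigenome segmentations) and three two-group patterns at 10% each — plus
200 risk and 1,000 null variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import StateMatrix, VariantSet, attach_states
from .power import SnpPanel

ANNOTATION_VOCAB = ("intergenic", "intronic", "utr", "coding", "regulatory")
ANNOTATION_PROBS = (0.35, 0.30, 0.10, 0.10, 0.15)

DEFAULT_N = 12
DEFAULT_L = 2000
DEFAULT_S = 6
DEFAULT_FREQS = (0.70, 0.10, 0.10, 0.10)


def default_patterns(n_epigenomes: int = DEFAULT_N) -> list[np.ndarray]:
    """Planted partitions: one constitutive plus three distinct two-group splits."""
    n = n_epigenomes
    h = n // 2
    p0 = np.zeros(n, dtype=np.int64)
    p1 = np.array([0] * h + [1] * (n - h))
    third = n // 4
    p2 = np.array([0] * third + [1] * (n - 2 * third) + [0] * third)
    p3 = np.array([j % 2 for j in range(n)])
    return [p0, p1, p2, p3]


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside every generated dataset."""

    patterns: list[np.ndarray]
    pattern_freqs: np.ndarray
    position_pattern: np.ndarray
    concentration: float
    seed: int
    enriched_patterns: list[int] = field(default_factory=list)
    enrichment_fold: float = 1.0

    def to_json(self, path) -> None:
        payload = {
            "patterns": [p.tolist() for p in self.patterns],
            "pattern_freqs": np.asarray(self.pattern_freqs).tolist(),
            "position_pattern": self.position_pattern.tolist(),
            "concentration": self.concentration,
            "seed": self.seed,
            "enriched_patterns": list(self.enriched_patterns),
            "enrichment_fold": self.enrichment_fold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            [np.array(p) for p in d["patterns"]],
            np.array(d["pattern_freqs"]),
            np.array(d["position_pattern"]),
            d["concentration"],
            d["seed"],
            d.get("enriched_patterns", []),
            d.get("enrichment_fold", 1.0),
        )


def gen_state_matrix(
    n_epigenomes: int = DEFAULT_N,
    n_windows: int = DEFAULT_L,
    n_states: int = DEFAULT_S,
    true_patterns: list[np.ndarray] | None = None,
    pattern_freqs=DEFAULT_FREQS,
    concentration: float = 0.02,
    window_size: int = 200,
    chrom: str = "chr1",
    seed: int = 0,
) -> tuple[StateMatrix, PlantedTruth]:
    """Generate a state matrix from planted partitions with group-specific states."""
    if true_patterns is None:
        true_patterns = default_patterns(n_epigenomes)
    freqs = np.asarray(pattern_freqs, dtype=float)
    if len(freqs) != len(true_patterns):
        raise ValueError("one frequency per planted pattern required")
    if abs(freqs.sum() - 1.0) > 1e-9 or np.any(freqs < 0):
        raise ValueError("pattern_freqs must be a probability vector")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    for p in true_patterns:
        if len(p) != n_epigenomes:
            raise ValueError("pattern length must equal n_epigenomes")
        if len(np.unique(p)) > n_states:
            raise ValueError("more groups than states: dominant states cannot be distinct")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(true_patterns), size=n_windows, p=freqs)
    states = np.empty((n_windows, n_epigenomes), dtype=np.int64)
    alpha = np.full(n_states, concentration)
    for j in range(n_windows):
        pat = true_patterns[labels[j]]
        groups = np.unique(pat)
        dominants = rng.choice(n_states, size=len(groups), replace=False)
        for g, dom in zip(groups, dominants):
            theta = rng.dirichlet(alpha)
            top = int(np.argmax(theta))
            theta[top], theta[dom] = theta[dom], theta[top]
            members = np.where(pat == g)[0]
            states[j, members] = rng.choice(n_states, size=len(members), p=theta) + 1

    starts = np.arange(n_windows) * window_size
    windows = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + window_size}
    )
    ids = [f"E{i + 1:03d}" for i in range(n_epigenomes)]
    matrix = StateMatrix(ids, windows, states, n_states, window_size)
    truth = PlantedTruth(
        [np.asarray(p) for p in true_patterns], freqs, labels, concentration, seed
    )
    return matrix, truth


def default_clusters(epigenome_ids: list[str], n_clusters: int = 2):
    """Cluster definition aligned with the default first planted split."""
    from .data import ClusterDefinition

    n = len(epigenome_ids)
    per = max(1, n // n_clusters)
    return ClusterDefinition(
        {e: min(i // per, n_clusters - 1) + 1 for i, e in enumerate(epigenome_ids)}
    )


def _variant_table(
    windows: np.ndarray,
    matrix: StateMatrix,
    label: str,
    prefix: str,
    ld_cluster_size: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    n_clusters = int(np.ceil(len(windows) / ld_cluster_size))
    for k in range(n_clusters):
        members = windows[k * ld_cluster_size : (k + 1) * ld_cluster_size]
        cluster_id = f"{prefix}{k}"
        for w in members:
            win = matrix.window(int(w))
            pos = int(rng.integers(win.start, win.end))
            rows.append(
                {
                    "variant_id": f"{prefix}v{len(rows)}",
                    "chrom": win.chrom,
                    "pos": pos,
                    "ld_cluster": cluster_id,
                    "maf": float(np.round(rng.uniform(0.01, 0.5), 4)),
                    "annotation": rng.choice(ANNOTATION_VOCAB, p=ANNOTATION_PROBS),
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


def gen_variants(
    truth: PlantedTruth,
    matrix: StateMatrix,
    enriched_patterns=(1,),
    enrichment_fold: float = 10.0,
    n_risk: int = 200,
    n_null: int = 1000,
    ld_cluster_size: int = 1,
    seed: int = 0,
) -> tuple[VariantSet, VariantSet]:
    """Generate risk variants enriched at windows carrying chosen patterns.

    Risk LD clusters land on windows sampled with weight ``enrichment_fold``
    where the planted pattern is in ``enriched_patterns`` and weight 1
    elsewhere; proxies share their lead's window.  Null variants sample windows
    uniformly.  MAF and annotation come from the same model for both sets, so
    matched-null construction is testable.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    enriched = set(int(c) for c in enriched_patterns)
    labels = truth.position_pattern
    if enrichment_fold > 1 and not any(int(c) in enriched for c in np.unique(labels)):
        raise ValueError("no windows carry the requested enriched patterns")
    rng = np.random.default_rng(seed)

    w = np.where(np.isin(labels, list(enriched)), enrichment_fold, 1.0)
    w = w / w.sum()
    n_lead = int(np.ceil(n_risk / ld_cluster_size))
    lead_windows = rng.choice(len(labels), size=n_lead, p=w)
    risk_windows = np.repeat(lead_windows, ld_cluster_size)[:n_risk]
    null_windows = rng.integers(0, len(labels), size=n_null)

    risk_df = _variant_table(risk_windows, matrix, "risk", "r", ld_cluster_size, rng)
    null_df = _variant_table(null_windows, matrix, "null", "n", ld_cluster_size, rng)
    truth.enriched_patterns = sorted(enriched)
    truth.enrichment_fold = enrichment_fold
    return attach_states(risk_df, matrix), attach_states(null_df, matrix)


def gen_ld_panel(
    n_snps: int,
    block_size: int = 20,
    r_within: float = 0.8,
    seed: int = 0,
    spacing: int = 500,
    block_gap: int = 2_000_000,
) -> SnpPanel:
    """Block-diagonal LD panel; blocks separated beyond the 500 kb LD radius.

    Within-block spacing keeps whole blocks inside one LD window, so indirect
    association from a causal SNP spans exactly its block.
    """
    idx = np.arange(n_snps)
    block = idx // block_size
    within = idx % block_size
    positions = block * block_gap + within * spacing
    return SnpPanel(positions, block, r_within)


def simulate_dataset(preset: str = "default", seed: int = 0) -> dict:
    """One-call generation of a coherent dataset for all downstream modules."""
    if preset == "default":
        matrix, truth = gen_state_matrix(seed=seed)
        risk, null = gen_variants(truth, matrix, seed=seed + 1)
    elif preset == "tiny":
        matrix, truth = gen_state_matrix(n_windows=300, seed=seed)
        risk, null = gen_variants(truth, matrix, n_risk=40, n_null=200, seed=seed + 1)
    elif preset == "null":
        matrix, truth = gen_state_matrix(seed=seed)
        risk, null = gen_variants(truth, matrix, enrichment_fold=1.0, seed=seed + 1)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    clusters = default_clusters(matrix.epigenome_ids)
    return {
        "states": matrix,
        "truth": truth,
        "risk": risk,
        "null": null,
        "clusters": clusters,
    }
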