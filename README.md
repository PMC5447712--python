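# cspattern

Most disease-associated variants found by genome-wide association studies
(GWAS) are noncoding, and their effects on gene regulation are often
cell-type-specific.  `cspattern` is a toolkit for regulatory genomicists who
want to exploit that: given a multi-epigenome chromatin-state segmentation (a
position × epigenome matrix of integer state labels, e.g. an IDEAS- or
ChromHMM-style 25-state annotation of the 127 Roadmap/ENCODE epigenomes), it

1. discovers recurring **cell-type-specificity patterns (CSPs)** — partitions
   of the epigenomes into groups such that, within a group, chromatin states
   at a position share one distribution — with a Bayesian partition model;
2. quantifies CSP **enrichment at disease risk variants** with a two-group
   mixture and permutation tests;
3. computes **state-enrichment z-scores** over fixed epigenome clusters;
4. **predicts risk vs. null variants** from CSP likelihoods plus z-score
   principal components, against linear all-cell-type and best-single-cell-type
   baselines, evaluated by precision-recall AUC under repeated 50/50 splits;
5. simulates **prior-weighted GWAS power**, allocating the genome-wide testing
   budget by each SNP's predicted probability of being causal.

A seeded synthetic-data module generates every input with planted ground
truth, so the whole pipeline is testable end to end.

## The model

Let `X[i,j] ∈ {1..S}` be the state of epigenome `i = 1..N` at genomic window
`j = 1..L`.  A CSP `Ω_c` assigns the N epigenomes to at most K groups; window
j carries pattern `M_j ∈ {1..C}`.  Within each group k of the window's
pattern, states are multinomial with position-specific parameters, integrated
out under a Dirichlet(α) prior:

```
Pr(X[·,j] | Ω) = ∏_k  Γ(|α|)/∏_s Γ(α_s) · ∏_s Γ(n_kjs + α_s) / Γ(|n_kj| + |α|)
```

with `n_kjs` the count of state s in group k, and α set to 5 × the genome-wide
state proportions.  Group memberships and pattern frequencies carry
Dirichlet(1) priors and are integrated out as well, so the posterior is a
function of the discrete `{M_j}` and the groupings alone.  Fitting is by
iterative conditional maximization with a simulated-annealing prefix; the
Bayesian Occam penalty leaves excess pattern capacity empty, which is pruned.

For a trait's risk variants, a two-group mixture asks which variants co-occur
with CSPs at trait-specific frequencies (group 1) versus genome background
frequencies `p_c` (group 2); a Beta(1, β) prior with
β = max(10, largest LD-cluster size) favors the null.

For power, each SNP i receives the significance threshold
`p_i = p_cut · π_i / |π|` (uniform π = Bonferroni), where π are
predictor-derived causal priors; power is the fraction of simulated causal
SNPs within 1 kb of a detected significant SNP.

## Worked example

```python
from cspattern import synth, CSPModel, EnrichmentModel

matrix, truth = synth.gen_state_matrix(seed=0)      # 12 epigenomes x 2000 windows
res = CSPModel(matrix, n_patterns=10, n_groups=5).fit(
    n_iter=100, train_fraction=0.5, seed=0)
print(res.summary())
```

```
Cell-type-specificity pattern model
  positions: 2000 (trained on 1000)
  epigenomes: 12  capacity: 10 patterns x 5 groups
  non-empty patterns: 4
  final log posterior (training): -11312.994
  converged: True

  pattern groups    count  genome%
        0      2      193     9.7%
        1      2      179     8.9%
        2      1     1448    72.4%
        3      2      180     9.0%
```

The generator planted four patterns — one constitutive (all epigenomes in one
group, 70% of windows) and three two-group splits at 10% each — and the fit
recovers exactly that structure: pattern 2 is the constitutive pattern at
72.4% of the genome, and the three split patterns sit near their planted 10%
frequencies.  Excess capacity (10 patterns were allowed) is left empty and
pruned.

```python
risk, null = synth.gen_variants(truth, matrix, enriched_patterns=(1,),
                                enrichment_fold=10, n_risk=100, n_null=500, seed=1)
er = EnrichmentModel(risk, res.catalog, beta="auto", prior=res.prior).fit(seed=1)
print(er.summary())
```

```
Pattern-enrichment mixture
  variants: 100  beta: 10
  group 1 (pattern-associated): 46 (46.0%)
  group 2 (background): 54
  final log score: -1229.329
  top group-1 patterns: 1 (n=46)
```

The risk variants were planted at 10× background co-occurrence with one split
pattern; the mixture flags 46% of them as pattern-associated, all on that
pattern.  On risk sets drawn at background frequencies, the group-1 fraction
drops to a few percent.

A command-line interface mirrors the library
(`cspattern simulate|fit-csp|assign|enrich|zscores|predict|power`, each with
`--seed` and `--help`).

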