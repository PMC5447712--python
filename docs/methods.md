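# Methods

## Cell-type-specificity patterns

A CSP is a partition Ω of the N epigenomes into at most K groups.  The model
assumes that, conditional on the pattern at a window, the chromatin states of
the epigenomes within a group are exchangeable multinomial draws with
position-specific parameters.  Three integrations give a closed-form discrete
posterior:

* state frequencies within each (group, position) — Dirichlet(α), with α the
  genome-wide state proportions of the training subsample scaled to sum to 5
  (zero-frequency states floored at 1e-6 before scaling so every
  concentration stays positive);
* group memberships within each pattern — Dirichlet(1) over K groups, giving
  the prior Γ(K)·∏_k Γ(m_k+1)/Γ(N+K), which prefers concentrated partitions
  (Occam behavior: patterns and groups that the data do not need stay empty);
* genome pattern frequencies — Dirichlet(1) over C patterns, giving the
  occupancy term Γ(C)/Γ(L+C)·∏_c Γ(o_c+1).

The occupancy term has a configuration switch (`eq4_as_printed=True`) that
replaces Γ(o_c+1) with Γ(o_c+C).  The default is the normalized
Dirichlet-multinomial form; the alternative reproduces a variant of the
objective in which the per-pattern occupancy factor is inflated by the
capacity, which changes only the strength of the rich-get-richer effect
during assignment updates, not the maximizers on well-separated data.

### Fitting

Iterative conditional updates over the two discrete blocks: each window's
pattern index (enumerating all C candidates) and each epigenome's group in
each pattern (enumerating all K candidates), both scored by the exact change
in the joint posterior.  The first `anneal_iters` sweeps (default 50) sample
each update proportional to exp(Δ/T) with T decaying linearly from `t0`
(default 5) to 1; all later sweeps maximize, so the joint score is
non-decreasing from the end of annealing onward (asserted per sweep in the
tests).  Ties break to the lowest index, making runs reproducible under a
fixed seed.  Convergence = a full sweep with no change, or the iteration cap.

Two choices here departed from the obvious defaults, for cause:

* **Initialization is data-driven, not uniform-random.**  Each pattern's
  grouping is seeded from the distinct states at a randomly chosen training
  window (epigenomes sharing a state start in one group).  Uniform-random
  groupings collapse irrecoverably: from a one-group state, moving any single
  epigenome into its own group is penalized at every window (a singleton
  group forfeits the pooled-count likelihood), so a split that only pays once
  several epigenomes have moved together is never discovered by single-site
  updates.  Seeding from observed state vectors starts the sweeps at exactly
  the partitions the data can express.
* **Empty and duplicate patterns are reseeded during annealing.**  After each
  annealing sweep, any pattern with no windows, and any pattern whose
  canonical grouping duplicates a better-occupied one, is re-initialized from
  a window in the worst-fitting decile.  This is the classic empty-cluster
  move of k-means-style algorithms; it gives structure that lost the early
  competition fresh capacity.  It runs only while annealing, so the
  post-annealing monotonicity contract is untouched.

The annealing temperature should be commensurate with per-window
log-likelihood differences, which grow with N: at N=127 they are an order of
magnitude larger than at the desk-scale N=12, so a t0 tuned for one scale is
merely a hotter or colder start at another.  With reseeding the fit is robust
across t0 ∈ [1, 5] at desk scale.

Training uses a random subsample of windows (`train_fraction`); the remaining
windows are assigned afterwards by `assign_positions`, the MAP rule
argmax_c [log p_c + log marginal], with p_c the training occupancy
frequencies.  The library default keeps `train_fraction = 0.05`, appropriate
when L is in the millions; the desk-scale tests and the acceptance script use
0.5 of L = 2,000 windows, since what matters for estimating up to C·K group
memberships is the absolute number of training windows per pattern, not the
fraction.

## Enrichment mixture

Risk variants are modeled as a two-group mixture: group 1 co-occurs with
patterns at unknown trait-specific frequencies (Dirichlet(1), integrated
out), group 2 follows the genome background frequencies p_c taken from the
fitted catalog.  The group-1 weight q carries a Beta(1, β) prior; β is
max(10, largest LD-cluster size), which makes the null (no enrichment) the
preferred explanation — under background-drawn risk sets the fitted group-1
fraction averages a few percent, and it goes to zero as β grows.  Each
variant's pattern index is re-inferred inside the mixture rather than frozen
from the genome-wide assignment, and the state term of the score runs over
all risk variants under their current patterns.  Inference mirrors the
genome-wide fit (same annealing schedule), jointly enumerating the 2C
(group, pattern) candidates per variant.

Per-pattern permutation tests draw |risk| positions from the background
assignment with replacement (optionally one draw per LD cluster, shared by
its members) and report two-sided p-values: the smaller of the ≥/≤ tail
probabilities, each with the add-one correction (r+1)/(n_perm+1), doubled and
capped at 1.  The doubling plus discreteness makes the test slightly
conservative, never anti-conservative.

## State-enrichment z-scores

At a variant, for state s and epigenome cluster g (cluster definitions are an
input; G = 10 at full scale), z = (n_sg − n_s·p_g)/√(n_s·p_g(1−p_g)+1), with
n_s the total count of state s and p_g the cluster's share of epigenomes —
fixed genome-wide, not per position.  The +1 variance floor sends empty
counts to exactly zero.  Trait-level matrices average raw z over risk
variants and subtract the null-variant mean on the raw scale (averaging raw z
is variance-stable); the sign-log transform sign(z)·log(|z|+1) is applied
afterwards where features are needed.

## Prediction

Three feature sets feed a binomial GLM (IRLS; on separation or
non-convergence a weak L2 logistic fit is substituted, with a warning):

* **csp+enrichment** — C per-pattern Dirichlet-multinomial log likelihoods of
  the variant's state vector, plus the leading principal components (48 at
  full scale, rank-capped at desk scale) of the transformed S×G z-scores;
* **all-states** — principal components (96 at full scale, matching 48+48) of
  the S·N one-hot state indicators: the additive linear baseline;
* **single-cell-type** — one epigenome's state as a categorical predictor;
  the epigenome is chosen by in-sample PR-AUC on the training half only.

Component maps center but do not rescale (the blocks are already on common
scales), are fitted on training halves only, and are reused verbatim on test
halves; test-time state levels unseen in training collapse to the reference
level.  Evaluation is mean test-half average precision (step-wise PR-AUC —
interpolated PR curves are biased) over independent 50/50 splits (default
10); repeats leaving fewer than five risk variants in either half are skipped
with a reason.  Null sets are matched to the risk (MAF bin × annotation)
histogram by seeded sampling without replacement, with a nearest-bin fallback
for empty pool cells.  The trait's full risk set enters prediction without
the mixture's sub-selection.

## Power simulation

SNP panels are block-structured: correlation r_within inside a block, zero
across blocks, blocks separated beyond the 500 kb LD radius.  Causal SNPs are
placed by walking a predictor's precision-recall profile: at recall x with
precision q, the x·n_causal causal SNPs drawn so far must lie within the top
x·n_causal/q ranked SNPs, each increment sampling uniformly from that top set.
Effect sizes are N(0.1, 0.05²) (mean/sd), signed ±1 with equal probability,
and converted to statistics t = log(1+λ)·√n at n = 2,000 samples.  The
printed-division form t = log(1+λ)/n is available as `literal_t=True`; at
n = 2,000 it yields |t| ≈ 5·10⁻⁵ and zero power, so the √n scaling (the
standard per-observation log-odds effect aggregated over n samples) is the
default.  Non-causal SNPs within 500 kb of a causal SNP receive
r·t + √(1−r²)·z from their nearest causal; detection applies two-sided normal
p-values against the per-SNP thresholds p_i = p_cut·π_i/|π| (Σp_i = p_cut
exactly; uniform π is Bonferroni), and power is the fraction of causal SNPs
within 1 kb of a detected SNP.  Under the global null with uniform priors the
family-wise error stays at p_cut up to Monte-Carlo error; priors concentrated
near true causals raise power over the uniform run on the same seeds.

## Synthetic study conditions

The generator follows the model's own generative story.  Defaults: N = 12
epigenomes, L = 2,000 windows of 200 bp, S = 6 states, four planted patterns —
one constitutive at 70% frequency (mirroring the dominance of
non-cell-type-specific genome in real multi-epigenome segmentations) and
three distinct two-group splits at 10% each — with 200 risk and 1,000 null
variants, sized so the full suite runs in minutes.  Per position, each group
draws a state distribution from a symmetric Dirichlet(concentration) whose
largest coordinate is swapped onto a dominant state sampled without
replacement across the position's groups, so groups are well separated by
construction; without that, a two-group position whose groups happen to share
a dominant state is observationally constitutive and the planted label is
unidentifiable.  The default concentration is 0.02, chosen so that the
Bayes-optimal assignment under the true model recovers the planted labels
with ARI ≈ 0.92 — i.e. recovery benchmarks measure the fitter, not
irreducible emission noise (at concentration 0.1 the oracle itself tops out
near ARI 0.72).  Risk variants are placed on windows sampled with weight
`enrichment_fold` on the chosen patterns; LD clusters share their lead's
window; MAF is Uniform(0.01, 0.5) and annotations come from a five-category
vocabulary with identical distributions for risk and null sets, so
histogram-matching is testable.

What the generator does **not** emulate: realistic state-frequency profiles
(real segmentations have tens of states with highly skewed frequencies),
spatial autocorrelation of states along the genome, annotation errors
correlated across epigenomes, empirical LD (r decays continuously, not in
blocks), or MAF-dependent variant density.  Passing tests therefore
demonstrate correctness and internal consistency of the machinery under the
model's own assumptions at desk scale — not performance on Roadmap-scale
data, whose headline quantities depend on the real 127-epigenome maps and
GWAS-Catalog traits.

## Numerical choices and degenerate inputs

All Γ-terms are computed as log-gammas (scipy `gammaln`); empty groups
contribute exactly zero to the position marginal, so K is an upper bound, not
a commitment.  Ties in any argmax break to the lowest index.  A pattern with
zero background frequency but group-2 variants scores −∞ and is logged.
Catalogs with no non-empty patterns, empty variant sets, single-class label
vectors, non-positive Dirichlet concentrations, and thresholds outside (0,1)
raise immediately.  PCA widths are capped at the input rank with a warning.
Seeds propagate through `numpy.random.SeedSequence` spawning, so every
documented entry point is a pure function of its seed.

## Known limitations

The fitter is a mode-finder, not a sampler: it reports a MAP configuration
with no uncertainty over partitions.  Pattern capacity C and group capacity K
are fixed inputs (the Occam penalty prunes, but does not grow, capacity).
The permutation test treats background windows as exchangeable, ignoring
genomic autocorrelation.  The power simulator's block-LD panel and
profile-based causal placement are deliberate simplifications of fine-mapping
reality; its absolute power numbers are specific to the simulated panel size
and effect model and should be read comparatively (weighted vs. uniform), not
as field estimates.
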