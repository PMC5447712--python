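"""Bayesian model of recurring cell-type-specificity patterns (CSPs).

A CSP is a partition of the N epigenomes into at most K groups.  Conditional on
the pattern at a genomic position, the chromatin states of the epigenomes in
each group are exchangeable draws from a group- and position-specific
multinomial whose parameters are integrated out under a Dirichlet prior, giving
a closed-form Dirichlet-multinomial marginal per position.  Pattern occurrence
frequencies across the genome and the group memberships within each pattern are
likewise integrated out under Dirichlet(1) priors, so the whole posterior is a
function of two discrete variable blocks only: the per-position pattern index
M_j and the per-pattern epigenome grouping.  Fitting is by iterative
conditional maximization with a simulated-annealing prefix to escape local
modes.

All group and pattern indices are 0-based in code; state labels are 1..S as in
the input files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import StateMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DirichletPrior:
    """Dirichlet prior over the S chromatin states within a group.

    Built as (scale x genome-wide proportion of each state); zero-frequency
    states are floored so every concentration stays strictly positive.
    """

    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def total(self) -> float:
        return float(self.alpha.sum())

    @property
    def n_states(self) -> int:
        return len(self.alpha)

    @classmethod
    def from_proportions(cls, proportions, scale: float = 5.0, floor: float = 1e-6):
        p = np.maximum(np.asarray(proportions, dtype=float), floor)
        p = p / p.sum()
        return cls(scale * p)

    @classmethod
    def from_states(cls, states: StateMatrix, rows=None, scale: float = 5.0):
        return cls.from_proportions(states.state_proportions(rows), scale=scale)


@dataclass
class Partition:
    """Assignment of N epigenomes to groups 0..K-1 (empty groups permitted)."""

    group_of: np.ndarray
    n_groups: int

    def __post_init__(self):
        self.group_of = np.asarray(self.group_of, dtype=np.int64)
        if self.group_of.size and (
            self.group_of.min() < 0 or self.group_of.max() >= self.n_groups
        ):
            raise ValueError("group indices must lie in [0, n_groups)")

    @property
    def n_epigenomes(self) -> int:
        return len(self.group_of)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_of, minlength=self.n_groups)

    @property
    def n_nonempty_groups(self) -> int:
        return int((self.group_sizes > 0).sum())

    def canonical(self) -> "Partition":
        """Renumber groups by the index of their first member epigenome.

        Makes label-switched partitions comparable and serialization stable.
        """
        remap: dict[int, int] = {}
        for g in self.group_of:
            if int(g) not in remap:
                remap[int(g)] = len(remap)
        return Partition(np.array([remap[int(g)] for g in self.group_of]), self.n_groups)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.n_groups == other.n_groups and np.array_equal(
            self.canonical().group_of, other.canonical().group_of
        )


@dataclass
class CSPCatalog:
    """A set of fitted patterns with their genome occurrence counts.

    ``counts[c]`` is the number of assigned positions carrying pattern c;
    ``frequencies`` are the normalized counts used as prior pattern weights
    when extending the assignment to new positions.
    """

    patterns: list[Partition]
    counts: np.ndarray
    capacity: int | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.patterns):
            raise ValueError("one count per pattern required")
        if self.capacity is None:
            self.capacity = len(self.patterns)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.full(len(self.counts), np.nan)
        return self.counts / total

    @property
    def n_nonempty(self) -> int:
        return int((self.counts > 0).sum())

    def pruned(self) -> "CSPCatalog":
        """Drop empty patterns and canonicalize group labels."""
        keep = np.where(self.counts > 0)[0]
        pats = [self.patterns[c].canonical() for c in keep]
        return CSPCatalog(pats, self.counts[keep], capacity=len(keep))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CSPCatalog):
            return NotImplemented
        return (
            len(self.patterns) == len(other.patterns)
            and np.array_equal(self.counts, other.counts)
            and all(a == b for a, b in zip(self.patterns, other.patterns))
        )

    def save(self, path) -> None:
        """Serialize as a human-diffable text file (one pattern per row)."""
        with open(path, "w") as fh:
            fh.write(f"#cspattern-catalog\tn_patterns={len(self.patterns)}\n")
            fh.write("pattern_id\tcount\tn_groups\tgroup_of\n")
            for c, (pat, o) in enumerate(zip(self.patterns, self.counts)):
                groups = ",".join(str(int(g)) for g in pat.group_of)
                fh.write(f"{c}\t{int(o)}\t{pat.n_groups}\t{groups}\n")

    @classmethod
    def load(cls, path) -> "CSPCatalog":
        from .data import ParseError

        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines or not lines[0].startswith("#cspattern-catalog"):
            raise ParseError(f"{path}: not a catalog file")
        try:
            n_expected = int(lines[0].split("n_patterns=")[1])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed catalog header") from exc
        patterns, counts = [], []
        for ln in lines[2:]:
            parts = ln.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}: malformed catalog row {ln!r}")
            _, o, k, groups = parts
            patterns.append(
                Partition(np.array([int(g) for g in groups.split(",")]), int(k))
            )
            counts.append(int(o))
        if len(patterns) != n_expected:
            raise ParseError(
                f"{path}: truncated catalog ({len(patterns)} of {n_expected} patterns)"
            )
        return cls(patterns, np.array(counts))


@dataclass
class CSPAssignment:
    """Per-position pattern indices (0-based into a catalog)."""

    M: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.M)

    def counts(self, n_patterns: int) -> np.ndarray:
        return np.bincount(self.M, minlength=n_patterns)


# ---------------------------------------------------------------------------
# scoring


def _group_counts(X: np.ndarray, group_of: np.ndarray, n_groups: int, S: int) -> np.ndarray:
    """Per-position state counts within each group: shape (L, K, S)."""
    L = X.shape[0]
    counts = np.zeros((L, n_groups, S), dtype=np.int64)
    rows = np.arange(L)
    for i, g in enumerate(group_of):
        np.add.at(counts, (rows, g, X[:, i] - 1), 1)
    return counts


def partition_loglik(X: np.ndarray, partition: Partition, prior: DirichletPrior) -> np.ndarray:
    """Dirichlet-multinomial log marginal of each row of X under a partition.

    For each position, sums over groups k:
    logGamma(|a|) - sum_s logGamma(a_s) + sum_s logGamma(n_ks + a_s)
    - logGamma(n_k + |a|).  Empty groups contribute exactly zero.
    """
    X = np.asarray(X, dtype=np.int64)
    alpha, A = prior.alpha, prior.total
    S = prior.n_states
    K = partition.n_groups
    sizes = partition.group_sizes
    const = gammaln(A) - gammaln(alpha).sum()
    counts = _group_counts(X, partition.group_of, K, S)
    out = np.zeros(X.shape[0])
    for k in range(K):
        if sizes[k] == 0:
            continue
        out += (
            const
            + gammaln(counts[:, k, :] + alpha).sum(axis=1)
            - gammaln(sizes[k] + A)
        )
    return out


def position_log_marginal(states_at_j, partition: Partition, prior: DirichletPrior) -> float:
    """Log marginal likelihood of one position's state vector under a partition."""
    states_at_j = np.asarray(states_at_j, dtype=np.int64)
    return float(partition_loglik(states_at_j[None, :], partition, prior)[0])


def partition_log_prior(partition: Partition) -> float:
    """Dirichlet(1)-multinomial log prior of an epigenome grouping.

    logGamma(K) + sum_k logGamma(m_k + 1) - logGamma(N + K).
    """
    m = partition.group_sizes
    K = partition.n_groups
    return float(gammaln(K) + gammaln(m + 1).sum() - gammaln(m.sum() + K))


def model_log_posterior(
    catalog: CSPCatalog,
    assignment: CSPAssignment,
    states: StateMatrix | np.ndarray,
    prior: DirichletPrior,
    eq4_as_printed: bool = False,
) -> float:
    """Joint log posterior (up to a constant) of a catalog and assignment.

    Sum of per-position Dirichlet-multinomial terms under the assigned
    patterns, plus the marginalized pattern-frequency term
    logGamma(C) - logGamma(L + C) + sum_c logGamma(o_c + 1), plus the group
    prior of every pattern.  ``eq4_as_printed`` switches the per-pattern
    occupancy term to logGamma(o_c + C).
    """
    X = states.states if isinstance(states, StateMatrix) else np.asarray(states)
    C = len(catalog.patterns)
    M = assignment.M
    if len(M) and (M.min() < 0 or M.max() >= C):
        raise ValueError("assignment indexes a pattern outside the catalog")
    o = assignment.counts(C)
    score = 0.0
    for c in range(C):
        rows = np.where(M == c)[0]
        if len(rows):
            score += partition_loglik(X[rows], catalog.patterns[c], prior).sum()
    off = C if eq4_as_printed else 1
    score += gammaln(C) - gammaln(len(M) + C) + gammaln(o + off).sum()
    score += sum(partition_log_prior(p) for p in catalog.patterns)
    return float(score)


def assign_positions(
    catalog: CSPCatalog, states: StateMatrix | np.ndarray, prior: DirichletPrior
) -> CSPAssignment:
    """MAP pattern index per position: argmax_c [log p_c + log marginal].

    Ties break to the lowest pattern index.  Requires a catalog with at least
    one non-empty pattern (positive frequency).
    """
    if isinstance(states, StateMatrix):
        X = states.states
    else:
        X = np.asarray(states, dtype=np.int64)
    if catalog.n_nonempty == 0:
        raise ValueError("catalog has no non-empty patterns")
    freqs = catalog.frequencies
    scores = np.full((X.shape[0], len(catalog.patterns)), -np.inf)
    for c, pat in enumerate(catalog.patterns):
        if freqs[c] > 0:
            scores[:, c] = math.log(freqs[c]) + partition_loglik(X, pat, prior)
    return CSPAssignment(np.argmax(scores, axis=1))


# ---------------------------------------------------------------------------
# fitting


def _anneal_temperature(sweep: int, anneal_iters: int, t0: float) -> float | None:
    """Linear decay from t0 to 1 across the annealing prefix; None = maximize."""
    if sweep >= anneal_iters:
        return None
    if anneal_iters == 1:
        return t0
    return t0 + (1.0 - t0) * sweep / (anneal_iters - 1)


def _pick(scores: np.ndarray, temperature: float | None, rng: np.random.Generator) -> int:
    if temperature is None:
        return int(np.argmax(scores))  # argmax: lowest index wins ties
    w = np.exp((scores - scores.max()) / temperature)
    w /= w.sum()
    return int(rng.choice(len(scores), p=w))


class _GroupUpdater:
    """Incremental conditional updates of one pattern's epigenome grouping.

    Keeps the (L_c, K, S) within-group state counts for the positions currently
    assigned to the pattern, so that moving one epigenome between groups costs
    O(L_c) instead of a full likelihood re-evaluation.
    """

    def __init__(self, X_c: np.ndarray, group_of: np.ndarray, K: int, prior: DirichletPrior):
        self.X = X_c
        self.group_of = group_of
        self.K = K
        self.alpha = prior.alpha
        self.A = prior.total
        self.counts = _group_counts(X_c, group_of, K, prior.n_states)
        self.sizes = np.bincount(group_of, minlength=K)
        self.rows = np.arange(X_c.shape[0])

    def move_scores(self, i: int) -> np.ndarray:
        """Score of moving epigenome i to each group, relative to staying put."""
        a = self.group_of[i]
        s = self.X[:, i] - 1
        delta = np.zeros(self.K)
        # removing i from its current group changes that group's terms once
        lose = (
            -np.log(self.counts[self.rows, a, s] - 1 + self.alpha[s]).sum()
            + len(self.rows) * math.log(self.sizes[a] - 1 + self.A)
        )
        for k in range(self.K):
            if k == a:
                continue
            gain = (
                np.log(self.counts[self.rows, k, s] + self.alpha[s]).sum()
                - len(self.rows) * math.log(self.sizes[k] + self.A)
            )
            # Dirichlet(1) grouping prior: move from group of size m_a to m_k
            prior_delta = math.log(self.sizes[k] + 1) - math.log(self.sizes[a])
            delta[k] = lose + gain + prior_delta
        return delta

    def apply(self, i: int, k: int) -> bool:
        a = self.group_of[i]
        if k == a:
            return False
        s = self.X[:, i] - 1
        np.subtract.at(self.counts, (self.rows, a, s), 1)
        np.add.at(self.counts, (self.rows, k, s), 1)
        self.sizes[a] -= 1
        self.sizes[k] += 1
        self.group_of[i] = k
        return True


def fit_csp_model(
    states: StateMatrix | np.ndarray,
    n_patterns: int = 50,
    n_groups: int = 5,
    n_iter: int = 100,
    anneal_iters: int = 50,
    t0: float = 5.0,
    train_fraction: float = 0.05,
    seed: int = 0,
    eq4_as_printed: bool = False,
    prior: DirichletPrior | None = None,
) -> "CSPResults":
    """Fit the CSP model by annealed iterative conditional maximization.

    A random ``train_fraction`` of positions is used to fit the catalog; the
    remaining positions are assigned afterwards by MAP extension under the
    fitted pattern frequencies.  During the first ``anneal_iters`` sweeps,
    candidate values of each discrete variable are sampled with probability
    proportional to exp(score / T) with T decaying linearly from ``t0`` to 1;
    subsequent sweeps maximize, so the joint score is non-decreasing from then
    on.  Empty patterns are pruned from the returned catalog.
    """
    model = CSPModel(
        states,
        n_patterns=n_patterns,
        n_groups=n_groups,
        eq4_as_printed=eq4_as_printed,
        prior=prior,
    )
    return model.fit(
        n_iter=n_iter,
        anneal_iters=anneal_iters,
        t0=t0,
        train_fraction=train_fraction,
        seed=seed,
    )


class CSPModel:
    """Cell-type-specificity pattern model for a state matrix.

    Parameters
    ----------
    states : StateMatrix or (L, N) integer array
        Chromatin-state labels (1..S).  A bare array is wrapped with synthetic
        window coordinates.
    n_patterns : int
        Pattern capacity C.  Patterns left empty by the Occam behavior of the
        marginal likelihood are pruned after fitting.
    n_groups : int
        Maximum groups K per pattern.
    prior : DirichletPrior, optional
        State prior; by default built from the training subsample's state
        proportions, scaled by 5.
    eq4_as_printed : bool
        Use the Gamma(o_c + C) occupancy term instead of the normalized
        Gamma(o_c + 1) form.
    """

    def __init__(
        self,
        states,
        n_patterns: int = 50,
        n_groups: int = 5,
        prior: DirichletPrior | None = None,
        eq4_as_printed: bool = False,
    ):
        if isinstance(states, StateMatrix):
            self.states = states
            self.X = states.states
            self.S = states.n_states
        else:
            self.X = np.asarray(states, dtype=np.int64)
            self.states = None
            self.S = int(self.X.max())
        if self.X.shape[0] < 1:
            raise ValueError("need at least one position")
        if n_patterns < 1 or n_groups < 1:
            raise ValueError("n_patterns and n_groups must be >= 1")
        self.C = n_patterns
        self.K = n_groups
        self.prior = prior
        self.eq4_as_printed = eq4_as_printed

    def fit(
        self,
        n_iter: int = 100,
        anneal_iters: int = 50,
        t0: float = 5.0,
        train_fraction: float = 0.05,
        seed: int = 0,
    ) -> "CSPResults":
        if not 0 < train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        L, N = self.X.shape
        n_train = int(round(train_fraction * L))
        if n_train < 1:
            raise ValueError("train_fraction selects no positions")
        rng = np.random.default_rng(seed)
        train_idx = np.sort(rng.choice(L, size=n_train, replace=False))
        Xt = self.X[train_idx]

        prior = self.prior
        if prior is None:
            props = np.bincount(Xt.ravel() - 1, minlength=self.S).astype(float)
            prior = DirichletPrior.from_proportions(props / props.sum())

        C, K = self.C, self.K
        occ_off = C if self.eq4_as_printed else 1
        M = rng.integers(0, C, size=n_train)
        # Seed each pattern's grouping from the states at a random training
        # position (epigenomes sharing a state start in the same group).  A
        # uniform-random grouping collapses: from a one-group state, moving a
        # single epigenome out is always penalized, so conditional sweeps never
        # discover a split that only pays once several epigenomes have moved.
        G = np.empty((C, N), dtype=np.int64)
        for c in range(C):
            _, inv = np.unique(Xt[rng.integers(0, n_train)], return_inverse=True)
            G[c] = inv % K
        o = np.bincount(M, minlength=C)

        history: list[float] = []
        converged = False
        for sweep in range(n_iter):
            temp = _anneal_temperature(sweep, anneal_iters, t0)
            changed = 0

            # --- update per-position pattern indices
            lik = np.column_stack(
                [partition_loglik(Xt, Partition(G[c], K), prior) for c in range(C)]
            )
            for j in range(n_train):
                o[M[j]] -= 1
                scores = lik[j] + np.log(o + occ_off)
                new = _pick(scores, temp, rng)
                if new != M[j]:
                    changed += 1
                M[j] = new
                o[new] += 1

            # --- update epigenome groupings, one pattern at a time
            for c in range(C):
                upd = _GroupUpdater(Xt[M == c], G[c], K, prior)
                for i in range(N):
                    delta = upd.move_scores(i)
                    new = _pick(delta, temp, rng)
                    if upd.apply(i, new):
                        changed += 1
                G[c] = upd.group_of

            # During annealing, reseed patterns that are empty or duplicate
            # another pattern's grouping, drawing fresh partitions from the
            # states at poorly-fit positions so unrepresented structure gets
            # capacity.  Duplicates arise when mixed early assignments drive
            # several groupings to the same (usually constitutive) partition.
            if temp is not None:
                fit_now = lik[np.arange(n_train), M]
                worst = np.argsort(fit_now)[: max(1, n_train // 10)]
                seen: dict[tuple, int] = {}
                reseed = [c for c in range(C) if o[c] == 0]
                for c in np.argsort(-o):
                    key = tuple(Partition(G[c], K).canonical().group_of)
                    if o[c] > 0 and key in seen:
                        reseed.append(int(c))
                    seen.setdefault(key, int(c))
                for c in reseed:
                    j = int(rng.choice(worst))
                    _, inv = np.unique(Xt[j], return_inverse=True)
                    G[c] = inv % K

            cat = CSPCatalog([Partition(G[c].copy(), K) for c in range(C)], o.copy())
            history.append(
                model_log_posterior(
                    cat, CSPAssignment(M), Xt, prior, eq4_as_printed=self.eq4_as_printed
                )
            )
            if changed == 0 and temp is None:
                converged = True
                break
        if not converged:
            logger.warning("CSP fit did not converge in %d sweeps; returning best state", n_iter)

        full_catalog = CSPCatalog([Partition(G[c], K) for c in range(C)], o, capacity=C)
        catalog = full_catalog.pruned()
        # remap training labels onto the pruned catalog
        keep = np.where(o > 0)[0]
        remap = {int(old): new for new, old in enumerate(keep)}
        M_train = np.array([remap[int(c)] for c in M])

        M_full = np.empty(L, dtype=np.int64)
        M_full[train_idx] = M_train
        rest = np.setdiff1d(np.arange(L), train_idx)
        if len(rest):
            M_full[rest] = assign_positions(catalog, self.X[rest], prior).M
        return CSPResults(
            model=self,
            catalog=catalog,
            assignment=CSPAssignment(M_full),
            prior=prior,
            train_idx=train_idx,
            score_history=np.array(history),
            converged=converged,
        )


@dataclass
class CSPResults:
    """Fitted CSP catalog, full-genome assignment and fit diagnostics."""

    model: CSPModel
    catalog: CSPCatalog
    assignment: CSPAssignment
    prior: DirichletPrior
    train_idx: np.ndarray
    score_history: np.ndarray
    converged: bool
    _genome_counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def genome_counts(self) -> np.ndarray:
        if self._genome_counts is None:
            self._genome_counts = self.assignment.counts(self.catalog.n_patterns)
        return self._genome_counts

    @property
    def genome_frequencies(self) -> np.ndarray:
        return self.genome_counts / self.genome_counts.sum()

    @property
    def constitutive_index(self) -> int | None:
        """Index of the pattern grouping all epigenomes together, if fitted."""
        for c, pat in enumerate(self.catalog.patterns):
            if pat.n_nonempty_groups == 1:
                return c
        return None

    def summary(self) -> str:
        lines = [
            "Cell-type-specificity pattern model",
            f"  positions: {len(self.assignment)} (trained on {len(self.train_idx)})",
            f"  epigenomes: {self.catalog.patterns[0].n_epigenomes}"
            f"  capacity: {self.model.C} patterns x {self.model.K} groups",
            f"  non-empty patterns: {self.catalog.n_patterns}",
            f"  final log posterior (training): {self.score_history[-1]:.3f}",
            f"  converged: {self.converged}",
            "",
            f"  {'pattern':>7} {'groups':>6} {'count':>8} {'genome%':>8}",
        ]
        freqs = self.genome_frequencies
        for c, pat in enumerate(self.catalog.patterns):
            lines.append(
                f"  {c:>7} {pat.n_nonempty_groups:>6} {self.genome_counts[c]:>8}"
                f" {100 * freqs[c]:>7.1f}%"
            )
        return "\n".join(lines)
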