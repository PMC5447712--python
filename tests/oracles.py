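"""Independent straight-from-formula oracles used by the test suite.

Everything here is written as plain loops over math.lgamma, deliberately
sharing no code with the package's vectorized implementations.
"""

import itertools
import math
from math import lgamma


def dirichlet_multinomial_term(state_vector, group_of, n_groups, alpha):
    """Per-position log marginal: product over groups of Gamma-ratio terms."""
    S = len(alpha)
    A = sum(alpha)
    total = 0.0
    for k in range(n_groups):
        members = [i for i, g in enumerate(group_of) if g == k]
        counts = [0] * S
        for i in members:
            counts[state_vector[i] - 1] += 1
        n_k = len(members)
        term = lgamma(A) - sum(lgamma(a) for a in alpha)
        term += sum(lgamma(c + a) for c, a in zip(counts, alpha))
        term -= lgamma(n_k + A)
        total += term
    return total


def grouping_prior(group_of, n_groups):
    """log[ Gamma(K) * prod_k Gamma(m_k + 1) / Gamma(N + K) ]."""
    m = [sum(1 for g in group_of if g == k) for k in range(n_groups)]
    return lgamma(n_groups) + sum(lgamma(mk + 1) for mk in m) - lgamma(sum(m) + n_groups)


def joint_score(patterns, n_groups, assignment, X, alpha, occupancy_offset=1):
    """Full joint log score of a catalog + assignment on data X (list of rows).

    occupancy_offset=1 gives the normalized Gamma(o_c + 1) form;
    occupancy_offset=C reproduces the literal printed Gamma(o_c + C) form.
    """
    C = len(patterns)
    score = 0.0
    for j, row in enumerate(X):
        score += dirichlet_multinomial_term(row, patterns[assignment[j]], n_groups, alpha)
    o = [sum(1 for m in assignment if m == c) for c in range(C)]
    score += lgamma(C) - lgamma(len(assignment) + C)
    score += sum(lgamma(oc + occupancy_offset) for oc in o)
    score += sum(grouping_prior(p, n_groups) for p in patterns)
    return score


def brute_force_best(X, n_patterns, n_groups, alpha):
    """Global optimum of the joint score by exhaustive enumeration."""
    N = len(X[0])
    L = len(X)
    best = -math.inf
    groupings = list(itertools.product(range(n_groups), repeat=N))
    for pats in itertools.product(groupings, repeat=n_patterns):
        for assign in itertools.product(range(n_patterns), repeat=L):
            s = joint_score(list(pats), n_groups, list(assign), X, alpha)
            if s > best:
                best = s
    return best


def mixture_score(in_group1, assignment, X, patterns, n_groups, alpha, beta, background):
    """Two-group enrichment mixture log score, assembled term by term."""
    C = len(patterns)
    l1 = sum(1 for g in in_group1 if g)
    l2 = sum(1 for g in in_group1 if not g)
    z1 = [0] * C
    z2 = [0] * C
    for g, c in zip(in_group1, assignment):
        if g:
            z1[c] += 1
        else:
            z2[c] += 1
    score = (
        lgamma(1 + beta)
        + lgamma(l1 + 1)
        + lgamma(l2 + beta)
        - lgamma(beta)
        - lgamma(l1 + l2 + 1 + beta)
    )
    score += lgamma(C) - lgamma(l1 + C)
    score += sum(lgamma(z + 1) for z in z1)
    for c in range(C):
        if z2[c]:
            score += z2[c] * math.log(background[c])
    for j, row in enumerate(X):
        score += dirichlet_multinomial_term(row, patterns[assignment[j]], n_groups, alpha)
    return score


def average_precision(scores, labels):
    """Step-wise average precision computed rank by rank (ties by order)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    n_pos = sum(labels)
    tp = 0
    ap = 0.0
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            tp += 1
            ap += tp / rank
    return ap / n_pos
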