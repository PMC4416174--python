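"""Independent brute-force oracles used to cross-check the implementation.

Everything here works by exhaustive enumeration or the literal textbook
definition, deliberately sharing no code with the package.
"""

import itertools

import numpy as np
from scipy.stats import binom


def _path_log_prob(z, x, t, pi, A, p):
    """Complete-data log-probability of one state path (states in {1, 2})."""
    start = np.log([pi, 1.0 - pi])
    lp = start[z[0] - 1] + binom.logpmf(x[0], t[0], p[z[0] - 1])
    for n in range(1, len(z)):
        lp += np.log(A[z[n - 1] - 1, z[n] - 1])
        lp += binom.logpmf(x[n], t[n], p[z[n] - 1])
    return lp


def enumerate_posteriors(x, t, pi, A, p):
    """gamma, epsilon and log-likelihood by summing over all 2^N paths."""
    x, t = np.asarray(x), np.asarray(t)
    N = len(x)
    paths = list(itertools.product([1, 2], repeat=N))
    logps = np.array([_path_log_prob(z, x, t, pi, A, p) for z in paths])
    m = logps.max()
    w = np.exp(logps - m)
    total = w.sum()
    gamma = np.zeros((N, 2))
    epsilon = np.zeros((max(N - 1, 0), 2, 2))
    for z, wt in zip(paths, w):
        for n in range(N):
            gamma[n, z[n] - 1] += wt
        for n in range(1, N):
            epsilon[n - 1, z[n - 1] - 1, z[n] - 1] += wt
    return gamma / total, epsilon / total, float(m + np.log(total))


def enumerate_viterbi(x, t, pi, A, p):
    """Best path by enumeration; on ties the lexicographically smallest
    (state-1-preferring) path wins, matching the decoder's convention."""
    x, t = np.asarray(x), np.asarray(t)
    best, best_lp = None, -np.inf
    for z in itertools.product([1, 2], repeat=len(x)):
        lp = _path_log_prob(z, x, t, pi, A, p)
        if lp > best_lp + 1e-12:
            best, best_lp = z, lp
    return np.array(best)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up
    definition: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def mann_whitney_auc(scores, labels):
    """AUC as the normalized pairwise-comparison count (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(pos) * len(neg))


def expected_run_count(pi, A, n_bins):
    """Expected number of maximal methylated runs in an n-bin chain:
    P(z_1 = 2) + sum_n P(z_{n-1} = 1, z_n = 2), by marginal recursion."""
    marg = np.array([pi, 1.0 - pi])
    total = marg[1]
    for _ in range(1, n_bins):
        total += marg[0] * A[0, 1]
        marg = marg @ A
    return total
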