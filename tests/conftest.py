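"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import truncnorm

from karyotrace import hmm
from karyotrace.datatypes import SNPPanel


def make_panel(chrom, pos, mat, pat, **kw):
    """Small hand-built panel; mat/pat are (2, n) 0/1 arrays or lists."""
    pos = np.asarray(pos)
    n = len(pos)
    return SNPPanel(
        chrom=np.array([chrom] * n if isinstance(chrom, str) else chrom, dtype=object),
        pos=pos,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        mat_haps=np.asarray(mat, dtype=np.int8),
        pat_haps=np.asarray(pat, dtype=np.int8),
        **kw,
    )


# ---------------------------------------------------------------------------
# brute-force HMM oracle (independent route: scipy truncnorm, explicit
# ordered-matching transitions, exhaustive path enumeration)
# ---------------------------------------------------------------------------

def oracle_emission(b, mu, sigma, pi0):
    """Mixture density via scipy's truncated normal."""
    if np.isnan(b):
        return 1.0
    a, z = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return pi0 + (1.0 - pi0) * truncnorm.pdf(b, a, z, loc=mu, scale=sigma)


def _oracle_copy_prob(a, b, r):
    """P(multiset a -> multiset b) by explicit sum over distinct orderings."""
    if len(a) == 0:
        return 1.0
    total = 0.0
    for perm in set(itertools.permutations(b)):
        p = 1.0
        for x, y in zip(a, perm):
            p *= (1.0 - r) if x == y else r
        total += p
    return total


def oracle_loglik(baf, mat, pat, cm, hypothesis, sigma, pi0):
    """log P(baf) by exhaustive enumeration over all state paths."""
    states = hmm.enumerate_states(hypothesis)
    S, n = len(states), len(baf)
    k = hmm.COPY_NUMBER[hypothesis]
    # per-site per-state emission densities
    E = np.ones((n, S))
    for s, (m, p) in enumerate(states):
        if k == 0:
            continue
        for t in range(n):
            dose = sum(mat[i][t] for i in m) + sum(pat[j][t] for j in p)
            E[t, s] = oracle_emission(baf[t], dose / k, sigma, pi0)
    # transition matrices per gap
    r = 0.5 * (1.0 - np.exp(-2.0 * np.diff(np.asarray(cm, float)) / 100.0))
    T = np.empty((n - 1, S, S))
    for g in range(n - 1):
        for i, (ma, pa) in enumerate(states):
            for j, (mb, pb) in enumerate(states):
                T[g, i, j] = (_oracle_copy_prob(ma, mb, r[g])
                              * _oracle_copy_prob(pa, pb, r[g]))
    # initial distribution: uniform over ordered copy assignments
    w = np.array([(2.0 if len(set(m)) == 2 else 1.0)
                  * (2.0 if len(set(p)) == 2 else 1.0) for m, p in states])
    init = w / w.sum()
    # exhaustive sum over S^n paths, vectorized
    paths = np.array(list(itertools.product(range(S), repeat=n)))
    prob = init[paths[:, 0]] * E[0, paths[:, 0]]
    for t in range(1, n):
        prob = prob * T[t - 1, paths[:, t - 1], paths[:, t]] * E[t, paths[:, t]]
    return float(np.log(prob.sum()))


@pytest.fixture(scope="session")
def noise_free_params():
    """Near-deterministic emissions for truth-recovery checks."""
    return hmm.EmissionParams(sigma=0.01, pi0=0.0)
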