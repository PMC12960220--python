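"""Haplotype-transmission HMM over copy-number hypotheses.

For each chromosome of each embryo we ask: which multiset of parental
haplotypes (drawn from the four parental haplotypes m1, m2, p1, p2) best
explains the observed B-allele frequencies?  Six copy-number hypotheses
are entertained:

==============  ===  =====================================================
hypothesis       k   transmitted copies
==============  ===  =====================================================
nullisomy        0   none — BAF is pure noise
monosomy_m       1   maternal copy lost; one paternal haplotype remains
monosomy_p       1   paternal copy lost; one maternal haplotype remains
disomy           2   one maternal + one paternal haplotype
trisomy_m        3   two maternal (unordered multiset) + one paternal
trisomy_p        3   one maternal + two paternal (unordered multiset)
==============  ===  =====================================================

Hidden states are the transmitted haplotype multisets; transitions model
crossovers: each transmitted copy independently switches its source
haplotype between adjacent sites with the Haldane recombination fraction
r = (1 - exp(-2 d/100)) / 2 for inter-site distance d in cM.  Emissions
mix a uniform outlier component (weight pi0) with a truncated normal on
[0, 1] centred on the expected allelic dosage mu = (#ALT among
transmitted copies) / k.

All recursions run in log space (numba kernels) so that 50,000-site
chromosomes pose no underflow risk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import ndtr

from .datatypes import EmbryoBAF, GeneticMap, SNPPanel

# ---------------------------------------------------------------------------
# hypotheses and state spaces
# ---------------------------------------------------------------------------

HYPOTHESES = (
    "nullisomy",
    "monosomy_m",
    "monosomy_p",
    "disomy",
    "trisomy_m",
    "trisomy_p",
)

#: chromosome copy number under each hypothesis
COPY_NUMBER = {
    "nullisomy": 0,
    "monosomy_m": 1,
    "monosomy_p": 1,
    "disomy": 2,
    "trisomy_m": 3,
    "trisomy_p": 3,
}

#: parent whose contribution is abnormal (None for the euploid hypothesis)
ORIGIN = {
    "nullisomy": None,
    "monosomy_m": "maternal",
    "monosomy_p": "paternal",
    "disomy": None,
    "trisomy_m": "maternal",
    "trisomy_p": "paternal",
}

# A state is a pair of tuples: (maternal copy indices, paternal copy
# indices), each index in {0, 1} selecting a parental haplotype row.
# Same-parent copies are stored sorted (unordered multiset).
State = tuple[tuple[int, ...], tuple[int, ...]]

_PAIRS = ((0, 0), (0, 1), (1, 1))  # unordered two-copy multisets


def enumerate_states(hypothesis: str) -> list[State]:
    """Hidden states for a hypothesis, in a fixed canonical order."""
    if hypothesis == "nullisomy":
        return [((), ())]
    if hypothesis == "monosomy_m":                 # maternal copy lost
        return [((), (j,)) for j in (0, 1)]
    if hypothesis == "monosomy_p":
        return [((i,), ()) for i in (0, 1)]
    if hypothesis == "disomy":
        return [((i,), (j,)) for i in (0, 1) for j in (0, 1)]
    if hypothesis == "trisomy_m":
        return [(m, (j,)) for m in _PAIRS for j in (0, 1)]
    if hypothesis == "trisomy_p":
        return [((i,), p) for i in (0, 1) for p in _PAIRS]
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def haldane_r(d_cM):
    """Haldane recombination fraction for a distance in centimorgans."""
    d = np.asarray(d_cM, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("negative genetic distance")
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def _copies_transition(a: tuple[int, ...], b: tuple[int, ...], r: np.ndarray) -> np.ndarray:
    """Transition factor for one parent's copies, multiset ``a`` -> ``b``.

    Each copy switches independently with probability ``r``; for
    two-copy multisets the probability sums over ordered matchings of
    the destination to a fixed ordered representative of the source.
    """
    if len(a) != len(b):
        raise ValueError("copy count must be conserved within a hypothesis")
    one = np.ones_like(r)

    def step(i: int, j: int) -> np.ndarray:
        return (one - r) if i == j else r

    if len(a) == 0:
        return one
    if len(a) == 1:
        return step(a[0], b[0])
    # len == 2
    if b[0] == b[1]:
        return step(a[0], b[0]) * step(a[1], b[1])
    return step(a[0], b[0]) * step(a[1], b[1]) + step(a[0], b[1]) * step(a[1], b[0])


def initial_log_distribution(states: list[State]) -> np.ndarray:
    """Exchangeable-haplotype prior: uniform over *ordered* copy
    assignments, i.e. each multiset state weighted by its number of
    ordered representatives (2 for {i,j} with i != j, else 1)."""
    w = np.array([
        (2.0 if len(set(m)) == 2 else 1.0) * (2.0 if len(set(p)) == 2 else 1.0)
        for m, p in states
    ])
    return np.log(w / w.sum())


def transition_matrix(states: list[State], d_cM: float) -> np.ndarray:
    """Single inter-site transition matrix (rows sum to 1)."""
    r = haldane_r(np.array([float(d_cM)]))
    return _transition_stack(states, r)[0]


def _transition_stack(states: list[State], r: np.ndarray) -> np.ndarray:
    """Transition matrices for every inter-site gap: shape (len(r), S, S)."""
    S = len(states)
    out = np.empty((len(r), S, S))
    for i, (ma, pa) in enumerate(states):
        for j, (mb, pb) in enumerate(states):
            out[:, i, j] = _copies_transition(ma, mb, r) * _copies_transition(pa, pb, r)
    return out


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionParams:
    """Noise model: truncated-normal scale and uniform outlier weight."""

    sigma: float = 0.1
    pi0: float = 0.05

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def truncnorm01_logpdf(b, mu, sigma):
    """Log-density of a normal(mu, sigma) truncated to [0, 1]."""
    b = np.asarray(b, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    z = (b - mu) / sigma
    mass = ndtr((1.0 - mu) / sigma) - ndtr((0.0 - mu) / sigma)
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI - np.log(mass)


def emission_logpdf(b, mu, params: EmissionParams):
    """Log-density of the pi0-uniform + truncated-normal mixture.

    Broadcasts over ``b`` and ``mu``; NaN observations contribute 0.
    """
    b = np.asarray(b, dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_pi0 = np.log(params.pi0) if params.pi0 > 0 else -np.inf
        log_1m = np.log1p(-params.pi0) if params.pi0 < 1 else -np.inf
    bb = np.where(np.isnan(b), 0.5, b)
    tn = truncnorm01_logpdf(bb, mu, params.sigma)
    out = np.logaddexp(log_pi0, log_1m + tn)
    return np.where(np.isnan(b), 0.0, out)


def state_dosage_means(states: list[State], mat_haps: np.ndarray,
                       pat_haps: np.ndarray) -> np.ndarray:
    """Expected BAF mu per state per site, shape (S, n).  k=0 rows are NaN."""
    S = len(states)
    n = mat_haps.shape[1]
    mu = np.full((S, n), np.nan)
    for s, (m, p) in enumerate(states):
        k = len(m) + len(p)
        if k == 0:
            continue
        dose = np.zeros(n)
        for i in m:
            dose += mat_haps[i]
        for j in p:
            dose += pat_haps[j]
        mu[s] = dose / k
    return mu


def _emission_matrix(baf: np.ndarray, states: list[State], mat_haps: np.ndarray,
                     pat_haps: np.ndarray, params: EmissionParams) -> np.ndarray:
    """Per-site per-state emission log-densities, shape (n, S)."""
    n = len(baf)
    S = len(states)
    logE = np.zeros((n, S))
    mu = state_dosage_means(states, mat_haps, pat_haps)
    for s in range(S):
        if len(states[s][0]) + len(states[s][1]) == 0:
            continue  # nullisomy: uniform density 1 -> log 0
        logE[:, s] = emission_logpdf(baf, mu[s], params)
    return logE


# ---------------------------------------------------------------------------
# numba recursions
# ---------------------------------------------------------------------------

@njit(cache=False)
def _forward_log(logE, logT, log_init):
    n, S = logE.shape
    alpha = np.empty((n, S))
    for j in range(S):
        alpha[0, j] = log_init[j] + logE[0, j]
    for t in range(1, n):
        for j in range(S):
            m = -np.inf
            for i in range(S):
                v = alpha[t - 1, i] + logT[t - 1, i, j]
                if v > m:
                    m = v
            if m == -np.inf:
                alpha[t, j] = -np.inf
                continue
            acc = 0.0
            for i in range(S):
                acc += np.exp(alpha[t - 1, i] + logT[t - 1, i, j] - m)
            alpha[t, j] = m + np.log(acc) + logE[t, j]
    m = -np.inf
    for j in range(S):
        if alpha[n - 1, j] > m:
            m = alpha[n - 1, j]
    acc = 0.0
    for j in range(S):
        acc += np.exp(alpha[n - 1, j] - m)
    return alpha, m + np.log(acc)


@njit(cache=False)
def _backward_log(logE, logT):
    n, S = logE.shape
    beta = np.zeros((n, S))
    for t in range(n - 2, -1, -1):
        for i in range(S):
            m = -np.inf
            for j in range(S):
                v = logT[t, i, j] + logE[t + 1, j] + beta[t + 1, j]
                if v > m:
                    m = v
            if m == -np.inf:
                beta[t, i] = -np.inf
                continue
            acc = 0.0
            for j in range(S):
                acc += np.exp(logT[t, i, j] + logE[t + 1, j] + beta[t + 1, j] - m)
            beta[t, i] = m + np.log(acc)
    return beta


@njit(cache=False)
def _viterbi_log(logE, logT, log_init):
    n, S = logE.shape
    delta = np.empty((n, S))
    back = np.zeros((n, S), dtype=np.int64)
    for j in range(S):
        delta[0, j] = log_init[j] + logE[0, j]
    for t in range(1, n):
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[t - 1, i] + logT[t - 1, i, j]
                if v > best:  # strict: ties keep the lowest state index
                    best = v
                    arg = i
            delta[t, j] = best + logE[t, j]
            back[t, j] = arg
    best = -np.inf
    arg = 0
    for j in range(S):
        if delta[n - 1, j] > best:
            best = delta[n - 1, j]
            arg = j
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _prepare(baf, panel: SNPPanel, gmap: GeneticMap, chrom: str,
             hypothesis: str, params: EmissionParams):
    mask = panel.chrom_mask(chrom)
    if not np.any(mask):
        raise ValueError(f"no sites on chromosome {chrom!r}")
    pos = panel.pos[mask]
    baf = np.asarray(baf, dtype=np.float64)
    if len(baf) == panel.n_sites:
        baf = baf[mask]
    elif len(baf) != mask.sum():
        raise ValueError("BAF length matches neither panel nor chromosome")
    states = enumerate_states(hypothesis)
    cm = gmap.interpolate_cM(chrom, pos)
    r = haldane_r(np.diff(cm))
    with np.errstate(divide="ignore"):
        logT = np.log(_transition_stack(states, r))
    logE = _emission_matrix(baf, states, panel.mat_haps[:, mask],
                            panel.pat_haps[:, mask], params)
    return states, logE, logT, initial_log_distribution(states)


def forward_loglik(baf, panel: SNPPanel, gmap: GeneticMap, chrom: str,
                   hypothesis: str, params: EmissionParams) -> float:
    """Total log-likelihood of the BAF vector under one hypothesis."""
    _, logE, logT, log_init = _prepare(baf, panel, gmap, chrom, hypothesis, params)
    _, ll = _forward_log(logE, logT, log_init)
    return float(ll)


@dataclass
class HMMResult:
    """Decoded chromosome under one copy-number hypothesis."""

    hypothesis: str
    states: list[State]
    loglik: float
    posteriors: np.ndarray          # (n, S), rows sum to 1
    viterbi: np.ndarray             # (n,) state indices
    viterbi_loglik: float

    def single_copy_marginal(self, parent: str) -> np.ndarray:
        """P(the parent's single transmitted copy is haplotype 0), per site.

        Defined only when every state carries exactly one copy from that
        parent (disomy; the surviving parent of a monosomy).
        """
        side = 0 if parent == "maternal" else 1
        if any(len(s[side]) != 1 for s in self.states):
            raise ValueError(f"{parent} copy count is not 1 under {self.hypothesis}")
        sel = np.array([s[side][0] == 0 for s in self.states])
        return self.posteriors[:, sel].sum(axis=1)

    def bph_posterior(self, parent: str) -> np.ndarray:
        """P(two distinct haplotypes of ``parent`` present), per site."""
        side = 0 if parent == "maternal" else 1
        sel = np.array([len(set(s[side])) == 2 for s in self.states])
        return self.posteriors[:, sel].sum(axis=1)


def posterior_decode(baf, panel: SNPPanel, gmap: GeneticMap, chrom: str,
                     hypothesis: str, params: EmissionParams) -> HMMResult:
    """Forward–backward posteriors plus the Viterbi path."""
    states, logE, logT, log_init = _prepare(baf, panel, gmap, chrom, hypothesis, params)
    alpha, ll = _forward_log(logE, logT, log_init)
    beta = _backward_log(logE, logT)
    logpost = alpha + beta - ll
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    vpath, vll = _viterbi_log(logE, logT, log_init)
    return HMMResult(hypothesis, states, float(ll), post, vpath, float(vll))


def viterbi_path(baf, panel: SNPPanel, gmap: GeneticMap, chrom: str,
                 hypothesis: str, params: EmissionParams) -> np.ndarray:
    _, logE, logT, log_init = _prepare(baf, panel, gmap, chrom, hypothesis, params)
    path, _ = _viterbi_log(logE, logT, log_init)
    return path


def all_hypothesis_logliks(baf, panel: SNPPanel, gmap: GeneticMap, chrom: str,
                           params: EmissionParams) -> dict[str, float]:
    """Forward log-likelihood of every copy-number hypothesis."""
    return {h: forward_loglik(baf, panel, gmap, chrom, h, params)
            for h in HYPOTHESES}


# default noise-fitting grids
SIGMA_GRID = tuple(np.round(np.arange(0.05, 0.3001, 0.025), 4))
PI0_GRID = (0.01, 0.05, 0.1, 0.2, 0.35, 0.5)


def fit_noise(embryo: EmbryoBAF, panel: SNPPanel, gmap: GeneticMap,
              sigma_grid=SIGMA_GRID, pi0_grid=PI0_GRID) -> EmissionParams:
    """Grid-search emission parameters for one embryo.

    Maximizes the disomy forward log-likelihood summed over chromosomes;
    disomy is the overwhelmingly common state, so it anchors the fit.
    """
    if np.all(np.isnan(embryo.baf)):
        raise ValueError("all BAF values missing; cannot fit noise")
    best, best_ll = None, -np.inf
    for sigma in sigma_grid:
        for pi0 in pi0_grid:
            params = EmissionParams(sigma=float(sigma), pi0=float(pi0))
            ll = sum(forward_loglik(embryo.baf, panel, gmap, c, "disomy", params)
                     for c in panel.chromosomes())
            if ll > best_ll:
                best, best_ll = params, ll
    return best
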