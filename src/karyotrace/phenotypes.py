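"""Cohort phenotypes derived from calls and crossover events.

Per-subject crossover phenotypes (count, hotspot occupancy, replication
timing, GC content), aneuploidy summary tables with origin/type ratios,
and two bespoke cohort statistics:

* a parametric-bootstrap overdispersion test of per-patient aneuploidy
  incidence against a binomial null after quadratic maternal-age
  adjustment (Pearson dispersion ``phi``), and
* the one-way random-effects intraclass correlation of per-chromosome
  crossover counts within embryos (counts z-standardized per chromosome
  so that chromosome length does not confound the estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binomtest

from .datatypes import CrossoverEvent, IntervalTrack, PloidyCall

# ---------------------------------------------------------------------------
# crossover phenotypes
# ---------------------------------------------------------------------------

def _event_bed_interval(ev: CrossoverEvent) -> tuple[int, int]:
    """0-based half-open resolution interval of an event."""
    return ev.left - 1, ev.right


def crossover_count_phenotype(events: list[CrossoverEvent], embryo_ids: list[str],
                              parent: str) -> tuple[float, dict[str, int]]:
    """Mean autosomal crossover count per embryo for one parent.

    ``embryo_ids`` are the (post-filter, euploid) embryos to average
    over; embryos without events count zero.  Requires >= 3 embryos.
    """
    if len(embryo_ids) < 3:
        raise ValueError("at least three embryos required for a phenotype row")
    counts = {e: 0 for e in embryo_ids}
    for ev in events:
        if ev.parent == parent and ev.embryo_id in counts:
            counts[ev.embryo_id] += 1
    return float(np.mean(list(counts.values()))), counts


def hotspot_occupancy(events: list[CrossoverEvent], hotspots: IntervalTrack,
                      rule: str = "overlap") -> float:
    """Fraction of events falling in recombination hotspots.

    ``rule="overlap"``: the resolution interval intersects a hotspot by
    >= 1 bp.  ``rule="midpoint"``: the interval midpoint lies inside a
    hotspot.  Returns 0.0 for an empty event list or empty track.
    """
    if not events:
        return 0.0
    merged = hotspots.merged()
    hits = 0
    for ev in events:
        if rule == "overlap":
            s, e = _event_bed_interval(ev)
        elif rule == "midpoint":
            s = ev.midpoint - 1  # 0-based position of the 1-based midpoint
            e = s + 1
        else:
            raise ValueError(f"unknown hotspot rule {rule!r}")
        if merged.overlaps(ev.chrom, s, e):
            hits += 1
    return hits / len(events)


def crossover_context(events: list[CrossoverEvent], timing: IntervalTrack | None,
                      fasta=None, flank: int = 500) -> tuple[float, float]:
    """(mean replication timing, mean GC fraction) at event midpoints.

    Timing is the covering-interval value of the bedGraph track at the
    midpoint (events on uncovered positions are skipped).  GC is the G+C
    fraction of the ±``flank`` bp window (2*flank+1 bp) around the
    midpoint in the reference; windows are clipped at contig ends, but a
    midpoint outside its contig is an error.
    """
    timings, gcs = [], []
    for ev in events:
        mid0 = ev.midpoint - 1  # 0-based
        if timing is not None:
            v = timing.value_at(ev.chrom, mid0)
            if not np.isnan(v):
                timings.append(v)
        if fasta is not None:
            contig = fasta[ev.chrom]
            if mid0 < 0 or mid0 >= len(contig):
                raise ValueError(f"midpoint {ev.midpoint} outside contig {ev.chrom}")
            seq = str(contig[max(0, mid0 - flank): mid0 + flank + 1]).upper()
            gcs.append((seq.count("G") + seq.count("C")) / len(seq))
    mean_t = float(np.mean(timings)) if timings else float("nan")
    mean_gc = float(np.mean(gcs)) if gcs else float("nan")
    return mean_t, mean_gc


# ---------------------------------------------------------------------------
# aneuploidy summary
# ---------------------------------------------------------------------------

@dataclass
class RatioTest:
    """A two-category fraction with an exact binomial test against 0.5."""

    numerator: int
    denominator: int
    fraction: float
    p_value: float
    ci_low: float
    ci_high: float


def binomial_ratio(a: int, b: int) -> RatioTest:
    """Fraction a/(a+b) with exact two-sided binomial test vs 0.5."""
    n = a + b
    if n == 0:
        return RatioTest(a, 0, float("nan"), float("nan"), float("nan"), float("nan"))
    res = binomtest(a, n, 0.5, alternative="two-sided")
    ci = res.proportion_ci(confidence_level=0.95)
    return RatioTest(a, n, a / n, res.pvalue, ci.low, ci.high)


@dataclass
class AneuploidySummary:
    """Per-chromosome counts and headline ratios for a cohort."""

    table: pd.DataFrame                 # chrom x (type, origin) counts
    trisomy_ratio: RatioTest            # trisomies / (trisomies + monosomies)
    maternal_ratio: RatioTest           # maternal / (maternal + paternal)
    frac_embryos_aneuploid: float


def aneuploidy_summary(calls: list[PloidyCall],
                       excluded_embryos: set[str] | None = None) -> AneuploidySummary:
    """Tabulate aneuploid calls by chromosome, type and parental origin.

    Complex/genome-wide-abnormal embryos should be passed in
    ``excluded_embryos`` so that they do not enter the counts.
    """
    excluded = excluded_embryos or set()
    rows = []
    embryos: dict[str, bool] = {}
    for c in calls:
        if c.embryo_id in excluded:
            continue
        embryos.setdefault(c.embryo_id, False)
        if c.copy_number in (1, 3):
            kind = "trisomy" if c.copy_number == 3 else "monosomy"
            rows.append({"chrom": c.chrom, "type": kind, "origin": c.origin})
            embryos[c.embryo_id] = True
    if rows:
        table = (pd.DataFrame(rows)
                 .groupby(["chrom", "type", "origin"]).size()
                 .rename("count").reset_index())
        n_tri = int(table.loc[table["type"] == "trisomy", "count"].sum())
        n_mono = int(table.loc[table["type"] == "monosomy", "count"].sum())
        n_mat = int(table.loc[table["origin"] == "maternal", "count"].sum())
        n_pat = int(table.loc[table["origin"] == "paternal", "count"].sum())
    else:
        table = pd.DataFrame(columns=["chrom", "type", "origin", "count"])
        n_tri = n_mono = n_mat = n_pat = 0
    frac = (sum(embryos.values()) / len(embryos)) if embryos else float("nan")
    return AneuploidySummary(
        table=table,
        trisomy_ratio=binomial_ratio(n_tri, n_mono),
        maternal_ratio=binomial_ratio(n_mat, n_pat),
        frac_embryos_aneuploid=frac,
    )


# ---------------------------------------------------------------------------
# overdispersion of per-patient aneuploidy incidence
# ---------------------------------------------------------------------------

@dataclass
class OverdispersionResult:
    phi: float
    p_value: float
    B: int
    coef: np.ndarray                    # logit-scale fit: intercept[, age, age^2]


def _irls_binomial(y: np.ndarray, n: np.ndarray, X: np.ndarray,
                   beta0: np.ndarray | None = None,
                   max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Logit-link binomial GLM fit by iteratively reweighted least squares."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim) if beta0 is None else beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(n * mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - n * mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def pearson_dispersion(y: np.ndarray, n: np.ndarray, X: np.ndarray,
                       beta: np.ndarray) -> float:
    """phi = sum of squared Pearson residuals / (N - p)."""
    mu = expit(X @ beta)
    resid2 = (y - n * mu) ** 2 / (n * mu * (1.0 - mu))
    return float(resid2.sum() / (len(y) - X.shape[1]))


def overdispersion_test(affected: np.ndarray, total: np.ndarray,
                        maternal_age: np.ndarray | None, B: int = 999,
                        rng: np.random.Generator | int | None = None) -> OverdispersionResult:
    """Parametric-bootstrap test of binomial overdispersion.

    Fits a logit-link binomial mean model (quadratic in maternal age when
    ages are given, intercept-only otherwise), computes the Pearson
    dispersion ``phi``, then simulates ``B`` pure-binomial datasets at
    the fitted means, refits each, and reports the add-one bootstrap
    p-value P(phi_b >= phi_obs).
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = np.asarray(affected, dtype=np.float64)
    n = np.asarray(total, dtype=np.float64)
    keep = n > 0                        # zero-trial patients carry no information
    y, n = y[keep], n[keep]
    if maternal_age is not None:
        a = np.asarray(maternal_age, dtype=np.float64)[keep]
        X = np.column_stack([np.ones_like(a), a, a * a])
    else:
        X = np.ones((len(y), 1))
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than patients")
    beta = _irls_binomial(y, n, X)
    phi_obs = pearson_dispersion(y, n, X, beta)
    mu = expit(X @ beta)
    n_int = n.astype(np.int64)
    exceed = 0
    for _ in range(B):
        yb = rng.binomial(n_int, mu).astype(np.float64)
        bb = _irls_binomial(yb, n, X, beta0=beta)
        if pearson_dispersion(yb, n, X, bb) >= phi_obs:
            exceed += 1
    return OverdispersionResult(phi=phi_obs, p_value=(1 + exceed) / (B + 1),
                                B=B, coef=beta)


# ---------------------------------------------------------------------------
# cross-chromosome ICC of crossover counts
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_groups: int


def _icc1(values: np.ndarray) -> float:
    """One-way random-effects ICC(1) from ANOVA mean squares.

    ``values`` is (n_groups, k) with groups = embryos and k observations
    (chromosomes) per group.
    """
    G, k = values.shape
    N = G * k
    grand = values.mean()
    gmeans = values.mean(axis=1)
    msb = k * np.sum((gmeans - grand) ** 2) / (G - 1)
    msw = np.sum((values - gmeans[:, None]) ** 2) / (N - G)
    return float((msb - msw) / (msb + (k - 1) * msw))


def crossover_icc(counts: np.ndarray, n_boot: int = 199,
                  rng: np.random.Generator | int | None = None) -> ICCResult:
    """ICC of per-chromosome crossover counts within embryos.

    ``counts`` is (n_embryos, n_chromosomes); counts are z-standardized
    within each chromosome (column) before the one-way ANOVA so that
    chromosome length does not drive the correlation.  The CI is a
    percentile bootstrap over embryos.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need counts for at least two chromosomes")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sd = counts.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (counts - counts.mean(axis=0)) / sd
    icc = _icc1(z)
    G = z.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _icc1(z[rng.integers(0, G, size=G)])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ICCResult(icc=icc, ci_low=float(lo), ci_high=float(hi), n_groups=G)
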