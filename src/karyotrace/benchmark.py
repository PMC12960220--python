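"""Cohort-scale evaluation of the caller against simulator ground truth.

Used by the acceptance checks and the examples: simulate many families,
run the full calling pipeline, and score copy-number / origin / meiotic
class / crossover recovery against the recorded truth.  Also provides
the statistical-calibration harnesses for the overdispersion test and
the ICC estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import expit

from . import hmm
from .datatypes import CrossoverEvent
from .phenotypes import overdispersion_test
from .pipeline import call_family
from .simulate import MODE_TO_HYPOTHESIS, SimConfig, simulate_family


@dataclass
class CohortMetrics:
    """Aggregated recovery metrics over a simulated cohort."""

    n_chromosomes: int = 0
    copy_number_correct: int = 0
    origin_total: int = 0
    origin_correct: int = 0
    mi_total: int = 0
    mi_correct: int = 0
    mitotic_total: int = 0
    mitotic_correct: int = 0
    disomic_total: int = 0
    count_exact: int = 0
    matched: int = 0
    contained: int = 0
    resolutions: list = field(default_factory=list)
    # per-embryo mean maternal crossover count on called-disomic chromosomes,
    # split by called aneuploidy status
    disomic_rate_aneuploid: list = field(default_factory=list)
    disomic_rate_euploid: list = field(default_factory=list)

    @property
    def copy_number_accuracy(self) -> float:
        return self.copy_number_correct / self.n_chromosomes

    @property
    def origin_accuracy(self) -> float:
        return self.origin_correct / self.origin_total

    @property
    def mi_class_accuracy(self) -> float:
        return self.mi_correct / self.mi_total

    @property
    def mitotic_class_accuracy(self) -> float:
        return self.mitotic_correct / self.mitotic_total

    @property
    def count_exact_rate(self) -> float:
        return self.count_exact / self.disomic_total

    @property
    def containment_rate(self) -> float:
        return self.contained / self.matched

    @property
    def median_resolution_bp(self) -> float:
        return float(np.median(self.resolutions))


def _match_events(events: list[CrossoverEvent], truths: np.ndarray):
    """Optimal 1:1 matching of called events to true crossover positions."""
    if not events or len(truths) == 0:
        return []
    mids = np.array([e.midpoint for e in events], dtype=float)
    cost = np.abs(mids[:, None] - truths[None, :])
    ri, ci = linear_sum_assignment(cost)
    return [(events[i], truths[j]) for i, j in zip(ri, ci)]


def evaluate_simulated_cohort(config: SimConfig, n_families: int,
                              seed: int) -> CohortMetrics:
    """Simulate ``n_families`` and score the full pipeline against truth."""
    params = hmm.EmissionParams(sigma=config.sigma, pi0=config.pi0)
    m = CohortMetrics()
    for f in range(n_families):
        rng = np.random.default_rng([seed, f])
        fam = simulate_family(config, rng, family_id=f"f{f}")
        res = call_family(fam.panel, fam.gmap, fam.embryos, fam.centromeres, params)
        events_by_key: dict[tuple, list[CrossoverEvent]] = {}
        for ev in res.callset.crossovers:
            events_by_key.setdefault((ev.embryo_id, ev.chrom, ev.parent), []).append(ev)

        for truth in fam.truths:
            calls = {c.chrom: c for c in res.callset.calls_for(truth.embryo_id)}
            embryo_aneuploid = any(c.is_aneuploid for c in calls.values())
            disomic_counts = []
            for chrom, ct in truth.chroms.items():
                call = calls[chrom]
                expected = MODE_TO_HYPOTHESIS[ct.mode]
                m.n_chromosomes += 1
                m.copy_number_correct += call.copy_number == ct.k
                if ct.k in (1, 3):
                    m.origin_total += 1
                    m.origin_correct += call.call == expected
                if ct.mode == "maternal_MI_BPH":
                    m.mi_total += 1
                    m.mi_correct += (call.call == "trisomy_m"
                                     and call.meiotic_class == "meiotic_MI_like")
                if ct.mode == "mitotic_trisomy":
                    m.mitotic_total += 1
                    m.mitotic_correct += (call.call == "trisomy_m"
                                          and call.meiotic_class == "putative_mitotic")
                if ct.mode == "euploid":
                    for parent, tx in (("maternal", ct.maternal_crossovers),
                                       ("paternal", ct.paternal_crossovers)):
                        evs = events_by_key.get((truth.embryo_id, chrom, parent), [])
                        m.disomic_total += 1
                        m.count_exact += len(evs) == len(tx)
                        for ev, x in _match_events(evs, np.sort(tx)):
                            m.matched += 1
                            m.contained += ev.left < x <= ev.right
                            m.resolutions.append(ev.resolution_bp)
                    if call.call == "disomy":
                        n_mat = len(events_by_key.get(
                            (truth.embryo_id, chrom, "maternal"), []))
                        disomic_counts.append(n_mat)
            if disomic_counts:
                bucket = (m.disomic_rate_aneuploid if embryo_aneuploid
                          else m.disomic_rate_euploid)
                bucket.append(float(np.mean(disomic_counts)))
    return m


# ---------------------------------------------------------------------------
# statistical calibration harnesses
# ---------------------------------------------------------------------------

#: logit-quadratic maternal-age risk curve used by the calibration cohorts:
#: risk ~0.19 at age 30 rising to ~0.55 by age 43
AGE_CURVE = (7.5, -0.6, 0.01)


def _patient_cohort(n_patients: int, mean_embryos: float, rho: float,
                    rng: np.random.Generator):
    """Per-patient (affected, total, age) with optional beta-binomial ICC."""
    age = rng.uniform(25.0, 45.0, n_patients)
    b0, b1, b2 = AGE_CURVE
    p = expit(b0 + b1 * age + b2 * age * age)
    n = rng.poisson(mean_embryos, n_patients)
    keep = n > 0
    age, p, n = age[keep], p[keep], n[keep]
    if rho > 0:
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        p = rng.beta(a, b)
    y = rng.binomial(n, p)
    return y.astype(float), n.astype(float), age


def overdispersion_rejection_rate(n_datasets: int, n_patients: int = 2000,
                                  mean_embryos: float = 6.0, rho: float = 0.0,
                                  B: int = 99, alpha: float = 0.05,
                                  seed: int = 0) -> float:
    """Fraction of simulated cohorts where the bootstrap test rejects.

    ``rho = 0`` gives the type-I error under the pure-binomial null;
    ``rho > 0`` gives power under a beta-binomial alternative.
    """
    rejections = 0
    for d in range(n_datasets):
        rng = np.random.default_rng([seed, 7919, d])
        y, n, age = _patient_cohort(n_patients, mean_embryos, rho, rng)
        res = overdispersion_test(y, n, age, B=B, rng=rng)
        rejections += res.p_value <= alpha
    return rejections / n_datasets


def exchangeable_counts(n_embryos: int, n_chromosomes: int, rho: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-embryo per-chromosome standardized counts with exchangeable
    correlation ``rho`` (a shared embryo effect plus independent noise)."""
    shared = rng.normal(size=(n_embryos, 1))
    noise = rng.normal(size=(n_embryos, n_chromosomes))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
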