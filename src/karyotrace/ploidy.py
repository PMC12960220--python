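"""Per-chromosome copy-number calling and meiotic-class labelling.

Model selection compares the forward log-likelihoods of the six
copy-number hypotheses under a (default uniform) prior; a call is issued
only when the winning posterior clears a confidence threshold.  Trisomies
are sub-classified from the BPH profile — the per-site posterior
probability that two *distinct* same-parent haplotypes are present:

* BPH at the centromere  -> meiosis-I-type error,
* SPH at the centromere with BPH distally -> meiosis-II-type error,
* SPH throughout -> putative mitotic (post-zygotic) duplication.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .datatypes import EmbryoBAF, EmbryoFlags, GeneticMap, PloidyCall, SNPPanel
from . import hmm

#: default posterior threshold below which "nocall" is reported
TAU = 0.90
#: half-width of the pericentromeric window used for MI/MII classification
BPH_WINDOW_BP = 5_000_000
#: windowed mean-BPH cut separating BPH from SPH
BPH_CUT = 0.5


def call_copy_number(logliks: dict[str, float], embryo_id: str, chrom: str,
                     prior: dict[str, float] | None = None,
                     tau: float = TAU) -> PloidyCall:
    """Select the copy-number hypothesis with the highest posterior.

    ``posterior(h) ∝ exp(logL_h) · prior(h)``; reports "nocall" when the
    maximum posterior falls below ``tau``.
    """
    missing = set(hmm.HYPOTHESES) - set(logliks)
    if missing:
        raise ValueError(f"missing hypothesis log-likelihoods: {sorted(missing)}")
    labels = list(hmm.HYPOTHESES)
    logp = np.array([logliks[h] for h in labels], dtype=np.float64)
    if prior is not None:
        logp = logp + np.log([prior[h] for h in labels])
    logp -= logsumexp(logp)
    post = np.exp(logp)
    posteriors = dict(zip(labels, post.tolist()))
    best = int(np.argmax(post))
    if post[best] >= tau:
        call = labels[best]
        return PloidyCall(embryo_id, chrom, posteriors, call,
                          hmm.COPY_NUMBER[call], hmm.ORIGIN[call])
    return PloidyCall(embryo_id, chrom, posteriors, "nocall", None, None)


def _windowed_mean(pos: np.ndarray, values: np.ndarray, half_width: int) -> np.ndarray:
    """Mean of ``values`` over sites within ±half_width of each site."""
    cs = np.concatenate(([0.0], np.cumsum(values)))
    left = np.searchsorted(pos, pos - half_width, side="left")
    right = np.searchsorted(pos, pos + half_width, side="right")
    return (cs[right] - cs[left]) / np.maximum(right - left, 1)


def classify_trisomy_origin(call: PloidyCall, pos: np.ndarray, centromere_bp: int,
                            window_bp: int = BPH_WINDOW_BP,
                            cut: float = BPH_CUT) -> str:
    """Meiotic class of a trisomy from its BPH posterior profile."""
    if call.copy_number != 3:
        raise ValueError("meiotic classification applies to trisomies only")
    if call.bph_profile is None:
        raise ValueError("call lacks a BPH profile")
    bph = np.asarray(call.bph_profile, dtype=np.float64)
    near_cen = np.abs(pos - centromere_bp) <= window_bp
    if near_cen.any() and float(bph[near_cen].mean()) >= cut:
        return "meiotic_MI_like"
    distal = ~near_cen
    if distal.any():
        wm = _windowed_mean(pos[distal], bph[distal], window_bp)
        if float(wm.max()) >= cut:
            return "meiotic_MII_like"
    return "putative_mitotic"


def flag_embryo(calls: list[PloidyCall], complex_threshold: int = 5,
                genome_wide_fraction: float = 0.8) -> EmbryoFlags:
    """Cohort exclusion flags: complex aneuploidy and genome-wide patterns.

    "Complex" = more than ``complex_threshold`` aneuploid chromosomes.
    "Genome-wide abnormal" = at least ``genome_wide_fraction`` of called
    chromosomes are same-parent trisomies (triploidy pattern) or
    same-parent monosomies (haploidy pattern).
    """
    if not calls:
        raise ValueError("no calls supplied")
    embryo_id = calls[0].embryo_id
    n_aneu = sum(c.is_aneuploid for c in calls)
    called = [c for c in calls if c.call != "nocall"]
    gw = False
    if called:
        for pattern in ("trisomy_m", "trisomy_p", "monosomy_m", "monosomy_p"):
            frac = sum(c.call == pattern for c in called) / len(called)
            if frac >= genome_wide_fraction:
                gw = True
    return EmbryoFlags(embryo_id, complex_aneuploid=n_aneu > complex_threshold,
                       genome_wide_abnormal=gw)


def call_chromosome(embryo: EmbryoBAF, panel: SNPPanel, gmap: GeneticMap,
                    chrom: str, params: hmm.EmissionParams,
                    centromere_bp: int | None = None,
                    prior: dict[str, float] | None = None,
                    tau: float = TAU) -> tuple[PloidyCall, hmm.HMMResult | None]:
    """Full single-chromosome pipeline: likelihoods, call, class, decoding.

    Returns the call plus the decoded HMM result under the called
    hypothesis (None for nullisomy / nocall, where no decoding is
    meaningful).
    """
    logliks = hmm.all_hypothesis_logliks(embryo.baf, panel, gmap, chrom, params)
    call = call_copy_number(logliks, embryo.embryo_id, chrom, prior, tau)
    if call.call in ("nocall", "nullisomy"):
        return call, None
    res = hmm.posterior_decode(embryo.baf, panel, gmap, chrom, call.call, params)
    if call.copy_number == 3:
        parent = call.origin
        call.bph_profile = res.bph_posterior(parent)
        if centromere_bp is not None:
            pos = panel.pos[panel.chrom_mask(chrom)]
            call.meiotic_class = classify_trisomy_origin(call, pos, centromere_bp)
    return call, res


def is_maternal_meiotic(call: PloidyCall, count_monosomies: bool = True) -> bool:
    """Whether a call counts as a maternal meiotic-origin aneuploidy.

    Trisomy classes MI/MII qualify directly.  Monosomy meiotic status is
    not inferable from transmission data alone; by default maternal
    monosomies are counted (``count_monosomies=True``).
    """
    if call.origin != "maternal":
        return False
    if call.copy_number == 3:
        return call.meiotic_class in ("meiotic_MI_like", "meiotic_MII_like")
    if call.copy_number == 1:
        return count_monosomies
    return False
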