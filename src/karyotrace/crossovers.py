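"""Crossover mapping: sibling-based parental phasing, posterior
haplotype-switch calling on disomic chromosomes, and cohort filters.

True crossovers are meiosis-specific; parental phase errors instead
produce apparent switches at the *same* interval in most siblings.  The
artifact filter exploits exactly that asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CrossoverEvent, EmbryoBAF, SNPPanel
from .hmm import HMMResult

#: hard-call BAF thresholds for the phasing transmission indicator
BAF_LOW = 0.25
BAF_HIGH = 0.75
#: default switch-posterior threshold
GAMMA = 0.90


@dataclass
class PhasedParents:
    """Phasing result: a fully phased panel plus per-site confidence.

    ``confidence`` holds, per parent, the majority-vote margin in [0, 1]
    at parent-heterozygous sites (NaN elsewhere).  The global haplotype
    labelling per (parent, chromosome) is arbitrary; the chosen anchor is
    recorded in ``flip_log``.
    """

    panel: SNPPanel
    confidence: dict[str, np.ndarray]
    flip_log: dict[tuple[str, str], str] = field(default_factory=dict)


def _transmission_indicator(baf: np.ndarray, het_parent_other_allele: np.ndarray) -> np.ndarray:
    """Allele transmitted by the heterozygous parent, from hard-called BAF.

    The other parent is homozygous for ``het_parent_other_allele`` (a),
    so expected BAF is (m + a)/2 with m the transmitted allele.  BAF is
    quantized at 0.25/0.75; inconsistent combinations give -1 (missing).
    """
    a = het_parent_other_allele
    out = np.full(len(baf), -1, dtype=np.int8)
    low = baf < BAF_LOW
    high = baf > BAF_HIGH
    mid = ~low & ~high & ~np.isnan(baf)
    out[(a == 0) & low] = 0
    out[(a == 0) & mid] = 1
    out[(a == 1) & high] = 1
    out[(a == 1) & mid] = 0
    return out


def phase_by_transmission(panel: SNPPanel, siblings: list[EmbryoBAF]) -> PhasedParents:
    """Phase both parents from the co-transmission pattern in siblings.

    At informative sites (one parent heterozygous, the other homozygous)
    each sibling's transmitted allele is hard-called from its BAF; the
    site-to-site phase orientation is then chosen left-to-right to
    minimize the implied number of haplotype switches summed over
    siblings (majority vote).  Requires at least three siblings.
    """
    if len(siblings) < 3:
        raise ValueError("at least three sibling embryos required")
    mat = panel.mat_haps.copy()
    pat = panel.pat_haps.copy()
    confidence = {p: np.full(panel.n_sites, np.nan) for p in ("maternal", "paternal")}
    flip_log: dict[tuple[str, str], str] = {}

    for parent, haps, other in (("maternal", mat, pat), ("paternal", pat, mat)):
        het = haps[0] != haps[1]
        hom_other = other[0] == other[1]
        for chrom in panel.chromosomes():
            info = np.flatnonzero(het & hom_other & panel.chrom_mask(chrom))
            if len(info) == 0:
                continue
            # transmitted-allele matrix: (n_sib, n_info) in {0,1,-1}
            x = np.stack([
                _transmission_indicator(s.baf[info], other[0][info]) for s in siblings
            ])
            orient = np.zeros(len(info), dtype=np.int8)
            flip_log[(parent, chrom)] = (
                f"haplotype labels anchored at site index {int(info[0])}")
            h_prev = np.full(len(siblings), -1, dtype=np.int8)
            obs0 = x[:, 0] >= 0
            h_prev[obs0] = x[obs0, 0]  # orientation 0 at the anchor
            confidence[parent][info[0]] = 1.0 if obs0.any() else 0.0
            for j in range(1, len(info)):
                obs = (x[:, j] >= 0) & (h_prev >= 0)
                if obs.any():
                    # switches implied under orientation 0 vs 1
                    sw0 = int(np.sum(h_prev[obs] != x[obs, j]))
                    sw1 = int(np.sum(h_prev[obs] != (1 - x[obs, j])))
                    orient[j] = 1 if sw1 < sw0 else 0
                    confidence[parent][info[j]] = abs(sw0 - sw1) / int(obs.sum())
                else:
                    orient[j] = orient[j - 1]
                    confidence[parent][info[j]] = 0.0
                upd = x[:, j] >= 0
                h_prev[upd] = x[upd, j] ^ orient[j]
            # write phased alleles: hap0 carries allele `orient`, hap1 its complement
            haps[0, info] = orient
            haps[1, info] = 1 - orient

    phased = SNPPanel(chrom=panel.chrom, pos=panel.pos, ref=panel.ref, alt=panel.alt,
                      mat_haps=mat, pat_haps=pat, mat_phased=True, pat_phased=True)
    return PhasedParents(phased, confidence, flip_log)


def call_crossovers(result: HMMResult, panel: SNPPanel, chrom: str, embryo_id: str,
                    parent: str, gamma: float = GAMMA,
                    min_run: int = 2, flank_guard: int = 3,
                    flank_guard_max: int = 6,
                    anchor_conf: float = 0.99) -> list[CrossoverEvent]:
    """Crossovers of one parent on one disomic chromosome.

    Events are emitted where the maximum-posterior source haplotype flips
    between consecutive runs of *confident* informative sites
    (parent-heterozygous, haplotype marginal ≥ gamma).  The uniform
    outlier component of the noise model bounds how misleading any one
    site can be, but single strong outliers can displace the
    maximum-posterior flip by a site, and short runs of weakly misleading
    draws can displace it by a few; three guards make the reported
    interval robust to both:

    * runs shorter than ``min_run`` confident sites are ignored (and the
      same-haplotype runs they interrupt are merged), so an isolated
      outlier neither creates a spurious event pair nor truncates a
      flanking run;
    * each flank is anchored at least ``flank_guard`` confident sites
      outward from the flip, past any single misleading draw; and
    * the anchor keeps receding (to at most ``flank_guard_max`` sites)
      until the haplotype marginal reaches ``anchor_conf``, past short
      weakly-misleading stretches.
    """
    phased = panel.mat_phased if parent == "maternal" else panel.pat_phased
    if not phased:
        raise ValueError(f"{parent} haplotypes are unphased; phase before calling")
    mask = panel.chrom_mask(chrom)
    marg = result.single_copy_marginal(parent)       # P(hap 0), chromosome-local
    pos = panel.pos[mask]
    het = panel.het_mask(parent)[mask]
    conf_val = np.maximum(marg, 1.0 - marg)
    idx = np.flatnonzero(het & (conf_val >= gamma))
    if len(idx) == 0:
        return []
    hap = (marg[idx] < 0.5).astype(int)
    # maximal runs of confident sites on one haplotype ...
    starts = np.flatnonzero(np.concatenate(([True], hap[1:] != hap[:-1])))
    ends = np.concatenate((starts[1:], [len(hap)]))
    kept = [(s, e) for s, e in zip(starts, ends) if e - s >= min_run]
    # ... merged across dropped (outlier) runs of the opposite haplotype
    runs: list[list[int]] = []          # each: list of positions into `idx`
    for s, e in kept:
        if runs and hap[runs[-1][0]] == hap[s]:
            runs[-1].extend(range(s, e))
        else:
            runs.append(list(range(s, e)))

    def anchor(sites_outward: list[int]) -> int:
        """First site ≥ flank_guard out that is anchor-confident."""
        for k, s in enumerate(sites_outward, start=1):
            if k >= flank_guard and conf_val[idx[s]] >= anchor_conf:
                return s
            if k >= min(flank_guard_max, len(sites_outward)):
                return s
        return sites_outward[-1]

    events: list[CrossoverEvent] = []
    for left_run, right_run in zip(runs[:-1], runs[1:]):
        i = idx[anchor(left_run[::-1])]
        j = idx[anchor(right_run)]
        events.append(CrossoverEvent(
            embryo_id=embryo_id, parent=parent, chrom=chrom,
            left=int(pos[i]), right=int(pos[j]),
            gamma_left=float(max(marg[i], 1 - marg[i])),
            gamma_right=float(max(marg[j], 1 - marg[j])),
        ))
    return events


@dataclass
class FilterResult:
    """Filtered events plus the exclusion log."""

    events: list[CrossoverEvent]
    phase_artifacts: list[CrossoverEvent]
    excluded_embryos: set[str]
    log: list[str] = field(default_factory=list)


def filter_artifacts(events: list[CrossoverEvent], families: dict[str, list[str]],
                     share_threshold: float = 0.5, n_sd: float = 3.0) -> FilterResult:
    """Remove shared-interval phase artifacts and flag outlier embryos.

    ``families`` maps family_id -> sibling embryo ids considered (all
    siblings with usable disomic data, whether or not they have events).

    1.  Within families of ≥3 siblings, events with an identical
        (parent, chrom, interval) shared by more than ``share_threshold``
        of the siblings are removed as parental phase errors.
    2.  Embryos whose per-parent total event count deviates more than
        ``n_sd`` standard deviations from the cohort parent-specific
        mean are flagged for exclusion from phenotype tables (their
        events are retained in the returned list).
    """
    log: list[str] = []
    embryo_family = {e: f for f, sibs in families.items() for e in sibs}

    # --- shared-interval phase artifacts -----------------------------------
    shared: dict[tuple, set[str]] = {}
    for ev in events:
        k = (embryo_family.get(ev.embryo_id), ev.parent, ev.chrom, ev.left, ev.right)
        shared.setdefault(k, set()).add(ev.embryo_id)
    bad_keys = set()
    for (fam, parent, chrom, left, right), carriers in shared.items():
        sibs = families.get(fam, [])
        if len(sibs) >= 3 and len(carriers) / len(sibs) > share_threshold:
            bad_keys.add((fam, parent, chrom, left, right))
            log.append(f"phase artifact: {fam} {parent} {chrom}:{left}-{right} "
                       f"shared by {len(carriers)}/{len(sibs)} siblings")
    kept, artifacts = [], []
    for ev in events:
        k = (embryo_family.get(ev.embryo_id), ev.parent, ev.chrom, ev.left, ev.right)
        (artifacts if k in bad_keys else kept).append(ev)

    # --- outlier embryos (parent-specific 3 s.d. rule) ----------------------
    all_embryos = [e for sibs in families.values() for e in sibs]
    excluded: set[str] = set()
    for parent in ("maternal", "paternal"):
        counts = {e: 0 for e in all_embryos}
        for ev in kept:
            if ev.parent == parent and ev.embryo_id in counts:
                counts[ev.embryo_id] += 1
        vals = np.array(list(counts.values()), dtype=float)
        if len(vals) < 2:
            continue
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        for e, c in counts.items():
            if abs(c - mean) > n_sd * sd:
                excluded.add(e)
                log.append(f"embryo {e} excluded: {parent} count {c} vs "
                           f"cohort mean {mean:.2f} (sd {sd:.2f})")
    return FilterResult(kept, artifacts, excluded, log)
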