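"""Forward simulator for families of IVF embryos with known meioses.

The generator emulates the statistical structure the HMM assumes: diploid
parents drawn from per-site allele frequencies, crossovers placed as a
Poisson process on the genetic-map (cM) scale with no interference,
whole-chromosome mis-segregation in the canonical cytogenetic modes, and
noisy bulk-biopsy BAF signals (truncated-normal around the allelic dosage
plus a uniform outlier component).

Mis-segregation modes
---------------------
``maternal_MI_BPH``
    Meiosis-I-type gain: both maternal homologues transmitted — the two
    maternal copies are distinct at the centromere (BPH), recombinant
    distally.
``maternal_MII``
    Meiosis-II-type gain: two sister chromatids of one homologue — same
    homologue at the centromere (SPH), with BPH possible distal to
    crossovers.
``mitotic_trisomy``
    Post-zygotic duplication: an exact copy of one transmitted maternal
    chromatid (SPH everywhere).
``maternal_monosomy`` / ``paternal_monosomy``
    Loss of the named parent's copy (k = 1).
``paternal_trisomy``
    Paternal meiotic gain (MI-type BPH at the centromere).
``nullisomy``
    Both copies absent (k = 0): BAF is pure noise.
``triploid``
    A genome-wide extra maternal haploid complement (k = 3 everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, ndtr, ndtri

from .datatypes import EmbryoBAF, GeneticMap, SNPPanel

MODES = (
    "euploid",
    "maternal_MI_BPH",
    "maternal_MII",
    "maternal_monosomy",
    "paternal_trisomy",
    "paternal_monosomy",
    "mitotic_trisomy",
    "nullisomy",
    "triploid",
)

#: expected per-chromosome call for each simulated mode
MODE_TO_HYPOTHESIS = {
    "euploid": "disomy",
    "maternal_MI_BPH": "trisomy_m",
    "maternal_MII": "trisomy_m",
    "maternal_monosomy": "monosomy_m",
    "paternal_trisomy": "trisomy_p",
    "paternal_monosomy": "monosomy_p",
    "mitotic_trisomy": "trisomy_m",
    "nullisomy": "nullisomy",
    "triploid": "trisomy_m",
}


@dataclass
class SimConfig:
    """Study conditions for one simulated family cohort."""

    n_sites: int = 2000                      # per chromosome
    n_chromosomes: int = 2
    chrom_length_bp: int = 100_000_000
    maf_bounds: tuple[float, float] = (0.1, 0.5)
    cm_per_mb: float = 1.0                   # ~1 cM/Mb, the genome average
    sigma: float = 0.1                       # biopsy BAF noise scale
    pi0: float = 0.05                        # uniform outlier weight
    n_embryos: int = 8
    #: per-embryo probability of each mis-segregation mode
    aneuploidy_rates: dict[str, float] = field(default_factory=dict)
    #: >0 couples fewer maternal crossovers to higher mis-segregation risk
    crossover_coupling: float = 0.0
    centromere_frac: float = 0.4             # metacentric-ish placement
    maternal_age: float = 35.0
    paternal_age: float = 37.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        bad = set(self.aneuploidy_rates) - set(MODES)
        if bad:
            raise ValueError(f"unknown mis-segregation mode(s): {sorted(bad)}")
        if sum(self.aneuploidy_rates.values()) > 1.0 + 1e-12:
            raise ValueError("mode probabilities sum to more than 1")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.uniform(
            {c: self.chrom_length_bp for c in self.chrom_names}, self.cm_per_mb
        )

    def centromeres(self) -> dict[str, int]:
        return {c: int(self.chrom_length_bp * self.centromere_frac)
                for c in self.chrom_names}


@dataclass
class ChromTruth:
    """Ground truth for one chromosome of one embryo."""

    chrom: str
    mode: str                              # effective mode on this chromosome
    k: int
    maternal_paths: list[np.ndarray]       # transmitted copies, (n,) in {0,1}
    paternal_paths: list[np.ndarray]
    maternal_crossovers: np.ndarray        # bp, of the (first) transmitted gamete
    paternal_crossovers: np.ndarray

    def bph_fraction(self, parent: str = "maternal") -> float:
        """Fraction of sites where two distinct same-parent haplotypes are present."""
        paths = self.maternal_paths if parent == "maternal" else self.paternal_paths
        if len(paths) != 2:
            return 0.0
        return float(np.mean(paths[0] != paths[1]))


@dataclass
class TrueMeiosis:
    """Full ground truth for one embryo."""

    embryo_id: str
    family_id: str
    mode: str                              # embryo-level mode
    affected_chroms: list[str]
    chroms: dict[str, ChromTruth]

    @property
    def is_aneuploid(self) -> bool:
        return self.mode != "euploid"


@dataclass
class FamilySim:
    """One simulated family: parents, sibling embryos, and ground truth."""

    config: SimConfig
    panel: SNPPanel
    gmap: GeneticMap
    embryos: list[EmbryoBAF]
    truths: list[TrueMeiosis]
    centromeres: dict[str, int]


# ---------------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------------

def simulate_parental_haplotypes(config: SimConfig, rng: np.random.Generator) -> SNPPanel:
    """Four parental haplotypes drawn from per-site allele frequencies."""
    chroms, poss, freqs = [], [], []
    for c in config.chrom_names:
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp, dtype=np.int64),
            size=config.n_sites, replace=False))
        chroms.append(np.full(config.n_sites, c, dtype=object))
        poss.append(pos)
        lo, hi = config.maf_bounds
        freqs.append(rng.uniform(lo, hi, size=config.n_sites))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    f = np.concatenate(freqs)
    n = len(pos)
    mat = (rng.random((2, n)) < f).astype(np.int8)
    pat = (rng.random((2, n)) < f).astype(np.int8)
    return SNPPanel(
        chrom=chrom, pos=pos,
        ref=np.full(n, "A", dtype=object), alt=np.full(n, "G", dtype=object),
        mat_haps=mat, pat_haps=pat, mat_phased=True, pat_phased=True,
    )


def draw_crossovers(gmap: GeneticMap, chrom: str, rng: np.random.Generator) -> np.ndarray:
    """Crossover bp positions: Poisson(L/100) count, uniform on the cM scale."""
    L = gmap.length_cM(chrom)
    n = rng.poisson(L / 100.0)
    if n == 0:
        return np.empty(0)
    _, cm = gmap.anchors(chrom)
    u = rng.uniform(cm[0], cm[-1], size=n)
    return np.sort(np.asarray(gmap.interpolate_bp(chrom, u)))


def form_gamete(pos: np.ndarray, crossovers: np.ndarray, start: int) -> np.ndarray:
    """Transmitted-haplotype path: begins on ``start``, flips at each crossover."""
    if np.any(np.diff(crossovers) < 0):
        raise ValueError("crossovers must be sorted")
    nflips = np.searchsorted(crossovers, pos)
    return ((start + nflips) % 2).astype(np.int8)


def _gamete(gmap, chrom, pos, rng):
    xo = draw_crossovers(gmap, chrom, rng)
    path = form_gamete(pos, xo, int(rng.integers(2)))
    return path, xo


def apply_missegregation(mode: str, chrom: str, pos: np.ndarray, gmap: GeneticMap,
                         cen_bp: int, rng: np.random.Generator) -> ChromTruth:
    """Construct a chromosome's transmitted copies under one mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mis-segregation mode {mode!r}")
    cen_idx = int(np.argmin(np.abs(pos - cen_bp)))
    mp, mxo = _gamete(gmap, chrom, pos, rng)
    pp, pxo = _gamete(gmap, chrom, pos, rng)

    def second(path1, bph_at_cen: bool):
        """A second same-parent copy, anchored at the centromere."""
        p2, _ = _gamete(gmap, chrom, pos, rng)
        want_diff = bph_at_cen
        if (p2[cen_idx] != path1[cen_idx]) != want_diff:
            p2 = (1 - p2).astype(np.int8)
        return p2

    if mode == "euploid":
        return ChromTruth(chrom, mode, 2, [mp], [pp], mxo, pxo)
    if mode == "maternal_MI_BPH":
        return ChromTruth(chrom, mode, 3, [mp, second(mp, True)], [pp], mxo, pxo)
    if mode == "maternal_MII":
        return ChromTruth(chrom, mode, 3, [mp, second(mp, False)], [pp], mxo, pxo)
    if mode == "maternal_monosomy":
        return ChromTruth(chrom, mode, 1, [], [pp], np.empty(0), pxo)
    if mode == "paternal_trisomy":
        return ChromTruth(chrom, mode, 3, [mp], [pp, second(pp, True)], mxo, pxo)
    if mode == "paternal_monosomy":
        return ChromTruth(chrom, mode, 1, [mp], [], mxo, np.empty(0))
    if mode == "mitotic_trisomy":
        return ChromTruth(chrom, mode, 3, [mp, mp.copy()], [pp], mxo, pxo)
    if mode == "nullisomy":
        return ChromTruth(chrom, mode, 0, [], [], np.empty(0), np.empty(0))
    if mode == "triploid":  # per-chromosome effect: one extra maternal gamete
        extra, _ = _gamete(gmap, chrom, pos, rng)
        return ChromTruth(chrom, mode, 3, [mp, extra], [pp], mxo, pxo)
    raise AssertionError


def synthesize_baf(truth: dict[str, ChromTruth], panel: SNPPanel, sigma: float,
                   pi0: float, rng: np.random.Generator, embryo_id: str = "e0",
                   family_id: str = "f0", maternal_age: float = 35.0,
                   paternal_age: float = 37.0) -> EmbryoBAF:
    """Noisy BAF vector for one embryo given its per-chromosome truth.

    Expected BAF is (ALT dosage among transmitted copies)/k; observations
    are uniform outliers with probability ``pi0``, otherwise truncated
    normal on [0, 1] (sampled by inverse CDF).
    """
    baf = np.empty(panel.n_sites)
    for chrom, ct in truth.items():
        mask = panel.chrom_mask(chrom)
        n = int(mask.sum())
        if ct.k == 0:
            b = rng.uniform(0.0, 1.0, size=n)
        else:
            dose = np.zeros(n)
            mh, ph = panel.mat_haps[:, mask], panel.pat_haps[:, mask]
            idx = np.arange(n)
            for path in ct.maternal_paths:
                dose += mh[path, idx]
            for path in ct.paternal_paths:
                dose += ph[path, idx]
            mu = dose / ct.k
            lo = ndtr((0.0 - mu) / sigma)
            hi = ndtr((1.0 - mu) / sigma)
            u = rng.uniform(lo, hi)
            b = np.clip(mu + sigma * ndtri(u), 0.0, 1.0)
            out = rng.random(n) < pi0
            b[out] = rng.uniform(0.0, 1.0, size=int(out.sum()))
        baf[mask] = b
    return EmbryoBAF(embryo_id=embryo_id, family_id=family_id, baf=baf,
                     maternal_age=maternal_age, paternal_age=paternal_age)


# ---------------------------------------------------------------------------
# whole-family simulation
# ---------------------------------------------------------------------------

def _choose_mode(config: SimConfig, n_maternal_xo: int, expected_xo: float,
                 rng: np.random.Generator) -> str:
    """Embryo-level mode, optionally coupled to the maternal crossover count."""
    p_aneu = sum(config.aneuploidy_rates.values())
    if p_aneu <= 0.0:
        return "euploid"
    if config.crossover_coupling != 0.0 and p_aneu < 1.0:
        eta = logit(p_aneu) - config.crossover_coupling * (n_maternal_xo - expected_xo)
        p_aneu = float(expit(eta))
    if rng.random() >= p_aneu:
        return "euploid"
    modes = list(config.aneuploidy_rates)
    w = np.array([config.aneuploidy_rates[m] for m in modes])
    return str(rng.choice(modes, p=w / w.sum()))


def simulate_family(config: SimConfig, rng: np.random.Generator | int,
                    family_id: str = "f0") -> FamilySim:
    """Shared parents, independent meioses, full truth records."""
    if config.n_embryos < 1:
        raise ValueError("n_embryos must be at least 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    panel = simulate_parental_haplotypes(config, rng)
    gmap = config.genetic_map()
    cens = config.centromeres()
    expected_xo = sum(gmap.length_cM(c) for c in config.chrom_names) / 100.0

    embryos, truths = [], []
    for e in range(config.n_embryos):
        eid = f"{family_id}_e{e}"
        # maternal meiosis first: its crossover total may modulate risk
        mat_draws = {}
        for c in config.chrom_names:
            pos = panel.pos[panel.chrom_mask(c)]
            xo = draw_crossovers(gmap, c, rng)
            path = form_gamete(pos, xo, int(rng.integers(2)))
            mat_draws[c] = (path, xo)
        n_xo = sum(len(x) for _, x in mat_draws.values())
        mode = _choose_mode(config, n_xo, expected_xo, rng)

        if mode == "euploid":
            affected: list[str] = []
        elif mode == "triploid":
            affected = list(config.chrom_names)
        else:
            affected = [str(rng.choice(config.chrom_names))]

        chroms: dict[str, ChromTruth] = {}
        for c in config.chrom_names:
            pos = panel.pos[panel.chrom_mask(c)]
            if c in affected:
                chroms[c] = apply_missegregation(mode, c, pos, gmap, cens[c], rng)
            else:
                path, xo = mat_draws[c]
                pp, pxo = _gamete(gmap, c, pos, rng)
                chroms[c] = ChromTruth(c, "euploid", 2, [path], [pp], xo, pxo)
        truths.append(TrueMeiosis(eid, family_id, mode, affected, chroms))
        embryos.append(synthesize_baf(
            chroms, panel, config.sigma, config.pi0, rng, embryo_id=eid,
            family_id=family_id, maternal_age=config.maternal_age,
            paternal_age=config.paternal_age))
    return FamilySim(config, panel, gmap, embryos, truths, cens)
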