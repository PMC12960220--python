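"""Core in-memory containers shared across the toolkit.

Conventions
-----------
* SNP positions are 1-based base pairs; BED-style interval tracks are
  0-based half-open.
* Alleles are coded 0 = REF, 1 = ALT; panels are strictly biallelic.
* Haplotype matrices have shape ``(2, n_sites)`` — one row per parental
  haplotype — with dtype ``int8``.
* Missing BAF values are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Parents, in the order used throughout the package.
PARENTS = ("maternal", "paternal")


@dataclass
class SNPPanel:
    """Biallelic SNP sites with the four parental haplotypes.

    Positions must be strictly increasing within each chromosome and
    chromosomes must be stored contiguously.  ``mat_phased`` /
    ``pat_phased`` record whether the corresponding haplotype rows carry
    real phase (as opposed to an arbitrary ordering of an unphased
    genotype).
    """

    chrom: np.ndarray          # (n,) object/str
    pos: np.ndarray            # (n,) int64, 1-based
    ref: np.ndarray            # (n,) str
    alt: np.ndarray            # (n,) str
    mat_haps: np.ndarray       # (2, n) int8 in {0, 1}
    pat_haps: np.ndarray       # (2, n) int8 in {0, 1}
    mat_phased: bool = True
    pat_phased: bool = True

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.mat_haps = np.asarray(self.mat_haps, dtype=np.int8)
        self.pat_haps = np.asarray(self.pat_haps, dtype=np.int8)
        if self.mat_haps.shape != (2, self.n_sites) or self.pat_haps.shape != (2, self.n_sites):
            raise ValueError("haplotype matrices must have shape (2, n_sites)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return [self.chrom[i] for i in np.sort(idx)]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return np.asarray(self.chrom == chrom)

    def subset(self, mask: np.ndarray) -> "SNPPanel":
        return SNPPanel(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            mat_haps=self.mat_haps[:, mask],
            pat_haps=self.pat_haps[:, mask],
            mat_phased=self.mat_phased,
            pat_phased=self.pat_phased,
        )

    def haps(self, parent: str) -> np.ndarray:
        if parent == "maternal":
            return self.mat_haps
        if parent == "paternal":
            return self.pat_haps
        raise ValueError(f"unknown parent {parent!r}")

    def het_mask(self, parent: str) -> np.ndarray:
        """Sites where the given parent is heterozygous."""
        h = self.haps(parent)
        return h[0] != h[1]


@dataclass
class EmbryoBAF:
    """Per-embryo B-allele-frequency vector aligned to a :class:`SNPPanel`."""

    embryo_id: str
    family_id: str
    baf: np.ndarray            # (n,) float64 in [0, 1], NaN = missing
    maternal_age: float = float("nan")
    paternal_age: float = float("nan")

    def __post_init__(self) -> None:
        self.baf = np.asarray(self.baf, dtype=np.float64)
        present = ~np.isnan(self.baf)
        if np.any((self.baf[present] < 0) | (self.baf[present] > 1)):
            raise ValueError(f"BAF outside [0, 1] for embryo {self.embryo_id}")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.baf)


class GeneticMap:
    """Piecewise-linear bp ↔ cM map, one set of anchors per chromosome.

    Queries are linearly interpolated between anchors; positions beyond
    the terminal anchors clamp to the terminal cM values.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if len(bp) < 2:
                raise ValueError(f"{chrom}: at least two map anchors required")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"{chrom}: bp anchors must be strictly increasing")
            if np.any(np.diff(cm) < 0) or np.any(cm < 0):
                raise ValueError(f"{chrom}: cM anchors must be non-negative and non-decreasing")
            self._anchors[chrom] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map: ``cm_per_mb`` centimorgans per megabase."""
        return cls({
            c: (np.array([1.0, float(L)]), np.array([0.0, (L - 1) * cm_per_mb / 1e6]))
            for c, L in chrom_lengths.items()
        })

    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def interpolate_cM(self, chrom: str, pos_bp) -> np.ndarray | float:
        """cM position(s) of ``pos_bp`` on ``chrom`` (clamped at map ends)."""
        if chrom not in self._anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        bp, cm = self._anchors[chrom]
        out = np.interp(np.asarray(pos_bp, dtype=np.float64), bp, cm)
        return float(out) if np.isscalar(pos_bp) else out

    def interpolate_bp(self, chrom: str, pos_cm) -> np.ndarray | float:
        """Inverse query: bp position(s) at cumulative cM (used for sampling)."""
        if chrom not in self._anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        bp, cm = self._anchors[chrom]
        # np.interp needs strictly increasing x; collapse flat cM stretches
        keep = np.concatenate(([True], np.diff(cm) > 0))
        out = np.interp(np.asarray(pos_cm, dtype=np.float64), cm[keep], bp[keep])
        return float(out) if np.isscalar(pos_cm) else out

    def length_cM(self, chrom: str) -> float:
        bp, cm = self._anchors[chrom]
        return float(cm[-1] - cm[0])

    def span_bp(self, chrom: str) -> tuple[float, float]:
        bp, _ = self._anchors[chrom]
        return float(bp[0]), float(bp[-1])

    def anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._anchors[chrom]


class IntervalTrack:
    """Sorted genomic intervals (0-based half-open), optionally valued.

    Hotspot BED tracks carry no values; bedGraph tracks carry one float
    per interval.  Overlapping unvalued intervals are merged on
    construction via :meth:`merged`.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]]):
        self._iv: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]] = {}
        for chrom, (start, end, value) in intervals.items():
            start = np.asarray(start, dtype=np.int64)
            end = np.asarray(end, dtype=np.int64)
            if np.any(end <= start):
                raise ValueError(f"{chrom}: interval end must exceed start")
            order = np.argsort(start, kind="stable")
            value = None if value is None else np.asarray(value, dtype=np.float64)[order]
            self._iv[chrom] = (start[order], end[order], value)

    def chromosomes(self) -> list[str]:
        return list(self._iv)

    def get(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        empty = (np.empty(0, np.int64), np.empty(0, np.int64), None)
        return self._iv.get(chrom, empty)

    def merged(self) -> "IntervalTrack":
        """Union of intervals per chromosome (values dropped)."""
        out = {}
        for chrom, (start, end, _) in self._iv.items():
            ms, me = [], []
            for s, e in zip(start, end):
                if ms and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            out[chrom] = (np.array(ms, np.int64), np.array(me, np.int64), None)
        return IntervalTrack(out)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) (0-based half-open) intersects any interval."""
        s, e, _ = self.get(chrom)
        if len(s) == 0:
            return False
        i = int(np.searchsorted(s, end))      # intervals starting before `end`
        return bool(np.any(e[:i] > start))

    def value_at(self, chrom: str, pos: int) -> float:
        """Value of the interval covering 0-based ``pos``; NaN if uncovered."""
        s, e, v = self.get(chrom)
        if v is None or len(s) == 0:
            return float("nan")
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return float("nan")


@dataclass
class CrossoverEvent:
    """A parental haplotype switch localized between two informative SNPs.

    ``left`` / ``right`` are 1-based positions of the flanking informative
    SNPs; the crossover lies in ``(left, right]``.  ``gamma_left`` /
    ``gamma_right`` are the haplotype marginal posteriors at the flanks.
    """

    embryo_id: str
    parent: str
    chrom: str
    left: int
    right: int
    gamma_left: float
    gamma_right: float

    @property
    def resolution_bp(self) -> int:
        return self.right - self.left

    @property
    def midpoint(self) -> int:
        return (self.left + self.right) // 2

    def key(self) -> tuple:
        return (self.embryo_id, self.parent, self.chrom, self.left, self.right)


@dataclass
class PloidyCall:
    """Per-chromosome copy-number call for one embryo."""

    embryo_id: str
    chrom: str
    posteriors: dict[str, float]          # hypothesis label -> posterior
    call: str                             # hypothesis label or "nocall"
    copy_number: int | None               # k of the call, None for nocall
    origin: str | None                    # "maternal"/"paternal"/None
    meiotic_class: str = "NA"             # MI_like / MII_like / putative_mitotic / NA
    #: per-site P(two distinct same-parent haps); not serialized, excluded from ==
    bph_profile: np.ndarray | None = field(default=None, compare=False)

    @property
    def is_aneuploid(self) -> bool:
        return self.call not in ("disomy", "nocall")


@dataclass
class EmbryoFlags:
    """Cohort-level exclusion flags for one embryo."""

    embryo_id: str
    complex_aneuploid: bool
    genome_wide_abnormal: bool

    @property
    def excluded(self) -> bool:
        return self.complex_aneuploid or self.genome_wide_abnormal


@dataclass
class CallSet:
    """Bundle of ploidy calls + crossover events + run metadata."""

    ploidy_calls: list[PloidyCall] = field(default_factory=list)
    crossovers: list[CrossoverEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def calls_for(self, embryo_id: str) -> list[PloidyCall]:
        return [c for c in self.ploidy_calls if c.embryo_id == embryo_id]

    def embryo_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.ploidy_calls:
            seen.setdefault(c.embryo_id, None)
        for e in self.crossovers:
            seen.setdefault(e.embryo_id, None)
        return list(seen)

    def validate(self) -> None:
        """Every crossover must reference an embryo with a disomic call
        for its chromosome (when ploidy calls are present at all)."""
        if not self.ploidy_calls:
            return
        disomic = {(c.embryo_id, c.chrom) for c in self.ploidy_calls if c.call == "disomy"}
        for ev in self.crossovers:
            if (ev.embryo_id, ev.chrom) not in disomic:
                raise ValueError(
                    f"crossover for {ev.embryo_id}/{ev.chrom} lacks a disomy call"
                )
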