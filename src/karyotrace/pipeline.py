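"""End-to-end orchestration: family -> ploidy calls + crossovers + flags.

This is the path the CLI and the acceptance checks run; the individual
stages live in :mod:`hmm`, :mod:`ploidy` and :mod:`crossovers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crossovers as xo
from . import hmm, ploidy
from .datatypes import CallSet, CrossoverEvent, EmbryoBAF, EmbryoFlags, GeneticMap, PloidyCall, SNPPanel


@dataclass
class FamilyResult:
    """Calls, events and flags for one family of sibling embryos."""

    callset: CallSet
    flags: dict[str, EmbryoFlags]
    decoded: dict[tuple[str, str], hmm.HMMResult] = field(default_factory=dict)

    def euploid_embryos(self) -> list[str]:
        """Embryos with no aneuploid call and no exclusion flag."""
        out = []
        for eid in self.callset.embryo_ids():
            if self.flags[eid].excluded:
                continue
            if any(c.is_aneuploid for c in self.callset.calls_for(eid)):
                continue
            out.append(eid)
        return out


def call_family(panel: SNPPanel, gmap: GeneticMap, embryos: list[EmbryoBAF],
                centromeres: dict[str, int] | None = None,
                params: hmm.EmissionParams | None = None,
                fit_noise: bool = False,
                gamma: float = xo.GAMMA,
                tau: float = ploidy.TAU,
                keep_decoded: bool = False) -> FamilyResult:
    """Call ploidy and crossovers for every embryo of one family.

    Parents must be phased (use :func:`karyotrace.crossovers.
    phase_by_transmission` first if they are not).  Noise parameters are
    either supplied, grid-fitted per embryo (``fit_noise=True``), or
    default.
    """
    if params is None and not fit_noise:
        params = hmm.EmissionParams()
    calls: list[PloidyCall] = []
    events: list[CrossoverEvent] = []
    decoded: dict[tuple[str, str], hmm.HMMResult] = {}
    for embryo in embryos:
        p = hmm.fit_noise(embryo, panel, gmap) if fit_noise else params
        for chrom in panel.chromosomes():
            cen = None if centromeres is None else centromeres.get(chrom)
            call, res = ploidy.call_chromosome(embryo, panel, gmap, chrom, p,
                                               centromere_bp=cen, tau=tau)
            calls.append(call)
            if keep_decoded and res is not None:
                decoded[(embryo.embryo_id, chrom)] = res
            if call.call == "disomy" and res is not None:
                for parent in ("maternal", "paternal"):
                    events.extend(xo.call_crossovers(
                        res, panel, chrom, embryo.embryo_id, parent, gamma))
    flags = {}
    for embryo in embryos:
        own = [c for c in calls if c.embryo_id == embryo.embryo_id]
        flags[embryo.embryo_id] = ploidy.flag_embryo(own)
    callset = CallSet(ploidy_calls=calls, crossovers=events,
                      metadata={"n_embryos": len(embryos),
                                "gamma": gamma, "tau": tau})
    return FamilyResult(callset=callset, flags=flags, decoded=decoded)
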