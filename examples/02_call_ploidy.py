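"""Call chromosome copy number, parental origin and meiotic class.

Simulates embryos carrying different mis-segregation modes, runs the
six-hypothesis transmission HMM on each chromosome, and compares the
calls with the simulator's truth.  The posterior column shows how
decisively the winning hypothesis beats the alternatives.
"""

from karyotrace import hmm, ploidy
from karyotrace.simulate import MODE_TO_HYPOTHESIS, SimConfig, simulate_family

params = hmm.EmissionParams(sigma=0.1, pi0=0.05)
print(f"{'true mode':20s} {'call':12s} {'posterior':>9s} {'meiotic class':>18s}")
for mode in ("euploid", "maternal_MI_BPH", "maternal_MII", "mitotic_trisomy",
             "maternal_monosomy", "nullisomy"):
    rates = {} if mode == "euploid" else {mode: 1.0}
    cfg = SimConfig(n_sites=3000, n_chromosomes=1, n_embryos=1,
                    aneuploidy_rates=rates)
    fam = simulate_family(cfg, rng=11)
    call, _ = ploidy.call_chromosome(
        fam.embryos[0], fam.panel, fam.gmap, "chr1", params,
        centromere_bp=fam.centromeres["chr1"])
    ok = "ok" if call.call == MODE_TO_HYPOTHESIS[mode] else "MISS"
    print(f"{mode:20s} {call.call:12s} {call.posteriors[call.call]:9.4f} "
          f"{call.meiotic_class:>18s}  {ok}")

# Trisomies additionally carry a meiotic class read off the BPH profile:
# both-parental-homologues at the centromere marks a meiosis-I error,
# distal-only BPH a meiosis-II error, and no BPH anywhere a mitotic
# (post-zygotic) duplication.
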