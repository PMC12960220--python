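"""Simulate a family of sibling embryos with known meioses.

Builds one family of 6 embryos on two 100-Mb chromosomes with a 20%
per-embryo aneuploidy rate, then prints each embryo's true mis-segregation
mode and crossover counts — the ground truth every downstream example
tries to recover from the noisy BAF data alone.
"""

from karyotrace.simulate import SimConfig, simulate_family

config = SimConfig(
    n_sites=2000, n_chromosomes=2, n_embryos=6,
    sigma=0.1, pi0=0.05,
    aneuploidy_rates={"maternal_MI_BPH": 0.1, "maternal_monosomy": 0.1},
)
family = simulate_family(config, rng=8)

print(f"panel: {family.panel.n_sites} SNPs on {family.panel.chromosomes()}")
print(f"{'embryo':10s} {'mode':20s} {'maternal xo':>12s} {'paternal xo':>12s}")
for truth in family.truths:
    n_mat = sum(len(c.maternal_crossovers) for c in truth.chroms.values())
    n_pat = sum(len(c.paternal_crossovers) for c in truth.chroms.values())
    print(f"{truth.embryo_id:10s} {truth.mode:20s} {n_mat:12d} {n_pat:12d}")

# Each chromosome is ~100 cM, so euploid meioses average ~2 maternal and
# ~2 paternal crossovers across the two chromosomes; aneuploid rows show
# which mis-segregation mode corrupted which chromosome.
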