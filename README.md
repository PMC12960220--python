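# karyotrace

Joint aneuploidy calling and meiotic crossover mapping from SNP-array
data of IVF embryo biopsies, by tracing the transmission of parental
haplotypes.

Preimplantation genetic testing (PGT) genotypes a few trophectoderm
cells per blastocyst together with both parents. At each biallelic SNP
the embryo's B-allele frequency (BAF) has expectation
*(ALT dosage among transmitted chromosomes) / (copy number)*, so the BAF
track along a chromosome encodes which parental haplotypes were
transmitted. karyotrace models that track with a hidden Markov model
whose hidden states are the transmitted haplotype multisets over
{m1, m2, p1, p2} under six copy-number hypotheses — nullisomy,
maternal/paternal monosomy, disomy, maternal/paternal trisomy. Haplotype
switches along the chain are meiotic crossovers (Haldane transition
kernel, r = (1 − e^(−2d/100))/2 for d cM between sites); emissions are a
truncated-normal around the expected dosage μ ∈ {0, 1/k, …, 1} mixed
with a uniform outlier component (weight π0). Model selection across
hypotheses yields per-chromosome copy number, parental origin and —
from the BPH/SPH profile around the centromere — the meiotic class of
trisomies (MI-like, MII-like, or mitotic). The package is aimed at
statistical geneticists and embryology researchers studying
recombination, aneuploidy and their shared genetic basis.

Beyond the caller it provides:

* a **meiosis simulator** (families of sibling embryos with full ground
  truth: crossovers on a genetic map, nine mis-segregation modes, noisy
  biopsy BAF);
* **crossover phenotypes** (counts, hotspot occupancy, replication
  timing and GC context) and **aneuploidy summaries** with exact
  binomial ratio tests;
* a parametric-bootstrap **overdispersion test** of per-patient
  aneuploidy incidence (Pearson dispersion φ after quadratic
  maternal-age adjustment);
* the cross-chromosome **intraclass correlation** of crossover counts
  within embryos (one-way random-effects ICC on z-standardized counts);
* a **selection-proxy model**: lifetime euploid-embryo output W(g)
  integrated over the maternal reproductive window, s_proxy = 1 − W1/W0,
  and the drift threshold α\* = 1/(2·Ne·s).

## Worked example

Simulate a family, call a trisomic chromosome, and classify it
(`examples/02_call_ploidy.py`):

```python
from karyotrace import hmm, ploidy
from karyotrace.simulate import SimConfig, simulate_family

cfg = SimConfig(n_sites=3000, n_chromosomes=1, n_embryos=1,
                aneuploidy_rates={"maternal_MI_BPH": 1.0})
fam = simulate_family(cfg, rng=11)
call, _ = ploidy.call_chromosome(
    fam.embryos[0], fam.panel, fam.gmap, "chr1",
    hmm.EmissionParams(sigma=0.1, pi0=0.05),
    centromere_bp=fam.centromeres["chr1"])
print(call.call, call.posteriors[call.call], call.meiotic_class)
```

prints

```
trisomy_m 1.0000 meiotic_MI_like
```

a maternal trisomy called with posterior ≈ 1 and classified as a
meiosis-I error, because both maternal homologues are present at the
centromere (BPH). Running the full example sweeps all modes:

```
true mode            call         posterior      meiotic class
euploid              disomy          1.0000                 NA  ok
maternal_MI_BPH      trisomy_m       1.0000    meiotic_MI_like  ok
maternal_MII         trisomy_m       1.0000   meiotic_MII_like  ok
mitotic_trisomy      trisomy_m       1.0000   putative_mitotic  ok
maternal_monosomy    monosomy_m      1.0000                 NA  ok
nullisomy            nullisomy       1.0000                 NA  ok
```

The other examples cover simulation (`01`), crossover mapping against
ground truth (`03`), cohort statistics — ratio tests, overdispersion φ,
ICC — (`04`), and the selection proxy (`05`). A thin CLI wraps the same
library calls for shell use:

```bash
karyotrace simulate --seed 5 --out sim/
karyotrace call --vcf sim/parents.vcf --baf sim/baf.tsv \
    --map sim/genetic_map.tsv --centromeres sim/centromeres.tsv \
    --sigma 0.1 --out calls/
karyotrace phenotypes --calls calls/ --out pheno/
karyotrace selection --config selection.yaml --out sel/
```

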