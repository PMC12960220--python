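# Methods

## Problem setting

Preimplantation genetic testing (PGT) of IVF embryos genotypes a few
trophectoderm cells of each day-5 blastocyst on a SNP array, alongside DNA
from both parents. At each biallelic SNP the embryo yields a B-allele
frequency (BAF) — the fraction of array signal attributable to the ALT
allele, whose expectation is (ALT dosage among transmitted chromosomes) /
(chromosome copy number). Because the four parental haplotypes are known
(or can be phased from sibling embryos), the BAF track along a chromosome
encodes *which* parental haplotypes were transmitted. Two biologically
distinct signals live in that encoding:

* **haplotype switches** along a chromosome = meiotic crossovers, and
* **which multiset of haplotypes is present** = copy number, parental
  origin and mechanism of whole-chromosome aneuploidy.

karyotrace models both jointly with a hidden Markov model over
haplotype-transmission states, then derives the downstream cohort
phenotypes (crossover counts and sequence context, aneuploidy ratios, an
overdispersion test of patient-specific risk, the cross-chromosome ICC of
crossover counts) and a selection-proxy model for aneuploidy risk alleles.

## The transmission HMM

Six copy-number hypotheses are scored per chromosome per embryo:
nullisomy (k=0), maternal/paternal monosomy (k=1; the label names the
parent whose copy is *lost*), disomy (k=2), and maternal/paternal trisomy
(k=3). Hidden states are the transmitted haplotype multisets over
{m1, m2, p1, p2}: 1 state for nullisomy, 2 per monosomy, 4 for disomy and
6 for each trisomy (3 unordered same-parent pairs × 2 from the other
parent).

**Transitions.** Each transmitted copy independently switches its source
haplotype between adjacent sites with the Haldane recombination fraction
r = (1 − e^(−2d/100))/2 for inter-site distance d cM (linear interpolation
of the genetic map, clamped at map ends). Multi-copy transition
probabilities sum over ordered matchings of the destination multiset; the
initial distribution is uniform over *ordered* copy assignments (weight
1/4, 1/2, 1/4 for same-parent pairs), which is the exchangeable-haplotype
prior, is stationary under the transition kernel, and makes the collapsed
6-state trisomy chain exactly equal to its ordered 8-state counterpart.
Interference is ignored: at array inter-site scales (tens of kb, ≪1 cM)
its effect on r is negligible.

**Emissions.** Observed BAF b in [0,1] follows a two-component mixture:
with probability π0 a uniform outlier (array artifacts, mosaic signal,
mis-clustered probes), otherwise a normal with per-state mean
μ = dosage/k and scale σ truncated to [0,1]. Missing sites contribute
log-likelihood 0; under nullisomy the emission is the uniform density.
Defaults σ = 0.1, π0 = 0.05 describe a ~6-cell biopsy on a clinical
array; both are grid-fittable per embryo (σ ∈ 0.05…0.30 step 0.025,
π0 ∈ {0.01, 0.05, 0.1, 0.2, 0.35, 0.5}) by maximizing the disomy
likelihood, and the generating grid point is recovered on simulated data.

All recursions (forward, backward, Viterbi) run in log space (numba
kernels); 50,000-site chromosomes pose no underflow risk. Forward
likelihoods agree with exhaustive path enumeration to <1e−8 on small
chromosomes for all six hypotheses.

## Copy-number calling and meiotic classification

Posterior(h) ∝ exp(logL_h)·prior(h) with a uniform prior by default; the
argmax is called only if its posterior ≥ τ = 0.90, else "nocall". For
trisomies, the per-site BPH posterior — the probability that two
*distinct* same-parent haplotypes are present — classifies the mechanism:
mean BPH ≥ 0.5 over the centromere ± 5 Mb ⇒ meiosis-I-like; otherwise a
maximal 5-Mb-windowed BPH ≥ 0.5 elsewhere ⇒ meiosis-II-like; otherwise
putative mitotic duplication. Monosomy mechanism is not identifiable from
transmission data; maternal monosomies are counted as maternal meiotic
errors under a configurable flag (default on). Embryo-level flags mark
complex aneuploidy (>5 affected chromosomes) and genome-wide patterns
(≥80% of called chromosomes same-parent trisomies or monosomies,
i.e. triploidy/haploidy signatures); flagged embryos are excluded from
cohort summaries.

## Crossover calling

On disomic chromosomes the forward–backward marginal of the transmitted
haplotype is evaluated at informative (parent-heterozygous) sites.
Events are emitted where the maximum-posterior haplotype flips between
runs of confident sites (marginal ≥ γ = 0.90). Because the uniform
outlier component bounds — but does not eliminate — how misleading a
single site can be, three guards protect the reported interval:

1. runs of fewer than 2 confident sites are ignored and the
   same-haplotype runs they interrupt are merged (isolated outliers
   neither create spurious event pairs nor truncate flanking runs);
2. each flank recedes at least 3 confident sites outward from the flip,
   past any single strong outlier; and
3. it keeps receding (up to 6 sites) until the marginal reaches 0.99,
   past short stretches of weakly misleading draws.

The reported interval (left flank, right flank] then brackets the true
crossover essentially always (0 misses in ~2,700 matched events at
σ = 0.1, π0 = 0.05) at a resolution of a few informative-site spacings
(median ≈ 300 kb at 20-kb site spacing).

Parents unphased at input are phased from ≥3 sibling embryos: at sites
where one parent is heterozygous and the other homozygous, each sibling's
transmitted allele is hard-called from BAF (<0.25 / >0.75 quantization);
a left-to-right majority vote picks the orientation minimizing implied
switches, leaving one arbitrary global flip per (parent, chromosome),
which is recorded. Residual phase errors produce identical apparent
crossovers in most siblings and are removed by the sharing filter
(identical interval in >50% of ≥3 siblings). Embryos whose per-parent
total crossover count deviates >3 s.d. from the cohort parent-specific
mean are excluded from phenotype tables.

## The meiosis simulator

The simulator is the package's ground-truth instrument and emulates the
statistical structure the HMM assumes — not array physics. Per family:
four parental haplotypes drawn from per-site allele frequencies
(MAF ~ U(0.1, 0.5) by default, 1-based positions uniform on the
chromosome), crossovers as a Poisson process with intensity L/100 on the
cM scale (no interference, no obligate crossover — real meioses show
both interference and crossover assurance, so simulated counts are
slightly more dispersed than real ones), gametes switching haplotype at
each crossover, and BAF = truncated-normal(μ, σ) with a π0 uniform
outlier admixture, sampled by inverse CDF. Mis-segregation modes: MI-type
gains (distinct homologues at the centromere), MII-type gains (same
homologue at the centromere, recombinant distally), mitotic duplications
(identical chromatids), monosomies, nullisomy and triploidy. MII gains
whose sister chromatids happen not to recombine are *intrinsically*
indistinguishable from mitotic duplications; classification accuracy is
therefore asserted only for the MI/mitotic extremes. An optional
negative coupling multiplies the per-embryo mis-segregation logit by the
deficit of that meiosis's maternal crossover count from its expectation,
reproducing the observation that aneuploid embryos carry fewer
crossovers on their disomic chromosomes. What passing simulation tests
do **not** show: robustness to probe-specific BAF bias, segmental
aneuploidy, or within-biopsy mosaicism, none of which the generator
produces (mosaicism and segmental events are explicit non-goals).

## Cohort statistics

**Aneuploidy summaries** count trisomies/monosomies by chromosome and
origin after exclusions and test the trisomy:monosomy and
maternal:paternal fractions against 0.5 with exact binomial tests.

**Overdispersion.** Per patient, affected/total embryo counts are fit by
a logit-link binomial GLM with maternal age + age² (IRLS, implemented
directly and cross-checked against statsmodels). Dispersion
φ = Σ Pearson residuals²/(n−p). Significance via parametric bootstrap:
B = 999 (tests use 99) pure-binomial resamples at the fitted means,
add-one p-value. Type-I error is within ±0.02 of 0.05 over 500 null
cohorts of 2,000 patients; power ≥ 0.8 against beta-binomial
heterogeneity at ρ = 0.05.

**Cross-chromosome ICC.** Per-embryo per-chromosome crossover counts are
z-standardized within chromosome (removing the length confound), then
ICC(1) from one-way random-effects ANOVA mean squares with embryo as the
grouping factor; percentile bootstrap CI over embryos. Cross-checked
against pingouin; recovers ρ ∈ {0, 0.1, 0.2} within ±0.02 at 10,000
embryos.

**Crossover context.** Hotspot occupancy counts events whose resolution
interval overlaps a merged hotspot interval by ≥1 bp (a midpoint rule is
available); replication timing is read from a bedGraph at the interval
midpoint; GC content is the G+C fraction of the midpoint ± 500 bp window
from an indexed FASTA.

## Selection-proxy model

Per-meiosis aneuploidy risk is logistic: logit p = β0 + β1·a + β2·a² +
βg·g for maternal age a and allele count g. Lifetime euploid output
W(g) = ∫ f(a)(1 − p_g(a)) da over the reproductive window [a0, a1]
(defaults 18–35 years), with f a normalized age weighting (uniform by
default; real age-specific fertility schedules decline with age, so a
tabulated weighting is accepted). Integration is trapezoid at 0.05-year
steps (error ≪1e−6 for logistic curves). The proxy s = 1 − W(1)/W(0)
contrasts heterozygote carriers with non-carriers (per-allele comparison;
additive effects make g=2 optional), and α ∈ (0,1] scales the proxy to
realized fitness: selection beats drift when α·s > 1/(2Ne), giving the
threshold α* = 1/(2·Ne·s). With constant risks the proxy has the closed
form 1 − (1−p1)/(1−p0), used as an exact check; with a rising age curve
s is increasing in the window's upper bound.

## Numerical and degenerate-input choices

* Ties in Viterbi break toward the lowest state index; calls are
  deterministic across runs.
* Zero-trial patients are dropped from the overdispersion fit; IRLS
  weights are floored at 1e−10.
* Empty chromosomes, <3 siblings for phasing, <3 embryos for a phenotype
  row, single-chromosome ICC, non-positive σ, and s ≤ 0 in α* all raise
  explicit errors rather than degrading silently.
* BED/bedGraph intervals are 0-based half-open; SNP positions 1-based.
  A crossover between flanking SNPs at 1-based L and R is written as BED
  [L−1, R).
* All randomness flows through a single seeded generator; fixed seeds
  give bit-identical cohorts.

## Problem sizes used by the checks

The end-to-end acceptance check simulates 100 families × 8 embryos on
2 chromosomes × 5,000 sites (σ = 0.1, π0 = 0.05, 25% aneuploidy across
eight modes, crossover–risk coupling 0.5); the calibration checks use
500 null cohorts (overdispersion) and 10,000 embryos × 5 chromosomes
(ICC). `scripts/acceptance.py` runs a 40-family cohort and 200 null
cohorts by default — sizes chosen so the whole script completes in a few
minutes on one CPU while leaving every rate estimable to ~1% — and scales
up via `--families` / `--null-datasets`.

## Known limitations

* No LRR (total intensity) channel: balanced abnormalities invisible to
  BAF alone (e.g. some tetraploidies) are out of reach; tetrasomy and
  higher are not modelled.
* Segmental aneuploidy and mosaic biopsies are not modelled; a mosaic
  trisomy will surface as a low-confidence or mitotic-like call.
* Phasing requires ≥3 informative siblings; families of 1–2 embryos can
  only be called with externally phased parents.
* The simulator's Poisson crossover process lacks interference and
  crossover assurance, so absolute crossover-count distributions differ
  from human meiosis in their tails; recovery rates quoted here are
  conditional on the simulator's own structure.
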