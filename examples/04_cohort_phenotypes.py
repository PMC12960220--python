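"""Cohort statistics: aneuploidy ratios, overdispersion, crossover ICC.

Three statistics summarize a cohort: the trisomy/monosomy and
maternal/paternal ratios of aneuploid chromosomes (with exact binomial
tests against 0.5), a parametric-bootstrap test of whether per-patient
aneuploidy incidence is overdispersed beyond its binomial expectation
after maternal-age adjustment, and the intraclass correlation of
crossover counts across chromosomes within an embryo.
"""

import numpy as np
from scipy.special import expit

from karyotrace import benchmark as bm
from karyotrace import phenotypes as ph

rng = np.random.default_rng(3)

# --- aneuploidy ratios from a pair of counts -------------------------------
tri = ph.binomial_ratio(580, 345)       # trisomies vs monosomies
origin = ph.binomial_ratio(840, 84)     # maternal vs paternal origin
print(f"trisomy fraction  {tri.fraction:.3f}  (p = {tri.p_value:.2e})")
print(f"maternal fraction {origin.fraction:.3f}  (p = {origin.p_value:.2e})")

# --- overdispersion of per-patient aneuploidy incidence --------------------
age = rng.uniform(25, 45, 2000)
n = rng.poisson(6, 2000)
p = expit(7.5 - 0.6 * age + 0.01 * age ** 2)
rho = 0.05                               # patient-specific heterogeneity
y = rng.binomial(n, rng.beta(p * 19, (1 - p) * 19))
res = ph.overdispersion_test(y.astype(float), n.astype(float), age, B=199, rng=rng)
print(f"dispersion phi = {res.phi:.3f}, bootstrap p = {res.p_value:.3f} "
      f"(B = {res.B})")

# --- cross-chromosome ICC of crossover counts ------------------------------
counts = bm.exchangeable_counts(5000, 5, rho=0.18, rng=rng)
icc = ph.crossover_icc(counts, n_boot=199, rng=rng)
print(f"crossover ICC = {icc.icc:.3f}  (95% CI {icc.ci_low:.3f}-{icc.ci_high:.3f})")

# phi > 1 with a small p-value says patients differ in risk beyond age;
# a positive ICC says crossover counts covary across chromosomes of one
# meiosis, which is what justifies using disomic chromosomes of
# aneuploid embryos as a within-embryo readout of crossover activity.
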