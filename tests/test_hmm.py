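"""HMM core: states, transitions, emissions, recursions, noise fitting."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from karyotrace import hmm
from karyotrace.datatypes import GeneticMap
from karyotrace.simulate import SimConfig, simulate_family

from conftest import make_panel, oracle_loglik


def random_instance(rng, n_sites):
    """A tiny random panel + BAF vector + map for oracle comparison."""
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), n_sites, replace=False))
    mat = rng.integers(0, 2, (2, n_sites))
    pat = rng.integers(0, 2, (2, n_sites))
    panel = make_panel("chr1", pos, mat, pat)
    gmap = GeneticMap.uniform({"chr1": 10_000_000}, cm_per_mb=rng.uniform(0.5, 3.0))
    baf = rng.uniform(0, 1, n_sites)
    if rng.random() < 0.3:
        baf[rng.integers(n_sites)] = np.nan
    return panel, gmap, baf


class TestStates:
    @pytest.mark.parametrize("hyp,n", [("disomy", 4), ("monosomy_m", 2),
                                       ("monosomy_p", 2), ("trisomy_m", 6),
                                       ("trisomy_p", 6), ("nullisomy", 1)])
    def test_state_counts(self, hyp, n):
        assert len(hmm.enumerate_states(hyp)) == n

    def test_trisomy_m_composition(self):
        for m, p in hmm.enumerate_states("trisomy_m"):
            assert len(m) == 2 and len(p) == 1

    def test_unknown_hypothesis(self):
        with pytest.raises(ValueError):
            hmm.enumerate_states("tetrasomy")


class TestTransitions:
    def test_haldane_closed_form(self):
        # 50 cM: r = (1 - e^{-1})/2
        assert hmm.haldane_r(50.0) == pytest.approx((1 - np.exp(-1)) / 2)
        assert hmm.haldane_r(50.0) == pytest.approx(0.3161, abs=1e-4)
        assert hmm.haldane_r(0.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            hmm.haldane_r(-1.0)

    @pytest.mark.parametrize("hyp", hmm.HYPOTHESES)
    def test_zero_distance_is_identity(self, hyp):
        states = hmm.enumerate_states(hyp)
        T = hmm.transition_matrix(states, 0.0)
        np.testing.assert_allclose(T, np.eye(len(states)), atol=1e-15)

    @pytest.mark.parametrize("hyp", hmm.HYPOTHESES)
    @pytest.mark.parametrize("d", [0.01, 0.5, 5.0, 50.0, 500.0])
    def test_rows_sum_to_one(self, hyp, d):
        T = hmm.transition_matrix(hmm.enumerate_states(hyp), d)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_exchangeable_prior_is_stationary(self):
        # prepending uninformative sites must not perturb the chain
        states = hmm.enumerate_states("trisomy_m")
        pi = np.exp(hmm.initial_log_distribution(states))
        T = hmm.transition_matrix(states, 7.3)
        np.testing.assert_allclose(pi @ T, pi, atol=1e-12)


class TestEmissions:
    def test_truncnorm_closed_form(self):
        # mu=0.5, sigma=0.1: density phi(0)/0.1 / Z with Z ~ 1
        params = hmm.EmissionParams(sigma=0.1, pi0=0.0)
        got = float(hmm.emission_logpdf(0.5, 0.5, params))
        assert got == pytest.approx(1.3836, abs=1e-3)
        # independent route: scipy truncnorm
        ref = truncnorm.logpdf(0.5, -5, 5, loc=0.5, scale=0.1)
        assert got == pytest.approx(float(ref), abs=1e-12)

    def test_pure_uniform_gives_zero(self):
        params = hmm.EmissionParams(sigma=0.1, pi0=1.0)
        for b, mu in [(0.0, 0.5), (0.37, 0.0), (1.0, 1.0)]:
            assert float(hmm.emission_logpdf(b, mu, params)) == pytest.approx(0.0)

    def test_missing_contributes_zero(self):
        params = hmm.EmissionParams(sigma=0.1, pi0=0.1)
        assert float(hmm.emission_logpdf(np.nan, 0.5, params)) == 0.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            hmm.EmissionParams(sigma=0.0)


class TestForward:
    def test_uniform_emissions_loglik_zero(self):
        # pi0 = 1: all emission densities are 1, so logL = 0 for every hypothesis
        rng = np.random.default_rng(0)
        panel, gmap, baf = random_instance(rng, 12)
        params = hmm.EmissionParams(sigma=0.1, pi0=1.0)
        for hyp in hmm.HYPOTHESES:
            ll = hmm.forward_loglik(baf, panel, gmap, "chr1", hyp, params)
            assert ll == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("hyp", hmm.HYPOTHESES)
    def test_matches_brute_force(self, hyp):
        rng = np.random.default_rng(42)
        params = hmm.EmissionParams(sigma=0.12, pi0=0.07)
        for _ in range(8):
            n = int(rng.integers(2, 7))
            panel, gmap, baf = random_instance(rng, n)
            cm = gmap.interpolate_cM("chr1", panel.pos)
            ref = oracle_loglik(baf, panel.mat_haps, panel.pat_haps, cm, hyp,
                                params.sigma, params.pi0)
            got = hmm.forward_loglik(baf, panel, gmap, "chr1", hyp, params)
            assert got == pytest.approx(ref, abs=1e-9)

    def test_missing_site_prepend_invariance(self):
        rng = np.random.default_rng(1)
        panel, gmap, baf = random_instance(rng, 10)
        params = hmm.EmissionParams(sigma=0.1, pi0=0.05)
        # same panel with an extra leading site whose BAF is missing
        pos2 = np.concatenate(([panel.pos[0] - 1000], panel.pos))
        mat2 = np.column_stack(([0, 1], panel.mat_haps))
        pat2 = np.column_stack(([1, 0], panel.pat_haps))
        panel2 = make_panel("chr1", pos2, mat2, pat2)
        baf2 = np.concatenate(([np.nan], baf))
        for hyp in hmm.HYPOTHESES:
            a = hmm.forward_loglik(baf, panel, gmap, "chr1", hyp, params)
            b = hmm.forward_loglik(baf2, panel2, gmap, "chr1", hyp, params)
            assert b == pytest.approx(a, abs=1e-9)

    def test_empty_chromosome_errors(self):
        rng = np.random.default_rng(2)
        panel, gmap, baf = random_instance(rng, 5)
        with pytest.raises(ValueError):
            hmm.forward_loglik(baf, panel, gmap, "chr9", "disomy",
                               hmm.EmissionParams())

    def test_no_underflow_on_long_chromosome(self):
        # 50,000 sites: log-space recursion must stay finite
        rng = np.random.default_rng(3)
        n = 50_000
        pos = np.sort(rng.choice(np.arange(1, 250_000_000), n, replace=False))
        panel = make_panel("chr1", pos, rng.integers(0, 2, (2, n)),
                           rng.integers(0, 2, (2, n)))
        gmap = GeneticMap.uniform({"chr1": 250_000_000})
        baf = rng.uniform(0, 1, n)
        ll = hmm.forward_loglik(baf, panel, gmap, "chr1", "disomy",
                                hmm.EmissionParams(sigma=0.05, pi0=0.0))
        assert np.isfinite(ll)


@pytest.fixture(scope="module")
def disomy_sim():
    cfg = SimConfig(n_sites=1200, n_chromosomes=1, n_embryos=1,
                    sigma=0.01, pi0=0.0)
    return simulate_family(cfg, 9)


class TestPosteriorsAndViterbi:
    def test_posteriors_sum_to_one(self, disomy_sim):
        fam = disomy_sim
        res = hmm.posterior_decode(fam.embryos[0].baf, fam.panel, fam.gmap,
                                   "chr1", "trisomy_m", hmm.EmissionParams(0.1, 0.05))
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_noise_free_marginal_tracks_truth(self, disomy_sim, noise_free_params):
        fam = disomy_sim
        truth = fam.truths[0].chroms["chr1"]
        res = hmm.posterior_decode(fam.embryos[0].baf, fam.panel, fam.gmap,
                                   "chr1", "disomy", noise_free_params)
        marg = res.single_copy_marginal("maternal")   # P(hap 0)
        pos = fam.panel.pos
        het = fam.panel.het_mask("maternal")
        # away from switch intervals the true haplotype is near-certain
        off_switch = np.ones(len(pos), bool)
        for x in truth.maternal_crossovers:
            off_switch &= np.abs(pos - x) > 2_000_000
        sel = het & off_switch
        true_path = truth.maternal_paths[0]
        p_true = np.where(true_path == 0, marg, 1 - marg)
        assert np.all(p_true[sel] > 0.999)

    def test_parent_swap_symmetry(self):
        rng = np.random.default_rng(5)
        panel, gmap, baf = random_instance(rng, 30)
        swapped = make_panel("chr1", panel.pos, panel.pat_haps, panel.mat_haps)
        params = hmm.EmissionParams(0.1, 0.05)
        ll_m = hmm.forward_loglik(baf, panel, gmap, "chr1", "trisomy_m", params)
        ll_p = hmm.forward_loglik(baf, swapped, gmap, "chr1", "trisomy_p", params)
        assert ll_m == pytest.approx(ll_p, abs=1e-10)
        rm = hmm.posterior_decode(baf, panel, gmap, "chr1", "disomy", params)
        rp = hmm.posterior_decode(baf, swapped, gmap, "chr1", "disomy", params)
        np.testing.assert_allclose(rm.single_copy_marginal("maternal"),
                                   rp.single_copy_marginal("paternal"), atol=1e-10)

    def test_viterbi_bounded_by_forward_and_deterministic(self, disomy_sim):
        fam = disomy_sim
        params = hmm.EmissionParams(0.1, 0.05)
        res = hmm.posterior_decode(fam.embryos[0].baf, fam.panel, fam.gmap,
                                   "chr1", "disomy", params)
        assert res.viterbi_loglik <= res.loglik + 1e-9
        again = hmm.viterbi_path(fam.embryos[0].baf, fam.panel, fam.gmap,
                                 "chr1", "disomy", params)
        np.testing.assert_array_equal(res.viterbi, again)

    def test_viterbi_switches_at_true_crossovers(self, noise_free_params):
        cfg = SimConfig(n_sites=1500, n_chromosomes=1, n_embryos=1,
                        sigma=0.01, pi0=0.0)
        fam = simulate_family(cfg, 21)
        truth = fam.truths[0].chroms["chr1"]
        res = hmm.posterior_decode(fam.embryos[0].baf, fam.panel, fam.gmap,
                                   "chr1", "disomy", noise_free_params)
        mat_path = np.array([res.states[s][0][0] for s in res.viterbi])
        switches = np.flatnonzero(np.diff(mat_path) != 0)
        assert len(switches) == len(truth.maternal_crossovers)
        pos = fam.panel.pos
        for s, x in zip(switches, np.sort(truth.maternal_crossovers)):
            assert pos[s] < x <= pos[s + 1]


class TestFitNoise:
    def test_recovers_generating_grid_point(self):
        cfg = SimConfig(n_sites=5000, n_chromosomes=1, n_embryos=1,
                        sigma=0.10, pi0=0.10)
        fam = simulate_family(cfg, 17)
        fitted = hmm.fit_noise(fam.embryos[0], fam.panel, fam.gmap)
        assert fitted.sigma == pytest.approx(0.10)
        assert fitted.pi0 == pytest.approx(0.10)
        assert min(hmm.SIGMA_GRID) <= fitted.sigma <= max(hmm.SIGMA_GRID)

    def test_attains_grid_maximum(self):
        cfg = SimConfig(n_sites=400, n_chromosomes=1, n_embryos=1)
        fam = simulate_family(cfg, 23)
        grid_s = (0.075, 0.1, 0.15)
        grid_p = (0.01, 0.05, 0.2)
        fitted = hmm.fit_noise(fam.embryos[0], fam.panel, fam.gmap, grid_s, grid_p)
        lls = {(s, p): hmm.forward_loglik(fam.embryos[0].baf, fam.panel, fam.gmap,
                                          "chr1", "disomy", hmm.EmissionParams(s, p))
               for s in grid_s for p in grid_p}
        assert (fitted.sigma, fitted.pi0) == max(lls, key=lls.get)

    def test_all_missing_rejected(self):
        cfg = SimConfig(n_sites=50, n_chromosomes=1, n_embryos=1)
        fam = simulate_family(cfg, 2)
        fam.embryos[0].baf[:] = np.nan
        with pytest.raises(ValueError):
            hmm.fit_noise(fam.embryos[0], fam.panel, fam.gmap)
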