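"""Phenotype statistics: counts, hotspots, context, overdispersion, ICC."""

import numpy as np
import pytest

from karyotrace import hmm, phenotypes as ph
from karyotrace.datatypes import CrossoverEvent, IntervalTrack, PloidyCall


def _ev(left, right, embryo="e1", parent="maternal", chrom="chr1"):
    return CrossoverEvent(embryo, parent, chrom, left, right, 0.99, 0.99)


class TestCrossoverCount:
    def test_simple_mean(self):
        events = []
        for eid, n in [("e1", 50), ("e2", 48), ("e3", 52)]:
            events += [_ev(1000 * i + 1, 1000 * i + 500, embryo=eid)
                       for i in range(n)]
        mean, counts = ph.crossover_count_phenotype(events, ["e1", "e2", "e3"],
                                                    "maternal")
        assert mean == pytest.approx(50.0)
        assert counts == {"e1": 50, "e2": 48, "e3": 52}

    def test_embryos_without_events_count_zero(self):
        mean, _ = ph.crossover_count_phenotype([_ev(1, 2)], ["e1", "e2", "e3"],
                                               "maternal")
        assert mean == pytest.approx(1 / 3)

    def test_fewer_than_three_embryos_rejected(self):
        with pytest.raises(ValueError):
            ph.crossover_count_phenotype([], ["e1", "e2"], "maternal")


class TestHotspotOccupancy:
    track = IntervalTrack({"chr1": (np.array([1000, 5000]),
                                    np.array([1100, 5200]), None)})

    def test_all_inside(self):
        events = [_ev(1001, 1050), _ev(5001, 5100)]
        assert ph.hotspot_occupancy(events, self.track) == 1.0

    def test_empty_track_or_events(self):
        empty = IntervalTrack({})
        assert ph.hotspot_occupancy([_ev(1001, 1050)], empty) == 0.0
        assert ph.hotspot_occupancy([], self.track) == 0.0

    def test_abutting_interval_not_counted(self):
        # event BED interval [1100, 1200) abuts hotspot [1000, 1100): no overlap
        assert ph.hotspot_occupancy([_ev(1101, 1200)], self.track) == 0.0
        # one bp of overlap counts: [1099, 1200)
        assert ph.hotspot_occupancy([_ev(1100, 1200)], self.track) == 1.0

    def test_invariant_under_hotspot_split(self):
        split = IntervalTrack({"chr1": (np.array([1000, 1050, 5000]),
                                        np.array([1050, 1100, 5200]), None)})
        events = [_ev(1001, 1050), _ev(5001, 5100), _ev(7000, 7100)]
        assert (ph.hotspot_occupancy(events, split)
                == ph.hotspot_occupancy(events, self.track))

    def test_midpoint_rule(self):
        # midpoint 1200 (1-based) -> 0-based 1199, outside hotspot [1000, 1100)
        ev = _ev(1000, 1400)
        assert ph.hotspot_occupancy([ev], self.track, rule="midpoint") == 0.0
        # midpoint 1050 -> 0-based 1049, inside
        ev2 = _ev(1000, 1100)
        assert ph.hotspot_occupancy([ev2], self.track, rule="midpoint") == 1.0


class TestCrossoverContext:
    def test_gc_extremes(self, tmp_path):
        from pyfaidx import Fasta
        fa_path = tmp_path / "ref.fa"
        fa_path.write_text(">chr1\n" + "GC" * 2000 + "AT" * 2000 + "\n")
        fa = Fasta(str(fa_path))
        _, gc = ph.crossover_context([_ev(1001, 2001)], None, fa)   # mid 1501, GC block
        assert gc == pytest.approx(1.0)
        _, at = ph.crossover_context([_ev(5001, 6001)], None, fa)   # AT block
        assert at == pytest.approx(0.0)

    def test_constant_timing_track(self):
        track = IntervalTrack({"chr1": (np.array([0]), np.array([10_000]),
                                        np.array([0.5]))})
        t, _ = ph.crossover_context([_ev(100, 200), _ev(5000, 6000)], track, None)
        assert t == pytest.approx(0.5)

    def test_uncovered_midpoints_skipped(self):
        track = IntervalTrack({"chr1": (np.array([0]), np.array([1000]),
                                        np.array([0.25]))})
        t, _ = ph.crossover_context([_ev(100, 200), _ev(5000, 6000)], track, None)
        assert t == pytest.approx(0.25)

    def test_midpoint_outside_contig_errors(self, tmp_path):
        from pyfaidx import Fasta
        fa_path = tmp_path / "ref.fa"
        fa_path.write_text(">chr1\n" + "ACGT" * 100 + "\n")
        fa = Fasta(str(fa_path))
        with pytest.raises(ValueError, match="outside contig"):
            ph.crossover_context([_ev(10_000, 10_100)], None, fa)


def _call(embryo, chrom, call, k, origin):
    return PloidyCall(embryo, chrom, {h: 1 / 6 for h in hmm.HYPOTHESES},
                      call, k, origin)


class TestAneuploidySummary:
    def test_counts_ratios_and_totals(self):
        calls = [
            _call("e1", "chr1", "trisomy_m", 3, "maternal"),
            _call("e1", "chr2", "disomy", 2, None),
            _call("e2", "chr1", "monosomy_m", 1, "maternal"),
            _call("e2", "chr2", "trisomy_p", 3, "paternal"),
            _call("e3", "chr1", "disomy", 2, None),
            _call("e3", "chr2", "disomy", 2, None),
        ]
        s = ph.aneuploidy_summary(calls)
        assert s.table["count"].sum() == 3
        assert s.trisomy_ratio.fraction == pytest.approx(2 / 3)
        assert s.maternal_ratio.fraction == pytest.approx(2 / 3)
        assert s.frac_embryos_aneuploid == pytest.approx(2 / 3)

    def test_excluded_embryos_dropped(self):
        calls = [_call("e1", "chr1", "trisomy_m", 3, "maternal"),
                 _call("e2", "chr1", "disomy", 2, None)]
        s = ph.aneuploidy_summary(calls, excluded_embryos={"e1"})
        assert s.table.empty
        assert np.isnan(s.trisomy_ratio.fraction)

    def test_zero_aneuploidies_na_ratios(self):
        calls = [_call("e1", "chr1", "disomy", 2, None)]
        s = ph.aneuploidy_summary(calls)
        assert s.table.empty
        assert np.isnan(s.trisomy_ratio.fraction)
        assert s.frac_embryos_aneuploid == 0.0

    def test_published_scale_ratios(self):
        # ratio arithmetic at cohort scale (counts as printed inputs)
        assert ph.binomial_ratio(84_044, 8_441).fraction == pytest.approx(0.909, abs=5e-4)
        assert ph.binomial_ratio(57_974, 34_511).fraction == pytest.approx(0.6268, abs=5e-5)
        assert ph.binomial_ratio(84_044, 8_441).p_value < 1e-100


class TestOverdispersion:
    def test_hand_computed_dispersion(self):
        # intercept-only fit of (1/2, 0/2, 2/2): p-hat = 0.5,
        # phi = (0 + 2 + 2) / (3 - 1) = 2.0
        y = np.array([1.0, 0.0, 2.0])
        n = np.array([2.0, 2.0, 2.0])
        X = np.ones((3, 1))
        beta = ph._irls_binomial(y, n, X)
        assert float(beta[0]) == pytest.approx(0.0, abs=1e-8)   # logit(0.5)
        assert ph.pearson_dispersion(y, n, X, beta) == pytest.approx(2.0)

    def test_irls_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        n = rng.integers(1, 10, 300).astype(float)
        age = rng.uniform(25, 45, 300)
        p = 1 / (1 + np.exp(-(-8 + 0.2 * age)))
        y = rng.binomial(n.astype(int), p).astype(float)
        X = np.column_stack([np.ones(300), age, age ** 2])
        beta = ph._irls_binomial(y, n, X)
        ref = sm.GLM(np.column_stack([y, n - y]), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, rtol=1e-6)
        phi = ph.pearson_dispersion(y, n, X, beta)
        assert phi == pytest.approx(ref.pearson_chi2 / ref.df_resid, rel=1e-6)

    def test_detects_overdispersion(self):
        rng = np.random.default_rng(11)
        n = rng.poisson(6, 1500)
        age = rng.uniform(25, 45, 1500)
        p = 1 / (1 + np.exp(-(7.5 - 0.6 * age + 0.01 * age ** 2)))
        rho = 0.15
        a, b = p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho
        y = rng.binomial(n, rng.beta(a, b))
        res = ph.overdispersion_test(y, n, age, B=99, rng=7)
        assert res.phi > 1.1
        assert res.p_value <= 0.05

    def test_null_not_rejected_typically(self):
        rng = np.random.default_rng(13)
        n = rng.poisson(6, 1500)
        age = rng.uniform(25, 45, 1500)
        p = 1 / (1 + np.exp(-(7.5 - 0.6 * age + 0.01 * age ** 2)))
        y = rng.binomial(n, p)
        res = ph.overdispersion_test(y, n, age, B=99, rng=7)
        assert res.p_value > 0.05
        assert 0.8 < res.phi < 1.2

    def test_b_floor_and_zero_trials(self):
        with pytest.raises(ValueError):
            ph.overdispersion_test(np.array([1.0]), np.array([2.0]), None, B=10)
        # zero-trial patients are dropped, not propagated
        y = np.array([1.0, 0.0, 2.0, 0.0])
        n = np.array([2.0, 2.0, 2.0, 0.0])
        res = ph.overdispersion_test(y, n, None, B=99, rng=1)
        assert res.phi == pytest.approx(2.0)


class TestICC:
    def test_identical_within_embryo_gives_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=500)
        counts = np.column_stack([col, col, col])
        res = ph.crossover_icc(counts, n_boot=19, rng=1)
        assert res.icc == pytest.approx(1.0, abs=1e-10)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(5)
        counts = rng.normal(size=(5000, 4))
        res = ph.crossover_icc(counts, n_boot=19, rng=2)
        assert res.icc == pytest.approx(0.0, abs=0.03)

    def test_exchangeable_recovery(self):
        rng = np.random.default_rng(8)
        rho = 0.15
        u = rng.normal(size=(8000, 1))
        counts = np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.normal(size=(8000, 5))
        res = ph.crossover_icc(counts, n_boot=19, rng=3)
        assert res.icc == pytest.approx(rho, abs=0.02)
        assert -1.0 <= res.icc <= 1.0

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(21)
        counts = rng.normal(size=(40, 3)) + rng.normal(size=(40, 1))
        z = (counts - counts.mean(0)) / counts.std(0, ddof=1)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(40), 3),
            "raters": np.tile(np.arange(3), 40),
            "scores": z.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        res = ph.crossover_icc(counts, n_boot=19, rng=4)
        assert res.icc == pytest.approx(icc1, abs=1e-10)

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            ph.crossover_icc(np.ones((10, 1)))
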