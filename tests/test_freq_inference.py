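"""Likelihood, ML fitting, closed forms, support limits and LRTs."""

import math

import numpy as np
import pytest

from acedup.allele_model import PhenotypeClass, canonical_model
from acedup.freq_inference import (
    CountTable,
    allele_counting_null,
    fit_ml,
    log_likelihood,
    lrt,
    saturated_closed_form,
    support_limits,
)
from acedup.pipeline import pool_d1

P = PhenotypeClass.parse


class TestLogLikelihood:
    def test_saturated_value_yopougon_2015(self, yop15_3, model_a):
        # counts (1, 13, 45) at their own relative frequencies: sum n ln(n/N)
        # requires class freqs realisable by the model; use the exact MLE
        f = saturated_closed_form(yop15_3, model_a, False)
        L = log_likelihood(yop15_3, f, model_a, False)
        assert L == pytest.approx(-35.93, abs=5e-3)
        assert L == pytest.approx(yop15_3.saturated_logL(), abs=1e-9)

    def test_zero_frequency_with_observations_is_minus_inf(self, yop15_3, model_a):
        L = log_likelihood(yop15_3, {"R": 0.0, "S": 0.6, "D": 0.4}, model_a, False)
        assert L == -math.inf

    def test_all_mass_in_one_class_gives_zero(self, model_a):
        t = CountTable("x", 0, {P("[RR]"): 0, P("[SS]"): 30, P("[RS]"): 0})
        assert log_likelihood(t, {"R": 0.0, "S": 1.0, "D": 0.0}, model_a, False) == 0.0

    def test_partition_mismatch_rejected(self, yop15_3, model_a):
        with pytest.raises(ValueError):
            log_likelihood(yop15_3, {"R": 0.3, "S": 0.4, "D": 0.3}, model_a, True)


class TestSaturatedClosedForm:
    def test_model_a_yopougon_2015(self, yop15_3, model_a):
        f = saturated_closed_form(yop15_3, model_a, False)
        assert f["R"] == pytest.approx(math.sqrt(1 / 59), abs=1e-12)
        assert f["S"] == pytest.approx(math.sqrt(13 / 59), abs=1e-12)
        assert f["D"] == pytest.approx(0.4004, abs=1e-4)

    def test_model_c_yopougon_2015(self, yop15_5, model_c):
        f = saturated_closed_form(yop15_5, model_c, True)
        assert f["S_D1"] == pytest.approx(0.0, abs=1e-12)
        assert f["D1"] == pytest.approx(1 - math.sqrt(1 - 25 / 59), abs=1e-9)
        assert f["Di"] == pytest.approx(0.1595, abs=1e-4)

    def test_non_canonical_model_not_invertible(self, yop15_5, model_b):
        assert saturated_closed_form(yop15_5, model_b, True) is None


class TestFitML:
    def test_matches_closed_form_on_all_saturated_samples(
        self, samples3, samples5, model_a, model_c
    ):
        for tables, model, d1 in ((samples3, model_a, False), (samples5, model_c, True)):
            for t in tables:
                exact = saturated_closed_form(t, model, d1)
                if exact is None:
                    continue
                fit = fit_ml(t, model, d1, seed=0, n_restarts=1)
                for name, f in exact.items():
                    assert fit.freqs[name] == pytest.approx(f, abs=1e-4), (
                        t.population, t.year, name,
                    )

    def test_never_exceeds_saturated_bound(self, samples3, samples5, model_a, model_b, model_c):
        for tables, model, d1 in (
            (samples3, model_a, False),
            (samples5, model_b, True),
            (samples5, model_c, True),
        ):
            for t in tables:
                fit = fit_ml(t, model, d1, seed=0, n_restarts=1)
                assert fit.logL <= t.saturated_logL() + 1e-6

    def test_model_b_yopougon_2015_estimates(self, yop15_5, model_b):
        fit = fit_ml(yop15_5, model_b, True, seed=0, n_restarts=2)
        assert round(fit.freqs["R"], 2) == 0.25
        assert round(fit.freqs["S"], 2) == 0.51
        assert round(fit.freqs["S_D1"], 2) == 0.00
        assert round(fit.freqs["D1"], 2) == 0.24

    def test_boundary_pure_s_sample(self, model_a):
        t = CountTable("x", 0, {P("[RR]"): 0, P("[SS]"): 40, P("[RS]"): 0})
        fit = fit_ml(t, model_a, False, seed=0, n_restarts=1)
        assert fit.freqs["S"] == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_given_seed(self, yop15_5, model_b):
        f1 = fit_ml(yop15_5, model_b, True, seed=7, n_restarts=1)
        f2 = fit_ml(yop15_5, model_b, True, seed=7, n_restarts=1)
        assert f1.freqs == f2.freqs and f1.logL == f2.logL

    def test_needs_at_least_two_alleles(self, yop15_3):
        with pytest.raises(ValueError):
            fit_ml(yop15_3, canonical_model("A")[:1], False)

    def test_parameter_recovery_at_large_n(self, model_c):
        # 20 seeded replicates at N = 10,000: every allele with true
        # frequency >= 0.05 recovered within +/- 0.02
        from acedup.synthetic_data import simulate_phenotype_counts

        true = {"R": 0.13, "S": 0.45, "S_D1": 0.05, "D1": 0.22, "Di": 0.15}
        for seed in range(20):
            table, _ = simulate_phenotype_counts(true, model_c, True, 10_000, seed)
            fit = fit_ml(table, model_c, True, seed=seed, n_restarts=1)
            for name, f_true in true.items():
                if f_true >= 0.05:
                    assert abs(fit.freqs[name] - f_true) < 0.02, (seed, name)


class TestSupportLimits:
    def test_contains_point_estimate_and_matches_printed_limits(self, yop15_3, model_a):
        fit = fit_ml(yop15_3, model_a, False, seed=0, n_restarts=1)
        sl = support_limits(yop15_3, model_a, fit)
        for name, (lo, hi) in sl.items():
            assert lo <= fit.freqs[name] <= hi
        # the D allele interval brackets the estimate the way the printed
        # [0.23 : 0.55] interval does
        lo, hi = sl["D"]
        assert lo == pytest.approx(0.23, abs=0.015)
        assert hi == pytest.approx(0.55, abs=0.015)
        assert lo < 0.40 < hi

    def test_boundary_frequency_gets_zero_lower_limit(self, yop12_3, model_a):
        fit = fit_ml(yop12_3, model_a, False, seed=0, n_restarts=1)
        assert fit.freqs["R"] == pytest.approx(0.0, abs=1e-6)
        sl = support_limits(yop12_3, model_a, fit)
        assert sl["R"][0] == 0.0


class TestLRT:
    def test_yopougon_2015_model_a_vs_two_allele_null(self, yop15_3, model_a):
        fit = fit_ml(yop15_3, model_a, False, seed=0, n_restarts=1)
        res = lrt(allele_counting_null(yop15_3), fit)
        assert round(res.statistic, 2) == 24.42
        assert res.p_value == pytest.approx(7.73e-7, rel=0.01)

    def test_yopougon_2012_non_significant(self, yop12_3, model_a):
        fit = fit_ml(yop12_3, model_a, False, seed=0, n_restarts=1)
        res = lrt(allele_counting_null(yop12_3), fit)
        assert round(res.statistic, 2) == 2.38
        assert res.p_value > 0.05

    def test_identical_models_give_zero(self, yop15_3, model_a):
        fit = fit_ml(yop15_3, model_a, False, seed=0, n_restarts=1)
        res = lrt(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_models_rejected(self, yop15_3, yop15_5, model_a, model_b):
        fa = fit_ml(yop15_3, model_a, False, seed=0, n_restarts=1)
        fb = fit_ml(yop15_5, model_b, True, seed=0, n_restarts=1)
        with pytest.raises(ValueError):
            lrt(fa, fb)  # D is not in model B: not nested

    def test_partition_mismatch_rejected(self, yop15_3, yop15_5, model_b, model_c):
        # B is nested in C, but fits on different phenotype partitions
        # must not be compared
        fb = fit_ml(yop15_5, model_b, True, seed=0, n_restarts=1)
        fb3 = allele_counting_null(yop15_3)
        fc = fit_ml(yop15_5, model_c, True, seed=0, n_restarts=1)
        assert lrt(fb, fc).statistic == pytest.approx(4.61, abs=0.01)
        with pytest.raises(ValueError):
            lrt(fb3, fc)

    def test_invariant_to_allele_relabeling(self, yop15_3):
        from acedup.allele_model import AlleleSpec

        base = canonical_model("A")
        renamed = [AlleleSpec({"R": "R", "S": "S", "D": "Dup"}[a.name], a.copies, a.amplicon_count)
                   for a in base]
        f1 = fit_ml(yop15_3, base, False, seed=0, n_restarts=1)
        f2 = fit_ml(yop15_3, renamed, False, seed=0, n_restarts=1)
        null = allele_counting_null(yop15_3)
        s1 = lrt(null, f1).statistic
        s2 = lrt(null, f2).statistic
        assert s1 == pytest.approx(s2, abs=1e-6)


class TestCountTable:
    def test_n_is_count_sum(self, samples5):
        assert sum(t.N for t in samples5) == 305

    def test_bad_partition_rejected(self):
        with pytest.raises(ValueError):
            CountTable("x", 0, {P("[RR]"): 1, P("[SS]"): 2})

    def test_csv_round_trip(self, yop15_5):
        df = yop15_5.to_frame()
        back, = CountTable.from_frame(df)
        assert back.counts == yop15_5.counts
        assert back.d1_test is True

    def test_pooling_collapses_d1_split(self, yop15_5):
        t3 = pool_d1(yop15_5)
        assert t3.counts[P("[RS]")] == 45
        assert t3.counts[P("[SS]")] == 13
        assert t3.N == yop15_5.N
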