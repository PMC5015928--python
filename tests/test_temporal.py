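import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temposel.simulate import SamplingSchedule
from temposel.temporal import (TemporalFrequencySeries, build_frequency_series,
                               delta_f, delta_f_many, fst_many, logistic_beta,
                               neutral_thresholds, temporal_fst)

from conftest import genotype_matrix

GENS = (0, 15, 25, 35, 45)


def series(freqs, generations=GENS, n=None):
    return TemporalFrequencySeries("locus", tuple(generations),
                                   np.asarray(freqs, dtype=float),
                                   None if n is None else np.asarray(n))


class TestBuildSeries:
    def _panel_matrix(self):
        # 10 lines per cohort, one population; marker 0 has 6 of 10 lines
        # carrying allele 1 in the first cohort
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 2, size=(50, 8)).astype(np.int8)
        calls[:10, 0] = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0]
        cohorts = sum([[c] * 10 for c in
                       ("pre1970s", "1970s", "1980s", "1990s", "2000s")], [])
        return genotype_matrix(calls, panel_extra={
            "population": ["MG0-I"] * 50, "cohort": cohorts})

    def test_frequency_counting(self):
        g = self._panel_matrix()
        out = build_frequency_series(g, "MG0-I", (0.0, 1.0))
        first = next(s for s in out if s.locus == "m1_1")
        assert first.freqs[0] == pytest.approx(0.6)
        assert first.sample_sizes[0] == 10

    def test_initial_frequency_filter(self):
        g = self._panel_matrix()
        narrow = build_frequency_series(g, "MG0-I", (0.5, 0.6))
        for s in narrow:
            assert 0.5 <= s.freqs[0] <= 0.6
        scan = build_frequency_series(g, "MG0-I", (0.0, 0.95),
                                      strict_upper=True)
        for s in scan:
            assert s.freqs[0] < 0.95

    def test_empty_cohort_names_cohort(self):
        calls = np.zeros((4, 5), dtype=np.int8)
        g = genotype_matrix(calls, panel_extra={
            "population": ["MG0-I"] * 4,
            "cohort": ["pre1970s", "1970s", "1980s", "1990s"]})
        with pytest.raises(ValueError, match="2000s"):
            build_frequency_series(g, "MG0-I")


class TestDeltaF:
    def test_constant_series_zero(self):
        assert delta_f(series([0.5] * 5)) == 0.0

    def test_three_point_closed_form(self):
        # OLS slope of (0.5, 0.65, 0.75) on (0, 15, 25) is exactly 0.01
        assert delta_f(series([0.5, 0.65, 0.75], (0, 15, 25))) == \
            pytest.approx(0.01, abs=1e-12)

    def test_truncation_at_first_fixed_timepoint(self):
        # 0.98 > 0.95 at generation 15: keep (0.5, 0.98), drop the rest
        s = series([0.5, 0.98, 0.99, 1.0], (0, 15, 25, 35))
        assert delta_f(s) == pytest.approx(0.48 / 15)

    def test_single_usable_timepoint_flagged_zero(self):
        slopes, n_used = delta_f_many(np.array([[0.97, 1.0, 1.0]]),
                                      (0, 10, 20))
        assert slopes[0] == 0.0
        assert n_used[0] == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_polarity_antisymmetry(self, seed):
        f = np.random.default_rng(seed).uniform(0, 1, size=(3, 5))
        a, _ = delta_f_many(f, GENS)
        b, _ = delta_f_many(1 - f, GENS)
        np.testing.assert_allclose(a, -b, atol=1e-12)


class TestLogisticBeta:
    def test_constant_half_zero_slope(self):
        res = logistic_beta(series([0.5] * 5))
        assert res.beta == pytest.approx(0.0, abs=1e-8)

    def test_recovers_generating_slope(self):
        t = np.array(GENS, dtype=float)
        p = 1 / (1 + np.exp(-(-1 + 0.1 * t)))
        res = logistic_beta(series(p))
        assert res.beta == pytest.approx(0.1, abs=1e-3)
        assert res.converged

    def test_all_fixed_series_is_separated_sentinel(self):
        res = logistic_beta(series([1.0] * 5))
        assert res.separated
        assert res.beta == np.inf
        res0 = logistic_beta(series([0.0] * 5))
        assert res0.beta == -np.inf

    def test_weighted_uses_sample_sizes(self):
        s = series([0.5, 0.6, 0.7, 0.8, 0.85], n=[31, 28, 59, 59, 22])
        wtd = logistic_beta(s, weighted=True)
        unw = logistic_beta(s, weighted=False)
        assert wtd.weighted and not unw.weighted
        assert wtd.beta != unw.beta

    def test_matches_statsmodels_on_interior_series(self, rng):
        import statsmodels.api as sm

        x = np.column_stack([np.ones(5), np.array(GENS, dtype=float)])
        for _ in range(5):
            y = rng.uniform(0.05, 0.95, size=5)
            ours = logistic_beta(series(y)).beta
            ref = sm.GLM(y, x, family=sm.families.Binomial()).fit().params[1]
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_matches_r_glm_on_absorbed_series(self, tmp_path):
        cases = np.array([
            [0.2, 0.1, 0.0, 0.0, 0.0],       # absorbed at zero
            [0.2, 0.6, 0.9, 1.0, 1.0],       # absorbed at one
            [0.8, 0.95, 1.0, 1.0, 1.0],
            [0.5, 0.65, 0.7, 0.8, 0.85],     # interior
        ])
        np.savetxt(tmp_path / "y.tsv", cases, delimiter="\t")
        script = (
            f'y <- as.matrix(read.table("{tmp_path}/y.tsv"))\n'
            "x <- c(0,15,25,35,45)\n"
            "b <- apply(y, 1, function(r) suppressWarnings("
            "coef(glm(r~x, family=binomial))[2]))\n"
            'cat(paste(b, collapse="\\n"))\n')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_betas = np.array([float(v) for v in out.stdout.split()])
        ours = np.array([logistic_beta(series(c)).beta for c in cases])
        np.testing.assert_allclose(ours, r_betas, atol=1e-6)


class TestTemporalFst:
    def test_no_differentiation(self):
        assert temporal_fst(series([0.5, 0.6, 0.5, 0.55, 0.5])) == \
            pytest.approx(0.0)

    def test_half_to_fixed_exact_value(self):
        # J_w = 0.75, J_b = 0.625 -> fst = 1/3 (endpoints 0.5 and 1.0)
        s = series([0.5, 0.6, 0.7, 0.9, 1.0])
        assert temporal_fst(s) == pytest.approx(1 / 3, abs=1e-6)

    def test_mirror_symmetry(self):
        s = series([0.5, 0.4, 0.3, 0.1, 0.0])
        assert temporal_fst(s) == pytest.approx(1 / 3, abs=1e-6)

    def test_both_ends_fixed_same_allele_zero(self):
        fst, _ = fst_many(np.array([[1.0, 1.0, 1.0]]))
        assert fst[0] == 0.0

    def test_polarity_invariance(self, rng):
        f = rng.uniform(0, 1, size=(4, 5))
        a, _ = fst_many(f)
        b, _ = fst_many(1 - f)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestNeutralThresholds:
    def test_tail_self_consistency(self):
        from temposel.simulate import (observe_frequencies,
                                       wright_fisher_frequencies)
        nt = neutral_thresholds(200, [0.55], tail=0.05, n_sim=20000, seed=1)
        # fresh neutral replicates exceed the threshold ~5% of the time
        gens = np.array(GENS)
        pop = wright_fisher_frequencies(200, 0.0, 0.55, 45, reps=20000,
                                        seed=99)[:, gens]
        slopes, _ = delta_f_many(pop, gens)
        rate = np.mean(np.abs(slopes) > nt.threshold)
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_monotone_in_ne(self):
        lo = neutral_thresholds(100, [0.55], n_sim=10000, seed=2).threshold
        hi = neutral_thresholds(400, [0.55], n_sim=10000, seed=2).threshold
        assert hi < lo

    def test_order_of_magnitude_at_study_scale(self):
        # with the study schedule and shallow depths, thresholds land in
        # the low-0.01s per generation for Ne between 100 and 300
        sched = SamplingSchedule(sample_sizes=(31, 28, 59, 59, 22))
        for ne in (115, 200, 273):
            thr = neutral_thresholds(ne, [0.55, 0.7, 0.85], sched,
                                     n_sim=8000, seed=3).threshold
            assert 0.008 < thr < 0.025
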