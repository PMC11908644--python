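import math

import numpy as np
import pytest

import panselect as ps
from panselect.mixture import (
    CONSERVED,
    DIVERGENT,
    NEUTRAL,
    ClassifiedBin,
    _bh_reject,
)


def simulate_scores(
    n: int,
    seed: int,
    pi: float = 0.5,
    mu: float = 0.05,
    sigma: float = 0.02,
    mu_log: float = 0.0,
    sigma_log: float = 0.5,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    from_gauss = rng.random(n) < pi
    return np.where(
        from_gauss,
        rng.normal(mu, sigma, n),
        rng.lognormal(mu_log, sigma_log, n),
    )


def as_bin_scores(values) -> list[ps.BinScore]:
    return [
        ps.BinScore(i, i * 10, (i + 1) * 10, math.exp(-v), float(v), 1)
        for i, v in enumerate(values)
    ]


class TestGaussianCore:
    def test_recovers_clean_gaussian(self):
        rng = np.random.default_rng(0)
        mu, sigma = ps.fit_gaussian_core(rng.normal(0.05, 0.02, 10_000))
        assert mu == pytest.approx(0.05, abs=0.005)
        assert sigma == pytest.approx(0.02, abs=0.005)

    def test_left_anchored_fit_ignores_heavy_tail(self):
        x = simulate_scores(10_000, seed=1, pi=0.9)
        mu, sigma = ps.fit_gaussian_core(x)
        assert mu == pytest.approx(0.05, abs=0.01)

    def test_degenerate_scores_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mu, sigma = ps.fit_gaussian_core([0.1] * 100)
        assert mu == 0.1
        assert 0 < sigma < 1e-12

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="noisy"):
            ps.fit_gaussian_core(np.linspace(0.0, 1.0, 10))


class TestLognormalTail:
    def test_recovers_pure_tail(self):
        rng = np.random.default_rng(2)
        tail = rng.lognormal(0.0, 0.5, 2000)
        mu_l, sigma_l = ps.fit_lognormal_tail(tail, (0.05, 0.02))
        assert mu_l == pytest.approx(0.0, abs=0.05)
        assert sigma_l == pytest.approx(0.5, abs=0.05)

    def test_no_scores_above_threshold_is_tail_free(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.05, 0.02, 1000)
        with pytest.warns(UserWarning, match="tail-free"):
            result = ps.fit_lognormal_tail(x, (0.05, 10.0))
        assert result is None

    def test_no_positive_scores_is_tail_free(self):
        with pytest.warns(UserWarning, match="tail-free"):
            assert ps.fit_lognormal_tail([0.0] * 50, (0.0, 1e-16)) is None

    def test_tiny_tail_falls_back_to_all_positive(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.lognormal(0.0, 0.5, 500), [50.0] * 5]
        )
        with pytest.warns(UserWarning, match="all positive"):
            mu_l, sigma_l = ps.fit_lognormal_tail(x, (40.0, 1.0))
        assert mu_l == pytest.approx(0.0, abs=0.1)


class TestScoreMixtureFit:
    def test_default_combination_is_equal_weight(self):
        res = ps.ScoreMixture(simulate_scores(5000, seed=5)).fit()
        assert res.pi == 0.5
        assert not res.tail_free

    def test_parameter_recovery_across_seeds(self):
        for seed in range(5):
            res = ps.ScoreMixture(simulate_scores(10_000, seed=seed)).fit()
            assert res.mu == pytest.approx(0.05, abs=0.005)
            assert res.sigma == pytest.approx(0.02, abs=0.005)
            assert res.mu_log == pytest.approx(0.0, abs=0.05)
            assert res.sigma_log == pytest.approx(0.5, abs=0.05)

    def test_em_recovers_mixing_weight(self):
        x = simulate_scores(10_000, seed=6, pi=0.8)
        res = ps.ScoreMixture(x).fit(estimate_weight=True)
        assert res.pi == pytest.approx(0.8, abs=0.03)
        assert res.em_iterations > 0

    def test_tail_free_model_has_pi_one(self):
        with pytest.warns(UserWarning):
            res = ps.ScoreMixture([0.0] * 100).fit()
        assert res.tail_free
        assert res.pi == 1.0

    def test_summary_lists_parameters(self):
        res = ps.ScoreMixture(simulate_scores(2000, seed=7)).fit()
        text = res.summary()
        for token in ("Gaussian mu", "log-normal", "pi"):
            assert token in text


@pytest.fixture(scope="module")
def results():
    return ps.ScoreMixture(simulate_scores(10_000, seed=8)).fit()


class TestMixtureDistribution:
    def test_cdf_monotone_and_normalised(self, results):
        grid = np.linspace(-1.0, 50.0, 2001)
        cdf = results.cdf(grid)
        assert np.all(np.diff(cdf) >= 0)
        assert results.cdf(-100.0) == pytest.approx(0.0, abs=1e-12)
        assert results.cdf(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_pdf_integrates_to_one(self, results):
        grid = np.linspace(-0.5, 60.0, 200_001)
        mass = np.trapezoid(results.pdf(grid), grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_tails_sum_to_one(self, results):
        x = np.array([0.0, 0.05, 0.5, 2.0])
        p_cons, p_div = results.p_values(x)
        assert np.allclose(p_cons + p_div, 1.0)

    def test_simulation_matches_cdf(self, results):
        draws = results.simulate(20_000, seed=9)
        u = results.cdf(draws)
        # probability integral transform: u should be uniform
        assert abs(np.mean(u) - 0.5) < 0.01
        assert abs(np.mean(u < 0.25) - 0.25) < 0.02


class TestClassification:
    def test_median_score_is_neutral(self, results):
        median = float(
            np.median(results.simulate(100_001, seed=11))
        )
        [cls] = results.classify(as_bin_scores([median]), alpha=0.05)
        assert cls.label == NEUTRAL

    def test_zero_score_is_conserved(self, results):
        [cls] = results.classify(as_bin_scores([0.0]), alpha=0.05)
        assert cls.label == CONSERVED
        assert cls.p_value <= 0.05

    def test_extreme_score_is_divergent(self, results):
        [cls] = results.classify(as_bin_scores([30.0]), alpha=0.05)
        assert cls.label == DIVERGENT

    def test_annotates_bin_scores_in_place(self, results):
        scores = as_bin_scores([0.05, 3.0])
        results.classify(scores, alpha=0.05)
        for s in scores:
            assert s.p_conserved is not None
            assert s.p_divergent is not None

    def test_null_calibration(self, results):
        draws = results.simulate(10_000, seed=12)
        classified = results.classify(as_bin_scores(draws), alpha=0.05)
        se3 = 3.0 * math.sqrt(0.05 * 0.95 / 10_000)
        for label in (CONSERVED, DIVERGENT):
            rate = sum(c.label == label for c in classified) / 10_000
            assert abs(rate - 0.05) < se3

    def test_increasing_score_never_moves_toward_conserved(self, results):
        grid = np.linspace(0.0, 20.0, 400)
        rank = {CONSERVED: 0, NEUTRAL: 1, DIVERGENT: 2}
        labels = [
            rank[c.label]
            for c in results.classify(as_bin_scores(grid), alpha=0.05)
        ]
        assert labels == sorted(labels)

    def test_gaussian_null_option(self, results):
        scores = as_bin_scores([0.0])
        [mix] = results.classify(scores, alpha=0.05, null="mixture")
        [gauss] = results.classify(scores, alpha=0.05, null="gaussian")
        assert gauss.label == CONSERVED
        assert gauss.p_value >= mix.p_value

    def test_fdr_is_more_conservative(self, results):
        draws = results.simulate(2000, seed=13)
        plain = results.classify(as_bin_scores(draws), alpha=0.05)
        corrected = results.classify(
            as_bin_scores(draws), alpha=0.05, fdr=True
        )
        n_plain = sum(c.label != NEUTRAL for c in plain)
        n_fdr = sum(c.label != NEUTRAL for c in corrected)
        assert n_fdr <= n_plain

    def test_invalid_alpha_rejected(self, results):
        with pytest.raises(ValueError):
            results.classify(as_bin_scores([0.1]), alpha=1.5)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(14)
        p = rng.random(200) ** 2
        expected = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(_bh_reject(p, 0.05), expected)


class TestMergeRegions:
    @staticmethod
    def _bins(n, width=10):
        return [
            ps.Bin(i, (i * width, (i + 1) * width), None, None, {})
            for i in range(n)
        ]

    def test_run_length_merge(self):
        labels = [CONSERVED, CONSERVED, NEUTRAL,
                  DIVERGENT, DIVERGENT, DIVERGENT]
        classified = [
            ClassifiedBin(i, label, 0.01 * (i + 1))
            for i, label in enumerate(labels)
        ]
        regions = ps.merge_regions(classified, self._bins(6))
        assert [(r.start, r.end, r.label, r.n_bins) for r in regions] == [
            (0, 20, CONSERVED, 2),
            (30, 60, DIVERGENT, 3),
        ]
        assert regions[0].min_p == pytest.approx(0.01)
        assert regions[1].min_p == pytest.approx(0.04)

    def test_all_neutral_is_empty(self):
        classified = [ClassifiedBin(i, NEUTRAL, 0.5) for i in range(4)]
        assert ps.merge_regions(classified, self._bins(4)) == []

    def test_alternating_classes_do_not_merge(self):
        labels = [CONSERVED, DIVERGENT, CONSERVED, DIVERGENT]
        classified = [
            ClassifiedBin(i, label, 0.01) for i, label in enumerate(labels)
        ]
        regions = ps.merge_regions(classified, self._bins(4))
        assert len(regions) == 4
        assert all(r.n_bins == 1 for r in regions)
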