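"""BCa intervals, permutation tests, HN trend test, classification."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from barotrend.errors import DegenerateInputError, ParameterError
from barotrend.inference import (
    TREND_SCORES, HNResult, bca_interval, classify_trends, hn_trend_test,
    permutation_test_corr, strength_band,
)


class TestBca:
    def test_reduces_to_percentile_when_unbiased_symmetric(self):
        # symmetric bootstrap values centred on theta_hat, constant jackknife
        # skewness -> z0 = 0 and a = 0
        boot = np.concatenate([-np.linspace(0.1, 1, 500), np.linspace(0.1, 1, 500)])
        jack = np.array([-1.0, 0.0, 1.0])  # skewness exactly zero
        res = bca_interval(0.0, boot, jack, level=0.95)
        assert res.z0 == pytest.approx(0.0, abs=1e-12)
        assert res.a == pytest.approx(0.0, abs=1e-12)
        assert res.lower == pytest.approx(np.quantile(boot, 0.025), abs=1e-9)
        assert res.upper == pytest.approx(np.quantile(boot, 0.975), abs=1e-9)

    def test_constant_bootstrap_rejected(self):
        with pytest.raises(DegenerateInputError):
            bca_interval(0.5, np.full(500, 0.5), np.arange(5.0))

    def test_matches_scipy_reference_on_sample_mean(self):
        """Cross-implementation check against scipy.stats.bootstrap (BCa)."""
        from scipy.stats import bootstrap as scipy_bootstrap

        rng = np.random.default_rng(8)
        data = 0.5 + 0.05 * rng.standard_normal(20)
        B = 4000
        # our interval from explicit bootstrap + jackknife of the mean
        boots = np.array(
            [data[rng.integers(20, size=20)].mean() for _ in range(B)]
        )
        jack = np.array([np.delete(data, i).mean() for i in range(20)])
        ours = bca_interval(data.mean(), boots, jack, level=0.95)
        ref = scipy_bootstrap(
            (data,), np.mean, n_resamples=B, confidence_level=0.95,
            method="BCa", random_state=np.random.default_rng(21),
        ).confidence_interval
        assert ours.lower == pytest.approx(ref.low, abs=0.005)
        assert ours.upper == pytest.approx(ref.high, abs=0.005)

    def test_one_sided_pileup_is_flagged(self):
        boot = np.linspace(0.2, 0.9, 500)
        res = bca_interval(0.1, boot, np.arange(10.0))  # all boots above theta
        assert res.flagged


class TestPermutation:
    def test_p_bounded_below_for_perfect_correlation(self, rng):
        x = np.sort(rng.normal(size=20))
        res = permutation_test_corr(x, x, gamma=0.1, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1.0 / 1000.0)
        assert res.p_value >= 1.0 / (res.n_perm + 1)

    def test_matches_exact_enumeration_at_n4(self):
        x = np.array([0.3, 1.2, -0.7, 2.1])
        y = np.array([1.0, -0.2, 0.8, 1.7])
        t_obs = abs(permutation_test_corr(x, y, 0.0, n_perm=1, seed=0).observed)
        stats = []
        xc = x - x.mean()
        for perm in itertools.permutations(range(4)):
            yp = y[list(perm)]
            yc = yp - yp.mean()
            stats.append(abs(float(xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))))
        p_exact = np.mean([s >= t_obs - 1e-12 for s in stats])
        res = permutation_test_corr(x, y, 0.0, n_perm=24 * 200, seed=5)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_type_one_error_near_nominal(self):
        """Rejection rate at 0.05 over 1000 null datasets lies in [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_data = 1000
        for _ in range(n_data):
            x, y = rng.standard_normal((2, 200))
            res = permutation_test_corr(
                x, y, gamma=0.1, n_perm=999, seed=rng.integers(2**31)
            )
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_data <= 0.07

    def test_degenerate_input_raises(self):
        with pytest.raises(DegenerateInputError):
            permutation_test_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], 0.0, 10)


def _enumerate_hn_null(samples, scores):
    """Exact permutation mean/sd of the weighted HN statistic."""
    pooled = np.concatenate(samples)
    ranks = rankdata(pooled, method="average")
    sizes = [len(s) for s in samples]
    N = len(pooled)
    q = np.asarray(scores, dtype=float)
    c = q - float(np.array(sizes) @ q) / N
    w = np.array(sizes) * c
    ts = []
    idx = set(range(N))
    for g1 in itertools.combinations(range(N), sizes[0]):
        rest = idx - set(g1)
        for g2 in itertools.combinations(sorted(rest), sizes[1]):
            g3 = sorted(rest - set(g2))
            means = [
                ranks[list(g)].mean() for g in (g1, g2, g3)
            ]
            ts.append(float(w @ means))
    ts = np.array(ts)
    return ts.mean(), ts.std()


class TestHNTrend:
    def test_exact_standardization_small_instance(self):
        samples = [np.array([1.0, 2.0]), np.array([5.0, 6.0]), np.array([3.0, 4.0])]
        scores = (1, 2, 1)
        res = hn_trend_test(samples, scores)
        mu, sd = _enumerate_hn_null(samples, scores)
        assert mu == pytest.approx(0.0, abs=1e-12)
        ranks = rankdata(np.concatenate(samples))
        w = np.array([2, 2, 2]) * (np.array([1, 2, 1]) - 8 / 6)
        t_obs = float(w @ [ranks[:2].mean(), ranks[2:4].mean(), ranks[4:].mean()])
        assert res.z == pytest.approx(t_obs / sd, abs=1e-12)

    @pytest.mark.parametrize("sizes", [(2, 2, 2), (3, 3, 3), (2, 3, 4), (2, 2, 5)])
    @pytest.mark.parametrize("pattern", list(TREND_SCORES))
    def test_exact_standardization_all_small_instances(self, sizes, pattern):
        """z agrees with the exact permutation-null standardization, N <= 9."""
        seed = sizes[0] * 10007 + sizes[1] * 101 + sizes[2] + len(pattern)
        rng = np.random.default_rng(seed)
        samples = [rng.normal(size=m) for m in sizes]
        scores = TREND_SCORES[pattern]
        res = hn_trend_test(samples, scores)
        mu, sd = _enumerate_hn_null(samples, scores)
        ranks = rankdata(np.concatenate(samples))
        q = np.asarray(scores, dtype=float)
        N = sum(sizes)
        c = q - float(np.array(sizes) @ q) / N
        w = np.array(sizes) * c
        means, start = [], 0
        for m in sizes:
            means.append(ranks[start:start + m].mean())
            start += m
        t_obs = float(w @ means)
        assert mu == pytest.approx(0.0, abs=1e-9)
        assert res.z == pytest.approx((t_obs - mu) / sd, abs=1e-9)

    def test_null_simulation_mean_and_level(self):
        rng = np.random.default_rng(31)
        zs, rej = [], 0
        n_sim = 2000
        for _ in range(n_sim):
            samples = [rng.standard_normal(30) for _ in range(3)]
            res = hn_trend_test(samples, TREND_SCORES["concave"])
            zs.append(res.z)
            rej += res.p_value < 0.05
        assert abs(np.mean(zs)) < 3.5 / math.sqrt(n_sim)
        assert 0.03 <= rej / n_sim <= 0.07

    def test_concave_consistency_direction(self, rng):
        samples = [
            rng.normal(0, 1, 200), rng.normal(5, 1, 200), rng.normal(0, 1, 200)
        ]
        res = hn_trend_test(samples, TREND_SCORES["concave"])
        assert res.z > 10 and res.p_value < 0.001

    def test_all_tied_rejected(self):
        with pytest.raises(DegenerateInputError):
            hn_trend_test([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]], (1, 2, 3))
        with pytest.raises(ParameterError):
            hn_trend_test([[1.0, 2.0]] * 3, (2, 2, 2))


class TestClassification:
    def _hn(self, p_by_pattern):
        return {
            name: [HNResult(z=1.0, p_value=p_by_pattern.get(name, 0.5),
                            scores=TREND_SCORES[name])]
            for name in TREND_SCORES
        }

    def test_concave_with_preht_strongest(self):
        medians = np.array([[0.5, 0.618, 0.444]])
        res = classify_trends(
            medians, np.array([[True, True, True]]),
            self._hn({"concave": 0.001}), ["ansi"],
        )[0]
        assert res.umbrella == "concave"
        assert res.strongest == "preHt"
        assert res.band == "strong"

    def test_monotonic_increasing_without_umbrella(self):
        medians = np.array([[0.2, 0.3, 0.45]])
        res = classify_trends(
            medians, np.array([[True, True, True]]),
            self._hn({"increasing": 0.004}), ["rr_tp"],
        )[0]
        assert res.monotonic == "increasing" and res.umbrella == "none"
        assert res.endpoint_profile == "pos -> pos"

    def test_exact_tie_reported(self):
        medians = np.array([[0.4, -0.4, 0.1]])
        res = classify_trends(
            medians, np.array([[True, True, False]]), self._hn({}), ["hr"]
        )[0]
        assert res.strongest == "tie"

    def test_strength_bands(self):
        assert strength_band(0.1) == "negligible"
        assert strength_band(-0.25) == "weak"
        assert strength_band(0.45) == "medium"
        assert strength_band(-0.8) == "strong"
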