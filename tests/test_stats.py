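"""Agreement analytics: Sn scale, outlier screen, Bland-Altman, correlations,
JND transform, repeated-measures block analysis."""

import math
import statistics

import numpy as np
import pytest

from psychocompare.stats import (
    bland_altman,
    block_analysis,
    correlation,
    one_sample_bias,
    screen_outliers,
    sn_scale,
    transform_jnd,
)


def sn_oracle(values):
    """Plain-loop double-median Sn with the same published definition:
    himed over all j (h = n//2 + 1), lomed rank (n+1)//2, c = 1.1926,
    finite-sample factor."""
    x = list(values)
    n = len(x)
    himeds = []
    for i in range(n):
        diffs = sorted(abs(x[i] - x[j]) for j in range(n))
        himeds.append(diffs[n // 2])  # 0-based (n//2 + 1)-th order statistic
    lomed = sorted(himeds)[(n + 1) // 2 - 1]
    small = {2: 0.743, 3: 1.851, 4: 0.954, 5: 1.351, 6: 0.993, 7: 1.198, 8: 1.005, 9: 1.131}
    c_n = small.get(n, n / (n - 0.9) if n % 2 == 1 else 1.0)
    return c_n * 1.1926 * lomed


class TestSn:
    def test_exact_match_with_double_median_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            x = rng.normal(0, rng.uniform(0.1, 10), n)
            assert sn_scale(x) == pytest.approx(sn_oracle(x), rel=1e-12)

    def test_translation_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(32)
        x = rng.normal(5, 2, 21)
        assert sn_scale(x + 17.3) == pytest.approx(sn_scale(x), rel=1e-12)
        assert sn_scale(-2.5 * x) == pytest.approx(2.5 * sn_scale(x), rel=1e-12)

    def test_gaussian_consistency(self):
        # consistency constant: Sn estimates sigma for large normal samples
        rng = np.random.default_rng(33)
        x = rng.normal(0, 3.0, 4001)
        assert sn_scale(x) == pytest.approx(3.0, rel=0.05)

    def test_robust_to_heavy_contamination_unlike_sd(self):
        # Sn has a ~50% breakdown point: even 40% gross contamination only
        # inflates it by a small factor (rank inflation), while the SD
        # explodes with the outliers; at 10% contamination the change stays
        # under 50%
        rng = np.random.default_rng(34)
        x = rng.normal(0, 1, 30)
        heavy = x.copy()
        heavy[:12] = 1e6  # 40% contamination
        assert sn_scale(heavy) < 6 * sn_scale(x)
        assert np.std(heavy) > 10 * np.std(x)
        light = x.copy()
        light[:3] = 1e6  # 10% contamination
        assert abs(sn_scale(light) - sn_scale(x)) < 0.5 * sn_scale(x)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            sn_scale([1.0])


class TestOutlierScreen:
    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(35)
        x = rng.normal(0, 1, 21)
        x[7] = 10.0
        screen = screen_outliers(x, criterion=3)
        assert screen.flags[7]
        assert screen.flags.sum() == 1

    def test_all_equal_values_flag_nothing(self):
        screen = screen_outliers(np.full(10, 2.5))
        assert not screen.flags.any()
        assert screen.degenerate_scale

    def test_flags_invariant_under_affine_transform(self):
        rng = np.random.default_rng(36)
        x = rng.normal(0, 1, 25)
        x[3] = 8.0
        base = screen_outliers(x).flags
        np.testing.assert_array_equal(screen_outliers(3.0 * x - 7.0).flags, base)


class TestBlandAltman:
    def test_identical_measures_give_zero_everything(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = bland_altman(a, a)
        assert rep.bias == 0 and rep.loa_low == 0 and rep.loa_high == 0
        assert rep.agreement_span == 0

    def test_constant_offset_is_pure_bias(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = bland_altman(a + 0.5, a)
        assert rep.bias == pytest.approx(0.5)
        assert rep.sd_diff == pytest.approx(0.0)

    def test_toy_vectors_against_hand_arithmetic(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.1, 1.9, 3.2, 3.8]
        d = [ai - bi for ai, bi in zip(a, b)]  # -0.1, 0.1, -0.2, 0.2
        bias = sum(d) / 4
        sd = statistics.stdev(d)
        rep = bland_altman(a, b)
        assert rep.bias == pytest.approx(bias, abs=1e-12)
        assert rep.loa_low == pytest.approx(bias - 1.96 * sd, abs=1e-12)
        assert rep.loa_high == pytest.approx(bias + 1.96 * sd, abs=1e-12)
        # t-based CIs, t_{3, .975} = 3.18244...
        t = 3.182446305284263
        assert rep.ci_bias[1] - rep.ci_bias[0] == pytest.approx(2 * t * sd / 2, abs=1e-9)
        assert rep.ci_loa_low[1] - rep.ci_loa_low[0] == pytest.approx(
            2 * t * sd * math.sqrt(3 / 4), abs=1e-9
        )

    def test_span_identity_and_swap_symmetry(self):
        rng = np.random.default_rng(37)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.agreement_span == pytest.approx(2 * 1.96 * ab.sd_diff, abs=1e-12)
        assert ba.bias == pytest.approx(-ab.bias, abs=1e-12)
        assert ba.loa_low == pytest.approx(-ab.loa_high, abs=1e-12)
        assert ba.loa_high == pytest.approx(-ab.loa_low, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])

    def test_empirical_coverage_of_limits(self):
        """Differences of unbiased noisy measurement pairs fall inside the
        limits of agreement at roughly the nominal ~95% rate."""
        rng = np.random.default_rng(38)
        truth = rng.uniform(0, 1, 200)
        a = truth + rng.normal(0, 0.1, 200)
        b = truth + rng.normal(0, 0.1, 200)
        rep = bland_altman(a, b)
        d = a - b
        coverage = np.mean((d >= rep.loa_low) & (d <= rep.loa_high))
        assert 0.92 <= coverage <= 0.98


class TestCorrelation:
    def test_perfect_correlation_either_method(self):
        a = np.linspace(0, 1, 20)
        assert correlation(a, a, method="pearson").r == pytest.approx(1.0)
        assert correlation(a, a, method="spearman").r == pytest.approx(1.0)

    def test_monotone_nonlinear_transform_spearman_one_pearson_below(self):
        a = np.linspace(0.1, 3.0, 25)
        b = np.exp(3 * a)
        assert correlation(a, b, method="spearman").r == pytest.approx(1.0)
        assert correlation(a, b, method="pearson").r < 1.0

    def test_pearson_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(39)
        a = rng.normal(0, 1, 21)
        b = 0.6 * a + rng.normal(0, 0.8, 21)
        # independent direct computation
        am, bm = a.mean(), b.mean()
        r_direct = ((a - am) * (b - bm)).sum() / math.sqrt(
            ((a - am) ** 2).sum() * ((b - bm) ** 2).sum()
        )
        assert correlation(a, b, method="pearson").r == pytest.approx(r_direct, abs=1e-12)

    def test_normality_gate_picks_spearman_for_skewed_margins(self):
        rng = np.random.default_rng(40)
        a = rng.normal(0, 1, 40)
        b = np.exp(rng.normal(0, 1.5, 40))  # grossly non-normal margin
        assert correlation(a, b).method == "spearman"
        rng2 = np.random.default_rng(4040)
        assert correlation(rng2.normal(0, 1, 40), rng2.normal(0, 1, 40)).method == "pearson"

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(41)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        assert correlation(a, b).r == correlation(b, a).r

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(10), np.arange(10))


class TestTransformJnd:
    def test_positive_values_plain_log(self):
        jnds = np.array([0.05, 0.1, 0.2])
        out, shift, shifted = transform_jnd(jnds)
        np.testing.assert_allclose(out, np.log(jnds))
        assert shift == 0.0 and not shifted

    def test_scale_multiplication_adds_log_k(self):
        jnds = np.array([0.05, 0.1, 0.2])
        base, _, _ = transform_jnd(jnds)
        scaled, _, _ = transform_jnd(3.0 * jnds)
        np.testing.assert_allclose(scaled - base, np.log(3.0))

    def test_negative_values_shifted_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out, shift, shifted = transform_jnd(np.array([-0.02, 0.05, 0.1]))
        assert shifted and shift > 0.02
        assert np.all(np.isfinite(out))

    def test_boxcox_profile_supports_log_for_lognormal_jnds(self):
        """Grid-search Box-Cox profile likelihood on a log-normal sample:
        the mle lambda is near 0, supporting the log transform."""
        rng = np.random.default_rng(42)
        x = np.exp(rng.normal(-2.4, 0.4, 200))  # JND-like log-normal sample
        lambdas = np.linspace(-1, 1, 201)
        n = x.size
        logx_sum = np.log(x).sum()

        def profile_ll(lam):
            y = np.log(x) if abs(lam) < 1e-12 else (x**lam - 1) / lam
            return -0.5 * n * np.log(y.var()) + (lam - 1) * logx_sum

        best = lambdas[int(np.argmax([profile_ll(l) for l in lambdas]))]
        assert -0.3 < best < 0.3


class TestBlockAnalysis:
    def test_identical_blocks_give_zero_f(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        res = block_analysis(x)
        assert res.F == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_worked_table_against_independent_partition(self):
        # 4 subjects x 3 blocks
        x = np.array(
            [
                [10.0, 8.0, 6.0],
                [12.0, 11.0, 9.0],
                [9.0, 9.0, 8.0],
                [11.0, 10.0, 7.0],
            ]
        )
        # independent plain-loop partition
        n, k = x.shape
        grand = x.sum() / (n * k)
        ss_subj = sum(k * (row.mean() - grand) ** 2 for row in x)
        ss_block = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_total = sum((v - grand) ** 2 for v in x.ravel())
        ss_err = ss_total - ss_subj - ss_block
        f_expected = (ss_block / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        res = block_analysis(x)
        assert res.F == pytest.approx(f_expected, rel=1e-12)
        assert res.df == (2, 6)
        assert res.pairwise[(1, 3)]["diff"] == pytest.approx(x[:, 0].mean() - x[:, 2].mean())

    def test_agrees_with_pingouin_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(43)
        x = rng.normal(0, 1, (12, 3)) + np.array([0.0, 0.2, 0.5])
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "block": np.tile(np.arange(3), 12),
                "value": x.ravel(),
            }
        )
        ref = pg.rm_anova(data=long, dv="value", within="block", subject="subject")
        res = block_analysis(x)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_missing_blocks_dropped_with_warning(self):
        x = np.array([[1.0, 2.0, 3.0], [np.nan, 2.0, 3.0], [2.0, 2.5, 3.5]])
        with pytest.warns(RuntimeWarning):
            res = block_analysis(x)
        assert res.n_observers == 2
        assert res.dropped == 1


class TestBias:
    def test_one_sample_bias_against_reference(self):
        rng = np.random.default_rng(44)
        x = rng.normal(1.6, 0.05, 30)
        res = one_sample_bias(x, 1.6)
        assert res["p"] > 0.01
        res_biased = one_sample_bias(x + 0.5, 1.6)
        assert res_biased["p"] < 1e-6
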