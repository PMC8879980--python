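"""Evaluation statistics: deviation identities, margins, paired-test
dispatch, correlation, confidence intervals, and sample size."""

import numpy as np
import pytest

from ecapmap import (
    channel_deviations,
    duration_comparison,
    map_comparison,
    mean_ci,
    one_sided_sample_size,
    paired_compare,
    pooled_r2,
    srt_comparison,
)
from conftest import make_map


class TestChannelDeviations:
    def test_relative_deviation_arithmetic(self):
        clin = make_map(mcl=np.full(12, 20.0))
        ecap = make_map(label="LiveECAPMAP", mcl=np.full(12, 15.0))
        burst = make_map(label="LiveBurstMAP", mcl=np.full(12, 20.0))
        dev = channel_deviations(clin, ecap, burst)
        assert dev[0].rd_ecap_mcl == pytest.approx(25.0)
        assert dev[0].rd_burst_mcl == pytest.approx(0.0)
        assert dev[0].delta_mcl == pytest.approx(25.0)

    def test_magnitude_discards_sign(self):
        clin = make_map(mcl=np.full(12, 20.0))
        over = make_map(label="LiveECAPMAP", mcl=np.full(12, 25.0))
        dev = channel_deviations(clin, over, clin)
        assert dev[0].rd_ecap_mcl == pytest.approx(25.0)

    def test_identical_maps_give_zero(self):
        clin = make_map()
        dev = channel_deviations(clin, clin, clin)
        assert all(d.rd_ecap_mcl == 0 and d.delta_mcl == 0 for d in dev)

    def test_only_jointly_active_channels_included(self):
        active = np.ones(12, dtype=bool)
        active[5] = False
        clin = make_map()
        ecap = make_map(label="LiveECAPMAP", active=active)
        dev = channel_deviations(clin, ecap, clin)
        assert len(dev) == 11
        assert all(d.channel != 5 for d in dev)

    def test_zero_clinical_mcl_excluded_with_warning(self):
        clin = make_map()
        clin.mcl[2] = 0.0  # active but zero reference
        clin.thr[2] = 0.0
        with pytest.warns(UserWarning, match="E03"):
            dev = channel_deviations(clin, make_map(), make_map())
        assert len(dev) == 11


class TestAggregates:
    def test_map_comparison_is_mean_of_channels(self):
        clin = make_map(mcl=np.full(12, 20.0))
        mcl = np.full(12, 20.0)
        mcl[:3] = [18.0, 16.0, 14.0]  # 10, 20, 30 % deviations
        ecap = make_map(label="LiveECAPMAP", mcl=mcl)
        dev = channel_deviations(clin, ecap, clin)
        comp = map_comparison(dev[:3])
        assert comp.rd_ecap_map == pytest.approx(20.0)
        assert comp.delta_map == pytest.approx(20.0)
        # linearity: delta_map equals the mean of the per-channel deltas
        assert comp.delta_map == pytest.approx(np.mean([d.delta_mcl for d in dev[:3]]))

    @pytest.mark.parametrize(
        "fd_ecap,fd_burst,expected",
        [(10.0, 10.0, 0.0), (5.0, 10.0, 50.0), (0.0, 10.0, 100.0)],
    )
    def test_duration_saving(self, fd_ecap, fd_burst, expected):
        assert duration_comparison(fd_ecap, fd_burst).delta_fd == pytest.approx(expected)

    def test_duration_requires_positive_reference(self):
        with pytest.raises(ValueError):
            duration_comparison(1.0, 0.0)

    def test_srt_contrasts(self):
        comp = srt_comparison(srt_clin=-5.0, srt_ecap=-1.0, srt_burst=-4.0)
        assert comp.rd_ecap_srt == pytest.approx(4.0)
        assert comp.rd_burst_srt == pytest.approx(1.0)
        assert comp.delta_srt == pytest.approx(3.0)
        assert not comp.non_inferior  # 3 dB >= 2 dB margin

    def test_srt_antisymmetric_under_swap(self):
        a = srt_comparison(-5.0, -2.0, -4.0)
        b = srt_comparison(-5.0, -4.0, -2.0)
        assert a.delta_srt == pytest.approx(-b.delta_srt)

    def test_equal_srts_non_inferior(self):
        comp = srt_comparison(-3.0, -3.0, -3.0)
        assert comp.delta_srt == 0.0 and comp.non_inferior


class TestPooledR2:
    def test_perfect_linear_relation(self):
        x = np.arange(20.0)
        r2, p = pooled_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            r2, _ = pooled_r2(rng.normal(size=1000), rng.normal(size=1000))
            hits += r2 < 0.01
        assert hits >= 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pooled_r2(np.ones(10), np.arange(10.0))


class TestPairedCompare:
    def test_all_zero_differences_reported_as_p_one(self):
        a = np.arange(10.0)
        res = paired_compare(a, a)
        assert res.method == "signed-rank"
        assert res.p_value == 1.0
        assert not res.significant

    def test_shifted_normal_differences_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(200):
            base = rng.normal(0, 1, 50)
            if paired_compare(base + 1.0, base + rng.normal(0, 1, 50) * 0).significant:
                hits += 1
        assert hits >= 190

    def test_heavy_tails_route_to_signed_rank(self):
        rng = np.random.default_rng(2)
        methods = [
            paired_compare(rng.standard_cauchy(40), np.zeros(40)).method
            for _ in range(40)
        ]
        assert methods.count("signed-rank") > 20

    def test_normal_differences_route_to_t(self):
        rng = np.random.default_rng(3)
        methods = [
            paired_compare(rng.normal(0, 1, 40), np.zeros(40)).method
            for _ in range(40)
        ]
        assert methods.count("paired-t") > 30

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0], [0.0, 0.0])


class TestSampleSize:
    def test_reproduces_study_endpoints(self):
        # map-deviation endpoint: 20% margin, 37.63% SD
        assert one_sided_sample_size(20.0, 37.63) == 22
        # fitting-duration endpoint: 1.17 min margin, 2.16 min SD
        assert one_sided_sample_size(1.17, 2.16) == 22

    def test_margin_equal_to_sd(self):
        assert one_sided_sample_size(1.0, 1.0) == 7

    def test_monotonicity(self):
        assert one_sided_sample_size(10.0, 20.0) >= one_sided_sample_size(20.0, 20.0)
        assert one_sided_sample_size(20.0, 40.0) >= one_sided_sample_size(20.0, 20.0)
        assert one_sided_sample_size(20.0, 20.0, power=0.9) >= one_sided_sample_size(
            20.0, 20.0, power=0.8
        )

    def test_t_based_option_at_least_normal(self):
        assert one_sided_sample_size(20.0, 37.63, use_t=True) >= 22

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sided_sample_size(0.0, 1.0)
        with pytest.raises(ValueError):
            one_sided_sample_size(1.0, -1.0)


class TestMeanCi:
    def test_constant_values_zero_width(self):
        mean, lo, hi = mean_ci(np.full(10, 3.0))
        assert mean == lo == hi == 3.0

    def test_widens_with_level(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        _, lo95, hi95 = mean_ci(x, 0.95)
        _, lo99, hi99 = mean_ci(x, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_coverage_of_true_mean(self):
        rng = np.random.default_rng(5)
        covered = sum(
            lo <= 0 <= hi
            for lo, hi in (
                mean_ci(rng.normal(size=50))[1:] for _ in range(500)
            )
        )
        assert 0.93 * 500 < covered < 0.97 * 500
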