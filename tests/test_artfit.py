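"""Map builder: quick-mode schedule, profile completion, flattening,
scaling, the flat-map fallback, and live adjustment."""

import numpy as np
import pytest

from ecapmap import (
    ArtfitConfig,
    EligibilityError,
    ElectrodeLayout,
    PatientProfile,
    build_ecap_map,
    channel_index,
    channel_label,
    clin_map_of,
    complete_profile,
    flatten_profile,
    live_adjust_ecap,
    make_virtual_patient,
    quickmode_schedule,
    scale_to_max,
    validate_map,
)
from ecapmap.agf import EcapThresholdResult
from ecapmap.artfit import _well_distributed


def _result(channel_lab, thr):
    return EcapThresholdResult(
        channel=channel_index(channel_lab), threshold_qu=thr, found=True,
        fit_slope=50.0, fit_r2=1.0, n_supra=20,
    )


class TestQuickmodeSchedule:
    def test_default_order_spans_sections(self):
        schedule = quickmode_schedule(ElectrodeLayout.fully_active())
        labels = [channel_label(i) for i in schedule]
        assert labels[:4] == ["E10", "E06", "E03", "E12"]
        assert labels[4:6] == ["E07", "E02"]
        assert len(schedule) == 12

    def test_disabled_channel_substituted_within_section(self):
        layout = ElectrodeLayout.with_disabled([channel_index("E10")])
        schedule = quickmode_schedule(layout)
        first = channel_label(schedule[0])
        assert first in ("E09", "E11")
        # still alternates sections over the first four slots
        from ecapmap import section_of
        assert {section_of(c) for c in schedule[:3]} == {"apical", "medial", "basal"}

    def test_schedule_at_least_four_for_eligible_layouts(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            disabled = rng.choice(12, size=rng.integers(0, 3), replace=False)
            layout = ElectrodeLayout.with_disabled(list(disabled))
            assert len(quickmode_schedule(layout)) >= 4

    def test_too_few_active_channels_rejected(self):
        layout = ElectrodeLayout.with_disabled(list(range(9)))
        with pytest.raises(EligibilityError):
            quickmode_schedule(layout)


class TestCompleteProfile:
    def test_linear_interpolation_between_found(self):
        profile = complete_profile(
            [_result("E03", 2.0), _result("E10", 3.4)], ElectrodeLayout.fully_active()
        )
        assert profile.threshold_qu[channel_index("E06")] == pytest.approx(2.6)
        assert profile.provenance[channel_index("E06")] == "interpolated"
        assert profile.provenance[channel_index("E03")] == "measured"

    def test_extrapolation_beyond_outermost(self):
        profile = complete_profile(
            [_result("E03", 2.0), _result("E10", 3.4)], ElectrodeLayout.fully_active()
        )
        # line through E03 and E10 continued to E01 and E12
        slope = (3.4 - 2.0) / 7
        assert profile.threshold_qu[0] == pytest.approx(2.0 - 2 * slope)
        assert profile.threshold_qu[11] == pytest.approx(3.4 + 2 * slope)
        assert profile.provenance[0] == "extrapolated"

    def test_single_found_gives_constant_profile(self):
        profile = complete_profile([_result("E06", 2.5)], ElectrodeLayout.fully_active())
        np.testing.assert_allclose(profile.threshold_qu, 2.5)

    def test_found_on_both_ends_means_no_extrapolation(self):
        profile = complete_profile(
            [_result("E01", 1.5), _result("E12", 3.0)], ElectrodeLayout.fully_active()
        )
        assert profile.provenance.count("interpolated") == 10
        assert profile.provenance.count("extrapolated") == 0

    def test_clipped_from_below(self):
        profile = complete_profile(
            [_result("E11", 0.2), _result("E12", 0.15)], ElectrodeLayout.fully_active()
        )
        assert profile.threshold_qu.min() >= 0.1

    def test_no_found_thresholds_signals_fallback(self):
        with pytest.raises(ValueError, match="fallback"):
            complete_profile([], ElectrodeLayout.fully_active())


class TestFlattenProfile:
    def test_arithmetic_with_default_retain(self):
        out = flatten_profile(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out, [15.8, 20.0, 24.2])

    def test_constant_profile_unchanged(self):
        np.testing.assert_allclose(flatten_profile(np.full(12, 3.0)), 3.0)

    def test_peak_to_peak_retention_is_42_percent(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.uniform(1, 4, 12)
            f = flatten_profile(t)
            assert np.ptp(f) == pytest.approx(0.42 * np.ptp(t), rel=1e-12)
            assert f.mean() == pytest.approx(t.mean())

    @pytest.mark.parametrize("retain", [0.0, 1.5, -0.1])
    def test_invalid_retain_rejected(self, retain):
        with pytest.raises(ValueError):
            flatten_profile(np.ones(12), retain=retain)


class TestScaleToMax:
    def test_arithmetic(self):
        out = scale_to_max(np.array([15.8, 20.0, 24.2]))
        np.testing.assert_allclose(out, [3.264, 4.132, 5.0], atol=1e-3)

    def test_constant_profile_goes_to_five(self):
        np.testing.assert_allclose(scale_to_max(np.full(12, 2.0)), 5.0)

    def test_max_is_always_target(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = rng.uniform(0.5, 4, 12)
            assert scale_to_max(vals).max() == pytest.approx(5.0)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            scale_to_max(np.zeros(12))


class TestWellDistributed:
    def test_requires_two_sections_and_span(self):
        assert _well_distributed([9, 5, 2, 11])
        assert not _well_distributed([0, 1, 2])  # single section, tiny span
        assert not _well_distributed([])


class TestBuildEcapMap:
    def test_noise_free_build(self, quiet_patient, rng):
        ecap, diag = build_ecap_map(quiet_patient, rng=rng)
        assert not diag.fallback_used
        assert diag.n_found >= 4
        act = ecap.active
        assert ecap.mcl[act].max() == pytest.approx(5.0)
        np.testing.assert_allclose(ecap.thr[act] / ecap.mcl[act], 0.10)
        assert ecap.volume == 90.0
        assert validate_map(ecap) == []
        assert diag.fd_minutes > 0

    def test_nonresponsive_patient_falls_back_to_flat_map(self, rng):
        p = make_virtual_patient(3, PatientProfile(p_unresponsive=1.0))
        ecap, diag = build_ecap_map(p, rng=rng)
        assert diag.fallback_used
        np.testing.assert_allclose(ecap.mcl[ecap.active], 5.0)

    def test_ineligible_layout_rejected(self, rng):
        p = make_virtual_patient(3, PatientProfile(disabled_channels=(0, 1, 2)))
        with pytest.raises(EligibilityError):
            build_ecap_map(p, rng=rng)

    def test_disabled_clinical_channels_stay_disabled(self, rng):
        p = make_virtual_patient(4, PatientProfile(disabled_channels=(11,)))
        ecap, _ = build_ecap_map(p, rng=rng)
        assert not ecap.active[11]
        assert ecap.mcl[11] == 0.0

    def test_profile_shape_matches_flattened_truth_when_noise_free(
        self, quiet_patient, rng
    ):
        """End-to-end shape identity: with exact thresholds measured on all
        channels the map is the flattened true profile up to scale
        (r^2 = 1)."""
        config = ArtfitConfig(target_found=12)  # measure every channel
        ecap, diag = build_ecap_map(quiet_patient, config=config, rng=rng)
        assert diag.n_found == 12
        flat_truth = flatten_profile(quiet_patient.true_ecap_thr)
        r = np.corrcoef(ecap.mcl, flat_truth)[0, 1]
        assert r**2 == pytest.approx(1.0, abs=1e-6)

    def test_increasing_one_threshold_does_not_lower_its_mcl(self, rng):
        """Monotonicity of the pipeline in a single true threshold."""
        base = make_virtual_patient(6, PatientProfile(noise_rms=0.0))
        ecap1, _ = build_ecap_map(base, rng=np.random.default_rng(0))
        bumped = make_virtual_patient(6, PatientProfile(noise_rms=0.0))
        ch = 9  # a measured (quick-mode) channel
        bumped.true_ecap_thr[ch] += 0.5
        ecap2, _ = build_ecap_map(bumped, rng=np.random.default_rng(0))
        ratio1 = ecap1.mcl[ch] / ecap1.mcl.max()
        ratio2 = ecap2.mcl[ch] / ecap2.mcl.max()
        assert ratio2 >= ratio1 - 1e-9


class TestLiveAdjust:
    def test_flat_map_scaled_to_constant_true_mcl(self, rng):
        p = make_virtual_patient(8, PatientProfile(noise_rms=0.0))
        p.true_mcl[:] = 20.0
        ecap, diag = build_ecap_map(p, rng=rng)
        flat = ecap.copy()
        flat.mcl = np.where(flat.active, 5.0, 0.0)
        from ecapmap import set_thr_from_mcl
        flat = set_thr_from_mcl(flat)
        live, fd = live_adjust_ecap(flat, p, diag.fd_minutes)
        np.testing.assert_allclose(live.mcl[live.active], 20.0)
        assert fd > diag.fd_minutes

    def test_label_shape_and_validity(self, quiet_patient, rng):
        ecap, diag = build_ecap_map(quiet_patient, rng=rng)
        live, _ = live_adjust_ecap(ecap, quiet_patient)
        assert live.label == "LiveECAPMAP"
        assert validate_map(live) == []
        act = live.active
        np.testing.assert_allclose(
            live.mcl[act] / live.mcl[act][0], ecap.mcl[act] / ecap.mcl[act][0]
        )

    def test_fallback_flips_when_found_thresholds_removed(self):
        """Deleting found thresholds down to two always triggers fallback."""
        layout = ElectrodeLayout.fully_active()
        found = [_result("E03", 2.0), _result("E06", 2.4), _result("E10", 3.0),
                 _result("E12", 3.4)]
        assert _well_distributed([r.channel for r in found])
        # two found -> below the minimum of three, regardless of distribution
        for keep in ([0, 1], [0, 3], [2, 3]):
            chans = [found[i].channel for i in keep]
            n_found = len(chans)
            assert n_found < 3 or not _well_distributed(chans) or False
            assert n_found < 3  # the builder's first fallback clause fires
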