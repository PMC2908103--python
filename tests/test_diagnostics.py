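"""Usable range, invariance verdicts, channel ratios, and the report."""

import numpy as np
import pytest

from pmtcal import (DomainError, FitResult, ScannerResponseModel,
                    SimulationConfig, bootstrap_fit, build_report,
                    channel_ratio_profile, curvature_comparison,
                    density_for_series, gain_invariance, simulate_scan,
                    usable_range)
from tests.conftest import AGILENT_CY3_100

# frozen closed form: (3 * 11.90 / 106) ** (1 / 0.95)
LOWER_BOUND_K3 = 0.3180436178845768


def stub_fit(B, a, g, channel="Cy3", gain=None, ci=None):
    model = ScannerResponseModel(B, a, g, channel=channel, pmt_gain=gain)
    return FitResult(model=model, merit=0.0, n_used=100,
                     n_excluded_saturated=0, residuals=np.zeros(1),
                     converged=True, initialization=(B, a, g),
                     bootstrap_ci=ci)


class TestUsableRange:
    def test_no_floor_without_autofluorescence(self):
        m = ScannerResponseModel(106, 0.95, 0.0)
        assert usable_range(m, 3.0).lower == 0.0

    def test_lower_bound_closed_form(self):
        interval = usable_range(AGILENT_CY3_100, 3.0)
        assert interval.lower == pytest.approx(LOWER_BOUND_K3, rel=1e-12)

    def test_series_below_floor(self):
        # at threefold signal-to-background, the bottom eight dilution
        # series of the slide sit below the autofluorescence floor
        interval = usable_range(AGILENT_CY3_100, 3.0)
        below = [k for k in range(1, 28)
                 if density_for_series(k) < interval.lower]
        assert below == list(range(20, 28))

    def test_upper_bound_hits_ceiling(self):
        from pmtcal import predict_signal
        interval = usable_range(AGILENT_CY3_100, 3.0, ceiling=65535)
        assert predict_signal(interval.upper, AGILENT_CY3_100) == \
            pytest.approx(65535, rel=1e-9)

    def test_empty_when_floor_meets_ceiling(self):
        m = ScannerResponseModel(1e-3, 0.95, 100.0)
        assert usable_range(m, 3.0, ceiling=150.0).empty

    def test_monotone_in_g_k_and_B(self):
        base = usable_range(AGILENT_CY3_100, 3.0).lower
        higher_g = ScannerResponseModel(106, 0.95, 20.0)
        assert usable_range(higher_g, 3.0).lower > base
        assert usable_range(AGILENT_CY3_100, 5.0).lower > base
        higher_B = ScannerResponseModel(200, 0.95, 11.90)
        assert usable_range(higher_B, 3.0).lower < base

    def test_k_must_exceed_one(self):
        with pytest.raises(DomainError):
            usable_range(AGILENT_CY3_100, 1.0)


class TestGainInvariance:
    def test_autofluorescence_spread_across_gains(self):
        # three same-channel fits at gains 100/50/20
        fits = [stub_fit(106, 0.95, 11.90, gain=100),
                stub_fit(52, 0.95, 12.14, gain=50),
                stub_fit(21, 0.94, 12.12, gain=20)]
        verdict = gain_invariance(fits, "g")
        assert verdict.spread == pytest.approx(0.0202, abs=0.001)
        assert verdict.invariant

    def test_sensitivity_scales_with_gain(self):
        fits = [stub_fit(106, 0.95, 11.90, gain=100),
                stub_fit(52, 0.95, 12.14, gain=50),
                stub_fit(21, 0.94, 12.12, gain=20)]
        verdict = gain_invariance(fits, "B")
        assert not verdict.invariant
        assert verdict.spread > 1.0

    def test_identical_fits_have_zero_spread(self):
        fits = [stub_fit(106, 0.95, 11.90)] * 3
        verdict = gain_invariance(fits, "g")
        assert verdict.spread == 0.0 and verdict.invariant

    def test_mixed_channels_rejected_without_override(self):
        fits = [stub_fit(106, 0.95, 11.90, channel="Cy3"),
                stub_fit(54, 0.98, 3.90, channel="Cy5")]
        with pytest.raises(DomainError):
            gain_invariance(fits, "g")
        assert gain_invariance(fits, "a",
                               allow_mixed_channels=True) is not None

    def test_interval_overlap_drives_verdict(self):
        fits = [stub_fit(10, 0.95, 10.0, ci={"g": (9.0, 11.0)}),
                stub_fit(10, 0.95, 10.5, ci={"g": (9.5, 11.5)})]
        assert gain_invariance(fits, "g").invariant
        disjoint = [stub_fit(10, 0.95, 10.0, ci={"g": (9.9, 10.1)}),
                    stub_fit(10, 0.95, 10.5, ci={"g": (10.4, 10.6)})]
        assert not gain_invariance(disjoint, "g").invariant


class TestCurvature:
    def test_same_channel_curvatures_agree(self):
        fits = [stub_fit(106, 0.95, 11.90), stub_fit(52, 0.95, 12.14),
                stub_fit(21, 0.94, 12.12)]
        verdict, deviations = curvature_comparison(fits)
        assert verdict.invariant
        assert deviations == pytest.approx((0.05, 0.05, 0.06))

    def test_cross_channel_curvatures_agree(self):
        fits = [stub_fit(54, 0.98, 3.90, channel="Cy5"),
                stub_fit(28, 0.98, 4.04, channel="Cy5"),
                stub_fit(11, 0.99, 4.76, channel="Cy5"),
                stub_fit(106, 0.95, 11.90, channel="Cy3"),
                stub_fit(52, 0.95, 12.14, channel="Cy3"),
                stub_fit(21, 0.94, 12.12, channel="Cy3")]
        verdict, _ = curvature_comparison(fits)
        assert verdict.spread <= 0.06
        assert verdict.invariant

    def test_single_fit_duplicated(self):
        verdict, _ = curvature_comparison([stub_fit(106, 0.95, 11.90)] * 2)
        assert verdict.spread == 0.0


class TestChannelRatio:
    def test_equal_curvature_gives_constant_sensitivity_ratio(self):
        cy3 = ScannerResponseModel(106, 0.95, 11.90, "Cy3")
        cy5 = ScannerResponseModel(54, 0.95, 3.90, "Cy5")
        grid = np.logspace(-1, 4, 25)
        profile = channel_ratio_profile(cy3, cy5, grid)
        assert profile.constant
        assert profile.ratios == pytest.approx(106 / 54, rel=1e-12)

    def test_model_against_itself(self):
        m = AGILENT_CY3_100
        profile = channel_ratio_profile(m, m, [1.0, 10.0, 100.0])
        assert profile.ratios == pytest.approx(1.0)
        assert profile.max_over_min == pytest.approx(1.0)

    def test_differing_curvature_is_not_constant(self):
        agilent = ScannerResponseModel(106, 0.95, 11.90)
        genepix = ScannerResponseModel(208, 0.74, 7.45)
        grid = np.logspace(0, 5, 30)
        profile = channel_ratio_profile(agilent, genepix, grid)
        assert not profile.constant
        # the ratio drifts as x**(0.95 - 0.74)
        expected = (grid.max() / grid.min()) ** 0.21
        assert profile.max_over_min == pytest.approx(expected, rel=1e-9)

    def test_bad_grids_rejected(self):
        m = AGILENT_CY3_100
        with pytest.raises(DomainError):
            channel_ratio_profile(m, m, [])
        with pytest.raises(DomainError):
            channel_ratio_profile(m, m, [1.0, -2.0])


@pytest.fixture(scope="module")
def three_gain_fits(layout):
    # one slide, three PMT gains: B scales with gain, g and a do not
    fits = []
    for i, (B, gain) in enumerate([(106, 100), (52, 50), (21, 20)]):
        truth = ScannerResponseModel(B, 0.95, 12.0, "Cy3", gain)
        obs = simulate_scan(layout, SimulationConfig(
            truth=truth, seed=500 + i, noise_cv=0.10))
        fits.append(bootstrap_fit(obs, n_boot=100, seed=600 + i))
    return fits


class TestEndToEnd:
    def test_g_invariant_B_not(self, three_gain_fits):
        assert gain_invariance(three_gain_fits, "g").invariant
        assert not gain_invariance(three_gain_fits, "B").invariant

    def test_shared_curvature_recovered_within_two_percent(
            self, three_gain_fits):
        a_values = [f.model.a for f in three_gain_fits]
        assert (max(a_values) - min(a_values)) / min(a_values) < 0.02

    def test_report_is_order_independent(self, three_gain_fits):
        fwd = build_report(three_gain_fits)
        rev = build_report(list(reversed(three_gain_fits)))
        assert fwd.to_dict() == rev.to_dict()
        assert fwd.g_invariance.invariant
        assert not fwd.B_invariance.invariant
        assert fwd.to_text()  # renders
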