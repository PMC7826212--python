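"""Calibration, inversion, unit conversion and validation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riscreen.errors import ConfigError, FitError
from riscreen.quantitation import (
    RecoverySpec,
    fit_calibration,
    invert_calibration,
    lod_loq,
    quantify_study,
    recovery,
    rsd,
    stability_series,
    vial_to_herb,
)


class TestFitCalibration:
    def test_noiseless_line(self):
        curve = fit_calibration([(x, 2 * x + 1) for x in (1, 2, 5, 10, 20, 50)])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_chlorpyrifos_published_equation(self):
        """Responses generated exactly from the published regression line are
        recovered exactly."""
        levels = [(x, 402 * x + 3.55e3) for x in (5, 10, 50, 100, 200, 400)]
        curve = fit_calibration(levels, pesticide="Chlorpyrifos")
        assert curve.slope == pytest.approx(402.0)
        assert curve.intercept == pytest.approx(3550.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_procymidone_slope_under_noise(self):
        """1% multiplicative response noise leaves the slope within 3%
        (median over 100 seeds) of the published 594."""
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            levels = [
                (x, (594 * x + 2.91e3) * (1 + rng.normal(0, 0.01)))
                for x in (5, 10, 50, 100, 200, 400)
            ]
            slopes.append(fit_calibration(levels).slope)
        assert np.median(np.abs(np.array(slopes) - 594.0) / 594.0) < 0.03

    def test_too_few_levels(self):
        with pytest.raises(FitError):
            fit_calibration([(1, 2), (2, 4)])
        with pytest.raises(FitError):
            fit_calibration([(1, 2), (1, 3), (1, 4)])


@pytest.fixture(scope="module")
def chlorpyrifos():
    return fit_calibration(
        [(x, 402 * x + 3550) for x in (5, 10, 50, 100, 200, 400)],
        pesticide="Chlorpyrifos",
    )


class TestInvertCalibration:
    def test_response_at_intercept_is_zero(self, chlorpyrifos):
        est = invert_calibration(chlorpyrifos, 3550.0)
        assert est.ugl == 0.0 and not est.clipped

    def test_worked_inversion(self, chlorpyrifos):
        assert invert_calibration(chlorpyrifos, 43750.0).ugl == pytest.approx(100.0)

    def test_negative_clipped_with_flag(self, chlorpyrifos):
        est = invert_calibration(chlorpyrifos, 1000.0)
        assert est.ugl == 0.0 and est.clipped

    @settings(max_examples=100, deadline=None)
    @given(conc=st.floats(0.0, 400.0))
    def test_round_trip(self, chlorpyrifos, conc):
        resp = chlorpyrifos.response_at(conc)
        assert invert_calibration(chlorpyrifos, resp).ugl == pytest.approx(conc, abs=1e-9)


class TestVialToHerb:
    def test_standard_prep(self):
        # 3 g of herb reconstituted in 1 mL: vial µg/L -> herb µg/kg is /3
        assert vial_to_herb(300.0, 3.0, 1.0) == pytest.approx(100.0)

    def test_zero(self):
        assert vial_to_herb(0.0) == 0.0

    def test_dilution_linearity(self):
        assert vial_to_herb(300.0, dilution_factor=2.0) == pytest.approx(
            2 * vial_to_herb(300.0)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            vial_to_herb(1.0, sample_mass_g=0.0)


class TestRecovery:
    def test_identities(self):
        assert recovery(RecoverySpec(A=50.0, B=10.0, C=50.0)) == 0.0
        assert recovery(RecoverySpec(A=0.0, B=10.0, C=10.0)) == 100.0

    def test_published_spike_example(self):
        """Native 159.29 µg/kg spiked with 100; determined 254.51."""
        assert recovery(RecoverySpec(A=159.29, B=100.0, C=254.51)) == pytest.approx(95.22)

    def test_scale_invariance(self):
        a = recovery(RecoverySpec(A=12.0, B=30.0, C=40.0))
        b = recovery(RecoverySpec(A=120.0, B=300.0, C=400.0))
        assert a == pytest.approx(b)

    def test_nonpositive_spike(self):
        with pytest.raises(ConfigError):
            RecoverySpec(A=1.0, B=0.0, C=2.0)


class TestRsd:
    def test_constant_series(self):
        assert rsd([7.0] * 6) == 0.0

    def test_unit_example(self):
        assert rsd([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_simulated_two_percent(self):
        vals = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            vals.append(rsd(rng.normal(100.0, 2.0, 6)))
        assert np.median(vals) == pytest.approx(2.0, rel=0.15)

    def test_errors(self):
        with pytest.raises(ConfigError):
            rsd([1.0])
        with pytest.raises(ConfigError):
            rsd([1.0, -1.0])


class TestLodLoq:
    def test_worked_example(self):
        lod, loq = lod_loq(noise=3.0, peak_height_per_conc=100.0)
        assert lod == pytest.approx(0.09)
        assert loq == pytest.approx(0.30)

    @settings(max_examples=50, deadline=None)
    @given(noise=st.floats(1e-6, 1e6), slope=st.floats(1e-6, 1e6))
    def test_ratio_is_ten_thirds(self, noise, slope):
        lod, loq = lod_loq(noise, slope)
        assert loq / lod == pytest.approx(10.0 / 3.0)

    def test_noise_linearity(self):
        lod1, loq1 = lod_loq(3.0, 100.0)
        lod2, loq2 = lod_loq(6.0, 100.0)
        assert (lod2, loq2) == pytest.approx((2 * lod1, 2 * loq1))

    def test_invalid(self):
        with pytest.raises(ConfigError):
            lod_loq(0.0, 1.0)
        with pytest.raises(ConfigError):
            lod_loq(1.0, 0.0)


class TestStability:
    HOURS = (0, 2, 4, 8, 24, 48)

    def test_constant_areas(self):
        assert stability_series([(h, 5.0e4) for h in self.HOURS]) == 0.0

    def test_drifting_series_stays_in_published_band(self):
        """1%/day drift plus 1% noise keeps the 48-h RSD below 4.15%."""
        worst = 0.0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            series = [
                (h, 5.0e4 * (1 - 0.01 * h / 24.0) * (1 + rng.normal(0, 0.01)))
                for h in self.HOURS
            ]
            worst = max(worst, stability_series(series))
        assert worst < 4.15

    def test_single_point(self):
        with pytest.raises(ConfigError):
            stability_series([(0, 1.0)])


class TestQuantifyStudy:
    def test_unconfirmed_reported_nd(self, printed_panel, curves):
        from .test_screening import peaks_for
        from riscreen.screening import screen_sample

        peaks = peaks_for(printed_panel, {"Procymidone": 14.617}, include_qualifier=False)
        hits = screen_sample(peaks, printed_panel, sample_id="S1")
        results = quantify_study({"S1": hits}, curves)
        assert [(r.pesticide, r.status) for r in results] == [("Procymidone", "ND")]

    def test_missing_curve_names_pesticide(self, printed_panel):
        from .test_screening import peaks_for
        from riscreen.screening import screen_sample

        peaks = peaks_for(printed_panel, {"Tefluthrin": 11.982})
        hits = screen_sample(peaks, printed_panel, sample_id="S1")
        with pytest.raises(ConfigError, match="Tefluthrin"):
            quantify_study({"S1": hits}, {})

    def test_area_inversion_and_conversion(self, printed_panel, curves):
        from .test_screening import peak_at
        from riscreen.screening import screen_sample

        proc = next(r for r in printed_panel.records if r.entry_name == "Procymidone")
        vial = 300.0
        area = curves["Procymidone"].response_at(vial)
        peaks = {
            proc.quantifier: [peak_at(14.617, area=area)],
            proc.qualifier: [peak_at(14.617, area=0.5 * area)],
        }
        hits = screen_sample(peaks, printed_panel, sample_id="S1")
        [res] = quantify_study({"S1": hits}, curves)
        assert res.vial_conc == pytest.approx(vial, abs=1e-9)
        assert res.herb_conc == pytest.approx(100.0, abs=1e-6)
        assert res.status == "quantified"
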