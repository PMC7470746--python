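"""Peak picking, baseline correction, integration and calibration."""

import math
import warnings

import numpy as np
import pytest

from crossfeed import (
    Chromatogram,
    ChromatogramSpec,
    LinearCalibration,
    NoiseSpec,
    correct_baseline,
    fit_standard_curve,
    gen_chromatogram,
    integrate_area,
    internal_standard_quantify,
    pick_peak,
    quantify,
    quantify_chromatogram,
)
from crossfeed.errors import (
    CalibrationError,
    InvalidArgumentError,
    QuantificationError,
)
from crossfeed.hplc_quant import StandardCurve

GAUSS_AREA = lambda a, s: a * s * math.sqrt(2 * math.pi)


def make_chrom(peaks, slope=0.0, intercept=0.0, dt=0.005):
    spec = ChromatogramSpec(
        peaks=peaks, baseline_slope=slope, baseline_intercept=intercept,
        sampling_interval=dt,
    )
    return Chromatogram.from_frame(gen_chromatogram(spec))


class TestPickPeak:
    def test_single_gaussian_found_at_center(self):
        chrom = make_chrom(((7.0, 50.0, 0.05),))
        idx = pick_peak(chrom)
        assert abs(chrom.rt[idx] - 7.0) <= 0.005 + 1e-12

    def test_flat_signal_has_no_peak(self):
        chrom = make_chrom(())
        assert pick_peak(chrom) is None

    def test_tallest_of_two_peaks_wins(self):
        chrom = make_chrom(((6.8, 60.0, 0.05), (7.5, 40.0, 0.05)))
        idx = pick_peak(chrom)
        assert abs(chrom.rt[idx] - 6.8) <= 0.005 + 1e-12

    def test_plateau_uses_center_index(self):
        rt = 6.5 + 0.1 * np.arange(9)
        signal = np.array([0.0, 1, 2, 3, 3, 3, 2, 1, 0.0])
        idx = pick_peak(Chromatogram(rt, signal), window=(6.5, 7.4))
        assert idx == 4

    def test_window_validation(self):
        chrom = make_chrom(((7.0, 50.0, 0.05),))
        with pytest.raises(InvalidArgumentError):
            pick_peak(chrom, window=(8.0, 6.5))
        with pytest.raises(InvalidArgumentError):
            pick_peak(chrom, window=(20.0, 21.0))

    def test_edge_maximum_is_not_a_peak(self):
        # monotone ramp: the window max sits on the edge, so no peak
        rt = np.linspace(6.0, 9.0, 100)
        chrom = Chromatogram(rt, 2.0 * rt)
        assert pick_peak(chrom) is None


class TestBaselineCorrection:
    def test_linear_baseline_is_removed_exactly(self):
        # triangular peak on a line; flanking points sit exactly on the line
        rt = np.linspace(6.5, 7.5, 21)
        line = 3.0 + 2.0 * rt
        peak = np.zeros_like(rt)
        peak[8:13] = [0.0, 5.0, 8.0, 5.0, 0.0]
        chrom = Chromatogram(rt, line + peak)
        seg = correct_baseline(chrom, 10)
        lo, hi = seg.left_index, seg.right_index
        assert np.allclose(seg.corrected, peak[lo : hi + 1], atol=1e-10)
        assert seg.corrected[0] == 0.0 and seg.corrected[-1] == 0.0

    def test_gaussian_on_ramp_area_within_two_percent(self):
        chrom = make_chrom(((7.0, 50.0, 0.05),), slope=3.0, intercept=10.0, dt=0.002)
        idx = pick_peak(chrom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg = correct_baseline(chrom, idx)
        area = integrate_area(seg.rt, seg.corrected)
        assert area == pytest.approx(GAUSS_AREA(50.0, 0.05), rel=0.02)

    def test_boundary_fallback_sets_flag(self):
        chrom = make_chrom(((7.0, 50.0, 0.05),))  # flanks decay monotonically
        idx = pick_peak(chrom)
        with pytest.warns(UserWarning, match="boundary"):
            seg = correct_baseline(chrom, idx)
        assert seg.boundary_flag

    def test_invalid_peak_index(self):
        chrom = make_chrom(((7.0, 50.0, 0.05),))
        with pytest.raises(InvalidArgumentError):
            correct_baseline(chrom, 0)


class TestIntegration:
    def test_zero_segment(self):
        assert integrate_area([0.0, 1.0], [0.0, 0.0]) == 0.0

    def test_unit_rectangle(self):
        assert integrate_area([0.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_fine_gaussian(self):
        t = np.linspace(-1, 1, 4001)
        y = 5.0 * np.exp(-(t**2) / (2 * 0.1**2))
        assert integrate_area(t, y) == pytest.approx(GAUSS_AREA(5.0, 0.1), rel=1e-3)

    def test_needs_two_points(self):
        with pytest.raises(InvalidArgumentError):
            integrate_area([1.0], [1.0])


class TestStandardCurve:
    def test_exact_linear_points(self):
        curve = fit_standard_curve([(0.1, 0.2), (0.5, 1.0), (1.0, 2.0)])
        assert curve.slope == pytest.approx(2.0, rel=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.valid_range == (0.1, 1.0)

    def test_replicates_enter_the_fit(self):
        # the replicate at 1.0 pulls the slope below the 2.0 of the clean points
        curve = fit_standard_curve([(0.0, 0.0), (1.0, 2.0), (1.0, 1.0)])
        lone = fit_standard_curve([(0.0, 0.0), (1.0, 2.0)])
        assert curve.slope < lone.slope

    def test_single_concentration_is_singular(self):
        with pytest.raises(CalibrationError):
            fit_standard_curve([(0.5, 1.0), (0.5, 1.1)])

    def test_sklearn_calibration_round_trip(self):
        cal = LinearCalibration().fit([0.0, 0.5, 1.0], [0.1, 1.1, 2.1])
        conc = cal.inverse(cal.predict([0.25, 0.75]))
        assert np.allclose(conc, [0.25, 0.75])
        assert cal.get_params() == {"valid_range": None}


class TestQuantify:
    def _curve(self):
        return fit_standard_curve(
            [(c, 10.0 * c + 1.0) for c in (0.03, 0.1, 0.3, 1.0)]
        )

    def test_identity_on_calibration_points(self):
        curve = self._curve()
        for conc in (0.03, 0.1, 0.3, 1.0):
            result = quantify(curve.response(conc), curve)
            assert result.concentration == pytest.approx(conc, rel=1e-9)
            assert result.in_range

    def test_range_flags(self):
        curve = self._curve()
        low = quantify(curve.intercept, curve)  # area at intercept => conc 0
        assert low.concentration == pytest.approx(0.0, abs=1e-12)
        assert "below_range" in low.flags
        high = quantify(curve.response(2.0), curve)
        assert "above_range" in high.flags and not high.in_range

    def test_zero_slope_curve_rejected(self):
        import pandas as pd

        flat = StandardCurve(
            points=pd.DataFrame(), slope=0.0, intercept=1.0, valid_range=(0.03, 1.0)
        )
        with pytest.raises(CalibrationError):
            quantify(1.0, flat)


class TestInternalStandard:
    def test_values(self):
        assert internal_standard_quantify(0.0, 1.0, 50.0, 30.0) == 0.0
        # 5 uL of 10 uM labeled GSH (50 pmole) into 30 uL at unit area ratio
        assert internal_standard_quantify(1.0, 1.0, 50.0, 30.0) == pytest.approx(
            1.667, abs=1e-3
        )
        full = internal_standard_quantify(1.0, 1.0, 50.0, 30.0)
        assert internal_standard_quantify(0.5, 1.0, 50.0, 30.0) == pytest.approx(
            full / 2
        )

    def test_zero_internal_standard_area(self):
        with pytest.raises(QuantificationError):
            internal_standard_quantify(1.0, 0.0, 50.0, 30.0)


class TestEndToEnd:
    def _area_of(self, conc, noise=NoiseSpec()):
        chrom = Chromatogram.from_frame(
            gen_chromatogram(
                ChromatogramSpec(
                    peaks=((7.0, 80.0 * conc, 0.05),),
                    baseline_slope=2.0,
                    baseline_intercept=5.0,
                    sampling_interval=0.002,
                ),
                noise,
            )
        )
        idx = pick_peak(chrom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg = correct_baseline(chrom, idx)
        return integrate_area(seg.rt, seg.corrected)

    def test_spike_recovery_within_two_percent(self):
        standards = [(c, self._area_of(c)) for c in (0.03, 0.1, 0.3, 0.5, 1.0)]
        curve = fit_standard_curve(standards)
        result = quantify(self._area_of(0.5), curve)
        assert result.concentration == pytest.approx(0.5, rel=0.02)
        assert result.in_range

    def test_full_pipeline_flags_out_of_range_sample(self):
        standards = [(c, self._area_of(c)) for c in (0.03, 0.1, 0.3, 0.5, 1.0)]
        curve = fit_standard_curve(standards)
        chrom = Chromatogram.from_frame(
            gen_chromatogram(
                ChromatogramSpec(
                    peaks=((7.0, 160.0, 0.05),),
                    baseline_slope=2.0,
                    baseline_intercept=5.0,
                    sampling_interval=0.002,
                )
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = quantify_chromatogram(chrom, curve)
        assert "above_range" in q.flags
        assert q.concentration == pytest.approx(2.0, rel=0.05)

    def test_no_peak_propagates(self):
        curve = fit_standard_curve([(0.1, 1.0), (1.0, 10.0)])
        flat = Chromatogram(np.linspace(6.0, 9.0, 200), np.zeros(200))
        q = quantify_chromatogram(flat, curve)
        assert "no_peak" in q.flags and math.isnan(q.concentration)
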