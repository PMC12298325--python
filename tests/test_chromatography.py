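"""Baseline, peak picking and integration against closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from venomquant import chromatography as ch
from venomquant.records import InputError, ParameterError


def gaussian_trace(amps, means, sigma=0.1, dt=0.002, span=(0.0, 10.0),
                   baseline=0.0, drift=0.0):
    t = np.arange(span[0], span[1] + dt / 2, dt)
    sig = np.full_like(t, baseline) + drift * t
    for a, m in zip(amps, means):
        sig += a * np.exp(-0.5 * ((t - m) / sigma) ** 2)
    return ch.ChromatogramTrace(t, sig)


class TestReadTrace:
    def test_reads_small_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_min,absorbance_mau\n0,1\n1,2\n2,1\n3,0\n4,0\n")
        assert len(ch.read_trace(p)) == 5

    def test_headerless_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,1\n1,2\n2,1\n")
        assert len(ch.read_trace(p)) == 3

    def test_duplicated_time_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,1\n1,2\n1,3\n2,1\n")
        with pytest.raises(InputError, match="increasing"):
            ch.read_trace(p)

    def test_header_only_is_no_samples(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_min,absorbance_mau\n")
        with pytest.raises(InputError, match="no samples"):
            ch.read_trace(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,1\n1,2\nxx,yy\n3,1\n")
        with pytest.raises(InputError, match="line 3"):
            ch.read_trace(p)


class TestEstimateBaseline:
    def test_flat_trace_gives_flat_baseline(self):
        tr = gaussian_trace([], [], baseline=3.5)
        b = ch.estimate_baseline(tr, window=1.0)
        np.testing.assert_allclose(b, 3.5)
        np.testing.assert_allclose(tr.absorbance - b, 0.0)

    def test_linear_drift_removed_around_narrow_peak(self):
        # analytic oracle: drift-free corrected area = a * sigma * sqrt(2*pi);
        # a rolling-minimum baseline clips peak tails by ~drift x window, so
        # the drift/window product must stay small against the peak height
        tr = gaussian_trace([1.0], [5.0], sigma=0.1, drift=0.002)
        b = ch.estimate_baseline(tr, window=1.0)
        corrected = np.clip(tr.absorbance - b, 0, None)
        area = np.trapezoid(corrected, tr.time)
        assert area == pytest.approx(0.1 * math.sqrt(2 * math.pi), rel=0.01)

    def test_tiny_window_degenerates_to_trace(self):
        tr = gaussian_trace([1.0], [5.0])
        b = ch.estimate_baseline(tr, window=1e-6)
        np.testing.assert_array_equal(b, tr.absorbance)

    def test_window_beyond_span_rejected(self):
        tr = gaussian_trace([1.0], [5.0])
        with pytest.raises(ParameterError):
            ch.estimate_baseline(tr, window=100.0)

    def test_baseline_never_exceeds_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 0.01)
        sig = 0.1 * t + rng.normal(0, 0.2, t.shape)
        tr = ch.ChromatogramTrace(t, sig)
        b = ch.estimate_baseline(tr, window=2.0)
        assert (b <= sig + 1e-12).all()


class TestDetectPeaks:
    def test_single_gaussian_apex_at_mean(self):
        tr = gaussian_trace([1.0], [5.0])
        b = np.zeros(len(tr))
        peaks = ch.detect_peaks(tr, b)
        assert len(peaks) == 1
        # brute-force argmax oracle
        apex_oracle = tr.time[np.argmax(tr.absorbance)]
        assert abs(peaks["apex_min"][0] - apex_oracle) <= 0.002

    def test_two_gaussians_boundary_at_valley(self):
        tr = gaussian_trace([1.0, 0.8], [4.0, 6.0], sigma=0.3)
        b = np.zeros(len(tr))
        peaks = ch.detect_peaks(tr, b)
        assert len(peaks) == 2
        # brute-force valley search between the apexes
        i0, i1 = peaks["apex_idx"][0], peaks["apex_idx"][1]
        valley_oracle = tr.time[i0 + np.argmin(tr.absorbance[i0:i1 + 1])]
        assert abs(peaks["end_min"][0] - valley_oracle) <= 0.002
        assert peaks["end_min"][0] == peaks["start_min"][1]

    def test_all_zero_signal_gives_empty_table(self):
        tr = gaussian_trace([], [])
        peaks = ch.detect_peaks(tr, np.zeros(len(tr)))
        assert len(peaks) == 0

    def test_prominence_threshold_filters_small_peaks(self):
        tr = gaussian_trace([1.0, 0.005], [4.0, 7.0])
        b = np.zeros(len(tr))
        assert len(ch.detect_peaks(tr, b, min_prominence=0.05)) == 1
        assert len(ch.detect_peaks(tr, b, min_prominence=0.001)) == 2


class TestIntegratePeaks:
    def test_rectangular_pulse_exact_area(self):
        dt = 0.01
        t = np.arange(0, 10, dt)
        sig = np.where((t >= 4) & (t < 6), 2.0, 0.0)
        tr = ch.ChromatogramTrace(t, sig)
        peaks = ch.detect_peaks(tr, np.zeros(len(t)), min_prominence=0.1)
        peaks = ch.integrate_peaks(tr, np.zeros(len(t)), peaks)
        # trapezoid sees half-height samples at the two edges: h*w exactly
        # when boundaries sit outside the pulse
        assert peaks["corrected_area"][0] == pytest.approx(2.0 * 2.0, rel=1e-2)

    def test_gaussian_area_closed_form(self):
        tr = gaussian_trace([1.0], [5.0], sigma=0.1, dt=0.002)
        z = np.zeros(len(tr))
        peaks = ch.integrate_peaks(tr, z, ch.detect_peaks(tr, z))
        assert peaks["corrected_area"][0] == pytest.approx(0.2507, abs=1e-3)

    def test_fraction_ratio_from_analytic_areas(self):
        tr = gaussian_trace([3.0, 1.0], [3.0, 7.0], sigma=0.2)
        z = np.zeros(len(tr))
        peaks = ch.integrate_peaks(tr, z, ch.detect_peaks(tr, z))
        assert peaks["fraction"].to_numpy() == pytest.approx([0.75, 0.25], abs=1e-3)

    def test_trapezoid_converges_with_sampling(self):
        # integrate over fixed interior boundaries where the integrand's
        # curvature makes the trapezoid error h^2-dominated; the erf oracle
        # is evaluated on the exact (grid-snapped) boundaries used
        from scipy.special import erf

        errs = []
        for dt in (0.05, 0.01, 0.002):
            tr = gaussian_trace([1.0], [5.0], sigma=0.1, dt=dt)
            z = np.zeros(len(tr))
            peaks = ch.detect_peaks(tr, z)
            bounds = pd.DataFrame(
                [{"peak_id": "P1", "start_min": 4.87, "end_min": 5.13}]
            )
            peaks = ch.apply_manual_boundaries(tr, peaks, bounds)
            peaks = ch.integrate_peaks(tr, z, peaks)
            s, e = peaks["start_min"][0], peaks["end_min"][0]
            oracle = (
                0.1
                * math.sqrt(2 * math.pi)
                * 0.5
                * (erf((e - 5.0) / (0.1 * math.sqrt(2)))
                   - erf((s - 5.0) / (0.1 * math.sqrt(2))))
            )
            errs.append(abs(peaks["corrected_area"][0] - oracle))
        assert errs[0] > errs[1] > errs[2]

    def test_fractions_sum_to_one(self):
        tr = gaussian_trace([1.0, 0.5, 0.2], [2.0, 5.0, 8.0], sigma=0.2)
        z = np.zeros(len(tr))
        peaks = ch.integrate_peaks(tr, z, ch.detect_peaks(tr, z))
        assert peaks["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_detect_integrate_idempotent(self):
        tr = gaussian_trace([1.0, 0.5], [3.0, 7.0], sigma=0.2)
        z = np.zeros(len(tr))
        a = ch.integrate_peaks(tr, z, ch.detect_peaks(tr, z))
        b = ch.integrate_peaks(tr, z, ch.detect_peaks(tr, z))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_signal_is_error(self):
        tr = gaussian_trace([1.0], [5.0])
        z = np.zeros(len(tr))
        peaks = ch.detect_peaks(tr, z)
        with pytest.raises(InputError, match="no integrable"):
            ch.integrate_peaks(tr, tr.absorbance.copy(), peaks)


class TestExcludeAndRenormalize:
    @pytest.fixture
    def three_peaks(self):
        tr = gaussian_trace([1.0, 1.0, 2.0], [2.0, 5.0, 8.0], sigma=0.2)
        z = np.zeros(len(tr))
        return ch.integrate_peaks(tr, z, ch.detect_peaks(tr, z))

    def test_exclusion_renormalizes(self, three_peaks):
        out = ch.exclude_and_renormalize(three_peaks, ["P1"])
        assert math.isnan(out["fraction"][0])
        assert out["fraction"][1] == pytest.approx(1 / 3, abs=1e-3)
        assert out["fraction"][2] == pytest.approx(2 / 3, abs=1e-3)

    def test_empty_exclusion_is_identity(self, three_peaks):
        out = ch.exclude_and_renormalize(three_peaks, [])
        pd.testing.assert_frame_equal(out, three_peaks)

    def test_excluding_all_rejected(self, three_peaks):
        with pytest.raises(InputError):
            ch.exclude_and_renormalize(three_peaks, ["P1", "P2", "P3"])

    def test_unknown_id_rejected(self, three_peaks):
        with pytest.raises(InputError, match="P9"):
            ch.exclude_and_renormalize(three_peaks, ["P9"])

    def test_impurity_exclusion_on_fixture(self, clean_run_dir, fixture_venom):
        # excluding the contaminant-only peaks leaves the toxin-bearing
        # fractions summing to 1
        from venomquant import chromatography

        trace = chromatography.read_trace(clean_run_dir["paths"]["trace"])
        b = chromatography.estimate_baseline(trace, 6.0)
        peaks = chromatography.detect_peaks(trace, b, min_prominence=1e-3,
                                            min_area_fraction=0.0)
        peaks = chromatography.integrate_peaks(trace, b, peaks)
        # the first two detected peaks are the early impurity peaks
        out = ch.exclude_and_renormalize(peaks, ["P1", "P2"])
        rest = out.loc[~out["excluded"].astype(bool), "fraction"]
        assert rest.sum() == pytest.approx(1.0, abs=1e-9)
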