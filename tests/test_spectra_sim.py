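"""Spectral simulator: peak rendering, editing behaviour, cohorts, Vernier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stereomrs import io as smio
from stereomrs.group_stats import paired_t
from stereomrs.spectra_sim import (
    AcquisitionConfig,
    CohortConfig,
    PeakSpec,
    ppm_axis,
    render_peak,
    simulate_acquisition,
    simulate_cohort,
    simulate_cohort_truth,
    simulate_vernier,
    truth_table,
)


class TestRenderPeak:
    def test_height_at_center(self, axis):
        pk = PeakSpec("g", 3.0, 2.0, 0.08)
        y = render_peak(pk, axis)
        assert y[np.argmin(np.abs(axis - 3.0))] == pytest.approx(2.0, abs=1e-3)

    def test_half_maximum_at_half_width(self):
        x = np.array([2.9, 3.0, 3.05, 3.2])
        y = render_peak(PeakSpec("g", 3.0, 2.0, 0.1), x)
        assert y[2] == pytest.approx(1.0)

    def test_lorentzian_closed_form(self):
        # a / (1 + (2*delta/fwhm)^2) at delta = 0.1, fwhm = 0.1 -> 1/5
        x = np.array([2.5, 3.0, 3.1, 3.5])
        y = render_peak(PeakSpec("l", 3.0, 1.0, 0.1, "lorentzian"), x)
        assert y[2] == pytest.approx(0.2)

    @settings(deadline=None, max_examples=25)
    @given(g=st.floats(0.0, 1.0))
    def test_mixed_is_convex_combination(self, g):
        x = np.linspace(2.0, 4.0, 401)
        mixed = render_peak(PeakSpec("m", 3.0, 1.5, 0.1, "mixed", g), x)
        gauss = render_peak(PeakSpec("g", 3.0, 1.5, 0.1, "gaussian"), x)
        lorentz = render_peak(PeakSpec("l", 3.0, 1.5, 0.1, "lorentzian"), x)
        np.testing.assert_allclose(mixed, g * gauss + (1 - g) * lorentz, atol=1e-12)

    def test_center_outside_axis_rejected(self, axis):
        with pytest.raises(ValueError, match="outside the axis range"):
            render_peak(PeakSpec("bad", 99.0, 1.0, 0.1), axis)

    def test_non_monotonic_axis_rejected(self):
        with pytest.raises(ValueError, match="monotonic"):
            render_peak(PeakSpec("g", 3.0, 1.0, 0.1), np.array([1.0, 3.0, 2.0]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(amplitude=-1.0),
            dict(fwhm=0.0),
            dict(shape="mixed", g_fraction=1.5),
            dict(edit_class="bogus"),
        ],
    )
    def test_invalid_peak_specs_rejected(self, kwargs):
        base = dict(name="p", center=3.0, amplitude=1.0, fwhm=0.1)
        base.update(kwargs)
        with pytest.raises(ValueError):
            PeakSpec(**base)


class TestSimulateAcquisition:
    def test_unedited_cancels_in_difference(self):
        cfg = AcquisitionConfig(noise_sd=0.0)
        tcr = PeakSpec("tCr", 3.03, 1.0, 0.06, "mixed", 0.7, "unedited")
        acq = simulate_acquisition(cfg, [tcr])
        on = acq.transients[acq.edit_labels == "ON"].mean(axis=0)
        off = acq.transients[acq.edit_labels == "OFF"].mean(axis=0)
        np.testing.assert_allclose(on - off, 0.0, atol=1e-14)

    def test_edited_appears_with_full_amplitude(self, axis):
        cfg = AcquisitionConfig(noise_sd=0.0)
        tcr = PeakSpec("tCr", 3.03, 1.0, 0.06, "mixed", 0.7, "unedited")
        gaba = PeakSpec("gaba", 3.0, 0.25, 0.08, "gaussian", 1.0, "edited")
        acq = simulate_acquisition(cfg, [tcr, gaba])
        on = acq.transients[acq.edit_labels == "ON"].mean(axis=0)
        off = acq.transients[acq.edit_labels == "OFF"].mean(axis=0)
        np.testing.assert_allclose(on - off, render_peak(gaba, axis), atol=1e-14)

    def test_inverted_doubles_with_flipped_sign(self, axis):
        cfg = AcquisitionConfig(noise_sd=0.0)
        naa = PeakSpec("naa", 2.0, 1.0, 0.05, "gaussian", 1.0, "inverted")
        tcr = PeakSpec("tCr", 3.03, 1.0, 0.06, "gaussian", 1.0, "unedited")
        acq = simulate_acquisition(cfg, [tcr, naa])
        on = acq.transients[acq.edit_labels == "ON"].mean(axis=0)
        off = acq.transients[acq.edit_labels == "OFF"].mean(axis=0)
        np.testing.assert_allclose(on - off, -2.0 * render_peak(naa, axis), atol=1e-14)

    def test_seed_determinism(self, standard_peaks):
        cfg = AcquisitionConfig(noise_sd=0.02, freq_drift_sd=1.0, phase_drift_sd=5.0, seed=7)
        a = simulate_acquisition(cfg, standard_peaks)
        b = simulate_acquisition(cfg, standard_peaks)
        np.testing.assert_array_equal(a.transients, b.transients)

    def test_noise_calibration_in_signal_free_region(self, standard_peaks):
        cfg = AcquisitionConfig(noise_sd=0.02, seed=3)
        acq = simulate_acquisition(cfg, standard_peaks)
        axis = acq.axis
        region = (axis > 8.0) & (axis < 12.0)  # no simulated resonances
        sd = acq.transients[:, region].std()
        assert sd == pytest.approx(0.02, rel=0.05)

    def test_odd_transients_rejected(self, standard_peaks):
        with pytest.raises(ValueError, match="even"):
            AcquisitionConfig(n_transients=255)


class TestInterchangeFormat:
    def test_csv_roundtrip_and_byte_determinism(self, tmp_path, standard_peaks):
        cfg = AcquisitionConfig(n_transients=8, n_points=256, noise_sd=0.01, seed=1)
        acq = simulate_acquisition(cfg, standard_peaks)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        smio.write_spectra_csv(acq, p1)
        smio.write_spectra_csv(acq, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = smio.read_spectra_csv(p1)
        np.testing.assert_allclose(back.transients, acq.transients, rtol=1e-6)
        assert list(back.edit_labels) == list(acq.edit_labels)
        assert back.config.spectral_width == cfg.spectral_width

    def test_h5_roundtrip(self, tmp_path, standard_peaks):
        cfg = AcquisitionConfig(n_transients=8, n_points=256, noise_sd=0.01, seed=1)
        acq = simulate_acquisition(cfg, standard_peaks)
        p = tmp_path / "a.h5"
        smio.write_spectra_h5(acq, p)
        back = smio.read_spectra_h5(p)
        np.testing.assert_array_equal(back.transients, acq.transients)
        assert list(back.edit_labels) == list(acq.edit_labels)


class TestCohort:
    def test_exact_counterbalancing_even_cohort(self):
        subs = simulate_cohort_truth(CohortConfig(n_subjects=20, seed=0))
        orders = [s.order for s in subs]
        assert orders.count("single_first") == 10
        assert orders.count("mixed_first") == 10

    def test_odd_cohort_warns_and_splits_by_one(self):
        with pytest.warns(UserWarning, match="counterbalancing"):
            subs = simulate_cohort_truth(CohortConfig(n_subjects=7, seed=0))
        orders = [s.order for s in subs]
        assert abs(orders.count("single_first") - orders.count("mixed_first")) == 1

    def test_null_construction_equal_condition_means(self):
        cfg = CohortConfig(n_subjects=400, gaba_effect=0.0, glx_effect=0.0, seed=1)
        tt = truth_table(simulate_cohort_truth(cfg))
        means = tt.groupby("condition")["true_gaba_tcr"].mean()
        # no injected effect: all condition means equal up to sampling noise
        assert np.ptp(means.to_numpy()) < 3 * tt["true_gaba_tcr"].sem() * 2

    def test_downstream_rejection_matches_power_oracle(self):
        """Paired-t rejection rate at the default effect sizes matches the
        closed-form noncentral-t power computation for a paired design."""
        # d_z = effect / (within_sd * sqrt(2)); defaults: 0.04 / (0.04*sqrt(2))
        dz = 0.04 / (0.04 * np.sqrt(2))
        n = 20
        tcrit = stats.t.ppf(0.975, n - 1)
        nc = dz * np.sqrt(n)
        power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        reps, rej = 200, 0
        for s in range(reps):
            subs = simulate_cohort_truth(CohortConfig(seed=s))
            single = [x.gaba_tcr["single"] for x in subs]
            mixed = [x.gaba_tcr["mixed"] for x in subs]
            rej += paired_t(single, mixed).p < 0.05
        assert rej / reps == pytest.approx(power, abs=0.08)

    def test_cohort_acquisitions_and_truth_align(self):
        cohort = CohortConfig(n_subjects=2, seed=4)
        acq_cfg = AcquisitionConfig(n_transients=8, n_points=256, noise_sd=0.0)
        subjects, it = simulate_cohort(cohort, acq_cfg)
        for s, acqs in it:
            assert set(acqs) == {"rest1", "single", "mixed", "rest2"}
            # second rest is half length
            assert acqs["rest2"].transients.shape[0] == 4
            assert acqs["single"].truth["true_gaba_tcr"] == s.gaba_tcr["single"]


class TestVernier:
    def test_step_function_limit(self):
        t = simulate_vernier(0.0, 1e-6, offsets=np.array([-6.4, 6.4]), n_per_offset=50, seed=0)
        right = t[t.offset_arcmin > 0]["response_right"]
        left = t[t.offset_arcmin < 0]["response_right"]
        assert right.all() and not left.any()

    def test_probability_half_at_bias_point(self):
        t = simulate_vernier(2.0, 2.0, offsets=np.array([2.0]), n_per_offset=4000, seed=1)
        assert t["response_right"].mean() == pytest.approx(0.5, abs=0.03)

    def test_lapse_floor_and_ceiling(self):
        t = simulate_vernier(
            0.0, 0.5, lapse=0.2, offsets=np.array([-20.0, 20.0]), n_per_offset=3000, seed=2
        )
        p_far_left = t[t.offset_arcmin < 0]["response_right"].mean()
        assert p_far_left == pytest.approx(0.1, abs=0.03)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_vernier(0.0, 0.0)
        with pytest.raises(ValueError):
            simulate_vernier(0.0, 1.0, offsets=np.array([np.inf]))
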