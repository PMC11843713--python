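"""Timing histograms, width estimators, CTR sweeps, classification and
pair-resolution algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import segtof as st
from segtof.timing import (
    GAUSSIAN_FWTM_FWHM_RATIO,
    build_histogram,
    calibrate_energy,
    classify_deciles,
    ctr_vs_dtk,
    ctr_vs_k,
    energy_window_filter,
    fwhm_fwtm,
    kernels_by_photon_number,
    side_peak_locator,
    solve_pair_resolutions,
    subtract_reference,
    tdiff_by_energy,
)


class TestBuildHistogram:
    def test_counts_conserved(self):
        rng = np.random.default_rng(20)
        x = rng.normal(0, 100, size=1234)
        h = build_histogram(x, 25.0)
        assert h.counts.sum() == 1234 and h.n_events == 1234

    def test_single_value(self):
        h = build_histogram([40.0], 25.0)
        assert h.counts.sum() == 1

    def test_empty(self):
        h = build_histogram([], 25.0)
        assert h.counts.sum() == 0 and h.n_events == 0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([1.0], 0.0)


class TestFwhmFwtm:
    def test_gaussian_closed_form(self):
        """1e6 Gaussian samples, sigma = 100 ps: FWHM ~ 235.48 ps and
        FWTM ~ 429.19 ps (2 sqrt(2 ln 2) sigma and 2 sqrt(2 ln 10) sigma)."""
        rng = np.random.default_rng(21)
        h = build_histogram(rng.normal(0.0, 100.0, size=1_000_000), 5.0)
        for method in ("gauss_fit", "direct"):
            fwhm, fwtm = fwhm_fwtm(h, method)
            assert fwhm == pytest.approx(235.48, rel=0.01)
            assert fwtm == pytest.approx(429.19, rel=0.01)

    def test_heavy_tailed_mixture_exceeds_gaussian_ratio(self):
        rng = np.random.default_rng(22)
        x = np.concatenate(
            [rng.normal(0, 80, size=800_000), rng.normal(0, 400, size=200_000)]
        )
        fwhm, fwtm = fwhm_fwtm(build_histogram(x, 10.0), "gauss_fit")
        assert fwtm / fwhm > GAUSSIAN_FWTM_FWHM_RATIO

    def test_fwtm_not_below_fwhm(self, bgo_stream):
        d = bgo_stream["t_adaptive_ps"] - bgo_stream["reference_ps"]
        for method in ("gauss_fit", "direct"):
            fwhm, fwtm = fwhm_fwtm(build_histogram(d, 25.0), method)
            assert fwtm >= fwhm

    def test_flat_histogram_rejected(self):
        h = build_histogram([], 25.0)
        with pytest.raises(ValueError):
            fwhm_fwtm(h)


class TestCtrSweeps:
    def test_saturated_k_equals_single_pixel_ctr(self, bgo_stream):
        """k beyond max |delta T| always selects the same pixel, so the
        sweep reproduces the single-pixel CTR exactly."""
        df = bgo_stream
        kmax = float(np.nanmax(np.abs(df["delta_t_ps"]))) + 1.0
        curve = ctr_vs_k(df, [-kmax, kmax])
        d_a = (df["t_a_ps"].fillna(df["t_b_ps"]) - df["reference_ps"]).to_numpy()
        fwhm_a, _ = fwhm_fwtm(build_histogram(d_a, 25.0))
        assert curve["fwhm_ps"].iloc[1] == pytest.approx(fwhm_a, rel=1e-9)

    def test_earlier_timestamp_beats_single_pixels(self, bgo_stream):
        """k = 0 improves FWHM and FWTM over either pixel alone."""
        df = bgo_stream
        kmax = float(np.nanmax(np.abs(df["delta_t_ps"]))) + 1.0
        curve = ctr_vs_k(df, [-kmax, 0.0, kmax])
        fwhm = curve.set_index("k_ps")["fwhm_ps"]
        fwtm = curve.set_index("k_ps")["fwtm_ps"]
        assert fwhm[0.0] <= min(fwhm[-kmax], fwhm[kmax])
        assert fwtm[0.0] <= min(fwtm[-kmax], fwtm[kmax]) * 1.02

    def test_dtk_saturation_matches_unselected(self, bgo_stream):
        df = bgo_stream
        dtk_max = float(np.nanmax(np.abs(df["delta_t_ps"]))) + 1.0
        curve = ctr_vs_dtk(df, [dtk_max])
        finite = df["delta_t_ps"].notna()
        d = (
            np.minimum(df["t_a_ps"], df["t_b_ps"]) - df["reference_ps"]
        )[finite].to_numpy()
        fwhm, _ = fwhm_fwtm(build_histogram(d, 25.0))
        assert curve["fwhm_ps"].iloc[0] == pytest.approx(fwhm, rel=1e-9)
        assert curve["n_selected"].iloc[0] == int(finite.sum())


class TestClassification:
    def test_deciles_partition_equally(self, bgo_stream):
        table = classify_deciles(bgo_stream, 10)
        n = table["n_events"].sum()
        assert table["n_events"].between(n // 10 - 1, n // 10 + 1).all()
        assert table["event_fraction"].sum() == pytest.approx(1.0)

    def test_single_group_reproduces_global_ctr(self, bgo_stream):
        table = classify_deciles(bgo_stream, 1)
        finite = bgo_stream["delta_t_ps"].notna()
        d = (
            np.minimum(bgo_stream["t_a_ps"], bgo_stream["t_b_ps"])
            - bgo_stream["reference_ps"]
        )[finite]
        fwhm, _ = fwhm_fwtm(build_histogram(d, 25.0))
        assert table["fwhm_ps"].iloc[0] == pytest.approx(fwhm, rel=1e-9)

    def test_small_input_rejected(self):
        df = pd.DataFrame(
            {
                "delta_t_ps": [1.0, 2.0],
                "t_a_ps": [0.0, 0.0],
                "t_b_ps": [0.0, 0.0],
                "reference_ps": [0.0, 0.0],
            }
        )
        with pytest.raises(ValueError):
            classify_deciles(df, 10)

    def test_kernels_single_photon_number(self):
        df = pd.DataFrame(
            {
                "t_a_ps": np.random.default_rng(1).normal(0, 50, 300),
                "t_b_ps": np.random.default_rng(2).normal(0, 50, 300),
                "reference_ps": np.zeros(300),
                "n_total": np.full(300, 4),
            }
        )
        table = kernels_by_photon_number(df)
        assert len(table) == 1 and table["n_total"].iloc[0] == 4
        assert table["event_fraction"].iloc[0] == 1.0


class TestPairResolutions:
    def test_symmetric_quadrature(self):
        r = solve_pair_resolutions(141.42, 141.42, 141.42)
        assert r == pytest.approx((100.0, 100.0, 100.0), rel=1e-3)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        r1=hyp.floats(10, 300),
        r2=hyp.floats(10, 300),
        r3=hyp.floats(10, 300),
    )
    def test_inverts_forward_quadrature(self, r1, r2, r3):
        """solve ∘ forward-quadrature is the identity to 1e-9 relative."""
        c12 = np.hypot(r1, r2)
        c13 = np.hypot(r1, r3)
        c23 = np.hypot(r2, r3)
        s1, s2, s3 = solve_pair_resolutions(c12, c13, c23)
        assert s1 == pytest.approx(r1, rel=1e-9)
        assert s2 == pytest.approx(r2, rel=1e-9)
        assert s3 == pytest.approx(r3, rel=1e-9)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            solve_pair_resolutions(1.0, 1.0, 10.0)

    def test_reference_subtraction(self):
        assert subtract_reference(186.0, 83.0) == pytest.approx(
            np.sqrt(186.0**2 - 83.0**2)
        )
        with pytest.raises(ValueError):
            subtract_reference(50.0, 83.0)


class TestEnergyTools:
    def test_photopeak_events_all_retained(self, bgo_stream):
        kept = energy_window_filter(bgo_stream, 400.0, 600.0)
        assert len(kept) > 0.95 * len(bgo_stream)

    def test_out_of_window_removed(self):
        df = pd.DataFrame({"energy_kev": [300.0, 511.0, 650.0]})
        assert energy_window_filter(df, 400.0, 600.0)["energy_kev"].tolist() == [511.0]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            energy_window_filter(pd.DataFrame({"energy_kev": []}), 600.0, 400.0)

    def test_continuum_retained_fraction(self):
        """With a photopeak/continuum mixture, the 400-600 keV window keeps
        (up to Poisson-smeared leakage) the photopeak fraction."""
        phys = st.PhysicsConfig(energy_mode="compton_continuum")
        df = st.simulate_and_process(physics=phys, n_events=4000, seed=33)
        frac = len(energy_window_filter(df)) / len(df)
        assert frac == pytest.approx(phys.photopeak_fraction, abs=0.05)

    def test_calibration_unit_charge(self):
        assert calibrate_energy(np.full(500, 2.0)) == pytest.approx(255.5)

    def test_calibration_mixture_recovery(self):
        """Photopeak location recovered within 1% on a continuum+photopeak
        charge mixture of 1e4 events."""
        rng = np.random.default_rng(25)
        peak = 10_000.0
        photo = rng.normal(peak, 0.045 * peak, size=5000)
        cont = rng.uniform(0.1 * peak, 0.67 * peak, size=5000)
        factor = calibrate_energy(np.concatenate([photo, cont]))
        assert factor == pytest.approx(511.0 / peak, rel=0.01)

    def test_calibration_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_energy([])

    def test_tdiff_by_energy_single_bin_is_global(self, bgo_stream):
        out = tdiff_by_energy(bgo_stream, [0.0, 700.0])
        assert len(out) == 1
        assert out[0].hist.n_events == int(bgo_stream["delta_t_ps"].notna().sum())

    def test_tdiff_by_energy_empty_bin(self, bgo_stream):
        out = tdiff_by_energy(bgo_stream, [0.0, 10.0])
        assert out[0].n_events == 0 and out[0].mean_n_total == 0.0

    def test_tdiff_by_energy_unordered_edges_rejected(self, bgo_stream):
        with pytest.raises(ValueError):
            tdiff_by_energy(bgo_stream, [100.0, 50.0])


class TestSidePeakLocator:
    def test_pure_gaussian_has_no_side_peaks(self):
        rng = np.random.default_rng(26)
        h = build_histogram(rng.normal(0, 120, size=100_000), 25.0)
        assert side_peak_locator(h) == []

    def test_synthetic_side_peaks_located(self):
        rng = np.random.default_rng(27)
        center = rng.normal(0, 100, size=50_000)
        side = np.concatenate(
            [rng.normal(-1300, 60, size=4000), rng.normal(1300, 60, size=4000)]
        )
        h = build_histogram(np.concatenate([center, side]), 25.0)
        peaks = side_peak_locator(h, exclusion_ps=400)
        positions = sorted(p for p, _ in peaks)
        assert len(positions) == 2
        assert positions[0] == pytest.approx(-1300, abs=60)
        assert positions[1] == pytest.approx(1300, abs=60)
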