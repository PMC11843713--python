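"""Pulse templates, waveform rendering, crosstalk injection, energy integral."""

import numpy as np
import pytest

import segtof as st
from segtof.events import ORIGIN_OPTICAL_CROSSTALK, EmissionEvent
from segtof.waveform import (
    REFERENCE_AMPLITUDE_MV,
    inject_electronic_crosstalk,
    inject_optical_crosstalk,
    merged_energy_integral,
    render_waveform,
    single_spad_template,
)


class TestSingleSpadTemplate:
    def test_segmented_reference_amplitude(self):
        assert single_spad_template("segmented", 1.0).amplitude == 26.0

    def test_connected_default_factor(self):
        seg = single_spad_template("segmented")
        con = single_spad_template("connected")
        assert con.amplitude == pytest.approx(0.67 * seg.amplitude)

    @pytest.mark.parametrize("bias", [0.25, 0.5, 1.0, 1.7])
    def test_amplitude_ordering_for_any_bias(self, bias):
        """Fig-4-style ordering: nonsegmented < connected < segmented."""
        amps = [
            single_spad_template(m, bias).amplitude
            for m in ("nonsegmented", "connected", "segmented")
        ]
        assert amps[0] < amps[1] < amps[2]

    def test_zero_bias_zero_amplitude(self):
        assert single_spad_template("segmented", 0.0).amplitude == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            single_spad_template("octagonal")

    def test_pulse_peaks_below_one_ns(self):
        tpl = single_spad_template("segmented")
        assert 0 < tpl.peak_time < 1000.0
        t = np.linspace(0, 5000, 2001)
        assert tpl(t).max() == pytest.approx(tpl.amplitude, rel=1e-3)


class TestRenderWaveform:
    def test_no_arrivals_no_noise_is_zero(self):
        w = render_waveform([], single_spad_template(), noise_sigma=0.0)
        assert np.all(w.samples == 0.0)

    def test_single_arrival_peak_matches_template(self):
        tpl = single_spad_template()
        w = render_waveform([0.0], tpl, dt=20.0, noise_sigma=0.0)
        # peak within one-sample discretization of the template maximum
        t_peak_grid = w.times[np.argmax(w.samples)]
        assert abs(t_peak_grid - tpl.peak_time) <= 20.0
        assert w.samples.max() == pytest.approx(tpl.amplitude, rel=0.01)

    def test_superposition_of_coincident_arrivals(self):
        tpl = single_spad_template()
        w1 = render_waveform([100.0], tpl, noise_sigma=0.0, t0=0.0, n_samples=100)
        w2 = render_waveform([100.0, 100.0], tpl, noise_sigma=0.0, t0=0.0, n_samples=100)
        np.testing.assert_allclose(w2.samples, 2 * w1.samples, rtol=1e-12)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            render_waveform([0.0], single_spad_template(), noise_sigma=-1.0)


class TestElectronicCrosstalk:
    def _waves(self):
        tpl = single_spad_template()
        wa = render_waveform([0.0], tpl, noise_sigma=0.0, t0=-500.0, n_samples=80)
        wb = render_waveform([], tpl, noise_sigma=0.0, t0=-500.0, n_samples=80)
        return tpl, wa, wb

    def test_zero_fraction_is_identity(self):
        tpl, wa, wb = self._waves()
        cfg = st.CrosstalkConfig(electronic_amplitude_fraction=0.0)
        oa, ob = inject_electronic_crosstalk(wa, wb, [0.0], [], cfg, tpl)
        assert oa is wa and ob is wb

    def test_quiet_pixel_gets_opposite_polarity_deflection(self):
        tpl, wa, wb = self._waves()
        cfg = st.CrosstalkConfig(electronic_amplitude_fraction=0.5)
        _, ob = inject_electronic_crosstalk(wa, wb, [0.0], [], cfg, tpl)
        assert ob.samples.min() < -0.4 * 0.5 * tpl.amplitude

    def test_threshold_above_crosstalk_blocks_timestamp(self):
        """Raising the leading-edge threshold above the crosstalk amplitude
        removes the crosstalk-induced timestamp in the quiet pixel."""
        tpl = single_spad_template()
        cfg = st.CrosstalkConfig(electronic_amplitude_fraction=0.5)
        wa = render_waveform([0.0], tpl, noise_sigma=0.0, t0=-500.0, n_samples=100)
        wb = render_waveform([], tpl, noise_sigma=0.0, t0=-500.0, n_samples=100)
        _, ob = inject_electronic_crosstalk(wa, wb, [0.0], [], cfg, tpl)
        below = st.leading_edge_timestamp(ob, 0.3 * 0.5 * tpl.amplitude)
        above = st.leading_edge_timestamp(ob, 1.1 * 0.5 * tpl.amplitude)
        assert below is not None
        assert below > cfg.electronic_delay * 0.5  # rides the recovery lobe
        assert above is None

    def test_mismatched_grids_rejected(self):
        tpl, wa, _ = self._waves()
        other = render_waveform([], tpl, noise_sigma=0.0, t0=0.0, n_samples=80)
        with pytest.raises(ValueError):
            inject_electronic_crosstalk(wa, other, [], [], st.CrosstalkConfig(), tpl)


class TestOpticalCrosstalk:
    def _event(self, n=200):
        return EmissionEvent(
            event_id=0,
            deposited_energy_kev=511.0,
            interaction_time_ps=0.0,
            arrivals_a=np.zeros(n),
            arrivals_b=np.empty(0),
            reference_timestamp_ps=0.0,
        )

    def test_zero_probability_is_identity(self):
        ev = self._event()
        out = inject_optical_crosstalk(ev, st.CrosstalkConfig(optical_prob=0.0), 15.0)
        assert out is ev

    def test_secondary_lag_doubles_with_length(self):
        cfg = st.CrosstalkConfig(optical_prob=1.0, optical_jitter=0.0)
        ev = self._event()
        lag1 = inject_optical_crosstalk(ev, cfg, 10.0, np.random.default_rng(1))
        lag2 = inject_optical_crosstalk(ev, cfg, 20.0, np.random.default_rng(1))
        assert np.mean(lag2.arrivals_b) == pytest.approx(
            2 * np.mean(lag1.arrivals_b), rel=1e-12
        )

    def test_lower_probability_reduces_secondary_rate(self):
        ev = self._event(n=2000)
        hi = inject_optical_crosstalk(
            ev, st.CrosstalkConfig(optical_prob=0.2), 15.0, np.random.default_rng(2)
        )
        lo = inject_optical_crosstalk(
            ev, st.CrosstalkConfig(optical_prob=0.02), 15.0, np.random.default_rng(2)
        )
        assert lo.arrivals_b.size < hi.arrivals_b.size

    def test_secondaries_are_tagged(self):
        cfg = st.CrosstalkConfig(optical_prob=1.0)
        out = inject_optical_crosstalk(self._event(5), cfg, 15.0, np.random.default_rng(3))
        assert (out.origins_b == ORIGIN_OPTICAL_CROSSTALK).all()
        assert out.arrivals_b.size == 5


class TestLowpassFilter:
    def test_zero_tau_is_identity(self):
        w = render_waveform([0.0], single_spad_template(), noise_sigma=0.0)
        assert st.lowpass_filter(w, 0.0) is w

    def test_bandwidth_limit_softens_and_delays_the_edge(self):
        tpl = single_spad_template()
        w = render_waveform([0.0], tpl, dt=20.0, noise_sigma=0.0,
                            t0=-200.0, n_samples=600)
        f = st.lowpass_filter(w, 300.0)
        assert f.samples.max() < w.samples.max()
        from segtof.trigger import leading_edge_timestamp

        assert leading_edge_timestamp(f, 5.0) > leading_edge_timestamp(w, 5.0)
        # unit DC gain: the full integral is preserved up to trace truncation
        assert f.samples.sum() == pytest.approx(w.samples.sum(), rel=0.05)


class TestMergedEnergyIntegral:
    def test_zero_traces_integrate_to_zero(self):
        tpl = single_spad_template()
        wa = render_waveform([], tpl, noise_sigma=0.0, t0=0.0, n_samples=50)
        wb = render_waveform([], tpl, noise_sigma=0.0, t0=0.0, n_samples=50)
        assert merged_energy_integral(wa, wb) == 0.0

    @pytest.mark.parametrize("n", [1, 7, 25, 50])
    def test_linearity_in_photon_count(self, n):
        """Total charge = n x single-pulse integral for split pulse trains."""
        tpl = single_spad_template()
        t0, ns = -200.0, 2000  # long window captures the full decay
        # sample-aligned arrivals so every pulse has the identical sampled
        # integral (off-grid phases differ at the rectangular-rule level)
        arrivals = 80.0 * np.arange(n, dtype=float)
        wa = render_waveform(arrivals[: n // 2], tpl, noise_sigma=0.0, t0=t0, n_samples=ns)
        wb = render_waveform(arrivals[n // 2 :], tpl, noise_sigma=0.0, t0=t0, n_samples=ns)
        single = render_waveform([0.0], tpl, noise_sigma=0.0, t0=t0, n_samples=ns)
        zero = render_waveform([], tpl, noise_sigma=0.0, t0=t0, n_samples=ns)
        expected = n * merged_energy_integral(single, zero)
        assert merged_energy_integral(wa, wb) == pytest.approx(expected, rel=1e-6)

    def test_render_then_integrate_commutes_with_per_arrival_sum(self):
        tpl = single_spad_template()
        rng = np.random.default_rng(4)
        arrivals = rng.uniform(0, 1000, size=20)
        zero = render_waveform([], tpl, noise_sigma=0.0, t0=-100.0, n_samples=1500)
        whole = render_waveform(arrivals, tpl, noise_sigma=0.0, t0=-100.0, n_samples=1500)
        per_arrival = sum(
            merged_energy_integral(
                render_waveform([a], tpl, noise_sigma=0.0, t0=-100.0, n_samples=1500),
                zero,
            )
            for a in arrivals
        )
        assert merged_energy_integral(whole, zero) == pytest.approx(
            per_arrival, rel=1e-9
        )

    def test_mismatched_grids_rejected(self):
        tpl = single_spad_template()
        wa = render_waveform([], tpl, noise_sigma=0.0, t0=0.0, n_samples=50)
        wb = render_waveform([], tpl, noise_sigma=0.0, t0=0.0, n_samples=60)
        with pytest.raises(ValueError):
            merged_energy_integral(wa, wb)
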