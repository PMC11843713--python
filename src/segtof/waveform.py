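"""SPAD pulse templates, waveform rendering, crosstalk and charge integrals.

A fired SPAD contributes one biexponential voltage pulse; a pixel waveform
is the linear superposition of one pulse per detected photon plus Gaussian
noise, sampled at 80 ps (12.5 GS/s) by default.  Segmentation matters
through the template: a segmented pixel gives the largest, fastest pulse
(26 mV reference amplitude); electrically connecting two pixels or using a
single non-segmented SiPM of the same total area increases capacitance and
yields smaller, slower pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .config import CrosstalkConfig
from .events import ORIGIN_OPTICAL_CROSSTALK, EmissionEvent

__all__ = [
    "PulseTemplate",
    "Waveform",
    "single_spad_template",
    "render_waveform",
    "inject_electronic_crosstalk",
    "inject_optical_crosstalk",
    "lowpass_filter",
    "merged_energy_integral",
]

# (amplitude factor, rise tau ps, decay tau ps) per segmentation mode;
# amplitude factors are tunable defaults encoding the observed ordering
# nonsegmented < connected < segmented, anchored at 26 mV for segmented
_MODE_DEFAULTS = {
    "segmented": (1.0, 100.0, 800.0),
    "connected": (0.67, 200.0, 1200.0),
    "nonsegmented": (0.45, 300.0, 1600.0),
}
REFERENCE_AMPLITUDE_MV = 26.0


@dataclass(frozen=True)
class PulseTemplate:
    """Single-SPAD pulse: amplitude-normalized biexponential.

    ``p(t) = amplitude * (exp(-t/decay_tau) - exp(-t/rise_tau)) / peak``
    for t >= 0, where ``peak`` normalizes the maximum to 1.
    """

    amplitude: float
    rise_tau: float
    decay_tau: float
    segmentation_mode: str = "segmented"
    bias_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")

    @property
    def peak_time(self) -> float:
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * np.log(d / r)

    @property
    def _norm(self) -> float:
        tp = self.peak_time
        return np.exp(-tp / self.decay_tau) - np.exp(-tp / self.rise_tau)

    def __call__(self, t) -> np.ndarray:
        """Evaluate the pulse at times ``t`` (ps) after the SPAD firing."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        m = t > 0
        tm = t[m]
        out[m] = np.exp(-tm / self.decay_tau) - np.exp(-tm / self.rise_tau)
        return self.amplitude / self._norm * out

    def full_integral(self) -> float:
        """Analytic integral of the pulse over all time, mV*ps."""
        return self.amplitude / self._norm * (self.decay_tau - self.rise_tau)


@dataclass
class Waveform:
    """Uniformly sampled voltage trace: samples[i] at t0 + i*dt (ps, mV)."""

    t0: float
    dt: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    def same_grid(self, other: "Waveform") -> bool:
        return (
            self.dt == other.dt
            and self.t0 == other.t0
            and self.samples.size == other.samples.size
        )

    def copy(self) -> "Waveform":
        return Waveform(self.t0, self.dt, self.samples.copy())


def single_spad_template(
    segmentation_mode: str = "segmented", bias_scale: float = 1.0
) -> PulseTemplate:
    """Reference single-SPAD pulse template for a readout configuration.

    The segmented template has the 26 mV reference amplitude; connected and
    nonsegmented templates are scaled down (defaults 0.67 and 0.45) with
    slower rise/decay.  Amplitude scales linearly with ``bias_scale`` (an
    overvoltage proxy), preserving the mode ordering for any bias > 0.
    """
    if segmentation_mode not in _MODE_DEFAULTS:
        raise ValueError(f"unknown segmentation_mode {segmentation_mode!r}")
    if bias_scale < 0:
        raise ValueError("bias_scale must be >= 0")
    factor, rise, decay = _MODE_DEFAULTS[segmentation_mode]
    return PulseTemplate(
        amplitude=REFERENCE_AMPLITUDE_MV * factor * bias_scale,
        rise_tau=rise,
        decay_tau=decay,
        segmentation_mode=segmentation_mode,
        bias_scale=bias_scale,
    )


def _add_pulses(samples: np.ndarray, times: np.ndarray, arrivals, template, scale=1.0):
    """Accumulate template pulses (in place) at each arrival time."""
    arrivals = np.asarray(arrivals, dtype=float)
    arrivals = arrivals[arrivals < times[-1]]  # pulses are causal
    if arrivals.size == 0:
        return
    # broadcast in blocks to bound the (n_arrivals x n_samples) temporary
    block = max(1, 65536 // max(times.size, 1))
    for lo in range(0, arrivals.size, block):
        chunk = arrivals[lo : lo + block]
        samples += scale * template(times[None, :] - chunk[:, None]).sum(axis=0)


def render_waveform(
    arrivals,
    template: PulseTemplate,
    dt: float = 80.0,
    noise_sigma: float = 0.0,
    rng=None,
    t0: float | None = None,
    n_samples: int | None = None,
) -> Waveform:
    """Render a pixel waveform as a superposition of single-SPAD pulses.

    ``t0``/``n_samples`` fix the sampling grid; when omitted the grid spans
    [min(arrival) - 5*dt, max(arrival) + 5*decay_tau].  Gaussian noise of
    ``noise_sigma`` mV is added per sample.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    arrivals = np.asarray(arrivals, dtype=float)
    if t0 is None:
        t0 = float(arrivals.min() - 5 * dt) if arrivals.size else 0.0
    if n_samples is None:
        t_end = (
            float(arrivals.max() + 5 * template.decay_tau)
            if arrivals.size
            else t0 + 10 * dt
        )
        n_samples = max(int(np.ceil((t_end - t0) / dt)) + 1, 2)
    samples = np.zeros(n_samples)
    times = t0 + dt * np.arange(n_samples)
    _add_pulses(samples, times, arrivals, template)
    if noise_sigma > 0:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        samples += rng.normal(0.0, noise_sigma, size=n_samples)
    return Waveform(t0=t0, dt=dt, samples=samples)


def inject_electronic_crosstalk(
    waveform_a: Waveform,
    waveform_b: Waveform,
    firings_a,
    firings_b,
    cfg: CrosstalkConfig,
    template: PulseTemplate,
) -> tuple[Waveform, Waveform]:
    """Add common-cathode electronic crosstalk between the two pixels.

    Every SPAD firing in one pixel adds to the *other* pixel a bipolar
    transient: a negative (opposite-polarity) lobe at the firing time and a
    positive recovery lobe ``cfg.electronic_delay`` later, both with
    amplitude ``cfg.electronic_amplitude_fraction`` of the single-SPAD
    pulse.  With fraction 0 the inputs are returned unchanged.
    """
    if not waveform_a.same_grid(waveform_b):
        raise ValueError("waveforms must share the same sampling grid")
    frac = cfg.electronic_amplitude_fraction
    if frac == 0:
        return waveform_a, waveform_b
    out_a, out_b = waveform_a.copy(), waveform_b.copy()
    for firings, victim in ((np.asarray(firings_a, float), out_b),
                            (np.asarray(firings_b, float), out_a)):
        times = victim.times
        _add_pulses(victim.samples, times, firings, template, scale=-frac)
        _add_pulses(
            victim.samples, times, firings + cfg.electronic_delay, template, scale=frac
        )
    return out_a, out_b


def inject_optical_crosstalk(
    event: EmissionEvent, cfg: CrosstalkConfig, crystal_length: float, rng=None
) -> EmissionEvent:
    """Spawn optical-crosstalk arrivals in the opposite pixel.

    Each detected photon emits, with probability ``cfg.optical_prob``, a
    secondary photon that crosses the crystal to the other pixel with a lag
    of ``cfg.optical_delay_per_mm * crystal_length`` plus Gaussian jitter.
    Secondaries are tagged ``optical_crosstalk``.  Returns a new event;
    with probability 0 the original event is returned.
    """
    if cfg.optical_prob == 0:
        return event
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lag = cfg.optical_delay_per_mm * crystal_length

    def secondaries(src: np.ndarray) -> np.ndarray:
        n = int(rng.binomial(src.size, cfg.optical_prob)) if src.size else 0
        if n == 0:
            return np.empty(0)
        parents = rng.choice(src, size=n, replace=False)
        jit = rng.normal(0.0, cfg.optical_jitter, size=n) if cfg.optical_jitter else 0.0
        return parents + lag + jit

    sec_to_b = secondaries(event.arrivals_a)
    sec_to_a = secondaries(event.arrivals_b)
    return event.replace(
        arrivals_a=np.concatenate([event.arrivals_a, sec_to_a]),
        origins_a=np.concatenate(
            [event.origins_a, np.full(sec_to_a.size, ORIGIN_OPTICAL_CROSSTALK, np.int8)]
        ),
        arrivals_b=np.concatenate([event.arrivals_b, sec_to_b]),
        origins_b=np.concatenate(
            [event.origins_b, np.full(sec_to_b.size, ORIGIN_OPTICAL_CROSSTALK, np.int8)]
        ),
    )


def lowpass_filter(waveform: Waveform, tau: float) -> Waveform:
    """Apply a single-pole RC low-pass (time constant ``tau`` ps) to model
    the finite analog bandwidth of the readout chain.

    Discrete first-order filter ``y[i] = a*y[i-1] + (1-a)*x[i]`` with
    ``a = exp(-dt/tau)``; ``tau <= 0`` returns the input unchanged.
    """
    if tau <= 0:
        return waveform
    a = np.exp(-waveform.dt / tau)
    y = lfilter([1.0 - a], [1.0, -a], waveform.samples)
    return Waveform(waveform.t0, waveform.dt, y)


def merged_energy_integral(waveform_a: Waveform, waveform_b: Waveform) -> float:
    """Integral of the merged (sample-wise summed) energy signal, mV*ps.

    Rectangular rule (sum * dt), exactly linear in the superposed pulses.
    """
    if not waveform_a.same_grid(waveform_b):
        raise ValueError("waveforms must share the same sampling grid")
    return float((waveform_a.samples + waveform_b.samples).sum() * waveform_a.dt)
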