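"""Configuration containers for the segmented-readout TOF-PET pipeline.

Unit conventions used throughout the package: times in picoseconds (ps),
energies in keV, lengths in mm, voltages in mV, charges in mV*ps.

All containers are plain dataclasses with eager validation; they can be
round-tripped through YAML or JSON documents (`load_config`/`dump_config`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "PhysicsConfig",
    "ReadoutConfig",
    "CrosstalkConfig",
    "AnalysisConfig",
    "load_config",
    "dump_config",
]

# Compton edge for 511 keV photons: 2*E^2 / (m_e c^2 + 2E) = 340.7 keV
COMPTON_EDGE_511_KEV = 2 * 511.0**2 / (511.0 + 2 * 511.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class PhysicsConfig:
    """Emission, transport and detection model of one BGO crystal pixel
    read out by two segmented SiPM pixels (A and B).

    The defaults describe a 511 keV annihilation photon stopping in BGO:
    ~17 Cherenkov photons produced promptly and ~4000 scintillation photons
    emitted with a slow decay.  Scintillation kinetics and per-mm transport
    numbers are literature-style placeholders and deliberately configurable.

    Parameters
    ----------
    mean_cherenkov_photons : mean produced Cherenkov photons at 511 keV.
    mean_scint_photons : mean produced scintillation photons at 511 keV.
    scint_decay_tau : scintillation decay constant, ps (300 ns for BGO).
    scint_rise_tau : scintillation rise constant, ps.
    cherenkov_spread : width of the prompt Cherenkov emission burst, ps.
    light_yield_energy_scaling : "linear" — scintillation yield scales
        linearly with deposited energy.
    cherenkov_energy_scaling : "linear" (mean ∝ E) or "linear_threshold"
        (mean ∝ max(0, E - threshold), anchored to the 511 keV mean); the
        threshold mimics the Cherenkov production threshold of the recoil
        electron.
    cherenkov_threshold_kev : energy offset for the threshold rule.
    crystal_length : crystal length, mm.
    transit_spread_per_mm : mean of the exponential photon transit-delay
        tail per mm of crystal, ps/mm.
    loss_per_mm : bulk/surface loss rate; survival *= exp(-loss_per_mm * L).
    detection_prob : photon detection probability before length-dependent
        loss (PDE x optical transfer), in [0, 1].
    pixel_split_fraction : probability that a detected photon lands on
        pixel A (0.5 for a symmetric segmentation).
    reflector_mode : "white" (reflective wrap) or "black" (absorbing wrap:
        extra photon loss, narrower transit spread).
    black_survival_factor, black_spread_factor : multipliers applied in
        black mode.
    energy_mode : "photopeak_only" (all events deposit 511 keV) or
        "compton_continuum" (photopeak fraction at 511 keV plus a flat
        continuum up to the Compton edge).
    photopeak_fraction : photopeak weight in compton_continuum mode.
    continuum_min_kev : lower edge of the flat continuum.
    """

    mean_cherenkov_photons: float = 17.0
    mean_scint_photons: float = 4000.0
    scint_decay_tau: float = 300_000.0
    scint_rise_tau: float = 300.0
    cherenkov_spread: float = 2.0
    light_yield_energy_scaling: str = "linear"
    cherenkov_energy_scaling: str = "linear_threshold"
    cherenkov_threshold_kev: float = 50.0
    crystal_length: float = 15.0
    transit_spread_per_mm: float = 5.0
    loss_per_mm: float = 0.02
    detection_prob: float = 0.24
    pixel_split_fraction: float = 0.5
    reflector_mode: str = "white"
    black_survival_factor: float = 0.6
    black_spread_factor: float = 0.5
    energy_mode: str = "photopeak_only"
    photopeak_fraction: float = 0.5
    continuum_min_kev: float = 50.0

    def __post_init__(self) -> None:
        _require(self.mean_cherenkov_photons >= 0, "photon means must be >= 0")
        _require(self.mean_scint_photons >= 0, "photon means must be >= 0")
        _require(self.scint_decay_tau > 0, "time constants must be > 0")
        _require(self.scint_rise_tau > 0, "time constants must be > 0")
        _require(self.cherenkov_spread >= 0, "cherenkov_spread must be >= 0")
        _require(self.crystal_length > 0, "crystal_length must be > 0")
        _require(self.transit_spread_per_mm >= 0, "transit_spread_per_mm must be >= 0")
        _require(self.loss_per_mm >= 0, "loss_per_mm must be >= 0")
        _require(0.0 <= self.detection_prob <= 1.0, "detection_prob must be in [0, 1]")
        _require(
            0.0 <= self.pixel_split_fraction <= 1.0,
            "pixel_split_fraction must be in [0, 1]",
        )
        _require(
            self.reflector_mode in ("white", "black"),
            f"unknown reflector_mode {self.reflector_mode!r}",
        )
        _require(
            self.energy_mode in ("photopeak_only", "compton_continuum"),
            f"unknown energy_mode {self.energy_mode!r}",
        )
        _require(
            self.cherenkov_energy_scaling in ("linear", "linear_threshold"),
            f"unknown cherenkov_energy_scaling {self.cherenkov_energy_scaling!r}",
        )
        _require(
            self.light_yield_energy_scaling == "linear",
            f"unknown light_yield_energy_scaling {self.light_yield_energy_scaling!r}",
        )
        _require(0.0 <= self.photopeak_fraction <= 1.0, "photopeak_fraction in [0, 1]")

    @property
    def survival_prob(self) -> float:
        """Per-photon survival probability after length-dependent loss."""
        p = self.detection_prob * math.exp(-self.loss_per_mm * self.crystal_length)
        if self.reflector_mode == "black":
            p *= self.black_survival_factor
        return p

    @property
    def transit_spread(self) -> float:
        """Mean of the exponential transit-delay tail, ps."""
        s = self.transit_spread_per_mm * self.crystal_length
        if self.reflector_mode == "black":
            s *= self.black_spread_factor
        return s


@dataclass
class ReadoutConfig:
    """Digitizer and discriminator settings.

    dt defaults to 80 ps (12.5 GS/s).  The recorded trace spans
    [-trace_pre, +trace_post] ps around the annihilation interaction time,
    long enough to contain every trigger used in the timing analysis.
    """

    dt: float = 80.0
    noise_sigma: float = 1.5
    threshold: float = 10.0
    trace_pre: float = 2_000.0
    trace_post: float = 10_000.0
    segmentation_mode: str = "segmented"
    bias_scale: float = 1.0
    k_margin: float = 0.0
    lowpass_tau: float = 0.0  # single-pole bandwidth limit, ps; 0 = off

    def __post_init__(self) -> None:
        _require(self.dt > 0, "dt must be > 0")
        _require(self.noise_sigma >= 0, "noise_sigma must be >= 0")
        _require(self.threshold > 0, "threshold must be > 0")
        _require(self.trace_pre >= 0 and self.trace_post > 0, "trace window invalid")
        _require(self.bias_scale >= 0, "bias_scale must be >= 0")


@dataclass
class CrosstalkConfig:
    """Inter-pixel crosstalk model.

    Electronic crosstalk (common-cathode current sinking) is injected at
    waveform level: each fired SPAD in one pixel adds, to the other pixel, a
    bipolar transient — an opposite-polarity (negative) lobe at the firing
    time followed by a positive recovery lobe ``electronic_delay`` later.
    The recovery lobe is what a leading-edge discriminator can trigger on
    when the threshold sits below ``electronic_amplitude_fraction`` of the
    single-SPAD amplitude; its lag sets a crystal-length-independent side
    peak in the trigger-time-difference histogram.

    Optical crosstalk (light emitted by avalanching SPADs re-entering the
    crystal) is injected at arrival level: each detected photon spawns, with
    ``optical_prob``, a secondary arrival in the opposite pixel lagged by
    ``optical_delay_per_mm * crystal_length`` (plus jitter), so its side
    peak moves outward with crystal length.
    """

    electronic_amplitude_fraction: float = 0.0
    electronic_delay: float = 1_300.0
    optical_prob: float = 0.0
    optical_delay_per_mm: float = 50.0
    optical_jitter: float = 30.0

    def __post_init__(self) -> None:
        _require(
            0.0 <= self.electronic_amplitude_fraction <= 1.0,
            "electronic_amplitude_fraction must be in [0, 1]",
        )
        _require(0.0 <= self.optical_prob <= 1.0, "optical_prob must be in [0, 1]")
        _require(self.electronic_delay >= 0, "electronic_delay must be >= 0")
        _require(self.optical_delay_per_mm >= 0, "optical_delay_per_mm must be >= 0")
        _require(self.optical_jitter >= 0, "optical_jitter must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.electronic_amplitude_fraction > 0 or self.optical_prob > 0


@dataclass
class AnalysisConfig:
    """Timing-analysis settings.

    energy_window defaults to the 400-600 keV photopeak selection;
    bin_width to 25 ps; reference_fwhm documents the reference detector's
    own contribution (83 ps FWHM) for optional quadrature subtraction.
    """

    energy_window: tuple[float, float] = (400.0, 600.0)
    bin_width: float = 25.0
    delta_T_k: float = 300.0
    fwhm_method: str = "gauss_fit"
    reference_fwhm: float = 83.0
    window_integration: float = 1_000.0
    window_trigger: float = 300.0

    def __post_init__(self) -> None:
        self.energy_window = tuple(self.energy_window)  # type: ignore[assignment]
        _require(len(self.energy_window) == 2, "energy_window must be (lo, hi)")
        _require(self.energy_window[0] < self.energy_window[1], "energy window lo < hi")
        _require(self.bin_width > 0, "bin_width must be > 0")
        _require(self.fwhm_method in ("gauss_fit", "direct"), "unknown fwhm_method")
        _require(self.window_integration > 0, "window_integration must be > 0")
        _require(self.window_trigger > 0, "window_trigger must be > 0")


_SECTIONS = {
    "physics": PhysicsConfig,
    "readout": ReadoutConfig,
    "crosstalk": CrosstalkConfig,
    "analysis": AnalysisConfig,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config document into dataclass sections.

    The document may contain any of the keys ``physics``, ``readout``,
    ``crosstalk`` and ``analysis``; missing sections get defaults.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    doc = doc or {}
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = dict(doc.get(name, {}))
        if name == "analysis" and "energy_window" in section:
            section["energy_window"] = tuple(section["energy_window"])
        out[name] = cls(**section)
    return out


def dump_config(configs: dict[str, Any], path: str | Path) -> None:
    """Write dataclass config sections to YAML (or JSON for .json paths)."""
    doc = {}
    for name, cfg in configs.items():
        d = dataclasses.asdict(cfg)
        if "energy_window" in d:
            d["energy_window"] = list(d["energy_window"])
        doc[name] = d
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
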