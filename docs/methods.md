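# Methods

This note documents the physical model behind the `segtof` Monte Carlo,
the analysis estimators, the parameter defaults and their rationale, and
what the simulations do and do not establish about real detectors.

## Emission and transport model

One coincidence event deposits energy `E` in a BGO crystal pixel read out
by two segmented SiPM pixels (A, B).  Photon production is Poisson:

- **Cherenkov**: mean 17 at 511 keV, emitted uniformly within
  `cherenkov_spread` (default 2 ps) of the interaction.  The yield scales
  with deposited energy through a configurable rule; the default
  `linear_threshold` rule, `mean ∝ max(0, E − 50 keV)` anchored at
  511 keV, encodes the Cherenkov production threshold of the recoil
  electron.  Only monotonicity is physically established; the linear form
  is this package's choice.
- **Scintillation**: mean 4000 at 511 keV, linear in energy.  Emission
  times follow the biexponential law
  `f(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)`, sampled exactly as the sum of an
  exponential decay draw and an exponential rise delay.  Defaults
  `τ_d = 300 ns`, `τ_r = 300 ps` are literature-style BGO placeholders and
  deliberately configurable, not asserted values.

Transport to the photodetector is modeled statistically, not by ray
tracing.  Each photon survives with probability
`detection_prob × exp(−loss_per_mm × L)` (PDE × optical transfer with a
length-dependent loss), is assigned to pixel A with
`pixel_split_fraction` (0.5 for the symmetric segmentation), and is
delayed by an exponential transit tail of mean
`transit_spread_per_mm × L` that stands in for internal-reflection path
differences.  A black (absorbing) wrap multiplies survival by 0.6 and
narrows the transit tail by 0.5.  The reference detector is modeled at
timestamp level only: a Gaussian jitter of 83 ps FWHM on the interaction
time, matching how a characterized reference enters a coincidence
measurement.

**Default calibration.** With `detection_prob = 0.24` and the 15 mm
default crystal the simulated stream reproduces the operating point the
analysis is designed around: mean initial photon number ≈ 3.9
(unconditional) and a trigger-time-difference distribution spanning
roughly ±3000 ps centered at 0.  The conditional mean inside
|ΔT| ≤ 300 ps comes out ≈ 4.7.  These defaults were fixed once against
those two anchors and are not tuned per analysis.

## Waveforms and crosstalk

A fired SPAD contributes an amplitude-normalized biexponential pulse;
segmentation enters through the template: segmented 26 mV (rise 100 ps /
decay 800 ps), AB-connected 0.67 × 26 mV and slower, non-segmented
0.45 × 26 mV and slowest — the capacitance ordering
nonsegmented < connected < segmented holds for any bias scale.  The
amplitude ratios are tunable defaults; only the ordering is treated as
established.  Pixel waveforms are linear superpositions of one pulse per
detected photon plus white Gaussian noise (1.5 mV), sampled at 80 ps
(12.5 GS/s).  Records span −2 ns…+10 ns around the interaction — wide
enough to contain every trigger used in the timing analysis at the
default operating point.

**Electronic crosstalk** (common-cathode current sinking) is injected at
waveform level.  A purely opposite-polarity pulse could never produce a
leading-edge timestamp, yet the observed second side peaks are
threshold-sensitive crosstalk triggers; the model therefore uses a
bipolar transient per fired SPAD: a negative lobe at the firing time and
a positive recovery lobe `electronic_delay` (default 1300 ps) later, both
at `electronic_amplitude_fraction` of the single-SPAD amplitude.  This
reproduces all three signatures: opposite-polarity deflection in the
quiet pixel, side peaks near ±1300 ps independent of crystal length, and
no crosstalk timestamp once the threshold exceeds the crosstalk
amplitude.

**Optical crosstalk** (avalanche light re-entering the crystal) is
injected at arrival level: each detected photon spawns, with
`optical_prob`, a secondary arrival in the opposite pixel lagged by
`optical_delay_per_mm × L` plus 30 ps jitter.  Its side-peak offset
scales with crystal length, the discriminating signature.  The default
lag of 50 ps/mm is an effective path-length parameter chosen to separate
the optical peak cleanly from the central core at desk-scale statistics;
the crosstalk probabilities default to 0 (off) and the studies that need
them switch them on explicitly (0.05–0.12).

**Energy.**  The merged energy signal is the sample-wise sum of the two
pixel traces; its integral is linear in the photon count.  Because the
digitized records are truncated ~10 ns after onset while BGO emits for
~1 µs, the pipeline computes each event's full-pulse charge analytically
as `n_detected × single-pulse integral` — identical to integrating an
untruncated trace in a linear noise-free readout, with the
energy-resolution-dominating Poisson fluctuation of `n_detected` retained.
The photopeak of the charge histogram is then anchored at 511 keV and
events are selected in the 400–600 keV window.

## Triggering and photon counting

Timestamps come from leading-edge discrimination (default 10 mV, below
the 26 mV single-SPAD amplitude) with linear interpolation between the
bracketing samples.  The adaptive pickoff selects
`T_A if T_A − T_B ≤ k else T_B`; at `k = 0` this is the earlier
timestamp.  The margin comparison is implemented one-sided, matching the
selection rule's published behaviour; at the `k = 0` operating point a
symmetric variant is indistinguishable.  One-sided events (one pixel
never crosses threshold) fall back to the defined timestamp and are
excluded from ΔT-based analyses.

Initial photons are counted by integrating each pixel's trace over
[trigger, trigger + 1 ns) — each pixel's *own* trigger; a config switch
is unnecessary because the 300 ps window rule removes the events where
the distinction matters.  The charges of a stream form a periodic grid
whose pitch (the single-photon charge) is estimated from the smoothed
charge histogram's peak spacing (median of consecutive peak distances;
single cluster → the cluster location).  Counts are the nearest
non-negative integer of charge/pitch.  If one pixel triggers more than
300 ps (strict inequality) after the other, its count is zeroed: no
prompt photons reached it.  Photons arriving late in the window
contribute only partial charge (their tails extend past the window),
which produces the between-grid smear; the peak-spacing estimator is
robust to it.

## Timing estimators

Histograms default to 25 ps bins.  FWHM comes either from a Gaussian fit
to the histogram core (contiguous bins above 25% of the maximum) or from
direct interpolation; FWTM is always measured directly at 10% of the
peak height, because the mixed Cherenkov/scintillation response has far
heavier tails than a Gaussian and a core fit would misstate them.  Direct
interpolation operates on a lightly smoothed ([1,2,3,2,1]/9 kernel),
zero-padded curve: smoothing suppresses premature level crossings from
bin shot noise (without it the Gaussian FWTM/FWHM ratio biases ~1.5%
high), and padding handles sharp-edged distributions whose first bin
already exceeds the 10% level.  CTR is reported as measured, reference
jitter included; `subtract_reference` provides optional quadrature
subtraction.

**Locating the optimal pickoff margin.**  The FWHM-vs-k sweep of a
symmetric detector is a shallow bowl: the 25 ps grid neighbours of the
optimum differ by ~0.1 ps in expectation, far below the ~0.3–0.5 ps
statistical uncertainty of one FWHM estimate, so the raw grid argmin of a
single sweep is noise-dominated.  `optimal_margin` therefore fits a
quadratic to the measured curve within ±125 ps of the raw argmin and
snaps the vertex to the grid; the acceptance script additionally averages
sweeps over independent replicate streams (24 × 30 000 events) before
locating the minimum.  Both are standard noise-aware treatments of a
measured optimum; no symmetrization or prior on k = 0 is applied.

**Classification.**  Decile classes partition events by |ΔT| quantiles
with stable-order tie breaking; per-class FWHM/FWTM form the multikernel
table.  Kernels are also keyed by the total initial photon number; groups
under 50 events report NaN widths rather than unstable fits.

**Pair resolutions.**  `CTR_ij² = R_i² + R_j²` is solved exactly;
inconsistent triples (negative solved R²) raise.

## Problem sizes and study configurations

Test and acceptance runs use 10⁴–10⁵ simulated coincidences — enough to
resolve every directional effect studied while keeping full-suite runtime
at minutes.  Two studies use dedicated configurations: the side-peak
length study enables optical crosstalk at 0.12 so both side peaks are
measurable at 12 000 events; the photon-statistics scaling study uses
scintillation-only streams (N = 8k…64k emitted photons, unit detection,
no transit spread, 20 ps sampling, no reference jitter) so that the
measured FWHM ∝ N^(−1/2) photon-statistics law is not floored by
unrelated jitter terms or sampling-interpolation distortion.

## What the simulations do not show

The generator reproduces the *statistical structure* the analysis relies
on (Poisson photon counts and thinning, prompt-vs-slow emission,
length-dependent loss and transit spread, segmentation pulse shapes,
crosstalk signatures), not a validated optical model of any physical
detector.  Absolute CTR values depend on the real crystal, SiPM and
electronics and are not comparable to hardware measurements; directional
results (what improves when ΔT_k shrinks, when crystals shorten, when
initial photon counts rise) are the transferable content.  Dark counts,
afterpulsing, SPAD-level spatial structure and wavelength-resolved PDE
are out of scope; analog bandwidth is available only as an optional
single-pole low-pass (`ReadoutConfig.lowpass_tau`, off by default).  Energy deposition
is photopeak-only by default; the flat-continuum mode supports
energy-window studies but is not a physical Compton transport model.
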