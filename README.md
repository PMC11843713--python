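# segtof

Event characterization for **segmented-SiPM readout of hybrid
Cherenkov/scintillation TOF-PET detectors**.

## The problem

Bismuth germanate (BGO) is a dense PET scintillator that is also a
Cherenkov radiator: a 511 keV annihilation photon produces a prompt burst
of ~17 Cherenkov photons alongside ~4000 slow scintillation photons.
The Cherenkov photons carry picosecond-scale timing information, but their
small, fluctuating number makes the timing response event-dependent: some
events are triggered by a prompt Cherenkov bunch, others by late, sparse
scintillation light, so a single coincidence-timing-resolution (CTR)
kernel describes the detector poorly.

Splitting the SiPM readout of one crystal into **two segmented pixels A
and B** yields two timestamps and two charges per event.  This package
implements the full analysis chain built on that idea, together with a
Monte Carlo generator of coincidence events that stands in for
oscilloscope data:

- **synthetic events** — Poisson Cherenkov/scintillation emission,
  biexponential scintillation kinetics, crystal-length-dependent transport
  loss and transit spread, binomial splitting across the two pixels, and a
  reference detector with 83 ps FWHM Gaussian jitter;
- **waveforms** — segmentation-dependent single-SPAD pulse templates
  (26 mV segmented reference amplitude), linear pulse superposition,
  12.5 GS/s digitization, noise, and electronic/optical inter-pixel
  crosstalk;
- **triggering** — leading-edge discrimination with linear interpolation
  and the adaptive timestamp pickoff
  `T = T_A if T_A − T_B ≤ k else T_B` (at `k = 0`: the earlier
  timestamp);
- **initial-photon counting** — 1 ns integration of each timing signal
  from its own trigger, single-photon charge-grid calibration and
  quantization, and the 300 ps trigger-time-window rule that zeroes a
  late-triggering pixel;
- **timing analysis** — CTR histograms with FWHM/FWTM estimation
  (Gaussian-fit core or direct interpolation), CTR vs the pickoff margin
  `k` and vs the trigger-time-difference cut ΔT_k, decile event
  classification into multikernel timing tables, kernels vs initial photon
  number, side-peak location, energy calibration/windows (400–600 keV),
  and the pairwise quadrature system `CTR_ij² = R_i² + R_j²`.

## Worked example

```sh
python examples/01_adaptive_pickoff_sweep.py
```

```
  k_ps    fwhm_ps    fwtm_ps
-500.0 124.049239 301.000153
-250.0 123.597445 297.402800
   0.0 104.688868 249.762492
 250.0 123.191845 297.503378
 500.0 123.178102 300.168069

optimal margin k = 0 ps
CTR at the optimum: FWHM 104.7 ps, FWTM 249.8 ps
```

A 20 000-event symmetric stream is simulated, both pixels are
discriminated, and the CTR (width of `T_pick − T_reference`) is measured
for each pickoff margin `k`.  Large |k| always selects the same single
pixel and is ~20 ps worse in FWHM (and ~50 ps in FWTM) than `k = 0`,
the earlier-timestamp rule — the bowl bottoms out at zero margin.  The
other examples cover initial-photon counting (`02`), the multikernel
decile table (`03`), crosstalk side peaks (`04`) and the pair-resolution
algebra plus energy windows (`05`); each prints the numbers it computes
and a line on what they mean.

A thin CLI wraps the same library for shell use:

```sh
segtof simulate --n-events 2000 --seed 1 --out run/
segtof analyze --events run/events.csv --out run/results/
segtof sweep --events run/events.csv --out run/ctr_vs_k.csv
segtof fixtures --out fixtures/
```

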