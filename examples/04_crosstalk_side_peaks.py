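"""Reproduce the discrete side peaks of the trigger-time-difference
histogram and their crosstalk signatures.

Optical crosstalk (SPAD light re-entering the crystal) produces side peaks
whose offset grows with crystal length; electronic crosstalk (common-
cathode current sinking) produces side peaks at a fixed ~1300 ps recovery
lag independent of length.
"""

import segtof as st
from segtof.timing import build_histogram, side_peak_locator


def side_peaks(length_mm, crosstalk, seed, exclusion):
    phys = st.PhysicsConfig(crystal_length=length_mm)
    df = st.simulate_and_process(
        physics=phys, crosstalk=crosstalk, n_events=12_000, seed=seed
    )
    hist = build_histogram(df["delta_t_ps"].dropna(), 50.0)
    return side_peak_locator(hist, exclusion_ps=exclusion, min_height_fraction=0.02)


optical = st.CrosstalkConfig(optical_prob=0.12)
for length in (10.0, 20.0):
    peaks = side_peaks(length, optical, seed=61, exclusion=350.0)
    print(f"optical crosstalk, {length:.0f} mm crystal:",
          [(round(p), round(h, 3)) for p, h in peaks])

electronic = st.CrosstalkConfig(electronic_amplitude_fraction=0.5)
for length in (15.0, 20.0):
    peaks = side_peaks(length, electronic, seed=62, exclusion=900.0)
    print(f"electronic crosstalk, {length:.0f} mm crystal:",
          [(round(p), round(h, 3)) for p, h in peaks])

print(
    "\nEach entry is (side-peak position in ps, height as a fraction of the"
    "\ncentral peak).  Optical side peaks double from ~±500 to ~±1000 ps when"
    "\nthe crystal doubles; electronic side peaks stay near ±1300-1400 ps."
)
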