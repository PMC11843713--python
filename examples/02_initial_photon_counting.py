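"""Count initially detected photons and relate them to event selection.

The first nanosecond of each pixel's timing signal is integrated and
quantized on the single-photon charge grid.  Events with a small trigger
time difference |T_A - T_B| are Cherenkov-rich and carry more initial
photons — the physical basis for classifying events by temporal photon
density.
"""

import segtof as st
from segtof.photon_counting import poisson_fit

df = st.simulate_and_process(n_events=15_000, seed=7)

inside = df["delta_t_ps"].abs() <= 300.0
fit_all = poisson_fit(df["n_total"])
fit_in = poisson_fit(df.loc[inside, "n_total"])

print(f"single-photon charge grid pitch: {df.attrs['single_photon_charge']:.0f} mV*ps")
print(f"mean initial photon number, all events:        {fit_all.mean:.2f}")
print(f"mean initial photon number, |dT| <= 300 ps:    {fit_in.mean:.2f}")
print(f"fraction of events with a zeroed late pixel:   {df['zeroed_flag'].mean():.3f}")
print(
    "\nSelecting the central trigger-time-difference range raises the mean"
    "\ninitial photon count: small |T_A - T_B| tags events triggered by a"
    "\nprompt Cherenkov burst seen by both pixels."
)
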