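"""Sweep the adaptive timestamp pickoff margin k and find the optimum.

Simulates a symmetric two-pixel BGO detector in coincidence with an 83 ps
FWHM reference, then measures the coincidence timing resolution (CTR) of
adaptive(T_A, T_B, k) - T_reference for each k.  For a symmetric detector
the best margin is k = 0: always take the earlier of the two pixel
timestamps.
"""

import numpy as np

import segtof as st
from segtof.timing import ctr_vs_k, optimal_margin

df = st.simulate_and_process(n_events=20_000, seed=2024)
selected = st.energy_window_filter(df, 400.0, 600.0)

grid = np.arange(-500.0, 501.0, 25.0)
curve = ctr_vs_k(selected, grid)
k_opt = optimal_margin(curve)
row = curve.set_index("k_ps").loc[k_opt]

print(curve[curve.k_ps.isin([-500, -250, 0, 250, 500])].to_string(index=False))
print(f"\noptimal margin k = {k_opt:.0f} ps")
print(f"CTR at the optimum: FWHM {row.fwhm_ps:.1f} ps, FWTM {row.fwtm_ps:.1f} ps")
print(
    "\nThe FWHM/FWTM columns are the widths of the coincidence time-"
    "difference\nhistogram; smaller is better.  The bowl-shaped curve "
    "bottoms out at k = 0,\ni.e. the earlier-timestamp rule."
)
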