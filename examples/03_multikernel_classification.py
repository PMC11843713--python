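"""Build the multikernel table: per-class timing kernels from |T_A - T_B|.

Events are split into 10 equal-count classes by absolute trigger time
difference; each class gets its own FWHM/FWTM timing kernel.  Classes with
small |dT| (Cherenkov-rich) have much sharper kernels than the late
scintillation-triggered classes — the input a multikernel TOF
reconstruction needs.
"""

import segtof as st
from segtof.timing import classify_deciles, ctr_vs_dtk

df = st.simulate_and_process(n_events=20_000, seed=2024)
selected = st.energy_window_filter(df, 400.0, 600.0)

table = classify_deciles(selected, n_groups=10)
print(table[["class_id", "class_rule", "event_fraction", "fwhm_ps", "fwtm_ps"]]
      .to_string(index=False))

sweep = ctr_vs_dtk(selected, [300, 1000, 3000])
print("\nCTR vs trigger-time-difference cut:")
print(sweep.to_string(index=False))
print(
    "\nEach class holds 10% of the events; class 1 (smallest |dT|) has the"
    "\nnarrowest kernel.  Tightening the dT_k cut sharpens the CTR and pulls"
    "\nthe FWTM/FWHM ratio toward the single-Gaussian value 1.83."
)
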