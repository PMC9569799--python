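"""Scaled-down dose x slow-fraction x M ensemble sweep.

Five cells per condition on a reduced grid (the full study design uses
100 cells over 2/4/8 Gy x 20-80% slow x M in {0.14, 0.5} Gy).
"""

from radfate.fate import run_sweep

table = run_sweep(
    doses=(2.0, 8.0), f_slows=(0.2, 0.8), m_values=(0.14, 0.5),
    n_cells=5, seed=1,
)
cols = ["dose_gy", "f_slow", "m_gy_equiv", "apoptosis_pct",
        "mean_arrest_h", "mean_tgfb"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# Apoptosis rises with dose and slow fraction and falls when the ATM
# half-saturation threshold M is raised from 0.14 to 0.5 Gy-equivalents.
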