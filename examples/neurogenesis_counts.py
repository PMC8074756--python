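"""Neurogenesis quantification: per-mm SGZ densities of GFAP+, Sox2+ and
DCX+ cells, percent change versus control and the two-sample t-test.
"""

from abscopal.neurogenesis import marker_summary
from abscopal.synthetic import CellCountSimConfig, simulate_sgz_counts

cfg = CellCountSimConfig(
    n_per_group=6, control_density=12.0, cv=0.1,
    reductions={"GFAP": 37.22, "Sox2": 29.51, "DCX": 32.77},
)
counts = simulate_sgz_counts(cfg, seed=8)
summary = marker_summary(counts)
print(summary.round(4).to_string(index=False))
print("-> each marker's estimated percent reduction tracks the configured")
print("   truth; p-values come from the pooled-variance two-tailed t-test")
print("   on per-animal densities (significant at p <= 0.05).")
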