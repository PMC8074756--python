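"""miRNA differential expression: CPM filtering, dispersion estimation, the
NB exact test and the deregulation criteria (p <= 0.1, |FC| >= 3), followed
by the Venn overlap between two exposure modes.
"""

from abscopal.mirna import CountMatrix, classify_deregulated, cpm_filter, de_table
from abscopal.overlap import venn
from abscopal.synthetic import CountSimConfig, simulate_mirna_counts

# two conditions sharing most of their true signal, like partial- vs
# whole-body exposure at the same dose
shared = {i: 8.0 for i in range(12)}
pbi_cfg = CountSimConfig(n_per_group=3, n_features=400, dispersion=0.05,
                         de_features={**shared, 12: 6.0, 13: -5.0})
wbi_cfg = CountSimConfig(n_per_group=3, n_features=400, dispersion=0.05,
                         de_features=shared)

sets = {}
for name, cfg, seed in [("PBI", pbi_cfg, 1), ("WBI", wbi_cfg, 2)]:
    counts, groups, truth = simulate_mirna_counts(cfg, seed=seed)
    cm = cpm_filter(CountMatrix(counts, groups))
    tab = de_table(cm, "control", "treated")
    sets[name] = classify_deregulated(tab, name=name, modality=name,
                                      dose_gy=2.0, time="15d")
    print(f"{name}: {len(sets[name])} deregulated miRNAs "
          f"(true DE features: {len(cfg.de_features)})")

v = venn([sets["PBI"], sets["WBI"]])
print("shared:", v.intersections[("PBI", "WBI")],
      "| PBI-only:", v.region_count((True, False)),
      "| WBI-only:", v.region_count((False, True)))
print("-> the overlap mirrors the built-in truth: the WBI signal is a subset")
print("   of the PBI signal, so nearly all WBI calls recur in PBI.")
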