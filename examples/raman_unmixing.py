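"""Raman chain: simulate tissue spectra, preprocess, PCA, CLS unmixing and
group comparison of component weights.

Five sham (SI) and five irradiated (WBI) animals are simulated with the
irradiated group's histone-2A concentration raised; the pipeline recovers
the contrast from the noisy, baseline-contaminated spectra.
"""

import numpy as np

from abscopal.raman import cls_fit, compare_component_weights, fit_pca, preprocess
from abscopal.synthetic import (
    MixtureDesign, default_reference_library, simulate_tissue_spectra,
)

library = default_reference_library()
hist = library.names.index("histone 2A")

base = np.full(library.n_components, 0.5)
shifted = base.copy()
shifted[hist] += 0.08  # true histone-2A increase in the irradiated group

design = MixtureDesign(
    group_labels=["SI"] * 5 + ["WBI"] * 5,
    weights=np.vstack([np.tile(base, (5, 1)), np.tile(shifted, (5, 1))]),
    baseline_coeffs=(0.05, -0.05, 0.02, 0.1),  # fluorescence-like cubic
    noise_sd=0.002,
    spectra_per_sample=3,
)
spectra, truth = simulate_tissue_spectra(library, design, seed=20)

processed = [preprocess(s) for s in spectra]

pca = fit_pca(processed, n_components=2)
print("PCA explained variance fractions:", np.round(pca.explained_variance_ratio, 3))

# CLS weights per spectrum, averaged per animal (the experimental unit)
per_animal = {}
for s in processed:
    res = cls_fit(s, library)
    key = (s.metadata["group"], s.metadata["sample"])
    per_animal.setdefault(key, []).append(res.weights[hist])
weights = {"SI": [], "WBI": []}
for (group, _), vals in per_animal.items():
    weights[group].append(np.mean(vals))

cmp = compare_component_weights(weights, "histone 2A", "SI", "WBI")
print(f"histone 2A weight: SI {cmp.mean_a:.4f}+-{cmp.sem_a:.4f}, "
      f"WBI {cmp.mean_b:.4f}+-{cmp.sem_b:.4f}")
print(f"two-sample t p = {cmp.p_value:.2e} {cmp.stars}")
print("-> the irradiated group's higher histone-2A contribution survives the")
print("   full preprocessing chain and is flagged by the group test.")
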