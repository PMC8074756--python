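# abscopal

Tools for the multi-omics analysis of **out-of-field (abscopal) radiation
effects** in mouse hippocampus: when part of the body is irradiated and the
brain is shielded, does the shielded hippocampus still change? The package
implements the full statistical surface such a study needs — Raman spectral
biochemistry, small-count miRNA differential expression, label-free
proteomics significance filtering, subgranular-zone (SGZ) neurogenesis
statistics, and the cross-condition overlap arithmetic that constitutes the
headline comparisons — together with seeded synthetic-data generators so
every stage is testable against known ground truth.

## What it computes

**Raman biochemistry** (`abscopal.raman`). Spectra are wavenumber-calibrated
(e.g. against the 520.7 cm⁻¹ silicon line), divided by the instrument
response, cropped to 400–1800 cm⁻¹, rubberband-baseline corrected (lower
convex hull), vector normalized and Savitzky–Golay smoothed (7-point window,
5th-order polynomial). Processed spectra go to PCA or to classical least
squares (CLS) unmixing against a library of pure-component reference
spectra:

    S = a₁C₁ + a₂C₂ + … + aₙCₙ + E,   Cᵢ ≥ 0

where *S* is the measured spectrum, *aᵢ* the unit-norm reference spectra,
*Cᵢ* the component weights (concentrations) and *E* the residual. Group
contrasts in per-animal mean weights use a two-tailed two-sample t-test with
star annotation (\* p ≤ 0.05, \*\* p ≤ 0.01, \*\*\* p ≤ 0.001).

**miRNA differential expression** (`abscopal.mirna`). Features are kept at
> 1 count per million in ≥ 2 samples; a common negative binomial dispersion
φ (Var = μ + φμ²) is estimated by conditional maximum likelihood; each
feature gets a two-sided NB exact test conditional on its total (binomial
exact test at φ = 0). A feature is deregulated when p ≤ 0.1 and the signed
fold change satisfies FC ≥ 3 (up) or FC ≤ −3 (down). The PCR-array arm
quantifies follow-up panels by ΔΔCt: relative expression 2^−ΔΔCt, t-test on
per-sample ΔCt, deregulated at p ≤ 0.1.

**Proteomics statistics** (`abscopal.proteomics`). Median-ratio
normalization, fold changes as ratios of group median abundances clipped to
[0.01, 100], a background-variance significance test (the stable majority of
proteins estimates the null sd via MAD; z = √n·log FC/σ₀ referred to the
normal), Benjamini–Hochberg adjustment, and the three-gate deregulation
filter: q ≤ 0.05, ≥ 2 unique peptides, FC ≤ 0.77 or ≥ 1.3.

**Neurogenesis counts** (`abscopal.neurogenesis`). GFAP+/Sox2+/DCX+ cells
per mm of SGZ length, sections aggregated per animal, percent change versus
control, pooled-variance t-test at p ≤ 0.05.

**Overlap arithmetic and reporting** (`abscopal.overlap`). Venn
decompositions of deregulation sets (2–4 conditions), shared-fraction
percentages, signed percent changes of set sizes between time points,
shielded-dose arithmetic, and a deterministic consolidated JSON/Markdown
report.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/raman_unmixing.py` simulates five sham (SI) and five
irradiated (WBI) animals whose tissue spectra differ only in their true
histone-2A concentration (plus a cubic fluorescence baseline and noise),
runs the full preprocessing chain and CLS unmixing, and prints:

```
PCA explained variance fractions: [0.29 0.07]
histone 2A weight: SI 0.3158+-0.0004, WBI 0.3521+-0.0005
two-sample t p = 4.99e-12 ***
```

i.e. the histone-2A contribution recovered per animal (mean ± SEM of CLS
weights, arbitrary units) is higher in the irradiated group and the group
test flags it at the three-star level. `python examples/overlap_report.py`
reproduces the headline overlap arithmetic on the published set sizes:

```
shared protein fractions 15d: 48.0% of PBI, 62.0% of WBI
shared protein fractions 6mo: 55.7% of PBI, 24.3% of WBI
persistent miRNAs: 47.4% of the 19 shared
miRNA time course: PBI -52.0 % | WBI -31.6 %
protein time course WBI: 29.0 %
shielded brain dose: 4.0 mGy
```

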