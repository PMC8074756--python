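# Methods

This note documents the models, estimators and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the design
decisions taken where more than one reasonable implementation existed.

## Raman processing chain

The chain runs, in order: axis calibration → instrument-response correction
→ crop to 400–1800 cm⁻¹ → rubberband baseline subtraction → vector
normalization → Savitzky–Golay smoothing. The order matters: the baseline
must be estimated on response-corrected intensities, and normalization
precedes smoothing (smoothing perturbs the norm by well under 5%, and the
pipeline asserts ‖output‖ ∈ [0.95, 1.05]). Swapping normalization and
smoothing changes outputs only at the smoothing-residual level; the order
here is fixed and recorded in each spectrum's metadata stage list.

*Calibration.* One matched peak pair gives a rigid shift; p ≥ 2 pairs give a
least-squares polynomial remap of degree min(p − 1, 3). Degree is capped at
3 because grating distortions are smooth and higher degrees invite Runge
oscillation between anchor lines. A remap that breaks axis monotonicity is
an error, not a warning.

*Instrument response.* Correction is the pointwise division
spectrum × certified/measured on a shared axis. Certified curves of real
luminescence standards are proprietary-shaped, so tests use synthetic
response curves constructed forward-then-inverse.

*Rubberband baseline.* The baseline is the greatest convex minorant of the
(wavenumber, intensity) points — the lower convex hull, computed by
monotone chain in O(n) on the sorted axis — linearly interpolated between
hull vertices and anchored at both endpoints. The corrected spectrum is
exactly zero at hull vertices and nonnegative everywhere, and is invariant
under adding any constant to the input. This removes slowly varying
fluorescence background but, by construction, cannot remove concave
background components; the generator's default cubic baseline is sized so
the convex-minorant removal leaves the peaked signal at ≥ 0.99 correlation
with truth.

*Smoothing.* Savitzky–Golay with a 7-point window and 5th-order polynomial
(scipy's implementation; edge points come from evaluating the terminal
window's polynomial fit rather than truncating, preserving vector length
for PCA). A degree-5 polynomial signal passes through unchanged at interior
points to ≤ 1e-9.

*PCA.* SVD of mean-centered intensities. Sign indeterminacy is resolved by
making the largest-magnitude element of each loading positive, so loading
plots reproduce across runs and platforms.

*CLS unmixing.* Weights minimize ‖S − Σ Cᵢaᵢ‖², by default subject to
Cᵢ ≥ 0 (weights are concentrations; scipy's NNLS), with an unconstrained
least-squares mode for diagnostics. Reference spectra are vector-normalized
before fitting so weights are comparable across components. The residual
E = S − ΣCᵢaᵢ is returned in full and the reconstruction identity holds to
machine precision; in unconstrained mode the residual is orthogonal to the
library span. A rank-deficient library raises an error naming the most
collinear pair. Spectra on a different grid are linearly interpolated onto
the library axis.

*Group testing.* CLS weights are averaged over replicate spectra within an
animal before testing — the animal is the experimental unit; testing
individual spectra would pseudo-replicate. The comparison is a two-tailed
pooled-variance t-test with star codes at p ≤ 0.05/0.01/0.001. A fully
degenerate comparison (both groups constant and equal) reports p = 1 by
convention.

## miRNA differential expression

Counts are modeled negative binomial with Var = μ + φμ²; φ = 0 is the
Poisson limit. Library sizes are equalized by scaling each sample to the
geometric-mean library size and rounding to integer pseudo-counts — an
approximation to quantile adjustment that is exact when library sizes are
equal (the test suite cross-checks p-values against an independent
R implementation of the exact test on an equal-library-size matrix,
agreeing to within 5% on the log scale).

*Dispersion.* A single common φ is estimated by maximizing, over features
and replicated groups, the conditional likelihood of within-group counts
given their group totals (negative-multinomial conditional; the μ parameter
cancels). The Poisson boundary is compared explicitly via the multinomial
limit of the conditional likelihood, and estimates at or below 1e-4 snap to
exactly 0 — below that level dispersion is statistically indistinguishable
from Poisson at realistic depths.

*Exact test.* Conditional on a feature's total t, the group-A sum follows a
negative hypergeometric law with shapes n_A/φ and n_B/φ (binomial
(t, n_A/(n_A+n_B)) at φ = 0). The two-sided p sums the probabilities of all
splits no more likely than the observed one (minimum-likelihood convention),
computed in log space; p is clamped to (0, 1]. Swapping group labels leaves
p unchanged, and for a fixed total p is non-increasing in the extremity of
the split.

*Fold change and calls.* Signed FC uses treated/control CPM means with a
pseudo-offset ε = 0.5 guarding zeros (configurable); ratios r ≥ 1 report as
r, r < 1 as −1/r, so |FC| ≥ 1 always. Deregulation requires raw p ≤ 0.1 and
|FC| ≥ 3 — thresholds inclusive. p-values are deliberately not
multiplicity-adjusted for the call (the criterion is on raw p); a BH column
is emitted for transparency. Under a global null the two gates jointly call
≤ 1% of features.

*ΔΔCt.* Per-sample ΔCt = Ct(feature) − Ct(normalizer); relative expression
= 2^−(meanΔCt_trt − meanΔCt_ctrl); two-tailed t-test on ΔCt; deregulated at
p ≤ 0.1. The normalizer defaults to each sample's global mean Ct and is
recorded in the output; with small panels an explicit stable reference assay
should be supplied, since a panel-wide shift is absorbed by the global mean.

## Proteomics statistics

*Normalization.* Per-sample median-ratio scaling to a geometric-mean
pseudo-reference over proteins quantified in every run. Size factors are
centered to geometric mean 1, which makes the operation exactly idempotent.
This is a table-level stand-in for retention-time-dependent loading
normalization, which needs feature-level data not present in a
post-quantification table; both target the same per-sample loading error.

*Fold change.* Ratio of group median abundances, clipped to [0.01, 100]:
a protein with a zero control median reports 100, a zero treated median
reports 0.01, both-zero is missing. The cap mirrors how label-free
quantification conventionally prints on/off proteins.

*Background-variance test.* Most proteins do not change, so the spread of
their log-ratios estimates the null. The null sd σ₀ is the MAD × 1.4826 of
the √n-scaled log₂-ratios (n = replicates per group); each protein's
z = √n·log₂FC/σ₀ is referred to the standard normal, two-sided. Scaling by
√n *before* taking the MAD keeps the null p-values uniform at constant n
while still down-weighting low-replicate proteins when n varies. The MAD is
used rather than the sd so the spiked minority does not inflate σ₀ (a
trimmed-sd variant would behave similarly). The test requires ≥ 100 proteins
for the background to be estimable and errors on a degenerate (zero-spread)
table.

*Adjustment and filter.* Standard BH step-up with monotonicity enforcement.
The deregulation filter is three inclusive gates: q ≤ 0.05, unique
peptides ≥ 2, FC outside [0.77, 1.3]; direction is up at FC ≥ 1.3, down at
FC ≤ 0.77. Tightening any gate can only shrink the result set. Direction
concordance between two conditions counts shared proteins on the same side
of the dead band; pairs with one FC inside the dead band are reported as
indeterminate rather than forced into either class.

## Neurogenesis statistics

Densities are cells per mm of SGZ length; sections within an animal are
combined as total cells / total length (the length-weighted mean of section
densities), and the animal is the experimental unit. Percent change is
100·(mean control − mean treated)/mean control, so reductions are positive.
The test is a pooled-variance (Student) two-tailed t-test — Welch is
available via a flag — significant at p ≤ 0.05.

## Overlap arithmetic and report

Venn decompositions are exact set algebra over 2–4 sets with membership
lists retained; region counts sum to the union size by construction.
Feature identity is case-insensitive by default because gene and miRNA
symbols appear in mixed capitalization across sources; accession-keyed sets
use exact matching. Shared fractions and percent changes carry a
configurable rounding (integer or one decimal) because published percentages
mix both conventions; both roundings of the same ratio are supported.
Shielded dose is total dose × transmission fraction, reported in mGy.

The consolidated report serializes floats at 10 significant digits and
hashes its configuration, making reruns byte-identical and every number
traceable. Sections not run are reported explicitly as absent.

## Synthetic generators

All generators require an explicit integer seed (no global state) and are
byte-deterministic given (config, seed).

* **Spectra** are nonnegative mixtures Σ Cᵢaᵢ + polynomial baseline + iid
  Gaussian noise, truncated at zero. The default library has five
  components (DNA, histone 2A, TNFα, TGFβ, uric acid) with ≥ 3 bands each at
  field-typical positions — the minimal set exercising the reported
  contrasts; band positions are plausible, not measured. Not emulated:
  cosmic-ray spikes, detector etaloning, spatial mapping structure.
* **Counts** are NB(μ, φ) with per-feature log-normal baseline abundance,
  designated features at a chosen signed fold change, and treated-group
  means renormalized to keep library sizes comparable. Not emulated: isomiR
  structure, mapping artifacts, sample-specific composition bias.
* **Protein tables** are log₂-normal around protein-specific means
  (background sd 0.2 by default — a typical label-free replicate CV),
  with a changed subset at specified true ratios and unique-peptide counts
  1 + Poisson. Not emulated: missing values, shared-peptide ambiguity,
  intensity-dependent variance.
* **SGZ counts** draw per-animal densities Gaussian around
  control·(1 − reduction/100) with between-animal CV 0.1, convert to integer
  cells over fixed-length sections. Default reductions (37.22/29.51/32.77%
  for GFAP/Sox2/DCX) and n = 6 animals/group reflect the magnitudes such
  studies report.

Because the generators draw from exactly the models the estimators assume,
passing tests demonstrate correctness of the inference machinery and
closure of the generate→analyze loop — not robustness to the ways real
tissue data violate those models (baseline shapes that are not convex,
overdispersion heterogeneity across miRNAs, non-normal abundance noise).

## Problem sizes and tolerances

Simulation-based checks use 2000 features/proteins per replicate, 50 seeds
for null calibration, and 100 seeds for power checks — sizes at which
Monte-Carlo error is well below the asserted margins while the whole suite
runs in well under a minute per module. Closed-form comparisons assert at
1e-8–1e-12; brute-force oracles (convex minorant, binomial enumeration,
step-up BH, grid-search CLS) are implemented independently of the library
paths they check.
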