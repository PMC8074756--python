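"""Raman microspectroscopy processing chain for tissue sections.

The chain mirrors standard confocal-Raman practice for biological tissue:
wavenumber calibration against a known line (e.g. the 520.7 cm^-1 band of
crystalline silicon), division by the instrument response measured on a
fluorescence standard, cropping to the fingerprint region (400-1800 cm^-1),
rubberband (lower convex hull) baseline subtraction to remove the slowly
varying fluorescence background, vector normalization, Savitzky-Golay
smoothing, and finally either PCA for unsupervised structure or classical
least squares (CLS) unmixing against a library of pure-component reference
spectra:

    S = a1*C1 + a2*C2 + ... + an*Cn + E

where S is the measured spectrum, a_i the unit-norm reference spectra,
C_i >= 0 the component weights ("concentrations", arbitrary units) and E the
residual holding everything the library does not explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "Spectrum",
    "ReferenceLibrary",
    "CLSResult",
    "PCAModel",
    "GroupComparison",
    "SILICON_LINE_CM1",
    "calibrate_axis",
    "correct_instrument_response",
    "crop",
    "rubberband",
    "rubberband_baseline",
    "vector_normalize",
    "savgol_smooth",
    "preprocess",
    "fit_pca",
    "cls_fit",
    "compare_component_weights",
]

#: Raman shift of the first-order phonon line of crystalline silicon,
#: the usual single-point grating calibration anchor.
SILICON_LINE_CM1 = 520.7

MIN_SPECTRUM_LEN = 8


@dataclass
class Spectrum:
    """A single Raman spectrum: strictly increasing wavenumber axis (cm^-1),
    intensities (a.u.) and free-form metadata (sample id, group label, the
    list of processing stages applied so far, ...)."""

    axis: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("axis and intensities must be 1-D")
        if self.axis.size != self.intensities.size:
            raise ValueError("axis and intensities must have equal length")
        if self.axis.size < MIN_SPECTRUM_LEN:
            raise ValueError(
                f"spectrum needs at least {MIN_SPECTRUM_LEN} points, "
                f"got {self.axis.size}"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def with_(self, *, axis=None, intensities=None, stage=None) -> "Spectrum":
        """Return a copy with replaced data and (optionally) a stage appended
        to ``metadata['stages']``."""
        meta = dict(self.metadata)
        if stage is not None:
            meta["stages"] = list(meta.get("stages", [])) + [stage]
        return Spectrum(
            axis=self.axis if axis is None else np.asarray(axis, float),
            intensities=(
                self.intensities if intensities is None
                else np.asarray(intensities, float)
            ),
            metadata=meta,
        )

    def __len__(self) -> int:
        return self.axis.size


@dataclass
class ReferenceLibrary:
    """Pure-component reference spectra a_1..a_n on a shared axis.

    Each component spectrum is stored vector-normalized (unit Euclidean norm)
    so CLS weights are comparable across components.
    """

    names: list
    axis: np.ndarray
    spectra: np.ndarray  # shape (n_components, n_points), rows unit-norm

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.axis = np.asarray(self.axis, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if len(self.names) != self.spectra.shape[0]:
            raise ValueError("one name per component spectrum required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate component names in reference library")
        if self.spectra.shape[1] != self.axis.size:
            raise ValueError("component spectra must live on the library axis")
        norms = np.linalg.norm(self.spectra, axis=1)
        if np.any(norms == 0):
            raise ValueError("all-zero component spectrum")
        self.spectra = self.spectra / norms[:, None]

    @property
    def n_components(self) -> int:
        return self.spectra.shape[0]

    def component(self, name: str) -> np.ndarray:
        return self.spectra[self.names.index(name)]


@dataclass
class CLSResult:
    """Outcome of a classical-least-squares fit of one spectrum.

    ``weights[i]`` is the concentration C_i of ``component_names[i]``;
    ``residual`` is the full error vector E = S - sum_i C_i a_i, so the
    reconstruction identity S = sum C_i a_i + E holds exactly.
    """

    component_names: list
    weights: np.ndarray
    residual: np.ndarray
    residual_norm: float
    nonnegative: bool

    def weight(self, name: str) -> float:
        return float(self.weights[self.component_names.index(name)])


@dataclass
class PCAModel:
    """PCA of a set of spectra: mean spectrum, orthonormal loadings (rows),
    per-spectrum scores (zero column mean) and explained-variance fractions
    (non-increasing, summing to <= 1)."""

    mean: np.ndarray
    loadings: np.ndarray       # (n_components, n_points)
    scores: np.ndarray         # (n_spectra, n_components)
    explained_variance_ratio: np.ndarray


@dataclass
class GroupComparison:
    """Two-group comparison of CLS component weights, reported the way
    bar-plot figures annotate it: means, standard errors, a two-tailed
    two-sample t p-value and a star code (* p<=0.05, ** p<=0.01,
    *** p<=0.001)."""

    component: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    stars: str


# ---------------------------------------------------------------------------
# preprocessing stages
# ---------------------------------------------------------------------------

def calibrate_axis(
    observed_peak_positions: Sequence[float],
    known_peak_positions: Sequence[float],
    spectrum: Spectrum,
) -> Spectrum:
    """Remap the wavenumber axis from matched (observed, known) peak pairs.

    One pair gives a rigid shift; with p >= 2 pairs a least-squares polynomial
    of degree min(p - 1, 3) maps observed to known positions and is applied to
    the whole axis. Intensities are untouched.
    """
    obs = np.asarray(observed_peak_positions, dtype=float).ravel()
    known = np.asarray(known_peak_positions, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("at least one calibration peak pair is required")
    if obs.size != known.size:
        raise ValueError("observed and known peak lists differ in length")
    if obs.size == 1:
        new_axis = spectrum.axis + (known[0] - obs[0])
    else:
        degree = min(obs.size - 1, 3)
        coeffs = np.polyfit(obs, known, deg=degree)
        new_axis = np.polyval(coeffs, spectrum.axis)
    if not np.all(np.diff(new_axis) > 0):
        raise ValueError("calibration produced a non-monotone wavenumber axis")
    return spectrum.with_(axis=new_axis, stage="calibrate_axis")


def correct_instrument_response(
    spectrum: Spectrum,
    measured_standard: np.ndarray,
    certified_standard: np.ndarray,
) -> Spectrum:
    """Divide out the instrument response inferred from a luminescence
    standard (the role NIST SRM 2242 plays on real instruments):
    corrected = spectrum * certified / measured."""
    measured = np.asarray(measured_standard, dtype=float)
    certified = np.asarray(certified_standard, dtype=float)
    if measured.shape != spectrum.intensities.shape or \
            certified.shape != spectrum.intensities.shape:
        raise ValueError("standard spectra must share the spectrum's axis")
    if np.any(measured <= 0):
        raise ValueError("measured standard must be strictly positive")
    corrected = spectrum.intensities * certified / measured
    return spectrum.with_(intensities=corrected, stage="instrument_response")


def crop(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep axis points in the closed interval [lo, hi]."""
    if not lo < hi:
        raise ValueError("crop needs lo < hi")
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    n_kept = int(mask.sum())
    if n_kept == 0:
        raise ValueError(f"crop to [{lo}, {hi}] removes every point")
    if n_kept < MIN_SPECTRUM_LEN:
        raise ValueError(
            f"crop to [{lo}, {hi}] leaves {n_kept} points, "
            f"below the minimum spectrum length {MIN_SPECTRUM_LEN}"
        )
    return Spectrum(
        axis=spectrum.axis[mask],
        intensities=spectrum.intensities[mask],
        metadata={**spectrum.metadata,
                  "stages": list(spectrum.metadata.get("stages", [])) + ["crop"]},
    )


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), endpoints included,
    by Andrew's monotone chain (x already strictly increasing)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # drop i2 if it lies on or above the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rubberband baseline on raw arrays.

    The baseline is the piecewise-linear interpolation of the lower convex
    hull of the points (x_i, y_i), anchored at both endpoints; the corrected
    signal y - baseline is >= 0 everywhere and exactly 0 at hull vertices.
    Returns (baseline, corrected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("rubberband needs at least 3 points")
    idx = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    corrected = y - baseline
    corrected[idx] = 0.0  # exact zeros at hull vertices
    np.maximum(corrected, 0.0, out=corrected)
    return baseline, corrected


def rubberband_baseline(spectrum: Spectrum) -> tuple[np.ndarray, Spectrum]:
    """Rubberband baseline subtraction; returns (baseline, corrected)."""
    baseline, corrected = rubberband(spectrum.axis, spectrum.intensities)
    return baseline, spectrum.with_(intensities=corrected, stage="rubberband")


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = np.linalg.norm(spectrum.intensities)
    if norm == 0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return spectrum.with_(intensities=spectrum.intensities / norm,
                          stage="vector_normalize")


def savgol_smooth(spectrum: Spectrum, window: int = 7, polyorder: int = 5) -> Spectrum:
    """Savitzky-Golay smoothing (default 7-point window, 5th-order
    polynomial). Edges are handled by evaluating the terminal-window
    polynomial fits rather than truncating, so the vector length is
    preserved for PCA."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    if len(spectrum) < window:
        raise ValueError("spectrum shorter than the smoothing window")
    smoothed = signal.savgol_filter(
        spectrum.intensities, window_length=window, polyorder=polyorder,
        mode="interp",
    )
    return spectrum.with_(intensities=smoothed, stage="savgol")


def preprocess(
    spectrum: Spectrum,
    *,
    calibration_pairs: tuple[Sequence[float], Sequence[float]] | None = None,
    standard_pair: tuple[np.ndarray, np.ndarray] | None = None,
    crop_range: tuple[float, float] = (400.0, 1800.0),
    window: int = 7,
    polyorder: int = 5,
) -> Spectrum:
    """Full preprocessing chain, in the canonical order:

    calibrate_axis -> correct_instrument_response -> crop(400, 1800) ->
    rubberband_baseline -> vector_normalize -> savgol_smooth.

    ``calibration_pairs`` is (observed, known) peak positions and
    ``standard_pair`` is (measured, certified) standard spectra on the
    spectrum's axis; either may be None to skip that stage (synthetic data
    often needs neither). The stage list is recorded in metadata.
    """
    s = spectrum
    if calibration_pairs is not None:
        s = calibrate_axis(calibration_pairs[0], calibration_pairs[1], s)
    if standard_pair is not None:
        s = correct_instrument_response(s, standard_pair[0], standard_pair[1])
    s = crop(s, *crop_range)
    _, s = rubberband_baseline(s)
    s = vector_normalize(s)
    s = savgol_smooth(s, window=window, polyorder=polyorder)
    return s


# ---------------------------------------------------------------------------
# multivariate analysis
# ---------------------------------------------------------------------------

def _as_matrix(spectra: Sequence[Spectrum]) -> np.ndarray:
    axes = {tuple(np.round(s.axis, 9)) for s in spectra}
    if len(axes) != 1:
        raise ValueError("all spectra must share one axis; interpolate first")
    return np.vstack([s.intensities for s in spectra])


def fit_pca(spectra: Sequence[Spectrum], n_components: int) -> PCAModel:
    """PCA of mean-centered intensities via SVD.

    Loadings are the leading right singular vectors; the sign of each loading
    is fixed so its largest-magnitude element is positive, making loading
    plots reproducible. Scores are the centered data projected on the
    loadings.
    """
    if len(spectra) < 2:
        raise ValueError("PCA needs at least 2 spectra")
    X = _as_matrix(spectra)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("n_components must be in [1, min(n_spectra - 1, n_points)]")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_components]
    # deterministic sign: largest-|.| element of each loading made positive
    flip = np.sign(loadings[np.arange(n_components),
                            np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = Xc @ loadings.T
    var = s**2 / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    evr = var[:n_components] / total_var if total_var > 0 else np.zeros(n_components)
    return PCAModel(mean=mean, loadings=loadings, scores=scores,
                    explained_variance_ratio=evr)


def _interp_to(axis_from: np.ndarray, y: np.ndarray, axis_to: np.ndarray) -> np.ndarray:
    if axis_from.shape == axis_to.shape and np.allclose(axis_from, axis_to):
        return y
    return np.interp(axis_to, axis_from, y)


def cls_fit(
    spectrum: Spectrum,
    library: ReferenceLibrary,
    nonnegative: bool = True,
) -> CLSResult:
    """Classical least squares unmixing of a spectrum against a reference
    library: find C minimizing ||S - sum_i C_i a_i||^2, by default subject to
    C_i >= 0 (weights are physical concentrations). The spectrum is linearly
    interpolated onto the library axis if needed.
    """
    y = _interp_to(spectrum.axis, spectrum.intensities, library.axis)
    A = library.spectra.T  # (n_points, n_components)
    rank = np.linalg.matrix_rank(A)
    if rank < library.n_components:
        # name the most collinear pair for the error message
        G = np.abs(library.spectra @ library.spectra.T)
        np.fill_diagonal(G, 0.0)
        i, j = np.unravel_index(np.argmax(G), G.shape)
        raise ValueError(
            "rank-deficient reference library: components "
            f"{library.names[i]!r} and {library.names[j]!r} are collinear"
        )
    if nonnegative:
        weights, _ = optimize.nnls(A, y)
    else:
        weights, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = y - A @ weights
    return CLSResult(
        component_names=list(library.names),
        weights=weights,
        residual=residual,
        residual_norm=float(np.linalg.norm(residual)),
        nonnegative=nonnegative,
    )


def _star_code(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_component_weights(
    weights_by_group: Mapping[str, Sequence[float]],
    component: str,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Two-tailed two-sample (pooled-variance) t-test on per-animal CLS
    weights of one component between two groups, with figure-style star
    annotation. A fully degenerate comparison (zero variance in both groups,
    equal means) is reported as p = 1 by convention."""
    a = np.asarray(weights_by_group[group_a], dtype=float)
    b = np.asarray(weights_by_group[group_b], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(t_stat), float(p)
        if np.isnan(p):
            p = 1.0
    return GroupComparison(
        component=component, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)), sem_b=float(stats.sem(b)),
        t_statistic=t_stat, p_value=p, stars=_star_code(p),
    )
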