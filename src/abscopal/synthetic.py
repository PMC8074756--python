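"""Seeded generators for every input the analysis stages consume.

Each generator draws from an explicit statistical model and returns the data
together with its ground truth, so the whole pipeline is testable without any
measured data:

* tissue Raman spectra as nonnegative mixtures of peaked pure-component
  spectra plus a slowly varying polynomial baseline (the fluorescence
  background the rubberband stage must remove) and iid Gaussian noise;
* miRNA count matrices from a negative binomial with mean mu and variance
  mu + phi*mu^2 (phi = 0 is the Poisson limit), with designated features at
  a chosen signed fold change;
* label-free protein quantification tables with log-normal abundances around
  a stable background and a small changed subset;
* per-animal subgranular-zone (SGZ) cell counts with near-Gaussian per-mm
  densities and a stated percent reduction in treated groups.

Every generator takes an explicit integer seed; there is no global random
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raman import ReferenceLibrary, Spectrum

__all__ = [
    "PeakSpec",
    "MixtureDesign",
    "CountSimConfig",
    "ProteinSimConfig",
    "CellCountSimConfig",
    "DEFAULT_PEAK_TABLE",
    "default_axis",
    "make_reference_library",
    "default_reference_library",
    "simulate_tissue_spectra",
    "simulate_mirna_counts",
    "simulate_protein_table",
    "simulate_sgz_counts",
]


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit integer seed is required (reproducibility)")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center (cm^-1), full width at half maximum (cm^-1),
    amplitude (a.u.), and line shape (gaussian or lorentzian)."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        x = (axis - self.center) / self.width
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * x * x)
        return self.amplitude / (1.0 + 4.0 * x * x)  # lorentzian


#: Five-component default library standing in for the pure molecular species
#: most informative in irradiated hippocampus tissue: DNA, histone 2A, TNF-alpha,
#: TGF-beta and uric acid. Band positions loosely follow the classic Raman
#: assignments for nucleic acids (~785/1095/1340/1575), protein amide and
#: CH-deformation bands (~1003/1250/1450/1655) and purine ring modes (~640/1000).
DEFAULT_PEAK_TABLE: dict[str, tuple[PeakSpec, ...]] = {
    "DNA": (
        PeakSpec(785, 20, 1.0),
        PeakSpec(1095, 25, 0.8),
        PeakSpec(1340, 30, 0.6),
        PeakSpec(1480, 25, 0.5),
        PeakSpec(1575, 20, 0.7),
    ),
    "histone 2A": (
        PeakSpec(852, 18, 0.5),
        PeakSpec(1003, 12, 1.0),
        PeakSpec(1315, 28, 0.4),
        PeakSpec(1450, 30, 0.8),
        PeakSpec(1655, 35, 0.9),
    ),
    "TNFa": (
        PeakSpec(621, 15, 0.3),
        PeakSpec(1004, 12, 0.9),
        PeakSpec(1250, 40, 0.6, "lorentzian"),
        PeakSpec(1555, 25, 0.5),
        PeakSpec(1665, 30, 1.0),
    ),
    "TGFb": (
        PeakSpec(830, 20, 0.6),
        PeakSpec(1033, 15, 0.7),
        PeakSpec(1240, 35, 0.8, "lorentzian"),
        PeakSpec(1400, 25, 0.4),
        PeakSpec(1670, 28, 0.9),
    ),
    "uric acid": (
        PeakSpec(640, 15, 0.9),
        PeakSpec(888, 18, 0.5),
        PeakSpec(1000, 20, 0.6),
        PeakSpec(1120, 22, 0.4),
        PeakSpec(1438, 25, 1.0),
    ),
}


def default_axis(n_points: int = 701) -> np.ndarray:
    """Evenly spaced wavenumber axis over the 400-1800 cm^-1 fingerprint
    region (2 cm^-1 spacing at the default length)."""
    return np.linspace(400.0, 1800.0, n_points)


def make_reference_library(
    component_names: Sequence[str],
    peak_specs_per_component: Sequence[Sequence[PeakSpec]],
    axis: np.ndarray,
) -> ReferenceLibrary:
    """Build a pure-component reference library from peak lists.

    Each component spectrum is the sum of its band profiles, vector-normalized
    to unit Euclidean norm. Degenerate libraries (two components with
    numerically identical spectra) are rejected.
    """
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    if len(component_names) != len(peak_specs_per_component):
        raise ValueError("one peak list per component name required")
    rows = []
    for name, peaks in zip(component_names, peak_specs_per_component):
        peaks = tuple(peaks)
        if len(peaks) == 0:
            raise ValueError(f"component {name!r} has an empty peak list")
        for p in peaks:
            if not axis[0] <= p.center <= axis[-1]:
                raise ValueError(
                    f"peak center {p.center} cm^-1 of component {name!r} "
                    f"lies outside the axis [{axis[0]}, {axis[-1]}]"
                )
        rows.append(sum(p.profile(axis) for p in peaks))
    spectra = np.vstack(rows)
    norms = np.linalg.norm(spectra, axis=1)
    if np.any(norms == 0):
        raise ValueError("a component spectrum is identically zero on the axis")
    unit = spectra / norms[:, None]
    for i in range(unit.shape[0]):
        for j in range(i + 1, unit.shape[0]):
            if np.allclose(unit[i], unit[j], atol=1e-12):
                raise ValueError(
                    f"degenerate library: components {component_names[i]!r} "
                    f"and {component_names[j]!r} have identical spectra"
                )
    return ReferenceLibrary(names=list(component_names), axis=axis, spectra=unit)


def default_reference_library(axis: np.ndarray | None = None) -> ReferenceLibrary:
    """The five-component default library on the default axis."""
    if axis is None:
        axis = default_axis()
    names = list(DEFAULT_PEAK_TABLE)
    return make_reference_library(names, [DEFAULT_PEAK_TABLE[n] for n in names], axis)


@dataclass
class MixtureDesign:
    """Ground-truth design of a simulated tissue-spectrum experiment.

    ``weights`` holds one row of true component concentrations C_1..C_n per
    sample (animal); ``baseline_coeffs`` are polynomial coefficients (highest
    power first, evaluated on the axis rescaled to [0, 1]) of the additive
    fluorescence-like background; ``noise_sd`` is the sd of the iid Gaussian
    noise; ``spectra_per_sample`` is the number of replicate acquisitions per
    animal.
    """

    group_labels: list
    weights: np.ndarray  # (n_samples, n_components), >= 0
    baseline_coeffs: Sequence[float] = (0.0,)
    noise_sd: float = 0.0
    spectra_per_sample: int = 1

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if len(self.group_labels) != self.weights.shape[0]:
            raise ValueError("one group label per sample required")
        if np.any(self.weights < 0):
            raise ValueError("true component weights must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.spectra_per_sample < 1:
            raise ValueError("every sample needs at least one spectrum")


def simulate_tissue_spectra(
    library: ReferenceLibrary,
    design: MixtureDesign,
    seed: int,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Draw tissue spectra from the linear mixture model
    S = sum_i C_i a_i + baseline + noise, truncated at zero.

    Returns the spectra (metadata carries sample id, group, replicate) and a
    truth table with one row per sample holding the true weights.
    """
    rng = _require_seed(seed)
    if design.weights.shape[1] != library.n_components:
        raise ValueError("design weight rows must match the library size")
    x01 = (library.axis - library.axis[0]) / (library.axis[-1] - library.axis[0])
    baseline = np.polyval(np.asarray(design.baseline_coeffs, float), x01)
    spectra: list[Spectrum] = []
    rows = []
    for s_idx, (group, c) in enumerate(zip(design.group_labels, design.weights)):
        clean = c @ library.spectra
        for rep in range(design.spectra_per_sample):
            y = clean + baseline
            if design.noise_sd > 0:
                y = y + rng.normal(0.0, design.noise_sd, size=y.size)
            y = np.maximum(y, 0.0)
            spectra.append(Spectrum(
                axis=library.axis.copy(), intensities=y,
                metadata={"sample": f"s{s_idx}", "group": group, "replicate": rep},
            ))
        rows.append({"sample": f"s{s_idx}", "group": group,
                     **{name: c[i] for i, name in enumerate(library.names)}})
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Negative-binomial count simulation: two groups (control, treated) of
    ``n_per_group`` samples over ``n_features`` features. ``de_features`` maps
    feature index -> true signed fold change (|FC| >= 1; positive means up in
    the treated group, negative down, following the signed-FC convention where
    a ratio r < 1 is written as -1/r)."""

    n_per_group: int = 3
    n_features: int = 500
    library_size: int = 1_000_000
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    de_features: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean < 0:
            raise ValueError("baseline mean must be >= 0")
        for idx, fc in self.de_features.items():
            if abs(fc) < 1:
                raise ValueError(f"|signed FC| must be >= 1, got {fc} at {idx}")
            if not 0 <= idx < self.n_features:
                raise ValueError(f"DE feature index {idx} out of range")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with Var = mu + phi*mu^2; phi = 0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_mirna_counts(
    config: CountSimConfig, seed: int
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a miRNA raw-count matrix.

    Per-feature baseline expression is drawn log-normal around
    ``baseline_mean`` and converted to relative abundances; treated-group
    means are multiplied (signed FC > 0) or divided (< 0) by |FC|. Returns
    (counts features x samples, group labels per sample, truth table).
    """
    rng = _require_seed(seed)
    n, m = config.n_features, config.n_per_group
    base = config.baseline_mean * rng.lognormal(0.0, 1.0, size=n)
    frac = base / base.sum()
    effect = np.ones(n)
    for idx, fc in config.de_features.items():
        effect[idx] = fc if fc >= 1 else 1.0 / abs(fc)
    mu_ctrl = config.library_size * frac
    mu_trt = mu_ctrl * effect
    # renormalize treated so library sizes stay comparable
    mu_trt = mu_trt * (config.library_size / mu_trt.sum())
    counts = np.column_stack(
        [_nb_draw(rng, mu_ctrl, config.dispersion) for _ in range(m)]
        + [_nb_draw(rng, mu_trt, config.dispersion) for _ in range(m)]
    )
    features = [f"miR-{i}" for i in range(n)]
    samples = [f"ctrl_{j}" for j in range(m)] + [f"trt_{j}" for j in range(m)]
    matrix = pd.DataFrame(counts, index=features, columns=samples)
    groups = pd.Series(["control"] * m + ["treated"] * m, index=samples, name="group")
    truth = pd.DataFrame(
        {"feature": [features[i] for i in config.de_features],
         "true_signed_fc": list(config.de_features.values())}
    )
    return matrix, groups, truth


# ---------------------------------------------------------------------------
# protein abundance tables
# ---------------------------------------------------------------------------

@dataclass
class ProteinSimConfig:
    """Log-normal protein quantification table: ``n_proteins`` proteins in two
    groups of ``n_replicates`` runs; per-replicate log2 abundances are Gaussian
    with sd ``background_sd`` around protein-specific means. ``changed`` maps
    protein index -> true treated/control abundance ratio (> 0). Unique-peptide
    counts are 1 + Poisson(``up_mean`` - 1)."""

    n_proteins: int = 2000
    n_replicates: int = 4
    background_sd: float = 0.2
    changed: Mapping[int, float] = field(default_factory=dict)
    up_mean: float = 4.0

    def __post_init__(self) -> None:
        if self.background_sd <= 0:
            raise ValueError("background sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        for idx, ratio in self.changed.items():
            if ratio <= 0:
                raise ValueError("true ratios must be > 0")
            if not 0 <= idx < self.n_proteins:
                raise ValueError(f"changed protein index {idx} out of range")


def simulate_protein_table(
    config: ProteinSimConfig, seed: int
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a per-protein abundance table.

    Returns (table, group labels per abundance column, truth). The table has
    columns accession, gene, unique_peptides, then one abundance column per
    replicate run (control first).
    """
    rng = _require_seed(seed)
    n, m = config.n_proteins, config.n_replicates
    base_log2 = rng.uniform(15.0, 25.0, size=n)
    shift = np.zeros(n)
    for idx, ratio in config.changed.items():
        shift[idx] = np.log2(ratio)
    ctrl = base_log2[:, None] + rng.normal(0, config.background_sd, size=(n, m))
    trt = (base_log2 + shift)[:, None] + rng.normal(0, config.background_sd, size=(n, m))
    up = 1 + rng.poisson(max(config.up_mean - 1.0, 0.0), size=n)
    cols = [f"ctrl_{j}" for j in range(m)] + [f"trt_{j}" for j in range(m)]
    table = pd.DataFrame(
        np.power(2.0, np.hstack([ctrl, trt])), columns=cols,
    )
    table.insert(0, "unique_peptides", up)
    table.insert(0, "gene", [f"Gene{i}" for i in range(n)])
    table.insert(0, "accession", [f"P{i:05d}" for i in range(n)])
    groups = pd.Series(["control"] * m + ["treated"] * m, index=cols, name="group")
    truth = pd.DataFrame(
        {"accession": [f"P{i:05d}" for i in config.changed],
         "true_ratio": list(config.changed.values())}
    )
    return table, groups, truth


# ---------------------------------------------------------------------------
# SGZ cell counts
# ---------------------------------------------------------------------------

@dataclass
class CellCountSimConfig:
    """Per-animal SGZ cell-density simulation: densities are Gaussian around
    control_density * (1 - reduction/100) with coefficient of variation ``cv``
    between animals; counts arise from density x section length. ``reductions``
    maps marker name -> true percent reduction in the treated group."""

    n_per_group: int = 6
    control_density: float = 12.0       # cells per mm SGZ
    reductions: Mapping[str, float] = field(
        default_factory=lambda: {"GFAP": 37.22, "Sox2": 29.51, "DCX": 32.77}
    )
    cv: float = 0.1
    section_length_mm: float = 5.0
    sections_per_animal: int = 2

    def __post_init__(self) -> None:
        if self.control_density <= 0:
            raise ValueError("control density must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for marker, red in self.reductions.items():
            if not 0 <= red < 100:
                raise ValueError(f"reduction for {marker!r} must be in [0, 100)")


def simulate_sgz_counts(config: CellCountSimConfig, seed: int) -> pd.DataFrame:
    """Simulate a section-level SGZ count table with columns
    animal, group, marker, section, cells, length_mm."""
    rng = _require_seed(seed)
    rows = []
    for group in ("control", "treated"):
        for marker, red in config.reductions.items():
            mean = config.control_density * (
                1.0 if group == "control" else 1.0 - red / 100.0
            )
            for a in range(config.n_per_group):
                density = mean if config.cv == 0 else max(
                    rng.normal(mean, config.cv * mean), 0.0
                )
                for sec in range(config.sections_per_animal):
                    length = config.section_length_mm
                    cells = int(round(density * length))
                    rows.append({
                        "animal": f"{group[:1]}{a}", "group": group,
                        "marker": marker, "section": sec,
                        "cells": cells, "length_mm": length,
                    })
    return pd.DataFrame(rows)
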