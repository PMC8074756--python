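"""Plain-text readers and writers for the pipeline's exchange formats:
two-column spectra, reference-library directories, and TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .raman import ReferenceLibrary, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_library_dir",
    "write_library_dir",
    "read_count_matrix",
    "write_table",
]


def read_spectrum(path, **metadata) -> Spectrum:
    """Read a two-column (wavenumber cm^-1, intensity) whitespace- or
    comma-delimited text file; '#' lines are comments."""
    path = Path(path)
    data = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a two-column spectrum file")
    order = np.argsort(data[:, 0])
    return Spectrum(axis=data[order, 0], intensities=data[order, 1],
                    metadata={"source": str(path), **metadata})


def _is_whitespace(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," not in line
    return True


def write_spectrum(spectrum: Spectrum, path) -> None:
    header = "wavenumber_cm-1 intensity"
    np.savetxt(path, np.column_stack([spectrum.axis, spectrum.intensities]),
               header=header, fmt="%.10g")


def write_library_dir(library: ReferenceLibrary, directory) -> None:
    """One two-column spectrum file per component, named after it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, row in zip(library.names, library.spectra):
        safe = name.replace("/", "_").replace(" ", "_")
        write_spectrum(Spectrum(library.axis, row, {"component": name}),
                       directory / f"{safe}.txt")


def read_library_dir(directory) -> ReferenceLibrary:
    """Read a directory of component spectrum files into a library; all
    spectra must share one axis. Component names come from file stems."""
    directory = Path(directory)
    files = sorted(directory.glob("*.txt"))
    if not files:
        raise ValueError(f"no component spectra (*.txt) in {directory}")
    spectra = [read_spectrum(f) for f in files]
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis.shape != axis.shape or not np.allclose(s.axis, axis):
            raise ValueError("library component spectra do not share one axis")
    return ReferenceLibrary(
        names=[f.stem for f in files], axis=axis,
        spectra=np.vstack([s.intensities for s in spectra]),
    )


def read_count_matrix(counts_path, sample_sheet_path):
    """Read a features x samples TSV count matrix plus a sample sheet TSV
    with columns sample, group (extra columns such as dose or time pass
    through). Returns (counts DataFrame, groups Series, sample sheet)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks a {col!r} column")
    groups = sheet.set_index("sample")["group"]
    return counts, groups, sheet


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
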