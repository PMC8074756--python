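"""Post-quantification statistics for label-free proteomics tables.

Abundances are median-ratio normalized per sample to remove loading errors;
per-protein fold changes are ratios of group median abundances, clipped to
the conventional reporting band [0.01, 100] (a protein absent from one
group prints as 100 or 0.010 rather than infinity or zero). Significance
uses a background-variance test: the great majority of proteins do not
change, so the spread of their log-ratios estimates the null; each protein's
log-ratio, scaled by sqrt(replicates), is referred to a normal with that
robustly (MAD) estimated sd. p-values are Benjamini-Hochberg adjusted, and
the deregulation filter requires q <= 0.05, at least two unique peptides,
and a fold change outside [0.77, 1.3].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .overlap import DeregulationSet

__all__ = [
    "RATIO_CAP",
    "normalize_abundances",
    "protein_ratio",
    "background_ttest",
    "bh_adjust",
    "protein_de_table",
    "filter_deregulated",
    "direction_concordance",
]

#: Reporting cap for protein ratios; the floor is its reciprocal (0.01).
RATIO_CAP = 100.0


def _abundance_columns(table: pd.DataFrame, groups: pd.Series) -> list:
    return [c for c in table.columns if c in groups.index]


def normalize_abundances(table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Median-ratio normalization (per-sample scaling to a geometric-mean
    pseudo-reference) of the abundance columns; annotation columns pass
    through untouched. After normalization the median log-ratio of every
    sample to the reference is zero."""
    cols = _abundance_columns(table, groups)
    X = table[cols].values.astype(float)
    if np.any((X > 0).sum(axis=0) == 0):
        raise ValueError("a sample has no nonzero abundance")
    with np.errstate(divide="ignore"):
        logx = np.log(X)
    finite_rows = np.isfinite(logx).all(axis=1)
    if finite_rows.sum() == 0:
        raise ValueError("no protein quantified in every sample; cannot normalize")
    ref = logx[finite_rows].mean(axis=1, keepdims=True)  # geometric-mean reference
    log_f = np.median(logx[finite_rows] - ref, axis=0)
    factors = np.exp(log_f - log_f.mean())  # geometric mean 1 => idempotent
    out = table.copy()
    out[cols] = X / factors
    out.attrs["size_factors"] = dict(zip(cols, factors))
    return out


def protein_ratio(treated: np.ndarray, control: np.ndarray,
                  cap: float = RATIO_CAP) -> float:
    """Fold change as the ratio of median abundances, clipped to
    [1/cap, cap]. A zero control median with nonzero treated reports the cap
    (100); the reverse reports the floor (0.01); both medians zero is
    undefined and reports NaN."""
    mt = float(np.median(np.asarray(treated, dtype=float)))
    mc = float(np.median(np.asarray(control, dtype=float)))
    if mt < 0 or mc < 0:
        raise ValueError("abundances must be >= 0")
    if mt == 0 and mc == 0:
        return float("nan")
    if mc == 0:
        return cap
    if mt == 0:
        return 1.0 / cap
    return float(np.clip(mt / mc, 1.0 / cap, cap))


def background_ttest(log_ratios: np.ndarray,
                     n_replicates: np.ndarray | int) -> np.ndarray:
    """Background-variance significance test.

    The null sd sigma_0 is estimated from the central mass of the
    sqrt(n)-scaled per-protein log-ratios via the median absolute deviation
    (x 1.4826); each protein's statistic z = sqrt(n) * log-ratio / sigma_0 is
    referred to the standard normal, two-sided. Requires enough proteins
    (>= 100) for the background to be estimable.
    """
    L = np.asarray(log_ratios, dtype=float)
    if L.size < 100:
        raise ValueError("background test needs >= 100 proteins")
    n = np.broadcast_to(np.asarray(n_replicates, dtype=float), L.shape)
    scaled = np.sqrt(n) * L
    finite = np.isfinite(scaled)
    mad = np.median(np.abs(scaled[finite] - np.median(scaled[finite])))
    sigma0 = 1.4826 * mad
    if sigma0 == 0:
        raise ValueError("degenerate table: background sd is zero")
    z = scaled / sigma0
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~finite] = np.nan
    return p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving);
    NaN p-values propagate as NaN q-values."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def protein_de_table(table: pd.DataFrame, groups: pd.Series,
                     control_group: str = "control",
                     normalize: bool = True) -> pd.DataFrame:
    """End-to-end per-protein statistics: normalization, median-ratio fold
    change (capped), background-variance p, BH q.

    ``table`` needs columns accession (and optionally gene, unique_peptides)
    plus one abundance column per run named in ``groups``.
    """
    if normalize:
        table = normalize_abundances(table, groups)
    cols = _abundance_columns(table, groups)
    ctrl_cols = [c for c in cols if groups[c] == control_group]
    trt_cols = [c for c in cols if groups[c] != control_group]
    if not ctrl_cols or not trt_cols:
        raise ValueError("both a control and a treated group are required")
    ctrl = table[ctrl_cols].values.astype(float)
    trt = table[trt_cols].values.astype(float)
    fc = np.array([protein_ratio(t, c) for t, c in zip(trt, ctrl)])
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(fc)
    n_eff = min(len(ctrl_cols), len(trt_cols))
    p = background_ttest(log_ratio, n_eff)
    q = bh_adjust(p)
    out = pd.DataFrame({
        "accession": table["accession"].values,
        "fc": fc, "p": p, "q": q,
    })
    if "gene" in table.columns:
        out.insert(1, "gene", table["gene"].values)
    if "unique_peptides" in table.columns:
        out["unique_peptides"] = table["unique_peptides"].values
    return out.set_index("accession", drop=False)


def filter_deregulated(results: pd.DataFrame, q_thr: float = 0.05,
                       low: float = 0.77, high: float = 1.3,
                       min_up: int = 2, name: str = "condition",
                       **condition) -> DeregulationSet:
    """The three-gate deregulation filter: q <= q_thr, unique peptides >=
    min_up, and fold change outside the dead band (FC <= low or FC >= high).
    Direction is up for FC >= high, down for FC <= low."""
    if not low < 1 < high:
        raise ValueError("thresholds must satisfy low < 1 < high")
    up_col = results["unique_peptides"].values if "unique_peptides" in results \
        else np.full(len(results), min_up)
    fc = results["fc"].values
    q = results["q"].values
    passing = (q <= q_thr) & (up_col >= min_up) & ((fc <= low) | (fc >= high))
    directions = {
        acc: ("up" if f >= high else "down")
        for acc, f, keep in zip(results["accession"], fc, passing) if keep
    }
    return DeregulationSet(name=name, members=set(directions),
                           directions=directions, condition=dict(condition),
                           case_insensitive=False)


def direction_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                          low: float = 0.77, high: float = 1.3) -> dict:
    """Direction agreement of shared proteins between two result tables.

    A shared protein is concordant when both fold changes sit on the same
    side of the dead band (both >= high, or both <= low); proteins on
    opposite sides are discordant; pairs with either FC inside the dead band
    are counted as indeterminate. Returns counts plus the upregulated
    fraction among concordant proteins. An empty intersection yields an
    empty (all-zero) summary.
    """
    shared = results_a.index.intersection(results_b.index)
    concordant_up = concordant_down = discordant = indeterminate = 0
    for acc in shared:
        fa = float(results_a.loc[acc, "fc"])
        fb = float(results_b.loc[acc, "fc"])
        if fa >= high and fb >= high:
            concordant_up += 1
        elif fa <= low and fb <= low:
            concordant_down += 1
        elif (fa >= high and fb <= low) or (fa <= low and fb >= high):
            discordant += 1
        else:
            indeterminate += 1
    concordant = concordant_up + concordant_down
    return {
        "n_shared": int(len(shared)),
        "concordant": concordant,
        "concordant_up": concordant_up,
        "concordant_down": concordant_down,
        "discordant": discordant,
        "indeterminate": indeterminate,
        "fraction_up_among_concordant":
            (concordant_up / concordant) if concordant else float("nan"),
    }
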