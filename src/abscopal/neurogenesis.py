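"""Stage-specific neurogenesis quantification in the subgranular zone (SGZ).

Positive cells (GFAP+ radial-glia-like stem cells, Sox2+ transient
amplifying progenitors, DCX+ immature neurons) are expressed per mm of SGZ
length; sections are aggregated per animal by a length-weighted mean so the
animal, not the section, is the experimental unit. Group differences are
tested with a two-tailed two-sample Student t-test (pooled variance;
Welch available via flag), significant at p <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "density_per_mm",
    "percent_change",
    "group_ttest",
    "marker_summary",
]

REQUIRED_COLUMNS = ("animal", "group", "marker", "cells", "length_mm")


def density_per_mm(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-animal cell densities (cells per mm SGZ).

    ``counts`` has one row per section with columns animal, group, marker,
    cells, length_mm. Sections of one animal/marker are combined by the
    length-weighted mean of section densities, i.e. total cells over total
    length. Returns one row per (animal, group, marker) with a ``density``
    column.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (counts["length_mm"] <= 0).any():
        raise ValueError("SGZ length must be > 0")
    if (counts["cells"] < 0).any():
        raise ValueError("cell counts must be >= 0")
    agg = counts.groupby(["animal", "group", "marker"], as_index=False).agg(
        cells=("cells", "sum"), length_mm=("length_mm", "sum")
    )
    agg["density"] = agg["cells"] / agg["length_mm"]
    return agg


def percent_change(treated_densities: np.ndarray,
                   control_densities: np.ndarray) -> float:
    """Percent reduction of the treated group mean relative to control:
    100 * (mean control - mean treated)/mean control. Negative values are
    increases."""
    treated = np.asarray(treated_densities, dtype=float)
    control = np.asarray(control_densities, dtype=float)
    mc = control.mean()
    if mc <= 0:
        raise ValueError("control mean must be > 0")
    return float(100.0 * (mc - treated.mean()) / mc)


def group_ttest(treated_densities: np.ndarray, control_densities: np.ndarray,
                alpha: float = 0.05, welch: bool = False) -> dict:
    """Two-tailed two-sample t-test on per-animal densities (pooled variance
    by default). Returns the statistic, p-value and a significance flag at
    ``alpha``."""
    treated = np.asarray(treated_densities, dtype=float)
    control = np.asarray(control_densities, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need at least 2 animals per group")
    if treated.std(ddof=1) == 0 and control.std(ddof=1) == 0 \
            and treated.mean() == control.mean():
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(treated, control, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):
            p = 1.0
    return {"t": t_stat, "p": p, "significant": p <= alpha}


def marker_summary(counts: pd.DataFrame, control_group: str = "control",
                   alpha: float = 0.05, welch: bool = False) -> pd.DataFrame:
    """Per-marker group comparison: mean densities, percent change from
    control, p-value and star annotation, one row per (marker, treated
    group)."""
    dens = density_per_mm(counts)
    rows = []
    for marker, sub in dens.groupby("marker"):
        ctrl = sub.loc[sub["group"] == control_group, "density"].values
        if ctrl.size == 0:
            raise ValueError(f"no {control_group!r} animals for marker {marker!r}")
        for group, gsub in sub.groupby("group"):
            if group == control_group:
                continue
            trt = gsub["density"].values
            test = group_ttest(trt, ctrl, alpha=alpha, welch=welch)
            rows.append({
                "marker": marker, "group": group,
                "mean_control": float(ctrl.mean()), "mean_treated": float(trt.mean()),
                "percent_change": percent_change(trt, ctrl),
                "p": test["p"], "significant": test["significant"],
            })
    return pd.DataFrame(rows)
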