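"""Small-count miRNA differential expression and PCR-array quantification.

The sequencing arm filters features at >1 count per million (CPM) in at
least 2 samples, equalizes library sizes, estimates a common negative
binomial dispersion phi (Var = mu + phi*mu^2) by maximizing the conditional
likelihood of within-group counts given their totals, and tests each feature
with a two-sided NB exact test conditional on the overall total; at phi = 0
this reduces to the binomial (Poisson-conditional) exact test. Deregulation
uses the raw-p criteria p <= 0.1 together with a signed fold change
|FC| >= 3 (ratio when >= 1, negative reciprocal when < 1). p-values are not
multiplicity-adjusted for the call — the criterion is on raw p — but a
Benjamini-Hochberg column is emitted for transparency.

The PCR-array arm quantifies the follow-up panel by delta-delta-Ct:
relative expression 2^-ddCt with a two-sample t-test on per-sample delta-Ct,
deregulated at p <= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .overlap import DeregulationSet

__all__ = [
    "CountMatrix",
    "cpm_filter",
    "equalize_library_sizes",
    "estimate_dispersion",
    "nb_exact_test",
    "signed_fold_change",
    "de_table",
    "classify_deregulated",
    "ddct_quantify",
]


@dataclass
class CountMatrix:
    """Raw miRNA counts (features x samples) with per-sample group labels.
    Library sizes are the column sums."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integers")
        missing = [c for c in counts.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[counts.columns]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])


def cpm_filter(matrix: CountMatrix, min_cpm: float = 1.0,
               min_samples: int = 2) -> CountMatrix:
    """Keep features with CPM strictly above ``min_cpm`` in at least
    ``min_samples`` samples (CPM = 1e6 * count / library size)."""
    libsizes = matrix.library_sizes
    if (libsizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    cpm = 1e6 * matrix.counts / libsizes
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("CPM filter removed every feature")
    return CountMatrix(counts=matrix.counts.loc[keep], groups=matrix.groups)


def equalize_library_sizes(matrix: CountMatrix) -> CountMatrix:
    """Scale every sample to the geometric-mean library size, rounding to
    integer pseudo-counts, so the conditional NB machinery (which assumes a
    common effective library size) applies."""
    libsizes = matrix.library_sizes.astype(float)
    common = float(np.exp(np.log(libsizes).mean()))
    pseudo = np.round(matrix.counts * (common / libsizes)).astype(int)
    return CountMatrix(counts=pseudo, groups=matrix.groups)


def _group_conditional_loglik(y: np.ndarray, r: float) -> float:
    """Conditional log-likelihood of one feature's counts within one group
    given their total, under iid NB with size r = 1/phi (terms free of r
    dropped)."""
    n = y.size
    s = y.sum()
    return float(
        special.gammaln(y + r).sum() - n * special.gammaln(r)
        - special.gammaln(s + n * r) + special.gammaln(n * r)
    )


def estimate_dispersion(matrix: CountMatrix) -> float:
    """Common NB dispersion phi >= 0 maximizing the conditional likelihood
    pooled over features and replicated groups, after library-size
    equalization. Returns 0.0 when the Poisson boundary is optimal."""
    eq = equalize_library_sizes(matrix)
    group_rows = []
    for g in eq.groups.unique():
        cols = eq.samples_in(g)
        if len(cols) >= 2:
            group_rows.append(eq.counts[cols].values)
    if not group_rows:
        raise ValueError("dispersion estimation needs a group with >= 2 samples")

    def negloglik(log_phi: float) -> float:
        r = np.exp(-log_phi)  # r = 1/phi
        return -sum(
            _group_conditional_loglik(y, r)
            for block in group_rows for y in block
        )

    # multinomial (phi -> 0) limit of the conditional log-likelihood
    poisson_ll = 0.0
    for block in group_rows:
        for y in block:
            n, s = y.size, y.sum()
            # limit: log [ s! / (prod y_i!) * n^-s ]
            poisson_ll += float(
                special.gammaln(s + 1) - special.gammaln(y + 1).sum()
                - s * np.log(n)
            )
    res = optimize.minimize_scalar(
        negloglik, bounds=(np.log(1e-6), np.log(10.0)), method="bounded",
    )
    phi_hat = float(np.exp(res.x))
    # compare against the Poisson boundary; note negloglik drops the same
    # y-free terms as the limit above does not, so recompute comparably
    ll_hat = -negloglik(float(res.x))
    # conditional NB ll with the dropped factorial terms restored
    ll_hat_full = ll_hat + sum(
        float(special.gammaln(y.sum() + 1) - special.gammaln(y + 1).sum())
        for block in group_rows for y in block
    )
    if poisson_ll >= ll_hat_full or phi_hat <= 1e-4:
        return 0.0
    return phi_hat


def _exact_pvalue(a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for group-A total ``a`` given overall total ``t``.

    Conditional on t, the group-A total follows a negative hypergeometric
    law with shape parameters r_A = n_A/phi, r_B = n_B/phi (binomial
    Binomial(t, n_A/(n_A+n_B)) in the phi = 0 limit). The two-sided p sums
    the probabilities of all splits no more likely than the observed one
    (minimum-likelihood convention).
    """
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi == 0:
        logp = (
            special.gammaln(t + 1)
            - special.gammaln(x + 1) - special.gammaln(t - x + 1)
            + x * np.log(n_a / (n_a + n_b))
            + (t - x) * np.log(n_b / (n_a + n_b))
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            special.gammaln(x + r_a) - special.gammaln(x + 1)
            + special.gammaln(t - x + r_b) - special.gammaln(t - x + 1)
        )
        logp -= special.logsumexp(logp)
    p_obs = logp[a]
    p = float(np.exp(special.logsumexp(logp[logp <= p_obs + 1e-10])))
    return min(max(p, 1e-300), 1.0)


def nb_exact_test(matrix: CountMatrix, group_a: str, group_b: str,
                  phi: float) -> pd.Series:
    """Per-feature two-sided NB exact test between two groups at common
    dispersion ``phi``, after library-size equalization."""
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    cols_a = matrix.samples_in(group_a)
    cols_b = matrix.samples_in(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    eq = equalize_library_sizes(matrix)
    ya = eq.counts[cols_a].sum(axis=1).values
    yb = eq.counts[cols_b].sum(axis=1).values
    pvals = np.array([
        _exact_pvalue(int(a), int(a + b), len(cols_a), len(cols_b), phi)
        for a, b in zip(ya, yb)
    ])
    return pd.Series(pvals, index=matrix.counts.index, name="p")


def signed_fold_change(mean_a: float, mean_b: float, eps: float = 0.5) -> float:
    """Signed fold change of treated (b) over control (a) means with a
    pseudo-offset ``eps`` guarding zeros: r = (b + eps)/(a + eps), reported
    as r when r >= 1 and as -1/r otherwise (so |FC| >= 1 always)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if mean_a == 0 and mean_b == 0:
        raise ValueError("fold change undefined when both means are 0")
    r = (mean_b + eps) / (mean_a + eps)
    return float(r) if r >= 1 else float(-1.0 / r)


def de_table(matrix: CountMatrix, group_a: str, group_b: str,
             phi: float | None = None, eps: float = 0.5) -> pd.DataFrame:
    """Full DE result table (feature, FC, p, BH q) for treated ``group_b``
    versus control ``group_a``; phi is estimated if not given. Fold changes
    use CPM means so unequal library sizes do not masquerade as effects."""
    if phi is None:
        phi = estimate_dispersion(matrix)
    p = nb_exact_test(matrix, group_a, group_b, phi)
    cpm = 1e6 * matrix.counts / matrix.library_sizes
    mean_a = cpm[matrix.samples_in(group_a)].mean(axis=1)
    mean_b = cpm[matrix.samples_in(group_b)].mean(axis=1)
    fc = [
        signed_fold_change(a, b, eps=eps) if (a > 0 or b > 0) else np.nan
        for a, b in zip(mean_a, mean_b)
    ]
    q = multipletests(p.values, method="fdr_bh")[1]
    return pd.DataFrame(
        {"feature": matrix.counts.index, "fc": fc, "p": p.values, "q": q}
    ).set_index("feature", drop=False)


def classify_deregulated(results: pd.DataFrame, p_thr: float = 0.1,
                         fc_thr: float = 3.0, name: str = "condition",
                         **condition) -> DeregulationSet:
    """Partition a DE table into up / down / none and return the named set
    of deregulated features: up iff p <= p_thr and FC >= fc_thr, down iff
    p <= p_thr and FC <= -fc_thr."""
    if p_thr <= 0 or fc_thr <= 0:
        raise ValueError("thresholds must be > 0")
    fc = results["fc"].values
    p = results["p"].values
    up = (p <= p_thr) & (fc >= fc_thr)
    down = (p <= p_thr) & (fc <= -fc_thr)
    directions = {}
    for feat, is_up, is_down in zip(results["feature"], up, down):
        if is_up:
            directions[feat] = "up"
        elif is_down:
            directions[feat] = "down"
    return DeregulationSet(name=name, members=set(directions),
                           directions=directions, condition=dict(condition))


def ddct_quantify(ct: pd.DataFrame, groups: pd.Series,
                  control_group: str = "control",
                  normalizer: pd.Series | None = None,
                  p_thr: float = 0.1) -> pd.DataFrame:
    """Delta-delta-Ct quantification of a PCR array.

    ``ct`` is features x samples of cycle thresholds. ``normalizer`` gives
    the per-sample reference Ct; by default the global mean Ct of each sample
    is used (recorded in the output attrs). For each feature,
    dCt = Ct - normalizer per sample, relative expression = 2^-(mean dCt
    treated - mean dCt control), and p is the two-tailed two-sample t on the
    per-sample dCt; deregulated iff p <= ``p_thr``.
    """
    if not np.isfinite(ct.values).all():
        raise ValueError("Ct values must be finite")
    norm_name = "global_mean"
    if normalizer is None:
        normalizer = ct.mean(axis=0)
    else:
        norm_name = getattr(normalizer, "name", None) or "custom"
        missing = [c for c in ct.columns if c not in normalizer.index]
        if missing:
            raise ValueError(f"samples without normalizer Ct: {missing}")
    groups = groups.loc[ct.columns]
    ctrl_cols = list(groups.index[groups == control_group])
    trt_cols = list(groups.index[groups != control_group])
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    dct = ct - normalizer.loc[ct.columns]
    rows = []
    for feat, row in dct.iterrows():
        d_ctrl = row[ctrl_cols].values.astype(float)
        d_trt = row[trt_cols].values.astype(float)
        ddct = d_trt.mean() - d_ctrl.mean()
        if np.std(d_ctrl) == 0 and np.std(d_trt) == 0 and ddct == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(d_trt, d_ctrl, equal_var=True).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"feature": feat, "relative_expression": float(2.0 ** -ddct),
                     "ddct": float(ddct), "p": p, "deregulated": p <= p_thr})
    out = pd.DataFrame(rows).set_index("feature", drop=False)
    out.attrs["normalizer"] = norm_name
    return out
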