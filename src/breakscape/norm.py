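"""Count normalization, batch adjustment and inducible-element calling.

Sequencing-depth normalization follows the median-of-ratios construction:
each sample's size factor is the median, over elements detected in every
sample, of that sample's count divided by the element's geometric mean
across samples.  Inducible elements are those whose post-stimulation
signal exceeds a fold threshold (2x for accessibility, 1.5x for H3K27ac
acetylation) at Benjamini–Hochberg adjusted p < 0.05, where the p-value
tests the null that the log2 fold change is at most log2(threshold) — a
Welch t test on log2(normalized + 1) replicate values with an offset null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InducibleCall",
    "filter_low_counts",
    "size_factors",
    "normalize_counts",
    "batch_adjust",
    "classify_inducible",
    "bh_adjust",
]


@dataclass
class InducibleCall:
    element_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    inducible: bool


def filter_low_counts(counts: pd.DataFrame,
                      mode: str = "at_least_two_nonzero") -> pd.Series:
    """Element mask for low-count removal.

    ``at_least_two_nonzero`` keeps elements detected in >= 2 samples (the
    accessibility/acetylation/damage-mark convention); ``any_nonzero``
    keeps elements detected in >= 1 sample (the sparser cut-site
    convention).
    """
    nonzero = (counts > 0).sum(axis=1)
    if mode == "at_least_two_nonzero":
        return nonzero >= 2
    if mode == "any_nonzero":
        return nonzero >= 1
    raise ValueError(f"unknown mode {mode!r}")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to unit geometric mean.

    Only elements with strictly positive counts in every sample enter the
    reference (their geometric mean is finite); each sample's factor is the
    median ratio of its counts to those geometric means.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no element has positive counts in every sample; supply a "
            "pseudo-reference (e.g. add a pseudocount) or relax filtering")
    log_mat = np.log(mat[all_pos])
    log_geo = log_mat.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_mat - log_geo, axis=0))
    s = s / np.exp(np.mean(np.log(s)))  # unit geometric mean
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Depth-normalized counts: value_ij = counts_ij / s_j."""
    return counts / s.reindex(counts.columns)


def batch_adjust(log_normalized: pd.DataFrame, batch: Sequence,
                 condition: Sequence) -> pd.DataFrame:
    """Remove additive batch effects from log-scale values.

    Per element an additive two-factor linear model (condition + batch) is
    fitted by least squares and the fitted batch terms — centred so that
    batch effects sum to zero weighted by batch sizes — are subtracted.
    Condition contrasts are untouched.  A design in which batch and
    condition are confounded (the two-factor design matrix is rank
    deficient) is rejected.
    """
    batch = pd.Categorical(batch)
    condition = pd.Categorical(condition)
    n = log_normalized.shape[1]
    if len(batch) != n or len(condition) != n:
        raise ValueError("batch/condition labels must match sample count")
    if len(batch.categories) == 1:
        return log_normalized.copy()
    cond_d = pd.get_dummies(condition, drop_first=True).to_numpy(float)
    batch_d = pd.get_dummies(batch, drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(n), cond_d, batch_d])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch and condition are confounded; cannot adjust")
    Y = log_normalized.to_numpy(dtype=float).T  # samples x elements
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    nb = batch_d.shape[1]
    batch_beta = beta[-nb:]  # effects relative to the reference batch
    effect = batch_d @ batch_beta  # per-sample batch term, shape (n, E)
    effect -= effect.mean(axis=0, keepdims=True)  # sum to zero over samples
    adjusted = (Y - effect).T
    return pd.DataFrame(adjusted, index=log_normalized.index,
                        columns=log_normalized.columns)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, >= raw p)."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-element variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    variances by moment matching on log(s^2) and returns the posterior
    variances (d0*s0^2 + df*s^2)/(d0 + df) with total df d0 + df.  With few
    replicates per element this borrowing of strength across elements is
    what makes a threshold test at n=3 per group usable at all.
    """
    from scipy.special import digamma, polygamma
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2) + np.log(df / 2)
    evar = max(np.var(e, ddof=1) - polygamma(1, df / 2), 0.0)
    if evar <= 1e-12:
        return np.full_like(s2, np.exp(np.mean(e))), np.inf
    # invert trigamma by Newton iteration (solve polygamma(1, x) = evar)
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        step = polygamma(1, x) * (1 - polygamma(1, x) / evar) / polygamma(2, x)
        x -= step
        if abs(step) < 1e-10:
            break
    d0 = 2 * x
    s0_2 = np.exp(np.mean(e) + digamma(x) - np.log(x))
    return (d0 * s0_2 + df * s2) / (d0 + df), d0


def classify_inducible(normalized: pd.DataFrame,
                       pre_samples: Sequence[str],
                       post_samples: Sequence[str],
                       fold_threshold: float = 2.0,
                       alpha: float = 0.05,
                       pseudocount: float = 1.0,
                       var_floor: float = 1e-8,
                       moderation: bool = True) -> list[InducibleCall]:
    """Call elements whose post-stimulation signal exceeds a fold threshold.

    Per element, L = mean log2(post + pc) - mean log2(pre + pc); the null
    H0: L <= log2(fold_threshold) is tested one-sided by a t statistic
    with the threshold as offset, p-values are Benjamini–Hochberg adjusted
    across all tested elements, and an element is inducible iff the
    realised fold change meets the threshold AND adjusted p < alpha.
    An exactly-threshold fold change with tight replicates is NOT called —
    the offset null demands strict exceedance.  Zero replicate variance is
    floored at ``var_floor``.

    With ``moderation`` (default) the per-element pooled variance is shrunk
    toward a prior fitted across all elements (empirical Bayes, as in
    moderated-t / count-model dispersion sharing); without it a per-element
    Welch t is used, which at 2-3 replicates per group has very little
    power against the offset null.
    """
    if len(pre_samples) < 2 or len(post_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    pre = np.log2(normalized[list(pre_samples)].to_numpy(float) + pseudocount)
    post = np.log2(normalized[list(post_samples)].to_numpy(float) + pseudocount)
    n1, n2 = pre.shape[1], post.shape[1]
    m1, m2 = pre.mean(axis=1), post.mean(axis=1)
    v1 = np.maximum(pre.var(axis=1, ddof=1), var_floor)
    v2 = np.maximum(post.var(axis=1, ddof=1), var_floor)
    L = m2 - m1
    if moderation:
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        s2_tilde, d0 = _squeeze_var(s2, df_resid)
        se = np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
        df = np.full(len(L), df_resid + d0)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = (L - np.log2(fold_threshold)) / se
    p = stats.t.sf(t, np.minimum(df, 1e6))
    p_adj = bh_adjust(p)
    calls = []
    for eid, l_i, p_i, pa_i in zip(normalized.index, L, p, p_adj):
        ind = bool(2.0 ** l_i >= fold_threshold and pa_i < alpha)
        calls.append(InducibleCall(str(eid), float(l_i), float(p_i),
                                   float(pa_i), ind))
    return calls


def inducible_union(*call_lists: Sequence[InducibleCall]) -> dict[str, bool]:
    """Landscape inducibility: an element is inducible if any assay calls it
    (accessibility OR acetylation)."""
    out: dict[str, bool] = {}
    for calls in call_lists:
        for c in calls:
            out[c.element_id] = out.get(c.element_id, False) or c.inducible
    return out
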