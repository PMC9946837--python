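"""Mutation-frequency estimation, young-median normalization and robust
outlier removal.

The total mutation frequency of an amplicon is the number of mutated
consensus families (substitutions + indels) divided by the total number of
consensus bases assessed — the sum of unanimous family counts over all
non-primer positions.  Complementary substitutions are collapsed (C>T with
G>A and so on) because the strand of origin of a mutation is unknowable.
Age trends are expressed as fold change over the per-site median frequency
of young animals; extreme points are removed with a robust
FDR-controlled outlier test (ROUT) specialised to a location model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon import BASES, ConsensusTable

__all__ = [
    "COLLAPSED_CLASSES",
    "MutationProfile",
    "mutation_frequency",
    "class_frequencies",
    "profile_table",
    "normalize_to_young",
    "rout_outliers",
]

# collapsed substitution classes: (pyrimidine-context label, ((ref, alt), (ref', alt')))
COLLAPSED_CLASSES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "C>A|G>T": (("C", "A"), ("G", "T")),
    "C>G|G>C": (("C", "G"), ("G", "C")),
    "C>T|G>A": (("C", "T"), ("G", "A")),
    "T>A|A>T": (("T", "A"), ("A", "T")),
    "T>C|A>G": (("T", "C"), ("A", "G")),
    "T>G|A>C": (("T", "G"), ("A", "C")),
}


@dataclass
class MutationProfile:
    """Per-amplicon, per-sample mutation frequencies.

    Frequencies are NaN (missing) where the denominator is zero or no
    eligible reference base exists — missing is never conflated with zero.
    """

    amplicon_id: str
    sample_id: str = ""
    f_total: float = np.nan
    f_class: dict[str, float] = field(default_factory=dict)
    f_indel: float = np.nan
    denominator_bases: int = 0
    alt_family_count: int = 0


def mutation_frequency(table: ConsensusTable, primer_len: int | None = None,
                       sample_id: str = "") -> MutationProfile:
    """Total mutation frequency: mutated families / consensus bases assessed.

    The first ``primer_len`` bases (primer-annealing region) are excluded
    from both numerator and denominator.  Zero denominator yields a missing
    (NaN) frequency, not zero.
    """
    if primer_len is None:
        primer_len = table.primer_len
    mask = np.ones(table.length, dtype=bool)
    mask[:primer_len] = False
    alt = int(table.alt_families()[mask].sum())
    denom = int(table.n_families[mask].sum())
    f = alt / denom if denom > 0 else np.nan
    return MutationProfile(table.amplicon_id, sample_id, f_total=f,
                           denominator_bases=denom, alt_family_count=alt)


def class_frequencies(table: ConsensusTable, primer_len: int | None = None,
                      sample_id: str = "") -> MutationProfile:
    """Collapsed-class substitution frequencies and indel frequency.

    For class X>Y|X'>Y' the numerator pools X>Y families at reference-X
    positions with X'>Y' families at reference-X' positions, and the
    denominator is the total consensus depth over assessed positions whose
    reference base is X or X'.  Indels use every assessed position as
    denominator.  Classes with no eligible reference base are missing.
    """
    if primer_len is None:
        primer_len = table.primer_len
    mask = np.ones(table.length, dtype=bool)
    mask[:primer_len] = False
    ref_arr = np.frombuffer(table.reference.encode(), dtype="S1").astype("U1")
    prof = mutation_frequency(table, primer_len, sample_id)
    prof.f_class = {}
    for label, ((r1, a1), (r2, a2)) in COLLAPSED_CLASSES.items():
        eligible = mask & np.isin(ref_arr, [r1, r2])
        denom = int(table.n_families[eligible].sum())
        if not eligible.any() or denom == 0:
            prof.f_class[label] = np.nan
            continue
        num = int(table.subs[mask & (ref_arr == r1), BASES.index(a1)].sum()
                  + table.subs[mask & (ref_arr == r2), BASES.index(a2)].sum())
        prof.f_class[label] = num / denom
    denom_all = int(table.n_families[mask].sum())
    n_indel = int((table.dels + table.ins)[mask].sum())
    prof.f_indel = n_indel / denom_all if denom_all > 0 else np.nan
    return prof


def profile_table(profiles: list[MutationProfile]) -> pd.DataFrame:
    base_cols = ["amplicon_id", "sample_id", "f_total", "f_indel",
                 "denominator_bases", "alt_family_count"]
    if not profiles:
        return pd.DataFrame(columns=base_cols + list(COLLAPSED_CLASSES))
    rows = []
    for p in profiles:
        row = {"amplicon_id": p.amplicon_id, "sample_id": p.sample_id,
               "f_total": p.f_total, "f_indel": p.f_indel,
               "denominator_bases": p.denominator_bases,
               "alt_family_count": p.alt_family_count}
        row.update(p.f_class)
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_young(frequencies: pd.DataFrame,
                       young_label: str = "young") -> pd.DataFrame:
    """Fold change of each animal's per-site frequency over the young median.

    ``frequencies`` columns: site_id, animal_id, age_group, f_total.  Each
    value is divided by the median f_total of young animals at the same
    site.  Sites with no young animal are dropped with a warning; sites
    whose young median is zero yield missing values.  Missing input
    frequencies never enter the median.
    """
    required = {"site_id", "animal_id", "age_group", "f_total"}
    if missing := required - set(frequencies.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for site, g in frequencies.groupby("site_id", sort=False):
        young = g.loc[(g["age_group"] == young_label) & g["f_total"].notna(),
                      "f_total"]
        if young.empty:
            warnings.warn(f"site {site} absent in young group; dropped",
                          stacklevel=2)
            continue
        med = float(np.median(young))
        g = g.copy()
        g["value"] = g["f_total"] / med if med > 0 else np.nan
        out.append(g[["site_id", "animal_id", "age_group", "value"]])
    if not out:
        return pd.DataFrame(columns=["site_id", "animal_id", "age_group", "value"])
    return pd.concat(out, ignore_index=True)


def rout_outliers(values: np.ndarray, q: float = 0.001) -> np.ndarray:
    """Robust FDR-based outlier mask for a univariate sample (ROUT).

    Specialised to a constant (location) model: the robust centre is the
    median and the robust scale (RSDR) is the 68.27th percentile of absolute
    residuals with the small-sample correction n/(n-1).  Each point's
    t-ratio |residual|/RSDR is converted to a two-tailed p-value on n-1
    degrees of freedom and a Benjamini–Hochberg step-up at rate ``q`` flags
    the outliers.  Constant input yields no outliers.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    if np.isnan(values).any():
        raise ValueError("missing values must be excluded before outlier testing")
    n = len(values)
    resid = np.abs(values - np.median(values))
    rsdr = float(np.percentile(resid, 68.27)) * n / (n - 1)
    if rsdr == 0.0:
        # >68% of points identical: any nonzero residual is infinitely extreme
        return resid > 0
    t = resid / rsdr
    pvals = 2.0 * stats.t.sf(t, df=n - 1)
    return _bh_reject(pvals, q)


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * len(pvals) / np.arange(1, len(pvals) + 1)
    passed = np.minimum.accumulate(ranked[::-1])[::-1] <= q
    mask = np.zeros(len(pvals), dtype=bool)
    mask[order] = passed
    return mask
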