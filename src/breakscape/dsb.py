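"""Double-strand-break quantification from single-bp cut-site records.

An in-suspension breaks-labelling library (sBLISS) yields, after mapping,
one record per read: the single-bp genomic position of a DNA end, its
strand, and the UMI ligated onto the free end.  Unique breaks are the
distinct (chrom, pos, strand, UMI) tuples; PCR re-reads of one ligation
event collapse onto one tuple.  Break burden over a regulatory-element
landscape is the per-element count of unique events, and genome-wide
burden comparisons first downsample every sample to the common read depth
so unequal sequencing does not masquerade as unequal damage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegulatoryElement, SignalTrack, overlap_flag

__all__ = [
    "CutSiteSet",
    "QuartileLabel",
    "read_cut_sites_tsv",
    "write_cut_sites_tsv",
    "dedup_cut_sites",
    "element_counts",
    "quartile_stratify",
    "genomewide_breaks",
]

_RECORD_COLS = ["chrom", "pos", "strand", "umi"]


@dataclass
class CutSiteSet:
    """Deduplicated single-bp break events for one sample."""

    sample_id: str
    events: pd.DataFrame  # unique rows over (chrom, pos, strand, umi)
    total_reads: int

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class QuartileLabel:
    element_id: str
    quartile: str  # Q1 (lowest ratio) .. Q4 (highest)
    ratio: float
    q4_high: bool
    q1_low: bool
    zero_denominator: bool = False


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if missing := set(_RECORD_COLS) - set(records.columns):
        raise ValueError(f"cut-site records missing columns: {sorted(missing)}")
    if (records["pos"] < 0).any():
        raise ValueError("cut-site positions must be >= 0")
    bad = ~records["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {records.loc[bad, 'strand'].unique()}")
    return records


def dedup_cut_sites(records: pd.DataFrame, sample_id: str = "",
                    use_strand: bool = True) -> CutSiteSet:
    """Collapse PCR duplicates: one event per (chrom, pos, strand, umi).

    With ``use_strand=False`` the two break ends at one bp are collapsed
    (the event key drops strand).  Order-invariant and idempotent.
    """
    records = _check_records(records)
    key = _RECORD_COLS if use_strand else ["chrom", "pos", "umi"]
    events = (records[_RECORD_COLS].drop_duplicates(subset=key)
              .sort_values(_RECORD_COLS, kind="stable").reset_index(drop=True))
    return CutSiteSet(sample_id, events, total_reads=len(records))


def element_counts(sets: Sequence[CutSiteSet],
                   elements: Sequence[RegulatoryElement]) -> pd.DataFrame:
    """Unique-event counts per element per sample (elements x samples).

    Only the single-bp cut end is counted: an event lands in an element iff
    ``start <= pos < end``; strand is ignored.  Overlapping summit-window
    elements each count a shared event.
    """
    index = [e.element_id for e in elements]
    out = pd.DataFrame(0, index=pd.Index(index, name="element_id"),
                       columns=[s.sample_id for s in sets], dtype=np.int64)
    for cs in sets:
        by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in cs.events.groupby("chrom")}
        counts = np.zeros(len(elements), dtype=np.int64)
        for i, elem in enumerate(elements):
            pos = by_chrom.get(elem.interval.chrom)
            if pos is None:
                continue
            counts[i] = (np.searchsorted(pos, elem.interval.end, side="left")
                         - np.searchsorted(pos, elem.interval.start, side="left"))
        out[cs.sample_id] = counts
    return out


def quartile_stratify(elements: Sequence[RegulatoryElement],
                      numerator_track: SignalTrack,
                      denominator_track: SignalTrack,
                      peaks: Sequence[GenomicInterval],
                      eps: float = 1.0) -> list[QuartileLabel]:
    """Rank elements by control-normalized binding signal into quartiles.

    Per element the ratio is (binding sum)/(control sum + eps); elements are
    ranked by a stable sort on (ratio, chrom, start) and cut into four
    equal-count bins Q1 (lowest) .. Q4 (highest), sizes differing by at most
    one.  ``q4_high`` additionally requires overlap with a called binding
    peak; ``q1_low`` requires the absence of one.  Elements with zero
    control signal are still ranked (ratio = numerator/eps) and flagged.
    """
    if not elements:
        return []
    num = np.array([numerator_track.sum(e.interval) for e in elements])
    den = np.array([denominator_track.sum(e.interval) for e in elements])
    ratio = num / (den + eps)
    has_peak = overlap_flag(elements, peaks)
    order = sorted(range(len(elements)),
                   key=lambda i: (ratio[i], elements[i].interval.chrom,
                                  elements[i].interval.start))
    n = len(elements)
    labels: list[QuartileLabel | None] = [None] * n
    for rank, i in enumerate(order):
        qi = rank * 4 // n  # equal-count bins, sizes differ by <= 1
        quart = f"Q{qi + 1}"
        labels[i] = QuartileLabel(
            element_id=elements[i].element_id, quartile=quart,
            ratio=float(ratio[i]),
            q4_high=bool(qi == 3 and has_peak[i]),
            q1_low=bool(qi == 0 and not has_peak[i]),
            zero_denominator=bool(den[i] == 0))
    return labels  # type: ignore[return-value]


def genomewide_breaks(sets: Sequence[CutSiteSet], seed: int,
                      records_per_sample: Sequence[pd.DataFrame] | None = None
                      ) -> pd.Series:
    """Unique-break totals after downsampling all samples to equal depth.

    Input READS (pre-dedup records) are downsampled without replacement to
    the lowest read count across samples, then deduplicated; the unique
    (chrom, pos, strand, umi) total per sample is returned.  The same seed
    reproduces the same draw.  ``records_per_sample`` supplies the raw
    records when the sets were built elsewhere; otherwise each set's events
    are treated as its records (valid only if never deduplicated).
    """
    if len(sets) < 2:
        raise ValueError("genome-wide break comparison needs >= 2 samples")
    if records_per_sample is None:
        records_per_sample = [s.events for s in sets]
    depths = [s.total_reads for s in sets]
    if min(depths) == 0:
        zero = sets[int(np.argmin(depths))].sample_id
        raise ValueError(f"sample {zero} has zero reads")
    for s, rec in zip(sets, records_per_sample):
        if len(rec) != s.total_reads:
            raise ValueError(
                f"sample {s.sample_id}: {len(rec)} records != total_reads "
                f"{s.total_reads}")
    r_min = min(depths)
    rng = np.random.default_rng(seed)
    totals = {}
    for s, rec in zip(sets, records_per_sample):
        idx = rng.choice(len(rec), size=r_min, replace=False)
        sub = rec.iloc[np.sort(idx)]
        totals[s.sample_id] = dedup_cut_sites(sub, s.sample_id).n_events
    return pd.Series(totals, name="unique_breaks")


# ---------------------------------------------------------------- file I/O
# BED-like cut-site dialect: chrom, pos, pos+1, umi, sample, strand (no header)

def read_cut_sites_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "end", "umi", "sample_id", "strand"],
                     dtype={"chrom": str, "umi": str, "sample_id": str,
                            "strand": str})
    if ((df["end"] - df["pos"]) != 1).any():
        raise ValueError("cut sites must be single-bp (end = pos + 1)")
    return df.drop(columns="end")


def write_cut_sites_tsv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["end"] = out["pos"] + 1
    out[["chrom", "pos", "end", "umi", "sample_id", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)
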