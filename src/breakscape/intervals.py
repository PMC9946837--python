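"""Interval algebra for peak reproducibility, merging and summit-centred windows.

All coordinates are 0-based, half-open (BED convention): an interval
``(chrom, start, end)`` covers bases ``start .. end-1``.  These primitives
underlie the construction of the hippocampal regulatory-element landscape:
reproducible peak calls per assay and time point are concatenated, merged,
and reduced to fixed-width windows centred on the chromatin-accessibility
summit of each merged region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "RegulatoryElement",
    "merge_intervals",
    "reproducible_peaks",
    "summit_window",
    "build_landscape",
    "overlap_flag",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self!r}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start in {self!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


class SignalTrack:
    """Sparse per-base non-negative signal, stored as value runs per chromosome.

    Runs are half-open ``(start, end, value)`` triples; positions not covered
    by any run have value 0.  Supports the two queries the landscape needs:
    the leftmost argmax within an interval (summit finding) and the signal
    sum over an interval (aggregate binding signal).
    """

    def __init__(self, runs: Iterable[tuple[str, int, int, float]],
                 chrom_sizes: dict[str, int] | None = None):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}-{end}")
            if end <= start or start < 0:
                raise ValueError(f"malformed run {chrom}:{start}-{end}")
            if chrom_sizes is not None and end > chrom_sizes.get(chrom, np.inf):
                raise ValueError(f"run {chrom}:{start}-{end} exceeds chromosome bounds")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, rs in per_chrom.items():
            rs.sort()
            s = np.array([r[0] for r in rs], dtype=np.int64)
            e = np.array([r[1] for r in rs], dtype=np.int64)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            self._starts[chrom] = s
            self._ends[chrom] = e
            self._values[chrom] = np.array([r[2] for r in rs], dtype=float)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def _runs_in(self, iv: GenomicInterval) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = self._starts.get(iv.chrom)
        if s is None:
            z = np.empty(0, dtype=np.int64)
            return z, z, np.empty(0)
        e = self._ends[iv.chrom]
        v = self._values[iv.chrom]
        lo = int(np.searchsorted(e, iv.start, side="right"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        return (np.clip(s[lo:hi], iv.start, iv.end),
                np.clip(e[lo:hi], iv.start, iv.end), v[lo:hi])

    def argmax(self, iv: GenomicInterval) -> tuple[int, float]:
        """Leftmost position of the maximum value within ``iv`` (ties leftmost).

        Uncovered bases count as value 0; an all-zero interval returns value 0
        at the interval start (callers decide how to flag it).
        """
        s, e, v = self._runs_in(iv)
        nz = v > 0
        if not nz.any():
            return iv.start, 0.0
        best = float(v[nz].max())
        # leftmost run attaining the max; its clipped start is the leftmost base
        idx = int(np.flatnonzero(nz & (v == best))[0])
        return int(s[idx]), best

    def sum(self, iv: GenomicInterval) -> float:
        s, e, v = self._runs_in(iv)
        return float(((e - s) * v).sum())

    def dense(self, chrom: str, length: int) -> np.ndarray:
        """Materialise a per-base array (testing / small chromosomes only)."""
        out = np.zeros(length)
        s = self._starts.get(chrom)
        if s is None:
            return out
        for a, b, v in zip(s, self._ends[chrom], self._values[chrom]):
            out[a:min(b, length)] = v
        return out


@dataclass
class RegulatoryElement:
    """Fixed-width summit-centred regulatory element.

    ``source`` records which assay(s) contributed the underlying merged
    region: ``"ATAC"``, ``"K27ac"`` or ``"both"``.  ``clipped`` marks windows
    truncated at chromosome boundaries; ``flat_summit`` marks regions whose
    signal was all zero (summit fell back to the region midpoint).
    """

    interval: GenomicInterval
    summit: int
    source: str = "ATAC"
    inducible: bool = False
    element_id: str = ""
    clipped: bool = False
    flat_summit: bool = False

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval!r}")


def _as_arrays(intervals: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per: dict[str, tuple[list[int], list[int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, ([], []))[0].append(iv.start)
        per[iv.chrom][1].append(iv.end)
    return {c: (np.array(s, dtype=np.int64), np.array(e, dtype=np.int64))
            for c, (s, e) in per.items()}


def merge_intervals(intervals: Sequence[GenomicInterval], gap: int = 0
                    ) -> list[GenomicInterval]:
    """Merge intervals whose separation is at most ``gap`` bases.

    Adjacent intervals (separation 0) always merge; two peaks 151 bp apart
    stay separate at ``gap=150``.  Output is sorted and non-overlapping.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, (starts, ends) in sorted(_as_arrays(intervals).items()):
        order = np.lexsort((ends, starts))
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def reproducible_peaks(peak_sets: Sequence[Sequence[GenomicInterval]], m: int
                       ) -> list[GenomicInterval]:
    """Maximal intervals covered by at least ``m`` of the replicate peak sets.

    Each replicate's coverage is binarised (its own overlapping peaks count
    once), the per-base replicate-depth profile is thresholded at ``m`` and
    segmented.  Symmetric in replicate order; ``m=1`` equals merging the
    concatenation with gap 0.
    """
    n = len(peak_sets)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} out of range for {n} replicate sets")
    events: dict[str, list[tuple[int, int]]] = {}
    for peaks in peak_sets:
        for iv in merge_intervals(peaks, gap=0):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        depth = 0
        seg_start = None
        for pos, delta in ev:
            new_depth = depth + delta
            # process all deltas at identical positions together
            if seg_start is None and depth < m <= new_depth:
                seg_start = pos
            depth = new_depth
            if seg_start is not None and depth < m:
                if pos > seg_start:
                    out.append(GenomicInterval(chrom, seg_start, pos))
                seg_start = None
        # depth returns to 0 at the last event, so seg_start is always closed
    # coalesce touching segments produced by coincident events
    return merge_intervals(out, gap=0) if out else []


def summit_window(interval: GenomicInterval, track: SignalTrack, half_width: int,
                  chrom_size: int | None = None) -> RegulatoryElement:
    """Fixed-width window ``[summit-hw, summit+hw)`` about the signal summit.

    The summit is the leftmost position of the maximum track value within the
    interval; an all-zero interval falls back to the interval midpoint and is
    flagged.  Windows are clipped at 0 and at the chromosome end (flagged,
    never dropped).
    """
    summit, best = track.argmax(interval)
    flat = best == 0.0
    if flat:
        summit = (interval.start + interval.end) // 2
    start = summit - half_width
    end = summit + half_width
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_size is None and track.chrom_sizes:
        chrom_size = track.chrom_sizes.get(interval.chrom)
    if chrom_size is not None and end > chrom_size:
        end, clipped = chrom_size, True
    return RegulatoryElement(
        interval=GenomicInterval(interval.chrom, start, end),
        summit=summit, clipped=clipped, flat_summit=flat)


def build_landscape(atac_reproducible: Sequence[GenomicInterval],
                    k27_reproducible: Sequence[GenomicInterval],
                    atac_track: SignalTrack,
                    half_width: int = 500,
                    blacklist: Sequence[GenomicInterval] = (),
                    ) -> list[RegulatoryElement]:
    """Regulatory-element landscape: union of reproducible accessibility and
    H3K27ac regions, merged, reduced to summit-centred fixed-width windows.

    The summit is taken from the accessibility track ("maximal chromatin
    accessibility summit").  An optional blacklist is subtracted from the
    merged union before windows are formed.  Each element records whether it
    derives from an accessibility region, an acetylation region, or both.
    """
    union = merge_intervals(list(atac_reproducible) + list(k27_reproducible), gap=0)
    if blacklist:
        union = _subtract(union, blacklist)
    atac_merged = merge_intervals(atac_reproducible, 0) if atac_reproducible else []
    k27_merged = merge_intervals(k27_reproducible, 0) if k27_reproducible else []
    elements = []
    for i, region in enumerate(union):
        elem = summit_window(region, atac_track, half_width)
        in_atac = any(region.overlaps(p) for p in atac_merged)
        in_k27 = any(region.overlaps(p) for p in k27_merged)
        elem.source = "both" if (in_atac and in_k27) else ("K27ac" if in_k27 else "ATAC")
        elem.element_id = f"RE{i:06d}"
        elements.append(elem)
    return elements


def _subtract(intervals: list[GenomicInterval], blacklist: Sequence[GenomicInterval]
              ) -> list[GenomicInterval]:
    black = _as_arrays(merge_intervals(blacklist, 0))
    out: list[GenomicInterval] = []
    for iv in intervals:
        if iv.chrom not in black:
            out.append(iv)
            continue
        bs, be = black[iv.chrom]
        cur = iv.start
        for s, e in zip(bs, be):
            if e <= cur or s >= iv.end:
                continue
            if s > cur:
                out.append(GenomicInterval(iv.chrom, cur, min(s, iv.end)))
            cur = max(cur, e)
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end))
    return out


def overlap_flag(elements: Sequence[RegulatoryElement],
                 peaks: Sequence[GenomicInterval],
                 min_overlap: int = 1) -> np.ndarray:
    """Boolean per element: shares >= ``min_overlap`` bases with any peak."""
    peak_arr = _as_arrays(merge_intervals(peaks, 0)) if peaks else {}
    flags = np.zeros(len(elements), dtype=bool)
    for i, elem in enumerate(elements):
        iv = elem.interval
        arr = peak_arr.get(iv.chrom)
        if arr is None:
            continue
        ps, pe = arr
        lo = np.searchsorted(pe, iv.start, side="right")
        hi = np.searchsorted(ps, iv.end, side="left")
        for s, e in zip(ps[lo:hi], pe[lo:hi]):
            if min(iv.end, e) - max(iv.start, s) >= min_overlap:
                flags[i] = True
                break
    return flags


# ---------------------------------------------------------------- file I/O
# BED and bedGraph are tab-separated, 0-based half-open, no header.

def read_bed(path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={0: str},
                     comment="#")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"malformed BED record at line {bad[0] + 1}: "
            f"{row.chrom}\t{row.start}\t{row.end}")
    return [GenomicInterval(c, int(s), int(e))
            for c, s, e in df.itertuples(index=False)]


def write_bed(intervals: Sequence[GenomicInterval], path,
              names: Sequence[str] | None = None) -> None:
    df = pd.DataFrame({"chrom": [iv.chrom for iv in intervals],
                       "start": [iv.start for iv in intervals],
                       "end": [iv.end for iv in intervals]})
    if names is not None:
        df["name"] = list(names)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> SignalTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], dtype={0: str},
                     comment="#")
    return SignalTrack(df.itertuples(index=False, name=None), chrom_sizes)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))
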