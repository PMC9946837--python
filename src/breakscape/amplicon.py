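"""UMI-family grouping and consensus composition for targeted amplicons.

Reads from an ultrasensitive amplicon assay carry a 12-nt unique molecular
identifier (UMI) in the forward primer.  Reads sharing an (amplicon, UMI)
pair derive from one template molecule; a family of at least ``min_depth``
reads that agree unanimously at a position contributes one "consensus
family" count to that position's composition table.  Polymerase and
sequencing errors are private to single reads, so unanimity at depth >= 10
suppresses them to ~3*(e/3)^10 while true template mutations, shared by
every read of the family, survive.

Per-read calls use a compact aligned mini-syntax over the amplicon
reference: a string of length L with ``=`` (matches reference), ``A/C/G/T``
(substitution to that base) or ``-`` (deletion); insertions are separate
``anchor+SEQ`` tokens anchored to the reference position immediately left
of the inserted bases (e.g. ``17+GG``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AmpliconPanel",
    "Amplicon",
    "AmpliconRead",
    "UmiFamily",
    "ConsensusTable",
    "UmiQC",
    "group_umi_families",
    "consensus_composition",
    "filter_amplicons",
    "read_panel_fasta",
    "read_reads_tsv",
    "write_reads_tsv",
    "write_consensus_tsv",
    "read_consensus_tsv",
]

BASES = "ACGT"
# uint8 call codes: 0..3 = A,C,G,T; 4 = deletion
DEL_CODE = 4
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["-"] = DEL_CODE
_DECODE = np.array(list(BASES + "-"))


def encode_calls(call_string: str, reference: str) -> np.ndarray:
    """Decode the ``=ACGT-`` call string against the reference into codes."""
    if len(call_string) != len(reference):
        raise ValueError(
            f"call string length {len(call_string)} != reference length {len(reference)}")
    codes = np.empty(len(reference), dtype=np.uint8)
    for i, (c, r) in enumerate(zip(call_string, reference)):
        codes[i] = _CODE[r] if c == "=" else _CODE[c]
    return codes


def decode_calls(codes: np.ndarray, reference: str) -> str:
    chars = _DECODE[codes]
    ref = np.frombuffer(reference.encode(), dtype="S1").astype("U1")
    return "".join(np.where((chars == ref) & (codes != DEL_CODE), "=", chars))


@dataclass(frozen=True)
class Amplicon:
    """One target region: reference sequence plus primer geometry."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    reference: str
    primer_len: int = 22
    umi_len: int = 12

    def __post_init__(self) -> None:
        if len(self.reference) != self.end - self.start:
            raise ValueError(
                f"{self.amplicon_id}: reference length {len(self.reference)} "
                f"!= interval width {self.end - self.start}")
        if self.primer_len >= len(self.reference):
            raise ValueError(f"{self.amplicon_id}: primer_len >= amplicon length")

    @property
    def length(self) -> int:
        return len(self.reference)


@dataclass
class AmpliconPanel:
    amplicons: dict[str, Amplicon]

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self.amplicons[amplicon_id]

    def __iter__(self):
        return iter(self.amplicons.values())

    def __len__(self) -> int:
        return len(self.amplicons)


@dataclass
class AmpliconRead:
    """One aligned read: per-position call codes plus anchored insertions."""

    amplicon_id: str
    umi: str
    calls: np.ndarray  # uint8 codes over the amplicon
    insertions: tuple[tuple[int, str], ...] = ()


@dataclass
class UmiFamily:
    amplicon_id: str
    umi: str
    members: list[AmpliconRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class UmiQC:
    """Quality tallies from family grouping."""

    n_reads_in: int = 0
    n_discarded_umi: int = 0
    n_near_duplicate_umis: int = 0


@dataclass
class ConsensusTable:
    """Per-position unanimous consensus-family composition of one amplicon.

    Column semantics per position p (0-based on the amplicon):
    ``n_families`` unanimous families at p; ``ref`` of these calling the
    reference base; ``A,C,G,T`` substitution calls to each base (the
    reference base's own column is 0); ``del`` deletion calls; ``ins``
    families unanimously carrying an identical insertion anchored at p
    (counted on top of the base-call partition).  Invariant:
    ref + substitutions + del = n_families at every position.
    """

    amplicon_id: str
    reference: str
    n_families: np.ndarray
    ref: np.ndarray
    subs: np.ndarray  # shape (L, 4): unanimous substitution calls to A,C,G,T
    dels: np.ndarray
    ins: np.ndarray
    primer_len: int = 22

    def __post_init__(self) -> None:
        total = self.ref + self.subs.sum(axis=1) + self.dels
        if not np.array_equal(total, self.n_families):
            raise ValueError("class counts do not sum to n_families")

    @property
    def length(self) -> int:
        return len(self.reference)

    def alt_families(self) -> np.ndarray:
        """Per-position mutated-family count (substitutions + indels)."""
        return self.subs.sum(axis=1) + self.dels + self.ins

    def assessed(self) -> np.ndarray:
        """Boolean mask of assessed (non-primer) positions."""
        mask = np.ones(self.length, dtype=bool)
        mask[: self.primer_len] = False
        return mask


def group_umi_families(reads: Iterable[AmpliconRead]
                       ) -> tuple[list[UmiFamily], UmiQC]:
    """Partition reads by exact (amplicon, UMI); reads with N in the UMI are
    discarded and tallied.  No edit-distance collapsing is performed — the
    12-nt UMI space vastly exceeds template counts at assay scale — but
    near-duplicate UMIs (Hamming distance 1 within an amplicon) are counted
    in the QC report."""
    qc = UmiQC()
    groups: dict[tuple[str, str], list[AmpliconRead]] = {}
    for read in reads:
        qc.n_reads_in += 1
        if set(read.umi) - set(BASES):
            qc.n_discarded_umi += 1
            continue
        groups.setdefault((read.amplicon_id, read.umi), []).append(read)
    families = [UmiFamily(aid, umi, members)
                for (aid, umi), members in groups.items()]
    qc.n_near_duplicate_umis = _count_near_duplicates(groups)
    return families, qc


def _count_near_duplicates(groups: dict[tuple[str, str], list]) -> int:
    per_amp: dict[str, list[str]] = {}
    for aid, umi in groups:
        per_amp.setdefault(aid, []).append(umi)
    n = 0
    for umis in per_amp.values():
        if len(umis) > 2000:  # quadratic scan only at QC scale
            continue
        arr = np.frombuffer("".join(umis).encode(), dtype=np.uint8)
        arr = arr.reshape(len(umis), -1)
        for i in range(len(umis)):
            n += int(((arr[i + 1:] != arr[i]).sum(axis=1) == 1).sum())
    return n


def consensus_composition(families: Sequence[UmiFamily], min_depth: int = 10,
                          *, reference: str | None = None,
                          primer_len: int = 22) -> ConsensusTable:
    """Unanimous consensus composition over one amplicon's UMI families.

    A family contributes at position p iff its size is >= ``min_depth`` AND
    every member read makes the identical call at p; the contribution is one
    count to that call's class.  Families below ``min_depth`` contribute
    nowhere.  Unanimity is required across ALL members, not a subsample.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not families:
        raise ValueError("no families supplied")
    aids = {f.amplicon_id for f in families}
    if len(aids) != 1:
        raise ValueError(f"families span multiple amplicons: {sorted(aids)}")
    amplicon_id = aids.pop()
    qualifying = [f for f in families if f.size >= min_depth]
    L = len(families[0].members[0].calls)
    if reference is None:
        raise ValueError("reference sequence is required")
    if len(reference) != L:
        raise ValueError("reference length does not match read calls")
    ref_codes = encode_calls("=" * L, reference)

    n_families = np.zeros(L, dtype=np.int64)
    ref_counts = np.zeros(L, dtype=np.int64)
    subs = np.zeros((L, 4), dtype=np.int64)
    dels = np.zeros(L, dtype=np.int64)
    ins = np.zeros(L, dtype=np.int64)

    if qualifying:
        calls = np.vstack([r.calls for f in qualifying for r in f.members])
        sizes = np.array([f.size for f in qualifying])
        first = np.repeat(np.cumsum(np.concatenate(([0], sizes[:-1]))), sizes)
        agree = calls == calls[first]  # each read vs its family's first read
        bounds = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        unanimous = np.logical_and.reduceat(agree, bounds, axis=0)
        fam_call = calls[bounds.astype(np.int64)]  # the agreed call where unanimous
        for code in range(5):
            cls = unanimous & (fam_call == code)
            per_pos = cls.sum(axis=0)
            if code == DEL_CODE:
                dels += per_pos
            else:
                is_ref = ref_codes == code
                ref_counts[is_ref] += per_pos[is_ref]
                subs[~is_ref, code] += per_pos[~is_ref]
        n_families = unanimous.sum(axis=0)
        # insertions: unanimous iff every member carries the identical
        # (anchor, sequence) set; anchored to the base left of the insert
        for fi, fam in enumerate(qualifying):
            ins_sets = {r.insertions for r in fam.members}
            if len(ins_sets) == 1:
                for anchor, _seq in ins_sets.pop():
                    if 0 <= anchor < L and unanimous[fi, anchor]:
                        ins[anchor] += 1
    return ConsensusTable(
        amplicon_id=amplicon_id, reference=reference,
        n_families=n_families, ref=ref_counts, subs=subs, dels=dels, ins=ins,
        primer_len=primer_len)


def filter_amplicons(tables: Iterable[ConsensusTable],
                     min_mean_depth: float = 100.0) -> list[str]:
    """Keep amplicons whose mean consensus-family depth over assessed
    (non-primer) positions strictly exceeds ``min_mean_depth``."""
    kept = []
    for t in tables:
        if t.n_families[t.assessed()].mean() > min_mean_depth:
            kept.append(t.amplicon_id)
    return kept


# ---------------------------------------------------------------- file I/O

def read_panel_fasta(fasta_path, meta_tsv=None, primer_len: int = 22,
                     umi_len: int = 12) -> AmpliconPanel:
    """Amplicon references from FASTA; optional metadata TSV supplies
    coordinates (columns: amplicon_id, chrom, start, end)."""
    meta = {}
    if meta_tsv is not None:
        df = pd.read_csv(meta_tsv, sep="\t", dtype={"chrom": str})
        meta = {r.amplicon_id: r for r in df.itertuples(index=False)}
    amps = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        m = meta.get(rec.id)
        chrom = m.chrom if m else rec.id
        start = int(m.start) if m else 0
        end = int(m.end) if m else len(seq)
        amps[rec.id] = Amplicon(rec.id, chrom, start, end, seq,
                                primer_len=primer_len, umi_len=umi_len)
    return AmpliconPanel(amps)


def read_reads_tsv(path, panel: AmpliconPanel) -> list[AmpliconRead]:
    """Pre-parsed aligned reads: columns amplicon_id, umi, calls, insertions.

    ``insertions`` is empty or semicolon-separated ``anchor+SEQ`` tokens.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    reads = []
    for row in df.itertuples(index=False):
        amp = panel[row.amplicon_id]
        ins = []
        for token in filter(None, row.insertions.split(";")):
            anchor, seq = token.split("+")
            ins.append((int(anchor), seq))
        reads.append(AmpliconRead(row.amplicon_id, row.umi,
                                  encode_calls(row.calls, amp.reference),
                                  tuple(ins)))
    return reads


def write_reads_tsv(reads: Sequence[AmpliconRead], panel: AmpliconPanel,
                    path) -> None:
    rows = []
    for r in reads:
        ref = panel[r.amplicon_id].reference
        ins = ";".join(f"{a}+{s}" for a, s in r.insertions)
        rows.append((r.amplicon_id, r.umi, decode_calls(r.calls, ref), ins))
    pd.DataFrame(rows, columns=["amplicon_id", "umi", "calls", "insertions"]
                 ).to_csv(path, sep="\t", index=False)


def write_consensus_tsv(tables: Iterable[ConsensusTable], path) -> None:
    rows = []
    for t in tables:
        for p in range(t.length):
            rows.append((t.amplicon_id, p, t.reference[p], t.n_families[p],
                         t.ref[p], *t.subs[p], t.dels[p], t.ins[p]))
    pd.DataFrame(rows, columns=["amplicon_id", "pos", "ref_base", "n_families",
                                "ref", "A", "C", "G", "T", "del", "ins"]
                 ).to_csv(path, sep="\t", index=False)


def read_consensus_tsv(path, primer_len: int = 22) -> list[ConsensusTable]:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str, "ref_base": str})
    tables = []
    for aid, g in df.groupby("amplicon_id", sort=False):
        g = g.sort_values("pos")
        tables.append(ConsensusTable(
            amplicon_id=aid, reference="".join(g["ref_base"]),
            n_families=g["n_families"].to_numpy(),
            ref=g["ref"].to_numpy(),
            subs=g[["A", "C", "G", "T"]].to_numpy(),
            dels=g["del"].to_numpy(), ins=g["ins"].to_numpy(),
            primer_len=primer_len))
    return tables
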