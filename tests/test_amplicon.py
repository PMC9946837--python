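"""UMI-family grouping and unanimity consensus at depth 10."""

import numpy as np
import pytest

from breakscape.amplicon import (Amplicon, AmpliconPanel, AmpliconRead,
                                 ConsensusTable, DEL_CODE, UmiFamily,
                                 consensus_composition, decode_calls,
                                 encode_calls, filter_amplicons,
                                 group_umi_families, read_reads_tsv,
                                 write_reads_tsv)

REF = "ACGTACGTAC"


def make_read(umi="ACGTACGTACGT", calls="=" * 10, ins=(), aid="a1"):
    return AmpliconRead(aid, umi, encode_calls(calls, REF), tuple(ins))


def brute_force_consensus(families, reference, min_depth=10):
    """Enumerate every (family, position) pair — the slow oracle."""
    L = len(reference)
    ref_codes = encode_calls("=" * L, reference)
    n_fam = np.zeros(L, int)
    ref = np.zeros(L, int)
    subs = np.zeros((L, 4), int)
    dels = np.zeros(L, int)
    for fam in families:
        if fam.size < min_depth:
            continue
        for p in range(L):
            calls = {int(r.calls[p]) for r in fam.members}
            if len(calls) != 1:
                continue
            call = calls.pop()
            n_fam[p] += 1
            if call == DEL_CODE:
                dels[p] += 1
            elif call == ref_codes[p]:
                ref[p] += 1
            else:
                subs[p, call] += 1
    return n_fam, ref, subs, dels


class TestGrouping:
    def test_distinct_umis_make_singletons(self):
        reads = [make_read(umi=f"AAAAAAAAAAA{b}") for b in "ACGT"] + [
            make_read(umi=f"CCCCCCCCCCC{b}") for b in "ACGT"]
        fams, qc = group_umi_families(reads)
        assert len(fams) == 8 and all(f.size == 1 for f in fams)
        assert qc.n_reads_in == 8 and qc.n_discarded_umi == 0

    def test_family_sizes_from_shared_umis(self):
        counts = {"A" * 12: 12, "C" * 12: 10, "G" * 12: 8}
        reads = [make_read(umi=u) for u, k in counts.items() for _ in range(k)]
        fams, _ = group_umi_families(reads)
        assert sorted(f.size for f in fams) == [8, 10, 12]
        assert sum(f.size for f in fams) == len(reads)

    def test_umi_with_N_discarded_and_tallied(self):
        reads = [make_read(), make_read(umi="NNNNACGTACGT")]
        fams, qc = group_umi_families(reads)
        assert sum(f.size for f in fams) == 1
        assert qc.n_discarded_umi == 1

    def test_near_duplicate_umis_reported(self):
        reads = [make_read(umi="A" * 12), make_read(umi="A" * 11 + "C")]
        _, qc = group_umi_families(reads)
        assert qc.n_near_duplicate_umis == 1


class TestConsensus:
    def test_family_below_depth_contributes_nowhere(self):
        fam = UmiFamily("a1", "A" * 12, [make_read() for _ in range(9)])
        table = consensus_composition([fam], reference=REF, primer_len=2)
        assert table.n_families.sum() == 0

    def test_unanimity_required_at_each_position(self):
        # one discordant read kills position 0 only; rest stay counted
        members = [make_read() for _ in range(11)] + [make_read(calls="G" + "=" * 9)]
        fam = UmiFamily("a1", "A" * 12, members)
        table = consensus_composition([fam], reference=REF, primer_len=0)
        assert table.n_families[0] == 0
        assert (table.n_families[1:] == 1).all()
        assert (table.ref[1:] == 1).all()
        assert table.subs.sum() == 0

    def test_unanimous_substitution_counted_once(self):
        members = [make_read(calls="=G========") for _ in range(10)]
        fam = UmiFamily("a1", "A" * 12, members)
        table = consensus_composition([fam], reference=REF, primer_len=0)
        assert table.subs[1, 2] == 1  # position 1, call G (ref C)
        assert table.ref[1] == 0 and table.n_families[1] == 1

    def test_error_free_families_all_reference(self):
        fams = [UmiFamily("a1", f"{b}AAAAAAAAAAA".replace(" ", ""),
                          [make_read(umi=b + "A" * 11) for _ in range(10)])
                for b in "ACGT"]
        table = consensus_composition(fams, reference=REF, primer_len=0)
        assert table.subs.sum() == 0 and table.dels.sum() == 0
        assert (table.ref == 4).all()

    def test_insertion_unanimity_needs_identical_anchor_and_seq(self):
        same = [make_read(ins=((3, "GG"),)) for _ in range(10)]
        table = consensus_composition(
            [UmiFamily("a1", "A" * 12, same)], reference=REF, primer_len=0)
        assert table.ins[3] == 1
        mixed = [make_read(ins=((3, "GG"),)) for _ in range(9)] + [
            make_read(ins=((3, "GC"),))]
        table = consensus_composition(
            [UmiFamily("a1", "A" * 12, mixed)], reference=REF, primer_len=0)
        assert table.ins.sum() == 0

    def test_class_counts_sum_to_n_families(self):
        rng = np.random.default_rng(5)
        fams = _random_families(rng, n_fam=30, L=40)
        table = consensus_composition(fams, reference=_REF40, primer_len=0)
        total = table.ref + table.subs.sum(axis=1) + table.dels
        assert np.array_equal(total, table.n_families)

    def test_raising_min_depth_is_monotone(self):
        rng = np.random.default_rng(6)
        fams = _random_families(rng, n_fam=40, L=30)
        prev = consensus_composition(fams, min_depth=8, reference=_REF40[:30],
                                     primer_len=0)
        for depth in (10, 12, 14):
            cur = consensus_composition(fams, min_depth=depth,
                                        reference=_REF40[:30], primer_len=0)
            assert (cur.n_families <= prev.n_families).all()
            assert (cur.subs <= prev.subs).all()
            prev = cur

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fams = _random_families(rng, n_fam=min(50, 20 + seed * 5), L=50)
        table = consensus_composition(fams, reference=_REF40[:50] + _REF40[:10],
                                      primer_len=0)
        n_fam, ref, subs, dels = brute_force_consensus(
            fams, _REF40[:50] + _REF40[:10])
        assert np.array_equal(table.n_families, n_fam)
        assert np.array_equal(table.ref, ref)
        assert np.array_equal(table.subs, subs)
        assert np.array_equal(table.dels, dels)


_REF40 = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"


def _random_families(rng, n_fam, L):
    ref_codes = encode_calls("=" * L, _REF40[:L] + _REF40[: max(0, L - 40)])
    fams = []
    for i in range(n_fam):
        size = int(rng.integers(5, 16))
        base = ref_codes.copy()
        # plant some template-level variants
        for p in rng.integers(0, L, size=rng.integers(0, 3)):
            base[p] = rng.integers(0, 5)
        members = []
        for _ in range(size):
            calls = base.copy()
            err = rng.random(L) < 0.02
            calls[err] = rng.integers(0, 5, size=int(err.sum()))
            members.append(AmpliconRead("a1", f"umi{i}", calls))
        fams.append(UmiFamily("a1", f"umi{i}", members))
    return fams


class TestFilterAmplicons:
    def _table(self, depth_per_pos):
        n = np.asarray(depth_per_pos)
        return ConsensusTable("a", "A" * len(n), n, n.copy(),
                              np.zeros((len(n), 4), int),
                              np.zeros(len(n), int), np.zeros(len(n), int),
                              primer_len=0)

    def test_exactly_100_excluded_strictly(self):
        assert filter_amplicons([self._table([100] * 50)]) == []

    def test_101_kept(self):
        assert filter_amplicons([self._table([101] * 50)]) == ["a"]

    def test_fractional_mean_below_threshold_excluded(self):
        depths = [120, 90, 89] + [100] * 7  # mean 99.9
        assert np.mean(depths) < 100
        assert filter_amplicons([self._table(depths)]) == []


class TestReadIO:
    def test_roundtrip(self, tmp_path):
        panel = AmpliconPanel({"a1": Amplicon("a1", "c1", 0, 10, REF,
                                              primer_len=2)})
        reads = [make_read(calls="=G===-====", ins=((4, "TT"),)),
                 make_read(umi="C" * 12)]
        path = tmp_path / "reads.tsv"
        write_reads_tsv(reads, panel, path)
        back = read_reads_tsv(path, panel)
        for a, b in zip(reads, back):
            assert a.umi == b.umi
            assert np.array_equal(a.calls, b.calls)
            assert a.insertions == b.insertions

    def test_decode_encode_are_inverse(self):
        calls = "=G===-==T="
        codes = encode_calls(calls, REF)
        assert decode_calls(codes, REF) == calls
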