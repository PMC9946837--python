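"""Cut-site dedup, element counting, quartile stratification, downsampling."""

import numpy as np
import pandas as pd
import pytest

from breakscape.dsb import (dedup_cut_sites, element_counts,
                            genomewide_breaks, quartile_stratify,
                            read_cut_sites_tsv, write_cut_sites_tsv)
from breakscape.intervals import (GenomicInterval, RegulatoryElement,
                                  SignalTrack)
from breakscape.simulate import SimulationConfig, simulate_cut_sites


def records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "umi"])


def element(start, end, eid, chrom="c1"):
    return RegulatoryElement(GenomicInterval(chrom, start, end),
                             summit=(start + end) // 2, element_id=eid)


class TestDedup:
    def test_identical_records_collapse(self):
        recs = records([("c1", 10, "+", "AAAA"), ("c1", 10, "+", "AAAA"),
                        ("c1", 11, "+", "AAAA")])
        cs = dedup_cut_sites(recs, "s1")
        assert cs.n_events == 2 and cs.total_reads == 3

    def test_same_umi_two_positions_two_events(self):
        recs = records([("c1", 10, "+", "AAAA"), ("c1", 99, "+", "AAAA")])
        assert dedup_cut_sites(recs).n_events == 2

    def test_strand_in_key_by_default_and_switchable(self):
        recs = records([("c1", 10, "+", "AAAA"), ("c1", 10, "-", "AAAA")])
        assert dedup_cut_sites(recs).n_events == 2
        assert dedup_cut_sites(recs, use_strand=False).n_events == 1

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        recs = records([("c1", int(p), "+-"[s], u)
                        for p, s, u in zip(rng.integers(0, 50, 200),
                                           rng.integers(0, 2, 200),
                                           rng.choice(["AA", "CC", "GG"], 200))])
        cs1 = dedup_cut_sites(recs)
        shuffled = recs.sample(frac=1, random_state=0).reset_index(drop=True)
        cs2 = dedup_cut_sites(shuffled)
        pd.testing.assert_frame_equal(cs1.events, cs2.events)
        again = dedup_cut_sites(cs1.events.assign())
        assert again.n_events == cs1.n_events

    def test_pcr_duplicates_recover_planted_events(self):
        rng = np.random.default_rng(2)
        true = records([("c1", int(p), "+", f"u{i}")
                        for i, p in enumerate(rng.integers(0, 10_000, 500))])
        reps = rng.geometric(0.4, size=500)
        dup = true.loc[true.index.repeat(reps)].reset_index(drop=True)
        assert dedup_cut_sites(dup).n_events == 500


class TestElementCounts:
    def test_half_open_boundaries(self):
        elem = element(100, 200, "e0")
        sets = [dedup_cut_sites(records(
            [("c1", 99, "+", "a"), ("c1", 100, "+", "b"),
             ("c1", 199, "+", "c"), ("c1", 200, "+", "d")]), "s1")]
        counts = element_counts(sets, [elem])
        assert counts.loc["e0", "s1"] == 2

    def test_events_outside_all_elements_ignored(self):
        sets = [dedup_cut_sites(records(
            [("c1", i, "+", f"u{i}") for i in range(150, 155)]
            + [("c2", 150, "+", "x"), ("c1", 500, "+", "y")]), "s1")]
        counts = element_counts(sets, [element(100, 200, "e0")])
        assert counts.loc["e0", "s1"] == 5

    def test_overlapping_elements_both_count_shared_event(self):
        sets = [dedup_cut_sites(records([("c1", 150, "+", "a")]), "s1")]
        counts = element_counts(sets, [element(100, 200, "e0"),
                                       element(140, 240, "e1")])
        assert counts["s1"].tolist() == [1, 1]

    def test_invariant_to_chunking_a_sample(self):
        rng = np.random.default_rng(3)
        recs = records([("c1", int(p), "+", f"u{i}")
                        for i, p in enumerate(rng.integers(0, 1000, 300))])
        elems = [element(0, 400, "e0"), element(300, 800, "e1")]
        whole = element_counts([dedup_cut_sites(recs, "s")], elems)
        parts = [dedup_cut_sites(recs.iloc[:100], "p1"),
                 dedup_cut_sites(recs.iloc[100:], "p2")]
        split = element_counts(parts, elems)
        assert (whole["s"] == split.sum(axis=1)).all()


class TestQuartiles:
    def make(self, n=8):
        elems = [element(i * 1000, i * 1000 + 100, f"e{i}") for i in range(n)]
        runs = [("c1", e.interval.start, e.interval.end, float(i + 1))
                for i, e in enumerate(elems)]
        num = SignalTrack(runs)
        den = SignalTrack([("c1", 0, n * 1000 + 100, 1.0)])
        return elems, num, den

    def test_distinct_ratios_give_two_per_quartile(self):
        elems, num, den = self.make(8)
        labels = quartile_stratify(elems, num, den, peaks=[])
        quarts = [l.quartile for l in labels]
        assert quarts == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_quartile_sizes_differ_by_at_most_one(self):
        elems, num, den = self.make(10)
        labels = quartile_stratify(elems, num, den, peaks=[])
        sizes = pd.Series([l.quartile for l in labels]).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 10

    def test_q4_without_peak_is_not_high(self):
        elems, num, den = self.make(8)
        peaks = [elems[7].interval]  # only the very top element has a peak
        labels = quartile_stratify(elems, num, den, peaks)
        by_id = {l.element_id: l for l in labels}
        assert by_id["e7"].q4_high
        assert by_id["e6"].quartile == "Q4" and not by_id["e6"].q4_high
        assert by_id["e0"].q1_low and not by_id["e1"].q4_high

    def test_zero_denominator_ranked_and_flagged(self):
        elems = [element(0, 100, "e0"), element(1000, 1100, "e1")]
        num = SignalTrack([("c1", 0, 100, 5.0), ("c1", 1000, 1100, 1.0)])
        den = SignalTrack([("c1", 1000, 1100, 1.0)])  # e0 uncovered
        labels = quartile_stratify(elems, num, den, peaks=[], eps=1.0)
        by_id = {l.element_id: l for l in labels}
        assert by_id["e0"].zero_denominator
        assert by_id["e0"].ratio == pytest.approx(500 / 1.0)

    def test_labels_recover_generator_truth(self):
        from breakscape.simulate import simulate_elements, simulate_signal_tracks
        cfg = SimulationConfig()
        cfg.n_elements = 80
        elems = simulate_elements(cfg, 5)
        num, den, peaks, _, truth = simulate_signal_tracks(cfg, 6, elements=elems)
        labels = quartile_stratify(elems, num, den, peaks, eps=1.0)
        got = pd.Series({l.element_id: l.quartile for l in labels})
        agree = (got == truth.quartile.reindex(got.index)).mean()
        assert agree >= 0.95


class TestGenomewideBreaks:
    def sample(self, rng, n_events, depth, sid):
        true = records([("c1", int(p), "+", f"u{i}")
                        for i, p in enumerate(rng.integers(0, 10**6, n_events))])
        idx = rng.integers(0, n_events, size=depth - n_events)
        recs = pd.concat([true, true.iloc[idx]], ignore_index=True)
        return dedup_cut_sites(recs, sid), recs

    def test_identical_samples_equal_totals(self):
        rng = np.random.default_rng(4)
        cs, recs = self.sample(rng, 500, 900, "a")
        cs2 = dedup_cut_sites(recs, "b")
        totals = genomewide_breaks([cs, cs2], seed=1,
                                   records_per_sample=[recs, recs])
        assert totals["a"] == totals["b"]

    def test_deeper_sample_downsampled_to_min(self):
        rng = np.random.default_rng(5)
        cs1, r1 = self.sample(rng, 80, 100, "deep")
        cs2, r2 = self.sample(rng, 50, 60, "shallow")
        totals = genomewide_breaks([cs1, cs2], seed=7,
                                   records_per_sample=[r1, r2])
        assert totals.max() <= 60

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        cs1, r1 = self.sample(rng, 300, 500, "a")
        cs2, r2 = self.sample(rng, 400, 520, "b")
        t1 = genomewide_breaks([cs1, cs2], seed=3, records_per_sample=[r1, r2])
        t2 = genomewide_breaks([cs1, cs2], seed=3, records_per_sample=[r1, r2])
        assert t1.equals(t2)

    def test_single_sample_refused(self):
        rng = np.random.default_rng(7)
        cs, recs = self.sample(rng, 10, 15, "only")
        with pytest.raises(ValueError, match=">= 2 samples"):
            genomewide_breaks([cs], seed=0, records_per_sample=[recs])

    def test_zero_read_sample_refused(self):
        rng = np.random.default_rng(8)
        cs, recs = self.sample(rng, 10, 15, "ok")
        empty = dedup_cut_sites(records([]), "empty")
        with pytest.raises(ValueError, match="zero reads"):
            genomewide_breaks([cs, empty], seed=0,
                              records_per_sample=[recs, empty.events])


class TestCutSiteIO:
    def test_roundtrip(self, tmp_path):
        recs = records([("c1", 5, "+", "AAAA"), ("c2", 9, "-", "CCCC")])
        recs["sample_id"] = "s1"
        path = tmp_path / "cuts.tsv"
        write_cut_sites_tsv(recs, path)
        back = read_cut_sites_tsv(path)
        assert back["pos"].tolist() == [5, 9]
        assert back["strand"].tolist() == ["+", "-"]

    def test_rejects_multi_bp_records(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("c1\t5\t8\tAAAA\ts1\t+\n")
        with pytest.raises(ValueError, match="single-bp"):
            read_cut_sites_tsv(path)
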