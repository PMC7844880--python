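"""Per-base and per-read QC statistics against simulator ground truth."""

import numpy as np
import pytest

from seqsentry.mini_aligner import AlignmentRecord, PairRecord, align_pairs, pair_and_flag
from seqsentry.read_qc import (accumulate_base_stats, depth_distribution,
                               duplicate_rate, gc_bias, mapping_summary,
                               mark_duplicates)
from seqsentry.simulator import SimConfig, simulate_reads

from conftest import contig_regions


def proper_pair(ref, contig=0, s1=None, e2=None, length=150):
    c = ref.contigs[contig]
    if s1 is None:
        s1 = c.callable_interval[0] - 20
    if e2 is None:
        e2 = s1 + 350
    seq1 = c.seq[s1 : s1 + length]
    seq2 = c.seq[e2 - length : e2]
    a1 = AlignmentRecord("p", seq1, "I" * length, mapped=True, contig=contig,
                         start=s1, strand="+", cigar=[("M", length)], mapq=60)
    a2 = AlignmentRecord("p", seq2, "I" * length, mapped=True, contig=contig,
                         start=e2 - length, strand="-", cigar=[("M", length)],
                         mapq=60, is_read1=False)
    # mate2 record keeps reference-orientation bases internally
    from seqsentry._dna import revcomp

    a2.seq = revcomp(seq2)
    return pair_and_flag(a1, a2)


class TestBaseStats:
    def test_error_free_reads_no_mismatches(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=i) for i in range(5)]
        tables = accumulate_base_stats(pairs, ref)
        assert tables.qual_mismatch.sum() == 0
        assert tables.qual_total.sum() > 0
        # all pseudocounted bins sit at the cap
        emp = tables.empirical_quality()
        covered = tables.qual_total > 1000
        assert (emp[covered] >= 30).all()

    def test_depth_conservation_single_read(self, small_world):
        ref = small_world["ref"]
        c = ref.contigs[0]
        cs, ce = c.callable_interval
        s1 = cs  # read fully inside callable
        pair = proper_pair(ref, contig=0, s1=s1, e2=s1 + 400)
        tables = accumulate_base_stats([pair], ref)
        # both mates contribute their overlap with the callable span
        expected = sum(
            max(0, min(ce, st + 150) - max(cs, st))
            for st in (s1, s1 + 400 - 150)
        ) - sum(1 for st in (s1, s1 + 400 - 150) if st <= c.w < st + 150)
        assert sum(d.sum() for d in tables.depth) == expected

    def test_marker_column_excluded(self, small_world):
        ref = small_world["ref"]
        c = ref.contigs[0]
        # read carrying the ALT allele at the marker column
        s1 = c.w - 75
        seq = list(c.seq[s1 : s1 + 150])
        seq[c.w - s1] = c.marker.alt_allele
        a1 = AlignmentRecord("h", "".join(seq), "I" * 150, mapped=True,
                             contig=0, start=s1, strand="+",
                             cigar=[("M", 150)], nm=1, mapq=60)
        a2 = AlignmentRecord("h", "A" * 150, "I" * 150, mapped=False,
                             is_read1=False)
        tables = accumulate_base_stats([pair_and_flag(a1, a2)], ref)
        assert tables.qual_mismatch.sum() == 0  # alt base not a mismatch

    def test_planted_error_rate_recovered(self, small_world):
        """1% errors reported at Q20 give empirical quality ~20."""
        ref, genome = small_world["ref"], small_world["genome"]
        al = small_world["aligner"]
        cfg = SimConfig(seed=31, genome_length=200_000, n_markers=90,
                        base_quality=20, depth=6.0)  # error 1%
        pairs, _ = simulate_reads(genome, [c.marker for c in ref.contigs],
                                  cfg, regions=contig_regions(ref))
        aligned = align_pairs(pairs, al)
        tables = accumulate_base_stats(aligned, ref)
        n_bases = tables.qual_total[20]
        assert n_bases >= 1e5
        emp = tables.empirical_quality()[20]
        assert emp == pytest.approx(20.0, abs=1.0)

    def test_quality_by_cycle_decay(self, small_world):
        ref, genome = small_world["ref"], small_world["genome"]
        cfg = SimConfig(seed=32, genome_length=200_000, n_markers=90,
                        base_quality=38, quality_cycle_decay=0.1, depth=1.0)
        pairs, _ = simulate_reads(genome, [c.marker for c in ref.contigs],
                                  cfg, regions=contig_regions(ref))
        reads = [(p.seq1, p.qual1) for p in pairs]
        tables = accumulate_base_stats([], ref, all_reads=reads)
        mq = tables.mean_quality_by_cycle()
        assert mq[0] == pytest.approx(38, abs=0.5)
        assert mq[-1] < mq[0]


class TestDepth:
    def test_no_reads_all_zero(self, small_world):
        tables = accumulate_base_stats([], small_world["ref"],
                                       all_reads=[("A" * 150, "I" * 150)])
        dist = depth_distribution(tables)
        assert dist["mean"] == 0.0
        assert set(dist["histogram"]) == {0}

    def test_uniform_depth_recovery(self, small_world):
        ref, genome, al = (small_world["ref"], small_world["genome"],
                           small_world["aligner"])
        depth = 8.0
        cfg = SimConfig(seed=33, genome_length=200_000, n_markers=90,
                        depth=depth)
        pairs, _ = simulate_reads(genome, [c.marker for c in ref.contigs],
                                  cfg, regions=contig_regions(ref))
        aligned = align_pairs(pairs, al)
        tables = accumulate_base_stats(aligned, ref)
        dist = depth_distribution(tables)
        n_pos = tables.n_callable_positions
        se = np.sqrt(depth * 300 / n_pos)  # read-length correlation inflates SE
        assert dist["mean"] == pytest.approx(depth, abs=3 * se + 0.3)

    def test_depth_conservation_invariant(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=i) for i in range(10)]
        tables = accumulate_base_stats(pairs, ref)
        hist = depth_distribution(tables)["histogram"]
        total_from_hist = sum(d * n for d, n in hist.items())
        assert total_from_hist == sum(d.sum() for d in tables.depth)


class TestGcBias:
    def test_unbiased_flat(self, small_world):
        ref, genome, al = (small_world["ref"], small_world["genome"],
                           small_world["aligner"])
        cfg = SimConfig(seed=34, genome_length=200_000, n_markers=90, depth=15.0)
        pairs, _ = simulate_reads(genome, [c.marker for c in ref.contigs],
                                  cfg, regions=contig_regions(ref))
        aligned = align_pairs(pairs, al)
        tables = accumulate_base_stats(aligned, ref)
        bins = gc_bias(tables, bin_width=0.05)
        confident = [b for b in bins if not b["low_confidence"]]
        assert confident, "expected at least one well-populated GC bin"
        for b in confident:
            assert b["normalized_depth"] == pytest.approx(1.0, abs=0.15)

    def test_empty_bin_missing_not_zero(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=0)]
        bins = gc_bias(accumulate_base_stats(pairs, ref))
        assert any(b["normalized_depth"] is None for b in bins)

    def test_planted_gc_trend_recovered(self, small_world):
        """Depth increasing in GC yields increasing bin values.

        Synthetic contigs span a narrow GC range, so the planted effect is
        made steep (x3 across the range) to dominate Poisson noise.
        """
        ref = small_world["ref"]
        rng = np.random.default_rng(35)
        pairs = []
        for i, c in enumerate(ref.contigs):
            gc = sum(b in "GC" for b in c.seq) / len(c.seq)
            n = rng.poisson(40 * np.exp(20 * (gc - 0.5)))
            for k in range(int(n)):
                s1 = int(rng.integers(0, len(c.seq) - 400))
                pairs.append(proper_pair(ref, contig=i, s1=s1, e2=s1 + 400))
        tables = accumulate_base_stats(pairs, ref)
        bins = [b for b in gc_bias(tables, bin_width=0.02)
                if b["n_contigs"] >= 10]
        vals = [b["normalized_depth"] for b in bins]
        mids = [(b["gc_low"] + b["gc_high"]) / 2 for b in bins]
        assert len(vals) >= 2
        assert np.corrcoef(mids, vals)[0, 1] > 0.5


class TestDuplicates:
    def test_all_distinct_zero(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=i) for i in range(8)]
        assert duplicate_rate(pairs) == 0.0

    def test_three_identical_among_ten(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=i) for i in range(7)]
        pairs += [proper_pair(ref, contig=0, s1=160, e2=520) for _ in range(3)]
        assert duplicate_rate(pairs) == pytest.approx(2 / 10)

    def test_no_proper_pairs_missing(self):
        a1 = AlignmentRecord("x", "A" * 150, "I" * 150, mapped=False)
        a2 = AlignmentRecord("x", "A" * 150, "I" * 150, mapped=False,
                             is_read1=False)
        assert duplicate_rate([pair_and_flag(a1, a2)]) is None

    def test_planted_duplicate_rate(self, small_world):
        ref, genome, al = (small_world["ref"], small_world["genome"],
                           small_world["aligner"])
        cfg = SimConfig(seed=36, genome_length=200_000, n_markers=90,
                        depth=12.0, duplicate_rate=0.10)
        pairs, truth = simulate_reads(genome, [c.marker for c in ref.contigs],
                                      cfg, regions=contig_regions(ref))
        aligned = align_pairs(pairs, al)
        est = duplicate_rate(aligned)
        assert est == pytest.approx(truth.duplicate_fraction, abs=0.02)

    def test_mark_duplicates_consistent_with_rate(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=i) for i in range(5)]
        pairs += [proper_pair(ref, contig=1) for _ in range(2)]
        n_marked = mark_duplicates(pairs)
        n_proper = sum(p.proper for p in pairs)
        assert duplicate_rate(pairs) == pytest.approx(n_marked / n_proper)


class TestMappingSummary:
    def test_empty_input(self):
        s = mapping_summary(0, 0, [])
        assert s.total_reads == 0 and s.screen_pass_fraction is None

    def test_fraction_bounds(self, small_world):
        ref = small_world["ref"]
        pairs = [proper_pair(ref, contig=i) for i in range(4)]
        s = mapping_summary(10, 8, pairs)
        assert 0 <= s.screen_pass_fraction <= 1
        assert 0 <= s.mapped_fraction_of_screened <= 1
        assert s.caveats  # reduced-reference caveat always present

    def test_mixture_screen_fraction(self, small_world):
        from seqsentry.simulator import simulate_foreign_reads
        from seqsentry.spaced_hash import screen_reads_batch

        ref, genome, idx = (small_world["ref"], small_world["genome"],
                            small_world["index"])
        cfg = SimConfig(seed=37, genome_length=200_000, n_markers=90)
        inside, _ = simulate_reads(genome, [c.marker for c in ref.contigs],
                                   cfg, regions=contig_regions(ref),
                                   n_pairs=300)
        outside = simulate_foreign_reads(100_000, 300, cfg)
        reads = ([p.seq1 for p in inside] + [p.seq1 for p in outside])
        hits = screen_reads_batch(reads, idx)
        frac = (np.asarray(hits) >= 3).mean()
        assert frac == pytest.approx(0.5, abs=0.03)
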