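"""Base-level and read-level QC statistics.

Per-cycle quality comes straight from the raw reads; mismatch, depth and
GC statistics are restricted to the callable interval of each contig
(the central 2(w-r)+1 bases where reads align fully), excluding the
marker column itself so true alternate alleles are not counted as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import encode
from .mini_aligner import PairRecord
from .panel_builder import ReducedReference

MAX_QUAL = 64
EMPIRICAL_Q_CAP = 60.0
DEFAULT_GC_BIN_WIDTH = 0.025


@dataclass
class BaseQcTables:
    cycle_qual_sum: np.ndarray        # per-cycle summed reported quality
    cycle_count: np.ndarray
    qual_total: np.ndarray            # per reported-quality bin
    qual_mismatch: np.ndarray
    depth: list[np.ndarray]           # per contig, over callable positions
    contig_gc: np.ndarray
    n_callable_positions: int = 0

    def mean_quality_by_cycle(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.cycle_qual_sum / np.maximum(self.cycle_count, 1)

    def empirical_quality(self) -> np.ndarray:
        """Phred-scaled observed error per reported-quality bin.

        +1/+2 pseudocounts avoid infinities on zero mismatches; capped at 60.
        """
        rate = (self.qual_mismatch + 1.0) / (self.qual_total + 2.0)
        emp = -10.0 * np.log10(rate)
        return np.minimum(emp, EMPIRICAL_Q_CAP)


@dataclass
class ReadQcSummary:
    total_reads: int
    screen_pass_fraction: float | None
    mapped_fraction_of_screened: float | None
    whole_genome_mapped_proxy: float | None
    duplicate_rate: float | None
    mean_callable_depth: float | None
    read_length_histogram: dict[int, int] = field(default_factory=dict)
    caveats: list[str] = field(default_factory=list)


def accumulate_base_stats(pairs: list[PairRecord], ref: ReducedReference,
                          all_reads: list[tuple[str, str]] | None = None,
                          exclude_duplicates: bool = True) -> BaseQcTables:
    """One pass over alignments gathering base-level tallies.

    ``all_reads`` (seq, qual) supplies the pre-alignment per-cycle stats;
    when omitted the aligned pairs' reads are used.
    """
    max_cycle = 0
    reads_iter: list[tuple[str, str]] = []
    if all_reads is not None:
        reads_iter = all_reads
    else:
        for p in pairs:
            reads_iter.append((p.mate1.seq, p.mate1.qual))
            reads_iter.append((p.mate2.seq, p.mate2.qual))
    for seq, _ in reads_iter:
        max_cycle = max(max_cycle, len(seq))

    cycle_qual_sum = np.zeros(max_cycle)
    cycle_count = np.zeros(max_cycle, dtype=np.int64)
    for _, qual in reads_iter:
        q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int64) - 33
        cycle_qual_sum[: len(q)] += q
        cycle_count[: len(q)] += 1

    qual_total = np.zeros(MAX_QUAL, dtype=np.int64)
    qual_mismatch = np.zeros(MAX_QUAL, dtype=np.int64)
    depth = []
    contig_gc = np.zeros(len(ref.contigs))
    contig_codes = []
    for i, c in enumerate(ref.contigs):
        cs, ce = c.callable_interval
        depth.append(np.zeros(max(0, ce - cs), dtype=np.int64))
        codes = encode(c.seq)
        contig_codes.append(codes)
        contig_gc[i] = float(((codes == 1) | (codes == 2)).mean())

    n_callable = sum(len(d) for d in depth)

    for pair in pairs:
        if exclude_duplicates and pair.duplicate:
            continue
        for rec in (pair.mate1, pair.mate2):
            if not rec.mapped:
                continue
            c = ref.contigs[rec.contig]
            cs, ce = c.callable_interval
            center = c.w
            seq = rec.aligned_seq()
            qual = rec.aligned_qual()
            rcodes = encode(seq)
            quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int64) - 33
            # walk the cigar tracking read/ref offsets
            ri = 0
            gi = rec.start
            for op, length in rec.cigar:
                if op == "M":
                    g = np.arange(gi, gi + length)
                    mask = (g >= cs) & (g < ce) & (g != center)
                    if mask.any():
                        sel = np.nonzero(mask)[0]
                        gsel = g[sel]
                        q = np.clip(quals[ri + sel], 0, MAX_QUAL - 1)
                        mm = rcodes[ri + sel] != contig_codes[rec.contig][gsel]
                        np.add.at(qual_total, q, 1)
                        np.add.at(qual_mismatch, q[mm], 1)
                        np.add.at(depth[rec.contig], gsel - cs, 1)
                    ri += length
                    gi += length
                elif op == "I":
                    ri += length
                elif op == "D":
                    gi += length
    return BaseQcTables(cycle_qual_sum, cycle_count, qual_total, qual_mismatch,
                        depth, contig_gc, n_callable)


def depth_distribution(tables: BaseQcTables) -> dict:
    """Histogram plus mean/median depth over callable positions."""
    if tables.n_callable_positions == 0:
        return {"histogram": {}, "mean": None, "median": None}
    all_depth = np.concatenate([d for d in tables.depth]) if tables.depth else np.array([])
    vals, counts = np.unique(all_depth, return_counts=True)
    return {
        "histogram": {int(v): int(n) for v, n in zip(vals, counts)},
        "mean": float(all_depth.mean()),
        "median": float(np.median(all_depth)),
    }


def gc_bias(tables: BaseQcTables, bin_width: float = DEFAULT_GC_BIN_WIDTH) -> list[dict]:
    """Normalized mean callable depth per contig-GC bin.

    Bin value = pooled mean depth of the bin's contigs over the overall
    pooled mean; bins with <5 contigs are flagged low-confidence, empty
    bins report a missing value.
    """
    n_bins = int(round(1.0 / bin_width))
    totals = np.array([d.sum() for d in tables.depth], dtype=float)
    lengths = np.array([len(d) for d in tables.depth], dtype=float)
    overall = totals.sum() / lengths.sum() if lengths.sum() else 0.0
    out = []
    bins = np.minimum((tables.contig_gc / bin_width).astype(int), n_bins - 1)
    for b in range(n_bins):
        sel = bins == b
        n_contigs = int(sel.sum())
        if n_contigs == 0 or overall == 0:
            value = None
        else:
            value = float(totals[sel].sum() / lengths[sel].sum() / overall)
        out.append({
            "gc_low": b * bin_width,
            "gc_high": (b + 1) * bin_width,
            "n_contigs": n_contigs,
            "normalized_depth": value,
            "low_confidence": n_contigs < 5,
        })
    return out


def duplicate_rate(pairs: list[PairRecord]) -> float | None:
    """Fraction of proper pairs sharing both fragment endpoints with another.

    Groups by (contig, leftmost start, rightmost end, orientation); each
    group contributes size-1 duplicates.
    """
    groups: dict[tuple, int] = {}
    n_proper = 0
    for p in pairs:
        if not p.proper:
            continue
        n_proper += 1
        m1, m2 = p.mate1, p.mate2
        left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
        key = (m1.contig, left.start, right.end, left.strand + right.strand)
        groups[key] = groups.get(key, 0) + 1
    if n_proper == 0:
        return None
    dups = sum(n - 1 for n in groups.values())
    return dups / n_proper


def mark_duplicates(pairs: list[PairRecord]) -> int:
    """Flag all but the first pair of each fragment-endpoint group."""
    seen: set[tuple] = set()
    n_marked = 0
    for p in pairs:
        if not p.proper:
            continue
        m1, m2 = p.mate1, p.mate2
        left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
        key = (m1.contig, left.start, right.end, left.strand + right.strand)
        if key in seen:
            p.duplicate = True
            n_marked += 1
        else:
            seen.add(key)
    return n_marked


def mapping_summary(total_reads: int, n_screen_passed: int,
                    pairs: list[PairRecord],
                    tables: BaseQcTables | None = None) -> ReadQcSummary:
    """Three-number mapping summary with the reduced-reference caveat.

    The whole-genome mapped fraction cannot be measured directly against a
    reduced reference; the screened-and-mapped fraction is reported as a
    proxy with an explicit caveat (meaningful for whole-genome input only).
    """
    caveats = []
    n_mapped = sum((p.mate1.mapped + p.mate2.mapped) for p in pairs)
    lengths: dict[int, int] = {}
    for p in pairs:
        for s in (p.mate1.seq, p.mate2.seq):
            lengths[len(s)] = lengths.get(len(s), 0) + 1
    if total_reads == 0:
        return ReadQcSummary(0, None, None, None, None, None, {},
                             ["empty input: fractions not computed"])
    screen_frac = n_screen_passed / total_reads
    mapped_frac = n_mapped / n_screen_passed if n_screen_passed else None
    caveats.append("whole-genome mapped fraction is a proxy; "
                   "meaningful for whole-genome sequencing input only")
    dup = duplicate_rate(pairs)
    mean_depth = None
    if tables is not None and tables.n_callable_positions:
        mean_depth = depth_distribution(tables)["mean"]
    return ReadQcSummary(
        total_reads=total_reads,
        screen_pass_fraction=screen_frac,
        mapped_fraction_of_screened=mapped_frac,
        whole_genome_mapped_proxy=mapped_frac,
        duplicate_rate=dup,
        mean_callable_depth=mean_depth,
        read_length_histogram=lengths,
        caveats=caveats,
    )
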