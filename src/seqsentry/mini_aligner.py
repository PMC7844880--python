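"""Seed-and-extend alignment of screened reads to the reduced reference.

Candidate loci come from the spaced-hash probe hits via diagonal voting;
each candidate is verified ungapped first and by a small banded
edit-distance alignment if substitutions alone cannot explain the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import encode, revcomp
from .panel_builder import ReducedReference
from .spaced_hash import (KMER, N_WINDOWS, SCREEN_SPAN, WINDOW, SpacedHashIndex)

DEFAULT_MAX_MISMATCH = 5
DEFAULT_MAX_GAP = 3
DEFAULT_MIN_MAPQ = 20
MAX_CANDIDATES = 32


@dataclass
class AlignmentRecord:
    read_name: str
    seq: str
    qual: str
    mapped: bool
    contig: int = -1
    start: int = -1                      # 0-based leftmost reference position
    strand: str = "+"
    cigar: list[tuple[str, int]] = field(default_factory=list)
    nm: int = 0
    mapq: int = 0
    is_read1: bool = True

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        span = sum(n for op, n in self.cigar if op in ("M", "D"))
        return self.start + span

    def aligned_seq(self) -> str:
        """Read bases in reference orientation."""
        return self.seq if self.strand == "+" else revcomp(self.seq)

    def aligned_qual(self) -> str:
        return self.qual if self.strand == "+" else self.qual[::-1]


@dataclass
class PairRecord:
    mate1: AlignmentRecord
    mate2: AlignmentRecord
    proper: bool = False
    t_o: int | None = None
    duplicate: bool = False

    @property
    def name(self) -> str:
        return self.mate1.read_name


def _banded_align(read: np.ndarray, ref: np.ndarray, band: int):
    """Fitting alignment of the whole read inside a reference slice.

    Diagonals are restricted to +-band around the main one; leading and
    trailing reference bases are free.  Returns (nm, cigar, ref_start)
    within the slice, or None when no path fits the band.
    """
    n, m = len(read), len(ref)
    INF = 10 ** 9
    width = 2 * band + 1
    dp = np.full((n + 1, width), INF, dtype=np.int64)
    for d in range(width):
        if 0 <= d - band <= m:
            dp[0, d] = 0  # alignment may start at any leading ref offset
    for i in range(1, n + 1):
        for d in range(width):
            j = i + d - band
            if j < 0 or j > m:
                continue
            best = INF
            if j > 0 and dp[i - 1, d] < INF:
                best = dp[i - 1, d] + (0 if read[i - 1] == ref[j - 1] else 1)
            if d > 0 and dp[i, d - 1] < INF:
                best = min(best, dp[i, d - 1] + 1)       # deletion from read
            if d < width - 1 and dp[i - 1, d + 1] < INF:
                best = min(best, dp[i - 1, d + 1] + 1)   # insertion in read
            dp[i, d] = best
    d_end = int(np.argmin(dp[n]))
    nm = int(dp[n, d_end])
    if nm >= INF:
        return None
    ops: list[str] = []
    i, d = n, d_end
    while i > 0:
        j = i + d - band
        cur = dp[i, d]
        if j > 0 and dp[i - 1, d] < INF and cur == dp[i - 1, d] + (
            0 if read[i - 1] == ref[j - 1] else 1
        ):
            ops.append("M")
            i -= 1
        elif d > 0 and dp[i, d - 1] < INF and cur == dp[i, d - 1] + 1:
            ops.append("D")
            d -= 1
        elif d < width - 1 and dp[i - 1, d + 1] < INF and cur == dp[i - 1, d + 1] + 1:
            ops.append("I")
            i -= 1
            d += 1
        else:  # pragma: no cover - defensive
            return None
    ref_start = d - band
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return nm, cigar, ref_start


class Aligner:
    """Stateful wrapper caching encoded contigs and pattern shifts."""

    def __init__(self, index: SpacedHashIndex, ref: ReducedReference,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH,
                 max_gap: int = DEFAULT_MAX_GAP):
        self.index = index
        self.ref = ref
        self.max_mismatch = max_mismatch
        self.max_gap = max_gap
        self._codes = [encode(c.seq) for c in ref.contigs]
        self._pattern_pos = [list(p.positions) for p in index.patterns]

    # -- candidate generation ---------------------------------------------

    def _probe_keys(self, codes: list[int]) -> list[tuple[int, int, int | None]]:
        n_win = min(N_WINDOWS, len(codes) // WINDOW)
        out = []
        for w in range(n_win):
            base = w * WINDOW
            for pi, pos in enumerate(self._pattern_pos):
                key = 0
                ok = True
                for j in range(KMER):
                    c = codes[base + pos[j]]
                    if c > 3:
                        ok = False
                        break
                    key |= c << (2 * j)
                out.append((w, pi, key if ok else None))
        return out

    def _candidates(self, seq: str):
        votes: dict[tuple[int, int, str], int] = {}
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else revcomp(seq)
            codes = encode(oriented).tolist()
            for w, pi, key in self._probe_keys(codes):
                if key is None:
                    continue
                contigs, offsets = self.index.tables[pi].lookup(key)
                for ci, off in zip(contigs.tolist(), offsets.tolist()):
                    diag = off - w * WINDOW
                    k = (ci, diag, strand)
                    votes[k] = votes.get(k, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return [k for k, _ in ranked[:MAX_CANDIDATES]]

    # -- alignment ---------------------------------------------------------

    def align(self, name: str, seq: str, qual: str,
              is_read1: bool = True) -> AlignmentRecord:
        unmapped = AlignmentRecord(name, seq, qual, mapped=False, is_read1=is_read1)
        if len(seq) < WINDOW:
            return unmapped
        results = []
        read_codes = {"+": encode(seq), "-": encode(revcomp(seq))}
        n = len(seq)
        for ci, diag, strand in self._candidates(seq):
            ref_codes = self._codes[ci]
            rc = read_codes[strand]
            nm_cigar = None
            if 0 <= diag and diag + n <= len(ref_codes):
                mm = int((rc != ref_codes[diag : diag + n]).sum())
                if mm <= self.max_mismatch:
                    nm_cigar = (mm, [("M", n)], diag)
            if nm_cigar is None and self.max_gap > 0:
                lo = max(0, diag - self.max_gap)
                hi = min(len(ref_codes), diag + n + self.max_gap)
                if hi - lo >= n - self.max_gap:
                    res = _banded_align(rc, ref_codes[lo:hi], 2 * self.max_gap)
                    if res is not None:
                        nm, cigar, ref_start = res
                        indels = sum(c for op, c in cigar if op in "ID")
                        if nm - indels <= self.max_mismatch and indels <= self.max_gap:
                            nm_cigar = (nm, cigar, lo + ref_start)
            if nm_cigar is not None:
                nm, cigar, start = nm_cigar
                results.append((nm, ci, start, strand, cigar))
        if not results:
            return unmapped
        results.sort(key=lambda r: (r[0], r[1], r[2], 0 if r[3] == "+" else 1))
        nm, ci, start, strand, cigar = results[0]
        distinct = [r for r in results[1:] if (r[1], r[2], r[3]) != (ci, start, strand)]
        if not distinct:
            mapq = 60
        elif distinct[0][0] == nm:
            mapq = 0
        else:
            mapq = min(60, 10 * (distinct[0][0] - nm))
        return AlignmentRecord(name, seq, qual, mapped=True, contig=ci,
                               start=start, strand=strand, cigar=cigar,
                               nm=nm, mapq=mapq, is_read1=is_read1)


def pair_and_flag(a1: AlignmentRecord, a2: AlignmentRecord,
                  min_mapq: int = DEFAULT_MIN_MAPQ) -> PairRecord:
    """Classify a mate pair; compute the observed insert for proper pairs.

    Proper: both mapped on one contig with adequate mapq, opposite strands,
    leftmost mate forward, positive outer distance.
    """
    if a1.read_name != a2.read_name:
        raise ValueError(f"mate names differ: {a1.read_name} vs {a2.read_name}")
    pair = PairRecord(a1, a2)
    if not (a1.mapped and a2.mapped):
        return pair
    if a1.contig != a2.contig or a1.strand == a2.strand:
        return pair
    if a1.mapq < min_mapq or a2.mapq < min_mapq:
        return pair
    left, right = (a1, a2) if a1.start <= a2.start else (a2, a1)
    if left.strand != "+":
        return pair
    t_o = right.end - left.start
    if t_o <= 0:
        return pair
    pair.proper = True
    pair.t_o = t_o
    return pair


def align_pairs(pairs, aligner: Aligner,
                min_mapq: int = DEFAULT_MIN_MAPQ) -> list[PairRecord]:
    out = []
    for p in pairs:
        a1 = aligner.align(p.name, p.seq1, p.qual1, is_read1=True)
        a2 = aligner.align(p.name, p.seq2, p.qual2, is_read1=False)
        out.append(pair_and_flag(a1, a2, min_mapq))
    return out


# ---------------------------------------------------------------------------
# SAM I/O


def _sam_flag(rec: AlignmentRecord, mate: AlignmentRecord, proper: bool) -> int:
    flag = 0x1
    if proper:
        flag |= 0x2
    if not rec.mapped:
        flag |= 0x4
    if not mate.mapped:
        flag |= 0x8
    if rec.mapped and rec.strand == "-":
        flag |= 0x10
    if mate.mapped and mate.strand == "-":
        flag |= 0x20
    flag |= 0x40 if rec.is_read1 else 0x80
    return flag


def write_sam(pairs: list[PairRecord], ref: ReducedReference, path: str) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": len(c.seq)} for c in ref.contigs],
    }
    with pysam.AlignmentFile(path, "w", header=dict(header)) as out:
        for pair in pairs:
            for rec, mate in ((pair.mate1, pair.mate2), (pair.mate2, pair.mate1)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.read_name
                a.query_sequence = rec.aligned_seq()
                a.query_qualities = pysam.qualitystring_to_array(rec.aligned_qual())
                flag = _sam_flag(rec, mate, pair.proper)
                if pair.duplicate:
                    flag |= 0x400
                a.flag = flag
                if rec.mapped:
                    a.reference_id = rec.contig
                    a.reference_start = rec.start
                    a.mapping_quality = rec.mapq
                    a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
                    a.set_tag("NM", rec.nm)
                if mate.mapped:
                    a.next_reference_id = mate.contig
                    a.next_reference_start = mate.start
                if pair.proper and pair.t_o is not None:
                    sign = 1 if rec.start <= mate.start else -1
                    a.template_length = sign * pair.t_o
                out.write(a)


def read_sam(path: str, ref: ReducedReference,
             min_mapq: int = DEFAULT_MIN_MAPQ) -> list[PairRecord]:
    """Reconstruct pair records from a SAM produced by :func:`write_sam`."""
    import pysam

    by_name: dict[str, dict[int, AlignmentRecord]] = {}
    with pysam.AlignmentFile(path, "r") as sam:
        for a in sam:
            seq = a.query_sequence or ""
            qual = ("".join(chr(q + 33) for q in a.query_qualities)
                    if a.query_qualities is not None else "")
            if a.is_unmapped:
                rec = AlignmentRecord(a.query_name, seq, qual, mapped=False,
                                      is_read1=a.is_read1)
            else:
                strand = "-" if a.is_reverse else "+"
                if strand == "-":
                    seq, qual = revcomp(seq), qual[::-1]
                cigar = [("MIDNSHP=X"[op], n) for op, n in (a.cigartuples or [])]
                rec = AlignmentRecord(
                    a.query_name, seq, qual, mapped=True,
                    contig=a.reference_id, start=a.reference_start,
                    strand=strand, cigar=cigar,
                    nm=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    mapq=a.mapping_quality, is_read1=a.is_read1)
            by_name.setdefault(a.query_name, {})[1 if a.is_read1 else 2] = rec
    pairs = []
    for name, mates in by_name.items():
        if 1 in mates and 2 in mates:
            pairs.append(pair_and_flag(mates[1], mates[2], min_mapq))
    return pairs
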