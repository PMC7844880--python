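"""Marker selection and reduced-reference construction.

A reduced reference is a set of short contigs, each the flanking sequence
around a common SNP (the marker sits at the contig center).  Most markers
get short flanks; a configurable fraction get long flanks so that large
insert sizes remain observable.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

DEFAULT_W_SHORT = 250
DEFAULT_W_LONG = 1000
DEFAULT_LONG_FRACTION = 0.10
DEFAULT_MAF_MIN = 0.05
DEFAULT_N_TARGET = 10_000

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MarkerRecord:
    chrom: str
    pos: int                 # 1-based SNP position
    ref_allele: str
    alt_allele: str
    af: float                # alternate-allele frequency
    flank_class: str = "short"

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(f"{self.chrom}:{self.pos}: alleles must be A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref and alt alleles equal")
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"{self.chrom}:{self.pos}: af outside [0,1]")
        if self.flank_class not in ("short", "long"):
            raise ValueError("flank_class must be 'short' or 'long'")

    @property
    def maf(self) -> float:
        return min(self.af, 1.0 - self.af)


@dataclass
class MarkerPanel:
    markers: list[MarkerRecord]
    w_short: int = DEFAULT_W_SHORT
    w_long: int = DEFAULT_W_LONG
    long_fraction: float = DEFAULT_LONG_FRACTION

    def __len__(self) -> int:
        return len(self.markers)

    def w_for(self, marker: MarkerRecord) -> int:
        return self.w_long if marker.flank_class == "long" else self.w_short

    @property
    def n_long(self) -> int:
        return sum(1 for m in self.markers if m.flank_class == "long")


@dataclass
class ReducedContig:
    name: str
    marker: MarkerRecord
    seq: str
    w: int
    genome_offset: int                 # 0-based genome coord of contig base 0
    callable_interval: tuple[int, int]  # 0-based half-open, within contig

    def __post_init__(self) -> None:
        if len(self.seq) != 2 * self.w + 1:
            raise ValueError(f"{self.name}: contig length must be 2w+1")
        if self.seq[self.w] != self.marker.ref_allele:
            raise ValueError(f"{self.name}: center base differs from ref allele")


def callable_interval(w: int, read_len: int) -> tuple[int, int]:
    """Central 2(w-r)+1 bases, centered on the variant column w.

    A length-r read overlapping this span can always be placed fully
    inside the contig.
    """
    return (read_len, 2 * w + 1 - read_len)


@dataclass
class ReducedReference:
    contigs: list[ReducedContig]
    provenance: dict = field(default_factory=dict)
    _by_name: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_name:
            self._by_name = {c.name: i for i, c in enumerate(self.contigs)}
        if len(self._by_name) != len(self.contigs):
            raise ValueError("contig names not unique")

    def __len__(self) -> int:
        return len(self.contigs)

    def index_of(self, name: str) -> int:
        return self._by_name[name]

    def total_length(self) -> int:
        return sum(len(c.seq) for c in self.contigs)

    def sequences(self):
        for c in self.contigs:
            yield c.name, c.seq


# ---------------------------------------------------------------------------
# interval sets (BED-style, 0-based half-open)


class IntervalSet:
    """Per-chromosome sorted disjoint intervals with point/overlap queries."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in (intervals or {}).items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        ivs: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed BED line: {line!r}")
                ivs.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls(ivs)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Is the 0-based position inside any interval?"""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]


# ---------------------------------------------------------------------------
# operations


def select_markers(candidate_snps: list[MarkerRecord],
                   exclude_regions: IntervalSet | None = None,
                   target_regions: IntervalSet | None = None,
                   n_target: int = DEFAULT_N_TARGET,
                   maf_min: float = DEFAULT_MAF_MIN,
                   long_fraction: float = DEFAULT_LONG_FRACTION,
                   w_short: int = DEFAULT_W_SHORT,
                   w_long: int = DEFAULT_W_LONG,
                   seed: int = 0) -> MarkerPanel:
    """Uniformly sample eligible SNPs and build a marker panel.

    Eligibility: minor allele frequency strictly above ``maf_min``, not in
    ``exclude_regions``, inside ``target_regions`` when given.  After
    sampling, markers closer than 2*w_long are thinned greedily left to
    right so no two contigs can overlap.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    eligible = []
    for snp in candidate_snps:
        if snp.maf <= maf_min:
            continue
        pos0 = snp.pos - 1
        if exclude_regions is not None and exclude_regions.contains(snp.chrom, pos0):
            continue
        if target_regions is not None and not target_regions.contains(snp.chrom, pos0):
            continue
        eligible.append(snp)
    if not eligible:
        raise ValueError("no eligible markers after MAF/region filtering")

    rng = np.random.default_rng(seed)
    if len(eligible) > n_target:
        idx = rng.choice(len(eligible), size=n_target, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    else:
        chosen = list(eligible)
    chosen.sort(key=lambda m: (m.chrom, m.pos))

    kept: list[MarkerRecord] = []
    min_gap = 2 * w_long
    for m in chosen:
        if kept and kept[-1].chrom == m.chrom and m.pos - kept[-1].pos < min_gap:
            continue
        kept.append(m)

    n_long = round(long_fraction * len(kept))
    long_idx = set(rng.choice(len(kept), size=n_long, replace=False).tolist()) if n_long else set()
    markers = [
        MarkerRecord(m.chrom, m.pos, m.ref_allele, m.alt_allele, m.af,
                     "long" if i in long_idx else "short")
        for i, m in enumerate(kept)
    ]
    return MarkerPanel(markers, w_short=w_short, w_long=w_long,
                       long_fraction=long_fraction)


def extract_flanks(genome: dict[str, str], panel: MarkerPanel,
                   read_len: int) -> ReducedReference:
    """Cut one contig of length 2w+1 per marker, centered on the SNP.

    Markers are dropped (with a logged warning) when the flank runs off the
    chromosome, contains an ambiguous base, or the genome base at the
    marker position disagrees with the recorded reference allele.
    """
    contigs: list[ReducedContig] = []
    for m in panel.markers:
        w = panel.w_for(m)
        chrom_seq = genome.get(m.chrom)
        if chrom_seq is None:
            log.warning("marker %s:%d: chromosome missing from genome; dropped",
                        m.chrom, m.pos)
            continue
        start0 = m.pos - 1 - w
        end0 = m.pos + w
        if start0 < 0 or end0 > len(chrom_seq):
            log.warning("marker %s:%d: insufficient flank room; dropped", m.chrom, m.pos)
            continue
        seq = chrom_seq[start0:end0].upper()
        if seq[w] != m.ref_allele:
            log.warning("marker %s:%d: genome base %s != ref allele %s; dropped",
                        m.chrom, m.pos, seq[w], m.ref_allele)
            continue
        if any(b not in "ACGT" for b in seq):
            log.warning("marker %s:%d: ambiguous base in flank; dropped", m.chrom, m.pos)
            continue
        name = f"{m.chrom}_{m.pos}_{m.ref_allele}_{m.alt_allele}"
        contigs.append(ReducedContig(
            name=name, marker=m, seq=seq, w=w, genome_offset=start0,
            callable_interval=callable_interval(w, read_len)))
    return ReducedReference(
        contigs,
        provenance={"read_len": read_len, "w_short": panel.w_short,
                    "w_long": panel.w_long, "n_markers": len(panel)})


# ---------------------------------------------------------------------------
# on-disk round trip

_HEADER_FIELDS = ("chrom", "pos", "ref", "alt", "af", "w", "class", "offset", "callable")


def write_reduced_reference(ref: ReducedReference, prefix: str) -> tuple[str, str]:
    """FASTA (metadata in headers) + tab-delimited marker index."""
    fa_path, tsv_path = f"{prefix}.fa", f"{prefix}.markers.tsv"
    with open(fa_path, "w") as fa:
        for c in ref.contigs:
            m = c.marker
            cs, ce = c.callable_interval
            fa.write(
                f">{c.name} chrom={m.chrom} pos={m.pos} ref={m.ref_allele} "
                f"alt={m.alt_allele} af={m.af:.6g} w={c.w} class={m.flank_class} "
                f"offset={c.genome_offset} callable={cs}-{ce}\n")
            for i in range(0, len(c.seq), 60):
                fa.write(c.seq[i : i + 60] + "\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("contig_name\tchrom\tpos\tref\talt\taf\tw\tflank_class\n")
        for c in ref.contigs:
            m = c.marker
            tsv.write(f"{c.name}\t{m.chrom}\t{m.pos}\t{m.ref_allele}\t"
                      f"{m.alt_allele}\t{m.af:.6g}\t{c.w}\t{m.flank_class}\n")
    return fa_path, tsv_path


def read_reduced_reference(prefix: str) -> ReducedReference:
    from Bio import SeqIO

    contigs: list[ReducedContig] = []
    for rec in SeqIO.parse(f"{prefix}.fa", "fasta"):
        fields = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, _, v = tok.partition("=")
                fields[k] = v
        missing = [f for f in _HEADER_FIELDS if f not in fields]
        if missing:
            raise ValueError(
                f"record {rec.id}: header missing field(s) {', '.join(missing)}")
        marker = MarkerRecord(fields["chrom"], int(fields["pos"]), fields["ref"],
                              fields["alt"], float(fields["af"]), fields["class"])
        cs, ce = (int(x) for x in fields["callable"].split("-"))
        contigs.append(ReducedContig(
            name=rec.id, marker=marker, seq=str(rec.seq).upper(),
            w=int(fields["w"]), genome_offset=int(fields["offset"]),
            callable_interval=(cs, ce)))
    return ReducedReference(contigs)


def load_candidate_snps(vcf_path: str) -> list[MarkerRecord]:
    """Biallelic SNPs with an AF INFO field from a VCF."""
    import pysam

    out: list[MarkerRecord] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                continue
            af = rec.info.get("AF")
            if af is None:
                continue
            if isinstance(af, tuple):
                af = af[0]
            out.append(MarkerRecord(rec.chrom, rec.pos, ref, alt, float(af)))
    return out
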