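"""Per-marker pileup, genotype likelihoods, and VCF emission.

The likelihood model is the standard biallelic one: each base contributes
a mixture of the two allele identities weighted by the genotype's alt
dosage, with the per-base error read off its reported quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mini_aligner import PairRecord
from .panel_builder import ReducedReference

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 13

GENOTYPE_NAMES = ("0/0", "0/1", "1/1")


@dataclass
class PileupSite:
    marker_index: int
    # base identity codes: 0 = ref allele, 1 = alt allele, 2 = other
    base_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    quals: np.ndarray = field(default_factory=lambda: np.empty(0, np.int16))

    @property
    def depth(self) -> int:
        return len(self.base_ids)

    @property
    def n_ref(self) -> int:
        return int((self.base_ids == 0).sum())

    @property
    def n_alt(self) -> int:
        return int((self.base_ids == 1).sum())

    @property
    def n_other(self) -> int:
        return int((self.base_ids == 2).sum())


@dataclass
class GenotypeCall:
    gl: np.ndarray           # log10 likelihoods for (RR, RA, AA)
    pl: np.ndarray           # Phred-rescaled integers, min 0
    gp: np.ndarray           # posterior under HWE prior at panel AF
    gt: str                  # '0/0' | '0/1' | '1/1' | './.'

    @property
    def called(self) -> bool:
        return self.gt != "./."


def pileup(pairs: list[PairRecord], ref: ReducedReference,
           min_mapq: int = DEFAULT_MIN_MAPQ,
           min_baseq: int = DEFAULT_MIN_BASEQ,
           exclude_duplicates: bool = True) -> list[PileupSite]:
    """Base calls at each contig's center (marker) column.

    Reads below the mapq cutoff, bases below the baseq cutoff, and flagged
    duplicates are excluded.  Every marker yields a site, covered or not.
    """
    calls: list[tuple[list[int], list[int]]] = [([], []) for _ in ref.contigs]
    for pair in pairs:
        if exclude_duplicates and pair.duplicate:
            continue
        for rec in (pair.mate1, pair.mate2):
            if not rec.mapped or rec.mapq < min_mapq:
                continue
            contig = ref.contigs[rec.contig]
            center = contig.w
            ri, gi = 0, rec.start
            seq = rec.aligned_seq()
            qual = rec.aligned_qual()
            for op, length in rec.cigar:
                if op == "M":
                    if gi <= center < gi + length:
                        off = center - gi
                        q = ord(qual[ri + off]) - 33
                        if q >= min_baseq:
                            b = seq[ri + off]
                            m = contig.marker
                            bid = 0 if b == m.ref_allele else (1 if b == m.alt_allele else 2)
                            calls[rec.contig][0].append(bid)
                            calls[rec.contig][1].append(q)
                    ri += length
                    gi += length
                elif op == "I":
                    ri += length
                elif op == "D":
                    gi += length
    return [
        PileupSite(i, np.asarray(b, dtype=np.int8), np.asarray(q, dtype=np.int16))
        for i, (b, q) in enumerate(calls)
    ]


def genotype_likelihoods(site: PileupSite) -> np.ndarray:
    """log10 GL for alt dosage g in {0, 1, 2}.

    P(base|allele) = 1 - e if the base equals the allele, e/3 otherwise;
    P(base|g) = (g/2) P(base|alt) + (1 - g/2) P(base|ref).
    """
    if site.depth == 0:
        return np.zeros(3)
    e = 10.0 ** (-site.quals / 10.0)
    p_ref = np.where(site.base_ids == 0, 1.0 - e, e / 3.0)
    p_alt = np.where(site.base_ids == 1, 1.0 - e, e / 3.0)
    gl = np.empty(3)
    for g in range(3):
        per_base = (g / 2.0) * p_alt + (1.0 - g / 2.0) * p_ref
        gl[g] = np.log10(np.maximum(per_base, 1e-300)).sum()
    return gl


def call_genotype(site: PileupSite, af: float) -> GenotypeCall:
    """GL -> PL -> HWE posterior -> hard call."""
    if site.depth == 0:
        return GenotypeCall(np.zeros(3), np.zeros(3, dtype=int),
                            np.full(3, 1.0 / 3.0), "./.")
    gl = genotype_likelihoods(site)
    pl = np.round(-10.0 * (gl - gl.max())).astype(int)
    prior = np.array([(1 - af) ** 2, 2 * af * (1 - af), af ** 2])
    post = prior * 10.0 ** (gl - gl.max())
    gp = post / post.sum()
    gt = GENOTYPE_NAMES[int(np.argmax(gp))]
    return GenotypeCall(gl, pl, gp, gt)


def call_all(sites: list[PileupSite], panel_afs: np.ndarray) -> list[GenotypeCall]:
    return [call_genotype(s, float(panel_afs[s.marker_index])) for s in sites]


def write_vcf(calls: list[GenotypeCall], sites: list[PileupSite],
              ref: ReducedReference, path: str, sample: str = "SAMPLE",
              contig_lengths: dict[str, int] | None = None) -> None:
    """VCF 4.2 in genome coordinates with GT:PL:GP, sorted by (chrom, pos)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel allele frequency">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">')
    header.add_line('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">')
    chroms: dict[str, int] = {}
    for c in ref.contigs:
        m = c.marker
        need = m.pos + c.w + 1
        chroms[m.chrom] = max(chroms.get(m.chrom, 0), need)
    if contig_lengths:
        chroms.update(contig_lengths)
    for chrom, length in chroms.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_sample(sample)

    order = sorted(range(len(sites)),
                   key=lambda i: (ref.contigs[sites[i].marker_index].marker.chrom,
                                  ref.contigs[sites[i].marker_index].marker.pos))
    with pysam.VariantFile(path, "w", header=header) as out:
        for i in order:
            site, call = sites[i], calls[i]
            m = ref.contigs[site.marker_index].marker
            rec = out.new_record(contig=m.chrom, start=m.pos - 1,
                                 alleles=(m.ref_allele, m.alt_allele))
            rec.info["AF"] = m.af
            rec.info["DP"] = site.depth
            if call.called:
                gt = tuple(int(x) for x in call.gt.split("/"))
            else:
                gt = (None, None)
            rec.samples[sample]["GT"] = gt
            rec.samples[sample]["PL"] = tuple(int(x) for x in call.pl)
            rec.samples[sample]["GP"] = tuple(float(x) for x in call.gp)
            out.write(rec)


def genotype_concordance(calls: list[GenotypeCall], truth: np.ndarray) -> float:
    """Fraction of called sites matching true alt dosage."""
    n_called = 0
    n_match = 0
    for i, c in enumerate(calls):
        if not c.called:
            continue
        n_called += 1
        g = GENOTYPE_NAMES.index(c.gt)
        if g == int(truth[i]):
            n_match += 1
    return n_match / n_called if n_called else float("nan")


def panel_afs(ref: ReducedReference) -> np.ndarray:
    return np.array([c.marker.af for c in ref.contigs])
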