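"""Synthetic data generation: genomes, marker panels, reads, contamination.

Everything is driven by an explicit seed; identical configuration yields
byte-identical output.  This module is the test bed for the rest of the
package — no external downloads are ever required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._dna import revcomp
from .panel_builder import MarkerRecord

DEFAULT_READ_LEN = 150
DEFAULT_INSERT_MEAN = 350.0
DEFAULT_INSERT_SD = 50.0


@dataclass(frozen=True)
class SimConfig:
    seed: int
    genome_length: int = 1_000_000
    gc: float = 0.5
    n_markers: int = 500
    af_low: float = 0.05
    af_high: float = 0.5
    read_len: int = DEFAULT_READ_LEN
    depth: float = 10.0
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD
    base_quality: int = 30
    quality_cycle_decay: float = 0.0   # Phred lost per cycle, optional
    error_rate: float | None = None    # None -> implied by base_quality
    duplicate_rate: float = 0.0
    alpha: float = 0.0                 # contamination fraction
    chrom_name: str = "chrSim"

    def __post_init__(self) -> None:
        for name in ("gc", "duplicate_rate", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")

    @property
    def per_base_error(self) -> float:
        if self.error_rate is not None:
            return self.error_rate
        return 10.0 ** (-self.base_quality / 10.0)


@dataclass
class ReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class TruthSet:
    genotypes: np.ndarray            # (n_markers,) in {0,1,2}
    phase: np.ndarray                # which haplotype carries the alt when g==1
    insert_sizes: np.ndarray         # true fragment length per pair
    frag_start: np.ndarray           # 0-based genome start per pair
    duplicate_of: np.ndarray         # -1 for originals, else source pair index
    alpha: float = 0.0
    pc: np.ndarray | None = None

    @property
    def duplicate_fraction(self) -> float:
        n = len(self.duplicate_of)
        return float((self.duplicate_of >= 0).sum() / n) if n else 0.0


# ---------------------------------------------------------------------------
# genome & markers


def simulate_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[codes])


def plant_markers(genome: str, cfg: SimConfig, rng: np.random.Generator,
                  margin: int = 1001, min_spacing: int = 2000) -> list[MarkerRecord]:
    """Candidate SNPs on an evenly spaced grid with full flank room.

    Spacing is stretched to fill the genome but never drops below
    ``min_spacing`` (twice the default long flank half-width).
    """
    length = len(genome)
    n = cfg.n_markers
    usable = length - 2 * margin
    if n > 1:
        spacing = usable // (n - 1)
        if spacing < min_spacing:
            raise ValueError(
                f"genome of {length} bp cannot host {n} markers "
                f"at >= {min_spacing} bp spacing")
        positions0 = margin + spacing * np.arange(n)
    else:
        positions0 = np.array([length // 2])
    afs = rng.uniform(cfg.af_low + 1e-6, cfg.af_high, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    markers = []
    for i, p0 in enumerate(positions0):
        ref = genome[p0]
        alt = "ACGT"[("ACGT".index(ref) + alt_shift[i]) % 4]
        markers.append(MarkerRecord(cfg.chrom_name, int(p0) + 1, ref, alt, float(afs[i])))
    return markers


def simulate_reference_and_panel(cfg: SimConfig):
    """(genome dict, candidate markers) for panel construction."""
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_genome(cfg.genome_length, cfg.gc, rng)
    markers = plant_markers(genome, cfg, rng)
    return {cfg.chrom_name: genome}, markers


def simulate_genotypes(markers: list[MarkerRecord], rng: np.random.Generator,
                       afs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotypes plus a random phase for heterozygotes."""
    if afs is None:
        afs = np.array([m.af for m in markers])
    haps = rng.random((2, len(markers))) < afs
    genotypes = haps.sum(axis=0).astype(np.int8)
    phase = haps[0].astype(np.int8)  # 1 if haplotype 0 carries the alt
    return genotypes, phase


# ---------------------------------------------------------------------------
# reads


def _apply_genotype(hap_seq: np.ndarray, start: int, markers: list[MarkerRecord],
                    marker_pos0: np.ndarray, genotypes: np.ndarray,
                    phase: np.ndarray, hap: int) -> None:
    """Substitute alt alleles carried by this haplotype into a fragment."""
    end = start + len(hap_seq)
    lo = np.searchsorted(marker_pos0, start)
    hi = np.searchsorted(marker_pos0, end)
    for mi in range(lo, hi):
        g = genotypes[mi]
        carries = g == 2 or (g == 1 and phase[mi] == hap)
        if carries:
            hap_seq[marker_pos0[mi] - start] = ord(markers[mi].alt_allele)


def _quality_string(read_len: int, cfg: SimConfig) -> str:
    quals = np.maximum(
        2, cfg.base_quality - (cfg.quality_cycle_decay * np.arange(read_len))
    ).astype(int)
    return "".join(chr(q + 33) for q in quals)


def _error_probs(read_len: int, cfg: SimConfig) -> np.ndarray:
    if cfg.error_rate is not None:
        return np.full(read_len, cfg.error_rate)
    quals = np.maximum(2, cfg.base_quality - cfg.quality_cycle_decay * np.arange(read_len))
    return 10.0 ** (-quals / 10.0)


def simulate_reads(genome: dict[str, str], markers: list[MarkerRecord],
                   cfg: SimConfig,
                   regions: list[tuple[int, int]] | None = None,
                   n_pairs: int | None = None,
                   genotypes: np.ndarray | None = None,
                   phase: np.ndarray | None = None,
                   name_prefix: str = "sim") -> tuple[list[ReadPair], TruthSet]:
    """Paired FR reads from a diploid individual.

    Fragments are sampled uniformly from ``regions`` (default: the whole
    genome); insert sizes follow Normal(mean, sd) truncated at 2*read_len.
    Duplicates re-emit an earlier fragment's coordinates with fresh errors.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    chrom = cfg.chrom_name
    seq = genome[chrom]
    r = cfg.read_len
    if regions is None:
        regions = [(0, len(seq))]
    region_arr = np.array(regions)
    region_len = (region_arr[:, 1] - region_arr[:, 0])
    total_len = int(region_len.sum())
    if n_pairs is None:
        n_pairs = int(round(cfg.depth * total_len / (2 * r)))

    if genotypes is None or phase is None:
        genotypes, phase = simulate_genotypes(markers, rng)
    marker_pos0 = np.array([m.pos - 1 for m in markers])

    inserts = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
    while (inserts < 2 * r).any():
        bad = inserts < 2 * r
        inserts[bad] = rng.normal(cfg.insert_mean, cfg.insert_sd, size=int(bad.sum()))
    inserts = np.round(inserts).astype(np.int64)

    # fragment placement: pick a region by length, then a start inside it
    cum = np.cumsum(region_len)
    u = rng.integers(0, total_len, size=n_pairs)
    ridx = np.searchsorted(cum, u, side="right")
    offs = u - np.concatenate(([0], cum[:-1]))[ridx]
    starts = region_arr[ridx, 0] + offs
    # clamp so the fragment stays inside its region
    max_start = region_arr[ridx, 1] - inserts
    starts = np.minimum(starts, np.maximum(region_arr[ridx, 0], max_start))
    haps = rng.integers(0, 2, size=n_pairs)

    dup_of = np.full(n_pairs, -1, dtype=np.int64)
    if cfg.duplicate_rate > 0:
        is_dup = rng.random(n_pairs) < cfg.duplicate_rate
        is_dup[0] = False
        for i in np.nonzero(is_dup)[0]:
            src = int(rng.integers(0, i))
            while dup_of[src] >= 0:
                src = int(dup_of[src])
            dup_of[i] = src
            starts[i] = starts[src]
            inserts[i] = inserts[src]
            haps[i] = haps[src]

    pairs: list[ReadPair] = []
    qual = _quality_string(r, cfg)
    perr = _error_probs(r, cfg)
    for i in range(n_pairs):
        s, ins, hap = int(starts[i]), int(inserts[i]), int(haps[i])
        frag = np.frombuffer(seq[s : s + ins].encode(), dtype=np.uint8).copy()
        _apply_genotype(frag, s, markers, marker_pos0, genotypes, phase, hap)
        read1 = frag[:r].copy()
        read2_f = frag[ins - r :].copy()
        for arr in (read1, read2_f):
            errs = np.nonzero(rng.random(r) < perr)[0]
            for e in errs:
                cur = chr(arr[e])
                arr[e] = ord(rng.choice([b for b in "ACGT" if b != cur]))
        s1 = read1.tobytes().decode()
        s2 = revcomp(read2_f.tobytes().decode())
        pairs.append(ReadPair(f"{name_prefix}:{i}", s1, qual, s2, qual))

    truth = TruthSet(genotypes=genotypes, phase=phase, insert_sizes=inserts,
                     frag_start=starts, duplicate_of=dup_of, alpha=0.0)
    return pairs, truth


def simulate_foreign_reads(length: int, n_pairs: int, cfg: SimConfig,
                           name_prefix: str = "foreign") -> list[ReadPair]:
    """Read pairs from an unrelated random genome (screen-negative control)."""
    rng = np.random.default_rng(cfg.seed + 7)
    genome = {cfg.chrom_name: simulate_genome(length, cfg.gc, rng)}
    sub = replace(cfg, seed=cfg.seed + 7, duplicate_rate=0.0)
    pairs, _ = simulate_reads(genome, [], sub, n_pairs=n_pairs,
                              genotypes=np.empty(0, np.int8),
                              phase=np.empty(0, np.int8),
                              name_prefix=name_prefix)
    return pairs


def mix_contamination(pairs_a: list[ReadPair], pairs_b: list[ReadPair],
                      alpha: float, seed: int) -> tuple[list[ReadPair], float]:
    """Draw each output pair from B with probability alpha, else from A."""
    rng = np.random.default_rng(seed)
    n = len(pairs_a)
    from_b = rng.random(n) < alpha
    ib = rng.integers(0, len(pairs_b), size=n) if len(pairs_b) else np.zeros(n, int)
    out = []
    for i in range(n):
        src = pairs_b[int(ib[i])] if from_b[i] else pairs_a[i]
        out.append(ReadPair(f"mix:{i}", src.seq1, src.qual1, src.seq2, src.qual2))
    return out, float(from_b.mean()) if n else 0.0


# ---------------------------------------------------------------------------
# FASTQ I/O


def write_fastq(pairs: list[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1: str, path2: str) -> list[ReadPair]:
    import pysam

    pairs = []
    with pysam.FastxFile(path1) as r1, pysam.FastxFile(path2) as r2:
        for e1, e2 in zip(r1, r2):
            name = e1.name[:-2] if e1.name.endswith("/1") else e1.name
            pairs.append(ReadPair(name, e1.sequence, e1.quality or "",
                                  e2.sequence, e2.quality or ""))
    return pairs


def write_snp_vcf(markers: list[MarkerRecord], contig_lengths: dict[str, int],
                  path: str) -> None:
    """Minimal VCF 4.2 with AF INFO for candidate-SNP input."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in markers:
            fh.write(f"{m.chrom}\t{m.pos}\t.\t{m.ref_allele}\t{m.alt_allele}"
                     f"\t.\tPASS\tAF={m.af:.6g}\n")


# ---------------------------------------------------------------------------
# pileup-level fixtures (fast path for estimator recovery experiments)


def simulate_pileups(afs1: np.ndarray, afs2: np.ndarray, alpha: float,
                     depth: float, base_quality: int, seed: int,
                     genotypes1: np.ndarray | None = None):
    """Marker pileups for a two-person mixture, bypassing read alignment.

    Genotypes are Hardy-Weinberg draws at each person's site frequencies;
    read counts are Poisson(depth); each read comes from the contaminant
    with probability alpha and errs to a random other base at the rate
    implied by ``base_quality``.  Returns (pileups, genotypes1, genotypes2).
    """
    from .variant_qc import PileupSite

    rng = np.random.default_rng(seed)
    n = len(afs1)
    if genotypes1 is None:
        genotypes1 = rng.binomial(2, afs1).astype(np.int8)
    genotypes2 = rng.binomial(2, afs2).astype(np.int8)
    err = 10.0 ** (-base_quality / 10.0)
    depths = rng.poisson(depth, size=n)
    sites = []
    for i in range(n):
        d = int(depths[i])
        if d == 0:
            sites.append(PileupSite(i))
            continue
        from_b = rng.random(d) < alpha
        g = np.where(from_b, genotypes2[i], genotypes1[i])
        base = (rng.random(d) < g / 2.0).astype(np.int8)  # 1 = alt
        flip = rng.random(d) < err
        # identity codes: 0=ref, 1=alt, 2=other; an error picks uniformly
        # among the three non-true bases, one of which is the opposite
        # allele and two of which are 'other'
        wrong = rng.integers(0, 3, size=d)
        out = base.copy()
        for j in np.nonzero(flip)[0]:
            if wrong[j] == 0:
                out[j] = 1 - base[j]
            else:
                out[j] = 2
        quals = np.full(d, base_quality, dtype=np.int16)
        sites.append(PileupSite(i, out, quals))
    return sites, genotypes1, genotypes2


# ---------------------------------------------------------------------------
# contamination / ancestry fixtures


@dataclass
class SvdSimTruth:
    pc_by_pop: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_svd_panel(n_markers: int, seed: int, n_pc: int = 2,
                       populations: tuple[str, ...] = ("POPA", "POPB", "POPC"),
                       samples_per_pop: int = 20,
                       centroid_scale: float = 1.0):
    """Synthetic SVD panel with well-separated population clusters.

    Returns (mu, loadings, ref_coords, truth) where ref_coords is a list of
    (sample, pop, pc-vector).  Loadings are scaled so every population
    centroid keeps all site frequencies inside (0, 1).
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(0.3, 1.7, size=n_markers)
    loadings = rng.normal(0.0, 0.08, size=(n_markers, n_pc))
    k = len(populations)
    angles = 2 * np.pi * np.arange(k) / k
    centroids = centroid_scale * np.column_stack(
        [np.cos(angles), np.sin(angles)] + [np.zeros(k)] * (n_pc - 2))[:, :n_pc]
    truth = SvdSimTruth({pop: centroids[i] for i, pop in enumerate(populations)})
    ref_coords = []
    for i, pop in enumerate(populations):
        jitter = rng.normal(0, 0.05, size=(samples_per_pop, n_pc))
        for s in range(samples_per_pop):
            ref_coords.append((f"{pop}_{s:03d}", pop, centroids[i] + jitter[s]))
    return mu, loadings, ref_coords, truth
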