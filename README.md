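# seqsentry

Rapid quality assessment of raw short-read sequencing data without a full
genome alignment.  Instead of mapping every read to the whole reference,
seqsentry aligns only to a **variant-centric reduced reference**: a few
thousand small contigs, each the flanking sequence around a known common
SNP.  A mismatch-tolerant **spaced k-mer pre-filter** discards reads that
could never align to those contigs, so the expensive steps touch only a
tiny fraction of the input.  From the resulting partial alignment the
package derives:

- base-level QC: reported vs empirical base quality, quality by cycle,
  depth distribution and GC bias over the "callable" contig cores;
- read-level QC: mapping and duplicate rates, and a **censoring-corrected
  insert-size distribution** — pairs with only one mate inside a contig
  right-censor the insert size, and a Kaplan-Meier product-limit estimator
  removes the resulting bias;
- variant-level QC: per-marker pileups, genotype likelihoods (VCF with
  GT/PL/GP), and a joint likelihood estimate of **DNA contamination
  (alpha) and genetic ancestry** against an SVD allele-frequency panel.

A bundled simulator generates genomes, SNP panels, reads (with errors,
duplicates, and in-silico contamination) and SVD panels, so everything can
be built and tested offline.

## Design notes

- The read filter uses six 16-of-32 position patterns (four contiguous
  8-base blocks, one pattern per block pair).  Any two mismatch positions
  are jointly avoided by at least one pattern, so a 32-mer with <=2
  mismatches always matches >=1 table.  Screening the first 96 bases of a
  read makes 18 probes; at the default threshold of 3 hits, reads with
  fewer than 7 mismatches are guaranteed to pass (exactly — see
  `worst_case_min_hits`).
- The aligner is a seed-and-extend verifier driven by the same spaced-hash
  index (diagonal voting + banded edit distance), not a BWT engine; the
  output contract (SAM, pairing flags, NM) is the same.
- Insert-size censoring is anchored at each fragment's forward-strand
  mate by default (`censor_policy="left"`), which makes the product-limit
  estimate unbiased; see `seqsentry.insert_size_km` for the discussion.

## CLI

```sh
seqsentry simulate --seed 1 --out sim/                 # synthetic inputs
seqsentry index --ref sim/genome.fa --snps sim/snps.vcf --n 10000 \
    --seed 1 --out idx                                 # reduced reference + hash index
seqsentry screen --index idx --fastq R1.fq R2.fq --min-hits 3 --out scr
seqsentry align  --index idx --fastq R1.fq R2.fq --out aligned.sam
seqsentry insertsize --sam aligned.sam --ref idx --out ins
seqsentry genotype   --sam aligned.sam --ref idx --out sample.vcf
seqsentry contam     --sam aligned.sam --ref idx --panel panel --out c.json
seqsentry qc         --sam aligned.sam --ref idx --out qc.json
seqsentry run --index idx --fastq R1.fq R2.fq --out run/   # all-in-one + HTML report
```

Exit codes: 0 ok, 2 usage error, 3 data error.

## Layout

| module | role |
| --- | --- |
| `panel_builder` | marker selection, flank extraction, reduced-reference I/O |
| `spaced_hash` | pattern design, hash index, read screening, worst-case analysis |
| `mini_aligner` | seed-and-extend alignment, pairing, SAM I/O |
| `read_qc` | base/read-level statistics (quality, depth, GC, duplicates) |
| `insert_size_km` | insert tuples, Kaplan-Meier estimator, CDF distances |
| `variant_qc` | pileup, genotype likelihoods, VCF output |
| `contam_ancestry` | contamination/ancestry mixture likelihood and optimizer |
| `simulator` | synthetic genomes, reads, pileups, SVD panels |
| `report` / `cli` | pipeline orchestration, JSON report, HTML rendering |
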