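# cnvlite

Copy-number analysis from whole-genome sequencing, combining two
complementary signals:

* **Read depth (RD)** — reads counted in 100-bp bins, rebinned to any
  multiple of 100 bp, corrected for GC bias, segmented with a multi-scale
  mean-shift algorithm, and turned into deletion/duplication calls scored
  with four significance statistics (e-val1–4) plus mappability (q0),
  N-fraction (pN) and distance-to-gap (dG) annotations.
* **B-allele frequency (BAF)** — SNP and 1-bp-indel allele counts from a
  VCF, filtered by a strict accessibility mask, combined per bin into a
  symmetrized-beta likelihood on a discretized [0, 0.5] grid. The grid
  argmax is the maximum-likelihood BAF level; copy-number-neutral LOH is
  visible here even when RD is flat.

Regions can be genotyped (CN = 2 × mean RD / autosomal mean, with
boundary bins weighted by overlap), calls filtered on five parameters
(size, e-val1, q0, pN, dG), merged across samples by strict >50%
reciprocal overlap, and annotated against an offline gene table. All
tracks and calls live in a single HDF5 keyed store per sample; exports
include TSV, structural-variant VCF, and multi-resolution bedGraph tracks
(1/10/100 kb) for genome browsers. A synthetic fixture generator writes
FASTA/SAM/VCF files with planted deletions, duplications and CNN-LOH
events, so the whole pipeline is testable offline.

## CLI quick tour

```sh
# generate a small fixture set with a planted deletion
cnvlite simulate --preset del --out fixtures --length 2000000 --seed 7

# RD branch: parse alignments, bin + GC-correct, call CNVs
cnvlite rd parse fixtures/reads.sam --store sample.h5 --fasta fixtures/ref.fa
cnvlite rd his 10000 --store sample.h5
cnvlite rd call 10000 --store sample.h5

# SNP branch: import variants, apply strict mask, bin BAF likelihoods
cnvlite snp parse fixtures/sites.vcf --store sample.h5
cnvlite snp mask mask.bed --store sample.h5
cnvlite snp his 100000 --store sample.h5

# exports
cnvlite export tsv 10000 --store sample.h5 --out calls.tsv
cnvlite export vcf 10000 --store sample.h5 --out calls.vcf
cnvlite export jbrowse --store sample.h5 --out tracks/
```

The reference FASTA is only needed once: per-100-bp GC/AT/N content is
computed on first parse and stored in the keyed store, so later steps
(including GC correction) run without it.

## Python API

```python
from cnvlite import rd, baf, genome, genotype, simulate

seqs = simulate.simulate_reference({"1": 2_000_000}, seed=1)
asm = genome.compute_content(seqs)
rd100, q0100, _ = rd.parse_alignments("reads.sam", asm)
track = rd.rebin(rd100, 10_000)
gc = rd.gc_per_bin(asm, 10_000)
stats = rd.fit_rd_stats(track, gc, asm)
corrected, flags = rd.gc_correct(track, stats, gc)
segments = rd.mean_shift_segment(corrected, stats, flags)
calls = rd.call_cnvs(segments, corrected, stats, q0100, rd100, asm,
                     genome.find_gaps(asm))
```

## Tests

```sh
python -m pytest -q tests/
```

The suite is fully self-contained: every fixture (reference sequences,
SAM, VCF, BED) is generated at test time by `cnvlite.simulate` or small
writers in `tests/conftest.py`.

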