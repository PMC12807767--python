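# actghap

A toolkit for a hierarchical gene-haplotype nomenclature. Starting from a
transcript model (GFF3), a reference slice (FASTA) and haplotype-resolved
contig alignments (SAM/BAM), it:

- partitions each gene into 5'UTR / CDS / intron / 3'UTR regions plus fixed
  5 kb flanks (`gene_model`);
- calls variants from alignment CIGARs, classifies them into levels —
  **A** (protein-changing), **C** (synonymous coding), **T** (exonic
  non-coding), **G** (intronic), **U/D** (flanks) — and filters them with a
  Phred-scaled binomial variant quality (VQV) driven by per-contig
  homopolymer QV calibration tables (`variant_engine`);
- derives per-level haplotype sequences, clusters identical sequences, and
  assigns global frequency-ranked ids rendered as codes such as
  `HBB:a1c1t1g1` (id 0 = level not applicable; reference assemblies are
  ranked inside the same panel) (`nomenclature`);
- computes catalog statistics: Good-Turing cover ratio, Chao1
  richness/completeness, fixed-depth subsampled haplotype counts,
  length-normalized log2 z-scores, coverage summaries and OLS summaries
  (`diversity`);
- runs pairwise diplotype–expression association tests with cross-study
  effect-direction concordance filtering (`hapqtl`);
- generates every input synthetically — toy gene models, panels with
  controlled frequency spectra, homopolymer indel error injection with
  matched QV tables, diploid cohorts with planted expression effects
  (`synthetic`).

VQV semantics: a variant supported by `s` of `c` contigs under per-contig
error probability `p` gets `VQV = -10*log10(Pr[X >= s])`,
`X ~ Binomial(c, p)`; default retention thresholds are VQV ≥ 100 for A/C
(tail ≤ 1e-10) and VQV ≥ 50 for T/G/U/D (tail ≤ 1e-5).

## CLI

```sh
actghap simulate  --out sim --seed 1                 # synthetic inputs
actghap build     --gff sim/model.gff3 --fasta sim/reference.fa \
                  --sam sim/panel.sam --calibration sim/calibration.tsv \
                  --out build --flank 300            # catalog + codes
actghap assign    --catalog build/catalog.json --gff sim/model.gff3 \
                  --fasta sim/reference.fa --sam sim/panel.sam \
                  --out codes.tsv --flank 300        # sample -> codes
actghap dict-bam  --build-dir build --gff sim/model.gff3 \
                  --fasta sim/reference.fa --out dict.bam --flank 300
actghap diversity --catalog build/catalog.json --out div.tsv --seed 7
actghap hapqtl    --expression e1.tsv --expression e2.tsv \
                  --diplotypes dips.tsv --gene G1 --out assoc.tsv
```

`build` writes `catalog.json` / `catalog.tsv` (frequency-ranked clusters
with per-population counts), `variants.tsv` (level, flags, VQV, retained),
`codes.tsv` (per-haplotype composite codes) and `body_haplotypes.json`
(inputs for the dictionary BAM, where each record is one gene-body
haplotype carrying its level ids and population counts as `XA/XC/XT/XG/
XH/XP/XN` auxiliary tags).

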