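# promoterforge

Plant synthetic-biology circuits need more constitutive promoters than the
handful (35S, ubiquitin, actin) in common use: reusing the same promoter
invites recombination and homology-dependent silencing. `promoterforge`
implements a complete desk pipeline for mining new constitutive promoters
from transcriptome count data and engineering them into dCas9-repressible
NOR-gate promoters, together with the statistics used to score them in
ratio-metric fluorescence assays.

The pipeline, stage by stage:

1. **Stability ranking** (`promoterforge.rank`). Raw gene-level counts
   `K_ij` are normalized by median-of-ratios size factors
   `s_j = median_i ( K_ij / (prod_j K_ij)^(1/m) )` over genes with no zero
   counts (the DESeq2 scheme). Genes expressed in every sample are ranked by
   the coefficient of variation `CV_i = sd(K_i·/s) / mean(K_i·/s)` of their
   normalized counts, and the lowest `ceil(f·N)` genes are retained
   (default `f = 0.03`). A stress-condition CV, normalized separately
   against an untreated reference sample, is reported as an annotation only.
2. **Part extraction** (`promoterforge.parts`). The promoter part is the
   promoter plus the entire 5'UTR: from the base before the start codon
   upstream to at most 2,000 bp beyond the TSS or to the nearest annotated
   neighbouring gene, whichever is shorter. The terminator part is the 3'UTR
   plus at most 250 bp past the TES, truncated the same way. Genes whose
   parts overlap a neighbouring gene's span, or contain BsaI/BbsI
   recognition sites (Golden Gate/MoClo domestication), are removed.
3. **Motif scanning** (`promoterforge.motifs`). Promoters are scanned with
   MEME-format PWMs using log2-odds scores; thresholds come from an exact
   dynamic program over the background score distribution (default score
   p-value 1e-4).
4. **gRNA site placement** (`promoterforge.grna`). Two 23 bp windows (20 bp
   protospacer + NGG PAM), each inside the 500 bp upstream of the TSS, at
   least 67 bp apart edge-to-edge, and avoiding every predicted motif, are
   overwritten with target-site sequences verified absent from both strands
   of the genome — yielding a promoter repressible by either of two gRNAs
   through a dCas9 repressor (a NOR gate).
5. **Assay statistics** (`promoterforge.assay`). Transient screens:
   per-leaf negative-control median subtraction, mTURQ ratio normalization,
   selection of the 3 replicates closest to the group median, and Dunnett
   many-to-one tests at family-wise 0.05. NOR-gate assays: per-leaf
   normalization by the unrepressed (0,0) median, fold repression
   `median(0,0) / median(1,1)`, and one-way ANOVA with Tukey HSD summarized
   as a compact letter display.

Every stage is driven by seeded synthetic fixtures
(`promoterforge.simulate`) with recorded ground truth — a toy genome with
controlled intergenic spacing, negative-binomial count matrices with
planted stable genes, near-deterministic PWMs, and plate tables with known
repression ratios — so the whole pipeline is testable without downloads.

## Worked example

```sh
promoterforge simulate --seed 17 --outdir fixtures
promoterforge screen --counts fixtures/counts.tsv --genome fixtures/genome.fa \
    --gff fixtures/annotation.gff3 --motifs fixtures/motifs.meme --out run1
```

prints the filtering cascade (survivor counts per stage):

```
                stage  genes_in  genes_out                            parameters
     expressed_in_all       100        100          raw count > 0 in all samples
            lowest_cv       100          3       fraction=0.03, cv_cutoff=0.0640
      part_extraction         3          3 promoter_cap=2000, terminator_cap=250
       overlap_filter         3          2                    part vs gene spans
 domestication_filter         2          2                             BsaI,BbsI
placement_feasibility         2          2            tss_window=500, min_sep=67
```

Of 100 simulated genes, all pass the expressed-in-all filter, the 3 with
lowest CV are retained (3% retention, implied CV cutoff 0.064), one loses
its parts to a neighbouring gene's annotation, and the remaining two admit
two motif-avoiding, genome-orthogonal 23-mer sites — `run1/placements.tsv`
records the chosen windows (e.g. `G000: 1629-1652 and 1719-1742`, 67 bp
apart) and `run1/modified_promoters.fa` holds the NOR-gate promoter
sequences. The repression assay on the simulated plate table:

```sh
promoterforge assay-nor --table fixtures/plate_nor.csv
```

```
           mean letters
state
00     1.000000       a
01     0.565784       b
10     0.626649       b
11     0.479945       b
fold repression (0,0)/(1,1): 2.119
```

The unrepressed (0,0) state centres on 1 by construction; each single-input
state and the double-input state are significantly repressed (distinct CLD
letters from `a`), and the estimated fold repression recovers the simulated
2-fold ratio.

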