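# Methods

## Normalization and stability ranking

Counts are modelled as gene-level integers `K_ij` (gene *i*, sample *j*),
htseq-count style; rows whose id starts with `__` are counter sentinels and
dropped at parse time. Size factors follow the median-of-ratios scheme: the
pseudo-reference for gene *i* is the geometric mean of its counts across
samples, computed over the reference set of genes with no zero count, and
`s_j` is the median over that set of `K_ij / pseudo_i`. The median is taken
on the ratio scale (arithmetic interpolation at even reference-set sizes),
matching the convention of the widely used implementations; this is pinned
by a brute-force oracle test. Size factors are identifiable only up to a
common scale, so recovery tests compare estimates and truth after rescaling
both to geometric mean 1. A useful consequence worth stating explicitly:
rescaling one sample's raw counts shifts *all* normalized values by a single
global factor (the pseudo-reference moves by `k^(1/m)`), so normalized
values are only scale-equivariant — but CVs, CV rankings, and all ratio
statistics are exactly invariant, and that is what the tests assert.

The coefficient of variation uses the sample (n−1) standard deviation over
the arithmetic mean of normalized counts. The (n−1) choice is a convention
decision — either denominator produces the same ranking for a fixed sample
count — and is pinned by a hand-computed two-sample example
(values (1, 3) → CV = √2/2). CV is defined only for genes expressed in all
samples; "expressed" is evaluated on raw counts (any zero disqualifies),
before normalization.

Retention keeps the `ceil(f·N)` lowest-CV genes. The ceiling is forced by
the retention arithmetic the screen is built around: 3% of 10,096
expressed genes is 302.88, and the screen's reference behaviour keeps 303.
Ties at the cutoff break lexicographically by gene id so reruns are
deterministic.

Stress-condition samples are excluded from the main CV and handled in a
separate normalization: size factors are computed on the stress + reference
submatrix alone and the CV is taken across the stress samples only. The
result is an annotation column, never a filter. When the reference samples
are themselves part of the stress set they are deduplicated so the
degenerate "stress = all samples" case reduces exactly to the main CV.

## Part extraction

Internally all coordinates are 0-based half-open; GFF3 is parsed as 1-based
inclusive (via gffutils) and BED-style exports are half-open. TSS/TES come
from mRNA features, falling back to UTR bounds and finally to the gene span
(with a warning) — full gene models are assumed for real annotations.

The promoter part spans from the base immediately before the start codon
upstream to `min(TSS − 2000, nearest neighbour boundary)`; the terminator
part from the base after the stop codon to `min(TES + 250, neighbour
boundary)`. "Neighbour" means the nearest annotated gene-span edge on
either strand — the screen's definition is strand-agnostic, and overlapping
neighbours clamp the available distance to zero. Parts with no promoter
sequence left upstream of the TSS (neighbour at or inside the 5'UTR) are
flagged `zero_length` and excluded rather than erroring the run. When a
5'UTR itself would exceed the 2 kb cap the part still includes the entire
UTR: the cap constrains only the distance upstream of the TSS.

BsaI (GGTCTC) and BbsI (GAAGAC) recognition sequences come from standard
enzyme catalogues and live in a configurable table; both enzymes are
non-palindromic, so both strands are scanned. Domestication keeps a gene
only when both of its parts are free of all sites. The overlap and
domestication filters are independent set intersections and therefore
commute; a test asserts this on fixtures.

## Motif scanning

PWM scanning replaces the web-based binding-site prediction used in
promoter screens with a local, reproducible equivalent: log2-odds scores
against a background model (uniform unless the motif file provides one),
with probabilities regularized as `p' = (p + c·bg)/(1 + c)` at pseudocount
`c = 1e-3`. Because the stand-in's motif library and threshold differ from
any particular web service's, motif calls — and hence the exact candidate
list of any published screen — are not expected to be reproduced; what is
preserved is the rule structure downstream.

Score thresholds derive from an exact dynamic program: per-column scores
are discretized to a 1/1000 grid and convolved under the background model,
giving the full null score distribution; the threshold for a score p-value
(default 1e-4) is the smallest grid score whose tail mass is below it. The
DP agrees with an empirical shuffled-sequence null within Monte-Carlo error
and with Biopython's PSSM scoring on shared windows (both are test-only
cross-checks). Windows containing ambiguous bases score −inf and can never
be hits. Minus-strand hits are scored with the reverse-complemented matrix
and reported in the coordinates of the scanned sequence, which makes
scanning exactly strand-symmetric.

## gRNA site placement

A target site is 23 bp: a 20 bp protospacer plus NGG PAM at the 3' end
(SpCas9 convention, stored in config). Placement constraints: both windows
wholly inside the 500 bp immediately upstream of the TSS (containment, not
midpoint), neither intersecting any predicted motif interval, and an
edge-to-edge gap of at least 67 bp between window 1's end and window 2's
start. The edge-to-edge reading of "67 bp apart" is this package's
convention, pinned by the minimal-span example (113 bp is the smallest
window admitting a placement; a 115 bp window admits exactly 6). The
default placement maximizes the smaller of the two windows' distances to
the nearest forbidden boundary, tie-broken 5'-most — deterministic and easy
to audit; `all`/`count`/`first` modes expose the full enumeration, which is
checked against an exhaustive double loop.

Orthogonality is exact-substring absence over both genome strands. A
mismatch-tolerant mode is deliberately not the default: the screen's intent
is literature-validated guides with no perfect genomic match, and exact
matching keeps the guarantee crisp. Candidate sites come either from a
user-supplied library or from seeded random 20-mers + NGG; on any genome of
megabase scale the collision probability of a random 23-mer is ~`2n/4^23`,
so rejection is rare and the first `n` passing sites are deterministic
given the seed. Accepted sites are re-verified post hoc in tests. Window
replacement is byte-surgery: the modified promoter differs from the
original only inside the two windows (≤ 46 positions). Re-scanning a
modified promoter can create *new* motif hits at window junctions — the
engineering workflow tolerates this (it mirrors what happens with real
sequence replacement), and the tests assert only that no hit outside the
windows is lost.

## Assay statistics

The plate model: each leaf is a biological replicate carrying several
injections; each injection is read as 2 leaf discs × 12 reads = 24
datapoints. Transient normalization subtracts the per-leaf median YFP of
the mTURQ-only negative control, then divides by mTURQ per datapoint, so a
leaf-wide multiplicative gain applied jointly to all recorded channels
cancels exactly. Replicate selection keeps the `k = 3` replicates whose
median signals are closest to the median of replicate medians (ties by
replicate id); with ≤ k replicates all are kept with a warning.

The observation unit for the hypothesis tests defaults to the per-leaf
median: the 24 reads per injection are technical pseudo-replicates of one
biological sample, and treating them as independent would inflate the
nominal error rates. The datapoint-level unit remains available
(`unit="datapoint"`) because published analyses are often ambiguous on this
point. Dunnett many-to-one comparisons use the equicorrelated
multivariate-t critical points (scipy's implementation); the family-wise
type-I rate is verified by a 2,000-replicate null simulation to be within
±0.01 of 0.05. One numerical caveat: the multivariate-t CDF is evaluated by
quadrature, so in the single-treatment limit Dunnett's p agrees with the
two-sample t-test only to ~1e-4, and tests assert 5e-4.

NOR-gate assays divide each datapoint's YFP/mTURQ ratio by the per-leaf
median of the unrepressed (0,0) injection, mapping every leaf's (0,0)
median to exactly 1; variants of the no-input control (one vs two
non-matching guides) are pooled as a single (0,0) class. Fold repression is
`median(0,0) / median(1,1)` of the normalized signal. Group comparison is
one-way ANOVA, Tukey HSD at 0.05, and a compact letter display built by
insert-and-absorb: start from one column holding all groups, split every
column containing both members of a significant pair, absorb subset
columns, assign letters alphabetically. The invariant — two groups share a
letter iff not significantly different — is asserted directly against the
Tukey p-value matrix.

## Synthetic fixtures

Every generator is a pure function of (spec, seed) using a single
`numpy` Generator, so regeneration is byte-identical — asserted in tests.

*Genome*: genes laid out with controlled intergenic gaps (defaults exercise
both truncation regimes: 6 kb clear flanks, 1.2 kb and 150 bp squeezes, and
an overlapping-part case), explicit mRNA/UTR/CDS features, both strands.
Background sequence is scrubbed of all BsaI/BbsI occurrences so planted
sites are provably the only ones; motif consensi are embedded at recorded
offsets upstream of chosen TSSs. The sequence composition is i.i.d.
uniform — no isochores, no TATA context, no repeat structure — so passing
tests demonstrate rule correctness, not performance on real genomes.

*Counts*: `K_ij ~ NB(mean = mu_i·s_j, dispersion alpha_i)` with size
factors log-uniform in [0.5, 2] (geometric mean 1), background means
log-uniform in [10, 2000] with dispersions in [0.1, 0.6]
(RNA-seq-typical overdispersion), and 50 planted stable genes of 1,000
with dispersion 0.01 — at most one tenth of the background minimum, which
is what makes CV ranking able to separate them. A planted gene's NB CV is
roughly `sqrt(1/mu + alpha)` ≈ 0.12 versus ≥ 0.45 for background, so ≥ 90%
recovery in the lowest-5%-CV set is expected and asserted (the 5% set holds
~48 slots for 50 planted genes, capping recovery near 96%). The generator
has constant `mu_i` across samples: it emulates statistical shape, not
tissue-specific biology, so it cannot probe robustness to correlated
tissue effects.

*Plates*: `YFP = leaf_gain × strength × state_effect × lognormal(0, 0.2) +
autofluorescence` and `mTURQ = leaf_gain × control_strength × noise`, with
leaf gains lognormal(0, 0.4), 3 leaves, 2 discs × 12 reads. The additive
autofluorescence floor (default 10, ~1% of signal) exists so the
negative-control subtraction step is exercised meaningfully; it also means
ratio-based fold repression carries a small systematic compression (~2%
at defaults), well inside the sampling noise the recovery tests allow.
Default NOR state effects (1.0, 0.6, 0.6, 0.5) encode a true 2-fold
repression.

## Problem sizes and numerical choices

Simulation-backed checks run at sizes chosen to make their Monte-Carlo
error small relative to the asserted tolerance: 1,000 genes × 10 samples
for recovery properties, 2,000 replicates for the Dunnett family-wise rate
(binomial SE ≈ 0.005 against a ±0.01 band), 10 seeds × 72 datapoints for
fold-repression recovery, 200k draws for the motif-null cross-check. The
exact-DP score grid is 1/1000 of a log2-odds unit; interval arithmetic is
integer and exact; all tie-breaks (CV ranking, replicate selection,
placement choice) are lexicographic and documented above.

## Known limitations

- Motif calls are a functional stand-in for any particular prediction
  service; candidate lists from published screens are not reproducible by
  design.
- Orthogonality is exact-match only; off-target scoring with mismatches is
  out of scope.
- The count generator omits correlated tissue effects and library-specific
  GC biases; the genome generator omits realistic sequence composition.
- UTR-less annotations degrade TSS/TES to gene-span ends, which inflates
  promoter parts by the UTR length.
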