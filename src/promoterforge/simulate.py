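"""Seeded synthetic fixtures with recorded ground truth.

Everything downstream of the real data sources — a toy multi-gene genome
with annotation, a negative-binomial count matrix with sample size factors
and a planted set of stably expressed genes, a small PWM library with
planted promoter matches, and plate-reader fluorescence tables with known
repression ratios — can be generated here as a pure function of
(spec, seed). The recorded truth is sufficient to score every pipeline
stage without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motifs import PWM
from .parts import DEFAULT_ENZYMES
from .rank import CountMatrix

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _scrub_sites(seq: List[str], rng: np.random.Generator, patterns: Sequence[str]) -> None:
    """Destroy every occurrence of the patterns (both strands) in-place."""
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for pat in patterns:
            for p in (pat, _revcomp(pat)):
                pos = s.find(p)
                while pos != -1:
                    mid = pos + len(p) // 2
                    cur = seq[mid]
                    seq[mid] = "ACGT"[(("ACGT".index(cur)) + 1) % 4]
                    changed = True
                    s = "".join(seq)
                    pos = s.find(p, pos + 1)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneSpec:
    """Layout of one synthetic gene, lengths in bp (CDS multiple of 3)."""

    utr5: int = 120
    cds: int = 600
    utr3: int = 150
    strand: str = "+"
    gap_after: int = 3000  # intergenic distance to the next gene's span


@dataclass
class GenomeSpec:
    """A single-chromosome toy genome with controlled intergenic spacing.

    Defaults exercise both truncation regimes: some gaps exceed the 2 kb
    promoter cap, others are shorter so neighbour truncation binds.
    """

    chrom: str = "chr1"
    genes: List[GeneSpec] = field(
        default_factory=lambda: [
            GeneSpec(gap_after=6000),
            GeneSpec(strand="-", gap_after=1200),
            GeneSpec(gap_after=150),
            GeneSpec(strand="-", gap_after=4000),
            GeneSpec(gap_after=3000),
            GeneSpec(strand="-", gap_after=5000),
        ]
    )
    left_margin: int = 6000
    right_margin: int = 6000
    #: (gene_index, "promoter"|"terminator", enzyme name) -> plant a site
    planted_restriction: List[Tuple[int, str, str]] = field(default_factory=list)
    #: (gene_index, offset of motif start upstream of the TSS, consensus)
    planted_motifs: List[Tuple[int, int, str]] = field(default_factory=list)


@dataclass
class GenomeFixture:
    genome: Dict[str, str]
    gff3: str
    truth: pd.DataFrame  # per-gene ground-truth coordinates (0-based half-open)
    planted_sites: List[Tuple[str, str, str, int]]  # gene, part, enzyme, genomic pos
    planted_hits: List[Tuple[str, int, str]]  # gene, genomic pos, consensus

    def write(self, fasta_path, gff3_path) -> None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(gff3_path, "w") as fh:
            fh.write(self.gff3)


def gen_genome_annotation(spec: GenomeSpec, seed: int) -> GenomeFixture:
    """Build the toy genome, its GFF3, and the coordinate truth table.

    Background sequence is scrubbed of all BsaI/BbsI occurrences so that
    planted restriction sites are the only ones present; planted motif
    consensi are embedded upstream of the chosen genes' TSSs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cursor = spec.left_margin
    for i, g in enumerate(spec.genes):
        if g.cds % 3:
            raise ValueError(f"gene {i}: CDS length must be a multiple of 3")
        span = g.utr5 + g.cds + g.utr3
        start, end = cursor, cursor + span
        if g.strand == "+":
            tss, tes = start, end - 1
            cds_start, cds_end = start + g.utr5, start + g.utr5 + g.cds
        else:
            tss, tes = end - 1, start
            cds_start, cds_end = start + g.utr3, start + g.utr3 + g.cds
        rows.append(
            dict(
                gene_id=f"G{i:03d}",
                chrom=spec.chrom,
                strand=g.strand,
                start=start,
                end=end,
                tss=tss,
                tes=tes,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        cursor = end + g.gap_after
        if g.gap_after < 0:
            raise ValueError(f"gene {i}: negative intergenic gap")
    total = cursor - spec.genes[-1].gap_after + spec.right_margin
    seq = list(_random_seq(rng, total))
    truth = pd.DataFrame(rows).set_index("gene_id")

    # start/stop codons so the CDS is structurally plausible
    for _, r in truth.iterrows():
        if r.strand == "+":
            seq[r.cds_start : r.cds_start + 3] = "ATG"
            seq[r.cds_end - 3 : r.cds_end] = "TGA"
        else:
            seq[r.cds_end - 3 : r.cds_end] = list(_revcomp("ATG"))
            seq[r.cds_start : r.cds_start + 3] = list(_revcomp("TGA"))

    _scrub_sites(seq, rng, list(DEFAULT_ENZYMES.values()))

    planted_hits = []
    for idx, offset, consensus in spec.planted_motifs:
        r = truth.iloc[idx]
        if r.strand == "+":
            pos = r.tss - offset - len(consensus)
            seq[pos : pos + len(consensus)] = consensus
        else:
            pos = r.tss + 1 + offset
            seq[pos : pos + len(consensus)] = _revcomp(consensus)
        planted_hits.append((str(truth.index[idx]), int(pos), consensus))

    planted_sites = []
    for idx, part, enzyme in spec.planted_restriction:
        r = truth.iloc[idx]
        site = DEFAULT_ENZYMES[enzyme]
        # plant inside the UTR so the site always falls within the cloned part
        if part == "promoter":
            pos = (r.cds_start - 30) if r.strand == "+" else (r.cds_end + 10)
        else:
            pos = (r.cds_end + 10) if r.strand == "+" else (r.cds_start - 30)
        seq[pos : pos + len(site)] = site
        planted_sites.append((str(truth.index[idx]), part, enzyme, int(pos)))

    _assert_no_unplanted(seq, [p for _, _, _, p in planted_sites])

    gff = ["##gff-version 3"]
    for gid, r in truth.iterrows():
        common = f"{spec.chrom}\tsynth\t"
        attrs = f"ID={gid}"
        gff.append(
            f"{common}gene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}"
        )
        gff.append(
            f"{common}mRNA\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
            f"ID={gid}.1;Parent={gid}"
        )
        if r.strand == "+":
            utr5 = (r.start + 1, r.cds_start)
            utr3 = (r.cds_end + 1, r.end)
        else:
            utr5 = (r.cds_end + 1, r.end)
            utr3 = (r.start + 1, r.cds_start)
        if utr5[1] >= utr5[0]:
            gff.append(
                f"{common}five_prime_UTR\t{utr5[0]}\t{utr5[1]}\t.\t{r.strand}\t.\t"
                f"Parent={gid}.1"
            )
        gff.append(
            f"{common}CDS\t{r.cds_start + 1}\t{r.cds_end}\t.\t{r.strand}\t0\t"
            f"ID={gid}.cds;Parent={gid}.1"
        )
        if utr3[1] >= utr3[0]:
            gff.append(
                f"{common}three_prime_UTR\t{utr3[0]}\t{utr3[1]}\t.\t{r.strand}\t.\t"
                f"Parent={gid}.1"
            )
    return GenomeFixture(
        genome={spec.chrom: "".join(seq)},
        gff3="\n".join(gff) + "\n",
        truth=truth,
        planted_sites=planted_sites,
        planted_hits=planted_hits,
    )


def _assert_no_unplanted(seq: List[str], planted_positions: List[int]) -> None:
    s = "".join(seq)
    allowed = set(planted_positions)
    for pat in DEFAULT_ENZYMES.values():
        for p in (pat, _revcomp(pat)):
            pos = s.find(p)
            while pos != -1:
                if pos not in allowed:
                    raise AssertionError(
                        f"unplanted restriction site {p} at {pos}"
                    )
                pos = s.find(p, pos + 1)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountSpec:
    """Negative-binomial count matrix with planted stable genes.

    Background genes get gene-wise dispersion in ``background_dispersion``
    (RNA-seq-typical overdispersion); planted stable genes share the same
    mean model but a dispersion at most one tenth of the background minimum,
    so their CV across samples is markedly lower.
    """

    n_genes: int = 1000
    n_samples: int = 10
    n_planted: int = 50
    size_factor_range: Tuple[float, float] = (0.5, 2.0)  # log-uniform
    background_mean_range: Tuple[float, float] = (10.0, 2000.0)  # log-uniform
    background_dispersion: Tuple[float, float] = (0.1, 0.6)
    planted_mean_range: Tuple[float, float] = (200.0, 2000.0)
    planted_dispersion: float = 0.01


@dataclass
class CountFixture:
    matrix: CountMatrix
    size_factors: np.ndarray
    gene_means: np.ndarray
    dispersions: np.ndarray
    planted_gene_ids: List[str]


def gen_counts(spec: CountSpec, seed: int) -> CountFixture:
    """Sample K_ij ~ NB(mean = mu_i * s_j, dispersion alpha_i)."""
    rng = np.random.default_rng(seed)
    lo, hi = spec.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_samples))
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1, the estimable scale
    mu = np.exp(
        rng.uniform(
            np.log(spec.background_mean_range[0]),
            np.log(spec.background_mean_range[1]),
            spec.n_genes,
        )
    )
    alpha = rng.uniform(*spec.background_dispersion, spec.n_genes)
    planted_idx = rng.choice(spec.n_genes, spec.n_planted, replace=False)
    mu[planted_idx] = np.exp(
        rng.uniform(
            np.log(spec.planted_mean_range[0]),
            np.log(spec.planted_mean_range[1]),
            spec.n_planted,
        )
    )
    alpha[planted_idx] = spec.planted_dispersion
    mean = mu[:, None] * s[None, :]
    n_param = 1.0 / alpha
    p_param = n_param[:, None] / (n_param[:, None] + mean)
    counts = rng.negative_binomial(n_param[:, None], p_param)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j:02d}" for j in range(spec.n_samples)]
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    return CountFixture(
        matrix=cm,
        size_factors=s,
        gene_means=mu,
        dispersions=alpha,
        planted_gene_ids=[gene_ids[i] for i in sorted(planted_idx)],
    )


def gen_screen_counts(
    stable_gene_ids: Sequence[str],
    seed: int,
    n_background: int = 94,
    n_samples: int = 8,
    stable_mean: float = 500.0,
    stable_dispersion: float = 0.003,
    background_mean_range: Tuple[float, float] = (50.0, 2000.0),
    background_dispersion: Tuple[float, float] = (0.2, 0.6),
) -> CountFixture:
    """Count matrix coherent with a genome fixture: the annotated genes are
    the planted stable set, padded with overdispersed background genes."""
    rng = np.random.default_rng(seed)
    stable_gene_ids = list(stable_gene_ids)
    n_stable = len(stable_gene_ids)
    ids = stable_gene_ids + [f"BG{i:03d}" for i in range(n_background)]
    mu = np.concatenate(
        [
            np.full(n_stable, stable_mean),
            np.exp(
                rng.uniform(
                    np.log(background_mean_range[0]),
                    np.log(background_mean_range[1]),
                    n_background,
                )
            ),
        ]
    )
    alpha = np.concatenate(
        [
            np.full(n_stable, stable_dispersion),
            rng.uniform(*background_dispersion, n_background),
        ]
    )
    npar = 1.0 / alpha
    counts = rng.negative_binomial(
        npar[:, None], npar[:, None] / (npar[:, None] + mu[:, None]),
        size=(len(ids), n_samples),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=ids, columns=[f"S{j:02d}" for j in range(n_samples)])
    )
    return CountFixture(
        matrix=cm,
        size_factors=np.ones(n_samples),
        gene_means=mu,
        dispersions=alpha,
        planted_gene_ids=stable_gene_ids,
    )


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------


def gen_motifs(
    n_motifs: int, length: int, seed: int, consensus_prob: float = 0.97
) -> List[PWM]:
    """Near-deterministic PWMs: the consensus base carries most of the mass."""
    rng = np.random.default_rng(seed)
    pwms = []
    for k in range(n_motifs):
        consensus = rng.integers(0, 4, length)
        mat = np.full((4, length), (1 - consensus_prob) / 3)
        mat[consensus, np.arange(length)] = consensus_prob
        pwms.append(PWM(f"M{k:02d}", mat))
    return pwms


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------


@dataclass
class PlateSpec:
    """Plate-reader fixture: leaves x injections x 2 discs x 12 reads.

    The signal model is multiplicative — ``YFP = leaf_gain x construct
    strength x state effect x lognormal noise + autofluorescence`` and
    ``mTURQ = leaf_gain x control strength x noise`` — so the per-leaf
    ratio-metric normalizations cancel the leaf gain exactly up to noise.
    """

    n_leaves: int = 3
    discs: int = 2
    reads: int = 12
    leaf_gain_sd: float = 0.4  # sd of log leaf gain
    noise_sd: float = 0.2  # sd of log read noise
    autofluorescence: float = 10.0
    yfp_scale: float = 1000.0
    mturq_scale: float = 800.0
    #: transient design: construct label -> relative promoter strength
    construct_effects: Dict[str, float] = field(
        default_factory=lambda: {"P1": 1.0, "P2": 0.5}
    )
    #: NOR design: input state -> relative output of the gated promoter
    state_effects: Dict[str, float] = field(
        default_factory=lambda: {"00": 1.0, "01": 0.6, "10": 0.6, "11": 0.5}
    )


@dataclass
class PlateFixture:
    table: pd.DataFrame
    truth: Dict


def _reads(rng, spec: PlateSpec, leaf_gain: float, strength: float) -> np.ndarray:
    n = spec.discs * spec.reads
    noise = np.exp(rng.normal(0, spec.noise_sd, n))
    return leaf_gain * strength * noise


def gen_plate_table_transient(spec: PlateSpec, seed: int) -> PlateFixture:
    """Transient screen: each leaf carries every test construct plus the
    mTURQ-only negative control (autofluorescent YFP background only)."""
    rng = np.random.default_rng(seed)
    rows = []
    for leaf in range(spec.n_leaves):
        gain = float(np.exp(rng.normal(0, spec.leaf_gain_sd)))
        injections = [("neg", "negative_control", None, 0.0)] + [
            (label, "test", None, eff) for label, eff in spec.construct_effects.items()
        ]
        for label, role, state, eff in injections:
            yfp = _reads(rng, spec, gain, spec.yfp_scale * eff) + spec.autofluorescence
            mturq = _reads(rng, spec, gain, spec.mturq_scale)
            for i in range(spec.discs * spec.reads):
                rows.append(
                    dict(
                        leaf=f"L{leaf}",
                        injection=f"L{leaf}:{label}",
                        construct=label,
                        role=role,
                        state=state,
                        disc=i // spec.reads,
                        read=i % spec.reads,
                        YFP=float(yfp[i]),
                        mTURQ=float(mturq[i]),
                    )
                )
    table = pd.DataFrame(rows)
    table["state"] = table["state"].astype("string")
    return PlateFixture(
        table,
        truth=dict(construct_effects=dict(spec.construct_effects)),
    )


def gen_plate_table_nor(spec: PlateSpec, seed: int, gate: str = "mP1") -> PlateFixture:
    """NOR-gate assay: the four input states injected on every leaf."""
    rng = np.random.default_rng(seed)
    rows = []
    for leaf in range(spec.n_leaves):
        gain = float(np.exp(rng.normal(0, spec.leaf_gain_sd)))
        for state, eff in spec.state_effects.items():
            role = "unrepressed_control" if state == "00" else "test"
            yfp = _reads(rng, spec, gain, spec.yfp_scale * eff) + spec.autofluorescence
            mturq = _reads(rng, spec, gain, spec.mturq_scale)
            for i in range(spec.discs * spec.reads):
                rows.append(
                    dict(
                        leaf=f"L{leaf}",
                        injection=f"L{leaf}:{gate}:{state}",
                        construct=gate,
                        role=role,
                        state=state,
                        disc=i // spec.reads,
                        read=i % spec.reads,
                        YFP=float(yfp[i]),
                        mTURQ=float(mturq[i]),
                    )
                )
    table = pd.DataFrame(rows)
    table["state"] = table["state"].astype("string")
    true_fold = spec.state_effects["00"] / spec.state_effects["11"]
    return PlateFixture(
        table,
        truth=dict(
            state_effects=dict(spec.state_effects), true_fold_repression=true_fold
        ),
    )
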