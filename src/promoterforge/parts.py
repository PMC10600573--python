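"""Promoter and terminator part extraction from a genome + GFF3 annotation.

A "promoter part" is the promoter together with the entire 5'UTR: it runs
from the base immediately before the start codon upstream to at most 2,000 bp
beyond the TSS, or to the nearest annotated neighbouring gene, whichever is
shorter. A "terminator part" is the 3'UTR plus terminator: from the base
after the stop codon downstream to at most 250 bp past the TES, again
truncated by neighbours. Parts are then screened for type IIS restriction
sites (BsaI/BbsI, for Golden Gate/MoClo domestication) and for overlap with
neighbouring gene annotations.

Internal coordinates are 0-based half-open; GFF3 input is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

PROMOTER_CAP = 2000
TERMINATOR_CAP = 250

#: Recognition sequences from standard enzyme catalogues; both enzymes are
#: type IIS and non-palindromic, so both strands are scanned.
DEFAULT_ENZYMES = {"BsaI": "GGTCTC", "BbsI": "GAAGAC"}


@dataclass(frozen=True)
class GeneModel:
    """One gene's coordinates, 0-based half-open on the genome.

    ``tss``/``tes`` are the positions of the first/last transcribed base in
    transcription order; ``cds_start``/``cds_end`` bound the coding span
    genomically (start codon first base .. stop codon last base + 1).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    tes: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not (self.start <= self.cds_start < self.cds_end <= self.end):
            raise ValueError(f"{self.gene_id}: CDS outside gene span")


@dataclass
class PartRecord:
    """An extracted part with genomic provenance and filter flags."""

    gene_id: str
    part_kind: str  # "promoter_5utr" | "3utr_terminator"
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    sequence: str  # 5'->3' relative to the gene
    truncated_by_neighbour: bool = False
    upstream_extent_from_tss: Optional[int] = None
    downstream_extent_from_tes: Optional[int] = None
    filter_flags: set = field(default_factory=set)
    excluded: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _feature_children(db, gene, types):
    return list(db.children(gene, featuretype=types, order_by="start"))


def read_annotation(gff3_path, fasta_path) -> Tuple[List[GeneModel], Dict[str, str]]:
    """Parse gene models from GFF3 and load the genome FASTA.

    TSS/TES come from the mRNA (or UTR) features when present; when a gene
    has no transcript/UTR features the gene-span ends stand in for them,
    with a warning. Requires at least a CDS per gene.
    """
    with open(fasta_path) as fh:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        if gene.seqid not in genome:
            raise ValueError(f"gene {gid} references missing chromosome {gene.seqid}")
        cds = _feature_children(db, gene, "CDS")
        if not cds:
            raise ValueError(f"gene {gid} has no CDS feature")
        cds_start = min(c.start for c in cds) - 1
        cds_end = max(c.end for c in cds)
        mrnas = _feature_children(db, gene, ("mRNA", "transcript"))
        if mrnas:
            tx_start = min(m.start for m in mrnas) - 1
            tx_end = max(m.end for m in mrnas)
        else:
            utr5 = _feature_children(db, gene, "five_prime_UTR")
            utr3 = _feature_children(db, gene, "three_prime_UTR")
            if utr5 or utr3:
                bounds = [cds_start, cds_end]
                bounds += [u.start - 1 for u in utr5 + utr3]
                bounds += [u.end for u in utr5 + utr3]
                tx_start, tx_end = min(bounds), max(bounds)
            else:
                warnings.warn(
                    f"gene {gid}: no mRNA/UTR features; using gene span for TSS/TES"
                )
                tx_start, tx_end = gene.start - 1, gene.end
        if gene.strand == "+":
            tss, tes = tx_start, tx_end - 1
        else:
            tss, tes = tx_end - 1, tx_start
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                tss=tss,
                tes=tes,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models, genome


def find_neighbours(
    g: GeneModel, all_models: Sequence[GeneModel], chrom_length: int
) -> Tuple[int, int]:
    """Nearest annotated gene boundaries flanking ``g``'s span, on either strand.

    Returns genomic ``(left_bound, right_bound)``: the closest neighbour edge
    at or left of the gene start (0 when none) and at or right of the gene
    end (chromosome length when none). Overlapping neighbours clamp the
    bound to the gene span edge (distance 0).
    """
    left = 0
    right = chrom_length
    for o in all_models:
        if o.gene_id == g.gene_id or o.chrom != g.chrom:
            continue
        if o.start < g.start:
            left = max(left, min(o.end, g.start))
        if o.end > g.end:
            right = min(right, max(o.start, g.end))
    return left, right


def extract_promoter_part(
    g: GeneModel,
    genome: Dict[str, str],
    neighbours: Tuple[int, int],
    cap: int = PROMOTER_CAP,
) -> PartRecord:
    """Extract promoter + full 5'UTR, capped at ``cap`` bp upstream of the TSS.

    The part ends at the base immediately before the start codon. A neighbour
    boundary at or inside the 5'UTR leaves no promoter sequence; the part is
    then flagged ``zero_length`` and excluded.
    """
    left, right = neighbours
    seq = genome[g.chrom]
    if g.strand == "+":
        start = max(g.tss - cap, left)
        end = g.cds_start
        upstream = g.tss - start
        truncated = (g.tss - cap) < left
        raw = seq[start:end]
        part_seq = raw
    else:
        start = g.cds_end
        end = min(g.tss + 1 + cap, right)
        upstream = end - (g.tss + 1)
        truncated = (g.tss + 1 + cap) > right
        raw = seq[start:end]
        part_seq = str(Seq(raw).reverse_complement())
    rec = PartRecord(
        gene_id=g.gene_id,
        part_kind="promoter_5utr",
        chrom=g.chrom,
        start=start,
        end=end,
        strand=g.strand,
        sequence=part_seq,
        truncated_by_neighbour=truncated,
        upstream_extent_from_tss=upstream,
    )
    if upstream <= 0 or end <= start:
        rec.excluded = True
        rec.filter_flags.add("zero_length")
        rec.sequence = "" if end <= start else rec.sequence
    return rec


def extract_terminator_part(
    g: GeneModel,
    genome: Dict[str, str],
    neighbours: Tuple[int, int],
    cap: int = TERMINATOR_CAP,
) -> PartRecord:
    """Extract 3'UTR + terminator, capped at ``cap`` bp past the TES."""
    left, right = neighbours
    seq = genome[g.chrom]
    if g.strand == "+":
        start = g.cds_end
        end = min(g.tes + 1 + cap, right)
        downstream = end - (g.tes + 1)
        truncated = (g.tes + 1 + cap) > right
        part_seq = seq[start:end]
    else:
        start = max(g.tes - cap, left)
        end = g.cds_start
        downstream = g.tes - start
        truncated = (g.tes - cap) < left
        part_seq = str(Seq(seq[start:end]).reverse_complement())
    rec = PartRecord(
        gene_id=g.gene_id,
        part_kind="3utr_terminator",
        chrom=g.chrom,
        start=start,
        end=end,
        strand=g.strand,
        sequence=part_seq,
        truncated_by_neighbour=truncated,
        downstream_extent_from_tes=downstream,
    )
    if downstream <= 0 or end <= start:
        rec.excluded = True
        rec.filter_flags.add("zero_length")
        rec.sequence = "" if end <= start else rec.sequence
    return rec


def extract_parts(
    models: Sequence[GeneModel],
    genome: Dict[str, str],
    promoter_cap: int = PROMOTER_CAP,
    terminator_cap: int = TERMINATOR_CAP,
) -> Dict[str, Tuple[PartRecord, PartRecord]]:
    """Extract (promoter, terminator) part pairs for every gene."""
    out = {}
    for g in models:
        nb = find_neighbours(g, models, len(genome[g.chrom]))
        out[g.gene_id] = (
            extract_promoter_part(g, genome, nb, promoter_cap),
            extract_terminator_part(g, genome, nb, terminator_cap),
        )
    return out


def overlap_filter(
    parts: Dict[str, Tuple[PartRecord, PartRecord]],
    models: Sequence[GeneModel],
) -> List[str]:
    """Remove genes whose parts intersect any other gene's annotated span."""
    spans = [(m.gene_id, m.chrom, m.start, m.end) for m in models]
    survivors = []
    for gid, pair in parts.items():
        bad = False
        for part in pair:
            for oid, chrom, s, e in spans:
                if oid == gid or chrom != part.chrom:
                    continue
                if part.start < e and s < part.end:
                    part.filter_flags.add("overlaps_neighbour")
                    bad = True
        if not bad:
            survivors.append(gid)
    return survivors


def scan_restriction_sites(
    seq: str,
    enzymes: Optional[Dict[str, str]] = None,
    scan_both_strands: bool = True,
) -> List[Tuple[str, int, str]]:
    """All occurrences of each recognition sequence in ``seq``.

    Returns ``(enzyme, 0-based position, strand)`` tuples; minus-strand hits
    are occurrences of the reverse complement, reported at their position on
    the given sequence. ``N`` never matches.
    """
    enzymes = enzymes or DEFAULT_ENZYMES
    seq = seq.upper()
    hits = []
    for name, site in enzymes.items():
        site = site.upper()
        patterns = [(site, "+")]
        rc = str(Seq(site).reverse_complement())
        if scan_both_strands and rc != site:
            patterns.append((rc, "-"))
        for pat, strand in patterns:
            pos = seq.find(pat)
            while pos != -1:
                hits.append((name, pos, strand))
                pos = seq.find(pat, pos + 1)
    return sorted(hits, key=lambda h: (h[1], h[0], h[2]))


def domestication_filter(
    parts: Dict[str, Tuple[PartRecord, PartRecord]],
    enzymes: Optional[Dict[str, str]] = None,
) -> List[str]:
    """Keep genes whose both parts are free of all recognition sites."""
    enzymes = enzymes or DEFAULT_ENZYMES
    survivors = []
    for gid, pair in parts.items():
        clean = True
        for part in pair:
            hits = scan_restriction_sites(part.sequence, enzymes)
            for name, _, _ in hits:
                part.filter_flags.add(f"has_{name.lower()}")
            if hits:
                clean = False
        if clean:
            survivors.append(gid)
    return survivors


def parts_to_fasta(
    parts: Iterable[PartRecord], path
) -> None:
    """Write parts as multi-FASTA; headers carry provenance."""
    with open(path, "w") as fh:
        for p in parts:
            if p.excluded:
                continue
            fh.write(
                f">{p.gene_id}|{p.part_kind}|{p.chrom}:{p.start}-{p.end}({p.strand})\n"
            )
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")
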