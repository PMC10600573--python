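"""Placement of genome-orthogonal gRNA target sites into promoters.

Converts a constitutive promoter into a dCas9-repressible NOR-gate promoter
by overwriting two 23 bp windows (20 bp protospacer + 3 bp NGG PAM) with
target-site sequences absent from the host genome. Windows must fall inside
the 500 bp region upstream of the TSS, avoid every predicted TF binding
site, and keep an edge-to-edge gap of at least 67 bp between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .intervals import IntervalSet

SITE_LENGTH = 23  # 20 bp protospacer + 3 bp PAM
PROTOSPACER_LENGTH = 20
MIN_SEPARATION = 67  # bp between window1 end and window2 start
TSS_WINDOW = 500  # bp upstream of the TSS considered for placement


@dataclass(frozen=True)
class PlacementConstraints:
    site_length: int = SITE_LENGTH
    min_separation: int = MIN_SEPARATION
    tss_window: int = TSS_WINDOW
    forbidden: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        if min(self.site_length, self.min_separation, self.tss_window) <= 0:
            raise ValueError("all placement constants must be positive")


@dataclass
class PlacementPlan:
    """Two chosen site windows plus assigned sequences and modified promoter."""

    gene_id: str
    window1: Tuple[int, int]  # promoter-local, window1 5' of window2
    window2: Tuple[int, int]
    separation: int
    seq1: Optional[str] = None
    seq2: Optional[str] = None
    modified_promoter: Optional[str] = None


@dataclass(frozen=True)
class OrthogonalityReport:
    site: str
    found_in_genome: bool
    matches: Tuple[Tuple[str, int, str], ...]  # (chrom, position, strand)


def free_intervals(
    c: PlacementConstraints, promoter_len: int, tss_offset: int
) -> IntervalSet:
    """Placeable positions: the TSS-proximal window minus forbidden intervals.

    ``tss_offset`` is the promoter-local position of the TSS (first
    transcribed base). The placement window is the ``tss_window`` bp
    immediately upstream of it, clipped to the promoter.
    """
    win_start = max(0, tss_offset - c.tss_window)
    win_end = min(tss_offset, promoter_len)
    if win_end <= win_start:
        return IntervalSet()
    return c.forbidden.complement(win_start, win_end)


def enumerate_placements(
    free: IntervalSet,
    c: PlacementConstraints,
    gene_id: str = "",
    mode: str = "best",
) -> List[PlacementPlan] | int:
    """Ordered window pairs with each window inside one free interval.

    The gap between window1's end and window2's start must be at least
    ``min_separation``. ``mode`` is ``"all"`` (every placement), ``"count"``
    (their number), ``"first"`` (5'-most), or ``"best"`` (the placement
    maximizing the smaller of the two windows' distances to the nearest
    forbidden boundary, tie-broken 5'-most).
    """
    L = c.site_length
    starts: List[Tuple[int, Tuple[int, int]]] = []  # (start, containing interval)
    for s, e in free:
        for w in range(s, e - L + 1):
            starts.append((w, (s, e)))
    pairs: List[Tuple[int, int, Tuple[int, int], Tuple[int, int]]] = []
    for i, (w1, iv1) in enumerate(starts):
        for w2, iv2 in starts[i + 1 :]:
            if w2 - (w1 + L) >= c.min_separation:
                pairs.append((w1, w2, iv1, iv2))
    if mode == "count":
        return len(pairs)
    plans = [
        PlacementPlan(gene_id, (w1, w1 + L), (w2, w2 + L), w2 - (w1 + L))
        for w1, w2, _, _ in pairs
    ]
    if mode == "all":
        return plans
    if not plans:
        return []
    if mode == "first":
        return [plans[0]]
    if mode == "best":
        def slack(item):
            w1, w2, iv1, iv2 = item
            s1 = min(w1 - iv1[0], iv1[1] - (w1 + L))
            s2 = min(w2 - iv2[0], iv2[1] - (w2 + L))
            return min(s1, s2)

        best = max(
            range(len(pairs)),
            key=lambda k: (slack(pairs[k]), -pairs[k][0], -pairs[k][1]),
        )
        return [plans[best]]
    raise ValueError(f"unknown mode {mode!r}")


def check_orthogonality(site: str, genome: Dict[str, str]) -> OrthogonalityReport:
    """Exact-substring search of a 23-mer over both strands of the genome."""
    site = site.upper()
    if len(site) != SITE_LENGTH:
        raise ValueError(f"site must be {SITE_LENGTH} bp, got {len(site)}")
    if any(b not in "ACGT" for b in site):
        raise ValueError("ambiguous bases in site sequence")
    rc = str(Seq(site).reverse_complement())
    matches = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for pat, strand in ((site, "+"), (rc, "-")):
            pos = seq.find(pat)
            while pos != -1:
                matches.append((chrom, pos, strand))
                pos = seq.find(pat, pos + 1)
    return OrthogonalityReport(site, bool(matches), tuple(matches))


def random_site_library(n: int, seed: int, rng=None) -> List[str]:
    """Seeded random 23-mers: 20 nt protospacer + NGG PAM."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    sites = []
    for _ in range(n):
        proto = "".join(np.array(list("ACGT"))[rng.integers(0, 4, PROTOSPACER_LENGTH)])
        pam = "ACGT"[rng.integers(0, 4)] + "GG"
        sites.append(proto + pam)
    return sites


def propose_site_sequences(
    library: Sequence[str],
    genome: Dict[str, str],
    n_needed: int,
    seed: Optional[int] = None,
) -> List[str]:
    """First ``n_needed`` library sites passing the orthogonality check.

    Deterministic given the library order (and seed when the library was
    generated here). Raises with the list of rejects if the library runs out.
    """
    if not library:
        raise ValueError("empty site library")
    accepted: List[str] = []
    rejects: List[str] = []
    for site in library:
        rep = check_orthogonality(site, genome)
        if rep.found_in_genome:
            rejects.append(site)
        else:
            accepted.append(site)
        if len(accepted) == n_needed:
            return accepted
    raise ValueError(
        f"site library exhausted: needed {n_needed}, accepted {len(accepted)}, "
        f"rejected (found in genome): {rejects}"
    )


def build_modified_promoter(promoter: str, plan: PlacementPlan) -> str:
    """Overwrite the two windows with the assigned site sequences."""
    for window, site in ((plan.window1, plan.seq1), (plan.window2, plan.seq2)):
        s, e = window
        if not (0 <= s < e <= len(promoter)):
            raise ValueError(f"window {window} outside promoter of length {len(promoter)}")
        if site is None or len(site) != e - s:
            raise ValueError("site sequence missing or wrong length for window")
    out = list(promoter)
    out[plan.window1[0] : plan.window1[1]] = plan.seq1
    out[plan.window2[0] : plan.window2[1]] = plan.seq2
    modified = "".join(out)
    plan.modified_promoter = modified
    return modified


def design_nor_promoter(
    gene_id: str,
    promoter: str,
    tss_offset: int,
    forbidden: IntervalSet,
    genome: Dict[str, str],
    site_library: Optional[Sequence[str]] = None,
    seed: int = 0,
    constraints: Optional[PlacementConstraints] = None,
) -> Optional[PlacementPlan]:
    """End-to-end design: place windows, assign orthogonal sites, emit sequence.

    Returns None when no feasible placement exists.
    """
    c = constraints or PlacementConstraints(forbidden=forbidden)
    if c.forbidden is not forbidden:
        c = PlacementConstraints(
            c.site_length, c.min_separation, c.tss_window, forbidden
        )
    free = free_intervals(c, len(promoter), tss_offset)
    chosen = enumerate_placements(free, c, gene_id, mode="best")
    if not chosen:
        return None
    plan = chosen[0]
    if site_library is None:
        site_library = random_site_library(64, seed)
    plan.seq1, plan.seq2 = propose_site_sequences(site_library, genome, 2, seed)
    build_modified_promoter(promoter, plan)
    return plan
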