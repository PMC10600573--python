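"""PWM scanning of promoter sequences for predicted TF binding sites.

A local stand-in for web-based binding-site prediction: motifs are read from
MEME minimal format, converted to log2 odds against a background model, and
scored over every window on both strands. Score thresholds can be given
directly or derived from a p-value under the background model via an exact
dynamic program over the discretized score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import IntervalSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "PWM",
    "MotifHit",
    "read_motifs",
    "write_motifs",
    "pwm_logodds",
    "score_threshold_for_pvalue",
    "scan_promoter",
    "hits_to_intervalset",
]


@dataclass
class PWM:
    """Position probability matrix, rows A/C/G/T, columns = positions."""

    motif_id: str
    matrix: np.ndarray  # shape (4, L)
    pseudocount: float = 1e-3
    background: np.ndarray = None  # shape (4,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: matrix must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.pseudocount,
            self.background[::-1].copy(),
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """A predicted binding site, promoter-local 0-based half-open."""

    motif_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: Optional[float] = None


def read_motifs(path) -> List[PWM]:
    """Read PWMs from a MEME minimal-format file."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        mat = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        colsum = mat.sum(axis=0)
        if not np.allclose(colsum, colsum[0], atol=1e-6):
            raise ValueError(f"{m.name}: inconsistent matrix column sums")
        mat = mat / colsum
        bg = np.array([m.background[b] for b in BASES]) if m.background else None
        out.append(PWM(m.name, mat, background=bg))
    return out


def write_motifs(pwms: Sequence[PWM], path) -> None:
    """Write PWMs in MEME minimal format (round-trips through read_motifs)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            # large nsites so integer-count round-trips stay below 1e-9
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.length} "
                f"nsites= 1000000000 E= 0\n"
            )
            for col in p.matrix.T:
                fh.write(" " + " ".join(f"{v:.9f}" for v in col) + "\n")
            fh.write("\n")


def pwm_logodds(p: PWM) -> np.ndarray:
    """Log2-odds matrix: log2(adjusted probability / background).

    Probabilities are regularized with the pseudocount before taking odds so
    zero entries stay finite: ``p' = (p + c*bg) / (1 + c)``.
    """
    if p.pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    adj = (p.matrix + p.pseudocount * p.background[:, None]) / (1 + p.pseudocount)
    return np.log2(adj / p.background[:, None])


def max_score(p: PWM) -> float:
    return float(pwm_logodds(p).max(axis=0).sum())


def score_threshold_for_pvalue(p: PWM, pvalue: float, precision: int = 1000) -> float:
    """Smallest score whose background tail probability is <= ``pvalue``.

    Exact dynamic program: per-column log-odds scores are discretized to a
    1/``precision`` grid and the distribution of the window score under the
    background model is built by convolution over columns.
    """
    lo = pwm_logodds(p)
    scaled = np.round(lo * precision).astype(np.int64)
    offset = scaled.min(axis=0)
    span = scaled.max(axis=0) - offset
    dist = np.zeros(1)
    dist[0] = 1.0
    for j in range(p.length):
        col = np.zeros(span[j] + 1)
        for i in range(4):
            col[scaled[i, j] - offset[j]] += p.background[i]
        dist = np.convolve(dist, col)
    scores = (np.arange(dist.size) + offset.sum()) / precision
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= pvalue + 1e-15)[0]
    if ok.size == 0:
        return scores[-1] + 1.0 / precision  # unattainable
    return float(scores[ok[0]])


def score_pvalue(p: PWM, score: float, precision: int = 1000) -> float:
    """Background tail probability P(window score >= ``score``)."""
    lo = pwm_logodds(p)
    scaled = np.round(lo * precision).astype(np.int64)
    offset = scaled.min(axis=0)
    span = scaled.max(axis=0) - offset
    dist = np.zeros(1)
    dist[0] = 1.0
    for j in range(p.length):
        col = np.zeros(span[j] + 1)
        for i in range(4):
            col[scaled[i, j] - offset[j]] += p.background[i]
        dist = np.convolve(dist, col)
    scores = (np.arange(dist.size) + offset.sum()) / precision
    return float(dist[scores >= score - 0.5 / precision].sum())


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; anything else (N, ...) to 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def _window_scores(encoded: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score every window; windows containing ambiguous bases score -inf."""
    L = logodds.shape[1]
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([logodds, np.full((1, L), -np.inf)])
    scores = np.zeros(n)
    for j in range(L):
        scores += padded[encoded[j : j + n], j]
    return scores


def scan_promoter(
    seq: str,
    pwms: Iterable[PWM],
    threshold: Union[float, None] = None,
    pvalue: Optional[float] = 1e-4,
) -> List[MotifHit]:
    """All windows on both strands scoring at or above the threshold.

    The threshold is either an explicit log2-odds ``threshold`` or, by
    default, the score whose exact background p-value is <= ``pvalue``.
    Minus-strand hits are reported in the coordinates of ``seq``.
    """
    hits: List[MotifHit] = []
    enc = _encode(seq)
    for p in pwms:
        if len(seq) < p.length:
            continue
        if threshold is None:
            thr = score_threshold_for_pvalue(p, pvalue)
        else:
            thr = threshold
        for strand, lo in (("+", pwm_logodds(p)), ("-", pwm_logodds(p.reverse_complement()))):
            scores = _window_scores(enc, lo)
            for i in np.nonzero(scores >= thr - 1e-12)[0]:
                hits.append(
                    MotifHit(
                        motif_id=p.motif_id,
                        start=int(i),
                        end=int(i) + p.length,
                        strand=strand,
                        score=float(scores[i]),
                        pvalue=None if threshold is not None else float(pvalue),
                    )
                )
    return sorted(hits, key=lambda h: (h.start, h.end, h.motif_id, h.strand))


def hits_to_intervalset(hits: Iterable[MotifHit]) -> IntervalSet:
    """Merged union of hit intervals (promoter-local)."""
    return IntervalSet.from_pairs((h.start, h.end) for h in hits)
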