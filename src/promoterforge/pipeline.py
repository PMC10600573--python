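"""Orchestration of the full promoter-mining screen.

Runs the filtering cascade in order — expressed-in-all, lowest-CV retention,
part extraction, neighbour-overlap removal, restriction-site (domestication)
screening, motif scanning and gRNA-placement feasibility — and records the
number of genes surviving each stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import grna, motifs, parts, rank
from .intervals import IntervalSet


@dataclass
class PipelineConfig:
    """All screen constants in one place; defaults are the screen's standard
    operating point."""

    cv_fraction: float = 0.03
    promoter_cap: int = 2000
    terminator_cap: int = 250
    tss_window: int = 500
    site_length: int = 23
    min_separation: int = 67
    enzymes: Dict[str, str] = field(default_factory=lambda: dict(parts.DEFAULT_ENZYMES))
    motif_pvalue: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cv_fraction < 1:
            raise ValueError("cv_fraction must be in (0, 1)")
        for name in ("promoter_cap", "terminator_cap", "tss_window", "site_length", "min_separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CascadeReport:
    """Survivor bookkeeping: one row per stage, monotone non-increasing."""

    stages: List[Tuple[str, int, int, str]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, params: str = "") -> None:
        if self.stages and n_in != self.stages[-1][2]:
            raise ValueError("stage input does not match previous stage output")
        if n_out > n_in:
            raise ValueError(f"stage {name}: survivors increased")
        self.stages.append((name, n_in, n_out, params))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "genes_in", "genes_out", "parameters"]
        )


@dataclass
class ScreenResult:
    report: CascadeReport
    stats: pd.DataFrame
    parts: Dict[str, tuple]
    plans: Dict[str, grna.PlacementPlan]
    survivors: List[str]


def run_screen(
    config: PipelineConfig,
    counts: rank.CountMatrix,
    models: Sequence[parts.GeneModel],
    genome: Dict[str, str],
    pwms: Sequence[motifs.PWM],
    site_library: Optional[Sequence[str]] = None,
    outdir: Optional[Path] = None,
) -> ScreenResult:
    """Execute every stage in order and return the cascade report.

    Genes absent from the annotation simply cannot advance past the
    extraction stage; the count matrix drives the expression stages.
    """
    report = CascadeReport()
    n0 = len(counts.gene_ids)

    expressed = rank.filter_expressed_all(counts)
    report.add("expressed_in_all", n0, len(expressed), "raw count > 0 in all samples")

    stats = rank.gene_stats(counts)
    sel = rank.select_low_cv(stats, config.cv_fraction)
    report.add(
        "lowest_cv",
        len(expressed),
        sel.n_retained,
        f"fraction={config.cv_fraction}, cv_cutoff={sel.cv_cutoff:.4f}",
    )
    retained = set(sel.gene_ids)

    by_id = {m.gene_id: m for m in models}
    candidates = [g for g in sel.gene_ids if g in by_id]
    part_pairs = parts.extract_parts(
        [by_id[g] for g in candidates],
        genome,
        config.promoter_cap,
        config.terminator_cap,
    )
    with_parts = [
        g for g in candidates if not any(p.excluded for p in part_pairs[g])
    ]
    report.add(
        "part_extraction",
        sel.n_retained,
        len(with_parts),
        f"promoter_cap={config.promoter_cap}, terminator_cap={config.terminator_cap}",
    )

    pool = {g: part_pairs[g] for g in with_parts}
    no_overlap = parts.overlap_filter(pool, models)
    report.add("overlap_filter", len(with_parts), len(no_overlap), "part vs gene spans")

    pool = {g: part_pairs[g] for g in no_overlap}
    domesticated = parts.domestication_filter(pool, config.enzymes)
    report.add(
        "domestication_filter",
        len(no_overlap),
        len(domesticated),
        ",".join(config.enzymes),
    )

    plans: Dict[str, grna.PlacementPlan] = {}
    feasible: List[str] = []
    for g in domesticated:
        prom = part_pairs[g][0]
        model = by_id[g]
        if model.strand == "+":
            tss_offset = model.tss - prom.start
        else:
            tss_offset = prom.end - 1 - model.tss
        hits = motifs.scan_promoter(prom.sequence, pwms, pvalue=config.motif_pvalue)
        forbidden = motifs.hits_to_intervalset(hits)
        constraints = grna.PlacementConstraints(
            site_length=config.site_length,
            min_separation=config.min_separation,
            tss_window=config.tss_window,
            forbidden=forbidden,
        )
        plan = grna.design_nor_promoter(
            g,
            prom.sequence,
            tss_offset,
            forbidden,
            genome,
            site_library=site_library,
            seed=config.seed,
            constraints=constraints,
        )
        if plan is not None:
            plans[g] = plan
            feasible.append(g)
    report.add(
        "placement_feasibility",
        len(domesticated),
        len(feasible),
        f"tss_window={config.tss_window}, min_sep={config.min_separation}",
    )

    result = ScreenResult(report, stats, part_pairs, plans, feasible)
    if outdir is not None:
        _persist(result, config, Path(outdir))
    return result


def _persist(result: ScreenResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_frame().to_csv(outdir / "cascade.tsv", sep="\t", index=False)
    result.stats.to_csv(outdir / "gene_stats.tsv", sep="\t")
    flat = [p for pair in result.parts.values() for p in pair]
    parts.parts_to_fasta(flat, outdir / "parts.fa")
    rows = []
    for g, plan in result.plans.items():
        rows.append(
            dict(
                gene_id=g,
                window1=f"{plan.window1[0]}-{plan.window1[1]}",
                window2=f"{plan.window2[0]}-{plan.window2[1]}",
                separation=plan.separation,
                site1=plan.seq1,
                site2=plan.seq2,
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "placements.tsv", sep="\t", index=False)
    with open(outdir / "modified_promoters.fa", "w") as fh:
        for g, plan in result.plans.items():
            fh.write(f">{g}|modified\n{plan.modified_promoter}\n")
    manifest = dict(
        config=asdict(config),
        survivors=result.survivors,
        cascade=[list(s) for s in result.report.stages],
    )
    manifest["hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def annotate_candidates(
    survivors: pd.DataFrame, tables: Sequence[pd.DataFrame] = ()
) -> pd.DataFrame:
    """Left-join optional annotation tables (keyed by gene id) onto survivors."""
    out = survivors.copy()
    for t in tables:
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate keys in annotation table: {dups}")
        out = out.join(t, how="left")
    return out
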