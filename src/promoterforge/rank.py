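"""Count normalization and expression-stability ranking.

Implements the promoter-mining statistics: median-of-ratios size factors
(the DESeq2 normalization scheme), per-gene coefficient of variation (CV) on
the normalized counts, the expressed-in-all filter, retention of the
lowest-CV fraction of genes, and a separately normalized stress CV that is
reported as an annotation only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_counts",
    "compute_size_factors",
    "normalize_counts",
    "filter_expressed_all",
    "gene_stats",
    "select_low_cv",
    "stress_cv",
]


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    sample_groups
        Optional label per sample (e.g. ``"main"``, ``"stress"``,
        ``"reference"``) used to split stress samples out of the main CV
        computation.
    """

    counts: pd.DataFrame
    sample_groups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if self.counts.shape[1] < 2:
            raise ValueError("count matrix needs at least 2 samples")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        if self.sample_groups is not None:
            self.sample_groups = self.sample_groups.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        groups = None
        if self.sample_groups is not None:
            groups = self.sample_groups.loc[list(samples)]
        return CountMatrix(self.counts.loc[:, list(samples)], groups)

    def samples_in_group(self, group: str) -> list:
        if self.sample_groups is None:
            return []
        return list(self.sample_groups.index[self.sample_groups == group])


def read_counts(
    path, sample_groups: Optional[Mapping[str, str]] = None
) -> CountMatrix:
    """Read an htseq-count style TSV (gene id column + integer sample columns).

    Special counter rows whose id starts with ``__`` (``__no_feature``,
    ``__ambiguous``, ...) are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[~df.index.astype(str).str.startswith("__")]
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric counts in count table")
    if (arr < 0).any():
        raise ValueError("negative counts in count table")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("non-integer counts in count table")
    groups = None
    if sample_groups is not None:
        groups = pd.Series(
            {s: sample_groups.get(s) for s in df.columns}, name="group"
        )
    return CountMatrix(df, groups)


def write_counts(m: CountMatrix, path) -> None:
    """Write a CountMatrix back to htseq-style TSV (inverse of read_counts)."""
    out = m.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def compute_size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The pseudo-reference for gene *i* is the geometric mean of its counts
    over samples; genes with any zero count are excluded from the reference
    set. The size factor of sample *j* is the median over reference genes of
    ``K_ij / pseudo_reference_i``.
    """
    arr = m.counts.to_numpy(dtype=float)
    ref_mask = (arr > 0).all(axis=1)
    if not ref_mask.any():
        raise ValueError("no gene with all-positive counts; cannot normalize")
    ref = arr[ref_mask]
    pseudo = np.exp(np.log(ref).mean(axis=1))
    s = np.median(ref / pseudo[:, None], axis=0)
    return pd.Series(s, index=m.sample_ids, name="size_factor")


def normalize_counts(m: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if set(size_factors.index) != set(m.sample_ids):
        raise ValueError("size-factor samples do not match count matrix samples")
    return m.counts / size_factors.reindex(m.sample_ids)


def filter_expressed_all(m: CountMatrix) -> pd.Index:
    """Gene ids with a raw count > 0 in every sample."""
    mask = (m.counts.to_numpy() > 0).all(axis=1)
    return m.gene_ids[mask]


def gene_stats(
    m: CountMatrix, size_factors: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-gene stability statistics on the normalized counts.

    Returns a DataFrame indexed by gene id with columns ``geometric_mean``,
    ``cv`` and ``expressed_in_all``. The CV is the sample (n-1 denominator)
    standard deviation divided by the arithmetic mean of the normalized
    counts; it is only defined for expressed-in-all genes (NaN otherwise),
    as is the geometric mean.
    """
    if size_factors is None:
        size_factors = compute_size_factors(m)
    norm = normalize_counts(m, size_factors).to_numpy()
    expressed = (m.counts.to_numpy() > 0).all(axis=1)
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(expressed, sd / mean, np.nan)
        geo = np.where(expressed, np.exp(np.log(np.where(norm > 0, norm, 1.0)).mean(axis=1)), np.nan)
    return pd.DataFrame(
        {"geometric_mean": geo, "cv": cv, "expressed_in_all": expressed},
        index=m.gene_ids,
    )


@dataclass
class LowCVSelection:
    """Genes retained by the lowest-CV filter, sorted ascending by CV."""

    gene_ids: list
    cv_cutoff: float
    n_retained: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_retained = len(self.gene_ids)


def select_low_cv(stats: pd.DataFrame, fraction: float = 0.03) -> LowCVSelection:
    """Retain the ``ceil(fraction * N)`` genes with smallest CV.

    Ties at the cutoff are broken lexicographically by gene id. N counts only
    genes with a defined CV (expressed in all samples).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    usable = stats.loc[stats["cv"].notna()]
    n_total = len(usable)
    if n_total == 0:
        raise ValueError("no genes with defined CV")
    n_keep = math.ceil(fraction * n_total)
    # ties at equal CV broken lexicographically by gene id
    ranked = usable.iloc[np.lexsort((usable.index.to_numpy(), usable["cv"].to_numpy()))]
    kept = ranked.iloc[:n_keep]
    return LowCVSelection(list(kept.index), float(kept["cv"].max()))


def stress_cv(
    m: CountMatrix,
    stress_samples: Sequence[str],
    reference_samples,
) -> pd.Series:
    """CV of stress samples normalized together with an untreated reference.

    Size factors are computed on the stress + reference submatrix alone; the
    CV is then taken across the stress samples only. Reported as an
    annotation column, never used for the main retention filter.
    """
    if isinstance(reference_samples, str):
        reference_samples = [reference_samples]
    stress_samples = list(stress_samples)
    if not stress_samples:
        raise ValueError("stress sample set is empty")
    if len(stress_samples) < 2:
        raise ValueError("CV across stress samples needs >= 2 stress samples")
    extra_refs = [r for r in reference_samples if r not in stress_samples]
    sub = m.subset_samples(stress_samples + extra_refs)
    s = compute_size_factors(sub)
    norm = normalize_counts(sub, s).loc[:, stress_samples].to_numpy()
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.Series(cv, index=m.gene_ids, name="stress_cv")


def rank_table(
    m: CountMatrix,
    fraction: float = 0.03,
    stress_group: str = "stress",
    reference_group: str = "reference",
) -> pd.DataFrame:
    """Full ranking table: stats, stress CV annotation and retained flag.

    Samples labelled with ``stress_group`` are excluded from the main
    normalization and CV; they feed the stress CV column only (normalized
    against samples labelled ``reference_group``).
    """
    stress = m.samples_in_group(stress_group)
    main_samples = [s for s in m.sample_ids if s not in stress]
    main = m.subset_samples(main_samples) if stress else m
    stats = gene_stats(main)
    if stress:
        refs = m.samples_in_group(reference_group)
        if not refs:
            warnings.warn(
                "stress samples present but no reference-group sample; "
                "skipping stress CV"
            )
            stats["stress_cv"] = np.nan
        else:
            stats["stress_cv"] = stress_cv(m, stress, refs)
    else:
        stats["stress_cv"] = np.nan
    sel = select_low_cv(stats, fraction)
    stats["retained"] = stats.index.isin(sel.gene_ids)
    stats.attrs["cv_cutoff"] = sel.cv_cutoff
    return stats
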