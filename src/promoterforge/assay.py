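"""Ratio-metric fluorescence assay statistics for agroinfiltration screens.

Two analyses are covered:

* transient promoter screens — per-leaf background subtraction against a
  negative-control injection, mTURQ ratio normalization, replicate selection
  and Dunnett many-to-one comparisons against the negative control;
* NOR-gate repression assays — per-leaf normalization against the
  unrepressed (0,0) injection, fold repression between the (0,0) and (1,1)
  states, and one-way ANOVA with Tukey HSD all-pairs comparisons summarized
  as a compact letter display (CLD).

The observation unit for the hypothesis tests is the per-leaf (biological
replicate) median: the 24 plate-reader reads per injection per leaf are
technical pseudo-replicates. This is configurable via ``unit=``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = [
    "leaf",
    "injection",
    "construct",
    "role",
    "state",
    "disc",
    "read",
    "YFP",
    "mTURQ",
]

ROLE_TEST = "test"
ROLE_NEGATIVE = "negative_control"
ROLE_UNREPRESSED = "unrepressed_control"


def read_plate_table(path) -> pd.DataFrame:
    """Read a long-format plate-reader CSV and validate its columns."""
    df = pd.read_csv(path, dtype={"state": "string"})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    return df


def normalize_transient(table: pd.DataFrame) -> pd.DataFrame:
    """Per-datapoint signal: (YFP - leaf's negative-control median YFP) / mTURQ.

    Every leaf must carry a negative-control injection. Datapoints with
    non-positive mTURQ are dropped with a warning.
    """
    table = table.copy()
    neg = table[table["role"] == ROLE_NEGATIVE]
    if neg.empty:
        raise ValueError("no negative_control injections in table")
    neg_median = neg.groupby("leaf")["YFP"].median()
    missing = set(table["leaf"]) - set(neg_median.index)
    if missing:
        raise ValueError(f"leaves lacking a negative control: {sorted(missing)}")
    bad = table["mTURQ"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} datapoints with mTURQ <= 0")
        table = table[~bad]
    base = table["leaf"].map(neg_median)
    table["signal"] = (table["YFP"] - base) / table["mTURQ"]
    return table


def replicate_medians(
    signals: pd.DataFrame, value: str = "signal"
) -> pd.DataFrame:
    """Median signal per (construct, leaf) biological replicate."""
    return (
        signals.groupby(["construct", "leaf"], sort=True)[value]
        .median()
        .reset_index()
    )


def select_replicates(
    signals: pd.DataFrame, k: int = 3, value: str = "signal"
) -> pd.DataFrame:
    """Keep, per construct, the k replicates whose medians sit closest to the
    median of replicate medians; ties broken by leaf id."""
    meds = replicate_medians(signals, value)
    keep_pairs = []
    for construct, grp in meds.groupby("construct"):
        if len(grp) <= k:
            if len(grp) < k:
                warnings.warn(
                    f"{construct}: only {len(grp)} replicates (< {k}); keeping all"
                )
            keep = grp["leaf"]
        else:
            center = grp[value].median()
            dist = (grp[value] - center).abs()
            order = grp.assign(_d=dist).sort_values(["_d", "leaf"])
            keep = order["leaf"].iloc[:k]
        keep_pairs += [(construct, leaf) for leaf in keep]
    mask = pd.MultiIndex.from_frame(signals[["construct", "leaf"]]).isin(keep_pairs)
    return signals[mask]


def dunnett_vs_control(
    signals: pd.DataFrame,
    control_label: str,
    value: str = "signal",
    alpha: float = 0.05,
    unit: str = "replicate_median",
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of each construct against a control.

    Family-wise error is controlled at ``alpha`` over the many-to-one family
    (equicorrelated multivariate-t critical points). Returns a DataFrame with
    adjusted p-values and a significance flag per non-control construct.
    Groups with fewer than 2 observations are excluded with a warning.
    """
    if unit == "replicate_median":
        data = replicate_medians(signals, value).rename(columns={value: "y"})
    elif unit == "datapoint":
        data = signals.rename(columns={value: "y"})[["construct", "y"]]
    else:
        raise ValueError("unit must be 'replicate_median' or 'datapoint'")
    groups = {c: g["y"].to_numpy(float) for c, g in data.groupby("construct")}
    if control_label not in groups:
        raise ValueError(f"control {control_label!r} not found")
    control = groups.pop(control_label)
    usable, labels = [], []
    for label, y in sorted(groups.items()):
        if y.size < 2:
            warnings.warn(f"{label}: <2 observations; excluded from Dunnett test")
            continue
        usable.append(y)
        labels.append(label)
    if not usable:
        raise ValueError("no treatment group with >= 2 observations")
    res = stats.dunnett(*usable, control=control)
    return pd.DataFrame(
        {
            "construct": labels,
            "mean_diff": [y.mean() - control.mean() for y in usable],
            "p_adjusted": res.pvalue,
            "significant": res.pvalue < alpha,
        }
    ).set_index("construct")


def nor_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-leaf fold change of YFP/mTURQ against the (0,0) unrepressed median.

    Every leaf must carry an unrepressed (0,0) injection; after dividing by
    its per-leaf median, the (0,0) median is exactly 1 on each leaf.
    """
    table = table.copy()
    table["ratio"] = table["YFP"] / table["mTURQ"]
    unrep = table[(table["role"] == ROLE_UNREPRESSED) | (table["state"] == "00")]
    if unrep.empty:
        raise ValueError("no unrepressed (0,0) injections in table")
    ref = unrep.groupby("leaf")["ratio"].median()
    missing = set(table["leaf"]) - set(ref.index)
    if missing:
        raise ValueError(f"leaves lacking an unrepressed control: {sorted(missing)}")
    table["fold_change"] = table["ratio"] / table["leaf"].map(ref)
    return table


def fold_repression(norm: pd.DataFrame, value: str = "fold_change") -> float:
    """Median (0,0) signal divided by median (1,1) signal; >= 1 = repression."""
    on = norm.loc[norm["state"] == "00", value]
    off = norm.loc[norm["state"] == "11", value]
    if on.empty or off.empty:
        raise ValueError("both (0,0) and (1,1) states are required")
    denom = float(off.median())
    if denom <= 0:
        raise ValueError("non-positive (1,1) median; fold repression undefined")
    return float(on.median()) / denom


def _cld_insert_absorb(
    labels: Sequence[str], significant: Dict[Tuple[str, str], bool]
) -> Dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Starts from one column containing every group; each significant pair
    splits the columns containing both; columns that become subsets of
    another are absorbed. Letters are assigned alphabetically.
    """
    columns: List[set] = [set(labels)]
    for (a, b), sig in sorted(significant.items()):
        if not sig:
            continue
        new_cols: List[set] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop duplicates and any column that is a strict subset
        uniq: List[set] = []
        for col in new_cols:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]
    columns.sort(key=lambda col: min(labels.index(m) for m in col))
    letters = {lab: "" for lab in labels}
    for letter, col in zip(string.ascii_lowercase, columns):
        for member in col:
            letters[member] += letter
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def anova_tukey_cld(
    norm: pd.DataFrame,
    group: str = "state",
    value: str = "fold_change",
    alpha: float = 0.05,
    unit: str = "replicate_median",
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD all-pairs, summarized as CLD letters.

    Two groups share a letter iff their difference is not significant at
    ``alpha``. Returns per-group mean, letter, and the ANOVA p-value in
    ``.attrs["anova_pvalue"]``.
    """
    if unit == "replicate_median":
        data = (
            norm.groupby([group, "leaf"], sort=True)[value].median().reset_index()
        )
    else:
        data = norm[[group, "leaf", value]]
    labels = sorted(data[group].unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [data.loc[data[group] == g, value].to_numpy(float) for g in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        # all observations identical: no evidence of any difference
        out = pd.DataFrame(
            {"mean": [s.mean() for s in samples], "letters": "a"}, index=labels
        )
        out.attrs["anova_pvalue"] = 1.0
        return out
    anova = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    significant = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            significant[(labels[i], labels[j])] = bool(
                tukey.pvalue[i, j] < alpha
            )
    letters = _cld_insert_absorb(labels, significant)
    out = pd.DataFrame(
        {"mean": [s.mean() for s in samples], "letters": [letters[g] for g in labels]},
        index=pd.Index(labels, name=group),
    )
    out.attrs["anova_pvalue"] = float(anova.pvalue)
    out.attrs["tukey_pvalues"] = tukey.pvalue
    return out
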