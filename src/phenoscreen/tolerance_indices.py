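"""Stress tolerance and susceptibility indices for genotype screening.

Given per-genotype trait means under control (non-stress, ``y_ns``) and
deficient (stress, ``y_s``) arms, computes the seven classical indices
used to rank low-phosphorus tolerance:

===== =========================================== =================
index definition                                  selection pattern
===== =========================================== =================
MPI   (y_ns + y_s) / 2                            maximum
MRP   y_s / Ybar_s + y_ns / Ybar_ns               maximum
REI   (y_s / Ybar_s) * (y_ns / Ybar_ns)           maximum
TOL   y_ns - y_s                                  minimum
STI   (y_ns * y_s) / Ybar_ns^2                    maximum
SSI   (1 - y_s / y_ns) / SI                       minimum
DTE   100 * y_s / y_ns  (percent)                 maximum
===== =========================================== =================

Ybar denotes the unweighted grand mean of genotype means within an arm,
and the stress intensity SI = 1 - Ybar_s / Ybar_ns (Fischer-Maurer).
Useful identities that hold exactly: y_ns = MPI + TOL/2,
DTE = 100 (1 - SSI * SI) for SI > 0, and MRP/REI are the sum and the
product of the same two performance ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

INDEX_NAMES = ("MPI", "MRP", "REI", "TOL", "STI", "SSI", "DTE_pct")

#: which extreme of each index marks the most tolerant genotype
SELECTION_PATTERN = {
    "MPI": "max",
    "MRP": "max",
    "REI": "max",
    "TOL": "min",
    "STI": "max",
    "SSI": "min",
    "DTE_pct": "max",
}


@dataclass
class ToleranceIndexSet:
    """Per-genotype index values plus the panel-level stress intensity."""

    indices: pd.DataFrame  # genotype x INDEX_NAMES
    stress_intensity: float
    trait: str | None = None


def stress_intensity(grand_mean_s: float, grand_mean_ns: float) -> float:
    """Fischer-Maurer stress intensity SI = 1 - Ybar_s / Ybar_ns."""
    if grand_mean_ns == 0:
        raise ValueError("control grand mean must be non-zero")
    return 1.0 - grand_mean_s / grand_mean_ns


def stress_pairs(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Genotype means per arm: columns ``y_ns`` (control), ``y_s`` (deficient)."""
    means = table.groupby(["genotype", "treatment"])[trait].mean().unstack()
    for arm in ("control", "deficient"):
        if arm not in means.columns:
            raise ValueError(f"trait table lacks the {arm!r} treatment arm")
    return means.rename(columns={"control": "y_ns", "deficient": "y_s"})


def compute_indices(pairs: pd.DataFrame, trait: str | None = None) -> ToleranceIndexSet:
    """All seven indices for each genotype.

    ``pairs`` is a genotype-indexed frame with columns ``y_ns`` and
    ``y_s``.  Grand means are unweighted means over genotype means,
    excluding genotypes with missing values (warned).  SSI is reported
    as NaN when SI = 0 (no stress differential at panel level); a
    genotype with y_ns = 0 gets NaN SSI and DTE with a warning, while
    its other indices remain defined.
    """
    if not {"y_ns", "y_s"} <= set(pairs.columns):
        raise ValueError("pairs must have columns 'y_ns' and 'y_s'")
    complete = pairs[["y_ns", "y_s"]].dropna()
    if len(complete) < len(pairs):
        warnings.warn(
            "genotypes with missing arm means are excluded from grand means",
            stacklevel=2,
        )
    if complete.empty:
        raise ValueError("no genotype has both arm means defined")
    gm_ns = float(complete["y_ns"].mean())
    gm_s = float(complete["y_s"].mean())
    if gm_ns == 0 or gm_s == 0:
        raise ValueError("grand means must be non-zero")
    si = stress_intensity(gm_s, gm_ns)

    y_ns, y_s = pairs["y_ns"], pairs["y_s"]
    out = pd.DataFrame(index=pairs.index)
    out["MPI"] = (y_ns + y_s) / 2.0
    out["MRP"] = y_s / gm_s + y_ns / gm_ns
    out["REI"] = (y_s / gm_s) * (y_ns / gm_ns)
    out["TOL"] = y_ns - y_s
    out["STI"] = (y_ns * y_s) / gm_ns**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(y_ns != 0, y_s / y_ns, np.nan)
    if (y_ns == 0).any():
        warnings.warn(
            "genotypes with zero control mean get undefined SSI and DTE",
            stacklevel=2,
        )
    out["SSI"] = (1.0 - ratio) / si if si != 0 else np.nan
    out["DTE_pct"] = 100.0 * ratio
    return ToleranceIndexSet(indices=out, stress_intensity=si, trait=trait)


def indices_from_table(table: pd.DataFrame, trait: str) -> ToleranceIndexSet:
    """Convenience: :func:`stress_pairs` then :func:`compute_indices`."""
    return compute_indices(stress_pairs(table, trait), trait=trait)


def classify_genotypes(index_set: ToleranceIndexSet, index_name: str) -> pd.DataFrame:
    """Rank genotypes by one index; rank 1 = most tolerant.

    Maximum-value indices rank descending, minimum-value ones ascending;
    ties share the mean rank.  Genotypes in the better half are labelled
    "tolerant", the rest "susceptible".  Missing index values are left
    unranked; an all-missing index is an error.
    """
    if index_name not in SELECTION_PATTERN:
        raise KeyError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    values = index_set.indices[index_name]
    defined = values.dropna()
    if defined.empty:
        raise ValueError(f"all {index_name} values are missing; cannot rank")
    if len(defined) < 2:
        raise ValueError("ranking needs at least two genotypes with defined values")
    keyed = defined if SELECTION_PATTERN[index_name] == "min" else -defined
    ranks = pd.Series(rankdata(keyed.to_numpy()), index=defined.index)
    out = pd.DataFrame({"value": values})
    out["rank"] = ranks.reindex(values.index)
    median_rank = float(np.median(ranks))
    out["label"] = np.where(
        out["rank"].notna() & (out["rank"] <= median_rank), "tolerant", "susceptible"
    )
    out.loc[out["rank"].isna(), "label"] = "unranked"
    return out.sort_values("rank")


def index_trait_correlation(
    index_set: ToleranceIndexSet, trait_means_deficient: pd.Series
) -> pd.Series:
    """Pearson r between each index and a trait's deficient-arm genotype
    means, over the shared genotype set (NaNs dropped pairwise)."""
    from .screening_stats import pearson

    if len(trait_means_deficient) < 3:
        raise ValueError("need at least 3 genotypes for a correlation")
    out = {}
    for name in INDEX_NAMES:
        joined = pd.concat(
            [index_set.indices[name], trait_means_deficient], axis=1, join="inner"
        ).dropna()
        if len(joined) < 3 or joined.iloc[:, 0].nunique() == 1 or joined.iloc[:, 1].nunique() == 1:
            warnings.warn(f"correlation undefined for {name} (constant or short vector)")
            out[name] = np.nan
            continue
        out[name], _ = pearson(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
    return pd.Series(out, name=trait_means_deficient.name)
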