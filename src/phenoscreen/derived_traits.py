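"""Derived physiological quantities from genotype x treatment trait tables.

Covers phosphorus utilisation efficiency (PUE), the family of
"contribution" percentages that apportion dry matter between plant
parts, and signed relative differences between control and deficient
arms (e.g. the percent change in average root diameter under low P).
"""

from __future__ import annotations

import pandas as pd


def pue(p_content_control: float, p_content_deficient: float, p_applied: float) -> float:
    """Phosphorus utilisation efficiency.

    (P content under control - P content under deficiency) / P applied.
    Tissue P is on a mg/g dry-weight basis; ``p_applied`` is a
    user-supplied positive scalar whose units set the units of the
    result (the source protocols leave them implicit).  May be negative
    when tissue P rises under deficiency.
    """
    if p_applied <= 0:
        raise ValueError("p_applied must be positive")
    return (p_content_control - p_content_deficient) / p_applied


def contribution_percent(part_weight: float, denominator_weight: float) -> float:
    """Generic contribution kernel: 100 * part / denominator.

    The named contribution measures are this kernel with a specific
    denominator: total leaf weight (own development), total dry weight
    (total development / dry-matter partitioning), shoot dry weight, or
    root dry weight.
    """
    if denominator_weight <= 0:
        raise ValueError("denominator weight must be positive")
    if part_weight < 0:
        raise ValueError("part weight must be non-negative")
    return 100.0 * part_weight / denominator_weight


def relative_difference(control_value: float, deficient_value: float) -> float:
    """Percent change from control to deficient; positive = increase
    under deficiency (so a thickening root diameter reads positive)."""
    if control_value == 0:
        raise ValueError("control value must be non-zero")
    return 100.0 * (deficient_value - control_value) / control_value


def leaf_contributions(
    table: pd.DataFrame,
    leaf_cols: list[str],
    stem_col: str = "stem_dw",
    root_col: str = "root_dw",
) -> pd.DataFrame:
    """Per-genotype, per-treatment contribution percentages.

    Parts are the individual leaves, the stem and the root; total dry
    weight is their sum and shoot dry weight is leaves + stem.  For each
    leaf position i the output carries (namespaced under ``derived.``):

    * ``leaf{i}_own_pct``   — leaf_i / total leaf weight x 100
    * ``leaf{i}_total_pct`` — leaf_i / total dry weight x 100
    * ``leaf{i}_to_shoot_pct`` / ``leaf{i}_to_root_pct``
    * ``partition_<part>_pct`` — part / total dry weight x 100, for
      every part; these sum to 100 per plant by construction.

    Contributions are computed per replicate and then averaged within
    genotype x treatment, preserving within-genotype variance for the
    downstream statistics.
    """
    required = set(leaf_cols) | {stem_col, root_col, "genotype", "treatment"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"trait table is missing columns: {sorted(missing)}")
    parts = list(leaf_cols) + [stem_col, root_col]
    work = table[["genotype", "treatment"]].copy()
    total_leaf = table[leaf_cols].sum(axis=1)
    total = table[parts].sum(axis=1)
    shoot = total_leaf + table[stem_col]
    if (total <= 0).any() or (total_leaf <= 0).any():
        raise ValueError("total and total-leaf dry weights must be positive")
    for i, col in enumerate(leaf_cols, start=1):
        work[f"derived.leaf{i}_own_pct"] = 100.0 * table[col] / total_leaf
        work[f"derived.leaf{i}_total_pct"] = 100.0 * table[col] / total
        work[f"derived.leaf{i}_to_shoot_pct"] = 100.0 * table[col] / shoot
        work[f"derived.leaf{i}_to_root_pct"] = 100.0 * table[col] / table[root_col]
    for col in parts:
        work[f"derived.partition_{col}_pct"] = 100.0 * table[col] / total
    return work.groupby(["genotype", "treatment"], sort=True).mean()


def pue_table(
    table: pd.DataFrame, p_content_col: str, p_applied: float
) -> pd.Series:
    """Per-genotype PUE from replicate-mean tissue P in the two arms."""
    means = table.groupby(["genotype", "treatment"])[p_content_col].mean().unstack()
    for arm in ("control", "deficient"):
        if arm not in means.columns:
            raise ValueError(f"trait table lacks the {arm!r} treatment arm")
    out = (means["control"] - means["deficient"]) / float(p_applied)
    if p_applied <= 0:
        raise ValueError("p_applied must be positive")
    out.name = f"derived.pue_{p_content_col}"
    return out
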