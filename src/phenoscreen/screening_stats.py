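"""Multivariate screening statistics for genotype x treatment panels.

Implements the statistical battery used to screen genotype panels under
contrasting phosphorus regimes: balanced two-way fixed-effects ANOVA
with a sum-of-squares percentage partition, broad-sense heritability
from within-treatment one-way ANOVA, descriptive variability (CV, GCV,
skewness), Pearson trait correlations, PCA with a mean-threshold
genotype selection rule, and Ward-D2 hierarchical clustering with row
Z-score scaling for heat maps.

The two-way model is Y_ijk = mu + alpha_i + beta_j + gamma_ij + e_ijk
(genotype i, P concentration j, replicate k).  Broad-sense heritability
within a treatment is H2 = sigma2_g / sigma2_p x 100 with
sigma2_p = sigma2_g + sigma2_e / r, where sigma2_g is estimated as
max(0, (MS_G - MS_E) / r) from the one-way genotype ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

TREATMENTS = ("control", "deficient")


# ---------------------------------------------------------------------------
# ANOVA and variance components
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Balanced two-way ANOVA decomposition for one trait.

    ``table`` has one row per term (genotype, concentration,
    genotype:concentration, error) with df, sum_sq, mean_sq, F, p_value
    and ss_pct (the term's share of the total sum of squares); ss_pct
    sums to 100 over the four terms.
    """

    trait: str
    table: pd.DataFrame

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _check_balanced(sub: pd.DataFrame, by: list[str]) -> int:
    counts = sub.groupby(by, observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(
            "design is unbalanced (unequal cell counts); impute cell means or "
            "subset to a balanced design before the ANOVA"
        )
    return int(counts.iloc[0])


def two_way_anova(table: pd.DataFrame, trait: str) -> AnovaResult:
    """Classical balanced two-way fixed-effects ANOVA with SS%% partition.

    Sums of squares are computed from cell and marginal means (the
    textbook balanced decomposition); F statistics test each term
    against the error mean square.  Requires >= 2 genotypes, exactly 2
    treatments and >= 2 replicates per cell.
    """
    sub = table.dropna(subset=[trait])
    genos = sub["genotype"].unique()
    treats = sub["treatment"].unique()
    if len(genos) < 2 or len(treats) != 2:
        raise ValueError("need >= 2 genotypes and exactly 2 treatments")
    r = _check_balanced(sub, ["genotype", "treatment"])
    if r < 2:
        raise ValueError("need >= 2 replicates per genotype x treatment cell")
    y = sub[trait].to_numpy(dtype=float)
    grand = y.mean()
    a, b = len(genos), len(treats)
    n = len(y)

    g_means = sub.groupby("genotype")[trait].mean()
    c_means = sub.groupby("treatment")[trait].mean()
    cell_means = sub.groupby(["genotype", "treatment"])[trait].mean()

    ss_g = b * r * float(((g_means - grand) ** 2).sum())
    ss_c = a * r * float(((c_means - grand) ** 2).sum())
    ss_cells = r * float(((cell_means - grand) ** 2).sum())
    ss_gc = ss_cells - ss_g - ss_c
    ss_tot = float(((y - grand) ** 2).sum())
    ss_e = ss_tot - ss_cells

    df_g, df_c = a - 1, b - 1
    df_gc = df_g * df_c
    df_e = n - a * b
    rows = []
    ms_e = ss_e / df_e if df_e > 0 else np.nan
    for term, ss, df in (
        ("genotype", ss_g, df_g),
        ("concentration", ss_c, df_c),
        ("genotype:concentration", ss_gc, df_gc),
        ("error", ss_e, df_e),
    ):
        ms = ss / df if df > 0 else np.nan
        if term != "error" and ms_e > 0:
            f = ms / ms_e
            p = float(stats.f.sf(f, df, df_e))
        else:
            f, p = np.nan, np.nan
        rows.append(
            {
                "term": term,
                "df": df,
                "sum_sq": ss,
                "mean_sq": ms,
                "F": f,
                "p_value": p,
                "ss_pct": 100.0 * ss / ss_tot if ss_tot > 0 else np.nan,
            }
        )
    return AnovaResult(trait=trait, table=pd.DataFrame(rows).set_index("term"))


@dataclass
class VarianceComponents:
    """One-way genotype variance decomposition within one treatment."""

    sigma2_g: float
    sigma2_e: float
    r: int
    sigma2_p: float = field(init=False)
    H2_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.sigma2_p = self.sigma2_g + self.sigma2_e / self.r
        self.H2_pct = (
            100.0 * self.sigma2_g / self.sigma2_p if self.sigma2_p > 0 else 0.0
        )


def heritability(table: pd.DataFrame, trait: str, treatment: str) -> VarianceComponents:
    """Broad-sense heritability of a trait within one treatment arm.

    One-way ANOVA on genotypes gives MS_G and MS_E; the genotypic
    variance estimate is max(0, (MS_G - MS_E)/r) (negative estimates
    truncated, keeping H2 in [0, 100]).
    """
    sub = table[table["treatment"] == treatment].dropna(subset=[trait])
    if sub.empty:
        raise ValueError(f"no data for treatment {treatment!r}")
    r = _check_balanced(sub, ["genotype"])
    if r < 2:
        raise ValueError("heritability needs >= 2 replicates per genotype")
    a = sub["genotype"].nunique()
    if a < 2:
        raise ValueError("heritability needs >= 2 genotypes")
    y = sub[trait].to_numpy(dtype=float)
    grand = y.mean()
    g_means = sub.groupby("genotype")[trait].mean()
    ss_g = r * float(((g_means - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ms_g = ss_g / (a - 1)
    ms_e = (ss_tot - ss_g) / (a * (r - 1))
    sigma2_g = max(0.0, (ms_g - ms_e) / r)
    return VarianceComponents(sigma2_g=sigma2_g, sigma2_e=ms_e, r=r)


def descriptive_stats(table: pd.DataFrame, trait: str, treatment: str) -> dict:
    """Mean, sd, CV%%, GCV%% and skewness of a trait within a treatment.

    CV = 100 sd/mean; GCV = 100 sqrt(sigma2_g)/mean re-using the
    heritability variance components; skewness is the adjusted
    Fisher-Pearson coefficient.  Zero-mean traits get missing CV/GCV,
    constant traits missing skewness.
    """
    sub = table[table["treatment"] == treatment].dropna(subset=[trait])
    if len(sub) < 3:
        raise ValueError("need at least 3 observations")
    y = sub[trait].to_numpy(dtype=float)
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    if sd == 0:
        skew = np.nan
    else:
        skew = float(stats.skew(y, bias=False))
    try:
        vc = heritability(table, trait, treatment)
        sigma2_g = vc.sigma2_g
    except ValueError:
        sigma2_g = np.nan
    if mean == 0:
        warnings.warn("zero mean; CV and GCV are undefined", stacklevel=2)
        cv = gcv = np.nan
    else:
        cv = 100.0 * sd / abs(mean)
        gcv = 100.0 * float(np.sqrt(sigma2_g)) / abs(mean) if np.isfinite(sigma2_g) else np.nan
    return {"mean": mean, "sd": sd, "CV_pct": cv, "GCV_pct": gcv, "skewness": skew}


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p-value (the shared kernel)."""
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(
    genotype_means: pd.DataFrame, bonferroni: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait x trait Pearson correlations over genotype means.

    Returns ``(r, p)`` DataFrames; p-values are unadjusted two-sided
    t-tests unless ``bonferroni`` is set, in which case they are
    multiplied by the number of off-diagonal pairs (capped at 1).
    Constant traits get missing rows/columns with a warning.
    """
    if len(genotype_means) < 3:
        raise ValueError("need at least 3 genotypes")
    traits = list(genotype_means.columns)
    constant = [t for t in traits if genotype_means[t].nunique() <= 1]
    if constant:
        warnings.warn(f"constant traits have undefined correlations: {constant}")
    m = len(traits)
    r = pd.DataFrame(np.eye(m), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((m, m)), index=traits, columns=traits)
    n_pairs = m * (m - 1) // 2
    for i in range(m):
        for j in range(i + 1, m):
            if traits[i] in constant or traits[j] in constant:
                rij = pij = np.nan
            else:
                rij, pij = pearson(
                    genotype_means[traits[i]].to_numpy(),
                    genotype_means[traits[j]].to_numpy(),
                )
                if bonferroni:
                    pij = min(1.0, pij * n_pairs)
            r.iat[i, j] = r.iat[j, i] = rij
            p.iat[i, j] = p.iat[j, i] = pij
    for t in constant:
        r.loc[t, :] = r.loc[:, t] = np.nan
        p.loc[t, :] = p.loc[:, t] = np.nan
    return r, p


# ---------------------------------------------------------------------------
# PCA and genotype selection
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """SVD-based principal components of a genotype x trait matrix.

    ``loadings`` (trait x component) are orthonormal direction vectors;
    ``scores`` (genotype x component) are the centred data projected on
    them; ``explained_pct`` sums to 100 over the retained components
    (all of them); ``contributions_pct`` gives each trait's squared
    loading share per component, FactoMineR-style.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_pct: pd.Series
    contributions_pct: pd.DataFrame


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Principal component analysis by singular value decomposition.

    Columns are centred (and scaled to unit variance when
    ``standardize``); the sign of each component is fixed so that its
    largest-magnitude loading is positive, making results
    deterministic.  Missing values are an error, as is a constant
    column under standardization.
    """
    if matrix.isna().any().any():
        raise ValueError("PCA input must have no missing values")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 genotypes and >= 2 traits")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(matrix.columns[sd == 0])
            raise ValueError(f"constant columns cannot be standardized: {bad}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(matrix.shape[0] - 1, matrix.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|.| element of each loading vector positive
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comps = [f"PC{i + 1}" for i in range(k)]
    var = s**2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros(k)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=comps)
    scores = pd.DataFrame(u * s, index=matrix.index, columns=comps)
    contrib = pd.DataFrame(
        100.0 * loadings.to_numpy() ** 2, index=matrix.columns, columns=comps
    )
    return PcaResult(
        loadings=loadings,
        scores=scores,
        explained_pct=pd.Series(explained, index=comps),
        contributions_pct=contrib,
    )


def select_genotypes(
    pca_result: PcaResult,
    trait_means: pd.DataFrame,
    selection_traits: list[str],
) -> tuple[pd.DataFrame, list]:
    """Mean-threshold genotype selection across PCA quadrants.

    Each genotype is placed in a PC1/PC2 sign quadrant (Q1 = +/+,
    Q2 = -/+, Q3 = -/-, Q4 = +/- in score space) and flagged "superior"
    on each selection trait whose panel mean it exceeds, "inferior"
    otherwise (the panel mean of the respective trait is the selection
    threshold).  Returns the per-genotype label frame and a selection
    list containing, from every occupied quadrant, the genotype with
    the most superior flags and the one with the fewest — covering both
    contrasting responses.
    """
    if not selection_traits:
        raise ValueError("selection_traits must not be empty")
    missing = set(selection_traits) - set(trait_means.columns)
    if missing:
        raise KeyError(f"selection traits absent from trait means: {sorted(missing)}")
    scores = pca_result.scores
    if not {"PC1", "PC2"} <= set(scores.columns):
        raise ValueError("selection requires at least two principal components")
    common = scores.index.intersection(trait_means.index)
    if len(common) != len(scores.index):
        raise ValueError("scores and trait means must share the genotype set")

    pc1, pc2 = scores["PC1"], scores["PC2"]
    if (pc1 == 0).all() and (pc2 == 0).all():
        raise ValueError("no contrast: all genotypes collapse to a single point")
    quad = np.select(
        [
            (pc1 >= 0) & (pc2 >= 0),
            (pc1 < 0) & (pc2 >= 0),
            (pc1 < 0) & (pc2 < 0),
        ],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    out = pd.DataFrame({"quadrant": quad}, index=scores.index)
    thresholds = trait_means[selection_traits].mean()
    for t in selection_traits:
        out[f"superior_{t}"] = np.where(
            trait_means.loc[scores.index, t] > thresholds[t], "superior", "inferior"
        )
    flag_cols = [f"superior_{t}" for t in selection_traits]
    out["n_superior"] = (out[flag_cols] == "superior").sum(axis=1)
    if out["n_superior"].nunique() == 1 and trait_means[selection_traits].nunique().max() <= 1:
        raise ValueError("no contrast: all genotypes sit at the selection threshold")
    selected: list = []
    for q, grp in out.groupby("quadrant"):
        ranked = grp["n_superior"].sort_values()
        selected.append(ranked.index[-1])  # most superior flags
        if len(ranked) > 1 and ranked.index[0] not in selected:
            selected.append(ranked.index[0])  # most inferior
    return out, selected


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Ward-D2 clustering of items (rows) and features (columns)."""

    item_linkage: np.ndarray
    feature_linkage: np.ndarray | None
    scaled: pd.DataFrame
    labels: pd.Series


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, sd 1 (population sd): Z = (x - mu)/sigma."""
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sigma = values.std(axis=1, ddof=0, keepdims=True)
    bad = np.where(sigma[:, 0] == 0)[0]
    if len(bad):
        names = list(matrix.index[bad])
        raise ValueError(f"constant rows cannot be Z-scored: {names}")
    return pd.DataFrame((values - mu) / sigma, index=matrix.index, columns=matrix.columns)


def ward_cluster(
    matrix: pd.DataFrame, scale_rows: bool = True, k: int = 2
) -> ClusterResult:
    """Agglomerative clustering with Ward's D2 criterion.

    Rows (items) are optionally Z-scored first — the heat-map
    convention — then clustered on Euclidean distances; a feature
    dendrogram is built on the transposed scaled matrix.  Flat labels
    come from cutting the item dendrogram at ``k`` clusters.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 items to cluster")
    if not 1 <= k <= len(matrix):
        raise ValueError("k must lie in [1, n_items]")
    scaled = row_zscore(matrix) if scale_rows else matrix.astype(float).copy()
    item_linkage = linkage(scaled.to_numpy(), method="ward")
    feature_linkage = (
        linkage(scaled.to_numpy().T, method="ward") if matrix.shape[1] >= 2 else None
    )
    labels = pd.Series(
        fcluster(item_linkage, t=k, criterion="maxclust"), index=matrix.index, name="cluster"
    )
    return ClusterResult(
        item_linkage=item_linkage,
        feature_linkage=feature_linkage,
        scaled=scaled,
        labels=labels,
    )


def genotype_trait_means(
    table: pd.DataFrame, treatment: str | None = "deficient"
) -> pd.DataFrame:
    """Genotype x trait matrix of means, optionally within one treatment."""
    sub = table if treatment is None else table[table["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no rows for treatment {treatment!r}")
    traits = [c for c in table.columns if c not in ("genotype", "treatment", "rep")]
    return sub.groupby("genotype")[traits].mean()
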