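"""Trait-table IO, configuration and the reproducible pipeline driver.

The pipeline chains simulate -> extract -> indices -> screen: synthetic
plant images and a trait table are generated from one top-level seed,
geometric traits are extracted from the images, tolerance indices are
computed per trait, and the screening statistics (ANOVA, heritability,
correlations, PCA, Ward clustering) are written as CSV.  A JSON run
manifest records the config, software version and SHA-256 checksums of
every output so that reruns with the same config and seed can be
verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .image_traits import DEFAULT_THRESHOLDS, HSBThresholds, extract_directory
from .screening_stats import (
    correlation_matrix,
    genotype_trait_means,
    heritability,
    pca,
    row_zscore,
    select_genotypes,
    two_way_anova,
    ward_cluster,
)
from .synthetic_data import (
    SimModel,
    default_demo_spec,
    render_plant,
    simulate_trait_table,
    write_plant_image,
)
from .tolerance_indices import INDEX_NAMES, classify_genotypes, indices_from_table

logger = logging.getLogger("phenoscreen")

VALID_TREATMENTS = ("control", "deficient")
KEY_COLUMNS = ("genotype", "treatment", "rep")


# ---------------------------------------------------------------------------
# trait-table IO
# ---------------------------------------------------------------------------


class TraitTableError(ValueError):
    pass


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a tidy trait-table CSV.

    The header must start with genotype, treatment, rep; treatment
    labels must be "control" or "deficient"; (genotype, treatment, rep)
    must be unique; trait cells must be numeric (empty = missing).
    Errors name the offending row (1-based, excluding the header).
    """
    table = pd.read_csv(path, dtype={"genotype": str})
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(f"missing key columns: {missing}")
    bad = ~table["treatment"].isin(VALID_TREATMENTS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise TraitTableError(
            f"row {row}: unknown treatment {table['treatment'].iloc[row - 1]!r}; "
            f"allowed labels are {VALID_TREATMENTS}"
        )
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 1
        raise TraitTableError(f"row {row}: duplicate (genotype, treatment, rep) key")
    trait_cols = [c for c in table.columns if c not in KEY_COLUMNS]
    for col in trait_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise TraitTableError(
                f"row {row}: non-numeric value {table[col].iloc[row - 1]!r} in column {col!r}"
            )
        table[col] = coerced
    return table


def write_trait_table(table: pd.DataFrame, path) -> None:
    """Write a tidy trait table as UTF-8 comma-separated CSV."""
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML or JSON."""

    out_dir: str = "phenoscreen_out"
    images_dir: str | None = None  # None -> simulate into <out_dir>/images
    trait_table: str | None = None  # None -> simulate
    seed: int = 0
    n_genotypes: int = 18
    n_reps: int = 3
    traits: list[str] = field(
        default_factory=lambda: ["shoot_length", "shoot_dw", "root_dw", "mec_diameter"]
    )
    selection_traits: list[str] = field(
        default_factory=lambda: ["shoot_length", "shoot_dw"]
    )
    index_trait: str = "shoot_length"
    hsb: HSBThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    standardize_pca: bool = True
    n_clusters: int = 2
    n_demo_images: int = 3

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "hsb" in raw:
            raw["hsb"] = HSBThresholds(
                **{k: tuple(v) for k, v in raw["hsb"].items()}
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> "ok" | "failed: ..."
    checksums: dict = field(default_factory=dict)  # relative path -> sha256
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate -> extract -> indices -> screen.

    Stage outputs land under ``config.out_dir``; a failing stage is
    recorded in the manifest and stops the run, leaving prior outputs
    in place.  All randomness flows from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__, seed=config.seed)
    logger.info("pipeline start (seed=%d)", config.seed)

    def finish(path: Path) -> None:
        manifest.checksums[str(path.relative_to(out))] = _sha256(path)

    def fail(stage: str, exc: Exception) -> RunManifest:
        manifest.stages[stage] = f"failed: {exc}"
        logger.error("stage %s failed: %s", stage, exc)
        manifest.write(out / "manifest.json")
        return manifest

    # -- simulate ----------------------------------------------------------
    try:
        if config.trait_table is None:
            model = SimModel(
                n_genotypes=config.n_genotypes,
                n_reps=config.n_reps,
                seed=config.seed,
            )
            table, _ = simulate_trait_table(model, config.traits)
            table_path = out / "traits_simulated.csv"
            write_trait_table(table, table_path)
            finish(table_path)
        else:
            table = read_trait_table(config.trait_table)
        if config.images_dir is None:
            images_dir = out / "images"
            images_dir.mkdir(exist_ok=True)
            for i in range(config.n_demo_images):
                spec = default_demo_spec(seed=config.seed + i)
                for view in ("top", "front", "back"):
                    img, _, meta = render_plant(spec, view, seed=config.seed + i)
                    path = images_dir / f"plant{i + 1:02d}_{view}.png"
                    write_plant_image(path, img, meta)
                    finish(path)
        else:
            images_dir = Path(config.images_dir)
        manifest.stages["simulate"] = "ok"
    except Exception as exc:  # noqa: BLE001 - stage boundary
        return fail("simulate", exc)

    # -- extract -----------------------------------------------------------
    if config.images_dir is None and config.n_demo_images == 0:
        manifest.stages["extract"] = "skipped (no images requested)"
        images_dir = None
    try:
        if images_dir is not None:
            geo = extract_directory(images_dir, config.hsb)
            geo_path = out / "image_traits.csv"
            geo.to_csv(geo_path, index=False)
            finish(geo_path)
            manifest.stages["extract"] = "ok"
    except Exception as exc:  # noqa: BLE001
        return fail("extract", exc)

    # -- indices -----------------------------------------------------------
    try:
        idx_dir = out / "indices"
        idx_dir.mkdir(exist_ok=True)
        si_summary = {}
        for trait in config.traits:
            idx = indices_from_table(table, trait)
            frame = idx.indices.copy()
            for name in INDEX_NAMES:
                frame[f"rank_{name}"] = classify_genotypes(idx, name)["rank"]
            path = idx_dir / f"indices_{trait}.csv"
            frame.to_csv(path)
            finish(path)
            si_summary[trait] = idx.stress_intensity
        si_path = idx_dir / "stress_intensity.json"
        si_path.write_text(json.dumps(si_summary, indent=1))
        finish(si_path)
        manifest.stages["indices"] = "ok"
    except Exception as exc:  # noqa: BLE001
        return fail("indices", exc)

    # -- screen ------------------------------------------------------------
    try:
        anova_rows = []
        herit_rows = []
        for trait in config.traits:
            res = two_way_anova(table, trait)
            t = res.table.reset_index()
            t.insert(0, "trait", trait)
            anova_rows.append(t)
            for treatment in VALID_TREATMENTS:
                vc = heritability(table, trait, treatment)
                herit_rows.append(
                    {
                        "trait": trait,
                        "treatment": treatment,
                        "sigma2_g": vc.sigma2_g,
                        "sigma2_e": vc.sigma2_e,
                        "r": vc.r,
                        "sigma2_p": vc.sigma2_p,
                        "H2_pct": vc.H2_pct,
                    }
                )
        _write = lambda df, name: (df.to_csv(out / name, index=False), finish(out / name))
        _write(pd.concat(anova_rows, ignore_index=True), "anova.csv")
        _write(pd.DataFrame(herit_rows), "heritability.csv")

        means = genotype_trait_means(table, treatment="deficient")
        corr, corr_p = correlation_matrix(means)
        corr.to_csv(out / "corr.csv")
        finish(out / "corr.csv")
        corr_p.to_csv(out / "corr_p.csv")
        finish(out / "corr_p.csv")

        pca_res = pca(means, standardize=config.standardize_pca)
        pca_res.loadings.to_csv(out / "pca_loadings.csv")
        finish(out / "pca_loadings.csv")
        pca_res.scores.to_csv(out / "pca_scores.csv")
        finish(out / "pca_scores.csv")

        labels_frame, selected = select_genotypes(
            pca_res, means, config.selection_traits
        )
        labels_frame["selected"] = labels_frame.index.isin(selected)
        labels_frame.to_csv(out / "selection.csv")
        finish(out / "selection.csv")

        clust = ward_cluster(means.T, scale_rows=True, k=min(config.n_clusters, len(means.columns)))
        clust.scaled.to_csv(out / "row_scaled_matrix.csv")
        finish(out / "row_scaled_matrix.csv")
        geno_clust = ward_cluster(means, scale_rows=False, k=config.n_clusters)
        geno_clust.labels.to_frame().to_csv(out / "clusters.csv")
        finish(out / "clusters.csv")
        manifest.stages["screen"] = "ok"
    except Exception as exc:  # noqa: BLE001
        return fail("screen", exc)

    manifest.write(out / "manifest.json")
    logger.info("pipeline done: %s", out)
    return manifest
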