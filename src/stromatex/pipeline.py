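"""End-to-end runs: discovery/validation classification and cohort analysis.

Two orchestrations tie the stages together:

* :func:`run_discovery_validation` -- simulate labeled discovery and
  validation tiles, deconvolve, extract the 212-feature panel, run the
  Bonferroni differential screen on discovery, train the Random Forest,
  predict the validation tiles and evaluate the confusion matrix.
* :func:`run_cohort` -- simulate (or ingest) a TMA cohort of per-core
  cell tables, quantify cores and tumors, compare composition across
  sample groups and tally CD8 topography patterns.

Both are pure functions of a :class:`PipelineConfig` (single seed); when
given an output directory they write every tabular artifact as CSV/JSON
along with the resolved config, so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, cores, stats, topography
from .stains import MASSON_TRICHROME, StainMatrix, density_to_gray, od_to_density, rgb_to_od
from .synthetic import (
    CohortScenario,
    FiberTile,
    LabeledTileset,
    derive_seed,
    generate_cohort,
    generate_labeled_tileset,
    generate_tma_layout,
)
from .texture import GaborConfig, SftaConfig, tile_features

__all__ = [
    "PipelineConfig",
    "extract_tile_features",
    "tileset_features",
    "run_discovery_validation",
    "run_cohort",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run (fully serializable)."""

    seed: int = 0
    # discovery/validation tile counts: 100+/99- discovery, 151 validation
    n_discovery_pos: int = 100
    n_discovery_neg: int = 99
    n_validation_pos: int = 76
    n_validation_neg: int = 75
    d_max: float = 2.0
    alpha0: float = 0.05
    sfta: SftaConfig = field(default_factory=SftaConfig)
    gabor: GaborConfig = field(default_factory=GaborConfig)
    forest: classify.ForestConfig = field(default_factory=classify.ForestConfig)
    marker_thresholds: cores.MarkerThresholds = field(default_factory=cores.MarkerThresholds)
    infiltration_threshold: float = topography.DEFAULT_THRESHOLD
    n_patients: int = 42
    n_samples: int = 3
    n_cores: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_tile_features(
    tile: FiberTile | np.ndarray,
    matrix: StainMatrix = MASSON_TRICHROME,
    sfta: SftaConfig = SftaConfig(),
    gabor: GaborConfig = GaborConfig(),
    d_max: float = 2.0,
) -> pd.Series:
    """Deconvolve one RGB tile and compute its 212-feature vector."""
    rgb = tile.rgb if isinstance(tile, FiberTile) else tile
    dens = od_to_density(rgb_to_od(rgb, matrix.i0), matrix)
    return tile_features(
        density_to_gray(dens.blue, d_max), density_to_gray(dens.red, d_max), sfta, gabor
    )


def tileset_features(
    tileset: LabeledTileset,
    matrix: StainMatrix = MASSON_TRICHROME,
    sfta: SftaConfig = SftaConfig(),
    gabor: GaborConfig = GaborConfig(),
    d_max: float = 2.0,
) -> pd.DataFrame:
    """Feature table (rows = tiles, 212 named columns) of a tileset."""
    rows = [extract_tile_features(t, matrix, sfta, gabor, d_max) for t in tileset.tiles]
    df = pd.DataFrame(rows)
    df.index = [f"tile_{i:04d}" for i in range(len(rows))]
    return df


def _write_config(config: PipelineConfig, out_dir: Path) -> None:
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(config.to_dict(), default=str)), fh)


def run_discovery_validation(config: PipelineConfig = PipelineConfig(), out_dir=None) -> dict:
    """Simulate, screen, train, predict and evaluate in one seeded run."""
    matrix = MASSON_TRICHROME
    log.info("generating discovery (%d+/%d-) and validation (%d+/%d-) tiles",
             config.n_discovery_pos, config.n_discovery_neg,
             config.n_validation_pos, config.n_validation_neg)
    discovery = generate_labeled_tileset(
        config.n_discovery_pos, config.n_discovery_neg, seed=derive_seed(config.seed, 1)
    )
    validation = generate_labeled_tileset(
        config.n_validation_pos, config.n_validation_neg, seed=derive_seed(config.seed, 2)
    )

    disc_x = tileset_features(discovery, matrix, config.sfta, config.gabor, config.d_max)
    val_x = tileset_features(validation, matrix, config.sfta, config.gabor, config.d_max)

    screen = stats.differential_screen(disc_x, discovery.labels, alpha0=config.alpha0)
    forest_cfg = dataclasses.replace(config.forest, seed=derive_seed(config.seed, 3))
    fitted = classify.train_forest(disc_x, discovery.labels, forest_cfg)
    calls = classify.predict(fitted, val_x)
    summary = classify.evaluate(calls, validation.labels)

    results = {
        "config": config,
        "discovery_features": disc_x,
        "validation_features": val_x,
        "discovery_labels": discovery.labels,
        "validation_labels": validation.labels,
        "screen": screen,
        "model": fitted,
        "calls": calls,
        "evaluation": summary,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_config(config, out_dir)
        disc_x.assign(label=discovery.labels).to_csv(out_dir / "discovery_features.csv")
        val_x.assign(label=validation.labels, call=calls).to_csv(out_dir / "validation_features.csv")
        screen.per_feature.to_csv(out_dir / "differential_features.csv")
        fitted.importances.rename("importance").to_csv(out_dir / "importances.csv")
        with open(out_dir / "evaluation.json", "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2)
    return results


def run_cohort(config: PipelineConfig = PipelineConfig(), out_dir=None,
               scenario: CohortScenario | None = None) -> dict:
    """Simulate a TMA cohort, quantify it and tally CD8 topography."""
    layout = generate_tma_layout(config.n_patients, config.n_samples, config.n_cores)
    cohort = generate_cohort(layout, seed=derive_seed(config.seed, 4), scenario=scenario)
    core_df, tumor_df = cores.summarize_cohort(
        cohort.tables, layout.manifest, config.marker_thresholds
    )
    comparisons = cores.group_compare(tumor_df)
    pheno = topography.tumor_phenotypes(tumor_df, config.infiltration_threshold)
    tallies = {
        mode: topography.cohort_patterns(tumor_df, mode, config.infiltration_threshold)
        for mode in ("stroma", "cancer", "phenotype")
    }
    results = {
        "config": config,
        "cohort": cohort,
        "core_summaries": core_df,
        "tumor_summaries": tumor_df,
        "comparisons": comparisons,
        "phenotypes": pheno,
        "tallies": tallies,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_config(config, out_dir)
        core_df.to_csv(out_dir / "core_summaries.csv")
        tumor_df.to_csv(out_dir / "tumor_summaries.csv", index=False)
        comparisons.to_csv(out_dir / "group_comparisons.csv")
        pheno.to_csv(out_dir / "tumor_phenotypes.csv", index=False)
        with open(out_dir / "topography_tallies.json", "w") as fh:
            json.dump({m: t.as_dict() for m, t in tallies.items()}, fh, indent=2)
    return results
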