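"""End-to-end staged pipeline: diet → biomass → means → upscaling →
composition → performance, with a reproducibility manifest.

Every stage persists its output under the run directory; the manifest
records the package version, seed, a hash of the configuration and the
SHA-256 of every stage file, so two runs with the same configuration and
seed produce bit-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import wrenprey
from wrenprey import allometry, community, diet as diet_mod, performance, scaling
from wrenprey.io import match_table_to_otu_matches, read_bundle, validate_tables
from wrenprey.synthetic import StudyBundle

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    bundle_dir: str | Path
    output_dir: str | Path
    registry_path: str | Path | None = None  # None -> packaged defaults
    taxonomy_thresholds: dict = field(
        default_factory=lambda: dict(diet_mod.DEFAULT_THRESHOLDS)
    )
    prey_min_samples: int = 2
    area_radius_m: float = 100.0
    n_permutations: int = 999
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.bundle_dir).exists():
            raise FileNotFoundError(f"bundle_dir {self.bundle_dir} does not exist")
        if self.registry_path is not None and not Path(self.registry_path).exists():
            raise FileNotFoundError(f"registry {self.registry_path} does not exist")
        t = self.taxonomy_thresholds
        if not (t["species"] > t["genus"] > t["family"] > t["order"]):
            raise ValueError("taxonomy thresholds must strictly decrease species→order")
        if self.area_radius_m <= 0:
            raise ValueError("area radius must be positive")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["bundle_dir"] = str(d["bundle_dir"])
        d["output_dir"] = str(d["output_dir"])
        d["registry_path"] = None if d["registry_path"] is None else str(d["registry_path"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all six stages on a bundle directory; returns the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = read_bundle(config.bundle_dir)
    issues = validate_tables(bundle)
    if issues:
        raise PipelineError(f"stage validate: {len(issues)} violation(s); first: {issues[0]}")

    stage_files: dict[str, str] = {}
    counts: dict[str, dict] = {}

    # stage 1: diet profiling -------------------------------------------------
    try:
        matches = match_table_to_otu_matches(bundle.match_table)
        assignments = [
            diet_mod.assign_taxonomy(m, thresholds=config.taxonomy_thresholds)
            for m in matches
        ]
        profile = diet_mod.diet_profile(assignments, bundle.otu_table)
        prey, prey_excluded = diet_mod.designate_prey(profile, config.prey_min_samples)
        # Hymenoptera is analyzed as an independent (invasive-ant) axis,
        # never as a prey order, regardless of occasional diet detections.
        prey = prey - {"Hymenoptera"}
        p = out / "diet_profile.csv"
        profile.per_order.to_csv(p, index=False)
        stage_files["diet"] = p.name
        (out / "prey_orders.json").write_text(
            json.dumps(
                {"prey_orders": sorted(prey), "excluded": prey_excluded,
                 "n_samples_positive": profile.n_samples_positive},
                indent=2, sort_keys=True,
            )
        )
        stage_files["prey"] = "prey_orders.json"
        counts["diet"] = {
            "otus_in": len(matches),
            "otus_retained": sum(1 for a in assignments if not a.excluded),
            "samples_total": int(len(bundle.otu_table)),
            "samples_positive": profile.n_samples_positive,
        }
    except Exception as e:
        raise PipelineError(f"stage diet: {e}") from e

    # stage 2: biomass -------------------------------------------------------
    try:
        registry = (
            allometry.default_registry()
            if config.registry_path is None
            else allometry.load_registry(config.registry_path)
        )
        blocks = allometry.cell_biomass(bundle.arthropod_table, registry)
        cells = allometry.aggregate_cells(bundle.arthropod_table, registry)
        p = out / "cell_biomass.csv"
        cells.to_csv(p, index=False)
        stage_files["biomass"] = p.name
        counts["biomass"] = {
            "records_in": int(len(bundle.arthropod_table)),
            "cells_out": int(len(cells)),
        }
    except Exception as e:
        raise PipelineError(f"stage biomass: {e}") from e

    # stage 3: marginal means -------------------------------------------------
    try:
        means_log = community.marginal_means(blocks, transform="log1p")
        p = out / "marginal_means_log1p.csv"
        means_log.to_csv(p, index=False)
        stage_files["means"] = p.name
        counts["means"] = {"cells": int(len(means_log))}
    except Exception as e:
        raise PipelineError(f"stage means: {e}") from e

    # stage 4: territory upscaling -------------------------------------------
    try:
        area = scaling.standard_area(config.area_radius_m)
        avail = scaling.upscale(cells, bundle.cover_table, area, prey)
        avail, pca_results = scaling.attach_composition_scores(avail, prey)
        p = out / "territory_availability.csv"
        avail.to_csv(p, index=False)
        stage_files["upscale"] = p.name
        (out / "upscale_provenance.json").write_text(
            json.dumps(
                {"area_m2": area, "radius_m": config.area_radius_m,
                 "prey_orders": sorted(prey)},
                indent=2, sort_keys=True,
            )
        )
        stage_files["upscale_provenance"] = "upscale_provenance.json"
        counts["upscale"] = {"territories": int(avail["territory"].nunique())}
    except Exception as e:
        raise PipelineError(f"stage upscale: {e}") from e

    # stage 5: composition statistics ------------------------------------------
    try:
        reports = {}
        for stratum, block in blocks.groupby("stratum", observed=True):
            comp = (
                block[block["taxon"].isin(prey)]
                .pivot_table(
                    index=["territory", "block", "time_block", "habitat_element"],
                    columns="taxon", values="biomass_mg", aggfunc="sum", fill_value=0.0,
                )
            )
            comp = comp.loc[comp.sum(axis=1) > 0]
            groups = comp.index.get_level_values("habitat_element")
            ok = pd.Series(groups).value_counts()
            keep = groups.isin(ok[ok >= 2].index)
            comp = comp.loc[keep]
            groups = comp.index.get_level_values("habitat_element")
            if groups.nunique() < 2:
                logger.warning("stage compose: <2 element groups in %s", stratum)
                continue
            dist = community.dissimilarity_matrix(comp.reset_index(drop=True))
            res = community.permanova(
                dist, list(groups), n_permutations=config.n_permutations,
                seed=config.seed,
            )
            reports[stratum] = res.to_dict()
        p = out / "permanova.json"
        p.write_text(json.dumps(reports, indent=2, sort_keys=True))
        stage_files["compose"] = p.name
        counts["compose"] = {k: v["n_samples"] for k, v in reports.items()}
    except Exception as e:
        raise PipelineError(f"stage compose: {e}") from e

    # stage 6: performance links ----------------------------------------------
    try:
        if bundle.nesting_table is None or bundle.nesting_table.empty:
            raise PipelineError("stage link: missing input nesting_table")
        summary = performance.summarize_nesting(bundle.nesting_table)
        results = []
        for stratum in sorted(avail["stratum"].unique()):
            block = avail[avail["stratum"] == stratum]
            for predictor, transform in [
                ("prey_total", None), ("hymenoptera_total", "log"), ("PC1", None),
            ]:
                for response, family in [
                    ("first_egg_julian", "gaussian"), ("fledglings", "poisson"),
                ]:
                    try:
                        r = performance.relate(
                            block, bundle.nesting_table, predictor, response,
                            family=family, transform=transform,
                        )
                        d = r.to_dict()
                        d["stratum"] = stratum
                        results.append(d)
                    except (ValueError, KeyError) as e:
                        logger.warning(
                            "link %s~%s (%s) skipped: %s", response, predictor, stratum, e
                        )
        links = pd.DataFrame(results)
        p = out / "performance_links.csv"
        links.to_csv(p, index=False)
        stage_files["link"] = p.name
        (out / "nesting_summary.json").write_text(
            json.dumps(
                {"metrics": {k: list(v) for k, v in summary.metrics.items()},
                 "pooled_clutch_size": summary.pooled_clutch_size,
                 "n_territories": summary.n_territories},
                indent=2, sort_keys=True,
            )
        )
        stage_files["nesting_summary"] = "nesting_summary.json"
        counts["link"] = {"tests": int(len(links))}
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage link: {e}") from e

    manifest = {
        "package_version": wrenprey.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {k: {"file": v, "sha256": _sha256(out / v)} for k, v in stage_files.items()},
        "record_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
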