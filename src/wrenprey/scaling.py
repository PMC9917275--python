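"""Cover-weighted upscaling of habitat-element biomass to territory level.

A territory is standardized to the area of a 100 m circular buffer around the
nest (31,416 m²). Per-element mean biomass (raw scale, per standardized
sample) is weighted by that element's percent cover in the territory and
multiplied by the standard area:

    availability(order, territory, stratum)
        = Σ_elements (cover% / 100) × mean_biomass(order, element, ...) × area

Bare ground is a focal element with its own sampled biomass; non-focal cover
(other vegetation, artificial surfaces) contributes zero biomass and its
fraction is reported rather than imputed — the conversion assumes equal
sampling effort per unit covered area, which is acknowledged to be crude.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import pandas as pd

from wrenprey.community import pca_composition, relative_composition

logger = logging.getLogger(__name__)

#: Cover categories that carry no sampled arthropod biomass.
NONFOCAL_CATEGORIES: tuple[str, ...] = ("other", "artificial")

STANDARD_RADIUS_M = 100.0


class CoverageMismatchError(ValueError):
    """An element has nonzero cover but no biomass estimate."""


def standard_area(radius_m: float) -> int:
    """Area (m²) of the circular territory buffer, rounded to the nearest
    integer for reporting. radius 100 m → 31,416 m²."""
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    return int(round(math.pi * radius_m**2))


def upscale(
    means: pd.DataFrame,
    cover: pd.DataFrame,
    area_m2: float,
    prey_orders: Iterable[str],
    hymenoptera_label: str = "Hymenoptera",
    nonfocal: Sequence[str] = NONFOCAL_CATEGORIES,
) -> pd.DataFrame:
    """Territory × stratum prey availability from element means and cover.

    Parameters
    ----------
    means
        Raw-scale cell means keyed by (site, territory, habitat_element,
        stratum, taxon) with column ``biomass_mg`` (e.g.
        :func:`wrenprey.allometry.aggregate_cells` output).
    cover
        Long table (territory, habitat_element, percent); includes the
        non-focal categories. Percents are of total mapped territory area.
    area_m2
        Standardization area, normally ``standard_area(100)``.
    prey_orders
        Orders summed into ``prey_total`` (Hymenoptera is an independent
        axis, never part of the prey total).

    Returns a wide table: one row per territory × stratum, one column per
    taxon, plus prey_total, hymenoptera_total and nonfocal_percent.
    """
    prey_orders = sorted(set(prey_orders) - {hymenoptera_label})
    cov = cover.copy()
    cov["percent"] = cov["percent"].astype(float)
    if (cov["percent"] < 0).any() or (cov["percent"] > 100).any():
        raise ValueError("cover percents must lie in [0, 100]")

    focal_cov = cov.loc[~cov["habitat_element"].isin(nonfocal)]
    nonfocal_pct = (
        cov.loc[cov["habitat_element"].isin(nonfocal)]
        .groupby("territory", observed=True)["percent"]
        .sum()
    )

    mean_elems = set(means["habitat_element"].unique())
    bad = focal_cov.loc[
        (focal_cov["percent"] > 0) & (~focal_cov["habitat_element"].isin(mean_elems))
    ]
    if not bad.empty:
        missing = sorted(bad["habitat_element"].unique())
        raise CoverageMismatchError(
            f"elements with nonzero cover but no biomass estimates: {missing}"
        )

    merged = means.merge(
        focal_cov[["territory", "habitat_element", "percent"]],
        on=["territory", "habitat_element"],
        how="left",
    )
    merged["percent"] = merged["percent"].fillna(0.0)
    merged["weighted"] = merged["percent"] / 100.0 * merged["biomass_mg"] * area_m2

    keys = ["site", "territory", "stratum"]
    wide = (
        merged.groupby(keys + ["taxon"], observed=True)["weighted"]
        .sum()
        .unstack("taxon", fill_value=0.0)
        .reset_index()
    )
    taxa = [c for c in wide.columns if c not in keys]
    present_prey = [t for t in prey_orders if t in taxa]
    wide["prey_total"] = wide[present_prey].sum(axis=1) if present_prey else 0.0
    wide["hymenoptera_total"] = (
        wide[hymenoptera_label] if hymenoptera_label in taxa else 0.0
    )
    wide = wide.merge(
        nonfocal_pct.rename("nonfocal_percent"), on="territory", how="left"
    )
    wide["nonfocal_percent"] = wide["nonfocal_percent"].fillna(0.0)
    if (wide[taxa].to_numpy() == 0).all():
        logger.warning("upscale: all availabilities are zero (covers all 0%%?)")
    return wide


def attach_composition_scores(
    availability: pd.DataFrame,
    prey_orders: Iterable[str],
    n_axes: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Attach per-stratum PC scores of relative prey-order biomass.

    For each stratum, the territories × prey-orders biomass block is
    row-normalized to proportions and run through the composition PCA; the
    first ``n_axes`` scores are merged back as columns ``PC1``, ``PC2``, …
    Returns the augmented table and a per-stratum dict of PCA results.
    """
    prey_orders = sorted(set(prey_orders) - {"Hymenoptera"})
    out = availability.copy()
    for i in range(n_axes):
        out[f"PC{i + 1}"] = float("nan")
    results: dict = {}
    for stratum, block in availability.groupby("stratum", observed=True):
        cols = [c for c in prey_orders if c in block.columns]
        comp = relative_composition(block.set_index("territory")[cols])
        res = pca_composition(comp, n_axes=n_axes)
        results[stratum] = res
        for i, axis in enumerate(res.scores.columns):
            mapping = res.scores[axis]
            mask = out["stratum"] == stratum
            out.loc[mask, f"PC{i + 1}"] = out.loc[mask, "territory"].map(mapping).values
    return out, results
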