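"""Length→biomass conversion and aggregation of arthropod field samples.

Each field record is a group of arthropods of one taxon (order, or suborder
for Hemiptera) with a shared body length, counted in one sampling unit
(territory × spatial block × time block × habitat element × stratum). Body
mass follows a per-taxon power law ``mass_mg = a * length_mm ** b`` with
published order/suborder-level coefficients; the packaged registry ships
editable literature-style defaults, not authoritative values, and studies
should substitute their own coefficient source.

A handful of rare taxa have no published coefficients and are excluded from
biomass (returned as a ``None`` sentinel and logged) rather than guessed.

Aggregation reduces record-level mass to cell biomass per
(territory × habitat element × stratum × taxon × time block), then averages
over spatial blocks and totals over time blocks — in exactly that order.
Sampling units absent from the records (an element missing from a block) are
treated as missing, i.e. left out of the block mean, not as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Taxa with no published length–biomass coefficients; biomass is not
#: estimated for them (they are rare both in the environment and in diets).
EXCLUDED_TAXA: frozenset[str] = frozenset(
    {"Raphidoptera", "Archaeognatha", "Pseudoscorpionida", "Ephemeroptera", "Siphonaptera"}
)

#: When Hymenoptera records carry no species flag, this fraction of
#: individuals is attributed to the invasive Argentine ant.
INVASIVE_ANT_FRACTION_DEFAULT = 0.95

RECORD_COLUMNS = [
    "site",
    "territory",
    "block",
    "time_block",
    "habitat_element",
    "stratum",
    "taxon",
    "count",
    "body_length_mm",
]

_UNIT_KEYS = ["site", "territory", "block", "time_block", "habitat_element", "stratum"]


class UnknownTaxonError(KeyError):
    """Taxon absent from the registry and not on the exclusion list."""


@dataclass(frozen=True)
class AllometricCoefficient:
    """Power-law parameters: mass_mg(L) = a * L**b, L in mm."""

    taxon: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"{self.taxon}: a and b must be positive")

    def mass_mg(self, length_mm: float) -> float:
        if length_mm <= 0:
            raise ValueError(f"body length must be positive, got {length_mm}")
        return self.a * length_mm**self.b


Registry = Mapping[str, AllometricCoefficient]


def load_registry(path: str | Path) -> dict[str, AllometricCoefficient]:
    """Load a taxon→(a, b) registry from YAML (mapping taxon: {a, b})
    or CSV (columns taxon, a, b)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text())
        items = ((t, v["a"], v["b"]) for t, v in raw.items())
    else:
        df = pd.read_csv(path)
        items = ((r.taxon, r.a, r.b) for r in df.itertuples())
    return {t: AllometricCoefficient(t, float(a), float(b)) for t, a, b in items}


def default_registry() -> dict[str, AllometricCoefficient]:
    """The packaged default registry (editable literature-style values)."""
    ref = resources.files("wrenprey.data") / "allometry_registry.yaml"
    raw = yaml.safe_load(ref.read_text())
    return {t: AllometricCoefficient(t, float(v["a"]), float(v["b"])) for t, v in raw.items()}


def record_mass(
    taxon: str,
    body_length_mm: float,
    count: int,
    registry: Registry,
) -> float | None:
    """Biomass (mg) of a record: count × a × length**b.

    Returns the ``None`` sentinel for taxa on the exclusion list (logged);
    raises :class:`UnknownTaxonError` for any other unregistered taxon and
    ``ValueError`` for nonpositive lengths or counts.
    """
    if body_length_mm <= 0:
        raise ValueError(f"body length must be positive, got {body_length_mm}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if taxon in EXCLUDED_TAXA:
        logger.debug("no biomass estimate for excluded taxon %s", taxon)
        return None
    coef = registry.get(taxon)
    if coef is None:
        raise UnknownTaxonError(
            f"taxon {taxon!r} not in registry and not on the exclusion list"
        )
    return count * coef.mass_mg(body_length_mm)


def cell_biomass(records: pd.DataFrame, registry: Registry) -> pd.DataFrame:
    """Block-level cell biomass.

    Sums record masses within each
    (site, territory, block, time_block, habitat_element, stratum, taxon)
    cell, zero-filling taxa that were absent from a sampling unit that was
    otherwise sampled. Excluded taxa are dropped (logged). Units never seen
    in the records stay absent, so downstream reductions treat them as
    missing rather than zero.
    """
    if records.empty:
        raise ValueError("records table is empty")
    df = records.copy()
    excl = df["taxon"].isin(EXCLUDED_TAXA)
    if excl.any():
        logger.info(
            "cell_biomass: dropping %d record(s) of excluded taxa %s",
            int(excl.sum()),
            sorted(df.loc[excl, "taxon"].unique()),
        )
    kept = df.loc[~excl].copy()
    kept["biomass_mg"] = [
        record_mass(t, l, c, registry)
        for t, l, c in zip(kept["taxon"], kept["body_length_mm"], kept["count"])
    ]
    cells = (
        kept.groupby(_UNIT_KEYS + ["taxon"], as_index=False, observed=True)["biomass_mg"]
        .sum()
    )
    # zero-fill taxa within sampled units (units are defined by any record,
    # including excluded-taxon records: the trap was there)
    units = df[_UNIT_KEYS].drop_duplicates()
    taxa = sorted(kept["taxon"].unique())
    full = units.merge(pd.DataFrame({"taxon": taxa}), how="cross")
    out = full.merge(cells, on=_UNIT_KEYS + ["taxon"], how="left")
    out["biomass_mg"] = out["biomass_mg"].fillna(0.0)
    return out


def aggregate_cells(
    records: pd.DataFrame,
    registry: Registry,
    time_reduce: str | None = "sum",
) -> pd.DataFrame:
    """Mean-over-blocks then (optionally) total-over-time cell biomass.

    Returns a tidy table keyed by (site, territory, habitat_element, stratum,
    taxon) — plus time_block when ``time_reduce`` is None — with column
    ``biomass_mg``. Block means skip missing element × block units;
    ``time_reduce`` is ``"sum"`` (default: total across all time blocks),
    ``"mean"``, or None (keep time blocks).
    """
    blocks = cell_biomass(records, registry)
    keys = ["site", "territory", "habitat_element", "stratum", "taxon", "time_block"]
    per_time = blocks.groupby(keys, as_index=False, observed=True)["biomass_mg"].mean()
    if time_reduce is None:
        return per_time
    if time_reduce not in {"sum", "mean"}:
        raise ValueError(f"time_reduce must be 'sum', 'mean' or None, got {time_reduce!r}")
    agg = getattr(per_time.groupby(keys[:-1], as_index=False, observed=True)["biomass_mg"], time_reduce)
    return agg()
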