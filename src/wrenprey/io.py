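"""Tabular readers/writers and schema validation for study bundles.

All tables are UTF-8 CSV with header rows, decimal points and no thousands
separators; Julian dates are stored as plain integers. Every writer's output
round-trips through its reader with value equality, which the pipeline's
bit-identical-manifest guarantee depends on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from wrenprey.performance import NESTING_COLUMNS
from wrenprey.synthetic import StudyBundle, StudyConfig

logger = logging.getLogger(__name__)

ARTHROPOD_COLUMNS = [
    "site", "territory", "block", "time_block", "habitat_element",
    "stratum", "taxon", "invasive_ant", "count", "body_length_mm", "source",
]
COVER_COLUMNS = ["site", "territory", "habitat_element", "percent"]
MATCH_COLUMNS = ["otu_id", "order", "family", "genus", "species", "percent_similarity"]

TABLE_FILES = {
    "otu_table": "otu_table.csv",
    "match_table": "match_table.csv",
    "arthropod_table": "arthropod_table.csv",
    "cover_table": "cover_table.csv",
    "nesting_table": "nesting_table.csv",
}


@dataclass(frozen=True)
class Violation:
    table: str
    row: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" row {self.row}" if self.row is not None else ""
        return f"{self.table}{where}: {self.message}"


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four data tables as CSV, the truth record as JSON and the
    configuration as YAML. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, fname in TABLE_FILES.items():
        df: pd.DataFrame = getattr(bundle, name)
        p = outdir / fname
        df.to_csv(p, index=(name == "otu_table"))
        paths[name] = p
    tp = outdir / "truth.json"
    tp.write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    paths["truth"] = tp
    cp = outdir / "config.yaml"
    bundle.config.save(cp)
    paths["config"] = cp
    return paths


def read_bundle(indir: str | Path) -> StudyBundle:
    """Read a bundle written by :func:`write_bundle`."""
    indir = Path(indir)
    tables = {}
    for name, fname in TABLE_FILES.items():
        p = indir / fname
        if not p.exists():
            # the nesting table is only needed by the performance stage,
            # which reports it as its own missing input
            if name == "nesting_table":
                tables[name] = None
                continue
            raise FileNotFoundError(f"missing {name} file: {p}")
        tables[name] = pd.read_csv(p, index_col=0 if name == "otu_table" else None)
    truth_path = indir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    cfg_path = indir / "config.yaml"
    config = StudyConfig.load(cfg_path) if cfg_path.exists() else None
    return StudyBundle(
        otu_table=tables["otu_table"],
        match_table=tables["match_table"],
        arthropod_table=tables["arthropod_table"],
        cover_table=tables["cover_table"],
        nesting_table=tables["nesting_table"],
        truth=truth,
        config=config,
    )


def validate_tables(
    bundle: StudyBundle,
    elements: list[str] | None = None,
    strata: list[str] | None = None,
    cover_tolerance: float = 1.0,
) -> list[Violation]:
    """Schema-check a bundle; a clean bundle returns an empty list.

    Element and stratum vocabularies default to the bundle config when
    present, else to the labels observed in the tables.
    """
    v: list[Violation] = []
    cfg = bundle.config
    if elements is None:
        elements = list(cfg.habitat_elements) if cfg else sorted(
            bundle.arthropod_table["habitat_element"].unique()
        )
    if strata is None:
        strata = list(cfg.strata) if cfg else ["canopy", "ground"]

    art = bundle.arthropod_table
    for i, row in art.iterrows():
        if row["habitat_element"] not in elements:
            v.append(Violation("arthropod_table", i, f"unknown element {row['habitat_element']!r}"))
        if row["stratum"] not in strata:
            v.append(Violation("arthropod_table", i, f"unknown stratum {row['stratum']!r}"))
        if row["count"] < 1:
            v.append(Violation("arthropod_table", i, f"count {row['count']} < 1"))
        if row["body_length_mm"] <= 0:
            v.append(Violation("arthropod_table", i, f"nonpositive length {row['body_length_mm']}"))

    cover = bundle.cover_table
    for terr, grp in cover.groupby("territory", observed=True):
        total = grp["percent"].sum()
        if abs(total - 100.0) > cover_tolerance:
            row = int(grp.index[0])
            v.append(Violation("cover_table", row, f"territory {terr} cover sums to {total:.2f}"))
    if (cover["percent"] < 0).any() or (cover["percent"] > 100).any():
        bad = cover.index[(cover["percent"] < 0) | (cover["percent"] > 100)][0]
        v.append(Violation("cover_table", int(bad), "percent outside [0, 100]"))

    nest = bundle.nesting_table
    if nest is None:
        nest = pd.DataFrame(columns=NESTING_COLUMNS)
    for i, row in nest.iterrows():
        if row["successful_clutches"] > row["nest_attempts"]:
            v.append(Violation("nesting_table", i, "successful_clutches > nest_attempts"))
        if row["fledglings"] > row["total_eggs"]:
            v.append(Violation("nesting_table", i, "fledglings > total_eggs"))
        if not (1 <= row["first_egg_julian"] <= 366):
            v.append(Violation("nesting_table", i, f"first_egg_julian {row['first_egg_julian']} outside [1, 366]"))

    if (bundle.otu_table.to_numpy() < 0).any():
        v.append(Violation("otu_table", None, "negative read counts"))
    sims = bundle.match_table["percent_similarity"]
    if ((sims < 0) | (sims > 100)).any():
        bad = bundle.match_table.index[(sims < 0) | (sims > 100)][0]
        v.append(Violation("match_table", int(bad), "percent_similarity outside [0, 100]"))
    missing_order = bundle.match_table["order"].isna()
    if missing_order.any():
        bad = bundle.match_table.index[missing_order][0]
        v.append(Violation("match_table", int(bad), "candidate missing order"))
    return v


def match_table_to_otu_matches(match_table: pd.DataFrame):
    """Convert a long match table into :class:`wrenprey.diet.OtuMatch`
    objects (one per OTU, candidates grouped)."""
    from wrenprey.diet import Candidate, OtuMatch, TaxonPath

    def _opt(x):
        return None if pd.isna(x) else str(x)

    matches = []
    for otu, grp in match_table.groupby("otu_id", observed=True, sort=True):
        cands = tuple(
            Candidate(
                TaxonPath(
                    order=str(r["order"]),
                    family=_opt(r.get("family")),
                    genus=_opt(r.get("genus")),
                    species=_opt(r.get("species")),
                ),
                float(r["percent_similarity"]),
            )
            for _, r in grp.iterrows()
        )
        matches.append(OtuMatch(otu_id=str(otu), candidates=cands))
    return matches
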