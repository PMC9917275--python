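"""Taxonomy assignment and diet-composition metrics for COI metabarcoding.

OTUs (97%-similarity sequence clusters) arrive with a list of candidate
reference-database matches, each a taxonomy path and a percent similarity.
Assignment follows a published threshold cascade: the best similarity caps the
deepest rank an OTU may be resolved to (species ≥ 99.3%, genus ≥ 94.9%,
family ≥ 91%, order ≥ 85.9%), and when several candidates tie at the best
similarity with conflicting taxonomy the OTU is resolved to their lowest
common ancestor. Regional-knowledge override rules (e.g. a family with a
single locally occurring species) are applied last. OTUs unresolved at the
order level are excluded from diet metrics.

Diet composition is summarized per arthropod order as frequency of occurrence
(FO, the percent of samples with detectable arthropod DNA in which the order
appears — the primary metric, robust to read-count biases), relative read
abundance (RRA, mean per-sample proportion of reads), OTU counts and minimum
species richness. Orders detected in more than one sample are designated prey
taxa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RANKS: tuple[str, ...] = ("order", "family", "genus", "species")

#: Percent-similarity cutoffs (inclusive) capping the deepest assignable rank.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "species": 99.3,
    "genus": 94.9,
    "family": 91.0,
    "order": 85.9,
}

_SIM_TIE_TOL = 1e-9


class MalformedTaxonomyError(ValueError):
    """A candidate taxonomy path is missing its order."""


class EmptyProfileError(ValueError):
    """No sample contains any retained OTU."""


@dataclass(frozen=True)
class TaxonPath:
    """A four-rank taxonomy path; lower ranks may be unknown (None)."""

    order: str
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def at(self, rank: str) -> str | None:
        return getattr(self, rank)

    def truncate(self, rank: str) -> "TaxonPath":
        """Path with all ranks below `rank` cleared."""
        keep = RANKS[: RANKS.index(rank) + 1]
        return TaxonPath(**{r: (self.at(r) if r in keep else None) for r in RANKS})

    def contains(self, other: "TaxonPath") -> bool:
        """True if self is an ancestor-or-equal of `other` (prefix match on
        the ranks self has filled)."""
        for r in RANKS:
            v = self.at(r)
            if v is not None and v != other.at(r):
                return False
        return True


@dataclass(frozen=True)
class Candidate:
    path: TaxonPath
    similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 100.0):
            raise ValueError(f"similarity {self.similarity} outside [0, 100]")


@dataclass(frozen=True)
class OtuMatch:
    """One OTU's reference-database candidates. Read counts live in the
    sample × OTU table and are joined at profiling time."""

    otu_id: str
    candidates: tuple[Candidate, ...] = ()


@dataclass(frozen=True)
class OverrideRule:
    """Regional-knowledge refinement: when the resolved path carries
    `name` at `rank`, reassign to `assign_name` at `assign_rank`."""

    rank: str
    name: str
    assign_rank: str
    assign_name: str


#: The study region hosts a single Armadillidiidae species, so family-level
#: matches are refined to it.
ARMADILLIDIIDAE_OVERRIDE = OverrideRule(
    rank="family",
    name="Armadillidiidae",
    assign_rank="species",
    assign_name="Armadillidium vulgare",
)


@dataclass(frozen=True)
class TaxonAssignment:
    otu_id: str
    resolved_rank: str  # species | genus | family | order | unresolved
    resolved_name: str  # empty iff unresolved
    path: TaxonPath | None  # resolved path truncated at resolved_rank
    provenance: str  # threshold | lca | override | excluded
    excluded: bool

    @property
    def order(self) -> str | None:
        return self.path.order if self.path is not None else None


def _threshold_rank(similarity: float, thresholds: Mapping[str, float]) -> str | None:
    """Deepest rank permitted by the similarity cascade, or None."""
    for rank in reversed(RANKS):  # species first
        if similarity >= thresholds[rank] - _SIM_TIE_TOL:
            return rank
    return None


def _lca(paths: Sequence[TaxonPath]) -> tuple[str | None, TaxonPath | None]:
    """Deepest rank (and path) on which all paths agree with a known name."""
    agreed: dict[str, str] = {}
    deepest: str | None = None
    for rank in RANKS:
        names = {p.at(rank) for p in paths}
        if len(names) != 1 or None in names:
            break
        agreed[rank] = names.pop()
        deepest = rank
    if deepest is None:
        return None, None
    return deepest, TaxonPath(**{r: agreed.get(r) for r in RANKS})


def assign_taxonomy(
    match: OtuMatch,
    overrides: Iterable[OverrideRule] = (ARMADILLIDIIDAE_OVERRIDE,),
    thresholds: Mapping[str, float] | None = None,
) -> TaxonAssignment:
    """Resolve one OTU through the similarity-threshold cascade.

    The best similarity caps the assignable rank; equal-best candidates with
    conflicting taxonomy are resolved to their lowest common ancestor, further
    capped by the threshold rank. Override rules run last. An OTU that cannot
    be resolved at least to order is flagged excluded.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if not match.candidates:
        return TaxonAssignment(match.otu_id, "unresolved", "", None, "excluded", True)

    for cand in match.candidates:
        if not cand.path.order:
            raise MalformedTaxonomyError(
                f"OTU {match.otu_id}: candidate path missing order"
            )

    best = max(c.similarity for c in match.candidates)
    cap = _threshold_rank(best, thresholds)
    if cap is None:
        return TaxonAssignment(match.otu_id, "unresolved", "", None, "excluded", True)

    tied = [c.path for c in match.candidates if best - c.similarity <= _SIM_TIE_TOL]
    lca_rank, lca_path = _lca(tied)
    if lca_rank is None:
        # equal-similarity candidates conflict even at order level
        return TaxonAssignment(match.otu_id, "unresolved", "", None, "excluded", True)

    # The resolved rank is the shallower of the threshold cap and the deepest
    # rank the tied candidates (or the single candidate's known ranks) support.
    depth = min(RANKS.index(cap), RANKS.index(lca_rank))
    rank = RANKS[depth]
    path = lca_path.truncate(rank)
    provenance = "lca" if (len(tied) > 1 and RANKS.index(lca_rank) < RANKS.index(cap)) else "threshold"

    for rule in overrides:
        if path.at(rule.rank) == rule.name:
            new_fields = {r: path.at(r) for r in RANKS}
            new_fields[rule.assign_rank] = rule.assign_name
            path = TaxonPath(**new_fields)
            rank = rule.assign_rank
            provenance = "override"
            break

    return TaxonAssignment(match.otu_id, rank, path.at(rank) or "", path, provenance, False)


@dataclass
class DietProfile:
    """Per-order diet composition among samples with detectable arthropod DNA.

    ``per_order`` columns: order, n_samples_detected, fo_percent, rra,
    n_otus, n_species. Rows are sorted by FO descending, ties alphabetical.
    """

    per_order: pd.DataFrame
    n_samples_positive: int

    def fo(self, order: str) -> float:
        row = self.per_order.loc[self.per_order["order"] == order]
        return float(row["fo_percent"].iloc[0]) if len(row) else 0.0

    def occurrences(self, order: str) -> int:
        row = self.per_order.loc[self.per_order["order"] == order]
        return int(row["n_samples_detected"].iloc[0]) if len(row) else 0


def diet_profile(
    assignments: Sequence[TaxonAssignment],
    otu_table: pd.DataFrame,
) -> DietProfile:
    """Compute FO, RRA, OTU counts and minimum species richness per order.

    Parameters
    ----------
    assignments
        Output of :func:`assign_taxonomy`; excluded OTUs are dropped here.
    otu_table
        Samples × OTUs read-count matrix (rows = sample ids, columns =
        OTU ids, nonnegative integers).
    """
    retained = {a.otu_id: a for a in assignments if not a.excluded}
    cols = [c for c in otu_table.columns if c in retained]
    n_dropped = sum(1 for a in assignments if a.excluded)
    if n_dropped:
        logger.info("diet_profile: %d OTUs excluded (unresolved at order)", n_dropped)
    sub = otu_table[cols]
    positive = sub.loc[(sub > 0).any(axis=1)]
    n_pos = len(positive)
    if n_pos == 0:
        raise EmptyProfileError("no sample contains any retained OTU")

    order_of = {otu: retained[otu].order for otu in cols}
    rows = []
    orders = sorted({o for o in order_of.values() if o})
    totals = positive.sum(axis=1).astype(float)
    for order in orders:
        o_cols = [c for c in cols if order_of[c] == order]
        reads = positive[o_cols].sum(axis=1).astype(float)
        n_det = int((reads > 0).sum())
        rra = float((reads / totals).mean())
        species = {
            retained[c].resolved_name
            for c in o_cols
            if retained[c].resolved_rank == "species"
        }
        rows.append(
            {
                "order": order,
                "n_samples_detected": n_det,
                "fo_percent": 100.0 * n_det / n_pos,
                "rra": rra,
                "n_otus": len(o_cols),
                "n_species": len(species),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["fo_percent", "order"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return DietProfile(per_order=table, n_samples_positive=n_pos)


def designate_prey(
    profile: DietProfile, min_samples: int = 2
) -> tuple[set[str], dict[str, str]]:
    """Designate prey taxa: orders detected in at least `min_samples`
    (default 2, i.e. "more than 1") positive samples.

    Returns the prey-order set and a reason map for excluded orders.
    """
    prey: set[str] = set()
    excluded: dict[str, str] = {}
    for _, row in profile.per_order.iterrows():
        if row["n_samples_detected"] >= min_samples:
            prey.add(row["order"])
        else:
            excluded[row["order"]] = (
                f"detected in {int(row['n_samples_detected'])} sample(s) "
                f"(< {min_samples})"
            )
    if excluded:
        logger.info("designate_prey: excluded %s", sorted(excluded))
    return prey, excluded


def round_fo(fo: float, decimals: int = 1) -> float:
    """Half-away-from-zero rounding used when printing FO percentages."""
    factor = 10**decimals
    return math.floor(fo * factor + 0.5) / factor
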