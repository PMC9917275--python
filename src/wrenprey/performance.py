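"""Nesting-outcome summaries and availability → performance links.

Reproductive performance per territory is recorded as the Julian date of the
first egg (earlier = stronger performance), nest attempts, successful
clutches, total eggs and fledglings. Summaries report the mean ± SE across
territories; clutch size is computed per territory as eggs / attempts and
then averaged (the pooled eggs/attempts ratio is also reported).

Links between territory-level arthropod availability (prey biomass,
Hymenoptera biomass, composition PC scores) and performance use each
territory as the unit of replication: a Pearson correlation + simple linear
fit for gaussian responses (first egg date) and a log-link Poisson GLM for
counts (fledglings). With n ≈ 8 territories these are exploratory,
hypothesis-generating tests; p-values are two-sided and uncorrected, which
the report flags as a caveat.

``rank_discordance`` contrasts how orders rank in the nestling diet
(frequency of occurrence) against how they rank in environmental biomass —
the study system shows strong discordance, with the most-consumed orders
rare in the environment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NESTING_COLUMNS = [
    "site",
    "territory",
    "first_egg_julian",
    "nest_attempts",
    "successful_clutches",
    "total_eggs",
    "fledglings",
    "mortality_note",
]


class DegenerateFitError(ValueError):
    """Predictor or response is constant; the fit is undefined."""


def load_packaged_nesting() -> pd.DataFrame:
    """The packaged 2012 nesting-monitoring dataset for the eight study
    territories (one season's outcomes per territory)."""
    ref = resources.files("wrenprey.data") / "nesting_monitoring_2012.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def validate_nesting(records: pd.DataFrame) -> None:
    if (records["successful_clutches"] > records["nest_attempts"]).any():
        raise ValueError("successful_clutches exceeds nest_attempts")
    if (records["fledglings"] > records["total_eggs"]).any():
        raise ValueError("fledglings exceed total_eggs")
    bad = ~records["first_egg_julian"].between(1, 366)
    if bad.any():
        raise ValueError("first_egg_julian outside [1, 366]")


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, se


@dataclass
class NestingSummary:
    """Across-territory mean ± SE of each nesting metric."""

    metrics: dict[str, tuple[float, float]]  # name -> (mean, se)
    pooled_clutch_size: float
    n_territories: int
    excluded_from_clutch: list[str] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return self.metrics[metric][0]

    def se(self, metric: str) -> float:
        return self.metrics[metric][1]

    def rounded(self, decimals: int = 1) -> dict[str, tuple[float, float]]:
        return {
            k: (round(m, decimals), round(s, decimals))
            for k, (m, s) in self.metrics.items()
        }


def summarize_nesting(records: pd.DataFrame) -> NestingSummary:
    """Mean and SE (sample SD / √n, n−1 denominator) of nesting metrics
    across territories; clutch size is per-territory eggs/attempts averaged
    across territories. Territories with zero attempts are excluded from the
    clutch-size mean with a warning."""
    if len(records) < 2:
        raise ValueError("need at least 2 territories to summarize")
    validate_nesting(records)
    metrics: dict[str, tuple[float, float]] = {}
    for name, col in [
        ("first_egg_julian", "first_egg_julian"),
        ("nest_attempts", "nest_attempts"),
        ("total_eggs", "total_eggs"),
        ("fledglings", "fledglings"),
    ]:
        metrics[name] = _mean_se(records[col].to_numpy())

    ok = records["nest_attempts"] > 0
    excluded = records.loc[~ok, "territory"].tolist()
    if excluded:
        logger.warning("clutch size undefined (0 attempts) for %s", excluded)
    ratios = (
        records.loc[ok, "total_eggs"] / records.loc[ok, "nest_attempts"]
    ).to_numpy()
    metrics["clutch_size"] = _mean_se(ratios)
    pooled = float(
        records.loc[ok, "total_eggs"].sum() / records.loc[ok, "nest_attempts"].sum()
    )
    return NestingSummary(
        metrics=metrics,
        pooled_clutch_size=pooled,
        n_territories=len(records),
        excluded_from_clutch=excluded,
    )


@dataclass(frozen=True)
class LinkResult:
    predictor: str
    response: str
    slope: float
    statistic: float
    p_value: float
    r_squared: float
    n: int
    family: str
    transform: str | None = None
    caveat: str = "raw two-sided p, no multiple-testing correction"

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "response": self.response,
            "slope": self.slope,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n": self.n,
            "family": self.family,
            "transform": self.transform,
            "caveat": self.caveat,
        }


def relate(
    availability: pd.DataFrame,
    records: pd.DataFrame,
    predictor: str,
    response: str,
    family: str = "gaussian",
    transform: str | None = None,
) -> LinkResult:
    """Relate one availability metric to one nesting response across
    territories (merged on ``territory``).

    gaussian → Pearson correlation test plus simple linear fit (slope, R²,
    two-sided p). poisson → log-link count GLM (Wald z and p for the slope).
    ``transform="log"`` log-transforms the predictor first (used for
    heavy-tailed non-native biomass totals).
    """
    if response in records.columns:
        merged = availability.merge(
            records[["territory", response]], on="territory", how="inner"
        )
    elif response in availability.columns:
        merged = availability.copy()
    else:
        raise KeyError(f"response {response!r} not found")
    merged = merged.dropna(subset=[predictor, response])
    n = len(merged)
    if n < 4:
        raise ValueError(f"need >= 4 matched territories, got {n}")
    x = merged[predictor].to_numpy(dtype=float)
    y = merged[response].to_numpy(dtype=float)
    if transform == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires positive predictor values")
        x = np.log(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("constant predictor or response")

    if family == "gaussian":
        fit = stats.linregress(x, y)
        return LinkResult(
            predictor=predictor,
            response=response,
            slope=float(fit.slope),
            statistic=float(fit.rvalue),
            p_value=float(fit.pvalue),
            r_squared=float(fit.rvalue**2),
            n=n,
            family="gaussian",
            transform=transform,
        )
    if family == "poisson":
        import statsmodels.api as sm

        exog = sm.add_constant(x)
        glm = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
        slope = float(glm.params[1])
        z = float(glm.tvalues[1])
        p = float(glm.pvalues[1])
        # McFadden pseudo-R² reported in the R² slot for count fits
        null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson()).fit()
        pseudo_r2 = float(1 - glm.llf / null.llf) if null.llf != 0 else float("nan")
        return LinkResult(
            predictor=predictor,
            response=response,
            slope=slope,
            statistic=z,
            p_value=p,
            r_squared=pseudo_r2,
            n=n,
            family="poisson",
            transform=transform,
        )
    raise ValueError(f"family must be 'gaussian' or 'poisson', got {family!r}")


@dataclass
class DiscordanceReport:
    """Paired diet-rank vs availability-rank comparison per stratum."""

    table: pd.DataFrame  # order, diet_fo, diet_rank, biomass, biomass_rank, flag
    rank_correlation: float  # Spearman's rho with midranks
    p_value: float
    diet_only: list[str]
    availability_only: list[str]


def rank_discordance(
    diet_profile,
    availability: pd.DataFrame,
    stratum: str,
    order_columns: list[str] | None = None,
) -> DiscordanceReport:
    """Contrast diet FO ranks with environmental biomass ranks.

    Ranks are 1 = highest; Spearman's rho (midranks for ties) quantifies
    concordance. Orders appearing in only one input are listed separately;
    orders in the top half of diet ranks but bottom half of biomass ranks
    are flagged ``high-diet/low-availability`` (and vice versa).
    """
    diet = diet_profile.per_order.set_index("order")["fo_percent"]
    block = availability.loc[availability["stratum"] == stratum]
    if block.empty:
        raise ValueError(f"no availability rows for stratum {stratum!r}")
    if order_columns is None:
        non_taxa = {
            "site", "territory", "stratum", "prey_total", "hymenoptera_total",
            "nonfocal_percent",
        }
        order_columns = [
            c for c in block.columns
            if c not in non_taxa and not str(c).startswith("PC")
        ]
    biomass = block[order_columns].sum(axis=0)
    biomass.index.name = None

    common = sorted(set(diet.index) & set(biomass.index))
    if not common:
        raise ValueError("diet and availability share no orders")
    d = diet[common]
    b = biomass[common]
    d_rank = d.rank(ascending=False, method="average")
    b_rank = b.rank(ascending=False, method="average")
    if len(common) >= 2 and d.nunique() > 1 and b.nunique() > 1:
        rho, p = stats.spearmanr(d, b)
    else:
        rho, p = float("nan"), float("nan")
    half = (len(common) + 1) / 2
    flags = []
    for o in common:
        if d_rank[o] <= half and b_rank[o] > half:
            flags.append("high-diet/low-availability")
        elif d_rank[o] > half and b_rank[o] <= half:
            flags.append("low-diet/high-availability")
        else:
            flags.append("")
    table = pd.DataFrame(
        {
            "order": common,
            "diet_fo": d.values,
            "diet_rank": d_rank.values,
            "biomass": b.values,
            "biomass_rank": b_rank.values,
            "flag": flags,
        }
    )
    return DiscordanceReport(
        table=table,
        rank_correlation=float(rho),
        p_value=float(p),
        diet_only=sorted(set(diet.index) - set(biomass.index)),
        availability_only=sorted(set(biomass.index) - set(diet.index)),
    )
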