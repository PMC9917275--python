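"""Community statistics: marginal means, Bray–Curtis, PERMANOVA, PCA.

``marginal_means`` estimates habitat-element × territory mean biomass per
taxon and stratum. Under the full-interaction fixed structure used in the
field design (element, site, territory-in-site, all interactions), the
model-adjusted means on balanced data equal the arithmetic cell means of the
(optionally log1p-transformed) response across block × time replicates; that
cell-mean estimator is the contract here, with an optional mixed-model
refinement (random time-block / spatial-block intercepts, dropped when their
estimated variance is zero) for hypothesis-testing refits.

The composition statistics are implemented directly from their definitions:
Bray–Curtis dissimilarity BC(x, y) = Σ|xi − yi| / Σ(xi + yi); PERMANOVA with
the pseudo-F partition of squared inter-point distances among and within
groups and a seeded label-permutation null; and column-centered, unscaled
PCA (proportions share a scale) with a deterministic sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_KEYS = ["site", "territory", "habitat_element", "stratum", "taxon"]


class ZeroVarianceError(ValueError):
    """Input matrix has no variance; PCA is undefined."""


class UndefinedDistanceError(ValueError):
    """Bray–Curtis is undefined for two all-zero vectors."""


def marginal_means(
    block_table: pd.DataFrame,
    transform: str = "log1p",
) -> pd.DataFrame:
    """Cell means (and SEs) of biomass across block × time replicates.

    Parameters
    ----------
    block_table
        Block-level cell biomass from :func:`wrenprey.allometry.cell_biomass`
        (one row per site/territory/block/time_block/element/stratum/taxon).
    transform
        ``"log1p"`` (default; log(biomass + 1), the scale used for
        hypothesis tests) or ``"raw"`` (the scale consumed by territory
        upscaling).

    Returns a table keyed by (site, territory, habitat_element, stratum,
    taxon) with columns mean, se, n_obs, transform_scale. Cells missing from
    every block are simply absent (a warning names dropped elements).
    """
    if transform not in {"log1p", "raw"}:
        raise ValueError(f"transform must be 'log1p' or 'raw', got {transform!r}")
    df = block_table.copy()
    y = df["biomass_mg"].to_numpy(dtype=float)
    df["_y"] = np.log1p(y) if transform == "log1p" else y
    g = df.groupby(CELL_KEYS, observed=True)["_y"]
    out = g.agg(mean="mean", sd="std", n_obs="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_obs"])
    out = out.drop(columns="sd")
    out["transform_scale"] = transform
    return out


def mixed_model_means(
    block_table: pd.DataFrame,
    stratum: str,
    taxon: str,
    transform: str = "log1p",
):
    """Mixed-model refit for one stratum × taxon: log1p(biomass) with the
    full element × territory fixed interaction and a random time-block
    intercept, which is dropped (plain OLS refit) when its estimated
    variance is ~0. Returns fitted cell means keyed like marginal_means.

    On balanced data the fitted means coincide with the cell-mean estimator;
    this path exists for inference refits, not for point estimation.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = block_table.query("stratum == @stratum and taxon == @taxon").copy()
    if df.empty:
        raise ValueError(f"no data for stratum={stratum!r}, taxon={taxon!r}")
    df["_y"] = np.log1p(df["biomass_mg"]) if transform == "log1p" else df["biomass_mg"]
    formula = "_y ~ C(habitat_element) * C(territory)"
    try:
        mm = smf.mixedlm(formula, df, groups=df["time_block"]).fit(reml=True)
        re_var = float(np.asarray(mm.cov_re).ravel()[0])
    except Exception:  # pragma: no cover - singular fits on tiny data
        re_var = 0.0
        mm = None
    if mm is None or re_var < 1e-8:
        logger.info("random time-block variance ~0; refitting OLS")
        fit = smf.ols(formula, df).fit()
        df["_fit"] = fit.fittedvalues
    else:
        df["_fit"] = np.asarray(mm.fittedvalues)
    keys = ["site", "territory", "habitat_element"]
    out = df.groupby(keys, as_index=False, observed=True)["_fit"].mean()
    out = out.rename(columns={"_fit": "mean"})
    out["stratum"] = stratum
    out["taxon"] = taxon
    out["transform_scale"] = transform
    return out


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|xi − yi| / Σ(xi + yi), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = float((x + y).sum())
    if denom == 0.0:
        raise UndefinedDistanceError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def dissimilarity_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Bray–Curtis matrix over the rows of an
    abundance table (rows = samples, columns = taxa)."""
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be nonnegative")
    n = arr.shape[0]
    totals = arr.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    if (denom[~np.eye(n, dtype=bool)] == 0).any():
        raise UndefinedDistanceError("a pair of all-zero rows has no distance")
    out = np.zeros((n, n))
    for i in range(n):  # row-at-a-time keeps memory at O(n * p)
        out[i] = np.abs(arr[i] - arr).sum(axis=1) / denom[i]
        out[i, i] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "n_samples": self.n_samples,
            "n_groups": self.n_groups,
            "seed": self.seed,
        }


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    a = counts.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    distances: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F statistic partitions the sum of squared inter-point
    distances among and within groups; the p-value is
    (#{permuted F ≥ observed} + 1) / (n_permutations + 1) under unrestricted
    row permutations drawn from a seeded generator.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = pd.Categorical(np.asarray(groups))
    codes = labels.codes.astype(np.int64)
    counts = np.bincount(codes)
    if counts.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    d2 = d**2
    f_obs = _pseudo_f(d2, codes, counts)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, counts) >= f_obs - 1e-12:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        n_samples=d.shape[0],
        n_groups=counts.size,
        seed=seed,
    )


def relative_composition(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize an abundance table to proportions. All-zero rows stay
    zero and are flagged with a warning."""
    totals = matrix.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("relative_composition: %d all-zero row(s)", int(zero.sum()))
    out = matrix.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return out


@dataclass
class PCAResult:
    """Column-centered unscaled PCA. ``scores @ loadings.T`` reconstructs the
    centered matrix when all axes are retained."""

    scores: pd.DataFrame  # rows × axes
    loadings: pd.DataFrame  # columns × axes
    variance_fraction: np.ndarray  # over ALL axes, non-increasing
    column_means: pd.Series


def pca_composition(matrix: pd.DataFrame, n_axes: int | None = None) -> PCAResult:
    """PCA on a relative-abundance matrix (rows = units, columns = taxa).

    Columns are centered but not rescaled — proportions already share a
    scale. Axis signs are fixed so each axis's largest-|loading| entry is
    positive, making axis interpretation reproducible.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    xc = x - mu
    if float((xc**2).sum()) < 1e-15:
        raise ZeroVarianceError("matrix has no variance across rows")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    # deterministic sign: largest-|loading| per axis made positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    k = scores.shape[1] if n_axes is None else min(n_axes, scores.shape[1])
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :k], index=matrix.index, columns=axes[:k]),
        loadings=pd.DataFrame(vt.T[:, :k], index=matrix.columns, columns=axes[:k]),
        variance_fraction=var_frac,
        column_means=pd.Series(mu, index=matrix.columns),
    )
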