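"""Population trait matrices: means, normalization, imputation, pooling.

The regression-tree response is a population x trait matrix of
provenance means, expressed in units of standard deviations from the
overall growth-chamber mean (so chambers with different temperature
programs become comparable), with missing population x chamber cells
imputed from the most similar populations, and finally pooled across
chambers (justified when population-by-environment interaction is weak).

Chamber-specific columns are named ``"<trait>:<chamber>"``; the pooled
matrix has one column per trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from genecol.synthetic import TRAITS

__all__ = [
    "TraitMatrix",
    "population_chamber_means",
    "normalize",
    "impute",
    "pool_across_chambers",
]


@dataclass
class TraitMatrix:
    """Population x column matrix with missingness book-keeping.

    Attributes
    ----------
    values : DataFrame
        Rows indexed by population; NaN marks missing cells.
    imputed : DataFrame
        Boolean mask of cells that were filled by imputation (always a
        subset of the cells originally missing).
    counts : DataFrame, optional
        Seedlings behind each mean (0 for originally missing cells).
    """

    values: pd.DataFrame
    imputed: pd.DataFrame = None  # type: ignore[assignment]
    counts: pd.DataFrame | None = None

    def __post_init__(self):
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def missing(self) -> pd.DataFrame:
        """Cells currently missing (NaN)."""
        return self.values.isna()

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            self.values.copy(),
            self.imputed.copy(),
            None if self.counts is None else self.counts.copy(),
        )


def population_chamber_means(
    observations: pd.DataFrame,
    traits: Sequence[str] = tuple(TRAITS),
    population: str = "seedlot_id",
    chamber: str = "chamber_id",
) -> TraitMatrix:
    """Arithmetic trait means per population x chamber, with cell counts.

    Populations absent from a chamber get NaN means with count 0.
    Columns are ``"<trait>:<chamber>"``.
    """
    g = observations.groupby([population, chamber], sort=True)
    means = g[list(traits)].mean().unstack(chamber)
    sizes = g.size().unstack(chamber).reindex(means.index).fillna(0).astype(int)
    counts = pd.DataFrame(
        {f"{t}:{c}": sizes[c] for t, c in means.columns}, index=means.index
    )
    means.columns = [f"{t}:{c}" for t, c in means.columns]
    means.index.name = "population"
    counts.index.name = "population"
    return TraitMatrix(values=means, counts=counts)


def normalize(matrix: TraitMatrix | pd.DataFrame) -> TraitMatrix:
    """Standardize each column to mean 0, SD 1 over its non-missing entries.

    The sample (n-1) SD convention is used, since population means are a
    sample of provenances.  Missing entries are ignored and left
    missing.  Idempotent.  A column with zero spread (or fewer than two
    observed values) cannot be normalized and is rejected by name.
    """
    tm = matrix if isinstance(matrix, TraitMatrix) else TraitMatrix(matrix.copy())
    vals = tm.values.copy()
    bad = []
    for col in vals.columns:
        v = vals[col]
        sd = v.std(ddof=1)
        if v.notna().sum() < 2 or not sd > 0:
            bad.append(col)
            continue
        vals[col] = (v - v.mean()) / sd
    if bad:
        raise ValueError(f"cannot normalize zero-spread column(s): {bad}")
    return TraitMatrix(vals, tm.imputed.copy(), tm.counts)


def _knn_fill(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaNs with the mean over the k nearest rows that observe the cell.

    Row distance is Euclidean over the columns observed in both rows,
    rescaled by sqrt(n_columns / n_shared) so sparsity does not shrink
    distances (the usual NaN-aware Euclidean convention).
    """
    n, m = values.shape
    out = values.copy()
    obs = ~np.isnan(values)
    filled_mask = np.zeros_like(obs)
    diff = values[:, None, :] - values[None, :, :]
    shared = obs[:, None, :] & obs[None, :, :]
    sq = np.where(shared, diff**2, 0.0).sum(axis=2)
    n_shared = shared.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(sq * m / n_shared)
    dist[n_shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)
    for i in range(n):
        for j in range(m):
            if obs[i, j]:
                continue
            donors = np.where(obs[:, j] & np.isfinite(dist[i]))[0]
            if len(donors) == 0:
                continue
            order = donors[np.argsort(dist[i, donors], kind="stable")]
            out[i, j] = values[order[:k], j].mean()
            filled_mask[i, j] = True
    return out, filled_mask


def impute(matrix: TraitMatrix, k: int = 5) -> TraitMatrix:
    """k-nearest-row imputation of missing cells.

    Each missing cell is filled with the mean of that column over the
    ``k`` rows nearest in Euclidean distance on shared non-missing
    columns.  Observed cells are never changed.  Rows with no observed
    value at all carry no information to match on and are rejected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values
    empty = vals.index[vals.isna().all(axis=1)]
    if len(empty):
        raise ValueError(f"rows with no observed values: {list(empty)}")
    filled, mask = _knn_fill(vals.to_numpy(float), k)
    out = pd.DataFrame(filled, index=vals.index, columns=vals.columns)
    imputed = matrix.imputed | pd.DataFrame(mask, index=vals.index, columns=vals.columns)
    return TraitMatrix(out, imputed, matrix.counts)


def pool_across_chambers(matrix: TraitMatrix) -> TraitMatrix:
    """Average chamber-specific normalized columns per trait; re-standardize.

    Input columns must be named ``"<trait>:<chamber>"`` and contain no
    missing values (impute first).  The pooled columns are re-normalized
    so the output is again in SD units around zero.
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("pooling requires a complete (imputed) matrix")
    traits = []
    for col in vals.columns:
        t = col.split(":")[0]
        if t not in traits:
            traits.append(t)
    pooled = pd.DataFrame(
        {
            t: vals[[c for c in vals.columns if c.split(":")[0] == t]].mean(axis=1)
            for t in traits
        },
        index=vals.index,
    )
    return normalize(TraitMatrix(pooled))
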