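"""Community-matrix preparation: rarity filters, Wisconsin double
standardisation with square-root transform, and Bray-Curtis dissimilarities.

The community matrix (the L table of the trait-environment analysis) is a
pandas DataFrame with sites as rows and species as columns, holding
non-negative abundances.  Preparation for ordination follows the standard
community-ecology sequence: drop very rare species (grand total <= 2
individuals) and depauperate sites (< 3 individuals), square-root transform,
scale each species by its maximum, scale each site by its total, and compute
Bray-Curtis dissimilarities between sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["FilterResult", "validate_community", "filter_rare", "wisconsin_sqrt", "bray_curtis"]


def validate_community(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("duplicate site or species identifiers")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("abundances must be finite and non-negative")
    return matrix


@dataclass
class FilterResult:
    matrix: pd.DataFrame
    dropped_species: list
    dropped_sites: list


def filter_rare(
    matrix: pd.DataFrame,
    min_species_total: int = 3,
    min_site_total: int = 3,
    mode: str = "abundance",
) -> FilterResult:
    """Drop rare species, then depauperate sites.

    Species whose grand-total abundance falls below ``min_species_total``
    (default: totals of 1 or 2, i.e. species found only once or twice) are
    removed first; sites whose remaining total is below ``min_site_total``
    are removed second. Applied once, not iterated to a fixed point.

    ``mode='occupancy'`` instead drops species present at fewer than
    ``min_species_total`` sites (an alternative reading of "found only once
    or twice").
    """
    validate_community(matrix)
    if mode == "abundance":
        species_stat = matrix.sum(axis=0)
    elif mode == "occupancy":
        species_stat = (matrix > 0).sum(axis=0)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    keep_species = species_stat[species_stat >= min_species_total].index
    dropped_species = [s for s in matrix.columns if s not in set(keep_species)]
    out = matrix[keep_species]
    if out.shape[1] == 0:
        raise ValueError("species filter removed every species")
    site_totals = out.sum(axis=1)
    keep_sites = site_totals[site_totals >= min_site_total].index
    dropped_sites = [s for s in matrix.index if s not in set(keep_sites)]
    out = out.loc[keep_sites]
    if out.shape[0] == 0:
        raise ValueError("site filter removed every site")
    return FilterResult(out, dropped_species, dropped_sites)


def wisconsin_sqrt(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform followed by Wisconsin double standardisation.

    Elementwise sqrt, then each species column divided by its maximum, then
    each site row divided by its total; every output row sums to 1.
    """
    validate_community(matrix)
    values = np.sqrt(matrix.to_numpy(dtype=float))
    col_max = values.max(axis=0)
    if (col_max == 0).any():
        bad = matrix.columns[col_max == 0].tolist()
        raise ValueError(f"all-zero species columns: {bad}")
    values = values / col_max
    row_tot = values.sum(axis=1)
    if (row_tot == 0).any():
        bad = matrix.index[row_tot == 0].tolist()
        raise ValueError(f"all-zero site rows: {bad}")
    values = values / row_tot[:, None]
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sites.

    D[a,b] = sum|x_a - x_b| / sum(x_a + x_b); 0 for identical rows, 1 for
    rows with disjoint support.
    """
    validate_community(matrix)
    values = matrix.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        bad = matrix.index[values.sum(axis=1) == 0].tolist()
        raise ValueError(f"zero-total site rows: {bad}")
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)
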