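"""Normalization and cohort stratification by a driver gene.

Two stratification primitives are provided:

* quartile high/low grouping for bulk cohorts — samples strictly below the
  lower quantile of driver expression form the low group, samples strictly
  above the upper quantile the high group, everything else is middle;
* positive/negative binarization for single cells — a cell is positive
  exactly when its (normalized) driver value exceeds zero.

Quantile thresholds use linear interpolation between order statistics
(type 7, numpy's default) with strict inequalities.  With 124, 103 and 50
distinct values this yields low/high groups of 31/31, 26/26 and 13/13
respectively.  Values tied exactly with a threshold are assigned to the
middle group with a warning, keeping low and high unambiguous.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix


class StratificationError(ValueError):
    """Raised when a value distribution cannot be stratified."""


@dataclass
class StratifiedGroups:
    """Quartile-based low / middle / high partition of a cohort."""

    low_ids: list[str]
    high_ids: list[str]
    middle_ids: list[str]
    driver_gene: str
    thresholds: tuple[float, float]
    convention: str = "type7-strict"

    def __post_init__(self) -> None:
        all_ids = self.low_ids + self.high_ids + self.middle_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("low/high/middle groups are not disjoint")

    @property
    def n_low(self) -> int:
        return len(self.low_ids)

    @property
    def n_high(self) -> int:
        return len(self.high_ids)


@dataclass
class BinaryGroups:
    """Positive (driver expressed) / negative (driver exactly zero) split."""

    positive_ids: list[str]
    negative_ids: list[str]
    driver_gene: str


def normalize_cpm(m: ExpressionMatrix, log_transform: bool = False) -> ExpressionMatrix:
    """Counts-per-million normalization, optionally on the log10(CPM+1) scale.

    CPM_gs = counts_gs / library_size_s * 1e6.  Columns with zero library
    size are rejected (their CPM is undefined).
    """
    if m.layer != "counts":
        raise ValueError(f"normalize_cpm expects layer=counts, got {m.layer!r}")
    colsums = m.data.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    cpm = m.data.div(colsums, axis=1) * 1e6
    if log_transform:
        return ExpressionMatrix(np.log10(cpm + 1.0), layer="log10cpm1")
    return ExpressionMatrix(cpm, layer="cpm")


def quantile_stratify(
    values: pd.Series, q: float = 0.25, driver_gene: str = "", min_samples: int = 8
) -> StratifiedGroups:
    """Partition samples into low / middle / high by driver-gene quantiles.

    Thresholds are the type-7 quantiles at ``q`` and ``1 - q``; membership
    is strict (low < lower threshold < middle < upper threshold < high).
    Values exactly equal to a threshold go to middle, with a warning.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    values = values.dropna()
    if len(values) < max(min_samples, 4):
        raise StratificationError(
            f"need >= {max(min_samples, 4)} samples to stratify, got {len(values)}"
        )
    arr = values.to_numpy(dtype=float)
    if np.all(arr == arr[0]):
        raise StratificationError("degenerate distribution, no stratification")
    lo_thr, hi_thr = np.quantile(arr, [q, 1.0 - q], method="linear")
    low = values.index[arr < lo_thr]
    high = values.index[arr > hi_thr]
    tied = ((arr == lo_thr) | (arr == hi_thr)).sum()
    if tied:
        warnings.warn(
            f"{tied} value(s) tie exactly with a quantile threshold; assigned to middle",
            stacklevel=2,
        )
    middle = values.index[(arr >= lo_thr) & (arr <= hi_thr)]
    return StratifiedGroups(
        low_ids=list(low),
        high_ids=list(high),
        middle_ids=list(middle),
        driver_gene=driver_gene.upper(),
        thresholds=(float(lo_thr), float(hi_thr)),
    )


def binarize_positive(m: ExpressionMatrix, gene: str) -> BinaryGroups:
    """Split cells into driver-positive (value > 0) and -negative (value == 0).

    Positivity is invariant to any library-size normalization, so this
    operates on whatever layer the matrix carries.
    """
    gene = gene.upper()
    if gene not in m.data.index:
        near = difflib.get_close_matches(gene, m.gene_ids, n=3)
        hint = f"; nearest symbols: {near}" if near else ""
        raise KeyError(f"gene {gene!r} not in matrix{hint}")
    vals = m.data.loc[gene]
    positive = list(vals.index[vals > 0])
    negative = list(vals.index[vals == 0])
    if not positive:
        warnings.warn(f"gene {gene} is zero in every cell", stacklevel=2)
    elif not negative:
        warnings.warn(
            f"gene {gene} is positive in every cell; negative group is empty", stacklevel=2
        )
    return BinaryGroups(positive_ids=positive, negative_ids=negative, driver_gene=gene)
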