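"""Growth rates and the pseudo-proliferation index.

Cell growth rate relates to doubling time by ``growth rate = ln(2) / T``.
When growth rates are not reported alongside a panel, the per-cell-line
mean (or median) of a curated proliferation-marker set serves as a proxy
— the pseudo-proliferation index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, MarkerSet, masked_pearson

LN2 = math.log(2.0)


def growth_rate_from_doubling(doubling_time):
    """``ln(2) / T`` for a doubling time in hours (scalar or array)."""
    t = np.asarray(doubling_time, dtype=float)
    if np.any(t <= 0):
        raise ValueError("doubling time must be positive")
    out = LN2 / t
    return float(out) if np.isscalar(doubling_time) or out.ndim == 0 else out


def make_growth_rate_table(doubling_times: pd.Series) -> pd.DataFrame:
    """Two-column table of doubling time (h) and growth rate (1/h)."""
    rates = growth_rate_from_doubling(doubling_times.to_numpy())
    return pd.DataFrame(
        {
            "doubling_time_hours": doubling_times.to_numpy(float),
            "growth_rate": rates,
        },
        index=doubling_times.index,
    )


@dataclass(frozen=True)
class IndexVector:
    """Pseudo-proliferation index of one dataset.

    ``values`` holds the per-cell-line statistic over observed marker
    signals; ``coverage`` the number of markers observed per cell line.
    Cell lines with no observed marker are dropped rather than imputed.
    """

    dataset_id: str
    statistic: str
    values: pd.Series
    coverage: pd.Series

    def __len__(self) -> int:
        return len(self.values)


def compute_index(
    dataset: ExpressionDataset,
    markers: MarkerSet,
    statistic: str = "mean",
) -> IndexVector:
    """Per-cell-line mean (or median) of observed marker signals.

    Missing markers are simply excluded from that cell line's statistic.
    Raises if the dataset contains none of the marker genes, naming them.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    present = [g for g in markers.genes if g in dataset.genes]
    if not present:
        raise ValueError(
            f"dataset {dataset.dataset_id} contains no marker gene; "
            f"expected any of: {', '.join(markers.genes)}"
        )
    sub = dataset.values.loc[present]
    if statistic == "mean":
        vals = sub.mean(axis=0, skipna=True)
    else:
        vals = sub.median(axis=0, skipna=True)
    coverage = sub.notna().sum(axis=0)
    keep = coverage > 0
    return IndexVector(
        dataset_id=dataset.dataset_id,
        statistic=statistic,
        values=vals[keep],
        coverage=coverage[keep],
    )


@dataclass(frozen=True)
class IndexAgreement:
    """Pairwise consistency of two pseudo-proliferation indexes."""

    r: float
    n_shared: int
    excluded: bool
    reason: str | None = None


def index_consistency(
    index_a: IndexVector | pd.Series,
    index_b: IndexVector | pd.Series,
    min_shared: int = 10,
) -> IndexAgreement:
    """Pearson correlation of two indexes on their shared cell lines.

    Pairs sharing fewer than ``min_shared`` cell lines are excluded (the
    result carries the reason instead of a correlation).  A zero-variance
    index is an error.
    """
    a = index_a.values if isinstance(index_a, IndexVector) else index_a
    b = index_b.values if isinstance(index_b, IndexVector) else index_b
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < min_shared:
        return IndexAgreement(
            r=float("nan"),
            n_shared=n,
            excluded=True,
            reason=f"only {n} shared cell lines (< {min_shared})",
        )
    av = a.loc[shared].to_numpy(float)
    bv = b.loc[shared].to_numpy(float)
    if np.nanstd(av) == 0 or np.nanstd(bv) == 0:
        raise ValueError("zero-variance index")
    r, n_used = masked_pearson(av[None, :], bv)
    return IndexAgreement(r=float(r[0]), n_shared=int(n_used[0]), excluded=False)
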