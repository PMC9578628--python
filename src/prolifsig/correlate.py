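"""Per-gene correlation to a reference vector, cross-dataset aggregation,
and randomized-index FDR thresholds.

For each dataset, missing values are replaced by the dataset-wide 1%
quantile of observed values (dropout concentrates at low abundance, so a
low constant is the conservative fill), every gene quantified in at least
``min_n`` cell lines is correlated (Pearson) with the reference vector
— pseudo-proliferation index or measured growth rates — and per-gene
correlations are averaged across the datasets where they could be
computed.  The null distribution of the |mean r| statistic is obtained by
permuting each dataset's index across its cell lines and re-running the
whole pipeline; its upper quantiles give empirical FDR thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, MarkerSet, masked_pearson
from .index import IndexVector, compute_index


def impute_low(dataset: ExpressionDataset, quantile: float = 0.01) -> ExpressionDataset:
    """Replace every missing value with one dataset-wide low quantile.

    The replacement is a single scalar: the ``quantile`` order statistic
    (linear interpolation convention) of all observed values in the
    dataset.  ``quantile=0`` substitutes the observed minimum.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    arr = dataset.values.to_numpy(float)
    if not np.isfinite(arr).any():
        raise ValueError(f"dataset {dataset.dataset_id} is fully missing")
    fill = float(np.nanquantile(arr, quantile))
    filled = dataset.values.fillna(fill)
    return dataset.with_values(filled, imputed_quantile=quantile, impute_value=fill)


def gene_correlations(
    dataset: ExpressionDataset,
    reference: IndexVector | pd.Series,
    min_n: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of every gene to the reference vector.

    Computed on pairwise-complete shared cell lines.  The returned frame
    (indexed by gene) has columns ``r``, ``n`` and ``status``; ``r`` is
    ``NaN`` with status ``low_coverage`` for genes observed in fewer than
    ``min_n`` shared cell lines and ``zero_variance`` where a correlation
    is undefined — deliberately *not* recorded as 0.
    """
    ref = reference.values if isinstance(reference, IndexVector) else reference
    shared = dataset.cell_lines.intersection(ref.index)
    if len(shared) == 0:
        raise ValueError(
            f"dataset {dataset.dataset_id} and reference share no cell lines"
        )
    x = dataset.values[shared].to_numpy(float)
    y = ref.loc[shared].to_numpy(float)
    r, n = masked_pearson(x, y)
    status = np.where(
        n < min_n, "low_coverage", np.where(np.isnan(r), "zero_variance", "ok")
    )
    r = np.where(status == "ok", r, np.nan)
    return pd.DataFrame(
        {"r": r, "n": n.astype(int), "status": status}, index=dataset.genes
    )


def aggregate_correlations(
    tables: Mapping[str, pd.DataFrame], min_datasets: int = 2
) -> pd.DataFrame:
    """Unweighted mean of per-dataset correlations.

    ``tables`` maps dataset id -> output of :func:`gene_correlations`.
    Genes with a computed correlation in fewer than ``min_datasets``
    datasets are dropped.  Note that the mean is signed: correlations of
    opposite sign cancel (r = 0.8 and -0.8 average to 0).

    Columns: one ``r_<dataset>``/``n_<dataset>`` pair per dataset,
    ``mean_r``, ``n_datasets`` and ``abs_mean_r``.
    """
    if not tables:
        raise ValueError("no correlation tables to aggregate")
    pieces = []
    for ds_id in sorted(tables):
        t = tables[ds_id]
        pieces.append(
            t[["r", "n"]].rename(columns={"r": f"r_{ds_id}", "n": f"n_{ds_id}"})
        )
    wide = pd.concat(pieces, axis=1, join="outer")
    r_cols = [c for c in wide.columns if c.startswith("r_")]
    r_mat = wide[r_cols]
    n_datasets = r_mat.notna().sum(axis=1)
    wide["mean_r"] = r_mat.mean(axis=1)
    wide["n_datasets"] = n_datasets.astype(int)
    wide["abs_mean_r"] = wide["mean_r"].abs()
    out = wide[n_datasets >= min_datasets].sort_index()
    return out


@dataclass(frozen=True)
class NullDistribution:
    """Pooled |mean r| values under randomized pseudo-proliferation index."""

    values: np.ndarray
    iterations: int
    seed: int

    def __len__(self) -> int:
        return len(self.values)


def randomized_null(
    datasets: Sequence[ExpressionDataset],
    markers: MarkerSet,
    iterations: int = 50,
    seed: int | None = None,
    statistic: str = "mean",
    impute_quantile: float = 0.01,
    min_n: int = 10,
    min_datasets: int = 2,
    exclude_markers: bool = True,
    shuffle: bool = True,
) -> NullDistribution:
    """Null |mean r| distribution from randomized index iterations.

    Per iteration, each dataset's pseudo-proliferation index is permuted
    independently across its cell lines (one permutation per dataset,
    shared by all genes), the per-gene correlation and cross-dataset
    aggregation pipeline is re-run, and the resulting absolute mean
    correlations are pooled over iterations.  Marker genes are excluded
    (they define the index).  ``shuffle=False`` keeps the identity
    permutation — a diagnostic mode in which the pooled values equal the
    observed statistics.
    """
    if seed is None:
        raise ValueError("randomized_null requires an explicit seed")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)

    prepared = []
    for ds in datasets:
        idx = compute_index(ds, markers, statistic=statistic)
        imputed = impute_low(ds, impute_quantile)
        genes = [g for g in imputed.genes if not (exclude_markers and g in markers)]
        shared = imputed.cell_lines.intersection(idx.values.index)
        x = imputed.values.loc[genes, shared].to_numpy(float)
        y = idx.values.loc[shared].to_numpy(float)
        prepared.append((np.asarray(genes), x, y))

    pooled = []
    for _ in range(iterations):
        tables = {}
        for k, (genes, x, y) in enumerate(prepared):
            yp = rng.permutation(y) if shuffle else y
            r, n = masked_pearson(x, yp)
            ok = (n >= min_n) & ~np.isnan(r)
            tables[f"d{k}"] = pd.DataFrame(
                {"r": np.where(ok, r, np.nan), "n": n}, index=genes
            )
        agg = aggregate_correlations(tables, min_datasets=min_datasets)
        pooled.append(agg["abs_mean_r"].to_numpy())
    values = np.concatenate(pooled) if pooled else np.array([])
    return NullDistribution(values=values, iterations=iterations, seed=seed)


def fdr_threshold(
    null: NullDistribution | np.ndarray,
    target_fdr: float = 0.001,
    mode: str = "quantile",
    observed: np.ndarray | None = None,
) -> float:
    """|mean r| threshold for a target false-discovery rate.

    ``mode="quantile"`` (default) returns the ``1 - target_fdr`` quantile
    of the pooled null (linear interpolation between order statistics).
    ``mode="plugin"`` instead returns the smallest observed value ``t``
    whose plug-in estimate ``FDR(t) = mean null count >= t per iteration /
    observed count >= t`` stays at or below the target; it requires the
    observed |mean r| values and returns ``inf`` when no threshold
    attains the target.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must lie in (0, 1)")
    if isinstance(null, NullDistribution):
        null_values, iterations = null.values, null.iterations
    else:
        null_values, iterations = np.asarray(null, dtype=float), 1
    if null_values.size == 0:
        raise ValueError("empty null distribution")

    if mode == "quantile":
        return float(np.quantile(null_values, 1.0 - target_fdr))
    if mode != "plugin":
        raise ValueError("mode must be 'quantile' or 'plugin'")
    if observed is None:
        raise ValueError("plugin mode requires the observed |mean r| values")
    obs = np.sort(np.asarray(observed, dtype=float))
    null_sorted = np.sort(null_values)
    candidates = np.unique(obs)
    for t in candidates:
        n_obs = obs.size - np.searchsorted(obs, t, side="left")
        n_null = null_sorted.size - np.searchsorted(null_sorted, t, side="left")
        if n_obs == 0:
            break
        if (n_null / iterations) / n_obs <= target_fdr:
            return float(t)
    return float("inf")


def correlation_analysis(
    datasets: Sequence[ExpressionDataset],
    markers: MarkerSet,
    statistic: str = "mean",
    impute_quantile: float = 0.01,
    min_n: int = 10,
    min_datasets: int = 2,
) -> tuple[pd.DataFrame, dict[str, IndexVector]]:
    """Observed cross-dataset correlation profiles for one omics layer.

    For each dataset: compute the pseudo-proliferation index on the
    (normalized, pre-imputation) matrix, impute missing values at the low
    quantile, and correlate every gene with the index; then aggregate
    across datasets.  Returns the profile table and the per-dataset index
    vectors.
    """
    tables = {}
    indexes = {}
    for ds in datasets:
        idx = compute_index(ds, markers, statistic=statistic)
        imputed = impute_low(ds, impute_quantile)
        tables[ds.dataset_id] = gene_correlations(imputed, idx, min_n=min_n)
        indexes[ds.dataset_id] = idx
    profiles = aggregate_correlations(tables, min_datasets=min_datasets)
    return profiles, indexes
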