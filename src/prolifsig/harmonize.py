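"""Cross-dataset preprocessing: variant collapsing, accession mapping,
missingness filters, probeset collapsing and per-sample normalization.

Proteomics search engines group peptides into protein groups
independently per dataset, so the same protein can surface under
different accession variants.  Before cross-dataset statistics these
variants are averaged into one row per gene, conflicting mappings are
resolved deterministically, sparsely observed samples/genes are removed,
and every sample is centred (median subtraction) or variance-stabilized.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

MAPPING_COLUMNS = ("dataset_id", "native_accessions", "homogenized_id")

_VARIANT_SUFFIX = re.compile(r"-\d+$")


@dataclass(frozen=True)
class FilterRecord:
    """Log record returned by :func:`filter_missingness`."""

    n_samples_removed: int
    n_genes_removed: int
    samples_removed: tuple[str, ...]
    genes_removed: tuple[str, ...]


def collapse_variants(
    dataset: ExpressionDataset, groups: pd.Series | None = None
) -> ExpressionDataset:
    """Average accession variants into one row per gene.

    ``groups`` maps variant id -> gene id; when absent, variants are
    derived from the ``<gene>-<digits>`` isoform suffix convention.  Each
    collapsed value is the mean over the variants observed in that sample;
    a sample where all variants are missing stays missing.  Idempotent.
    """
    if groups is None:
        groups = pd.Series(
            {g: _VARIANT_SUFFIX.sub("", g) for g in dataset.genes}
        )
    target = dataset.genes.to_series().map(groups).fillna(
        dataset.genes.to_series()
    )
    collapsed = dataset.values.groupby(target.to_numpy()).mean()
    collapsed = collapsed.sort_index()
    return dataset.with_values(collapsed, variants_collapsed=True)


def resolve_mapping(
    mapping: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve a many-to-many accession mapping to one id per accession.

    When a (dataset, native accession) pair is claimed by several
    homogenized ids, the winner is chosen by, in order: (1) the id
    matched in the highest number of datasets, (2) the id with the fewest
    "combined" accessions (total native accessions mapped to it), and
    (3) lexicographically smallest id — a deterministic final tie-break.

    Returns ``(resolved, conflicts)``.  ``resolved`` has one row per
    (dataset, homogenized id) with natives semicolon-joined; ``conflicts``
    reports every contested accession and the id chosen for it.  With
    ``strict=True`` conflicts raise instead.
    """
    missing = set(MAPPING_COLUMNS) - set(mapping.columns)
    if missing:
        raise ValueError(f"mapping table lacks columns: {sorted(missing)}")

    long = mapping.assign(
        native=mapping["native_accessions"].str.split(";")
    ).explode("native")
    long = long[["dataset_id", "native", "homogenized_id"]].drop_duplicates()

    # candidate scores
    n_datasets = long.groupby("homogenized_id")["dataset_id"].nunique()
    n_combined = long.groupby("homogenized_id")["native"].count()

    conflicts = []
    keep = []
    for (ds, native), grp in long.groupby(["dataset_id", "native"], sort=True):
        cands = sorted(grp["homogenized_id"].unique())
        if len(cands) == 1:
            keep.append((ds, native, cands[0]))
            continue
        ranked = sorted(
            cands, key=lambda h: (-int(n_datasets[h]), int(n_combined[h]), h)
        )
        winner = ranked[0]
        conflicts.append((ds, native, ";".join(cands), winner))
        keep.append((ds, native, winner))

    conflicts_df = pd.DataFrame(
        conflicts, columns=["dataset_id", "native", "candidates", "chosen"]
    )
    if strict and len(conflicts_df):
        raise ValueError(
            f"{len(conflicts_df)} contested accession mappings; "
            "run with strict=False to resolve them by the documented rule"
        )
    resolved_long = pd.DataFrame(
        keep, columns=["dataset_id", "native", "homogenized_id"]
    )
    resolved = (
        resolved_long.groupby(["dataset_id", "homogenized_id"])["native"]
        .apply(lambda s: ";".join(sorted(s)))
        .reset_index()
        .rename(columns={"native": "native_accessions"})
    )[list(MAPPING_COLUMNS)]
    return resolved, conflicts_df


def apply_mapping(
    dataset: ExpressionDataset, mapping: pd.DataFrame
) -> ExpressionDataset:
    """Rename rows to homogenized ids, averaging rows that merge.

    Rows mapped to the same homogenized id within the dataset keep their
    per-sample mean over observed values.  Rows absent from the mapping
    keep their native id.
    """
    sub = mapping[mapping["dataset_id"] == dataset.dataset_id]
    lookup: dict[str, str] = {}
    for _, row in sub.iterrows():
        for native in str(row["native_accessions"]).split(";"):
            lookup[native] = row["homogenized_id"]
    target = dataset.genes.to_series().map(lookup).fillna(dataset.genes.to_series())
    merged = dataset.values.groupby(target.to_numpy()).mean().sort_index()
    return dataset.with_values(merged, mapping_applied=True)


def filter_missingness(
    dataset: ExpressionDataset,
    max_gene_missing: float = 0.5,
    max_sample_missing: float = 0.7,
    samples_first: bool = True,
) -> tuple[ExpressionDataset, FilterRecord]:
    """Drop sparsely observed samples and genes.

    Comparisons are strictly greater-than: a sample is removed when more
    than 70% of its values are missing, a gene when more than 50% are
    (after sample removal, by default).  A gene missing in exactly half
    of the samples is kept.
    """
    values = dataset.values

    def _filter_samples(v: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        frac = v.isna().mean(axis=0)
        bad = frac.index[frac > max_sample_missing].tolist()
        return v.drop(columns=bad), bad

    def _filter_genes(v: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        frac = v.isna().mean(axis=1)
        bad = frac.index[frac > max_gene_missing].tolist()
        return v.drop(index=bad), bad

    if samples_first:
        values, bad_samples = _filter_samples(values)
        values, bad_genes = _filter_genes(values)
    else:
        values, bad_genes = _filter_genes(values)
        values, bad_samples = _filter_samples(values)

    if values.size == 0:
        warnings.warn(
            f"{dataset.dataset_id}: missingness filter removed everything",
            stacklevel=2,
        )
    record = FilterRecord(
        n_samples_removed=len(bad_samples),
        n_genes_removed=len(bad_genes),
        samples_removed=tuple(bad_samples),
        genes_removed=tuple(bad_genes),
    )
    return dataset.with_values(values, missingness_filtered=True), record


NORMALIZATION_METHODS = ("median_subtract", "log2_then_median", "vsn_approx")


def normalize(
    dataset: ExpressionDataset, method: str = "median_subtract"
) -> ExpressionDataset:
    """Per-sample normalization.

    ``median_subtract``
        Subtract each sample's median over observed values (idempotent).
    ``log2_then_median``
        log2-transform strictly positive intensities, then median-centre.
    ``vsn_approx``
        Inverse-hyperbolic-sine transform followed by per-sample median
        centring.  This is an approximation of variance-stabilizing
        normalization: arcsinh is linear near zero and logarithmic for
        large intensities (arcsinh(x) ~ ln(2x)), so differences between
        well-measured values converge to log-scale differences.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"method must be one of {NORMALIZATION_METHODS}")
    values = dataset.values
    if values.notna().sum(axis=0).eq(0).any():
        empty = values.columns[values.notna().sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with no observed values: {empty}")

    if method == "log2_then_median":
        if (values <= 0).any().any():
            raise ValueError("log2_then_median requires strictly positive values")
        values = np.log2(values)
    elif method == "vsn_approx":
        values = np.arcsinh(values)
    centred = values - values.median(axis=0, skipna=True)
    return dataset.with_values(centred, normalization=method)


def collapse_probesets(
    dataset: ExpressionDataset, probe_to_gene: pd.DataFrame
) -> ExpressionDataset:
    """Collapse probesets to genes.

    Probesets mapping to multiple genes are excluded first; for each gene
    with several remaining probesets, the one with the highest mean
    observed signal across all cell lines represents the gene.

    ``probe_to_gene`` needs columns ``probe`` and ``gene``.
    """
    for col in ("probe", "gene"):
        if col not in probe_to_gene.columns:
            raise ValueError("probe_to_gene requires columns 'probe' and 'gene'")
    pairs = probe_to_gene[["probe", "gene"]].drop_duplicates()
    multi = pairs.groupby("probe")["gene"].nunique()
    ambiguous = set(multi.index[multi > 1])
    pairs = pairs[~pairs["probe"].isin(ambiguous)]
    pairs = pairs[pairs["probe"].isin(dataset.genes)]

    mean_signal = dataset.values.mean(axis=1, skipna=True)
    pairs = pairs.assign(signal=pairs["probe"].map(mean_signal))
    # deterministic winner: highest mean signal, probe id breaks exact ties
    pairs = pairs.sort_values(
        ["gene", "signal", "probe"], ascending=[True, False, True]
    )
    winners = pairs.drop_duplicates("gene", keep="first")
    out = dataset.values.loc[winners["probe"]]
    out.index = winners["gene"].to_numpy()
    return dataset.with_values(out.sort_index(), probesets_collapsed=True)
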