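"""Core data containers shared across the pipeline.

The central object is :class:`ExpressionDataset`, a genes x cell-lines
matrix of relative quantities (log-like scale after normalization) with
``NaN`` marking missing values.  A :class:`MarkerSet` is a tiered list of
proliferation marker genes used to compute the pseudo-proliferation index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LAYERS = ("protein", "transcript")

#: Marker tiers, from the smallest to the largest nested set.
TIER_ORDER = ("literature", "cycling", "subunit")

# Proliferation markers reported in the pathology/cell-biology literature:
# PCNA, the MCM2-7 helicase complex, PLK1 and MKI67.
LITERATURE_MARKERS = (
    "PCNA", "MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7", "PLK1", "MKI67",
)

# Genes known to cycle at transcript level across the cell-division cycle.
CYCLING_MARKERS = (
    "FEN1", "RRM1", "RRM2", "CDK1", "RPA2", "RFC4", "RFC2", "PRIM2",
)

# Non-cycling subunits of complexes formed with the cycling genes above
# (DNA polymerase alpha, replication factor C, RPA, cohesin).
SUBUNIT_MARKERS = (
    "POLA1", "RFC3", "RPA1", "RPA3", "RFC5", "SMC3", "STAG2", "SMC1A",
)


@dataclass
class ExpressionDataset:
    """One panel's relative-quantification matrix.

    Parameters
    ----------
    dataset_id:
        Short identifier for the panel (e.g. ``"prot1"``).
    layer:
        ``"protein"`` or ``"transcript"``.
    values:
        DataFrame indexed by gene/protein-group id, columns are cell-line
        ids.  ``NaN`` encodes a missing value.
    meta:
        Free-form provenance record (normalization mode, filters applied).
    """

    dataset_id: str
    layer: str
    values: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in {self.dataset_id}: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell-line ids in {self.dataset_id}: {dups[:5]}")

    # -- convenience ------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_lines(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        """Overall fraction of missing cells in the matrix."""
        if self.values.size == 0:
            return 0.0
        return float(self.values.isna().to_numpy().mean())

    def with_values(self, values: pd.DataFrame, **meta) -> "ExpressionDataset":
        """Return a copy carrying ``values`` and updated metadata."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, values=values, meta=new_meta)

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column gene id, empty cell = missing."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(
        cls, path: str | Path, dataset_id: str, layer: str
    ) -> "ExpressionDataset":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        return cls(dataset_id=dataset_id, layer=layer, values=values)


@dataclass(frozen=True)
class MarkerSet:
    """Tiered proliferation-marker gene list.

    Tiers are nested: ``literature`` < ``literature+cycling`` < the full
    set including complex subunits.  The default set holds the 25 curated
    markers (the MCM2-7 complex, CDK1, PCNA, PLK1, RPA2, RRM1, RRM2, RFC4,
    RFC2, FEN1, MKI67, PRIM2, POLA1, RPA1, RPA3, RFC5, RFC3, SMC1A, SMC3
    and STAG2).
    """

    tiers: Mapping[str, str]  # gene id -> tier name

    def __post_init__(self) -> None:
        bad = set(self.tiers.values()) - set(TIER_ORDER)
        if bad:
            raise ValueError(f"unknown marker tiers: {sorted(bad)}")

    @classmethod
    def default(cls) -> "MarkerSet":
        tiers: dict[str, str] = {}
        for g in LITERATURE_MARKERS:
            tiers[g] = "literature"
        for g in CYCLING_MARKERS:
            tiers[g] = "cycling"
        for g in SUBUNIT_MARKERS:
            tiers[g] = "subunit"
        return cls(tiers=tiers)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.tiers))

    def __len__(self) -> int:
        return len(self.tiers)

    def __contains__(self, gene: str) -> bool:
        return gene in self.tiers

    def tier_subset(self, upto: str) -> "MarkerSet":
        """Nested subset up to and including tier ``upto``.

        ``upto="literature"`` gives the literature markers only;
        ``upto="cycling"`` adds the cycling genes; ``upto="subunit"``
        is the full set.
        """
        if upto not in TIER_ORDER:
            raise ValueError(f"upto must be one of {TIER_ORDER}")
        keep = TIER_ORDER[: TIER_ORDER.index(upto) + 1]
        return MarkerSet(tiers={g: t for g, t in self.tiers.items() if t in keep})

    def genes_in_tier(self, tier: str) -> tuple[str, ...]:
        return tuple(sorted(g for g, t in self.tiers.items() if t == tier))

    # -- GMT I/O ----------------------------------------------------------

    def to_gmt(self, path: str | Path) -> None:
        """One GMT line per tier, named ``markers_<tier>``."""
        with open(path, "w") as fh:
            for tier in TIER_ORDER:
                genes = self.genes_in_tier(tier)
                if genes:
                    fh.write("\t".join([f"markers_{tier}", tier, *genes]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "MarkerSet":
        tiers: dict[str, str] = {}
        for name, _desc, genes in read_gmt(path):
            tier = name.removeprefix("markers_")
            for g in genes:
                tiers[g] = tier
        return cls(tiers=tiers)


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into ``(name, description, genes)`` tuples."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append((parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def write_gmt(path: str | Path, sets: Iterable[tuple[str, str, Iterable[str]]]) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_doubling_times(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``cell_line<TAB>doubling_time_hours``."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("expected two columns: cell_line, doubling_time_hours")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    s.name = "doubling_time_hours"
    return s


def write_doubling_times(path: str | Path, doubling_times: pd.Series) -> None:
    out = doubling_times.rename("doubling_time_hours").rename_axis("cell_line")
    out.to_frame().to_csv(path, sep="\t")


def masked_pearson(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlation of ``x`` (m x n) against ``y`` (n,).

    Handles ``NaN`` in both arguments by pairwise-complete observations.
    Returns ``(r, n)`` where ``n`` is the number of complete pairs per
    row; rows with zero variance on either side get ``NaN``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    mask = np.isfinite(x) & np.isfinite(y)[None, :]
    n = mask.sum(axis=1)
    xz = np.where(mask, x, 0.0)
    yz = np.where(mask, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xz.sum(axis=1)
        sy = yz.sum(axis=1)
        sxx = (xz * xz).sum(axis=1)
        syy = (yz * yz).sum(axis=1)
        sxy = (xz * yz).sum(axis=1)
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        denom = np.sqrt(varx * vary)
        r = cov / denom
    r = np.where((n >= 2) & (denom > 0), r, np.nan)
    # guard against round-off pushing |r| over 1
    return np.clip(r, -1.0, 1.0), n
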