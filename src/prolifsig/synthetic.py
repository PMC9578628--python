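"""Synthetic multi-panel proteome/transcriptome studies with known truth.

The generator emulates the structure of public cell-line panels: several
partially overlapping cell-line sets, per-line doubling times, a planted
set of genes linearly coupled to growth rate (growth rate = ln(2)/doubling
time), a protein layer whose coupling is attenuated relative to the
transcript layer, intensity-dependent (missing-not-at-random) dropout, and
fragmented accession variants to exercise harmonization.  Every quantity
needed to score downstream inference (planted genes, slopes, growth rates)
is returned as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, MarkerSet, write_doubling_times, write_gmt

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters of the generator.

    Defaults describe a study of four proteomics and three transcriptomics
    panels over a shared pool of 60 cell lines, 5,000 genes of which 4%
    (200) are truly coupled to growth rate with a per-dataset transcript
    correlation of about 0.6, protein coupling attenuated by 0.8, and 25%
    intensity-dependent missingness.
    """

    n_datasets_protein: int = 4
    n_datasets_transcript: int = 3
    n_cell_lines: int = 60
    n_genes: int = 5000
    fraction_planted: float = 0.04
    noise_sd: float = 0.5
    planted_r: float = 0.6  # target per-dataset Pearson r of planted genes (transcript layer)
    protein_attenuation: float = 0.8
    missing_rate: float = 0.25
    missing_intensity_bias: float = 2.0  # logistic slope per SD of signal; 0 = MCAR
    id_fragmentation_rate: float = 0.1
    panel_overlap_fraction: float = 0.8
    doubling_time_median: float = 30.0  # hours
    doubling_time_log_sd: float = 0.4
    intercept_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_datasets_protein", "n_datasets_transcript"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_datasets_protein + self.n_datasets_transcript < 1:
            raise ValueError("at least one dataset is required")
        for name in (
            "fraction_planted",
            "missing_rate",
            "protein_attenuation",
            "id_fragmentation_rate",
            "panel_overlap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.planted_r < 1.0:
            raise ValueError("planted_r must lie in (0, 1)")
        if self.noise_sd < 0 or self.doubling_time_median <= 0:
            raise ValueError("noise_sd must be >= 0 and doubling_time_median > 0")

    @property
    def dataset_ids(self) -> tuple[str, ...]:
        prot = tuple(f"prot{i + 1}" for i in range(self.n_datasets_protein))
        rna = tuple(f"rna{i + 1}" for i in range(self.n_datasets_transcript))
        return prot + rna


@dataclass(frozen=True)
class PanelSimulation:
    """Global cell-line pool and each dataset's subset of it."""

    cell_line_ids: tuple[str, ...]
    doubling_times: pd.Series  # hours, indexed by cell line
    growth_rates: pd.Series  # 1/hours, = ln(2)/doubling time
    panel_overlap: Mapping[str, tuple[str, ...]]  # dataset id -> cell lines


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth for parameter-recovery tests."""

    planted_genes: frozenset[str]
    effect_slopes: pd.Series  # per planted gene, transcript-layer slope
    null_genes: frozenset[str]
    marker_genes: frozenset[str]
    marker_slopes: pd.Series

    def __post_init__(self) -> None:
        if (
            self.planted_genes & self.null_genes
            or self.planted_genes & self.marker_genes
            or self.null_genes & self.marker_genes
        ):
            raise ValueError("planted, null and marker gene sets must be disjoint")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.planted_genes | self.null_genes | self.marker_genes))


@dataclass(frozen=True)
class SimulationResult:
    panel: PanelSimulation
    truth: TruthLabels
    datasets: tuple[ExpressionDataset, ...]
    markers: MarkerSet

    def layer(self, layer: str) -> tuple[ExpressionDataset, ...]:
        return tuple(d for d in self.datasets if d.layer == layer)


def growth_rates_from_doubling(doubling_times: pd.Series) -> pd.Series:
    if (doubling_times <= 0).any():
        raise ValueError("doubling times must be positive")
    g = LN2 / doubling_times
    g.name = "growth_rate"
    return g


def simulate_panel(config: SimulationConfig) -> PanelSimulation:
    """Draw doubling times and per-dataset cell-line subsets.

    Doubling times are log-normal with the configured median and log-sd
    (defaults span a 17-80 h range typical of cultured cancer cell lines);
    growth rates follow the ln(2)/T rule exactly.
    """
    rng = _rng(config.seed, "panel")
    ids = tuple(f"CL{i + 1:03d}" for i in range(config.n_cell_lines))
    log_t = rng.normal(
        math.log(config.doubling_time_median),
        config.doubling_time_log_sd,
        size=config.n_cell_lines,
    )
    doubling = pd.Series(np.exp(log_t), index=list(ids), name="doubling_time_hours")
    growth = growth_rates_from_doubling(doubling)

    k = max(2, int(round(config.panel_overlap_fraction * config.n_cell_lines)))
    overlap: dict[str, tuple[str, ...]] = {}
    for ds_id in config.dataset_ids:
        chosen = rng.choice(config.n_cell_lines, size=k, replace=False)
        overlap[ds_id] = tuple(ids[i] for i in sorted(chosen))

    panel = PanelSimulation(
        cell_line_ids=ids,
        doubling_times=doubling,
        growth_rates=growth,
        panel_overlap=overlap,
    )
    _check_overlap(panel)
    return panel


def _check_overlap(panel: PanelSimulation, min_shared: int = 10) -> None:
    ids = list(panel.panel_overlap)
    if len(ids) < 2:
        return
    best = max(
        len(set(panel.panel_overlap[a]) & set(panel.panel_overlap[b]))
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    )
    if best < min_shared:
        raise ValueError(
            f"no dataset pair shares >= {min_shared} cell lines (best: {best}); "
            "increase panel_overlap_fraction or n_cell_lines"
        )


def simulate_truth(
    config: SimulationConfig, panel: PanelSimulation, markers: MarkerSet | None = None
) -> TruthLabels:
    """Assign planted/null/marker labels and effect slopes.

    Slopes are calibrated against the panel's empirical growth-rate spread
    so that a planted gene's expected per-dataset Pearson correlation (in
    the transcript layer, before dropout) equals ``config.planted_r``:
    ``slope = noise_sd * r / sqrt(1 - r^2) / sd(growth rate)``.  Marker
    genes get the same coupling; the protein layer multiplies slopes by
    ``protein_attenuation``.
    """
    rng = _rng(config.seed, "truth")
    markers = markers or MarkerSet.default()
    marker_genes = list(markers.genes)
    if len(marker_genes) >= config.n_genes:
        raise ValueError("n_genes must exceed the marker-set size")

    n_other = config.n_genes - len(marker_genes)
    other = [f"G{i + 1:05d}" for i in range(n_other)]
    n_planted = int(round(config.fraction_planted * config.n_genes))
    n_planted = min(n_planted, n_other)
    planted_idx = rng.choice(n_other, size=n_planted, replace=False)
    planted = sorted(other[i] for i in planted_idx)
    null = sorted(set(other) - set(planted))

    sd_g = float(panel.growth_rates.std(ddof=0))
    if sd_g <= 0:
        raise ValueError("growth rates have zero spread")
    r = config.planted_r
    base_slope = config.noise_sd * r / math.sqrt(1.0 - r * r) / sd_g
    if config.noise_sd == 0:
        base_slope = 1.0 / sd_g  # noiseless: any non-zero slope gives |r| = 1

    slopes = pd.Series(base_slope, index=planted, name="slope", dtype=float)
    marker_slopes = pd.Series(base_slope, index=marker_genes, name="slope", dtype=float)
    return TruthLabels(
        planted_genes=frozenset(planted),
        effect_slopes=slopes,
        null_genes=frozenset(null),
        marker_genes=frozenset(marker_genes),
        marker_slopes=marker_slopes,
    )


def simulate_dataset(
    panel: PanelSimulation,
    truth: TruthLabels,
    layer: str,
    config: SimulationConfig,
    dataset_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionDataset:
    """Simulate one panel's expression matrix.

    A gene's expected value in cell line ``c`` is
    ``intercept_g + slope_g * growth_rate[c]`` (slope 0 for null genes,
    attenuated in the protein layer) plus Gaussian noise.  Missingness is
    missing-not-at-random: the dropout probability follows a logistic
    curve decreasing with signal intensity, calibrated so the overall
    missing fraction matches ``config.missing_rate``.
    """
    if layer not in ("protein", "transcript"):
        raise ValueError(f"invalid layer {layer!r}")
    if dataset_id is None:
        dataset_id = f"{layer}-sim"
    if rng is None:
        rng = _rng(config.seed, f"dataset:{dataset_id}")

    cells = list(panel.panel_overlap.get(dataset_id, panel.cell_line_ids))
    if not cells:
        raise ValueError(f"dataset {dataset_id} has an empty cell-line panel")
    genes = list(truth.all_genes)
    g = panel.growth_rates.loc[cells].to_numpy()

    slopes = pd.Series(0.0, index=genes, dtype=float)
    slopes.loc[truth.effect_slopes.index] = truth.effect_slopes
    slopes.loc[truth.marker_slopes.index] = truth.marker_slopes
    if layer == "protein":
        slopes = slopes * config.protein_attenuation

    intercept = rng.normal(0.0, config.intercept_sd, size=len(genes))
    expected = intercept[:, None] + slopes.to_numpy()[:, None] * g[None, :]
    noise = rng.normal(0.0, config.noise_sd, size=expected.shape)
    values = expected + noise

    if config.missing_rate > 0:
        p_miss = _mnar_probabilities(
            values, config.missing_rate, config.missing_intensity_bias
        )
        drop = rng.random(values.shape) < p_miss
        values = np.where(drop, np.nan, values)

    frame = pd.DataFrame(values, index=genes, columns=cells)
    return ExpressionDataset(
        dataset_id=dataset_id, layer=layer, values=frame, meta={"simulated": True}
    )


def _mnar_probabilities(
    values: np.ndarray, missing_rate: float, intensity_bias: float
) -> np.ndarray:
    """Per-cell dropout probabilities with logistic intensity dependence.

    ``p(v) = sigmoid(b * (v0 - v) / sd)``; the midpoint ``v0`` is solved
    by bisection so the mean probability equals ``missing_rate``.  With
    ``intensity_bias == 0`` this reduces to uniform (MCAR) dropout.
    """
    if intensity_bias == 0:
        return np.full(values.shape, missing_rate)
    sd = float(np.std(values))
    if sd == 0:
        return np.full(values.shape, missing_rate)
    z = values / sd
    lo, hi = z.min() - 20.0 / intensity_bias, z.max() + 20.0 / intensity_bias
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mean_p = _sigmoid(intensity_bias * (mid - z)).mean()
        if mean_p < missing_rate:
            lo = mid
        else:
            hi = mid
    return _sigmoid(intensity_bias * (0.5 * (lo + hi) - z))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def simulate_study(
    config: SimulationConfig, markers: MarkerSet | None = None
) -> SimulationResult:
    """Simulate the full study: panel, truth, and all datasets.

    Deterministic: the same config (including seed) reproduces the exact
    same panel, labels and matrices.
    """
    markers = markers or MarkerSet.default()
    panel = simulate_panel(config)
    truth = simulate_truth(config, panel, markers)
    datasets = []
    for ds_id in config.dataset_ids:
        layer = "protein" if ds_id.startswith("prot") else "transcript"
        rng = _rng(config.seed, f"dataset:{ds_id}")
        datasets.append(
            simulate_dataset(panel, truth, layer, config, dataset_id=ds_id, rng=rng)
        )
    return SimulationResult(
        panel=panel, truth=truth, datasets=tuple(datasets), markers=markers
    )


# ---------------------------------------------------------------------------
# accession fragmentation


def fragment_ids(
    dataset: ExpressionDataset,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Split a fraction of genes into 2-3 accession variants.

    Emulates search outputs labelling the same protein differently across
    datasets.  Variant rows are perturbed copies of the original row named
    ``<gene>-<k>``.  Returns the fragmented dataset and the ground-truth
    mapping table (columns ``dataset_id``, ``native_accessions``
    semicolon-joined, ``homogenized_id``) usable as the harmonization key.
    """
    if rng is None:
        rng = _rng(config.seed, f"fragment:{dataset.dataset_id}")
    rate = config.id_fragmentation_rate
    rows = []
    mapping_rows = []
    for gene in dataset.genes:
        row = dataset.values.loc[gene]
        if rate > 0 and rng.random() < rate:
            k = int(rng.integers(2, 4))
            variants = []
            for j in range(k):
                name = f"{gene}-{j + 1}"
                perturbed = row + rng.normal(0.0, 0.1, size=len(row))
                perturbed[row.isna()] = np.nan
                rows.append(pd.Series(perturbed, name=name))
                variants.append(name)
            mapping_rows.append(
                (dataset.dataset_id, ";".join(variants), gene)
            )
        else:
            rows.append(row)
            mapping_rows.append((dataset.dataset_id, gene, gene))
    frame = pd.DataFrame(rows)
    frame.columns = dataset.cell_lines
    mapping = pd.DataFrame(
        mapping_rows, columns=["dataset_id", "native_accessions", "homogenized_id"]
    )
    return dataset.with_values(frame, fragmented=True), mapping


# ---------------------------------------------------------------------------
# differential-expression fixture


def simulate_de_table(
    signature_genes,
    n_genes: int,
    frac_signature_down: float,
    seed: int,
    background_down: float = 0.1,
) -> pd.DataFrame:
    """Simulate a differential-expression result table.

    Signature genes are down-regulated with probability
    ``frac_signature_down``; every other gene with ``background_down``.
    Down-regulated genes get a negative log2 fold change and a small
    q-value; unregulated genes get a near-zero fold change and a q-value
    uniform on [0.1, 1] — the fixture treats significance as perfectly
    calibrated, so only truly regulated genes can reach q <= 0.05.
    Columns: ``id``, ``log2fc``, ``qvalue``.
    """
    signature_genes = sorted(_as_gene_set(signature_genes))
    if len(signature_genes) > n_genes:
        raise ValueError("n_genes smaller than the signature")
    if not 0 <= frac_signature_down <= 1 or not 0 <= background_down <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    filler = [f"D{i + 1:05d}" for i in range(n_genes - len(signature_genes))]
    ids = signature_genes + filler
    is_sig = np.array([g in set(signature_genes) for g in ids])
    p_down = np.where(is_sig, frac_signature_down, background_down)
    down = rng.random(n_genes) < p_down
    log2fc = np.where(
        down,
        -np.abs(rng.normal(1.0, 0.4, size=n_genes)),
        rng.normal(0.0, 0.3, size=n_genes),
    )
    qvalue = np.where(
        down,
        rng.beta(1.0, 20.0, size=n_genes),
        rng.uniform(0.1, 1.0, size=n_genes),
    )
    return pd.DataFrame({"id": ids, "log2fc": log2fc, "qvalue": qvalue})


def _as_gene_set(obj) -> set[str]:
    if hasattr(obj, "genes"):
        return set(obj.genes)
    return set(obj)


# ---------------------------------------------------------------------------
# persistence


def write_study(result: SimulationResult, outdir: str | Path) -> None:
    """Write a simulated study as plain-text files.

    Expression matrices as TSV, doubling times as two-column TSV, truth
    labels and the marker set as GMT.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in result.datasets:
        ds.to_tsv(outdir / f"{ds.dataset_id}.tsv")
    write_doubling_times(outdir / "doubling_times.tsv", result.panel.doubling_times)
    result.markers.to_gmt(outdir / "markers.gmt")
    write_gmt(
        outdir / "truth.gmt",
        [
            ("planted", "genes coupled to growth rate", sorted(result.truth.planted_genes)),
            ("null", "genes with zero slope", sorted(result.truth.null_genes)),
            ("markers", "index marker genes", sorted(result.truth.marker_genes)),
        ],
    )


def _rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic child generator for a named simulation stage."""
    h = np.frombuffer(label.encode(), dtype=np.uint8)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(b) for b in h))
    )
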