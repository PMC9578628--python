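"""Gold-standard benchmarking, cutoff selection and the dual-omics
proliferation signature.

Genes are ranked by decreasing absolute mean correlation to the
pseudo-proliferation index and benchmarked against curated sets of
periodically expressed / E2F-target genes; the cumulative count of gold
standards along the ranking locates a correlation cutoff per omics layer.
The final signature is the set of genes whose signed mean correlation
passes the cutoff in *both* the proteome and the transcriptome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MarkerSet, read_gmt

# Reference values derived from large public cell-line panel compendia
# (five/six proteomics and three transcriptomics panels).  They are
# packaged for annotating user data at the published operating point; a
# de-novo analysis should derive its own cutoffs with `select_cutoff`.
REFERENCE_PROTEIN_CUTOFF = 0.344
REFERENCE_TRANSCRIPT_CUTOFF = 0.567
REFERENCE_PROTEIN_FDR_THRESHOLD = 0.189  # |mean r| at 0.1% FDR, proteome
REFERENCE_TRANSCRIPT_FDR_THRESHOLD = 0.251  # |mean r| at 0.1% FDR, transcriptome


@dataclass(frozen=True)
class GoldStandardSet:
    """Curated genes expected to track proliferation (e.g. periodic genes)."""

    name: str
    genes: frozenset[str]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gold-standard set {self.name!r} is empty")

    @classmethod
    def from_gmt(cls, path: str | Path) -> tuple["GoldStandardSet", ...]:
        return tuple(
            cls(name=name, genes=frozenset(genes), note=desc)
            for name, desc, genes in read_gmt(path)
        )


@dataclass(frozen=True)
class EnrichmentCurve:
    """Cumulative gold-standard count along a ranked gene list."""

    name: str
    genes: tuple[str, ...]  # ranked, best first
    scores: np.ndarray  # ranking statistic at each rank
    cumulative: np.ndarray  # non-decreasing gold counts
    total_gold: int  # |gold ∩ ranked|

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores) or len(self.genes) != len(
            self.cumulative
        ):
            raise ValueError("curve arrays must share one length")

    @property
    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """(rank fraction, recall) — both in [0, 1]."""
        n = len(self.genes)
        x = np.arange(1, n + 1) / n
        y = self.cumulative / max(self.total_gold, 1)
        return x, y

    def auc(self) -> float:
        """Normalized area under the recall curve (1 = all gold first)."""
        x, y = self.normalized
        return float(np.trapezoid(y, x))


def enrichment_curve(
    profiles: pd.DataFrame,
    gold: GoldStandardSet,
    min_datasets: int = 3,
    exclude: MarkerSet | None = None,
) -> EnrichmentCurve:
    """Cumulative gold-standard curve over the |mean r| ranking.

    Genes quantified in fewer than ``min_datasets`` datasets and the
    index markers (which would trivially score high) are excluded before
    ranking.  Ties in |mean r| are broken by gene id for determinism.
    """
    sub = profiles[profiles["n_datasets"] >= min_datasets]
    if exclude is not None:
        sub = sub[~sub.index.isin(exclude.genes)]
    sub = sub.dropna(subset=["abs_mean_r"])
    # stable sort on a pre-sorted index breaks |mean r| ties by gene id
    order = sub.sort_index().sort_values(
        "abs_mean_r", ascending=False, kind="mergesort"
    )
    member = order.index.isin(gold.genes)
    if not member.any():
        warnings.warn(
            f"gold set {gold.name!r} has no overlap with the ranked genes",
            stacklevel=2,
        )
    return EnrichmentCurve(
        name=gold.name,
        genes=tuple(order.index),
        scores=order["abs_mean_r"].to_numpy(),
        cumulative=np.cumsum(member),
        total_gold=int(member.sum()),
    )


@dataclass(frozen=True)
class CutoffResult:
    value: float
    strategy: str
    rank: int | None = None
    note: str | None = None


def select_cutoff(
    curves,
    strategy: str = "knee",
    value: float | None = None,
    target_recall: float = 0.9,
    fallback: float | None = None,
    min_knee_gap: float | None = None,
) -> CutoffResult:
    """Choose a correlation cutoff from gold-standard curves.

    ``knee``
        On the mean normalized curve, take the rank with the largest
        vertical excess over the diagonal chord (the point farthest from
        the no-enrichment line) and return the |mean r| at that rank.
        When the maximal excess is indistinguishable from the random
        fluctuation of an unenriched curve (below ``min_knee_gap``,
        default ``max(0.05, 2.2/sqrt(total gold))``), the knee is
        undefined: the ``fallback`` value (typically the permutation FDR
        threshold) is returned with a warning, or an error is raised.
    ``target_recall``
        Smallest rank at which mean recall reaches ``target_recall``.
    ``manual``
        Echo the user-provided ``value`` (the published operating point,
        for example) with a provenance note.
    """
    if strategy == "manual":
        if value is None:
            raise ValueError("manual strategy requires a value")
        return CutoffResult(value=float(value), strategy="manual", note="user-supplied")
    if isinstance(curves, EnrichmentCurve):
        curves = [curves]
    if not curves:
        raise ValueError("no curves supplied")
    first = curves[0]
    for c in curves[1:]:
        if c.genes != first.genes:
            raise ValueError("curves must share the same ranked gene list")
    ys = []
    for c in curves:
        if c.total_gold == 0:
            raise ValueError(f"curve {c.name!r} has no gold members (flat curve)")
        ys.append(c.normalized[1])
    x = first.normalized[0]
    y = np.mean(ys, axis=0)

    if strategy == "target_recall":
        if not 0 < target_recall <= 1:
            raise ValueError("target_recall must lie in (0, 1]")
        hits = np.nonzero(y >= target_recall)[0]
        if hits.size == 0:
            raise ValueError("target recall never reached")
        k = int(hits[0])
        return CutoffResult(
            value=float(first.scores[k]), strategy="target_recall", rank=k + 1
        )
    if strategy != "knee":
        raise ValueError("strategy must be 'knee', 'target_recall' or 'manual'")

    gap = y - x  # vertical distance above the chord of the diagonal
    k = int(np.argmax(gap))
    total_gold = int(np.mean([c.total_gold for c in curves]))
    if min_knee_gap is None:
        # scale of the maximal excess of an unenriched (random-gold)
        # curve, a Kolmogorov-style sqrt(n) bound, capped for tiny sets
        min_knee_gap = min(0.5, max(0.05, 2.2 / np.sqrt(max(total_gold, 1))))
    if gap[k] < min_knee_gap:
        if fallback is not None:
            warnings.warn(
                f"knee undefined (max excess {gap[k]:.3f} < {min_knee_gap:.3f}); "
                f"falling back to {fallback:.4g}",
                stacklevel=2,
            )
            return CutoffResult(
                value=float(fallback),
                strategy="knee",
                note="knee undefined; fallback threshold used",
            )
        raise ValueError(
            f"knee undefined: maximal excess over the diagonal is {gap[k]:.3f}"
        )
    return CutoffResult(value=float(first.scores[k]), strategy="knee", rank=k + 1)


@dataclass(frozen=True)
class Signature:
    """Genes passing the correlation cutoff in both omics layers."""

    genes: tuple[str, ...]
    table: pd.DataFrame  # gene-indexed: mean_r_protein, mean_r_transcript, signature
    t_prot: float
    t_rna: float

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        table = pd.read_csv(path, sep="\t", index_col=0)
        genes = tuple(sorted(table.index[table["signature"]]))
        return cls(genes=genes, table=table, t_prot=float("nan"), t_rna=float("nan"))


def build_signature(
    protein_profiles: pd.DataFrame,
    transcript_profiles: pd.DataFrame,
    t_prot: float = REFERENCE_PROTEIN_CUTOFF,
    t_rna: float = REFERENCE_TRANSCRIPT_CUTOFF,
) -> Signature:
    """Intersect the two single-layer threshold sets.

    A gene is a signature member iff its signed mean correlation to the
    pseudo-proliferation index is >= ``t_prot`` in the proteome and
    >= ``t_rna`` in the transcriptome, with both layers quantified.
    Marker genes are eligible here — passing the cutoffs on their own
    merit, not by construction.
    """
    joined = pd.concat(
        {
            "mean_r_protein": protein_profiles["mean_r"],
            "mean_r_transcript": transcript_profiles["mean_r"],
        },
        axis=1,
        join="outer",
    )
    both = joined.dropna()
    if both.empty:
        raise ValueError(
            "no gene quantified in both layers — check that the two "
            "profile tables share a gene-id namespace"
        )
    flag = (both["mean_r_protein"] >= t_prot) & (both["mean_r_transcript"] >= t_rna)
    table = both.assign(signature=flag).sort_index()
    genes = tuple(sorted(table.index[table["signature"]]))
    return Signature(genes=genes, table=table, t_prot=float(t_prot), t_rna=float(t_rna))
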