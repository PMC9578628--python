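"""Apply a proliferation signature to external result tables.

Differential-expression tables from drug screens or tumor cohorts are
annotated with signature membership so that hits driven by a change in
cell proliferation can be separated from treatment-specific regulation.
Also provides the cumulative signature curve along a significance
ranking, a hypergeometric enrichment test for flagged hits, and a
Jaccard-based reduction of redundant GO terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .signature import EnrichmentCurve, Signature

DE_COLUMNS = ("id", "log2fc", "qvalue")


def _signature_genes(signature) -> set[str]:
    if isinstance(signature, Signature):
        return set(signature.genes)
    if hasattr(signature, "genes"):
        return set(signature.genes)
    return set(signature)


def _check_de(table: pd.DataFrame) -> None:
    missing = set(DE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"DE table lacks columns: {sorted(missing)}")
    q = table["qvalue"].to_numpy(float)
    if np.nanmin(q) < 0 or np.nanmax(q) > 1:
        raise ValueError("q-values must lie in [0, 1]")


def flag_table(table: pd.DataFrame, signature) -> pd.DataFrame:
    """Add a boolean ``signature`` column to a DE table.

    Protein-group ids may hold several semicolon-separated accessions; a
    row is flagged when at least one member is a signature gene.  Extra
    columns pass through untouched.
    """
    _check_de(table)
    genes = _signature_genes(signature)
    flags = [
        any(acc in genes for acc in str(row_id).split(";"))
        for row_id in table["id"]
    ]
    out = table.copy()
    out["signature"] = flags
    if genes and not any(flags):
        sample = sorted(genes)[:3]
        warnings.warn(
            "no DE-table row matches the signature — id namespaces may "
            f"differ (signature looks like {sample}, table ids like "
            f"{table['id'].head(3).tolist()})",
            stacklevel=2,
        )
    return out


def _direction_mask(table: pd.DataFrame, direction: str) -> pd.Series:
    if direction == "down":
        return table["log2fc"] < 0
    if direction == "up":
        return table["log2fc"] > 0
    raise ValueError("direction must be 'down' or 'up'")


def cumulative_signature_curve(
    table: pd.DataFrame, signature, direction: str = "down"
) -> EnrichmentCurve:
    """Cumulative signature count along the significance ranking.

    Rows with a fold change of the stated sign are ranked by ascending
    q-value (ties broken by id) and signature flags accumulated — the
    final value equals the number of flagged rows of that sign.
    """
    flagged = flag_table(table, signature)
    sub = flagged[_direction_mask(flagged, direction)]
    sub = sub.sort_values(["qvalue", "id"], kind="mergesort")
    member = sub["signature"].to_numpy(bool)
    return EnrichmentCurve(
        name=f"signature_{direction}",
        genes=tuple(sub["id"]),
        scores=sub["qvalue"].to_numpy(float),
        cumulative=np.cumsum(member),
        total_gold=int(member.sum()),
    )


@dataclass(frozen=True)
class EnrichmentTestResult:
    """Signature over-representation among significant hits."""

    n_universe: int
    n_signature_in_universe: int
    n_hits: int
    n_flagged_hits: int
    flagged_fraction: float  # NaN when there is no hit
    p_value: float  # hypergeometric upper tail


def signature_enrichment_test(
    table: pd.DataFrame,
    signature,
    q_cutoff: float = 0.05,
    direction: str = "down",
) -> EnrichmentTestResult:
    """Are significant hits of the stated direction enriched in signature?

    Hits are rows with ``qvalue <= q_cutoff`` and the stated fold-change
    sign; the universe is every row of the table (the genes the original
    analysis tested).  The p-value is the one-sided hypergeometric upper
    tail for drawing at least the observed number of flagged hits —
    equivalent to a one-sided Fisher exact test on the 2x2 table.
    """
    flagged = flag_table(table, signature)
    n_universe = len(flagged)
    n_sig = int(flagged["signature"].sum())
    hits = flagged[(flagged["qvalue"] <= q_cutoff) & _direction_mask(flagged, direction)]
    n_hits = len(hits)
    n_flagged = int(hits["signature"].sum())
    if n_hits == 0:
        return EnrichmentTestResult(
            n_universe=n_universe,
            n_signature_in_universe=n_sig,
            n_hits=0,
            n_flagged_hits=0,
            flagged_fraction=float("nan"),
            p_value=1.0,
        )
    p = float(hypergeom.sf(n_flagged - 1, n_universe, n_sig, n_hits))
    return EnrichmentTestResult(
        n_universe=n_universe,
        n_signature_in_universe=n_sig,
        n_hits=n_hits,
        n_flagged_hits=n_flagged,
        flagged_fraction=n_flagged / n_hits,
        p_value=min(p, 1.0),
    )


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0 by convention."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def reduce_terms(terms: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Prune redundant enriched terms by member-set similarity.

    Terms are swept in ascending q-value order (ties broken by term id);
    a term is kept iff its Jaccard index with every already-kept term is
    below ``cutoff`` — so of any similar pair, the one with the lowest
    q-value survives, and the kept set is pairwise dissimilar.
    Idempotent.

    ``terms`` needs columns ``term``, ``members`` (set, or semicolon-
    joined string) and ``qvalue``.
    """
    for col in ("term", "members", "qvalue"):
        if col not in terms.columns:
            raise ValueError("terms table requires columns term, members, qvalue")
    if terms["qvalue"].isna().any():
        bad = terms.loc[terms["qvalue"].isna(), "term"].tolist()
        raise ValueError(f"terms with missing q-values: {bad}")

    parsed = [
        set(m) if not isinstance(m, str) else set(m.split(";"))
        for m in terms["members"]
    ]
    order = terms.assign(_members=parsed).sort_values(
        ["qvalue", "term"], kind="mergesort"
    )
    kept_members: list[set] = []
    kept_rows = []
    for _, row in order.iterrows():
        if all(jaccard(row["_members"], km) < cutoff for km in kept_members):
            kept_members.append(row["_members"])
            kept_rows.append(row)
    out = pd.DataFrame(kept_rows).drop(columns="_members")
    return out.reset_index(drop=True)


def volcano_plot(
    table: pd.DataFrame,
    signature,
    q_cutoff: float = 0.05,
    ax=None,
    title: str | None = None,
):
    """Volcano plot (log2 FC vs -log10 q) with signature genes highlighted."""
    import matplotlib.pyplot as plt

    flagged = flag_table(table, signature)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    y = -np.log10(np.clip(flagged["qvalue"].to_numpy(float), 1e-300, None))
    bg = ~flagged["signature"]
    ax.scatter(flagged.loc[bg, "log2fc"], y[bg.to_numpy()], s=8, c="grey", alpha=0.5,
               label="other")
    ax.scatter(flagged.loc[~bg, "log2fc"], y[(~bg).to_numpy()], s=10, c="tab:orange",
               label="signature")
    ax.axhline(-np.log10(q_cutoff), ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 q-value")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax
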