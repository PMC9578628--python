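# Methods

## Model and assumptions

The package treats relative cell proliferation as a latent per-cell-line
covariate. Growth rate and doubling time are linked deterministically,
*g* = ln 2 / *T* (hours⁻¹), and a gene's coupling to proliferation is
modeled — for simulation and for interpretation — as linear on the
normalized (log-like) expression scale: E[xᵍᶜ] = aᵍ + bᵍ·g꜀. The
pseudo-proliferation index is the per-cell-line mean of a curated marker
set; averaging ~25 markers with independent measurement noise suppresses
per-marker noise by √25, which is why the index can correlate > 0.9 with
true growth rates even when each marker correlates only ~0.6.

The signature derivation assumes that (i) marker genes track proliferation
in every panel, (ii) per-panel correlations to the index are exchangeable
enough that their unweighted mean is a sensible cross-dataset statistic,
and (iii) permuting the index within a panel destroys exactly the
association of interest while preserving the gene-value covariance
structure — the basis of the randomized-index FDR.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_n` | 10 | cell lines required to compute a per-panel Pearson r |
| `min_datasets` | 2 | panels required for a cross-dataset mean r (3 for the proteome enrichment curves, 2 for the transcriptome, matching panel counts) |
| `impute_quantile` | 0.01 | dataset-wide quantile substituted for missing values |
| `iterations` | 50 | randomized-index iterations pooled into the null |
| `target_fdr` | 0.001 | FDR level at which the |mean r| threshold is read off |
| `max_sample_missing` / `max_gene_missing` | 0.7 / 0.5 | strictly-greater-than missingness filters; samples are filtered before genes (configurable) |
| Jaccard `cutoff` | 0.5 | similarity above which two enriched terms are redundant |

## FDR definition

"α-FDR threshold" is implemented as the (1 − α) quantile of the pooled
null |mean r| values, with linear interpolation between order statistics
(`numpy.quantile` default) — fixed and documented so thresholds are
reproducible to machine precision. A plug-in estimator
FDR(t) = (mean null count ≥ t per iteration) / (observed count ≥ t) is
available as `fdr_threshold(..., mode="plugin")`; the two differ when the
observed distribution is heavily enriched. Both are exposed because the
quantile reading matches the way thresholds are customarily reported for
this procedure, while the plug-in ratio is the textbook empirical-FDR
estimator; the quantile is the default. Within one iteration, each panel's
index is permuted independently (panels have different cell-line sets, so
a shared permutation is not even well defined across them); one
permutation per panel per iteration is shared by all genes, preserving the
gene–gene correlation structure of the null.

## Cutoff selection

The published operating point for this kind of analysis was chosen by
visual inspection of gold-standard enrichment curves, so `select_cutoff`
defaults to honesty about that: `manual` echoes a user value, and the
packaged reference constants (0.344 protein / 0.567 transcript) reproduce
the published operating point for annotation use. For de-novo runs, the
`knee` strategy takes the rank of the mean normalized curve with the
largest vertical excess over the no-enrichment diagonal and maps it back
to that rank's |mean r|. The excess of an unenriched curve fluctuates at
the Kolmogorov scale ~1/√(gold size), so a knee below
min(0.5, max(0.05, 2.2/√n_gold)) is declared undefined and the
permutation-FDR threshold is used as fallback (with a warning). Ranking
ties in |mean r| are broken by gene id; enrichment-curve rankings exclude
the index markers (they would score high by construction), whereas
`build_signature` lets markers re-enter on their own correlations.

## Index computation order

The index is computed on normalized, *pre-imputation* values: imputation
with a low constant would drag down the index of cell lines with missing
markers, whereas excluding missing markers from the per-line statistic is
unbiased under the stated MNAR mechanism. Low-quantile imputation is then
applied before per-gene correlation, where it mainly affects sparsely
observed genes. Cell lines observing no marker at all are dropped from the
index rather than imputed.

## Synthetic-data generator

The generator emulates: log-normal doubling times (median 30 h,
σ_log = 0.4, spanning ≈ 17–80 h as in cultured cancer-cell panels);
per-dataset cell-line subsets (default 80% of a 60-line pool) so that
cross-panel intersections are realistic; planted genes whose slope is
calibrated from the panel's growth-rate spread to hit a target per-panel
correlation (default 0.6) at the default noise (σ = 0.5); a protein layer
whose slopes are multiplied by an attenuation factor (default 0.8),
reproducing the qualitative observation that transcripts correlate more
strongly with proliferation than their proteins; intensity-dependent
missingness, p(miss|v) = σ(b·(v₀ − v)/sd) with the midpoint solved by
bisection to hit the target overall rate (default 25%, b = 2 per SD) —
the MNAR pattern that justifies low-quantile imputation; and accession
fragmentation into 2–3 perturbed variant rows with a ground-truth mapping
key. The DE-table fixture treats statistical significance as perfectly
calibrated: only truly regulated genes can reach q ≤ 0.05.

What the generator does **not** emulate: peptide/spectral-level structure,
batch effects beyond per-sample shifts, correlated gene modules other than
the proliferation program, heavy-tailed noise, or panel-specific
normalization artifacts. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to every pathology of real panels.

## Problem sizes

Tests and the acceptance script run the calibration study at 4 panels ×
50 cell lines × 5,000 genes with 50 randomization iterations and 20
seeds, and the recovery study at 7 panels × 5,000 genes — sizes chosen to
make Monte-Carlo error small relative to the margins being tested while
keeping a full run in the minutes range on one CPU.

## Numerical choices and degenerate inputs

- Pearson r is computed from masked sum formulas over pairwise-complete
  observations, clipped to [−1, 1] against round-off; zero-variance genes
  are recorded as *not computed* (never as r = 0), and genes under the
  coverage floor carry a `low_coverage` status.
- Cross-dataset aggregation uses the signed mean: r = 0.8 and −0.8 average
  to 0 — deliberate, since a sign-inconsistent gene is not a reproducible
  proliferation correlate.
- `resolve_mapping` breaks conflicts by (datasets matched, fewest combined
  accessions, lexicographic id); the final key exists purely so resolution
  is deterministic. Conflicts are reported, never silently dropped.
- `vsn_approx` is an arcsinh transform with per-sample median centring —
  variance-stabilizing in shape (linear near zero, logarithmic for large
  values); it is an approximation and is recorded in the dataset metadata.
- Jaccard of two empty sets is 0 by convention; term reduction sweeps in
  ascending q (ties by term id) and keeps a term iff it is dissimilar to
  *all* previously kept terms, making the kept set pairwise dissimilar and
  the operation idempotent.
- The enrichment test for flagged hits is the one-sided hypergeometric
  upper tail (equivalently a one-sided Fisher exact test) with the DE
  table's own rows as the universe — not the genome, since only tested
  genes could have been hits.

## Known limitations

Reference cutoffs are packaged constants, valid for the id namespace and
normalization of the compendia they came from; applying them to data on a
different scale requires re-deriving cutoffs. The knee heuristic assumes a
single dominant inflection; multi-modal enrichment curves should be cut
manually. The generator's single attenuation factor cannot represent
gene-specific post-transcriptional regulation.
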