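"""Harmonize fragmented accession variants across a panel.

Fragments 20% of gene ids into 2-3 accession variants (as independent
search-engine runs would), resolves the mapping, collapses variants by
their per-sample mean, filters sparse rows/columns and median-centres.
"""

import prolifsig as ps

cfg = ps.SimulationConfig(
    n_genes=500,
    n_cell_lines=40,
    n_datasets_protein=1,
    n_datasets_transcript=0,
    id_fragmentation_rate=0.2,
    seed=3,
)
study = ps.simulate_study(cfg)
original = study.datasets[0]

fragmented, mapping = ps.fragment_ids(original, cfg)
print(f"original: {original.n_genes} rows -> fragmented: {fragmented.n_genes} rows")

resolved, conflicts = ps.resolve_mapping(mapping)
print(f"mapping resolved ({len(conflicts)} contested accessions)")

harmonized = ps.apply_mapping(fragmented, resolved)
match = set(harmonized.genes) == set(original.genes)
print(f"round trip recovers the original gene set: {match}")

filtered, record = ps.filter_missingness(harmonized)
print(f"missingness filter: removed {record.n_samples_removed} samples "
      f"(>70% missing) and {record.n_genes_removed} genes (>50% missing)")

normalized = ps.normalize(filtered, method="median_subtract")
med = normalized.values.median(axis=0, skipna=True).abs().max()
print(f"after median subtraction, max |per-sample median| = {med:.2e}")
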