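"""Prune redundant enriched GO terms by Jaccard similarity.

Terms whose member sets overlap at Jaccard >= 0.5 are considered
redundant; of each similar group only the term with the lowest q-value
survives the greedy ascending-q sweep.
"""

import pandas as pd

import prolifsig as ps

terms = pd.DataFrame(
    {
        "term": [
            "DNA replication",
            "DNA-templated replication",
            "chromosome segregation",
            "mitotic sister chromatid segregation",
            "ribosome biogenesis",
        ],
        "members": [
            "POLA1;PCNA;RFC2;RFC3;RFC4;MCM2;MCM3",
            "POLA1;PCNA;RFC2;RFC3;RFC4;MCM2;FEN1",
            "SMC1A;SMC3;STAG2;PLK1;BUB1",
            "SMC1A;SMC3;STAG2;PLK1;CENPA",
            "NOC3L;MAK16;PDCD11",
        ],
        "qvalue": [1e-8, 3e-7, 2e-6, 5e-5, 0.01],
    }
)

reduced = ps.reduce_terms(terms, cutoff=0.5)
print(f"{len(terms)} terms -> {len(reduced)} after redundancy reduction:")
for _, row in reduced.iterrows():
    print(f"  {row['term']}  (q = {row['qvalue']:.1e})")
# Each redundant pair collapses onto its most significant representative;
# the kept terms are pairwise dissimilar (all Jaccard < 0.5).
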