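"""Build a signaling gene-set library from raw term tables.

Constructs a toy set of pathway terms (a B-cell receptor signaling core plus
overlapping and background terms), then runs the full library pipeline:
over-representation test against a query gene list, FDR filtering,
kappa-redundancy elimination, and the minimum-size filter.
"""

import numpy as np

from sigbridge.genesets import TermRecord, build_library

rng = np.random.default_rng(0)
universe = [f"GENE{i:03d}" for i in range(400)]

bcr_core = universe[:40]
terms = [
    TermRecord("BCR_SIGNALING", "B cell receptor signaling pathway", genes=frozenset(bcr_core)),
    # near-duplicate of the core term: should fall to the redundancy filter
    TermRecord("BCR_SIGNALING_POS", "positive regulation of BCR signaling",
               genes=frozenset(bcr_core[:36] + universe[40:44])),
    # enriched but tiny: should fall to the size filter
    TermRecord("BCR_TINY", "BCR co-receptor complex", genes=frozenset(bcr_core[:6])),
]
terms += [
    TermRecord(f"BG{i:02d}", f"background pathway {i}",
               genes=frozenset(rng.choice(universe, 30, replace=False)))
    for i in range(12)
]

query = universe[:35]  # genes implicated by a differential screen
library, table = build_library(terms, query=query, universe=universe,
                               fdr=0.05, redundancy_cutoff=0.5, min_size=10)

print("enrichment table (top 5):")
print(table.head(5).to_string(index=False))
print()
print(f"final library: {len(library)} terms, {library.n_unique_genes} unique genes")
for t in library.terms:
    print(f"  {t.term_id}: {t.size} genes")
# The q column is the BH-adjusted over-representation p-value; only terms
# with q < 0.05 survive, redundant near-duplicates and sub-10-gene terms are
# dropped, so the kept terms are the independent, well-populated signals.
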