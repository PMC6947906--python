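"""Compare splice isoforms of one gene: does splicing remove the PrLD?

Two isoforms of a synthetic gene are scored; the short isoform lacks the
Q/N-rich block, so its score collapses and the gene is flagged as crossing
the classical 0.05 threshold.
"""

from prionscan import ProteinRecord, compare_isoforms, load_propensity_table
from prionscan.isoforms import crossing_genes

table = load_propensity_table()
full = ProteinRecord("ISO1-A", "ILVFAM" * 12 + "EKSG" * 12 + "QNQNSY" * 20 + "EKSG" * 12)
spliced = ProteinRecord("ISO1-B", "ILVFAM" * 12 + "EKSG" * 24)

comparisons = compare_isoforms("GENE1", [full, spliced], table)
for c in comparisons:
    print(
        f"{c.isoform_accession}: score {c.isoform_score:+.4f}, "
        f"delta to gene max {c.delta_to_max:.4f}, category {c.category}"
    )
print("threshold-crossing genes:", crossing_genes(comparisons))
print(
    "\n'crossing' means the gene expresses both a sub-threshold and an "
    "above-threshold isoform, so splicing alone can toggle predicted "
    "aggregation propensity."
)
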