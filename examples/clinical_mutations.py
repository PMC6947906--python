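"""Parse ClinVar-style protein changes and classify their score effects.

A mix of scoreable substitutions and excluded records (stop gain,
frameshift) is run against a synthetic protein; each scored mutation is
classified against the classical 0.05 threshold.
"""

from prionscan import ProteinRecord, load_propensity_table, score_clinical_table

table = load_propensity_table()
protein = ProteinRecord("DEMO2", "EKSG" * 15 + "QNQNSY" * 20 + "EKSG" * 15)
rows = [
    {"accession": "DEMO2", "protein_change": "p.S65Y", "phenotype": "myopathy-like"},
    {"accession": "DEMO2", "protein_change": "p.Asn100Lys", "phenotype": "neuropathy-like"},
    {"accession": "DEMO2", "protein_change": "p.Arg2Ter", "phenotype": "stop gain"},
    {"accession": "DEMO2", "protein_change": "p.Gly4fs", "phenotype": "frameshift"},
]
effects, rejects = score_clinical_table({"DEMO2": protein}, rows, table)
for e in effects:
    print(
        f"{e.protein_change}: wt {e.wt_score:.4f} -> mut {e.mut_score:.4f} "
        f"(delta {e.delta:+.4f}, {e.category})"
    )
for r in rejects:
    print(f"excluded {r['protein_change']}: {r['reject_reason']}")
print(
    "\nPositive deltas inside a high-scoring PrLD ('high_increasing') mark "
    "mutations predicted to enhance aggregation; stop/frameshift records are "
    "excluded rather than scored."
)
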