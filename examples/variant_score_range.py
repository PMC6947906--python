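"""Estimate how far single and pairwise variants can move a PrLD score.

A synthetic protein with a Q/N-rich candidate domain is combined with a
score-raising (S->Y) and a score-lowering (N->K) variant; all four sequences
(reference, two singletons, one pair) are scored and summarised.
"""

from prionscan import (
    ProteinRecord,
    SequenceVariant,
    load_propensity_table,
    summarize_variant_scores,
)

table = load_propensity_table()
protein = ProteinRecord("DEMO1", "EKSG" * 15 + "QNQNSY" * 20 + "EKSG" * 15)
variants = [
    SequenceVariant("DEMO1", 125, protein.sequence[124], "Y"),
    SequenceVariant("DEMO1", 130, protein.sequence[129], "K"),
]
summary = summarize_variant_scores(protein, variants, table)
print(f"reference score : {summary.reference_score:.4f}")
print(f"minimum score   : {summary.min_score:.4f}")
print(f"maximum score   : {summary.max_score:.4f}")
print(f"score range     : {summary.score_range:.4f}")
print(f"sequences scored: {summary.n_sequences_scored} "
      f"({summary.n_unique_scores} unique scores)")
print(
    "\nThe range is the spread of predicted aggregation propensity reachable "
    "by known variation inside the candidate PrLD; the reference always lies "
    "within it."
)
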