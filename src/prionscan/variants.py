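"""Enumeration and scoring of single- and pairwise-variant combinations.

For a protein with a candidate PrLD, every single amino-acid variant falling
inside a PrLD called on the reference sequence (at the relaxed 0.0 threshold)
is combined with every other such variant at a distinct position.  Each
resulting sequence — reference, singletons, and unordered pairs — is scored
and the per-protein minimum, maximum, range and unique-score count summarise
how far natural variation can move the predicted aggregation propensity.
Summaries whose theoretical minimum hits the -1.0 sentinel (a variant can
close the disorder gate everywhere) are flagged for exclusion from aggregate
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator

from .scoring import (
    CANONICAL_RESIDUES,
    PrLD,
    PropensityTable,
    ProteinRecord,
    ScoringConfig,
    find_prlds,
    protein_score,
)

logger = logging.getLogger("prionscan")

__all__ = [
    "SequenceVariant",
    "VariantScoreSummary",
    "VariantError",
    "apply_variants",
    "enumerate_combinations",
    "filter_variants_to_prlds",
    "summarize_variant_scores",
]


class VariantError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class SequenceVariant:
    """A single amino-acid substitution on a specific isoform sequence."""

    accession: str
    position: int  # 1-based
    ref_residue: str
    alt_residue: str

    def __post_init__(self):
        if self.ref_residue == self.alt_residue:
            raise VariantError(
                f"{self.accession}:{self.position} ref equals alt "
                f"({self.ref_residue})"
            )
        for aa in (self.ref_residue, self.alt_residue):
            if aa not in CANONICAL_RESIDUES:
                raise VariantError(
                    f"{self.accession}:{self.position} non-canonical residue {aa!r}"
                )
        if self.position < 1:
            raise VariantError(f"{self.accession}: position must be >= 1")

    def matches_reference(self, protein: ProteinRecord) -> bool:
        return (
            self.position <= protein.length
            and protein.sequence[self.position - 1] == self.ref_residue
        )


@dataclass(frozen=True)
class VariantScoreSummary:
    accession: str
    reference_score: float
    min_score: float
    max_score: float
    score_range: float
    n_unique_scores: int
    n_sequences_scored: int
    n_variants_considered: int
    excluded: bool  # theoretical minimum hit the no-disorder sentinel


def apply_variants(
    protein: ProteinRecord, variants: Iterable[SequenceVariant]
) -> ProteinRecord:
    """Return a new record with the substitutions applied.

    Rejects reference mismatches and multiple variants at one position.
    Idempotent for the empty set.
    """
    variants = list(variants)
    positions = [v.position for v in variants]
    if len(set(positions)) != len(positions):
        dup = sorted({p for p in positions if positions.count(p) > 1})
        raise VariantError(
            f"{protein.accession}: multiple variants at position(s) {dup}"
        )
    seq = list(protein.sequence)
    for v in variants:
        if v.position > protein.length:
            raise VariantError(
                f"{protein.accession}:{v.position} beyond protein length "
                f"{protein.length}"
            )
        if seq[v.position - 1] != v.ref_residue:
            raise VariantError(
                f"{protein.accession}:{v.position} reference mismatch "
                f"(sequence has {seq[v.position - 1]}, variant says "
                f"{v.ref_residue})"
            )
        seq[v.position - 1] = v.alt_residue
    return ProteinRecord(
        accession=protein.accession, sequence="".join(seq), gene=protein.gene
    )


def enumerate_combinations(
    variants: Iterable[SequenceVariant], pairs_only: bool = False
) -> Iterator[frozenset[SequenceVariant]]:
    """Lazily yield the reference (empty set), singletons, and unordered
    pairs of variants at distinct positions.

    Pairs sharing a position are never yielded.  With ``pairs_only`` the
    reference and singletons are suppressed.
    """
    variants = sorted(set(variants))
    if not pairs_only:
        yield frozenset()
        for v in variants:
            yield frozenset((v,))
    for v1, v2 in combinations(variants, 2):
        if v1.position != v2.position:
            yield frozenset((v1, v2))


def filter_variants_to_prlds(
    protein: ProteinRecord,
    variants: Iterable[SequenceVariant],
    prlds: Iterable[PrLD],
) -> list[SequenceVariant]:
    """Keep variants that match the reference sequence and fall inside a
    called PrLD; mismatching records are logged and skipped (public variant
    tables mix isoform coordinate frames)."""
    prlds = list(prlds)
    kept = []
    for v in variants:
        if not v.matches_reference(protein):
            logger.warning(
                "skipping variant %s:%d%s>%s: reference mismatch",
                v.accession, v.position, v.ref_residue, v.alt_residue,
            )
            continue
        if any(d.contains(v.position) for d in prlds):
            kept.append(v)
    return kept


def summarize_variant_scores(
    protein: ProteinRecord,
    variants: Iterable[SequenceVariant],
    table: PropensityTable,
    config: ScoringConfig | None = None,
    prld_threshold: float | None = None,
    pairs_only: bool = False,
    max_combinations: int | None = None,
) -> VariantScoreSummary:
    """Score all enumerated variant combinations of one protein.

    PrLD membership is decided on the reference sequence at
    ``prld_threshold`` (default: the relaxed 0.0 threshold); domain
    boundaries are not recomputed per variant.  ``max_combinations`` caps
    enumeration for pathological variant counts (default: no cap).
    """
    config = config or ScoringConfig()
    if prld_threshold is None:
        prld_threshold = config.relaxed_threshold
    reference_score = protein_score(protein, table, config)
    prlds = find_prlds(protein, table, config, threshold=prld_threshold)
    in_prld = filter_variants_to_prlds(protein, variants, prlds)

    scores: list[float] = []
    n_scored = 0
    for combo in enumerate_combinations(in_prld, pairs_only=pairs_only):
        if max_combinations is not None and n_scored >= max_combinations:
            logger.warning(
                "%s: combination cap of %d reached", protein.accession,
                max_combinations,
            )
            break
        mutant = apply_variants(protein, combo)
        scores.append(protein_score(mutant, table, config))
        n_scored += 1
    if pairs_only and not scores:
        scores = [reference_score]
        n_scored = 1

    min_score = min(scores)
    max_score = max(scores)
    return VariantScoreSummary(
        accession=protein.accession,
        reference_score=reference_score,
        min_score=min_score,
        max_score=max_score,
        score_range=max_score - min_score,
        n_unique_scores=len({round(s, 9) for s in scores}),
        n_sequences_scored=n_scored,
        n_variants_considered=len(in_prld),
        excluded=min_score == config.no_disorder_sentinel,
    )
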