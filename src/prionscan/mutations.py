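"""Clinical missense-variant parsing and wild-type vs mutant scoring.

Disease-associated variants arrive as HGVS-style protein changes
(``p.P275S``, ``p.Gly12Asp``).  Only single amino-acid substitutions are
scoreable; stop gains, frameshifts, indels and synonymous records are
excluded with a reason rather than an error.  Each substitution is applied
to its isoform sequence, the mutant is rescored under the identical
configuration, and the (wild-type, mutant) score pair is classified against
the classical 0.05 threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data.IUPACData import protein_letters_3to1

from .scoring import (
    CANONICAL_RESIDUES,
    PropensityTable,
    ProteinRecord,
    ScoringConfig,
    protein_score,
)
from .variants import SequenceVariant, apply_variants

logger = logging.getLogger("prionscan")

__all__ = [
    "ClinicalVariant",
    "MutationEffect",
    "ParseExclusion",
    "RefMismatchError",
    "parse_protein_change",
    "classify_effect",
    "score_mutation",
    "score_clinical_table",
]

_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1.items()}

_ONE_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_THREE_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|\*)$")


@dataclass(frozen=True)
class ParseExclusion:
    """A protein-change record that is not a scoreable substitution."""

    text: str
    reason: str  # stop | frameshift | indel | synonymous | unparseable


@dataclass(frozen=True)
class ClinicalVariant:
    accession: str
    protein_change: str
    position: int
    ref_residue: str
    alt_residue: str
    phenotype_annotation: str = ""
    isoform_accession: str | None = None

    @property
    def frame_accession(self) -> str:
        """Accession of the isoform whose coordinates the change uses."""
        return self.isoform_accession or self.accession


@dataclass(frozen=True)
class MutationEffect:
    accession: str
    protein_change: str
    wt_score: float
    mut_score: float
    delta: float
    category: str  # high_increasing | threshold_crossing | decreasing | subthreshold_other
    phenotype_annotation: str = ""


class RefMismatchError(ValueError):
    pass


def parse_protein_change(text: str):
    """Parse ``p.`` notation into (position, ref, alt) or a ParseExclusion.

    Accepts one-letter (``p.P275S``) and three-letter (``p.Gly12Asp``)
    substitutions.  Stop gains (``Ter``/``*``), frameshifes (``fs``),
    deletions/insertions/duplications and synonymous records (``=``) are
    excluded with a reason; anything else unrecognisable is excluded as
    ``unparseable``.  Never raises on malformed input.
    """
    raw = text.strip()
    body = raw
    if body.startswith("p."):
        body = body[2:]
    body = body.strip("()")
    if not body:
        return ParseExclusion(raw, "unparseable")
    if body.endswith("="):
        return ParseExclusion(raw, "synonymous")
    if "fs" in body:
        return ParseExclusion(raw, "frameshift")
    if any(tok in body for tok in ("delins", "del", "ins", "dup")):
        return ParseExclusion(raw, "indel")

    m = _ONE_RE.match(body)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt in ("*", "X"):
            return ParseExclusion(raw, "stop")
        if ref in CANONICAL_RESIDUES and alt in CANONICAL_RESIDUES:
            if ref == alt:
                return ParseExclusion(raw, "synonymous")
            return pos, ref, alt
        return ParseExclusion(raw, "unparseable")

    m = _THREE_RE.match(body)
    if m:
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if alt3 in ("Ter", "*"):
            return ParseExclusion(raw, "stop")
        ref = _THREE_TO_ONE.get(ref3)
        alt = _THREE_TO_ONE.get(alt3)
        if ref is None or alt is None:
            return ParseExclusion(raw, "unparseable")
        if ref == alt:
            return ParseExclusion(raw, "synonymous")
        return pos, ref, alt

    return ParseExclusion(raw, "unparseable")


def classify_effect(
    wt_score: float, mut_score: float, classical_threshold: float = 0.05
) -> str:
    """Total classification of a (wild-type, mutant) score pair."""
    delta = mut_score - wt_score
    if delta < 0:
        return "decreasing"
    if wt_score > classical_threshold and delta > 0:
        return "high_increasing"
    if wt_score < classical_threshold < mut_score:
        return "threshold_crossing"
    return "subthreshold_other"


def score_mutation(
    protein: ProteinRecord,
    variant: ClinicalVariant,
    table: PropensityTable,
    config: ScoringConfig | None = None,
) -> MutationEffect:
    """Score wild-type and mutant sequences under identical configuration."""
    config = config or ScoringConfig()
    if (
        variant.position > protein.length
        or protein.sequence[variant.position - 1] != variant.ref_residue
    ):
        found = (
            protein.sequence[variant.position - 1]
            if variant.position <= protein.length
            else "beyond end"
        )
        raise RefMismatchError(
            f"{variant.accession} {variant.protein_change}: sequence "
            f"{protein.accession} has {found} at position {variant.position}, "
            f"expected {variant.ref_residue}"
        )
    wt = protein_score(protein, table, config)
    mutant = apply_variants(
        protein,
        [
            SequenceVariant(
                accession=protein.accession,
                position=variant.position,
                ref_residue=variant.ref_residue,
                alt_residue=variant.alt_residue,
            )
        ],
    )
    mut = protein_score(mutant, table, config)
    return MutationEffect(
        accession=variant.accession,
        protein_change=variant.protein_change,
        wt_score=wt,
        mut_score=mut,
        delta=mut - wt,
        category=classify_effect(wt, mut, config.classical_threshold),
        phenotype_annotation=variant.phenotype_annotation,
    )


def score_clinical_table(
    proteins: Mapping[str, ProteinRecord],
    rows: Iterable[Mapping[str, str]],
    table: PropensityTable,
    config: ScoringConfig | None = None,
) -> tuple[list[MutationEffect], list[dict[str, str]]]:
    """Score a ClinVar-style table of rows with columns ``accession``,
    optional ``isoform_accession``, ``protein_change`` and ``phenotype``.

    Returns scored effects and a rejects list (row + reason) covering parse
    exclusions, unknown accessions, and reference mismatches.  Positions are
    interpreted on the isoform named by ``isoform_accession`` when present.
    """
    config = config or ScoringConfig()
    effects: list[MutationEffect] = []
    rejects: list[dict[str, str]] = []
    for row in rows:
        change = row.get("protein_change", "")
        parsed = parse_protein_change(change)
        if isinstance(parsed, ParseExclusion):
            rejects.append({**row, "reject_reason": parsed.reason})
            continue
        pos, ref, alt = parsed
        variant = ClinicalVariant(
            accession=row["accession"],
            protein_change=change,
            position=pos,
            ref_residue=ref,
            alt_residue=alt,
            phenotype_annotation=row.get("phenotype", ""),
            isoform_accession=row.get("isoform_accession") or None,
        )
        protein = proteins.get(variant.frame_accession)
        if protein is None:
            rejects.append({**row, "reject_reason": "unknown_accession"})
            continue
        try:
            effects.append(score_mutation(protein, variant, table, config))
        except RefMismatchError as exc:
            logger.warning("%s", exc)
            rejects.append({**row, "reject_reason": "ref_mismatch"})
    return effects, rejects
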