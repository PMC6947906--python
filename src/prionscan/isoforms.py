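"""Per-gene isoform comparison of aggregation propensity scores.

Alternative splicing can include or exclude an entire prion-like domain.
Isoforms are grouped by gene, each is scored, and every isoform is compared
with the highest-scoring isoform of its gene.  Categories follow the
threshold-crossing logic used for splicing analyses: an isoform at or below
the classical 0.05 threshold whose gene max exceeds it is "crossing"; an
above-threshold isoform with a higher-scoring sibling is "high_with_higher".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .scoring import (
    PropensityTable,
    ProteinRecord,
    ScoringConfig,
    protein_score,
)

__all__ = [
    "IsoformComparison",
    "CATEGORIES",
    "group_isoforms",
    "compare_isoforms",
    "compare_all_isoforms",
]

CATEGORIES = ("below_both", "crossing", "high_with_higher", "max_isoform")


@dataclass(frozen=True)
class IsoformComparison:
    gene: str
    isoform_accession: str
    isoform_score: float
    gene_max_score: float
    delta_to_max: float
    category: str


def group_isoforms(
    records: Iterable[ProteinRecord], gene_map: Mapping[str, str]
) -> tuple[dict[str, list[ProteinRecord]], list[ProteinRecord]]:
    """Partition records by gene; unmapped accessions go to an orphan list."""
    groups: dict[str, list[ProteinRecord]] = {}
    orphans: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
        gene = gene_map.get(rec.accession, rec.gene)
        if gene is None:
            orphans.append(rec)
        else:
            groups.setdefault(gene, []).append(rec)
    return groups, orphans


def _categorize(score: float, gene_max: float, classical: float) -> str:
    if score == gene_max:
        return "max_isoform"
    if score > classical:
        return "high_with_higher"
    if gene_max > classical:
        return "crossing"
    return "below_both"


def compare_isoforms(
    gene: str,
    group: Iterable[ProteinRecord],
    table: PropensityTable,
    config: ScoringConfig | None = None,
    affected_only: bool = False,
) -> list[IsoformComparison]:
    """Score each isoform of one gene and classify against the gene maximum.

    Score ties at the gene max all classify as ``max_isoform``.  With
    ``affected_only``, isoforms whose score equals the gene max are dropped,
    mirroring "only isoforms for which splicing affected the score" views.
    """
    config = config or ScoringConfig()
    group = list(group)
    if not group:
        raise ValueError(f"empty isoform group for gene {gene!r}")
    scores = {rec.accession: protein_score(rec, table, config) for rec in group}
    gene_max = max(scores.values())
    out = []
    for rec in group:
        s = scores[rec.accession]
        category = _categorize(s, gene_max, config.classical_threshold)
        if affected_only and category == "max_isoform":
            continue
        out.append(
            IsoformComparison(
                gene=gene,
                isoform_accession=rec.accession,
                isoform_score=s,
                gene_max_score=gene_max,
                delta_to_max=gene_max - s,
                category=category,
            )
        )
    return out


def compare_all_isoforms(
    records: Iterable[ProteinRecord],
    gene_map: Mapping[str, str],
    table: PropensityTable,
    config: ScoringConfig | None = None,
    affected_only: bool = False,
) -> tuple[list[IsoformComparison], list[ProteinRecord]]:
    """Group by gene, compare within each group; returns (comparisons, orphans)."""
    groups, orphans = group_isoforms(records, gene_map)
    comparisons: list[IsoformComparison] = []
    for gene in sorted(groups):
        comparisons.extend(
            compare_isoforms(
                gene, groups[gene], table, config, affected_only=affected_only
            )
        )
    return comparisons, orphans


def crossing_genes(
    comparisons: Iterable[IsoformComparison], config: ScoringConfig | None = None
) -> list[str]:
    """Genes with at least one isoform at or below the classical threshold and
    at least one above it (the threshold-crossing selection).  Genes whose
    every isoform stays at or below the threshold are excluded."""
    config = config or ScoringConfig()
    by_gene: dict[str, list[IsoformComparison]] = {}
    for c in comparisons:
        by_gene.setdefault(c.gene, []).append(c)
    hits = []
    for gene, comps in sorted(by_gene.items()):
        lo = any(c.isoform_score <= config.classical_threshold for c in comps)
        hi = any(c.isoform_score > config.classical_threshold for c in comps)
        if lo and hi:
            hits.append(gene)
    return hits
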