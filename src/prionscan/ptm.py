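"""Composition-controlled PTM enrichment within prion-like domains.

PrLDs have biased composition, so raw PTM counts inside them are misleading.
For each modification type the analysis counts *modifiable* residues (those
a PTM of that type can target) inside and outside PrLDs, splits each count
by observed modification status, and summarises the 2x2 table as an odds
ratio:

    OR = (f_in / (1 - f_in)) / (f_out / (1 - f_out)),   E = ln(OR)

where f_in / f_out are the modified fractions of modifiable residues inside
and outside PrLDs.  Significance uses a two-sided Fisher exact test with
Benjamini-Hochberg correction across PTM types at FDR 0.05; types with fewer
than 100 known sites proteome-wide are excluded before correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .scoring import PrLD, ProteinRecord

logger = logging.getLogger("prionscan")

__all__ = [
    "PTMSite",
    "ContingencyCounts",
    "PTMEnrichmentResult",
    "load_ptm_residue_map",
    "map_ptms_to_prlds",
    "build_contingency",
    "enrichment",
    "bh_adjust",
    "analyze_ptm_enrichment",
    "MIN_PROTEOME_SITES",
]

#: PTM types with fewer proteome-wide sites than this are excluded.
MIN_PROTEOME_SITES = 100


def load_ptm_residue_map(path=None) -> dict[str, frozenset[str]]:
    """Map each PTM type to the residues it can target.

    Defaults to the packaged table (S/T/Y phosphorylation; K acetylation,
    methylation, ubiquitination, sumoylation; R methylation); users may
    supply their own two-column TSV (ptm_type, residues).
    """
    if path is None:
        text = (resources.files("prionscan.data") / "ptm_residues.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mapping: dict[str, frozenset[str]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        ptm_type, residues = ln.split("\t")
        mapping[ptm_type.strip()] = frozenset(residues.strip())
    return mapping


@dataclass(frozen=True)
class PTMSite:
    accession: str
    position: int  # 1-based
    residue: str
    ptm_type: str


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 modifiable-residue counts for one PTM type."""

    ptm_type: str
    mod_in_prld: int
    unmod_in_prld: int
    mod_outside: int
    unmod_outside: int

    @property
    def n_sites_proteome(self) -> int:
        return self.mod_in_prld + self.mod_outside

    @property
    def modifiable_in_prld(self) -> int:
        return self.mod_in_prld + self.unmod_in_prld

    @property
    def modifiable_outside(self) -> int:
        return self.mod_outside + self.unmod_outside


@dataclass(frozen=True)
class PTMEnrichmentResult:
    ptm_type: str
    counts: ContingencyCounts
    f_mod_prld: float
    f_mod_nonprld: float
    odds_ratio: float
    log_enrichment: float
    log_enrichment_se: float
    fisher_p: float
    bh_q: float = math.nan
    significant: bool = False
    excluded_lowcount: bool = False
    undefined: bool = False  # zero cell: OR/SE not estimable


def _validate_sites(
    sites: Iterable[PTMSite],
    proteome: Mapping[str, ProteinRecord],
    residue_map: Mapping[str, frozenset[str]],
) -> list[PTMSite]:
    """Drop (with a log) sites beyond protein length, mismatching the
    sequence, of unknown type, or on a non-modifiable residue; de-duplicate
    (accession, position, type)."""
    seen: set[tuple[str, int, str]] = set()
    kept: list[PTMSite] = []
    for site in sites:
        protein = proteome.get(site.accession)
        if protein is None:
            logger.warning("PTM site on unknown accession %s", site.accession)
            continue
        if site.position < 1 or site.position > protein.length:
            logger.warning(
                "PTM site %s:%d beyond protein length %d",
                site.accession, site.position, protein.length,
            )
            continue
        if protein.sequence[site.position - 1] != site.residue:
            logger.warning(
                "PTM site %s:%d residue mismatch (%s in sequence, %s in table)",
                site.accession, site.position,
                protein.sequence[site.position - 1], site.residue,
            )
            continue
        targets = residue_map.get(site.ptm_type)
        if targets is None:
            logger.warning("unknown PTM type %r", site.ptm_type)
            continue
        if site.residue not in targets:
            logger.warning(
                "PTM site %s:%d residue %s not modifiable by %s",
                site.accession, site.position, site.residue, site.ptm_type,
            )
            continue
        key = (site.accession, site.position, site.ptm_type)
        if key in seen:
            continue
        seen.add(key)
        kept.append(site)
    return kept


def map_ptms_to_prlds(
    sites: Iterable[PTMSite],
    prlds_by_accession: Mapping[str, list[PrLD]],
    proteome: Mapping[str, ProteinRecord],
    residue_map: Mapping[str, frozenset[str]] | None = None,
) -> tuple[list[tuple[PTMSite, bool]], dict[tuple[str, int, int, str], int]]:
    """Label each site in/out of a PrLD (1-based inclusive membership) and
    count modifications per (PrLD, type).

    Returns (annotated sites, counts keyed by (accession, start, end, type)).
    """
    residue_map = residue_map or load_ptm_residue_map()
    annotated: list[tuple[PTMSite, bool]] = []
    per_prld: dict[tuple[str, int, int, str], int] = {}
    for site in _validate_sites(sites, proteome, residue_map):
        domains = prlds_by_accession.get(site.accession, [])
        inside = False
        for d in domains:
            if d.contains(site.position):
                inside = True
                key = (site.accession, d.start, d.end, site.ptm_type)
                per_prld[key] = per_prld.get(key, 0) + 1
        annotated.append((site, inside))
    return annotated, per_prld


def build_contingency(
    sites: Iterable[PTMSite],
    proteome: Mapping[str, ProteinRecord],
    prlds_by_accession: Mapping[str, list[PrLD]],
    ptm_type: str,
    residue_map: Mapping[str, frozenset[str]] | None = None,
    validated: bool = False,
) -> ContingencyCounts:
    """Count modifiable residues inside/outside PrLDs split by modification
    status for one PTM type.  Non-modified means modifiable but with no
    observed site of this type; a residue modified by another type still
    counts as unmodified here."""
    residue_map = residue_map or load_ptm_residue_map()
    targets = residue_map.get(ptm_type)
    if targets is None:
        raise KeyError(f"no modifiable-residue set declared for {ptm_type!r}")
    site_list = list(sites)
    if not validated:
        site_list = _validate_sites(site_list, proteome, residue_map)
    modified = {
        (s.accession, s.position)
        for s in site_list
        if s.ptm_type == ptm_type
    }

    mod_in = unmod_in = mod_out = unmod_out = 0
    for acc, protein in proteome.items():
        domains = prlds_by_accession.get(acc, [])
        inside_ranges = [(d.start, d.end) for d in domains]
        for idx, aa in enumerate(protein.sequence, start=1):
            if aa not in targets:
                continue
            inside = any(s <= idx <= e for s, e in inside_ranges)
            is_mod = (acc, idx) in modified
            if inside:
                if is_mod:
                    mod_in += 1
                else:
                    unmod_in += 1
            else:
                if is_mod:
                    mod_out += 1
                else:
                    unmod_out += 1
    return ContingencyCounts(
        ptm_type=ptm_type,
        mod_in_prld=mod_in,
        unmod_in_prld=unmod_in,
        mod_outside=mod_out,
        unmod_outside=unmod_out,
    )


def enrichment(
    counts: ContingencyCounts, continuity_correction: bool = False
) -> PTMEnrichmentResult:
    """Odds ratio, log enrichment, Wald standard error and two-sided Fisher
    exact p for one contingency table.

    A zero cell leaves OR/SE undefined and flags the result unless
    ``continuity_correction`` adds 0.5 to every cell (Haldane-Anscombe) for
    the OR/SE only; the Fisher p is always computed on the raw counts.
    """
    a, b = counts.mod_in_prld, counts.unmod_in_prld
    c, d = counts.mod_outside, counts.unmod_outside
    n_in = a + b
    n_out = c + d
    f_in = a / n_in if n_in else math.nan
    f_out = c / n_out if n_out else math.nan
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")

    cells = (a, b, c, d)
    undefined = any(x == 0 for x in cells)
    if undefined and continuity_correction:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
        undefined = False
    else:
        a_, b_, c_, d_ = cells
    if undefined:
        oratio = se = log_e = math.nan
    else:
        oratio = (a_ / b_) / (c_ / d_)
        log_e = math.log(oratio)
        se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return PTMEnrichmentResult(
        ptm_type=counts.ptm_type,
        counts=counts,
        f_mod_prld=f_in,
        f_mod_nonprld=f_out,
        odds_ratio=oratio,
        log_enrichment=log_e,
        log_enrichment_se=se,
        fisher_p=float(p),
        excluded_lowcount=counts.n_sites_proteome < MIN_PROTEOME_SITES,
        undefined=any(x == 0 for x in cells),
    )


def bh_adjust(
    results: Iterable[PTMEnrichmentResult], fdr: float = 0.05
) -> list[PTMEnrichmentResult]:
    """Fill Benjamini-Hochberg q-values and significance flags.

    Low-count-excluded types do not participate in the correction and keep
    NaN q-values.
    """
    results = list(results)
    testable_idx = [i for i, r in enumerate(results) if not r.excluded_lowcount]
    if testable_idx:
        pvals = [results[i].fisher_p for i in testable_idx]
        reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for i, q, rej in zip(testable_idx, qvals, reject):
            results[i] = replace(
                results[i], bh_q=float(q), significant=bool(rej)
            )
    return results


def analyze_ptm_enrichment(
    sites: Iterable[PTMSite],
    proteome: Mapping[str, ProteinRecord],
    prlds_by_accession: Mapping[str, list[PrLD]],
    residue_map: Mapping[str, frozenset[str]] | None = None,
    fdr: float = 0.05,
    continuity_correction: bool = False,
) -> list[PTMEnrichmentResult]:
    """Full per-type pipeline: contingency, enrichment, BH correction.

    Every PTM type present in the validated site table is analysed (in
    sorted order); the <100-site filter marks exclusions before correction.
    """
    residue_map = residue_map or load_ptm_residue_map()
    site_list = _validate_sites(sites, proteome, residue_map)
    types = sorted({s.ptm_type for s in site_list})
    results = []
    for ptm_type in types:
        counts = build_contingency(
            site_list, proteome, prlds_by_accession, ptm_type,
            residue_map=residue_map, validated=True,
        )
        results.append(enrichment(counts, continuity_correction))
    return bh_adjust(results, fdr=fdr)
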