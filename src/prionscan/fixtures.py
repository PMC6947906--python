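"""Deterministic synthetic proteomes with planted, testable structure.

Real proteome/variant/PTM tables are large external downloads; every other
module in this package is instead exercised on synthetic inputs with known
ground truth.  Proteins are concatenations of three block kinds whose
residue alphabets are packaged data chosen so the FoldIndex sign of each
block is analytically predictable:

``qn_prionlike``
    Q/N-rich with some S/G/Y/T/K/R — disordered, positive mean propensity,
    so planted blocks are recovered as called PrLDs.
``charged_disordered``
    D/E/K/R-rich — disordered but strongly prion-inhibiting.
``hydrophobic_ordered``
    I/L/V/F/A-rich — FoldIndex positive, never scored.

Variant tables plant substitutions inside PrLDs with direction labels
derived by rescoring; PTM tables plant per-type modification odds ratios by
rejection sampling until the realized in/out odds match the plan within 5%.
Identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import write_tsv
from .ptm import PTMSite, load_ptm_residue_map
from .scoring import (
    PropensityTable,
    ProteinRecord,
    ScoringConfig,
    find_prlds,
    load_propensity_table,
    protein_score,
)
from .variants import SequenceVariant, apply_variants

__all__ = [
    "BlockSpec",
    "FixtureSpec",
    "load_block_alphabets",
    "generate_proteome",
    "generate_variant_table",
    "generate_clinical_table",
    "generate_ptm_table",
    "write_fixture_bundle",
]

BLOCK_KINDS = ("qn_prionlike", "charged_disordered", "hydrophobic_ordered")

#: substitutions used when planting score-raising / score-lowering variants
_RAISING_ALTS = ("Y", "W")
_LOWERING_ALTS = ("K", "D")


def load_block_alphabets(path=None) -> dict[str, tuple[str, np.ndarray]]:
    """Residue alphabets and sampling weights per block kind (packaged TSV)."""
    if path is None:
        text = (
            resources.files("prionscan.data") / "block_alphabets.tsv"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    per_kind: dict[str, list[tuple[str, float]]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        kind, residue, weight = ln.split("\t")
        per_kind.setdefault(kind, []).append((residue, float(weight)))
    out = {}
    for kind, pairs in per_kind.items():
        residues = "".join(aa for aa, _ in pairs)
        weights = np.array([w for _, w in pairs])
        out[kind] = (residues, weights / weights.sum())
    return out


@dataclass(frozen=True)
class BlockSpec:
    kind: str
    min_len: int
    max_len: int

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("block lengths must satisfy 1 <= min <= max")


#: default architecture: ordered flanks, charged linkers, one central PrLD
DEFAULT_GRAMMAR = (
    BlockSpec("hydrophobic_ordered", 60, 100),
    BlockSpec("charged_disordered", 50, 80),
    BlockSpec("qn_prionlike", 90, 140),
    BlockSpec("charged_disordered", 50, 80),
    BlockSpec("hydrophobic_ordered", 60, 100),
)

#: default PTM plan: site counts and planted odds ratios per type.  Arginine
#: methylation is the planted-enrichment type (odds ratio 3); the remaining
#: types are planted neutral so per-type inference can be validated.
DEFAULT_PTM_PLAN: dict[str, tuple[int, float]] = {
    "serine-phosphorylation": (550, 1.0),
    "threonine-phosphorylation": (550, 1.0),
    "tyrosine-phosphorylation": (550, 1.0),
    "lysine-acetylation": (550, 1.0),
    "lysine-methylation": (550, 1.0),
    "lysine-ubiquitination": (550, 1.0),
    "arginine-methylation": (550, 3.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 80
    block_grammar: tuple[BlockSpec, ...] = DEFAULT_GRAMMAR
    variant_rate: float = 3.0  # mean planted variants per PrLD
    #: None resolves to DEFAULT_PTM_PLAN with site counts scaled to the
    #: proteome size (the stated counts assume the default 80 proteins)
    ptm_plan: Mapping[str, tuple[int, float]] | None = None
    isoform_plan: float = 0.3  # fraction of genes with a PrLD-spliced-out isoform

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.ptm_plan is None:
            scale = self.n_proteins / 80
            object.__setattr__(
                self,
                "ptm_plan",
                {
                    t: (max(20, round(n * scale)), oratio)
                    for t, (n, oratio) in DEFAULT_PTM_PLAN.items()
                },
            )
        if self.variant_rate < 0 or not 0 <= self.isoform_plan <= 1:
            raise ValueError("rates must be >= 0 (isoform_plan in [0, 1])")
        if not self.block_grammar:
            raise ValueError("block grammar must contain at least one block")
        for n_sites, oratio in self.ptm_plan.values():
            if n_sites < 1 or oratio <= 0:
                raise ValueError("ptm plan entries need n_sites >= 1, OR > 0")

    def rng(self, stage: int) -> np.random.Generator:
        """The single pseudo-random source, streamed per generation stage."""
        return np.random.default_rng([self.seed, stage])


def generate_proteome(
    spec: FixtureSpec,
) -> tuple[list[ProteinRecord], dict[str, str], list[dict]]:
    """Build the synthetic proteome.

    Returns (records, accession->gene map, truth rows).  Truth rows carry the
    planted block intervals (1-based inclusive); ``qn_prionlike`` entries are
    the planted PrLDs.  A fraction ``isoform_plan`` of genes get a second
    isoform with every qn block spliced out.
    """
    rng = spec.rng(stage=1)
    alphabets = load_block_alphabets()
    records: list[ProteinRecord] = []
    gene_map: dict[str, str] = {}
    truth: list[dict] = []
    for i in range(spec.n_proteins):
        accession = f"SYN{i:04d}"
        gene = f"GENE{i:04d}"
        parts: list[str] = []
        blocks: list[tuple[str, int, int]] = []
        pos = 0
        for block in spec.block_grammar:
            length = int(rng.integers(block.min_len, block.max_len + 1))
            residues, weights = alphabets[block.kind]
            seq = "".join(rng.choice(list(residues), size=length, p=weights))
            parts.append(seq)
            blocks.append((block.kind, pos + 1, pos + length))
            pos += length
        sequence = "".join(parts)
        records.append(ProteinRecord(accession=accession, sequence=sequence, gene=gene))
        gene_map[accession] = gene
        for kind, start, end in blocks:
            truth.append(
                {
                    "accession": accession,
                    "block_kind": kind,
                    "start": start,
                    "end": end,
                }
            )
        if rng.random() < spec.isoform_plan:
            spliced = "".join(
                part
                for part, (kind, _, _) in zip(parts, blocks)
                if kind != "qn_prionlike"
            )
            if spliced:
                iso_acc = f"{accession}-2"
                records.append(
                    ProteinRecord(accession=iso_acc, sequence=spliced, gene=gene)
                )
                gene_map[iso_acc] = gene
    return records, gene_map, truth


def planted_prld_intervals(truth: Sequence[dict]) -> dict[str, list[tuple[int, int]]]:
    """Planted qn intervals per accession from a proteome truth table."""
    out: dict[str, list[tuple[int, int]]] = {}
    for row in truth:
        if row["block_kind"] == "qn_prionlike":
            out.setdefault(row["accession"], []).append((row["start"], row["end"]))
    return out


def generate_variant_table(
    spec: FixtureSpec,
    proteome: Sequence[ProteinRecord],
    truth: Sequence[dict],
    table: PropensityTable | None = None,
    config: ScoringConfig | None = None,
) -> tuple[list[SequenceVariant], list[dict]]:
    """Plant substitutions inside planted PrLDs.

    Alternating raising (to Y/W) and lowering (to K/D) substitutions are
    placed at distinct positions; each variant's truth label is the sign of
    the score change when it is applied alone, obtained by rescoring.
    """
    table = table or load_propensity_table()
    config = config or ScoringConfig()
    rng = spec.rng(stage=2)
    intervals = planted_prld_intervals(truth)
    by_acc = {rec.accession: rec for rec in proteome}
    variants: list[SequenceVariant] = []
    labels: list[dict] = []
    for acc in sorted(intervals):
        protein = by_acc[acc]
        base = protein_score(protein, table, config)
        for start, end in intervals[acc]:
            n = int(rng.poisson(spec.variant_rate))
            n = min(n, end - start + 1)
            if n == 0:
                continue
            positions = sorted(
                int(p) for p in rng.choice(
                    np.arange(start, end + 1), size=n, replace=False
                )
            )
            for j, pos in enumerate(positions):
                ref = protein.sequence[pos - 1]
                pool = _RAISING_ALTS if j % 2 == 0 else _LOWERING_ALTS
                alt = next(aa for aa in pool if aa != ref)
                var = SequenceVariant(
                    accession=acc, position=pos, ref_residue=ref, alt_residue=alt
                )
                mutant = apply_variants(protein, [var])
                delta = protein_score(mutant, table, config) - base
                direction = (
                    "raising" if delta > 0 else "lowering" if delta < 0 else "neutral"
                )
                variants.append(var)
                labels.append(
                    {
                        "accession": acc,
                        "position": pos,
                        "ref": ref,
                        "alt": alt,
                        "delta": delta,
                        "direction": direction,
                    }
                )
    return variants, labels


_PHENOTYPES = (
    "synthetic aggregation disorder, type 1",
    "synthetic aggregation disorder, type 2",
    "benign synthetic trait",
)


def generate_clinical_table(
    spec: FixtureSpec,
    variants: Sequence[SequenceVariant],
) -> list[dict[str, str]]:
    """ClinVar-style rows (p.<ref><pos><alt> plus phenotype) from planted
    variants, with a few non-substitution records to exercise exclusions."""
    rng = spec.rng(stage=3)
    rows = []
    for v in variants:
        rows.append(
            {
                "accession": v.accession,
                "isoform_accession": v.accession,
                "protein_change": f"p.{v.ref_residue}{v.position}{v.alt_residue}",
                "phenotype": _PHENOTYPES[int(rng.integers(len(_PHENOTYPES)))],
            }
        )
    if rows:
        first = rows[0]["accession"]
        rows.append(
            {
                "accession": first,
                "isoform_accession": first,
                "protein_change": "p.Arg10Ter",
                "phenotype": "synthetic stop gain",
            }
        )
        rows.append(
            {
                "accession": first,
                "isoform_accession": first,
                "protein_change": "p.Gly20fs",
                "phenotype": "synthetic frameshift",
            }
        )
    return rows


def _solve_outside_odds(n_in: int, n_out: int, oratio: float, n_sites: int) -> float:
    """Outside odds o such that expected planted sites hit n_sites with
    inside odds oratio * o (bisection; expectation is monotone in o)."""

    def expected(o: float) -> float:
        o_in = oratio * o
        return n_in * o_in / (1 + o_in) + n_out * o / (1 + o)

    lo, hi = 1e-9, 1e6
    if expected(hi) < n_sites:
        raise ValueError(
            f"not enough modifiable residues ({n_in} in / {n_out} out) "
            f"to plant {n_sites} sites"
        )
    for _ in range(200):
        mid = (lo + hi) / 2
        if expected(mid) < n_sites:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_ptm_table(
    spec: FixtureSpec,
    proteome: Sequence[ProteinRecord],
    prld_intervals: Mapping[str, Sequence[tuple[int, int]]],
    max_attempts: int = 500,
) -> tuple[list[PTMSite], dict[str, float]]:
    """Plant per-type modification sites with the planned odds ratios.

    ``prld_intervals`` defines the in/out frame (1-based inclusive) that the
    odds ratios are planted against.  Each type is rejection-sampled until
    the realized odds ratio is within 5% of the plan and no contingency cell
    is empty.  Returns the sites and the realized odds ratio per type.
    """
    rng = spec.rng(stage=4)
    residue_map = load_ptm_residue_map()
    sites: list[PTMSite] = []
    realized: dict[str, float] = {}
    for ptm_type in sorted(spec.ptm_plan):
        n_sites, oratio = spec.ptm_plan[ptm_type]
        targets = residue_map[ptm_type]
        inside: list[tuple[str, int, str]] = []
        outside: list[tuple[str, int, str]] = []
        for rec in proteome:
            ranges = list(prld_intervals.get(rec.accession, ()))
            for idx, aa in enumerate(rec.sequence, start=1):
                if aa not in targets:
                    continue
                bucket = (
                    inside
                    if any(s <= idx <= e for s, e in ranges)
                    else outside
                )
                bucket.append((rec.accession, idx, aa))
        if not inside or not outside:
            raise ValueError(
                f"{ptm_type}: no modifiable residues "
                f"{'inside' if not inside else 'outside'} PrLDs"
            )
        o_out = _solve_outside_odds(len(inside), len(outside), oratio, n_sites)
        p_in = oratio * o_out / (1 + oratio * o_out)
        p_out = o_out / (1 + o_out)
        for attempt in range(max_attempts):
            pick_in = rng.random(len(inside)) < p_in
            pick_out = rng.random(len(outside)) < p_out
            a = int(pick_in.sum())
            c = int(pick_out.sum())
            b = len(inside) - a
            d = len(outside) - c
            if min(a, b, c, d) == 0:
                continue
            realized_or = (a / b) / (c / d)
            if abs(realized_or / oratio - 1) <= 0.05:
                break
        else:
            raise RuntimeError(
                f"{ptm_type}: could not realize planted OR {oratio} "
                f"within 5% in {max_attempts} attempts"
            )
        realized[ptm_type] = realized_or
        for (acc, pos, aa), hit in zip(inside, pick_in):
            if hit:
                sites.append(PTMSite(acc, pos, aa, ptm_type))
        for (acc, pos, aa), hit in zip(outside, pick_out):
            if hit:
                sites.append(PTMSite(acc, pos, aa, ptm_type))
    sites.sort(key=lambda s: (s.accession, s.position, s.ptm_type))
    return sites, realized


def write_fixture_bundle(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Emit a complete fixture bundle: FASTA, gene map, variant, ClinVar-style
    and PTM tables, plus a truth JSON.

    PTM odds ratios are planted against the PrLDs *called* on the synthetic
    proteome at the relaxed threshold, so downstream enrichment analysis sees
    exactly the realized odds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_propensity_table()
    config = ScoringConfig()

    records, gene_map, truth = generate_proteome(spec)
    variants, variant_truth = generate_variant_table(spec, records, truth, table, config)
    clinical = generate_clinical_table(spec, variants)
    called = {
        rec.accession: [
            (d.start, d.end)
            for d in find_prlds(rec, table, config, config.relaxed_threshold)
        ]
        for rec in records
    }
    sites, realized = generate_ptm_table(spec, records, called)

    paths = {
        "fasta": outdir / "proteome.fasta",
        "gene_map": outdir / "gene_map.tsv",
        "variants": outdir / "variants.tsv",
        "clinvar": outdir / "clinvar.tsv",
        "ptms": outdir / "ptms.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.accession} gene={rec.gene}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    write_tsv(
        paths["gene_map"],
        ["accession", "gene"],
        [(acc, gene) for acc, gene in sorted(gene_map.items())],
    )
    write_tsv(
        paths["variants"],
        ["accession", "position", "ref", "alt"],
        [(v.accession, v.position, v.ref_residue, v.alt_residue) for v in variants],
    )
    write_tsv(
        paths["clinvar"],
        ["accession", "isoform_accession", "protein_change", "phenotype"],
        [
            (r["accession"], r["isoform_accession"], r["protein_change"], r["phenotype"])
            for r in clinical
        ],
    )
    write_tsv(
        paths["ptms"],
        ["accession", "position", "residue", "ptm_type"],
        [(s.accession, s.position, s.residue, s.ptm_type) for s in sites],
    )
    payload = {
        "spec": {
            "seed": spec.seed,
            "n_proteins": spec.n_proteins,
            "variant_rate": spec.variant_rate,
            "isoform_plan": spec.isoform_plan,
            "ptm_plan": {k: list(v) for k, v in spec.ptm_plan.items()},
        },
        "planted_blocks": truth,
        "variant_labels": variant_truth,
        "called_prlds": called,
        "realized_ptm_odds_ratios": realized,
    }
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
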