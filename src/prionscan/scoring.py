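"""Windowed prion-propensity scoring with FoldIndex disorder gating.

This module implements the modified Prion Aggregation Prediction Algorithm
(mPAPA).  A protein is scanned with 41-residue windows; the score anchored at
a residue position is the mean of the per-window mean propensities over the
(up to) 41 consecutive full windows that end at or after that position — an
effective 81-residue context.  A position only receives a score when the
FoldIndex over that same governing span is negative (predicted intrinsically
disordered); proteins with no gated position are assigned the sentinel score
of -1.0.  Contiguous above-threshold regions are merged into prion-like
domain (PrLD) calls with explicit 1-based boundaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CANONICAL_RESIDUES",
    "PropensityTable",
    "ScoringConfig",
    "ProteinRecord",
    "ScoreProfile",
    "PrLD",
    "ResidueError",
    "load_propensity_table",
    "window_propensity",
    "window_foldindex",
    "position_scores",
    "protein_score",
    "find_prlds",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy, the scale underlying FoldIndex.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: FoldIndex uses hydrophobicity rescaled to [0, 1].
FOLDINDEX_HYDROPHOBICITY = {
    aa: (v + 4.5) / 9.0 for aa, v in KYTE_DOOLITTLE.items()
}

#: Unit side-chain charges at neutral pH as used by FoldIndex (His neutral).
FOLDINDEX_CHARGE = {aa: 0 for aa in CANONICAL_RESIDUES}
FOLDINDEX_CHARGE.update({"D": -1, "E": -1, "K": 1, "R": 1})

#: FoldIndex linear coefficients (slope on mean hydrophobicity, intercept).
FOLDINDEX_COEFFICIENTS = (2.785, -1.151)


class ResidueError(ValueError):
    """A sequence contains a residue outside the 20-letter canonical alphabet."""

    def __init__(self, accession: str, position: int, residue: str):
        self.accession = accession
        self.position = position
        self.residue = residue
        super().__init__(
            f"non-canonical residue {residue!r} at position {position} "
            f"in {accession or 'sequence'}"
        )


@dataclass(frozen=True)
class PropensityTable:
    """Per-residue prion propensity lookup (dimensionless, experimentally derived)."""

    propensity: Mapping[str, float]
    source_tag: str = ""

    def __post_init__(self):
        prop = dict(self.propensity)
        missing = set(CANONICAL_RESIDUES) - set(prop)
        extra = set(prop) - set(CANONICAL_RESIDUES)
        if missing or extra:
            raise ValueError(
                f"propensity table must cover exactly the 20 canonical residues "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        for aa, v in prop.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite propensity for residue {aa}")
        object.__setattr__(self, "propensity", MappingProxyType(prop))

    def __getitem__(self, residue: str) -> float:
        return self.propensity[residue]

    def checksum(self) -> str:
        payload = "".join(
            f"{aa}:{self.propensity[aa]:.9f};" for aa in CANONICAL_RESIDUES
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_propensity_table(path=None) -> PropensityTable:
    """Load a two-column (residue, propensity) TSV; defaults to the packaged table.

    The packaged values are the experimentally derived prion propensities
    released with the original PAPA implementation.
    """
    if path is None:
        ref = resources.files("prionscan.data") / "propensities.tsv"
        text = ref.read_text()
        tag = "packaged PAPA propensities (Sup35 mutagenesis-derived)"
    else:
        with open(path) as fh:
            text = fh.read()
        tag = str(path)
    prop = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # header row mandatory
        aa, val = ln.split("\t")
        prop[aa.strip()] = float(val)
    return PropensityTable(propensity=prop, source_tag=tag)


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the scan.

    window_size
        Length of the component window (41 residues by default).
    relaxed_threshold / classical_threshold
        0.0 defines candidate PrLDs for variant/PTM analyses; 0.05 is the
        classical aggregation-prone cutoff.
    no_disorder_sentinel
        Score reported for proteins with no FoldIndex-gated position (-1.0).
    foldindex_per_window
        When True, the disorder gate uses the mean of per-41-mer FoldIndex
        values over the governing windows (the pre-modification behaviour)
        instead of a single FoldIndex over the full governing span.
    """

    window_size: int = 41
    relaxed_threshold: float = 0.0
    classical_threshold: float = 0.05
    no_disorder_sentinel: float = -1.0
    foldindex_hydrophobicity: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(dict(FOLDINDEX_HYDROPHOBICITY))
    )
    foldindex_charge: Mapping[str, int] = field(
        default_factory=lambda: MappingProxyType(dict(FOLDINDEX_CHARGE))
    )
    foldindex_coefficients: tuple[float, float] = FOLDINDEX_COEFFICIENTS
    foldindex_per_window: bool = False

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if not self.relaxed_threshold < self.classical_threshold:
            raise ValueError("relaxed_threshold must be below classical_threshold")

    @property
    def effective_span(self) -> int:
        return 2 * self.window_size - 1


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    gene: str | None = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def noncanonical_positions(self) -> list[tuple[int, str]]:
        """1-based positions of residues outside the canonical alphabet."""
        canon = set(CANONICAL_RESIDUES)
        return [
            (i + 1, aa) for i, aa in enumerate(self.sequence) if aa not in canon
        ]


@dataclass(frozen=True)
class ScoreProfile:
    """Per-position window scores and disorder gating for one protein.

    ``raw_scores``, ``foldindex`` and ``disorder`` are parallel arrays over
    1-based ``positions``; a position is *scored* iff its disorder flag is
    set.  Empty arrays indicate a protein shorter than the window size.
    """

    accession: str
    positions: np.ndarray
    raw_scores: np.ndarray
    foldindex: np.ndarray
    disorder: np.ndarray
    sentinel: float = -1.0

    def scored_positions(self) -> list[tuple[int, float]]:
        return [
            (int(p), float(s))
            for p, s, d in zip(self.positions, self.raw_scores, self.disorder)
            if d
        ]

    @property
    def protein_score(self) -> float:
        if self.disorder.size and bool(self.disorder.any()):
            return float(self.raw_scores[self.disorder].max())
        return self.sentinel


@dataclass(frozen=True)
class PrLD:
    """A merged above-threshold candidate prion-like domain (1-based, inclusive)."""

    accession: str
    start: int
    end: int
    peak_score: float
    domain_sequence: str

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("PrLD coordinates must satisfy 1 <= start <= end")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def _residue_values(
    protein: ProteinRecord, mapping: Mapping[str, float]
) -> np.ndarray:
    try:
        return np.array([mapping[aa] for aa in protein.sequence], dtype=float)
    except KeyError:
        pos, aa = protein.noncanonical_positions()[0]
        raise ResidueError(protein.accession, pos, aa) from None


def window_propensity(window_sequence: str, table: PropensityTable) -> float:
    """Mean per-residue prion propensity of a window (composition-only)."""
    if not window_sequence:
        raise ValueError("empty window")
    try:
        return float(
            sum(table.propensity[aa] for aa in window_sequence)
            / len(window_sequence)
        )
    except KeyError:
        rec = ProteinRecord(accession="window", sequence=window_sequence)
        pos, aa = rec.noncanonical_positions()[0]
        raise ResidueError("window", pos, aa) from None


def window_foldindex(
    window_sequence: str, config: ScoringConfig | None = None
) -> float:
    """FoldIndex = slope * <hydrophobicity> - |<net charge>| + intercept.

    Negative values predict intrinsic disorder.
    """
    config = config or ScoringConfig()
    if not window_sequence:
        raise ValueError("empty window")
    slope, intercept = config.foldindex_coefficients
    try:
        h = sum(config.foldindex_hydrophobicity[aa] for aa in window_sequence)
        c = sum(config.foldindex_charge[aa] for aa in window_sequence)
    except KeyError:
        rec = ProteinRecord(accession="window", sequence=window_sequence)
        pos, aa = rec.noncanonical_positions()[0]
        raise ResidueError("window", pos, aa) from None
    n = len(window_sequence)
    return float(slope * (h / n) - abs(c / n) + intercept)


def _empty_profile(accession: str, sentinel: float) -> ScoreProfile:
    empty = np.array([], dtype=float)
    return ScoreProfile(
        accession=accession,
        positions=np.array([], dtype=int),
        raw_scores=empty,
        foldindex=empty,
        disorder=np.array([], dtype=bool),
        sentinel=sentinel,
    )


def position_scores(
    protein: ProteinRecord,
    table: PropensityTable,
    config: ScoringConfig | None = None,
) -> ScoreProfile:
    """Score every residue position of one protein.

    Only full ``window_size``-mers act as component windows.  The score at
    1-based position ``p`` is the mean of the per-window mean propensities
    over the governing windows — those starting in
    ``[max(1, p - w + 1), min(p, L - w + 1)]`` — so interior positions
    average exactly ``w`` windows (an effective ``2w - 1`` span) while
    positions within ``w - 1`` residues of either terminus average over the
    windows that exist (at least one).  The disorder gate is the FoldIndex
    computed over the union span of those governing windows.

    Proteins shorter than ``window_size`` yield an empty profile whose
    protein score is the sentinel.
    """
    config = config or ScoringConfig()
    w = config.window_size
    L = protein.length
    if L < w:
        return _empty_profile(protein.accession, config.no_disorder_sentinel)

    prop = _residue_values(protein, table.propensity)
    hydro = _residue_values(protein, config.foldindex_hydrophobicity)
    charge = _residue_values(protein, config.foldindex_charge)
    slope, intercept = config.foldindex_coefficients

    cprop = np.concatenate(([0.0], np.cumsum(prop)))
    win = (cprop[w:] - cprop[:-w]) / w  # mean propensity of window starting at j
    cwin = np.concatenate(([0.0], np.cumsum(win)))

    p = np.arange(L)  # 0-based anchor positions
    a = np.maximum(0, p - w + 1)  # first governing window start
    b = np.minimum(p, L - w)  # last governing window start
    raw = (cwin[b + 1] - cwin[a]) / (b - a + 1)

    span_end = b + w  # exclusive end of the union governing span
    if config.foldindex_per_window:
        chyd = np.concatenate(([0.0], np.cumsum(hydro)))
        cchg = np.concatenate(([0.0], np.cumsum(charge)))
        wh = (chyd[w:] - chyd[:-w]) / w
        wc = (cchg[w:] - cchg[:-w]) / w
        fiw = slope * wh - np.abs(wc) + intercept
        cfiw = np.concatenate(([0.0], np.cumsum(fiw)))
        fi = (cfiw[b + 1] - cfiw[a]) / (b - a + 1)
    else:
        chyd = np.concatenate(([0.0], np.cumsum(hydro)))
        cchg = np.concatenate(([0.0], np.cumsum(charge)))
        n = span_end - a
        mh = (chyd[span_end] - chyd[a]) / n
        mc = (cchg[span_end] - cchg[a]) / n
        fi = slope * mh - np.abs(mc) + intercept

    return ScoreProfile(
        accession=protein.accession,
        positions=p + 1,
        raw_scores=raw,
        foldindex=fi,
        disorder=fi < 0.0,
        sentinel=config.no_disorder_sentinel,
    )


def protein_score(
    protein: ProteinRecord,
    table: PropensityTable,
    config: ScoringConfig | None = None,
) -> float:
    """Maximum gated position score, or the -1.0 sentinel when nothing is gated."""
    return position_scores(protein, table, config).protein_score


def _merge_intervals(
    intervals: Iterable[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    merged: list[list[float]] = []
    for s, e, sc in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], sc)
        else:
            merged.append([s, e, sc])
    return [(int(s), int(e), float(sc)) for s, e, sc in merged]


def find_prlds(
    protein: ProteinRecord,
    table: PropensityTable,
    config: ScoringConfig | None = None,
    threshold: float | None = None,
) -> list[PrLD]:
    """Call candidate PrLDs: merged governing spans of gated positions scoring
    strictly above ``threshold`` (default: the relaxed 0.0 threshold)."""
    config = config or ScoringConfig()
    if threshold is None:
        threshold = config.relaxed_threshold
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    profile = position_scores(protein, table, config)
    if not profile.positions.size:
        return []
    w = config.window_size
    L = protein.length
    hits = profile.disorder & (profile.raw_scores > threshold)
    if not hits.any():
        return []
    p = profile.positions[hits] - 1  # back to 0-based
    scores = profile.raw_scores[hits]
    a = np.maximum(0, p - w + 1)
    e = np.minimum(p, L - w) + w - 1  # inclusive end of governing span
    merged = _merge_intervals(zip(a, e, scores))
    return [
        PrLD(
            accession=protein.accession,
            start=s + 1,
            end=en + 1,
            peak_score=sc,
            domain_sequence=protein.sequence[s : en + 1],
        )
        for s, en, sc in merged
    ]
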