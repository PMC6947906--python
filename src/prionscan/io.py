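"""FASTA/TSV readers and writers, config files, and run manifests.

All tabular interchange is tab-separated UTF-8 text with a mandatory header
row, '.' decimal separator, LF line endings on write and CRLF tolerated on
read.  Floating-point columns are written with 6 decimals.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .scoring import (
    CANONICAL_RESIDUES,
    ProteinRecord,
    ScoringConfig,
)

logger = logging.getLogger("prionscan")

__all__ = [
    "InputError",
    "read_fasta",
    "read_tsv",
    "write_tsv",
    "read_config",
    "RunManifest",
]

# exit-code categories used by the CLI
EXIT_MISSING_FILE = 2
EXIT_MALFORMED = 3
EXIT_EMPTY = 4
EXIT_RESIDUE = 5


class InputError(ValueError):
    """A malformed or unusable input; carries a CLI exit-code category."""

    def __init__(self, message: str, exit_code: int = EXIT_MALFORMED):
        super().__init__(message)
        self.exit_code = exit_code


def _parse_description(description: str) -> tuple[str, str | None]:
    tokens = description.split()
    accession = tokens[0]
    gene = None
    for tok in tokens[1:]:
        if tok.startswith("gene="):
            gene = tok[len("gene="):]
    return accession, gene


def read_fasta(
    path, residue_policy: str = "lenient"
) -> list[ProteinRecord]:
    """Read a multi-record FASTA into ProteinRecords.

    The accession is the first whitespace-delimited token of the description
    line; an optional ``gene=<symbol>`` token is honoured.  Under the default
    ``lenient`` policy, proteins containing residues outside the canonical
    20-letter alphabet (U/B/Z/X/* ...) are skipped with a logged warning,
    since the propensity table is defined only on canonical residues; under
    ``strict`` they raise.
    """
    if residue_policy not in ("strict", "lenient"):
        raise ValueError("residue_policy must be 'strict' or 'lenient'")
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}", EXIT_MISSING_FILE)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    canon = set(CANONICAL_RESIDUES)
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, gene = _parse_description(rec.description)
        if accession in seen:
            raise InputError(
                f"duplicate accession {accession!r} in {path}", EXIT_MALFORMED
            )
        seen.add(accession)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise InputError(
                f"empty sequence for {accession!r} in {path}", EXIT_MALFORMED
            )
        bad = [(i + 1, aa) for i, aa in enumerate(seq) if aa not in canon]
        if bad:
            pos, aa = bad[0]
            if residue_policy == "strict":
                raise InputError(
                    f"non-canonical residue {aa!r} at position {pos} "
                    f"in {accession}",
                    EXIT_RESIDUE,
                )
            logger.warning(
                "skipping %s: non-canonical residue %r at position %d",
                accession, aa, pos,
            )
            n_skipped += 1
            continue
        records.append(ProteinRecord(accession=accession, sequence=seq, gene=gene))
    if n_skipped:
        logger.warning("skipped %d protein(s) with non-canonical residues", n_skipped)
    if not records:
        raise InputError(f"no usable records in {path}", EXIT_EMPTY)
    return records


def read_tsv(path, required_columns: Sequence[str]) -> list[dict[str, str]]:
    """Read a headered TSV into a list of row dicts.

    Ragged rows and missing required columns are rejected with their
    1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}", EXIT_MISSING_FILE)
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"empty TSV: {path}", EXIT_EMPTY) from None
        header = [h.strip() for h in header]
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise InputError(
                f"{path}: missing required column(s) {missing} "
                f"(found {header})",
                EXIT_MALFORMED,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise InputError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {len(header)})",
                    EXIT_MALFORMED,
                )
            rows.append(dict(zip(header, (v.strip() for v in row))))
    if not rows:
        raise InputError(f"no data rows in {path}", EXIT_EMPTY)
    return rows


def _format_cell(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write rows as LF-terminated TSV; floats rounded to 6 decimals."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


_CONFIG_FLOAT_KEYS = {
    "relaxed_threshold",
    "classical_threshold",
    "no_disorder_sentinel",
}


def read_config(path, base: ScoringConfig | None = None) -> ScoringConfig:
    """Build a ScoringConfig from a key=value file overriding the defaults.

    Recognised keys: window_size, relaxed_threshold, classical_threshold,
    no_disorder_sentinel, foldindex_per_window.
    """
    base = base or ScoringConfig()
    overrides: dict = {}
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}", EXIT_MISSING_FILE)
    valid = {f.name for f in dc_fields(ScoringConfig)}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(
                f"{path}: line {lineno} is not key=value", EXIT_MALFORMED
            )
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise InputError(f"{path}: unknown config key {key!r}", EXIT_MALFORMED)
        if key == "window_size":
            overrides[key] = int(value)
        elif key == "foldindex_per_window":
            overrides[key] = value.lower() in ("1", "true", "yes")
        elif key in _CONFIG_FLOAT_KEYS:
            overrides[key] = float(value)
        else:
            raise InputError(
                f"{path}: key {key!r} cannot be set from a config file",
                EXIT_MALFORMED,
            )
    kwargs = {
        "window_size": base.window_size,
        "relaxed_threshold": base.relaxed_threshold,
        "classical_threshold": base.classical_threshold,
        "no_disorder_sentinel": base.no_disorder_sentinel,
        "foldindex_per_window": base.foldindex_per_window,
    }
    kwargs.update(overrides)
    return ScoringConfig(**kwargs)


@dataclass
class RunManifest:
    """Record of one run: inputs, configuration in force, tool version."""

    subcommand: str
    inputs: Mapping[str, str]
    config: Mapping[str, object]
    propensity_checksum: str
    version: str
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc
            ).isoformat(timespec="seconds")

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "subcommand": self.subcommand,
            "inputs": dict(self.inputs),
            "config": dict(self.config),
            "propensity_checksum": self.propensity_checksum,
            "version": self.version,
            "timestamp": self.timestamp,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
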