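"""Reading, curation, splitting and negative augmentation of peptide-CDR3 pair tables.

Input tables are CSV/TSV with a declared column mapping; repertoire files
are plain text (one CDR3 per line) or single-column CSV. No database
schema auto-detection is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from itcep.alphabet import (
    CDR3_MAX_LEN,
    CDR3_MIN_LEN,
    PEPTIDE_MAX_LEN,
    PEPTIDE_MIN_LEN,
    is_valid_sequence,
)

__all__ = [
    "PairRecord",
    "ColumnMapping",
    "CurationRules",
    "CurationReport",
    "parse_pair_table",
    "curate_pairs",
    "sample_negative_pairs",
    "split_shared_unique",
    "read_repertoire",
    "write_pair_table",
    "write_curation_report",
]


@dataclass(frozen=True)
class PairRecord:
    """One peptide-CDR3 observation with a binary label and provenance."""

    peptide: str
    cdr3: str
    label: int = 1
    source: str = ""
    confidence: float | None = None

    def key(self) -> tuple[str, str]:
        return (self.peptide, self.cdr3)


@dataclass(frozen=True)
class ColumnMapping:
    """Names of the columns holding each field in an input table.

    ``label``, ``source`` and ``confidence`` are optional; rows missing an
    optional column fall back to the defaults of :class:`PairRecord`.
    """

    peptide: str = "peptide"
    cdr3: str = "cdr3"
    label: str | None = None
    source: str | None = None
    confidence: str | None = None


@dataclass(frozen=True)
class CurationRules:
    peptide_min_len: int = PEPTIDE_MIN_LEN
    peptide_max_len: int = PEPTIDE_MAX_LEN
    cdr3_min_len: int = CDR3_MIN_LEN
    cdr3_max_len: int = CDR3_MAX_LEN
    # VDJdb-style rule: keep only records whose confidence score exceeds
    # this threshold. ``None`` disables the check (records without a
    # confidence value are never rejected for confidence).
    min_confidence_exclusive: float | None = 0.0
    dedup: bool = True
    # Non-C start is flagged as a warning, not rejected: the curation
    # rules cover length/format only, while the positional-preference
    # encoder assumes a shared start cysteine.
    warn_non_cysteine_start: bool = True


@dataclass
class CurationReport:
    """Accounting of a curation pass: every input is kept or rejected with a reason."""

    kept: int = 0
    rejected: list[tuple[PairRecord, str]] = field(default_factory=list)
    warnings: list[tuple[PairRecord, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.rejected:
            out[reason] = out.get(reason, 0) + 1
        return out


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def parse_pair_table(path: str | Path, mapping: ColumnMapping | None = None) -> list[PairRecord]:
    """Read a pair table into records, one per row.

    Residues are uppercased and stripped of surrounding whitespace. Rows
    with a blank peptide or CDR3 are retained as records with empty
    fields so that curation can reject them with reason ``missing-field``
    instead of the parser crashing.
    """
    mapping = mapping or ColumnMapping()
    df = _read_table(path)
    for col in (mapping.peptide, mapping.cdr3):
        if col not in df.columns:
            raise KeyError(f"mapped column {col!r} not found in {path}")
    for col in (mapping.label, mapping.source, mapping.confidence):
        if col is not None and col not in df.columns:
            raise KeyError(f"mapped column {col!r} not found in {path}")

    records: list[PairRecord] = []
    for _, row in df.iterrows():
        label = 1
        if mapping.label is not None:
            raw = str(row[mapping.label]).strip()
            label = int(float(raw)) if raw else 1
        confidence = None
        if mapping.confidence is not None:
            raw = str(row[mapping.confidence]).strip()
            confidence = float(raw) if raw else None
        records.append(
            PairRecord(
                peptide=str(row[mapping.peptide]).strip().upper(),
                cdr3=str(row[mapping.cdr3]).strip().upper(),
                label=label,
                source=str(row[mapping.source]).strip() if mapping.source else "",
                confidence=confidence,
            )
        )
    return records


def curate_pairs(
    records: Iterable[PairRecord], rules: CurationRules | None = None
) -> tuple[list[PairRecord], CurationReport]:
    """Apply length/alphabet/confidence/duplicate filters.

    Duplicate (peptide, cdr3) pairs keep the first occurrence in input
    order. All rejected records carry a reason code; the report accounts
    for every input record.
    """
    rules = rules or CurationRules()
    report = CurationReport()
    kept: list[PairRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if not rec.peptide or not rec.cdr3:
            report.rejected.append((rec, "missing-field"))
            continue
        if not is_valid_sequence(rec.peptide) or not is_valid_sequence(rec.cdr3):
            report.rejected.append((rec, "alphabet"))
            continue
        if not (rules.peptide_min_len <= len(rec.peptide) <= rules.peptide_max_len):
            report.rejected.append((rec, "peptide-length"))
            continue
        if not (rules.cdr3_min_len <= len(rec.cdr3) <= rules.cdr3_max_len):
            report.rejected.append((rec, "cdr3-length"))
            continue
        if (
            rules.min_confidence_exclusive is not None
            and rec.confidence is not None
            and rec.confidence <= rules.min_confidence_exclusive
        ):
            report.rejected.append((rec, "low-confidence"))
            continue
        if rules.dedup and rec.key() in seen:
            report.rejected.append((rec, "duplicate"))
            continue
        if rules.warn_non_cysteine_start and not rec.cdr3.startswith("C"):
            report.warnings.append((rec, "non-cysteine-start"))
        seen.add(rec.key())
        kept.append(rec)
    report.kept = len(kept)
    return kept, report


def sample_negative_pairs(
    positive_peptides: Sequence[str],
    repertoire: Sequence[str],
    n: int,
    seed: int,
    known_positive_pairs: Iterable[tuple[str, str]] = (),
) -> list[PairRecord]:
    """Draw ``n`` distinct label-0 pairs of a positive-set peptide with a repertoire CDR3.

    Peptide and CDR3 are drawn uniformly and independently; a draw that
    collides with a known positive pair or an already-sampled pair is
    resampled. Deterministic for a fixed seed. Raises ``ValueError`` when
    ``n`` exceeds the number of achievable distinct pairs.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return []
    if not positive_peptides or not repertoire:
        raise ValueError("both pools must be non-empty")

    peptides = sorted(set(positive_peptides))
    cdr3s = sorted(set(repertoire))
    forbidden = set(known_positive_pairs)
    n_forbidden_reachable = sum(1 for p, c in forbidden if p in set(peptides) and c in set(cdr3s))
    achievable = len(peptides) * len(cdr3s) - n_forbidden_reachable
    if n > achievable:
        raise ValueError(f"requested {n} negatives but only {achievable} distinct pairs achievable")

    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    taken: set[tuple[str, str]] = set()
    max_attempts = 50 * n + 1000
    attempts = 0
    while len(chosen) < n and attempts < max_attempts:
        attempts += 1
        pair = (
            peptides[int(rng.integers(len(peptides)))],
            cdr3s[int(rng.integers(len(cdr3s)))],
        )
        if pair in forbidden or pair in taken:
            continue
        taken.add(pair)
        chosen.append(pair)
    if len(chosen) < n:
        # Near-saturated pools: enumerate the remaining achievable pairs
        # and draw without replacement (still seed-deterministic).
        remaining = [
            (p, c)
            for p in peptides
            for c in cdr3s
            if (p, c) not in forbidden and (p, c) not in taken
        ]
        idx = rng.choice(len(remaining), size=n - len(chosen), replace=False)
        chosen.extend(remaining[int(i)] for i in idx)
    return [PairRecord(peptide=p, cdr3=c, label=0, source="sampled-negative") for p, c in chosen]


def split_shared_unique(
    eval_records: Sequence[PairRecord], training_peptides: Iterable[str]
) -> tuple[list[PairRecord], list[PairRecord]]:
    """Partition evaluation records by whether their peptide occurs in training."""
    train_set = set(training_peptides)
    shared = [r for r in eval_records if r.peptide in train_set]
    unique = [r for r in eval_records if r.peptide not in train_set]
    return shared, unique


def read_repertoire(path: str | Path) -> list[str]:
    """Read a repertoire file: one CDR3 per line, or a single-column CSV.

    A first line that is not a valid amino-acid sequence is treated as a
    header and skipped.
    """
    path = Path(path)
    lines = [ln.strip().upper() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and not is_valid_sequence(lines[0]):
        lines = lines[1:]
    return lines


def write_pair_table(records: Sequence[PairRecord], path: str | Path) -> None:
    """Write records as CSV with columns peptide, cdr3, label, source, confidence."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peptide", "cdr3", "label", "source", "confidence"])
        for rec in records:
            writer.writerow(
                [rec.peptide, rec.cdr3, rec.label, rec.source, "" if rec.confidence is None else rec.confidence]
            )


def write_curation_report(report: CurationReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peptide", "cdr3", "reason"])
        for rec, reason in report.rejected:
            writer.writerow([rec.peptide, rec.cdr3, reason])
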