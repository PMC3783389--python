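"""Readers and writers for every external representation the pipeline touches.

Sequences are held as RNA internally: FASTA input with ``T`` is converted to
``U`` on read, and all residues are uppercased.  Transcript coordinates are
1-based inclusive throughout the package, matching the convention of published
target tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN")

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

#: Column order of the target table (family, name, annotation, transcript,
#: score, range, cleavage site, category).
TARGET_TABLE_COLUMNS = (
    "family",
    "mirna",
    "annotation",
    "transcript",
    "score",
    "range",
    "cleavage_site",
    "category",
)

SIGNAL_TABLE_COLUMNS = ("probe_id", "mirna", "channel", "replicate", "fg", "bg_mean", "bg_sd")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def canonicalize_residues(raw: str, *, where: str = "sequence") -> str:
    """Uppercase, convert T to U, and validate against the RNA alphabet.

    Raises :class:`FormatError` naming the 1-based position of the first
    offending character.
    """
    residues = raw.upper().replace("T", "U")
    for pos, ch in enumerate(residues, start=1):
        if ch not in RNA_ALPHABET:
            raise FormatError(f"illegal character {ch!r} at position {pos} in {where}")
    return residues


def reverse_complement(residues: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return "".join(COMPLEMENT[c] for c in reversed(residues))


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (miRNA or transcript)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a nonempty token, got {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has empty residues")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise FormatError(f"record {self.id!r} contains non-RNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TagRecord:
    """A degradome tag: a short sequence with an integer abundance."""

    sequence: str
    count: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.count < 1:
            raise FormatError(f"tag count must be >= 1, got {self.count}")
        if not self.sequence:
            raise FormatError("tag sequence is empty")


@dataclass(frozen=True)
class SignalRow:
    """One microarray spot: probe, channel, replicate, foreground/background."""

    probe_id: str
    mirna: str
    channel: str
    replicate: int
    fg: float
    bg_mean: float
    bg_sd: float

    def __post_init__(self) -> None:
        if self.channel not in ("A", "B"):
            raise FormatError(f"channel must be 'A' or 'B', got {self.channel!r}")
        if self.replicate < 1:
            raise FormatError("replicate index must be >= 1")
        for name in ("fg", "bg_mean", "bg_sd"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise FormatError(f"{name} must be finite")
            if v < 0:
                raise FormatError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class TargetTableRow:
    """One row of the reported target table."""

    family: str
    mirna: str
    transcript: str
    annotation: str
    score: float
    start: int
    end: int
    cleavage_site: int
    category: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise FormatError("score must be >= 0")
        if not (self.start <= self.cleavage_site <= self.end):
            raise FormatError(
                f"cleavage site {self.cleavage_site} outside range {self.start}-{self.end}"
            )
        if self.category not in ("", "I", "II", "III"):
            raise FormatError(f"category must be I, II, III or empty, got {self.category!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into canonicalized :class:`SequenceRecord` objects.

    Line-wrapped residues are joined; T is read as U.  An empty file, a
    record with no residues, or a character outside {A,C,G,U,N,T} is an
    error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"record {rec.id!r} in {path} has empty residues")
        residues = canonicalize_residues(raw, where=f"record {rec.id!r}")
        desc = "" if rec.description == rec.id else rec.description
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap_width: int = 60) -> None:
    """Write records as FASTA with deterministic byte output.

    Residue lines are wrapped at ``wrap_width`` (default 60).
    """
    if wrap_width < 1:
        raise ValueError("wrap_width must be >= 1")
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap_width):
                fh.write(rec.residues[i : i + wrap_width] + "\n")


# ---------------------------------------------------------------------------
# Degradome tags

_FASTA_COUNT_RE = re.compile(r"^(?P<name>.*)-(?P<count>\d+)$")


def read_tags(
    path: str | Path,
    *,
    min_length: int = 15,
    max_length: int = 30,
) -> list[TagRecord]:
    """Read degradome tags from TSV (``sequence<TAB>count``) or FASTA.

    The FASTA dialect stores the abundance as a ``-<count>`` suffix on the
    header.  Duplicate sequences are merged by summing counts.  Counts must
    be positive integers; tag lengths must fall within the configured bounds.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    order: list[str] = []

    def add(seq_raw: str, count: int, where: str) -> None:
        seq = canonicalize_residues(seq_raw, where=where)
        if count <= 0:
            raise FormatError(f"non-positive tag count {count} in {where}")
        if not (min_length <= len(seq) <= max_length):
            raise FormatError(
                f"tag length {len(seq)} outside bounds [{min_length}, {max_length}] in {where}"
            )
        if seq not in counts:
            order.append(seq)
            counts[seq] = 0
        counts[seq] += count

    text = path.read_text()
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _FASTA_COUNT_RE.match(rec.id)
            if not m:
                raise FormatError(f"tag header {rec.id!r} lacks a '-<count>' suffix")
            add(str(rec.seq), int(m.group("count")), f"record {rec.id!r}")
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'sequence<TAB>count'")
            seq_raw, count_raw = parts
            try:
                count = int(count_raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: count {count_raw!r} is not an integer") from exc
            add(seq_raw, count, f"{path}:{lineno}")
    if not counts:
        raise FormatError(f"no tags found in {path}")
    return [TagRecord(sequence=s, count=counts[s]) for s in order]


def write_tags(tags: Iterable[TagRecord], path: str | Path) -> None:
    """Write tags as canonical two-column TSV (sequence, count)."""
    with open(path, "w", newline="\n") as fh:
        for tag in tags:
            fh.write(f"{tag.sequence}\t{tag.count}\n")


# ---------------------------------------------------------------------------
# Microarray signal tables

_THOUSANDS_RE = re.compile(r"^-?\d{1,3}(,\d{3})+(\.\d+)?$")


def _clean_numeric(value: object, column: str) -> float:
    """Parse a numeric cell, stripping '1,192'-style thousands separators."""
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if _THOUSANDS_RE.match(s):
        s = s.replace(",", "")
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {value!r} in column {column!r}") from exc


def read_signal_table(path: str | Path) -> list[SignalRow]:
    """Read a two-channel signal CSV into :class:`SignalRow` objects.

    Required columns: probe_id, mirna, channel, replicate, fg, bg_mean,
    bg_sd.  Numeric cells may carry thousands separators.
    """
    df = pd.read_csv(path, dtype=str)
    for col in SIGNAL_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"signal table {path} is missing required column {col!r}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            SignalRow(
                probe_id=str(rec.probe_id),
                mirna=str(rec.mirna),
                channel=str(rec.channel).strip(),
                replicate=int(_clean_numeric(rec.replicate, "replicate")),
                fg=_clean_numeric(rec.fg, "fg"),
                bg_mean=_clean_numeric(rec.bg_mean, "bg_mean"),
                bg_sd=_clean_numeric(rec.bg_sd, "bg_sd"),
            )
        )
    return rows


def write_signal_table(rows: Iterable[SignalRow], path: str | Path) -> None:
    """Write signal rows as CSV with the canonical column order."""
    df = pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "mirna": r.mirna,
                "channel": r.channel,
                "replicate": r.replicate,
                "fg": r.fg,
                "bg_mean": r.bg_mean,
                "bg_sd": r.bg_sd,
            }
            for r in rows
        ],
        columns=list(SIGNAL_TABLE_COLUMNS),
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Target tables


def write_target_table(rows: Iterable[TargetTableRow], path: str | Path) -> None:
    """Write a target table as TSV in the published column order.

    Ranges are rendered ``start-end`` (1-based inclusive).
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(TARGET_TABLE_COLUMNS) + "\n")
        for r in rows:
            score = f"{r.score:g}"
            fh.write(
                "\t".join(
                    [
                        r.family,
                        r.mirna,
                        r.annotation,
                        r.transcript,
                        score,
                        f"{r.start}-{r.end}",
                        str(r.cleavage_site),
                        r.category,
                    ]
                )
                + "\n"
            )


def read_target_table(path: str | Path) -> list[TargetTableRow]:
    """Read back a TSV target table written by :func:`write_target_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in TARGET_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"target table {path} is missing required column {col!r}")
    rows = []
    for rec in df.itertuples(index=False):
        m = re.match(r"^(\d+)-(\d+)$", rec.range)
        if not m:
            raise FormatError(f"malformed range {rec.range!r} in {path}")
        rows.append(
            TargetTableRow(
                family=rec.family,
                mirna=rec.mirna,
                transcript=rec.transcript,
                annotation=rec.annotation,
                score=float(rec.score),
                start=int(m.group(1)),
                end=int(m.group(2)),
                cleavage_site=int(rec.cleavage_site),
                category=rec.category,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# qPCR Ct tables

CT_TABLE_COLUMNS = ("sample", "assay", "experiment", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct CSV (sample, assay, experiment, ct)."""
    df = pd.read_csv(path, dtype={"sample": str, "assay": str})
    for col in CT_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"Ct table {path} is missing required column {col!r}")
    df["experiment"] = df["experiment"].astype(int)
    df["ct"] = df["ct"].astype(float)
    return df[list(CT_TABLE_COLUMNS)]
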