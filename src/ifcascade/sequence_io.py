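"""Sequence and annotation I/O with fixed coordinate conventions.

All internal coordinates are 0-based and half-open on the forward strand of
the reference sequence.  Offsets relative to a transcription start site
(TSS) are signed, gene-strand-relative integers: negative values lie
upstream of the TSS in the gene's direction of transcription.  Emitted BED
is 0-based half-open; human-readable reports produced by the command-line
layer are 1-based.

BED6 input is interpreted as 0-based half-open; GFF3 as 1-based closed and
converted on read.  For a ``+`` strand feature the TSS is the feature start;
for a ``-`` strand feature it is the last base of the feature (0-based
``end - 1``).
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Malformed sequence or annotation input."""


def normalize_sequence(seq: str, *, strict: bool = False, name: str = "?") -> str:
    """Uppercase ``seq`` and collapse non-ACGTN characters to ``N``.

    In strict mode any character outside the A/C/G/T/N alphabet raises
    :class:`SequenceError` instead of being normalized.
    """
    s = seq.upper()
    if set(s) <= NUCLEOTIDES:
        return s
    bad = sorted(set(s) - NUCLEOTIDES)
    if strict:
        raise SequenceError(f"sequence {name!r} contains non-ACGTN characters: {bad}")
    logger.warning("sequence %r: normalizing non-ACGTN characters %s to N", name, bad)
    return "".join(c if c in NUCLEOTIDES else "N" for c in s)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    if not set(seq) <= NUCLEOTIDES:
        raise SequenceError(f"invalid characters in sequence: {sorted(set(seq) - NUCLEOTIDES)}")
    return seq.translate(_RC_TABLE)[::-1]


class GenomeSequences(Mapping[str, str]):
    """Named nucleotide sequences — the substrate for every scan.

    Behaves as an ordered, read-only mapping of sequence name to uppercase
    A/C/G/T/N string.  Names must be unique and non-empty; sequences must
    be non-empty.
    """

    def __init__(self, records: Mapping[str, str], *, strict: bool = False):
        self._records: dict[str, str] = {}
        for name, seq in records.items():
            if not name:
                raise SequenceError("empty sequence name")
            if name in self._records:
                raise SequenceError(f"duplicate sequence name {name!r}")
            if not seq:
                raise SequenceError(f"sequence {name!r} is empty")
            self._records[name] = normalize_sequence(seq, strict=strict, name=name)

    def __getitem__(self, name: str) -> str:
        return self._records[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> dict[str, str]:
        return dict(self._records)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._records.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenomeSequences({self.lengths()})"


def read_fasta(path: str | Path, *, strict: bool = False) -> GenomeSequences:
    """Read a FASTA file into :class:`GenomeSequences`.

    Record order is preserved; duplicate headers are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise SequenceError(f"duplicate FASTA record name {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return GenomeSequences(records, strict=strict)


def write_fasta(genome: GenomeSequences, path: str | Path, *, width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    path = Path(path)
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass(frozen=True)
class TssRecord:
    """A gene's transcription start site on the forward coordinate axis."""

    gene_id: str
    seq_name: str
    tss: int  # 0-based position of the TSS base
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise SequenceError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise SequenceError(f"gene {self.gene_id!r}: negative TSS coordinate")


@dataclass(frozen=True)
class PromoterInterval:
    """Promoter window around a TSS, 0-based half-open, clipped to the sequence."""

    gene_id: str
    seq_name: str
    start: int
    end: int
    tss: int

    def __post_init__(self) -> None:
        if not (self.start <= self.tss < self.end):
            raise SequenceError(f"promoter of {self.gene_id!r} does not contain its TSS")


def _parse_bed6(lines: list[tuple[int, list[str]]]) -> list[TssRecord]:
    out = []
    for lineno, fields in lines:
        if len(fields) < 6:
            raise SequenceError(f"BED line {lineno}: expected >=6 fields, got {len(fields)}")
        seq_name, start, end, name, _score, strand = fields[:6]
        start_i, end_i = int(start), int(end)
        if strand not in {"+", "-"}:
            raise SequenceError(f"BED line {lineno}: missing or invalid strand {strand!r}")
        tss = start_i if strand == "+" else end_i - 1
        out.append(TssRecord(name, seq_name, tss, strand))
    return out


def _gff_attr(attrs: str, keys: tuple[str, ...] = ("ID", "gene_id", "Name")) -> str | None:
    for part in attrs.strip().strip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def _parse_gff3(lines: list[tuple[int, list[str]]], feature_types: set[str] | None) -> list[TssRecord]:
    out = []
    for lineno, fields in lines:
        if len(fields) < 9:
            raise SequenceError(f"GFF3 line {lineno}: expected 9 fields, got {len(fields)}")
        seq_name, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
        if feature_types is not None and ftype not in feature_types:
            continue
        if strand not in {"+", "-"}:
            raise SequenceError(f"GFF3 line {lineno}: missing or invalid strand {strand!r}")
        # GFF3 is 1-based closed: forward TSS = start-1; reverse TSS = end-1 (both 0-based).
        start_i, end_i = int(start), int(end)
        tss = start_i - 1 if strand == "+" else end_i - 1
        gene_id = _gff_attr(attrs) or f"feature{lineno}"
        out.append(TssRecord(gene_id, seq_name, tss, strand))
    return out


def read_tss(
    path: str | Path,
    fmt: str = "bed",
    *,
    genome: GenomeSequences | None = None,
    feature_types: set[str] | None = None,
) -> list[TssRecord]:
    """Read TSS records from a BED6 or GFF3 file.

    Parameters
    ----------
    fmt:
        ``"bed"`` (0-based half-open) or ``"gff3"`` (1-based closed,
        converted on read).
    genome:
        When given, records whose TSS falls outside the named sequence are
        rejected with a logged warning; unknown sequence names are errors.
    feature_types:
        For GFF3, restrict to these feature types (default: all rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    lines: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith(("track", "browser")):
            continue
        lines.append((lineno, line.split("\t") if "\t" in line else line.split()))
    if fmt in {"bed", "bed6"}:
        records = _parse_bed6(lines)
    elif fmt in {"gff", "gff3"}:
        records = _parse_gff3(lines, feature_types)
    else:
        raise ValueError(f"unknown TSS format {fmt!r} (expected 'bed' or 'gff3')")

    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise SequenceError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)

    if genome is not None:
        kept = []
        for rec in records:
            if rec.seq_name not in genome:
                raise SequenceError(f"gene {rec.gene_id!r}: unknown sequence {rec.seq_name!r}")
            if rec.tss >= len(genome[rec.seq_name]):
                logger.warning("gene %r: TSS %d outside %r; record rejected", rec.gene_id, rec.tss, rec.seq_name)
                continue
            kept.append(rec)
        records = kept
    return records


def build_promoters(
    tss_records: list[TssRecord],
    half_width: int = 2000,
    genome: GenomeSequences | None = None,
) -> list[PromoterInterval]:
    """Build ±``half_width`` promoter intervals around each TSS.

    The interval is ``[tss - half_width, tss + half_width + 1)`` so that a
    site exactly ``half_width`` bp downstream is still inside, mirroring the
    inclusive "within 2 kb of a TSS" promoter rule.  Intervals are clipped
    to sequence bounds when a genome is supplied.
    """
    if half_width <= 0:
        raise ValueError(f"half_width must be positive, got {half_width}")
    out = []
    for rec in tss_records:
        start = max(0, rec.tss - half_width)
        end = rec.tss + half_width + 1
        if genome is not None:
            if rec.seq_name not in genome:
                raise SequenceError(f"gene {rec.gene_id!r}: unknown sequence {rec.seq_name!r}")
            end = min(end, len(genome[rec.seq_name]))
        out.append(PromoterInterval(rec.gene_id, rec.seq_name, start, end, rec.tss))
    return out


def write_tss_bed(tss_records: list[TssRecord], path: str | Path) -> None:
    """Write TSS records as single-base BED6 intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for rec in tss_records:
            fh.write(f"{rec.seq_name}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_id}\t0\t{rec.strand}\n")
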