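"""Genome and interval-annotation I/O.

All coordinates inside the package are 0-based half-open.  Conversion from
1-based inclusive dialects (RepeatMasker ``.out``, GFF3) happens here and
only here.  Soft-masked (lowercase) bases are uppercased and are *not*
interpreted as repeats; repeat status comes exclusively from annotation
files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: uppercase sequence over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.chrom_id!r}")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.chrom_id!r} contains illegal symbol(s): "
                f"{', '.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IntervalAnnotation:
    """Labelled genomic interval (repeat class or gene id), 0-based half-open."""

    chrom_id: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom_id}:{self.start}-{self.end}"
            )
        if not self.label:
            raise ValueError(
                f"empty label for interval {self.chrom_id}:{self.start}-{self.end}"
            )


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence records.

    Sequences are uppercased; record order is preserved.  Duplicate headers
    or illegal symbols raise ``ValueError`` naming the offending record.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicated FASTA header: {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def genome_dict(genome: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    return {g.chrom_id: g for g in genome}


def _parse_bed(path: Path) -> list[IntervalAnnotation]:
    out: list[IntervalAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            out.append(IntervalAnnotation(fields[0], start, end, fields[3]))
    return out


def _parse_repeatmasker_out(path: Path) -> list[IntervalAnnotation]:
    # RepeatMasker .out: 3 header lines, then whitespace-delimited rows with
    # query sequence in col 5, begin/end (1-based inclusive) in cols 6-7 and
    # repeat class/family in col 11.
    out: list[IntervalAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
        try:
            begin, end = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
        out.append(IntervalAnnotation(fields[4], begin - 1, end, fields[10]))
    return out


def read_repeat_annotation(
    path: str | Path, dialect: str = "bed"
) -> list[IntervalAnnotation]:
    """Read repeat intervals; label is the repeat class/family string.

    ``dialect`` is ``"bed"`` (already half-open) or ``"repeatmasker_out"``
    (1-based inclusive, shifted here).
    """
    path = Path(path)
    if dialect == "bed":
        out = _parse_bed(path)
    elif dialect == "repeatmasker_out":
        out = _parse_repeatmasker_out(path)
    else:
        raise ValueError(f"unknown repeat dialect: {dialect!r}")
    if not out:
        logger.warning("no repeat intervals parsed from %s", path)
    return out


def read_gene_annotation(
    path: str | Path, dialect: str = "bed"
) -> list[IntervalAnnotation]:
    """Read gene intervals; label is the gene identifier.

    For GFF3 only rows of type ``gene`` are kept; the gene id is taken from
    the ``ID=`` attribute (falling back to ``Name=``, then the raw attribute
    column).
    """
    path = Path(path)
    if dialect == "bed":
        out = _parse_bed(path)
    elif dialect == "gff3":
        out = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
                if fields[2] != "gene":
                    continue
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer coordinate"
                    ) from exc
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                label = attrs.get("ID") or attrs.get("Name") or fields[8]
                out.append(IntervalAnnotation(fields[0], start - 1, end, label))
    else:
        raise ValueError(f"unknown gene dialect: {dialect!r}")
    if not out:
        logger.warning("no gene intervals parsed from %s", path)
    return out


def write_bed(intervals: Iterable[IntervalAnnotation], path: str | Path,
              header: str | None = None) -> None:
    """Write intervals as BED4 (0-based half-open)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for iv in intervals:
            fh.write(f"{iv.chrom_id}\t{iv.start}\t{iv.end}\t{iv.label}\n")
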