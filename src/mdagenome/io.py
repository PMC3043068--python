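"""FASTA/FASTQ reading and writing plus barcode demultiplexing.

Record parsing goes through Biopython's SeqIO; this module only adapts
its output to the package's :class:`~mdagenome.records.SequenceRecord`
model and adds the demultiplexing step (one mismatch allowed in a 10 bp
barcode by default).  Qualities are Phred+33.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO

from .records import BarcodeSpec, ReadSet, SequenceRecord

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A sequence file could not be parsed."""


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased.  An empty file yields an empty list.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    # Pre-scan for the two malformations Biopython silently tolerates,
    # so errors can name the offending line.
    with open(path) as fh:
        in_record = False
        have_seq = False
        header_line = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if in_record and not have_seq:
                    raise ParseError(
                        f"{path}: empty sequence for header at line {header_line}"
                    )
                if line == ">":
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                in_record, have_seq, header_line = True, False, lineno
            elif line.strip():
                if not in_record:
                    raise ParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                have_seq = True
        if in_record and not have_seq:
            raise ParseError(f"{path}: empty sequence for header at line {header_line}")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def read_fastq(path: PathLike, source_label: str = "unlabeled") -> ReadSet:
    """Read a 4-line-record FASTQ file (Phred+33) into a ReadSet."""
    path = Path(path)
    reads: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = np.array(rec.letter_annotations["phred_quality"], dtype=np.int16)
            reads.append(SequenceRecord(rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return ReadSet(reads, source_label=source_label)


def write_fastq(readset: Union[ReadSet, Iterable[SequenceRecord]], path: PathLike) -> None:
    """Write reads as FASTQ; reads lacking qualities get a uniform Q30."""
    reads = readset.reads if isinstance(readset, ReadSet) else list(readset)
    with open(path, "w") as fh:
        for rec in reads:
            if rec.quality is None:
                qual = "?" * len(rec.bases)  # '?' is Phred 30 at +33
            else:
                qual = "".join(chr(int(q) + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def read_barcode_manifest(path: PathLike, max_mismatch: int = 1) -> list[BarcodeSpec]:
    """Read a two-column (sample, barcode) whitespace-separated manifest."""
    specs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}: expected 2 columns at line {lineno}")
            specs.append(BarcodeSpec(parts[0], parts[1], max_mismatch))
    return specs


def demultiplex(
    reads: ReadSet, specs: list[BarcodeSpec]
) -> tuple[dict[str, ReadSet], ReadSet]:
    """Assign reads to samples by their leading barcode and trim it.

    A read is assigned to the sample whose barcode is within
    ``max_mismatch`` Hamming distance of the read's first ``len(barcode)``
    bases; the barcode bases are removed from assigned reads.  Returns
    (sample -> ReadSet, rejected ReadSet).

    Barcode sets must be mutually separated by Hamming distance
    > 2 * max_mismatch so assignment is unambiguous.
    """
    if not specs:
        raise ValueError("no barcode specs given")
    blen = len(specs[0].barcode)
    if any(len(s.barcode) != blen for s in specs):
        raise ValueError("all barcodes must have the same length")
    if len({s.sample for s in specs}) != len(specs):
        raise ValueError("duplicate sample names in barcode specs")
    for a, b in itertools.combinations(specs, 2):
        d = _hamming(a.barcode, b.barcode)
        if d <= a.max_mismatch + b.max_mismatch:
            raise ValueError(
                f"barcodes {a.barcode} ({a.sample}) and {b.barcode} ({b.sample}) "
                f"are Hamming distance {d} apart; ambiguous assignment possible"
            )
    assigned: dict[str, list[SequenceRecord]] = {s.sample: [] for s in specs}
    rejected: list[SequenceRecord] = []
    for rec in reads:
        prefix = rec.bases[:blen]
        hit = None
        if len(prefix) == blen:
            for spec in specs:
                if _hamming(prefix, spec.barcode) <= spec.max_mismatch:
                    hit = spec
                    break
        if hit is None:
            rejected.append(rec)
        else:
            qual = None if rec.quality is None else rec.quality[blen:]
            if len(rec.bases) > blen:
                assigned[hit.sample].append(
                    SequenceRecord(rec.id, rec.bases[blen:], qual)
                )
            else:
                rejected.append(rec)  # nothing left after trimming
    out = {
        sample: ReadSet(recs, source_label=sample) for sample, recs in assigned.items()
    }
    return out, ReadSet(rejected, source_label=f"{reads.source_label}:rejected")
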