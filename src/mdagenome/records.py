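"""Core sequence containers shared by every pipeline stage.

Coordinates are 0-based, half-open throughout the package; emitted text
formats use each format's native convention (documented per writer).
Bases outside {A, C, G, T} are normalised to ``N``; every composition
statistic excludes N from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def clean_bases(seq: str) -> str:
    """Uppercase ``seq`` and map any ambiguity code to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    bases: str
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.bases = clean_bases(self.bases)
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=np.int16)
            if len(self.quality) != len(self.bases):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.bases)}"
                )
            if (self.quality < 0).any():
                raise ValueError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, new_id: Optional[str] = None) -> "SequenceRecord":
        q = None if self.quality is None else self.quality[::-1].copy()
        return SequenceRecord(new_id or self.id, revcomp(self.bases), q)


@dataclass
class ReadSet:
    """An ordered collection of reads from one dataset (a cell or the bulk).

    ``pairing`` maps read id -> mate read id and must be symmetric
    (an involution without fixed points).
    """

    reads: list[SequenceRecord] = field(default_factory=list)
    source_label: str = "unlabeled"
    pairing: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if not self.source_label:
            raise ValueError("source_label must be non-empty")
        ids = [r.id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids in ReadSet {self.source_label!r}")
        if self.pairing is not None:
            known = set(ids)
            for a, b in self.pairing.items():
                if a == b:
                    raise ValueError(f"read {a!r} paired with itself")
                if self.pairing.get(b) != a:
                    raise ValueError(f"pairing not symmetric at {a!r}/{b!r}")
                if a not in known or b not in known:
                    raise ValueError(f"pairing references unknown read {a!r} or {b!r}")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.reads)

    def by_id(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.reads}

    def subset(self, ids: set[str], source_label: Optional[str] = None) -> "ReadSet":
        """ReadSet restricted to ``ids``; pairing kept where both mates survive."""
        reads = [r for r in self.reads if r.id in ids]
        pairing = None
        if self.pairing:
            pairing = {
                a: b for a, b in self.pairing.items() if a in ids and b in ids
            }
            pairing = pairing or None
        return ReadSet(reads, source_label or self.source_label, pairing)


@dataclass(frozen=True)
class BarcodeSpec:
    """A sample barcode expected at the 5' end of each read."""

    sample: str
    barcode: str
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcode", clean_bases(self.barcode))
        if not self.barcode:
            raise ValueError("barcode must be non-empty")
        if self.max_mismatch >= len(self.barcode):
            raise ValueError("max_mismatch must be smaller than the barcode length")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be nonnegative")
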