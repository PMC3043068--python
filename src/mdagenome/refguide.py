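"""Reference-guided orientation and ordering of assembly elements, plus
contaminant screening of contigs.

Orientation of each element is the strand whose summed alignment score
against the reference is larger; elements are then ordered by the
hit-length-weighted mean subject position of the hits co-oriented with
the chosen strand.  "Position" of a hit is the midpoint of its subject
interval (symmetric and invariant to splitting a hit in two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignmentHit, KmerIndex, MapCriteria, Scoring, align_to_index
from .records import SequenceRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass
class ElementLayout:
    element_id: str
    orientation: str  # '+' or '-'
    order_key: Optional[float]  # hit-length-weighted mean subject midpoint
    placed: bool
    tie: bool = False  # orientation was a tie (defaulted to '+')

    def __post_init__(self) -> None:
        if self.placed != (self.order_key is not None):
            raise ValueError("order_key must be defined iff placed")


def _element_hits(
    element: SequenceRecord,
    index: KmerIndex,
    scoring: Scoring,
    q_stride: int,
) -> list[AlignmentHit]:
    return align_to_index(element, index, scoring, q_stride=q_stride)


def orient_elements(
    elements: Sequence[SequenceRecord],
    reference: SequenceRecord,
    scoring: Scoring = Scoring(),
    q_stride: int = 4,
    hits_by_element: Optional[dict[str, list[AlignmentHit]]] = None,
) -> dict[str, str]:
    """Choose each element's orientation by maximising the summed
    alignment score to the reference.

    Hits with strand '+' support keeping the element forward; '-' hits
    support reverse-complementing it.  Ties (including no hits at all)
    default to '+' and are logged.
    """
    if not reference.bases:
        raise ValueError("reference must be non-empty")
    if hits_by_element is None:
        index = KmerIndex([reference])
        hits_by_element = {
            e.id: _element_hits(e, index, scoring, q_stride) for e in elements
        }
    orientations = {}
    for e in elements:
        fwd = sum(h.score for h in hits_by_element.get(e.id, []) if h.strand == "+")
        rev_ = sum(h.score for h in hits_by_element.get(e.id, []) if h.strand == "-")
        if fwd == rev_:
            logger.warning("element %s: orientation tie (%.0f); defaulting to +", e.id, fwd)
            orientations[e.id] = "+"
        else:
            orientations[e.id] = "+" if fwd > rev_ else "-"
    return orientations


def order_elements(
    elements: Sequence[SequenceRecord],
    reference: SequenceRecord,
    orientations: Optional[dict[str, str]] = None,
    scoring: Scoring = Scoring(),
    q_stride: int = 4,
) -> list[ElementLayout]:
    """Order elements along the reference.

    Using only hits whose strand matches the element's chosen
    orientation, order_key = sum(hit subject length * subject midpoint)
    / sum(hit subject length).  Elements are sorted ascending by
    order_key; elements with no co-oriented hits are unplaced and are
    appended after the placed ones in input order.
    """
    index = KmerIndex([reference])
    hits_by_element = {
        e.id: _element_hits(e, index, scoring, q_stride) for e in elements
    }
    if orientations is None:
        orientations = orient_elements(
            elements, reference, scoring, q_stride, hits_by_element
        )
    placed, unplaced = [], []
    for e in elements:
        o = orientations[e.id]
        hits = [h for h in hits_by_element.get(e.id, []) if h.strand == o]
        if not hits:
            unplaced.append(ElementLayout(e.id, o, None, placed=False))
            continue
        wsum = sum(h.s_end - h.s_start for h in hits)
        key = sum((h.s_end - h.s_start) * (h.s_start + h.s_end) / 2 for h in hits) / wsum
        placed.append(ElementLayout(e.id, o, float(key), placed=True))
    placed.sort(key=lambda el: (el.order_key, el.element_id))
    return placed + unplaced


def layout_from_hits(
    element_id: str,
    orientation: str,
    hits: Sequence[AlignmentHit],
) -> ElementLayout:
    """Order key from an explicit hit list (useful with external aligners)."""
    hits = [h for h in hits if h.strand == orientation]
    if not hits:
        return ElementLayout(element_id, orientation, None, placed=False)
    wsum = sum(h.s_end - h.s_start for h in hits)
    key = sum((h.s_end - h.s_start) * (h.s_start + h.s_end) / 2 for h in hits) / wsum
    return ElementLayout(element_id, orientation, float(key), placed=True)


def contaminant_screen(
    contigs: Sequence[SequenceRecord],
    contaminant_references: Sequence[SequenceRecord],
    criteria: MapCriteria = MapCriteria(),
    coverage_threshold: float = 0.50,
    scoring: Scoring = Scoring(),
    q_stride: int = 4,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Exclude contigs that are mostly contaminant sequence.

    A contig is excluded iff hits to any single contaminant reference
    meeting ``criteria`` cover at least ``coverage_threshold`` of its
    length.  Returns (kept, excluded) where each exclusion names the
    offending reference.
    """
    if not contaminant_references:
        return list(contigs), []
    index = KmerIndex(list(contaminant_references))
    kept, excluded = [], []
    for contig in contigs:
        hits = [
            h
            for h in align_to_index(contig, index, scoring, q_stride=q_stride)
            if h.identity >= criteria.min_identity and h.length >= criteria.min_length
        ]
        worst_ref, worst_cov = None, 0.0
        for ref in contaminant_references:
            ivals = sorted(
                (h.q_start, h.q_end) for h in hits if h.subject_id == ref.id
            )
            cov = 0
            last = -1
            for a, b in ivals:
                a = max(a, last)
                if b > a:
                    cov += b - a
                    last = b
            frac = cov / len(contig.bases)
            if frac > worst_cov:
                worst_ref, worst_cov = ref.id, frac
        if worst_cov >= coverage_threshold:
            excluded.append((contig, worst_ref))
        else:
            kept.append(contig)
    return kept, excluded


def write_layout_tsv(layouts: Sequence[ElementLayout], path) -> None:
    with open(path, "w") as fh:
        fh.write("# element\torientation\torder_key\tplaced\n")
        for el in layouts:
            key = f"{el.order_key:.1f}" if el.placed else "NA"
            fh.write(f"{el.element_id}\t{el.orientation}\t{key}\t{el.placed}\n")


def ordered_fasta_records(
    layouts: Sequence[ElementLayout], elements: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Elements in layout order, reverse-complemented per orientation."""
    by_id = {e.id: e for e in elements}
    out = []
    for el in layouts:
        e = by_id[el.element_id]
        out.append(e.reverse_complement() if el.orientation == "-" else e)
    return out
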