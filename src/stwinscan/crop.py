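"""Stwintron-to-canonical-intron derivation paths.

Three documented paths are modelled: type-1 (loss of the external intron,
keeping the internal one), type-2 (microhomology-mediated deletion of the
central region between the two 10-nt palindrome copies, retaining the 5'
copy), and long-intron (one-step excision substrate: the whole feature
minus its leading G1). Breakpoints of an observed parent/derivative pair
are recovered from a global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .family import global_align
from .scanner import Stwintron, find_canonical_introns
from .seqcore import GenomicSequence, Interval, IntronModel
from .symmetry import PalindromeHit, find_palindrome_hits


class NotACropPair(ValueError):
    """Raised when no crop-compatible deletion relates two sequences."""


@dataclass
class CropEvent:
    parent_id: str
    path: str  # type1 | type2 | long_intron
    breakpoint5: Optional[int]
    breakpoint3: Optional[int]
    retained_palindrome: Optional[Interval]
    product: str
    product_valid_intron: bool
    frame_note: str = "none"  # none | g1_exonised_requires_compensation


def _is_full_span_intron(product: str, model: IntronModel) -> bool:
    if len(product) < model.min_intron_len or len(product) > model.max_intron_len:
        return False
    hits = find_canonical_introns(
        GenomicSequence(id="product", residues=product), model, mode="exhaustive"
    )
    return any(h.location.start == 0 and h.location.end == len(product) for h in hits)


def _section_palindromes(
    parent_seq: str, stw: Stwintron, min_matches: int = 8
) -> tuple[list[PalindromeHit], list[PalindromeHit]]:
    """Palindrome hits split by the template's internal/external partition."""
    i_start, i_end = stw.internal_span
    hits = find_palindrome_hits(parent_seq, min_matches=min_matches)
    internal = [h for h in hits if i_start <= h.location.start and h.location.end <= i_end]
    external = [h for h in hits if h.location.start >= i_end]
    return internal, external


def predict_type2_crop(
    parent_id: str,
    parent_seq: str,
    stw: Stwintron,
    model: IntronModel,
    min_matches: int = 8,
) -> CropEvent:
    """MMEJ central deletion between the two palindrome copies.

    The deletion runs from the end of the 5' copy to the end of the 3'
    copy, so the deleted genomic span keeps exactly one (the 5'-positioned)
    palindrome copy. The reported product is the resulting canonical
    intron: ``(parent[:end5] + parent[end3:])`` minus the leading G1, which
    is exonised by the transition and requires frame compensation.
    """
    parent_seq = parent_seq.upper()
    internal_hits, external_hits = _section_palindromes(parent_seq, stw, min_matches)
    if not internal_hits or not external_hits:
        raise NotACropPair(
            "type-2 crop needs one palindrome copy in the internal section "
            "and one in the external section"
        )
    # best-scoring copy per section; leftmost on ties
    five = max(internal_hits, key=lambda h: (h.matches, -h.location.start))
    three = max(external_hits, key=lambda h: (h.matches, -h.location.start))
    end5 = five.location.end
    end3 = three.location.end
    product = (parent_seq[:end5] + parent_seq[end3:])[1:]
    return CropEvent(
        parent_id=parent_id,
        path="type2",
        breakpoint5=end5,
        breakpoint3=end3,
        retained_palindrome=Interval("product", five.location.start - 1, end5 - 1),
        product=product,
        product_valid_intron=_is_full_span_intron(product, model),
        frame_note="g1_exonised_requires_compensation",
    )


def predict_type1_crop(
    parent_id: str, parent_seq: str, stw: Stwintron, model: IntronModel
) -> CropEvent:
    """External-intron loss: the product is the internal intron verbatim."""
    i_start, i_end = stw.internal_span
    product = parent_seq.upper()[i_start:i_end]
    return CropEvent(
        parent_id=parent_id,
        path="type1",
        breakpoint5=i_end,
        breakpoint3=len(parent_seq),
        retained_palindrome=None,
        product=product,
        product_valid_intron=_is_full_span_intron(product, model),
        frame_note="none",
    )


def predict_long_intron(
    parent_id: str, parent_seq: str, stw: Stwintron, model: IntronModel
) -> CropEvent:
    """One-step product: the whole feature minus its leading G1, excised as
    one long canonical intron (internal donor, external BP and acceptor)."""
    product = parent_seq.upper()[1:]
    return CropEvent(
        parent_id=parent_id,
        path="long_intron",
        breakpoint5=0,
        breakpoint3=1,
        retained_palindrome=None,
        product=product,
        product_valid_intron=_is_full_span_intron(product, model),
        frame_note="g1_exonised_requires_compensation",
    )


def _canonicalise_deletion(parent: str, bp5: int, bp3: int) -> tuple[int, int]:
    """Fix the placement of a deletion that is ambiguous across a
    microhomology: deletions [bp5+s, bp3+s) are sequence-equivalent for a
    range of shifts. The convention is the placement whose 5' breakpoint
    coincides with the end of a palindrome copy (the retained 5' copy);
    the aligner's placement is kept when no shift achieves that."""
    s_hi = 0
    while bp3 + s_hi < len(parent) and parent[bp5 + s_hi] == parent[bp3 + s_hi]:
        s_hi += 1
    s_lo = 0
    while bp5 + s_lo > 0 and parent[bp5 + s_lo - 1] == parent[bp3 + s_lo - 1]:
        s_lo -= 1
    pal_ends = {h.location.end for h in find_palindrome_hits(parent)}
    for s in range(s_lo, s_hi + 1):
        if bp5 + s in pal_ends:
            return bp5 + s, bp3 + s
    # a slide reaching the sequence end is an external-loss (suffix) deletion
    if bp3 + s_hi == len(parent):
        return bp5 + s_hi, bp3 + s_hi
    # mutated derivatives can break exact slides: snap to the nearest
    # palindrome end when one lies within the microhomology's reach
    near = [e for e in pal_ends if abs(e - bp5) <= 12 and 0 < e and bp3 + e - bp5 <= len(parent)]
    if near:
        e = min(near, key=lambda e: abs(e - bp5))
        return e, bp3 + e - bp5
    return bp5, bp3


def infer_crop_breakpoints(
    parent_id: str,
    parent_seq: str,
    derivative_seq: str,
    stw: Stwintron | None = None,
    model: IntronModel | None = None,
    min_deletion: int = 20,
) -> CropEvent:
    """Recover crop breakpoints by aligning a derivative to its parent.

    The single largest internal run of parent positions absent from the
    derivative is reported as the crop; the path is classified from which
    parent sections survive (central deletion -> type2; loss of the region
    downstream of the internal intron -> type1; otherwise long_intron when
    only the leading nucleotide is missing).
    """
    parent_seq = parent_seq.upper()
    derivative_seq = derivative_seq.upper()
    if not parent_seq or not derivative_seq:
        raise ValueError("empty input sequence")
    aln = global_align(parent_seq, derivative_seq)

    # runs of columns with a gap in the derivative = deleted parent spans
    runs: list[tuple[int, int]] = []
    pos = 0
    run_start = None
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y == "-":
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None:
                runs.append((run_start, pos))
                run_start = None
        if x != "-":
            pos += 1
    if run_start is not None:
        runs.append((run_start, pos))

    big = [r for r in runs if r[1] - r[0] >= min_deletion]
    if not big:
        raise NotACropPair(f"no deletion >= {min_deletion} nt between the sequences")
    bp5, bp3 = max(big, key=lambda r: r[1] - r[0])
    bp5, bp3 = _canonicalise_deletion(parent_seq, bp5, bp3)

    path = "type2"
    if stw is not None:
        i_start, i_end = stw.internal_span
        if bp3 >= len(parent_seq) - 3 and abs(bp5 - i_end) <= 5:
            path = "type1"
        elif bp5 <= i_end <= bp3:
            path = "type2"
    retained = None
    if path == "type2":
        hits = find_palindrome_hits(derivative_seq)
        if hits:
            best = max(hits, key=lambda h: (h.matches, -h.location.start))
            retained = Interval("product", best.location.start, best.location.end)
    valid = (
        _is_full_span_intron(derivative_seq, model) if model is not None else False
    )
    return CropEvent(
        parent_id=parent_id,
        path=path,
        breakpoint5=bp5,
        breakpoint3=bp3,
        retained_palindrome=retained,
        product=derivative_seq,
        product_valid_intron=valid,
        frame_note="g1_exonised_requires_compensation" if path != "type1" else "none",
    )
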