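"""Detection of canonical U2 introns and donor-disrupted (D1,2) twin introns.

A (D1,2) feature starts with G1 followed by a complete internal intron; once
the internal intron is excised, G1 fuses with the five nucleotides after the
internal acceptor to reconstitute a functional donor for the external intron.
Splice-site pairing follows intron definition: for each donor the shortest
satisfying intron wins, with ties broken by leftmost branch point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .seqcore import GenomicSequence, Interval, IntronModel, iupac_match, reverse_complement


@dataclass(frozen=True)
class CanonicalIntron:
    location: Interval
    donor_seq: str
    bp_location: Interval
    acceptor_seq: str
    phase: int | str = "unknown"

    def __len__(self) -> int:
        return len(self.location)


@dataclass(frozen=True)
class Stwintron:
    """A located (D1,2) feature.

    ``location`` spans the full complex intervening sequence starting at G1.
    ``internal`` carries genomic coordinates; ``external_virtual`` is the
    intron reconstructed after internal excision, located on the spliced
    frame whose position 0 is G1 (so its location is always [0, Le)).
    """

    location: Interval
    internal: CanonicalIntron
    external_virtual: CanonicalIntron
    central_signature: str
    a23_alternative: bool
    g1_offset: int = 0

    def __len__(self) -> int:
        return len(self.location)

    @property
    def internal_span(self) -> tuple[int, int]:
        """Internal intron start/end relative to the feature start."""
        return (
            self.internal.location.start - self.location.start,
            self.internal.location.end - self.location.start,
        )


Mode = Literal["intron-definition", "exhaustive"]


def _pattern_hits(seq: str, pattern: str, start: int = 0, end: int | None = None) -> list[int]:
    end = len(seq) if end is None else end
    k = len(pattern)
    return [
        i
        for i in range(start, min(end, len(seq) - k) + 1)
        if i + k <= len(seq) and iupac_match(pattern, seq[i : i + k])
    ]


def _introns_from_donor(
    seq: str,
    donor_start: int,
    model: IntronModel,
    donor_pattern: str,
    mode: Mode,
    seq_id: str,
    strand: str = "+",
) -> list[CanonicalIntron]:
    """All (or the minimal) introns starting at a validated donor position.

    Candidates are ordered by length ascending, then leftmost branch point;
    intron-definition mode returns only the first.
    """
    out: list[CanonicalIntron] = []
    d_len = len(donor_pattern)
    bp_len = len(model.bp_pattern)
    a_len = len(model.acceptor_pattern)
    max_len = min(model.max_intron_len, len(seq) - donor_start)
    for length in range(model.min_intron_len, max_len + 1):
        end = donor_start + length
        acc = seq[end - a_len : end]
        if not iupac_match(model.acceptor_pattern, acc):
            continue
        # branch point element: 6 nt, ending bp_to_acceptor_min..max nt
        # upstream of the acceptor element, fully inside the intron.
        bp_end_hi = end - a_len - model.bp_to_acceptor_min
        bp_end_lo = end - a_len - model.bp_to_acceptor_max
        found_bp: Optional[int] = None
        for bp_end in range(max(bp_end_lo, donor_start + d_len + bp_len), bp_end_hi + 1):
            bp_start = bp_end - bp_len
            if bp_start < donor_start + d_len:
                continue
            if iupac_match(model.bp_pattern, seq[bp_start:bp_end]):
                found_bp = bp_start
                break  # leftmost BP
        if found_bp is None:
            continue
        out.append(
            CanonicalIntron(
                location=Interval(seq_id, donor_start, end, strand),
                donor_seq=seq[donor_start : donor_start + d_len],
                bp_location=Interval(seq_id, found_bp, found_bp + bp_len, strand),
                acceptor_seq=acc,
            )
        )
        if mode == "intron-definition":
            break
    return out


def find_canonical_introns(
    seq: GenomicSequence,
    model: IntronModel,
    region: Interval | None = None,
    mode: Mode = "intron-definition",
    donor_pattern: str | None = None,
) -> list[CanonicalIntron]:
    """Scan for canonical introns satisfying the motif grammar.

    In intron-definition mode only the minimal-length satisfying intron is
    reported per donor position; exhaustive mode reports every candidate.
    """
    s = seq.residues
    lo, hi = (region.start, region.end) if region is not None else (0, len(s))
    pattern = donor_pattern or model.donor_pattern
    out: list[CanonicalIntron] = []
    for d in _pattern_hits(s, pattern, lo, hi - len(pattern)):
        out.extend(
            intr
            for intr in _introns_from_donor(s, d, model, pattern, mode, seq.id)
            if intr.location.end <= hi
        )
    return out


def _internal_donor_patterns(model: IntronModel) -> list[str]:
    pats = [model.donor_pattern]
    if model.allow_gc_internal_donor:
        pats.append(model.gc_donor_pattern)
    return pats


def find_d12_stwintrons(
    seq: GenomicSequence,
    model: IntronModel,
    mode: Mode = "intron-definition",
) -> list[Stwintron]:
    """Detect (D1,2) stwintron candidates on the forward strand of *seq*.

    For each G1 position the candidate internal introns are tried shortest
    first; the first internal excision that reconstitutes a valid donor and
    a valid external intron defines the feature (all combinations are
    reported in exhaustive mode).
    """
    s = seq.residues
    d_len = len(model.donor_pattern)
    out: list[Stwintron] = []
    for g1 in range(len(s) - 1):
        if s[g1] != "G":
            continue
        internals: list[CanonicalIntron] = []
        for pat in _internal_donor_patterns(model):
            if g1 + 1 + d_len <= len(s) and iupac_match(pat, s[g1 + 1 : g1 + 1 + d_len]):
                internals.extend(
                    _introns_from_donor(s, g1 + 1, model, pat, "exhaustive", seq.id)
                )
        # shortest internal first, BP position breaks ties
        internals.sort(key=lambda c: (len(c), c.bp_location.start, c.location.end))
        for internal in internals:
            stw = _try_external(seq, g1, internal, model)
            if stw is not None:
                out.append(stw)
                if mode == "intron-definition":
                    break
    return out


def _try_external(
    seq: GenomicSequence, g1: int, internal: CanonicalIntron, model: IntronModel
) -> Stwintron | None:
    s = seq.residues
    d_len = len(model.donor_pattern)
    int_end = internal.location.end
    if int_end + d_len - 1 > len(s):
        return None
    reconstructed_donor = s[g1] + s[int_end : int_end + d_len - 1]
    if not iupac_match(model.donor_pattern, reconstructed_donor):
        return None
    # splinter frame: G1 followed by everything downstream of the internal
    splinter_tail = s[g1] + s[int_end:]
    ext_candidates = _introns_from_donor(
        splinter_tail, 0, model, model.donor_pattern, "intron-definition", seq.id
    )
    if not ext_candidates:
        return None
    ext = ext_candidates[0]
    ext_len = len(ext)
    genomic_end = int_end + ext_len - 1  # G1 contributes 1 nt upstream
    location = Interval(seq.id, g1, genomic_end)
    central = s[int_end - 2 : int_end + 1]
    a23 = genomic_end < len(s) and s[genomic_end] == "G"
    return Stwintron(
        location=location,
        internal=internal,
        external_virtual=ext,
        central_signature=central,
        a23_alternative=a23,
    )


def validate_stwintron(seq: GenomicSequence, stw: Stwintron, model: IntronModel) -> bool:
    """Re-derive the external intron after excising the internal one."""
    s = seq.residues
    spliced = s[stw.location.start] + s[stw.internal.location.end : stw.location.end]
    hits = find_canonical_introns(GenomicSequence(id="check", residues=spliced), model)
    return any(h.location.start == 0 and len(h) == len(spliced) for h in hits)


@dataclass
class ScanResult:
    stwintrons: list[Stwintron] = field(default_factory=list)
    introns: list[CanonicalIntron] = field(default_factory=list)


def _map_to_forward(iv: Interval, seq_len: int) -> Interval:
    return Interval(iv.seq_id, seq_len - iv.end, seq_len - iv.start, "-")


def _stw_to_forward(stw: Stwintron, seq_len: int) -> Stwintron:
    return Stwintron(
        location=_map_to_forward(stw.location, seq_len),
        internal=CanonicalIntron(
            location=_map_to_forward(stw.internal.location, seq_len),
            donor_seq=stw.internal.donor_seq,
            bp_location=_map_to_forward(stw.internal.bp_location, seq_len),
            acceptor_seq=stw.internal.acceptor_seq,
        ),
        external_virtual=stw.external_virtual,
        central_signature=stw.central_signature,
        a23_alternative=stw.a23_alternative,
    )


def scan_genome(
    sequences: Iterable[GenomicSequence],
    model: IntronModel,
    both_strands: bool = True,
    collect_introns: bool = False,
) -> ScanResult:
    """Batch driver: stwintron (and optionally intron) calls over a genome.

    Reverse-strand hits are reported on the forward coordinate axis with
    strand '-'. Output ordering is deterministic: (seq_id, start, strand).
    """
    result = ScanResult()
    for gs in sequences:
        result.stwintrons.extend(find_d12_stwintrons(gs, model))
        if collect_introns:
            result.introns.extend(find_canonical_introns(gs, model))
        if both_strands:
            rc = GenomicSequence(id=gs.id, residues=reverse_complement(gs.residues))
            for stw in find_d12_stwintrons(rc, model):
                result.stwintrons.append(_stw_to_forward(stw, len(gs)))
            if collect_introns:
                for intr in find_canonical_introns(rc, model):
                    result.introns.append(
                        CanonicalIntron(
                            location=_map_to_forward(intr.location, len(gs)),
                            donor_seq=intr.donor_seq,
                            bp_location=_map_to_forward(intr.bp_location, len(gs)),
                            acceptor_seq=intr.acceptor_seq,
                        )
                    )
    result.stwintrons.sort(key=lambda f: (f.location.seq_id, f.location.start, f.location.strand))
    result.introns.sort(key=lambda f: (f.location.seq_id, f.location.start, f.location.strand))
    return result
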