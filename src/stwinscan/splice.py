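"""Two-step excision simulation and junction verification queries.

The internal intron is removed first, yielding the splinter intermediate
(external intron still present); the external intron is then removed to
give the mature product. The alternative one-step product removes the
feature minus its leading G1, which stays exonic and shifts the frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .scanner import Stwintron

logger = logging.getLogger(__name__)


@dataclass
class SpliceProducts:
    pre_mrna: str
    splinter: str
    mature: str
    alt_mature: str
    frameshift: Optional[bool] = None


@dataclass
class JunctionQuery:
    name: str
    sequence: str
    kind: str  # mature_junction | splinter_junction
    truncated: bool = False


def splice_stwintron(
    pre_mrna: str, stw: Stwintron, frame_offset: int | None = None
) -> SpliceProducts:
    """Simulate excision of a stwintron placed within *pre_mrna*.

    ``frame_offset`` (nt from CDS start to the feature) enables the
    frameshift call on the one-step alternative product.
    """
    start, end = stw.location.start, stw.location.end
    i_start, i_end = stw.internal.location.start, stw.internal.location.end
    if not (0 <= start < end <= len(pre_mrna)):
        raise IndexError("stwintron coordinates out of range for pre-mRNA")
    if not (start < i_start < i_end <= end):
        raise IndexError("internal intron outside stwintron span")

    splinter = pre_mrna[:i_start] + pre_mrna[i_end:]
    mature = pre_mrna[:start] + pre_mrna[end:]
    # one-step excision leaves G1 exonic: remove [start+1, end)
    alt_mature = pre_mrna[: start + 1] + pre_mrna[end:]
    frameshift = None
    if frame_offset is not None:
        frameshift = (len(alt_mature) - len(mature)) % 3 != 0
    return SpliceProducts(
        pre_mrna=pre_mrna,
        splinter=splinter,
        mature=mature,
        alt_mature=alt_mature,
        frameshift=frameshift,
    )


def make_junction_queries(
    gene_seq: str, stw: Stwintron, width: int = 60
) -> list[JunctionQuery]:
    """Build fixed-width verification probes centred on splice junctions.

    The mature-junction probe fuses the bordering exons; the splinter probe
    fuses the upstream exon to the reconstructed external intron (starting
    with G1). Probes are truncated, with a warning, where the gene sequence
    runs out.
    """
    half = width // 2
    start, end = stw.location.start, stw.location.end
    i_end = stw.internal.location.end

    up = gene_seq[max(0, start - half) : start]
    down_mature = gene_seq[end : end + half]
    # external intron on the genomic axis begins at G1 then resumes after
    # the internal intron
    ext_tail = gene_seq[start] + gene_seq[i_end:]
    down_splinter = ext_tail[:half]

    queries = []
    for kind, downstream in (
        ("mature_junction", down_mature),
        ("splinter_junction", down_splinter),
    ):
        seq = up + downstream
        truncated = len(seq) < width
        if truncated:
            logger.warning(
                "%s query truncated to %d nt (context too short)", kind, len(seq)
            )
        queries.append(
            JunctionQuery(
                name=f"{stw.location.seq_id}_{start}_{kind}",
                sequence=seq,
                kind=kind,
                truncated=truncated,
            )
        )
    return queries
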