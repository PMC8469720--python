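"""Insertion-site analysis: intron phase, tandem-site-duplication scan,
seamless-integration check and the junction position-frequency matrix."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .family import global_align

BASES = "ACGT"
GAP = "-"


@dataclass
class TsdResult:
    present: bool
    length: int = 0
    sequence: str = ""


@dataclass
class SeamlessResult:
    status: str  # seamless | replacement | indeterminate
    n_lost: int = 0
    n_gained: int = 0


@dataclass
class InsertionReport:
    phase: int
    tsd: TsdResult
    seamless: Optional[SeamlessResult]
    flank5: str
    flank3: str


def intron_phase(cds_offset: int) -> int:
    """Intron phase from the CDS offset of the insertion point (nt 5' of the
    first intronic base, G1 included in the intron for stwintrons)."""
    if cds_offset < 0:
        raise ValueError("cds_offset must be non-negative")
    return cds_offset % 3


def tsd_scan(flank5: str, flank3: str, min_len: int = 2, max_len: int = 10) -> TsdResult:
    """Longest exact direct repeat ending at the 3' end of flank5 and
    starting at the 5' end of flank3 (the signature a DNA transposition
    would leave)."""
    flank5 = flank5.upper()
    flank3 = flank3.upper()
    if len(flank5) < max_len or len(flank3) < max_len:
        raise ValueError(f"flanks must be at least {max_len} nt")
    for k in range(max_len, min_len - 1, -1):
        if flank5[-k:] == flank3[:k]:
            return TsdResult(present=True, length=k, sequence=flank3[:k])
    return TsdResult(present=False)


def seamless_check(
    host_fusion: str,
    orthologue_window: str,
    junction_offset: int | None = None,
    min_window: int = 30,
    min_identity: float = 50.0,
) -> SeamlessResult:
    """Compare the host's exon-fusion sequence against an intron-less
    orthologue window.

    ``junction_offset`` is the index in *host_fusion* where the two exons
    meet (defaults to the midpoint). The integration is seamless iff the
    global alignment places no indel at or near the junction column (a
    small column window absorbs score-equivalent gap placements inside
    repeats); otherwise the inserted/deleted bases there are counted as
    replacement(n_lost, n_gained). Windows shorter than ``min_window`` per
    side, or orthologue windows below ``min_identity``, are indeterminate.
    """
    host_fusion = host_fusion.upper()
    orthologue_window = orthologue_window.upper()
    if junction_offset is None:
        junction_offset = len(host_fusion) // 2
    if junction_offset < min_window or len(host_fusion) - junction_offset < min_window:
        return SeamlessResult(status="indeterminate")
    aln = global_align(host_fusion, orthologue_window)
    if aln.percent_identity < min_identity:
        return SeamlessResult(status="indeterminate")

    # locate the junction column and count indel bases around it
    host_pos = 0
    junction_col = None
    for col, x in enumerate(aln.aligned_a):
        if host_pos == junction_offset:
            junction_col = col
            break
        if x != GAP:
            host_pos += 1
    if junction_col is None:
        junction_col = len(aln.aligned_a)

    n_lost = 0  # orthologue bases missing from the host at the junction
    n_gained = 0  # host bases absent from the orthologue at the junction
    near = 5
    # gap runs whose span reaches the junction neighbourhood
    run_start = None
    for c in range(len(aln.aligned_a) + 1):
        gap = c < len(aln.aligned_a) and GAP in (aln.aligned_a[c], aln.aligned_b[c])
        if gap and run_start is None:
            run_start = c
        elif not gap and run_start is not None:
            if run_start - near <= junction_col <= c + near:
                for k in range(run_start, c):
                    if aln.aligned_a[k] == GAP:
                        n_lost += 1
                    else:
                        n_gained += 1
            run_start = None
    if n_lost == 0 and n_gained == 0:
        return SeamlessResult(status="seamless")
    return SeamlessResult(status="replacement", n_lost=n_lost, n_gained=n_gained)


@dataclass
class JunctionMatrix:
    counts: np.ndarray  # (4, n_cols) observed counts over A,C,G,T
    frequencies: np.ndarray  # per column, over filled rows
    information_content: np.ndarray  # bits per column, 2 - H
    occupancy: np.ndarray  # filled rows / n_rows per column
    n_rows: int

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    def to_rows(self) -> list[dict]:
        rows = []
        for j in range(self.n_columns):
            row = {"position": j + 1}
            for k, b in enumerate(BASES):
                row[f"count_{b}"] = int(self.counts[k, j])
                row[f"freq_{b}"] = round(float(self.frequencies[k, j]), 6)
            row["information_bits"] = round(float(self.information_content[j]), 6)
            row["occupancy"] = round(float(self.occupancy[j]), 6)
            rows.append(row)
        return rows


def junction_matrix(rows: Sequence[str]) -> JunctionMatrix:
    """Position-frequency matrix over aligned junction rows.

    Rows must share one width; ``-`` marks an unoccupied cell (e.g. the
    intronic G column of members that lack a leading intronic G).
    Information content is 2 - H(column) in bits over observed frequencies
    of the filled cells, no pseudocounts; occupancy is the filled-row
    fraction.
    """
    if not rows:
        raise ValueError("no rows")
    width = len(rows[0])
    for r in rows:
        if len(r) != width:
            raise ValueError("inconsistent row widths")
    n = len(rows)
    counts = np.zeros((4, width), dtype=int)
    for r in rows:
        for j, c in enumerate(r.upper()):
            if c == GAP:
                continue
            if c not in BASES:
                raise ValueError(f"unexpected symbol {c!r} in junction row")
            counts[BASES.index(c), j] += 1
    filled = counts.sum(axis=0)
    freqs = np.zeros_like(counts, dtype=float)
    ic = np.zeros(width)
    for j in range(width):
        if filled[j] == 0:
            continue
        p = counts[:, j] / filled[j]
        freqs[:, j] = p
        h = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        ic[j] = 2.0 - h
    occupancy = filled / n
    return JunctionMatrix(
        counts=counts,
        frequencies=freqs,
        information_content=ic,
        occupancy=occupancy,
        n_rows=n,
    )


def build_junction_rows(
    flank_pairs: Sequence[tuple[str, str]],
    leading_g_rows: Sequence[bool],
    flank_width: int = 15,
) -> list[str]:
    """Assemble fixed-width junction rows from (flank5, flank3) pairs.

    Rows flagged in ``leading_g_rows`` contribute an intronic ``G`` column
    between the flanks (the stwintron's external-donor G1); others leave
    that column unoccupied, mirroring the partially filled logo column.
    """
    if len(flank_pairs) != len(leading_g_rows):
        raise ValueError("flank_pairs and leading_g_rows differ in length")
    rows = []
    for (f5, f3), has_g in zip(flank_pairs, leading_g_rows):
        f5 = f5.upper()[-flank_width:].rjust(flank_width, GAP)
        f3 = f3.upper()[:flank_width].ljust(flank_width, GAP)
        rows.append(f5 + ("G" if has_g else GAP) + f3)
    return rows
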