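"""Terminal-inverted-repeat detection, palindrome scanning and a simplified
two-molecule duplex score.

TIRs are revealed by globally aligning a sequence with its own reverse
complement; the terminal arm is the maximal prefix of alignment columns
whose sliding 10-column identity stays above the threshold. By the mirror
symmetry of a self-reverse-complement alignment, the 3' arm is implied by
the 5' one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .family import global_align
from .seqcore import Interval, iupac_mismatch_count, reverse_complement

PALINDROME = "WTTCTAGAAA"


@dataclass
class PalindromeHit:
    location: Interval
    matches: int
    observed: str
    w_base: str  # A, T or other

    @property
    def present(self) -> bool:
        return self.matches > 7


@dataclass
class SymmetryReport:
    tir_present: bool
    arm5: Optional[Interval]
    arm3: Optional[Interval]
    arm_length: int
    arm_identity: float
    spacer_length: int
    palindrome_hits: list[PalindromeHit] = field(default_factory=list)
    duplex_score: float = 0.0
    duplex_score_normalised: float = 0.0


def find_palindrome_hits(
    s: str, pattern: str = PALINDROME, min_matches: int = 8, seq_id: str = "seq"
) -> list[PalindromeHit]:
    """Score every window of ``len(pattern)`` nt; report windows whose match
    count reaches ``min_matches``. Overlapping hits are allowed."""
    s = s.upper().replace("U", "T")
    k = len(pattern)
    hits = []
    for i in range(len(s) - k + 1):
        win = s[i : i + k]
        matches = k - iupac_mismatch_count(pattern, win)
        if matches >= min_matches:
            w = win[0] if win[0] in "AT" else "other"
            hits.append(
                PalindromeHit(
                    location=Interval(seq_id, i, i + k),
                    matches=matches,
                    observed=win,
                    w_base=w,
                )
            )
    return hits


def _window_ok(matches: list[bool], start: int, w: int, min_frac: float) -> bool:
    win = matches[start : start + w]
    return sum(win) / len(win) >= min_frac


def find_tir(
    s: str,
    min_arm: int = 30,
    min_identity: float = 60.0,
    seq_id: str = "seq",
    window: int = 10,
) -> SymmetryReport:
    """Detect a terminal inverted repeat by self-reverse-complement alignment.

    When the alignment starts with a run of perfectly matching columns of
    at least ``min_arm``, that run is the arm (identity exactly 100%).
    Otherwise the arm is the maximal terminal run of alignment columns in
    which every sliding ``window``-column identity is >= ``min_identity``,
    trimmed back to the last matching column. ``tir_present`` requires the
    arm to cover at least ``min_arm`` nucleotides of *s*.
    """
    s = s.upper().replace("U", "T")
    if len(s) < 2 * min_arm:
        raise ValueError(f"sequence of {len(s)} nt shorter than 2 x min_arm")
    rc = reverse_complement(s)
    aln = global_align(s, rc)
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    match_flags = [x == y and x != "-" for x, y in cols]
    n_cols = len(cols)
    min_frac = min_identity / 100.0

    perfect = 0
    while perfect < n_cols and match_flags[perfect]:
        perfect += 1
    if perfect >= min_arm:
        limit = perfect
    else:
        # grow the prefix while every full window inside it passes
        limit = 0
        j = 0
        while j + window <= n_cols and _window_ok(match_flags, j, window, min_frac):
            limit = j + window
            j += 1
        # trim to the last matching column
        while limit > 0 and not match_flags[limit - 1]:
            limit -= 1

    if limit == 0:
        hits = find_palindrome_hits(s, seq_id=seq_id)
        score, norm, _ = duplex_score(s)
        return SymmetryReport(
            tir_present=False,
            arm5=None,
            arm3=None,
            arm_length=0,
            arm_identity=0.0,
            spacer_length=0,
            palindrome_hits=hits,
            duplex_score=score,
            duplex_score_normalised=norm,
        )

    prefix_cols = cols[:limit]
    arm_len = sum(1 for x, _ in prefix_cols if x != "-")
    matches = sum(match_flags[:limit])
    arm_identity = 100.0 * matches / limit

    arm5 = Interval(seq_id, 0, arm_len) if arm_len > 0 else None
    # mirror arm: rc positions [0, arm_len) map to s positions [L-arm_len, L)
    arm3 = Interval(seq_id, len(s) - arm_len, len(s)) if arm_len > 0 else None
    spacer = max(0, (len(s) - arm_len) - arm_len)
    present = arm_len >= min_arm

    hits = find_palindrome_hits(s, seq_id=seq_id)
    score, norm, _ = duplex_score(s)
    return SymmetryReport(
        tir_present=present,
        arm5=arm5,
        arm3=arm3,
        arm_length=arm_len,
        arm_identity=arm_identity,
        spacer_length=spacer,
        palindrome_hits=hits,
        duplex_score=score,
        duplex_score_normalised=norm,
    )


_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G.U on the DNA representation


def duplex_score(s: str) -> tuple[float, float, list[tuple[int, int]]]:
    """Best antiparallel gapless register of *s* against a second copy of
    itself: +2 per Watson-Crick pair, +1 per G.U wobble.

    Returns (score, score / (2 * len(s)), pairing map at the best register);
    the pairing map lists (i, j) index pairs with i from one molecule and j
    from the other.
    """
    s = s.upper().replace("U", "T")
    L = len(s)
    if L == 0:
        return 0.0, 0.0, []
    best_score = 0
    best_pairs: list[tuple[int, int]] = []
    # antiparallel register k: position i pairs with j = L - 1 + k - i
    for k in range(-(L - 1), L):
        score = 0
        pairs = []
        for i in range(L):
            j = L - 1 + k - i
            if 0 <= j < L:
                duo = (s[i], s[j])
                if duo in _WC:
                    score += 2
                    pairs.append((i, j))
                elif duo in _WOBBLE:
                    score += 1
                    pairs.append((i, j))
        if score > best_score:
            best_score = score
            best_pairs = pairs
    return float(best_score), best_score / (2.0 * L), best_pairs
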