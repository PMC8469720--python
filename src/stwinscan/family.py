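"""Sister-family collection and relative classification.

Global alignment is affine-gap Needleman-Wunsch-Gotoh with a fixed,
deterministic traceback (diagonal preferred over up over left), so that
identities and block structures are reproducible across runs. Percent
identity counts gap columns in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .scanner import Stwintron, find_canonical_introns, find_d12_stwintrons
from .seqcore import GenomicSequence, IntronModel

DEFAULT_SCORING = {"match": 2, "mismatch": -1, "gap_open": -4, "gap_extend": -1}

NEG_INF = float("-inf")


@dataclass
class LocalBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float  # percent over block columns

    def __len__(self) -> int:
        return self.a_end - self.a_start


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    local_blocks: list[LocalBlock] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def global_align(a: str, b: str, scoring: dict | None = None) -> PairwiseAlignment:
    """Optimal global alignment of *a* and *b* under an affine gap model.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. Traceback
    ties are broken diagonal > up (gap in b) > left (gap in a).
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    match, mismatch = sc["match"], sc["mismatch"]
    go, ge = sc["gap_open"], sc["gap_extend"]
    n, m = len(a), len(b)

    # M: a[i-1] aligned to b[j-1]; X: gap in b (consumes a); Y: gap in a.
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + go, Xp[j] + ge, Yp[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge)

    # choose final state: diagonal > up > left on ties
    end_scores = (M[n][m], X[n][m], Y[n][m])
    best = max(end_scores)
    state = end_scores.index(best)  # 0=M, 1=X, 2=Y

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - s
            state = _pick_state(prev, target)
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            prev = (M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            state = _pick_state(prev, X[i][j])
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = (M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
            state = _pick_state(prev, Y[i][j])
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    pid = 100.0 * matches / len(aligned_a)
    aln = PairwiseAlignment(aligned_a, aligned_b, best, pid)
    aln.local_blocks = _local_blocks(aligned_a, aligned_b)
    return aln


def _pick_state(candidates: tuple[float, float, float], target: float) -> int:
    for k, v in enumerate(candidates):
        if abs(v - target) < 1e-9:
            return k
    # numerical fallback: closest
    return min(range(3), key=lambda k: abs(candidates[k] - target))


def _local_blocks(aa: str, ab: str) -> list[LocalBlock]:
    """Maximal gap-free runs of aligned columns with per-block identity."""
    blocks: list[LocalBlock] = []
    ai = bi = 0
    run_a = run_b = run_cols = run_match = 0
    in_run = False
    for x, y in zip(aa, ab):
        if x != "-" and y != "-":
            if not in_run:
                run_a, run_b, run_cols, run_match = ai, bi, 0, 0
                in_run = True
            run_cols += 1
            if x == y:
                run_match += 1
        else:
            if in_run:
                blocks.append(
                    LocalBlock(run_a, run_a + run_cols, run_b, run_b + run_cols,
                               100.0 * run_match / run_cols)
                )
                in_run = False
        if x != "-":
            ai += 1
        if y != "-":
            bi += 1
    if in_run:
        blocks.append(
            LocalBlock(run_a, run_a + run_cols, run_b, run_b + run_cols,
                       100.0 * run_match / run_cols)
        )
    return blocks


@dataclass
class FamilyMember:
    member_id: str
    identity_to_seed: float
    alignment: PairwiseAlignment


def collect_family(
    candidates: Sequence[GenomicSequence],
    seed: GenomicSequence,
    min_identity: float = 55.0,
    scoring: dict | None = None,
) -> list[FamilyMember]:
    """Seed-centric family collection by full-length global identity."""
    members = []
    for cand in candidates:
        aln = global_align(seed.residues, cand.residues, scoring)
        if aln.percent_identity >= min_identity:
            members.append(FamilyMember(cand.id, aln.percent_identity, aln))
    members.sort(key=lambda fm: (-fm.identity_to_seed, fm.member_id))
    return members


CATEGORIES = (
    "full_sister",
    "sheared_internal",
    "sheared_external",
    "cropped_type1",
    "cropped_type2",
    "long_intron",
    "unrelated",
)


@dataclass
class FamilyAssignment:
    member_id: str
    category: str
    identity_to_seed: float
    evidence: Optional[PairwiseAlignment] = None
    extra_g_subgroup: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.extra_g_subgroup and self.category != "cropped_type2":
            raise ValueError("extra_g_subgroup is a type-2 attribute")


def _end_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    return global_align(a, b).percent_identity


def classify_relative(
    element_id: str,
    element_seq: str,
    template_seq: str,
    template_stw: Stwintron,
    model: IntronModel,
    min_identity: float = 55.0,
    scoring: dict | None = None,
) -> FamilyAssignment:
    """Assign a relative to a sister-family category against a template.

    ``template_stw`` must be the template's own (D1,2) call with the feature
    spanning ``template_seq`` from offset 0. Decision rules (fixed):

    * full_sister: element is itself a valid (D1,2) covering its full span,
      with global identity to the template >= min_identity and length >= 80%
      of the template.
    * cropped_type1 / cropped_type2 / long_intron: element is a canonical
      intron; provenance of its 5' and 3' ends against the template's
      internal/external sections decides the path.
    * sheared_internal / sheared_external: a gap-free local block >= 40
      columns at >= 60% identity lying >= 80% within one template section.
    * unrelated otherwise.
    """
    element_seq = element_seq.upper()
    i_start, i_end = template_stw.internal_span
    internal_seq = template_seq[i_start:i_end]
    L = len(template_seq)

    gseq = GenomicSequence(id=element_id, residues=element_seq)
    stw_hits = find_d12_stwintrons(gseq, model)
    is_full_span_stw = any(
        h.location.start == 0 and h.location.end == len(element_seq) for h in stw_hits
    )
    intron_hits = find_canonical_introns(gseq, model, mode="exhaustive")
    is_full_span_intron = any(
        h.location.start == 0 and h.location.end == len(element_seq)
        for h in intron_hits
    )

    aln = global_align(template_seq, element_seq, scoring)
    pid = aln.percent_identity
    id_int, id_ext = _section_identities(aln, i_start, i_end)

    if (
        is_full_span_stw
        and pid >= min_identity
        and min(id_int, id_ext) >= min_identity
        and len(element_seq) >= 0.8 * L
    ):
        return FamilyAssignment(element_id, "full_sister", pid, aln)

    if is_full_span_intron:
        # long intron: whole template minus G1 as one canonical intron
        if abs(len(element_seq) - (L - 1)) <= 0.15 * L:
            pid_long = global_align(template_seq[1:], element_seq, scoring).percent_identity
            if pid_long >= min_identity:
                return FamilyAssignment(element_id, "long_intron", pid, aln)
        w = 20
        tail_int = _end_identity(element_seq[-w:], internal_seq[-w:])
        tail_ext = _end_identity(element_seq[-w:], template_seq[-w:])
        head_int = _end_identity(element_seq[:w], internal_seq[:w])
        if (
            tail_int >= 60.0
            and tail_int > tail_ext
            and global_align(internal_seq, element_seq, scoring).percent_identity >= 60.0
        ):
            return FamilyAssignment(element_id, "cropped_type1", pid, aln)
        if head_int >= 60.0 and tail_ext >= 60.0:
            extra_g = len(element_seq) >= 4 and element_seq[-4] == "G"
            return FamilyAssignment(
                element_id, "cropped_type2", pid, aln, extra_g_subgroup=extra_g
            )

    # similarity restricted to one template section -> sheared sister;
    # the contrast requirement keeps diverged full copies out
    if id_int >= 60.0 and id_ext <= 56.0 and id_int - id_ext >= 20.0:
        return FamilyAssignment(element_id, "sheared_internal", pid, aln)
    if id_ext >= 60.0 and id_int <= 56.0 and id_ext - id_int >= 20.0:
        return FamilyAssignment(element_id, "sheared_external", pid, aln)

    return FamilyAssignment(element_id, "unrelated", pid, aln)


def _section_identities(
    aln: PairwiseAlignment, i_start: int, i_end: int
) -> tuple[float, float]:
    """Percent identity restricted to the columns overlapping the template's
    internal section and external section respectively (gap columns count
    in the denominator of the section whose template position they abut)."""
    pos = 0
    n_int = m_int = n_ext = m_ext = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        p = pos if x != "-" else max(pos - 1, 0)
        in_internal = i_start <= p < i_end
        match = x == y and x != "-"
        if in_internal:
            n_int += 1
            m_int += match
        else:
            n_ext += 1
            m_ext += match
        if x != "-":
            pos += 1
    id_int = 100.0 * m_int / n_int if n_int else 0.0
    id_ext = 100.0 * m_ext / n_ext if n_ext else 0.0
    return id_int, id_ext
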