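"""Synthetic genomes with planted (stw)intron families and ground truth.

The generator emulates the structure the analysis assumes: an ancestral
donor-disrupted twin-intron template with 45-55 nt terminal inverted
repeats overlapping two copies of the 10-nt palindrome, evolved copies
planted seamlessly at random coding positions, plus sheared hybrids and
cropped derivatives (type-1, type-2, long-intron). Every planted element
is recorded in a machine-readable truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np

from . import crop as crop_mod
from .scanner import find_d12_stwintrons, find_canonical_introns, Stwintron
from .seqcore import (
    GenomicSequence,
    Gff3Feature,
    Interval,
    IntronModel,
    IUPAC_SETS,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .symmetry import find_palindrome_hits, find_tir

BASES = "ACGT"


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Concrete DNA string drawn uniformly from an IUPAC pattern."""
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in pattern.upper()
    )


def _random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(BASES[i] for i in idx)


@dataclass
class TemplateParams:
    arm_length: tuple[int, int] = (45, 55)
    spacer_length: tuple[int, int] = (90, 110)
    palindrome: str = "TTTCTAGAAA"
    max_attempts: int = 1000


@dataclass
class Template:
    """A generated ancestral stwintron with its motif layout.

    All coordinates are relative to the feature (G1 at position 0).
    Protected intervals cover the splice-determining motifs; the two
    palindrome copies are recorded separately.
    """

    sequence: str
    internal_span: tuple[int, int]
    protected: list[tuple[int, int]]
    palindrome5: tuple[int, int]
    palindrome3: tuple[int, int]
    arm_length: int
    spacer_length: int
    stw: Stwintron

    def __len__(self) -> int:
        return len(self.sequence)


class TemplateInfeasible(RuntimeError):
    pass


def make_template(
    tp: TemplateParams, model: IntronModel, seed: int | np.random.Generator
) -> Template:
    """Rejection-sample a template satisfying the generator contract:
    the scanner finds exactly one full-span stwintron at offset 0 with the
    planted internal coordinates, the TIR detector reports an arm inside
    the configured range, and exactly two palindrome copies are present."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(tp.max_attempts):
        t = _build_template_once(tp, model, rng)
        if t is None:
            continue
        if _template_ok(t, tp, model):
            return t
    raise TemplateInfeasible(
        f"no valid template after {tp.max_attempts} attempts; ranges infeasible?"
    )


def _build_template_once(
    tp: TemplateParams, model: IntronModel, rng: np.random.Generator
) -> Template | None:
    arm_lo, arm_hi = tp.arm_length
    sp_lo, sp_hi = tp.spacer_length
    armlen = int(rng.integers(arm_lo, arm_hi + 1))
    spacer = int(rng.integers(sp_lo, sp_hi + 1))
    pal = tp.palindrome.upper()
    plen = len(pal)
    d_len = len(model.donor_pattern)
    bp_len = len(model.bp_pattern)
    a_len = len(model.acceptor_pattern)

    donor_i = _instantiate(model.donor_pattern, rng)
    bp_e = _instantiate(model.bp_pattern, rng)
    fill5_len = armlen - 1 - d_len - bp_len - plen
    if fill5_len < 0:
        return None
    # rc(bp_e) sits right after the internal donor so the mirrored arm
    # carries the external BP without breaking the inverted repeat
    arm5 = "G" + donor_i + reverse_complement(bp_e) + _random_dna(fill5_len, rng) + pal

    # middle section between the two palindrome copies
    bp_i = _instantiate(model.bp_pattern, rng)
    gap_i = int(rng.integers(model.bp_to_acceptor_min, model.bp_to_acceptor_min + 7))
    acc_i = _instantiate(model.acceptor_pattern, rng)
    dcont = "T" + _instantiate(model.donor_pattern[2:], rng)  # G1+this = donor
    fixed = bp_len + gap_i + a_len + len(dcont)
    if spacer < fixed + 10:
        return None
    fill_a_len = (spacer - fixed) // 2
    fill_b_len = spacer - fixed - fill_a_len
    mid = (
        _random_dna(fill_a_len, rng)
        + bp_i
        + _random_dna(gap_i, rng)
        + acc_i
        + dcont
        + _random_dna(fill_b_len, rng)
    )

    arm3 = list(reverse_complement(arm5))
    arm3[0] = "A"  # 3' palindrome copy carries W = A (imperfect)
    acc_e = "T" + "AG"
    arm3[-a_len:] = list(acc_e)
    arm3 = "".join(arm3)

    seq = arm5 + mid + arm3
    internal_end = armlen + fill_a_len + bp_len + gap_i + a_len
    internal_span = (1, internal_end)
    if internal_end - 1 < model.min_intron_len:
        return None
    external_len = 1 + (len(seq) - internal_end)
    if not (model.min_intron_len <= external_len <= model.max_intron_len):
        return None

    bp_i_start = armlen + fill_a_len
    acc_i_start = bp_i_start + bp_len + gap_i
    dcont_start = acc_i_start + a_len
    bp_e_start = len(seq) - a_len - (bp_len + 4) + 4 - bp_len  # see arm mirror
    # recompute exactly: rc(bp_e) occupies arm5[1+d_len : 1+d_len+bp_len],
    # mirroring to seq positions from the 3' end
    mirror_hi = len(seq) - (1 + d_len)
    bp_e_span = (mirror_hi - bp_len, mirror_hi)
    protected = [
        (0, 1 + d_len),  # G1 + internal donor
        (bp_i_start, bp_i_start + bp_len),
        (acc_i_start, acc_i_start + a_len),
        (dcont_start, dcont_start + len(dcont)),
        bp_e_span,
        (len(seq) - a_len, len(seq)),
    ]
    pal5 = (armlen - plen, armlen)
    pal3 = (len(seq) - armlen, len(seq) - armlen + plen)
    return Template(
        sequence=seq,
        internal_span=internal_span,
        protected=protected,
        palindrome5=pal5,
        palindrome3=pal3,
        arm_length=armlen,
        spacer_length=spacer,
        stw=None,  # filled in after validation
    )


def _template_ok(t: Template, tp: TemplateParams, model: IntronModel) -> bool:
    gs = GenomicSequence(id="template", residues=t.sequence)
    hits = find_d12_stwintrons(gs, model)
    full = [
        h
        for h in hits
        if h.location.start == 0 and h.location.end == len(t.sequence)
    ]
    if len(hits) != 1 or len(full) != 1:
        return False
    h = full[0]
    if h.internal_span != t.internal_span:
        return False
    pal_hits = find_palindrome_hits(t.sequence)
    if len(pal_hits) != 2:
        return False
    arm_lo, arm_hi = tp.arm_length
    rep = find_tir(t.sequence)
    if not rep.tir_present or not (arm_lo <= rep.arm_length <= arm_hi):
        return False
    t.stw = h
    # crop products must themselves obey intron definition end-to-end:
    # the minimal intron at their donor is the full product
    for product in (
        crop_mod.predict_type1_crop("t", t.sequence, h, model).product,
        crop_mod.predict_type2_crop("t", t.sequence, h, model).product,
        derive_long(t, model)[0],
    ):
        pgs = GenomicSequence(id="p", residues=product)
        phits = find_canonical_introns(pgs, model)
        if not any(
            x.location.start == 0 and x.location.end == len(product) for x in phits
        ):
            return False
    return True


@dataclass
class EvolvedCopy:
    sequence: str
    realised_divergence: float
    n_substitutions: int
    n_indels: int


def evolve_copy(
    sequence: str,
    rate: float,
    indel_rate: float = 0.0,
    protect_motifs: bool = True,
    protected: list[tuple[int, int]] | None = None,
    seed: int | np.random.Generator = 0,
) -> EvolvedCopy:
    """Apply uniform substitutions (and simple 1-nt indels) outside the
    protected motif intervals.

    With ``protect_motifs`` false the protection map is ignored and every
    position is mutable."""
    if not 0 <= rate < 0.5:
        raise ValueError("substitution rate must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prot = set()
    if protect_motifs and protected:
        for lo, hi in protected:
            prot.update(range(lo, hi))
    out: list[str] = []
    n_sub = n_indel = 0
    for i, base in enumerate(sequence):
        mutable = i not in prot
        if mutable and indel_rate > 0 and rng.random() < indel_rate:
            n_indel += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append(BASES[rng.integers(4)])  # insertion after i
            continue
        if mutable and rng.random() < rate:
            choices = [b for b in BASES if b != base]
            out.append(choices[rng.integers(3)])
            n_sub += 1
        else:
            out.append(base)
    new_seq = "".join(out)
    return EvolvedCopy(
        sequence=new_seq,
        realised_divergence=n_sub / len(sequence) if sequence else 0.0,
        n_substitutions=n_sub,
        n_indels=n_indel,
    )


# ---------------------------------------------------------------------------
# derivative construction
# ---------------------------------------------------------------------------

def _shift_spans(spans: list[tuple[int, int]], cut5: int, cut3: int, removed: int):
    """Project protected spans through a central deletion [cut5, cut3)."""
    out = []
    for lo, hi in spans:
        if hi <= cut5:
            out.append((lo, hi))
        elif lo >= cut3:
            out.append((lo - removed, hi - removed))
    return out


def derive_type1(t: Template, model: IntronModel) -> tuple[str, list[tuple[int, int]]]:
    ev = crop_mod.predict_type1_crop("template", t.sequence, t.stw, model)
    i_start, i_end = t.internal_span
    prot = [
        (max(lo, i_start) - i_start, min(hi, i_end) - i_start)
        for lo, hi in t.protected
        if lo < i_end and hi > i_start
    ]
    return ev.product, prot


def derive_type2(t: Template, model: IntronModel) -> tuple[str, list[tuple[int, int]]]:
    ev = crop_mod.predict_type2_crop("template", t.sequence, t.stw, model)
    cut5, cut3 = ev.breakpoint5, ev.breakpoint3
    removed = cut3 - cut5
    prot = _shift_spans(t.protected, cut5, cut3, removed)
    prot = [(max(0, lo - 1), hi - 1) for lo, hi in prot if hi > 1]  # drop G1
    return ev.product, prot


def derive_long(t: Template, model: IntronModel) -> tuple[str, list[tuple[int, int]]]:
    """Long-intron path: feature minus G1, with the internal BP degenerated
    (base-complemented, a fixed transformation) so the product behaves as a
    single canonical intron."""
    ev = crop_mod.predict_long_intron("template", t.sequence, t.stw, model)
    product = list(ev.product)
    bp_i = next(
        (lo, hi)
        for lo, hi in t.protected
        if t.internal_span[0] < lo < t.internal_span[1] and hi - lo == 6
    )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for p in range(bp_i[0] - 1, bp_i[1] - 1):  # -1: G1 removed
        product[p] = comp[product[p]]
    prot = [
        (lo - 1, hi - 1)
        for lo, hi in t.protected
        if (lo, hi) != bp_i
    ]
    prot = [(max(0, lo), hi) for lo, hi in prot if hi > 1]
    return "".join(product), prot


def make_sheared(
    t: Template,
    model: IntronModel,
    which: str,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> tuple[str, list[tuple[int, int]]]:
    """Hybrid stwintron sharing only one section with the family template.

    ``which`` names the conserved section: 'internal' keeps the template's
    internal intron and replaces the external remainder with a fresh,
    unrelated (but grammatically valid) section, and vice versa. The
    replaced section carries no palindrome copy and no mirrored arm."""
    i_end = t.internal_span[1]
    bp_len = len(model.bp_pattern)
    a_len = len(model.acceptor_pattern)
    for _ in range(max_attempts):
        if which == "internal":
            keep = t.sequence[:i_end]
            ext_len = len(t.sequence) - i_end  # keep overall size similar
            dcont = "T" + _instantiate(model.donor_pattern[2:], rng)
            gap = model.bp_to_acceptor_min
            fill = ext_len - len(dcont) - bp_len - gap - a_len
            if fill < 0:
                raise TemplateInfeasible("external section too short")
            fresh = (
                dcont
                + _random_dna(fill, rng)
                + _instantiate(model.bp_pattern, rng)
                + _random_dna(gap, rng)
                + "TAG"
            )
            seq = keep + fresh
            prot = [(lo, hi) for lo, hi in t.protected if hi <= i_end]
            prot += [
                (i_end, i_end + len(dcont)),
                (i_end + len(dcont) + fill, i_end + len(dcont) + fill + bp_len),
                (len(seq) - a_len, len(seq)),
            ]
            expected_internal = t.internal_span
        elif which == "external":
            keep = t.sequence[i_end:]
            int_len = i_end - 1
            donor_i = _instantiate(model.donor_pattern, rng)
            gap = model.bp_to_acceptor_min
            fill = int_len - len(donor_i) - bp_len - gap - a_len
            if fill < 0:
                raise TemplateInfeasible("internal section too short")
            fresh = (
                donor_i
                + _random_dna(fill, rng)
                + _instantiate(model.bp_pattern, rng)
                + _random_dna(gap, rng)
                + "CAG"
            )
            seq = "G" + fresh + keep
            prot = [
                (0, 1 + len(donor_i)),
                (1 + len(donor_i) + fill, 1 + len(donor_i) + fill + bp_len),
                (i_end - a_len, i_end),
            ]
            prot += [(lo, hi) for lo, hi in t.protected if lo >= i_end]
            expected_internal = (1, i_end)
        else:
            raise ValueError(which)
        gs = GenomicSequence(id="sheared", residues=seq)
        hits = find_d12_stwintrons(gs, model)
        full = [
            h
            for h in hits
            if h.location.start == 0
            and h.location.end == len(seq)
            and h.internal_span == expected_internal
        ]
        if len(hits) == 1 and len(full) == 1:
            return seq, prot
    raise TemplateInfeasible(f"no valid sheared ({which}) hybrid after {max_attempts} tries")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    seed: int = 0
    n_genes: int = 12
    gene_length: tuple[int, int] = (900, 1500)
    background_gc: float = 0.5
    template: TemplateParams = field(default_factory=TemplateParams)
    n_full_copies: int = 6
    n_sheared: int = 2
    n_type1: int = 2
    n_type2: int = 3
    n_long: int = 1
    divergence: tuple[float, float] = (0.0, 0.15)
    indel_rate: float = 0.0
    protect_motifs: bool = True
    background_introns_per_gene: tuple[int, int] = (3, 4)
    intergenic_length: int = 150

    def __post_init__(self) -> None:
        for r in (self.divergence, (self.indel_rate, self.indel_rate)):
            if not (0 <= r[0] <= 1 and 0 <= r[1] <= 1):
                raise ValueError("rates must lie in [0, 1]")
        for n in (self.n_genes, self.n_full_copies, self.n_sheared,
                  self.n_type1, self.n_type2, self.n_long):
            if n < 0:
                raise ValueError("counts must be non-negative")


@dataclass
class GroundTruthRecord:
    element_id: str
    gene_id: str
    category: str
    cds_offset: int
    phase: int
    genome_start: int
    genome_end: int
    length: int
    realised_divergence: float
    template_id: str
    sequence: str


@dataclass
class SyntheticGenome:
    params: SimParams
    genome: GenomicSequence
    features: list[Gff3Feature]
    truth: list[GroundTruthRecord]
    template: Template
    pre_insertion_genes: dict[str, str]

    def truth_json(self) -> list[dict]:
        return [asdict(r) for r in self.truth]

    def write(self, out_prefix: str | Path) -> None:
        out_prefix = Path(out_prefix)
        out_prefix.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], out_prefix / "genome.fasta")
        write_gff3(self.features, out_prefix / "genes.gff3")
        with open(out_prefix / "truth.json", "w") as fh:
            json.dump(self.truth_json(), fh, indent=2)
            fh.write("\n")


def copy_is_splice_valid(seq: str, category: str, model: IntronModel) -> bool:
    """True when the scanner still reads the copy end-to-end as the planted
    structure (full-span stwintron, or full-span minimal canonical intron
    for the cropped/long categories)."""
    gs = GenomicSequence(id="copy", residues=seq)
    if category.startswith(("full", "sheared")):
        hits = find_d12_stwintrons(gs, model)
        return any(
            h.location.start == 0 and h.location.end == len(seq) for h in hits
        )
    hits = find_canonical_introns(gs, model)
    return any(h.location.start == 0 and h.location.end == len(seq) for h in hits)


def _evolve_valid(
    base_seq: str,
    rate: float,
    params: "SimParams",
    prot: list[tuple[int, int]],
    category: str,
    model: IntronModel,
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> EvolvedCopy:
    """Evolve a copy, resampling until it remains splice-valid (family
    members are all splice-competent; mutations that silence or reroute the
    splice sites are treated as unobserved)."""
    ev = None
    for _ in range(max_attempts):
        ev = evolve_copy(
            base_seq,
            rate,
            indel_rate=params.indel_rate,
            protect_motifs=params.protect_motifs,
            protected=prot,
            seed=rng,
        )
        if not params.protect_motifs or copy_is_splice_valid(ev.sequence, category, model):
            return ev
    return ev


def _make_background_intron(model: IntronModel, rng: np.random.Generator) -> str:
    """A valid canonical intron of 50-90 nt for background gene structure."""
    for _ in range(200):
        donor = _instantiate(model.donor_pattern, rng)
        bp = _instantiate(model.bp_pattern, rng)
        acc = _instantiate(model.acceptor_pattern, rng)
        gap = int(rng.integers(model.bp_to_acceptor_min, model.bp_to_acceptor_min + 8))
        fill = int(rng.integers(30, 65))
        seq = donor + _random_dna(fill, rng) + bp + _random_dna(gap, rng) + acc
        gs = GenomicSequence(id="bgi", residues=seq)
        hits = find_canonical_introns(gs, model, mode="exhaustive")
        if any(h.location.start == 0 and h.location.end == len(seq) for h in hits):
            return seq
    raise TemplateInfeasible("could not build a background intron")


def build_genome(params: SimParams, model: IntronModel | None = None) -> SyntheticGenome:
    """Generate a genome, annotations and ground truth from *params*.

    Deterministic: identical params + seed give byte-identical outputs.
    """
    model = model or IntronModel()
    rng = np.random.default_rng(params.seed)
    template = make_template(params.template, model, rng)

    # element payloads: (category, base sequence, protection map)
    payloads: list[tuple[str, str, list[tuple[int, int]]]] = []
    for _ in range(params.n_full_copies):
        payloads.append(("full_sister", template.sequence, template.protected))
    for k in range(params.n_sheared):
        which = "internal" if k % 2 == 0 else "external"
        seq, prot = make_sheared(template, model, which, rng)
        payloads.append((f"sheared_{which}", seq, prot))
    if params.n_type1:
        seq, prot = derive_type1(template, model)
        for _ in range(params.n_type1):
            payloads.append(("cropped_type1", seq, prot))
    if params.n_type2:
        seq, prot = derive_type2(template, model)
        for _ in range(params.n_type2):
            payloads.append(("cropped_type2", seq, prot))
    if params.n_long:
        seq, prot = derive_long(template, model)
        for _ in range(params.n_long):
            payloads.append(("long_intron", seq, prot))

    lo, hi = params.divergence
    gene_ids = [f"gene{g + 1:03d}" for g in range(params.n_genes)]
    gene_cds = {
        gid: _random_dna(
            int(rng.integers(params.gene_length[0], params.gene_length[1] + 1)) // 3 * 3,
            rng,
            params.background_gc,
        )
        for gid in gene_ids
    }

    # plan insertions per gene: background introns plus planted elements
    insert_plan: dict[str, list[tuple[int, str, str, str, float]]] = {
        gid: [] for gid in gene_ids
    }
    for gid in gene_ids:
        n_bg = int(
            rng.integers(
                params.background_introns_per_gene[0],
                params.background_introns_per_gene[1] + 1,
            )
        )
        for b in range(n_bg):
            off = int(rng.integers(1, len(gene_cds[gid])))
            insert_plan[gid].append(
                (off, f"{gid}_bg{b + 1}", "background_intron",
                 _make_background_intron(model, rng), 0.0)
            )
    for k, (category, base_seq, prot) in enumerate(payloads):
        rate = float(rng.uniform(lo, hi))
        ev = _evolve_valid(
            base_seq,
            rate,
            params,
            prot,
            category,
            model,
            rng,
        )
        gid = gene_ids[int(rng.integers(params.n_genes))]
        off = int(rng.integers(1, len(gene_cds[gid])))
        insert_plan[gid].append(
            (off, f"elem{k + 1:03d}", category, ev.sequence, ev.realised_divergence)
        )

    # assemble: genes on one contig separated by intergenic spacers
    contig_id = "synth_contig_1"
    pieces: list[str] = []
    features: list[Gff3Feature] = []
    truth: list[GroundTruthRecord] = []
    cursor = 0

    for gid in gene_ids:
        spacer = _random_dna(params.intergenic_length, rng, params.background_gc)
        pieces.append(spacer)
        cursor += len(spacer)
        gene_start = cursor
        cds = gene_cds[gid]
        plan = sorted(insert_plan[gid], key=lambda x: (x[0], x[1]))
        built: list[str] = []
        prev = 0
        gpos = gene_start
        for off, elem_id, category, seq, div in plan:
            built.append(cds[prev:off])
            gpos += off - prev
            start, end = gpos, gpos + len(seq)
            built.append(seq)
            gpos = end
            prev = off
            iv = Interval(contig_id, start, end)
            ftype = "background_intron" if category == "background_intron" else "planted_element"
            features.append(
                Gff3Feature(
                    interval=iv,
                    feature_type=ftype,
                    attributes={"ID": elem_id, "category": category, "gene": gid},
                )
            )
            if category != "background_intron":
                truth.append(
                    GroundTruthRecord(
                        element_id=elem_id,
                        gene_id=gid,
                        category=category,
                        cds_offset=off,
                        phase=off % 3,
                        genome_start=start,
                        genome_end=end,
                        length=len(seq),
                        realised_divergence=div,
                        template_id="template",
                        sequence=seq,
                    )
                )
        built.append(cds[prev:])
        gpos += len(cds) - prev
        gene_seq = "".join(built)
        pieces.append(gene_seq)
        cursor = gene_start + len(gene_seq)
        features.append(
            Gff3Feature(
                interval=Interval(contig_id, gene_start, cursor),
                feature_type="gene",
                attributes={"ID": gid},
            )
        )
    pieces.append(_random_dna(params.intergenic_length, rng, params.background_gc))

    genome = GenomicSequence(id=contig_id, residues="".join(pieces))
    features.sort(key=lambda f: (f.interval.start, f.feature_type))
    return SyntheticGenome(
        params=params,
        genome=genome,
        features=features,
        truth=truth,
        template=template,
        pre_insertion_genes=dict(gene_cds),
    )
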