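"""Pipeline orchestration: scan -> family -> symmetry -> crop -> context.

Every stage is a pure function of its inputs and the run configuration;
running the same configuration twice produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import crop as crop_mod
from .context import build_junction_rows, intron_phase, junction_matrix, tsd_scan
from .family import classify_relative
from .scanner import Stwintron, find_canonical_introns, find_d12_stwintrons, scan_genome
from .seqcore import (
    GenomicSequence,
    Gff3Feature,
    Interval,
    IntronModel,
    read_fasta,
    read_gff3,
    write_gff3,
    write_report,
)
from .symmetry import find_palindrome_hits, find_tir

logger = logging.getLogger(__name__)

FLANK_WIDTH = 15


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    fasta: str
    out_dir: str
    gff3: Optional[str] = None
    seed_fasta: Optional[str] = None
    model: dict = field(default_factory=dict)
    min_identity: float = 55.0
    min_arm: int = 30
    min_tir_identity: float = 60.0
    both_strands: bool = True
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for p in (cfg.fasta, cfg.gff3, cfg.seed_fasta):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input path does not exist: {p}")
        return cfg


def _feature_sequence(genome: dict[str, GenomicSequence], iv: Interval) -> str:
    return genome[iv.seq_id].subseq(iv)


def _structure_key(seq: str, stw: Stwintron) -> tuple:
    """Sort key preferring template-like calls: a palindrome copy in each
    of the internal and external sections, then shorter features."""
    i_start, i_end = stw.internal_span
    hits = find_palindrome_hits(seq)
    in_internal = any(i_start <= h.location.start < i_end for h in hits)
    in_external = any(h.location.start >= i_end for h in hits)
    return (not (in_internal and in_external), len(seq), -len(hits))


def _pick_seed(
    stw_seqs: list[tuple[str, str, Stwintron]]
) -> tuple[str, str, Stwintron]:
    """Default seed: the most template-like detected stwintron (palindrome
    copy in both sections, shortest such feature), first name on ties."""
    best = None
    for name, seq, stw in stw_seqs:
        key = _structure_key(seq, _rebase_stw(stw)) + (name,)
        if best is None or key < best[0]:
            best = (key, (name, seq, stw))
    return best[1]


def run_pipeline(config: RunConfig) -> dict:
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = IntronModel.from_dict(config.model) if config.model else IntronModel()

    t0 = time.time()
    sequences = read_fasta(config.fasta)
    if not sequences or all(len(s) == 0 for s in sequences):
        raise PipelineError(f"no sequences in {config.fasta}")
    genome = {s.id: s for s in sequences}

    # --- stage: scan -------------------------------------------------------
    scan = scan_genome(sequences, model, both_strands=config.both_strands)
    logger.info("scan: %d stwintron candidates (%.1fs)", len(scan.stwintrons), time.time() - t0)
    stw_seqs = [
        (f"{s.location.seq_id}:{s.location.start}-{s.location.end}({s.location.strand})",
         _feature_sequence(genome, s.location), s)
        for s in scan.stwintrons
    ]
    gff = []
    for name, _, s in stw_seqs:
        gff.append(Gff3Feature(s.location, "stwintron", attributes={"ID": name}))
        gff.append(
            Gff3Feature(s.internal.location, "internal_intron",
                        attributes={"Parent": name})
        )
    write_gff3(gff, out / "stwintrons.gff3")
    write_report(
        [
            {
                "id": name,
                "seq_id": s.location.seq_id,
                "start": s.location.start,
                "end": s.location.end,
                "strand": s.location.strand,
                "length": len(s),
                "internal_start": s.internal_span[0],
                "internal_end": s.internal_span[1],
                "central_signature": s.central_signature,
                "a23_alternative": s.a23_alternative,
            }
            for name, _, s in stw_seqs
        ],
        out / "stwintrons.tsv",
    )

    # --- stage: family -----------------------------------------------------
    if config.seed_fasta:
        seed_rec = read_fasta(config.seed_fasta)
        if not seed_rec:
            raise PipelineError(f"no sequences in {config.seed_fasta}")
        seed_name, seed_seq = seed_rec[0].id, seed_rec[0].residues
        seed_hits = find_d12_stwintrons(
            GenomicSequence(id=seed_name, residues=seed_seq), model
        )
        full = [h for h in seed_hits if h.location.start == 0 and h.location.end == len(seed_seq)]
        if not full:
            raise PipelineError("seed sequence is not a full-span (D1,2) stwintron")
        seed_stw = full[0]
    elif stw_seqs:
        seed_name, seed_seq, seed_stw = _pick_seed(stw_seqs)
        seed_stw = _rebase_stw(seed_stw)
    else:
        seed_name = seed_seq = seed_stw = None

    candidates: list[tuple[str, str, Interval]] = [
        (name, seq, s.location) for name, seq, s in stw_seqs
    ]
    candidates.extend(_intron_candidates(sequences, model))

    assignments: list[tuple] = []
    if seed_stw is not None:
        expected_len = _expected_product_lengths(seed_seq, seed_stw, model)
        for cluster in _overlap_clusters(candidates):
            best = None
            for name, seq, iv in cluster:
                fa = classify_relative(
                    name, seq, seed_seq, seed_stw, model,
                    min_identity=config.min_identity,
                )
                # among overlapping alternative parses of one locus, keep
                # the one whose length best fits its assigned category
                dev = abs(len(seq) - expected_len.get(fa.category, len(seq)))
                key = (
                    fa.category == "unrelated",
                    dev,
                    -fa.identity_to_seed,
                    name,
                )
                if best is None or key < best[0]:
                    best = (key, fa, iv)
            _, fa, iv = best
            assignments.append((fa, iv))
        assignments.sort(key=lambda t: (t[1].seq_id, t[1].start, t[1].strand))
    candidate_seqs = {name: seq for name, seq, _ in candidates}
    write_report(
        [
            {
                "member_id": fa.member_id,
                "category": fa.category,
                "identity_to_seed": round(fa.identity_to_seed, 2),
                "extra_g_subgroup": fa.extra_g_subgroup,
            }
            for fa, _ in assignments
        ],
        out / "family.tsv",
    )

    # --- stage: symmetry ---------------------------------------------------
    symmetry_rows = []
    for fa, iv in assignments:
        if fa.category == "unrelated":
            continue
        name = fa.member_id
        seq = candidate_seqs[name]
        if len(seq) < 2 * config.min_arm:
            continue
        rep = find_tir(seq, min_arm=config.min_arm, min_identity=config.min_tir_identity)
        symmetry_rows.append(
            {
                "member_id": name,
                "category": fa.category,
                "tir_present": rep.tir_present,
                "arm_length": rep.arm_length,
                "arm_identity": round(rep.arm_identity, 2),
                "spacer_length": rep.spacer_length,
                "n_palindrome_hits": len(rep.palindrome_hits),
                "duplex_score_normalised": round(rep.duplex_score_normalised, 4),
            }
        )
    write_report(symmetry_rows, out / "symmetry.tsv")

    # --- stage: crop (predicted derivation products of the seed) ----------
    crop_rows = []
    if seed_stw is not None:
        for fn, path in (
            (crop_mod.predict_type1_crop, "type1"),
            (crop_mod.predict_type2_crop, "type2"),
            (crop_mod.predict_long_intron, "long_intron"),
        ):
            try:
                ev = fn(seed_name, seed_seq, seed_stw, model)
            except crop_mod.NotACropPair:
                continue
            crop_rows.append(
                {
                    "parent_id": ev.parent_id,
                    "path": ev.path,
                    "breakpoint5": ev.breakpoint5,
                    "breakpoint3": ev.breakpoint3,
                    "product_length": len(ev.product),
                    "product_valid_intron": ev.product_valid_intron,
                    "frame_note": ev.frame_note,
                }
            )
    write_report(crop_rows, out / "crops.tsv")

    # --- stage: context ----------------------------------------------------
    genes = []
    if config.gff3:
        genes = [f for f in read_gff3(config.gff3) if f.feature_type == "gene"]
    context_rows = []
    flank_pairs = []
    leading_g = []
    phases = []
    for fa, iv in assignments:
        if fa.category == "unrelated" or iv is None or iv.strand != "+":
            continue
        gs = genome[iv.seq_id]
        f5 = gs.residues[max(0, iv.start - FLANK_WIDTH) : iv.start]
        f3 = gs.residues[iv.end : iv.end + FLANK_WIDTH]
        if len(f5) < 10 or len(f3) < 10:
            continue
        tsd = tsd_scan(f5, f3) if min(len(f5), len(f3)) >= 10 else None
        phase = None
        for g in genes:
            if g.interval.seq_id == iv.seq_id and g.interval.start <= iv.start < g.interval.end:
                phase = intron_phase(iv.start - g.interval.start)
                break
        is_stw = fa.category.startswith(("full", "sheared"))
        context_rows.append(
            {
                "member_id": fa.member_id,
                "category": fa.category,
                "phase": phase if phase is not None else "",
                "tsd_present": tsd.present if tsd else "",
                "tsd_length": tsd.length if tsd else "",
                "flank5": f5,
                "flank3": f3,
            }
        )
        if phase is not None:
            phases.append(phase)
        if len(f5) == FLANK_WIDTH and len(f3) == FLANK_WIDTH:
            flank_pairs.append((f5, f3))
            leading_g.append(is_stw)
    write_report(context_rows, out / "context.tsv")

    pfm_rows = []
    if flank_pairs:
        jm = junction_matrix(build_junction_rows(flank_pairs, leading_g))
        pfm_rows = jm.to_rows()
    write_report(pfm_rows, out / "pfm.tsv")

    # --- summary -----------------------------------------------------------
    counts: dict[str, int] = {}
    for fa, _ in assignments:
        counts[fa.category] = counts.get(fa.category, 0) + 1
    tir_members = [r for r in symmetry_rows if r["tir_present"]]
    summary = {
        "n_sequences": len(sequences),
        "n_stwintron_candidates": len(scan.stwintrons),
        "seed": seed_name,
        "category_counts": dict(sorted(counts.items())),
        "n_tir_present": len(tir_members),
        "mean_arm_length": round(
            sum(r["arm_length"] for r in tir_members) / len(tir_members), 2
        )
        if tir_members
        else None,
        "mean_arm_identity": round(
            sum(r["arm_identity"] for r in tir_members) / len(tir_members), 2
        )
        if tir_members
        else None,
        "phase_distribution": {
            str(p): phases.count(p) for p in (0, 1, 2)
        }
        if phases
        else {},
        "n_tsd_present": sum(1 for r in context_rows if r["tsd_present"] is True),
        "n_members_with_two_palindromes": sum(
            1 for r in symmetry_rows if r["n_palindrome_hits"] >= 2
        ),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _rebase_stw(stw: Stwintron) -> Stwintron:
    """Re-express a genomic stwintron call with its feature at offset 0 of
    its own sequence (the frame classify_relative expects)."""
    off = stw.location.start
    return Stwintron(
        location=Interval("seed", 0, stw.location.end - off),
        internal=type(stw.internal)(
            location=Interval(
                "seed", stw.internal.location.start - off, stw.internal.location.end - off
            ),
            donor_seq=stw.internal.donor_seq,
            bp_location=Interval(
                "seed",
                stw.internal.bp_location.start - off,
                stw.internal.bp_location.end - off,
            ),
            acceptor_seq=stw.internal.acceptor_seq,
        ),
        external_virtual=stw.external_virtual,
        central_signature=stw.central_signature,
        a23_alternative=stw.a23_alternative,
    )


def _intron_candidates(
    sequences: list[GenomicSequence],
    model: IntronModel,
    pal_min_matches: int = 7,
) -> list[tuple[str, str, Interval]]:
    """Canonical-intron candidates for cropped/long sister relatives: any
    minimal intron parse containing a (possibly degenerated) palindrome."""
    out = []
    for gs in sequences:
        pal_positions = [
            h.location.start
            for h in find_palindrome_hits(gs.residues, min_matches=pal_min_matches)
        ]
        if not pal_positions:
            continue
        for intr in find_canonical_introns(gs, model):
            iv = intr.location
            if not any(iv.start <= p < iv.end for p in pal_positions):
                continue
            out.append(
                (
                    f"{iv.seq_id}:{iv.start}-{iv.end}(intron)",
                    gs.residues[iv.start : iv.end],
                    iv,
                )
            )
    return out


def _overlap_clusters(
    candidates: list[tuple[str, str, Interval]]
) -> list[list[tuple[str, str, Interval]]]:
    """Group candidates into clusters of same-strand overlapping intervals
    (alternative parses of one locus)."""
    ordered = sorted(candidates, key=lambda c: (c[2].seq_id, c[2].strand, c[2].start, c[2].end))
    clusters: list[list[tuple[str, str, Interval]]] = []
    for cand in ordered:
        iv = cand[2]
        if (
            clusters
            and clusters[-1][-1][2].seq_id == iv.seq_id
            and clusters[-1][-1][2].strand == iv.strand
            and iv.start < max(x[2].end for x in clusters[-1])
        ):
            clusters[-1].append(cand)
        else:
            clusters.append([cand])
    return clusters


def _expected_product_lengths(
    seed_seq: str, seed_stw: Stwintron, model: IntronModel
) -> dict[str, int]:
    """Expected feature length per category, derived from the seed."""
    L = len(seed_seq)
    i_start, i_end = seed_stw.internal_span
    try:
        t2_len = len(
            crop_mod.predict_type2_crop("seed", seed_seq, seed_stw, model).product
        )
    except crop_mod.NotACropPair:
        t2_len = (L - 1) // 2
    return {
        "full_sister": L,
        "sheared_internal": L,
        "sheared_external": L,
        "long_intron": L - 1,
        "cropped_type1": i_end - i_start,
        "cropped_type2": t2_len,
    }
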