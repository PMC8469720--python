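"""Sequence data model, IUPAC degenerate matching and report I/O.

Coordinates are 0-based half-open internally; GFF3 output is converted to
the standard 1-based inclusive convention on write.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# Degeneracy sets for the 15 IUPAC nucleotide codes (DNA form).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC_ALPHABET = frozenset(IUPAC_SETS)


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a non-IUPAC character."""


def _validate_iupac(s: str) -> None:
    for i, c in enumerate(s):
        if c not in IUPAC_ALPHABET:
            raise SequenceAlphabetError(
                f"non-IUPAC character {c!r} at position {i}"
            )


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string, degenerate codes included.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    W and S are self-complementary; R pairs with Y, K with M, N with N.
    """
    s = s.upper()
    _validate_iupac(s)
    return s.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every base of *window* lies in the degeneracy set of the
    corresponding *pattern* symbol.

    An ``N`` in the genomic window is treated conservatively: it satisfies
    only a pattern ``N``, never a more specific symbol.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    pattern = pattern.upper()
    window = window.upper()
    _validate_iupac(pattern)
    _validate_iupac(window)
    for p, w in zip(pattern, window):
        if w == "N":
            if p != "N":
                return False
        elif not IUPAC_SETS[w] <= IUPAC_SETS[p]:
            return False
    return True


def iupac_mismatch_count(pattern: str, window: str) -> int:
    """Number of positions where *window* falls outside *pattern*'s
    degeneracy set (same N policy as :func:`iupac_match`)."""
    if len(pattern) != len(window):
        raise ValueError("length mismatch")
    n = 0
    for p, w in zip(pattern.upper(), window.upper()):
        if w == "N":
            if p != "N":
                n += 1
        elif not IUPAC_SETS[w] <= IUPAC_SETS[p]:
            n += 1
    return n


@dataclass(frozen=True)
class Interval:
    """0-based half-open located interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomicSequence:
    """A named DNA sequence, uppercased on construction."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        _validate_iupac(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, iv: Interval) -> str:
        s = self.residues[iv.start : iv.end]
        return reverse_complement(s) if iv.strand == "-" else s


@dataclass
class IntronModel:
    """Motif grammar for canonical fungal U2 introns.

    donor_pattern is the DNA form of the consensus donor; the branch-point
    element is 6 nt with the branch A at its fifth position; the acceptor
    is the 3-nt terminal element.
    """

    donor_pattern: str = "GTRWGY"
    bp_pattern: str = "RCTRAC"
    acceptor_pattern: str = "YAG"
    min_intron_len: int = 40
    max_intron_len: int = 600
    bp_to_acceptor_min: int = 4
    bp_to_acceptor_max: int = 60
    allow_gc_internal_donor: bool = True

    def __post_init__(self) -> None:
        for pat, n, name in (
            (self.donor_pattern, 6, "donor"),
            (self.bp_pattern, 6, "branch point"),
            (self.acceptor_pattern, 3, "acceptor"),
        ):
            _validate_iupac(pat.upper())
            if len(pat) != n:
                raise ValueError(f"{name} pattern must be {n} nt, got {pat!r}")
        self.donor_pattern = self.donor_pattern.upper()
        self.bp_pattern = self.bp_pattern.upper()
        self.acceptor_pattern = self.acceptor_pattern.upper()
        floor = len(self.donor_pattern) + len(self.bp_pattern) + len(
            self.acceptor_pattern
        )
        if self.min_intron_len < floor:
            raise ValueError(
                f"min_intron_len {self.min_intron_len} below motif floor {floor}"
            )
        if self.max_intron_len < self.min_intron_len:
            raise ValueError("max_intron_len < min_intron_len")

    @property
    def gc_donor_pattern(self) -> str:
        """GC-AG variant of the donor, used for internal introns of
        GGC-starting features."""
        return self.donor_pattern[0] + "C" + self.donor_pattern[2:]

    @classmethod
    def from_dict(cls, d: dict) -> "IntronModel":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a (multi-)FASTA file into :class:`GenomicSequence` records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            GenomicSequence(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    if not records:
        logger.warning("no FASTA records in %s", path)
    return records


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class Gff3Feature:
    interval: Interval
    feature_type: str
    source: str = "stwinscan"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Sequence[Gff3Feature], path: str | Path) -> None:
    """Write features as GFF3, converting to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        f.source,
                        f.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        f.score,
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    """Read GFF3 back to internal 0-based half-open features."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, source, ftype, start, end, score, strand, _, attr_col = cols
            attrs = {}
            if attr_col != ".":
                for kv in attr_col.split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k] = v
            feats.append(
                Gff3Feature(
                    interval=Interval(seq_id, int(start) - 1, int(end), strand),
                    feature_type=ftype,
                    source=source,
                    score=score,
                    attributes=attrs,
                )
            )
    return feats


def write_report(rows: Sequence[dict], path: str | Path, format: str = "TSV") -> None:
    """Write tabular report rows as TSV (header row) or JSON (UTF-8)."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "TSV":
        with open(path, "w", encoding="utf-8") as fh:
            if rows:
                cols = list(rows[0].keys())
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
    elif fmt == "JSON":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(list(rows), fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
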