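"""Independent brute-force oracles used to validate the scanner.

These enumerate every (donor, branch point, acceptor) index triple directly
from the motif definitions, with no shared code path with the package's
scanning logic beyond the IUPAC degeneracy tables.
"""

from __future__ import annotations

from stwinscan.seqcore import IUPAC_SETS, IntronModel


def _match(pattern: str, window: str) -> bool:
    if len(pattern) != len(window):
        return False
    for p, w in zip(pattern, window):
        if w == "N":
            if p != "N":
                return False
        elif w not in IUPAC_SETS[p]:
            return False
    return True


def oracle_introns(seq: str, model: IntronModel, mode: str = "intron-definition",
                   donor_pattern: str | None = None):
    """All introns as (start, end, bp_start) tuples by exhaustive enumeration."""
    donor = donor_pattern or model.donor_pattern
    out = []
    for d in range(len(seq) - len(donor) + 1):
        if not _match(donor, seq[d : d + len(donor)]):
            continue
        cands = []
        for end in range(d + model.min_intron_len, min(len(seq), d + model.max_intron_len) + 1):
            if not _match(model.acceptor_pattern, seq[end - 3 : end]):
                continue
            bps = []
            for b in range(d + len(donor), end - 3 - 6 + 1):
                if not _match(model.bp_pattern, seq[b : b + 6]):
                    continue
                gap = (end - 3) - (b + 6)
                if model.bp_to_acceptor_min <= gap <= model.bp_to_acceptor_max:
                    bps.append(b)
            for b in bps:
                cands.append((end - d, b, end))
        cands.sort()
        if mode == "intron-definition":
            if cands:
                length, b, end = cands[0]
                # the scanner keeps the leftmost BP of the minimal intron
                min_len = cands[0][0]
                bs = [c[1] for c in cands if c[0] == min_len]
                out.append((d, d + min_len, min(bs)))
        else:
            out.extend((d, end, b) for length, b, end in cands)
    return out


def oracle_stwintrons(seq: str, model: IntronModel):
    """(g1, internal_start, internal_end, feature_end) by enumeration."""
    donors = [model.donor_pattern]
    if model.allow_gc_internal_donor:
        donors.append(model.donor_pattern[0] + "C" + model.donor_pattern[2:])
    out = []
    for g in range(len(seq) - 1):
        if seq[g] != "G":
            continue
        internals = []
        for pat in donors:
            if _match(pat, seq[g + 1 : g + 1 + len(pat)]):
                for start, end, b in oracle_introns(seq[g + 1 :], model, "exhaustive", pat):
                    if start == 0:
                        internals.append((end - start, g + 1 + b, g + 1, g + 1 + end))
        internals.sort()
        for _, _, i_start, i_end in internals:
            recon = seq[g] + seq[i_end : i_end + 5]
            if len(recon) < 6 or not _match(model.donor_pattern, recon):
                continue
            splinter = seq[g] + seq[i_end:]
            ext = [
                (start, end, b)
                for start, end, b in oracle_introns(splinter, model)
                if start == 0
            ]
            if not ext:
                continue
            ext_len = ext[0][1]
            out.append((g, i_start, i_end, i_end + ext_len - 1))
            break
    return out
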