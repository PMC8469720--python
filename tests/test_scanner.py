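import numpy as np
import pytest

from stwinscan.scanner import (
    find_canonical_introns,
    find_d12_stwintrons,
    scan_genome,
)
from stwinscan.seqcore import GenomicSequence, IntronModel, reverse_complement
from stwinscan.synth import _random_dna, evolve_copy, make_template, TemplateParams

from .oracles import oracle_introns, oracle_stwintrons


def _intron_tuples(introns):
    return [
        (i.location.start, i.location.end, i.bp_location.start) for i in introns
    ]


def _stw_tuples(stws):
    return [
        (s.location.start, s.internal.location.start, s.internal.location.end, s.location.end)
        for s in stws
    ]


class TestFindCanonicalIntrons:
    def test_single_planted_intron(self, model):
        # poly-A background cannot satisfy any motif by accident
        intron = "GTAAGT" + "A" * 40 + "ACTAAC" + "AAAA" + "TAG"
        seq = "A" * 120 + intron + "A" * 121
        gs = GenomicSequence(id="toy", residues=seq)
        got = find_canonical_introns(gs, model)
        expected = oracle_introns(seq, model)
        assert _intron_tuples(got) == expected
        assert len(got) == 1
        assert got[0].location.start == 120
        assert got[0].location.end == 120 + len(intron)

    def test_poly_a_is_empty(self, model):
        gs = GenomicSequence(id="polya", residues="A" * 300)
        assert find_canonical_introns(gs, model) == []

    def test_two_acceptors_nearer_chosen(self, model):
        intron = "GTAAGT" + "A" * 30 + "ACTAAC" + "AAAA" + "TAG"
        seq = "C" * 10 + intron + "AAAA" + "TAG" + "C" * 10
        gs = GenomicSequence(id="toy", residues=seq)
        got = find_canonical_introns(gs, model)
        oracle = oracle_introns(seq, model)
        assert _intron_tuples(got) == oracle
        assert got[0].location.end == 10 + len(intron)

    def test_exhaustive_mode_superset(self, model):
        intron = "GTAAGT" + "A" * 30 + "ACTAAC" + "AAAA" + "TAG"
        seq = "C" * 10 + intron + "AAAA" + "TAG" + "C" * 10
        gs = GenomicSequence(id="toy", residues=seq)
        got = find_canonical_introns(gs, model, mode="exhaustive")
        oracle = oracle_introns(seq, model, "exhaustive")
        assert sorted(_intron_tuples(got)) == sorted(oracle)
        assert len(got) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random(self, model, seed):
        rng = np.random.default_rng(seed)
        seq = _random_dna(800, rng)
        gs = GenomicSequence(id=f"r{seed}", residues=seq)
        assert _intron_tuples(find_canonical_introns(gs, model)) == oracle_introns(
            seq, model
        )


class TestFindD12Stwintrons:
    def test_template_detected_at_offset_zero(self, model, template42):
        gs = GenomicSequence(id="t", residues=template42.sequence)
        hits = find_d12_stwintrons(gs, model)
        assert len(hits) == 1
        stw = hits[0]
        assert stw.location.start == 0
        assert stw.location.end == len(template42.sequence)
        assert stw.internal_span == template42.internal_span
        assert stw.central_signature == "AGT"

    def test_oracle_equivalence_on_template_in_context(self, model, template42, rng):
        seq = _random_dna(200, rng) + template42.sequence + _random_dna(200, rng)
        gs = GenomicSequence(id="ctx", residues=seq)
        got = _stw_tuples(find_d12_stwintrons(gs, model))
        assert got == oracle_stwintrons(seq, model)

    def test_mutated_central_t_kills_feature(self, model, template42):
        seq = list(template42.sequence)
        i_end = template42.internal_span[1]
        assert seq[i_end] == "T"
        seq[i_end] = "C"
        gs = GenomicSequence(id="mut", residues="".join(seq))
        hits = [h for h in find_d12_stwintrons(gs, model) if h.location.start == 0]
        assert hits == []

    def test_a23_alternative_flag(self, model, template42):
        seq = template42.sequence + "GAAAAA"
        hits = find_d12_stwintrons(GenomicSequence(id="g", residues=seq), model)
        full = [h for h in hits if h.location.start == 0]
        assert full and full[0].a23_alternative is True
        seq2 = template42.sequence + "CAAAAA"
        hits2 = find_d12_stwintrons(GenomicSequence(id="c", residues=seq2), model)
        full2 = [h for h in hits2 if h.location.start == 0]
        assert full2 and full2[0].a23_alternative is False

    def test_revalidation_excise_and_rescan(self, model, template42, rng):
        """Excising the internal intron leaves a valid canonical intron at
        offset 0 of the remainder."""
        seq = _random_dna(100, rng) + template42.sequence + _random_dna(100, rng)
        gs = GenomicSequence(id="g", residues=seq)
        for stw in find_d12_stwintrons(gs, model):
            spliced = (
                seq[stw.location.start]
                + seq[stw.internal.location.end : stw.location.end]
            )
            sub = GenomicSequence(id="sub", residues=spliced)
            hits = find_canonical_introns(sub, model)
            assert any(
                h.location.start == 0 and h.location.end == len(spliced) for h in hits
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_random(self, model, seed):
        rng = np.random.default_rng(100 + seed)
        seq = _random_dna(1500, rng)
        gs = GenomicSequence(id=f"r{seed}", residues=seq)
        assert _stw_tuples(find_d12_stwintrons(gs, model)) == oracle_stwintrons(
            seq, model
        )


class TestScanGenome:
    def test_reverse_strand_coordinates(self, model, template42, rng):
        fwd = _random_dna(150, rng) + template42.sequence + _random_dna(150, rng)
        rev = reverse_complement(fwd)
        gs = GenomicSequence(id="c1", residues=rev)
        res = scan_genome([gs], model)
        minus = [s for s in res.stwintrons if s.location.strand == "-"]
        assert any(
            s.location.start == 150 and s.location.end == 150 + len(template42.sequence)
            for s in minus
        )
        # the reported interval re-extracts to the template on the - strand
        hit = next(
            s for s in minus
            if s.location.start == 150
            and s.location.end == 150 + len(template42.sequence)
        )
        assert gs.subseq(hit.location) == template42.sequence

    def test_empty_genome(self, model):
        res = scan_genome([], model)
        assert res.stwintrons == [] and res.introns == []

    def test_deterministic_ordering(self, model, template42, rng):
        seqs = [
            GenomicSequence(
                id=f"c{k}",
                residues=_random_dna(100, rng) + template42.sequence + _random_dna(100, rng),
            )
            for k in range(3)
        ]
        a = scan_genome(seqs, model)
        b = scan_genome(seqs, model)
        assert _stw_tuples(a.stwintrons) == _stw_tuples(b.stwintrons)
        keys = [
            (s.location.seq_id, s.location.start, s.location.strand)
            for s in a.stwintrons
        ]
        assert keys == sorted(keys)


class TestRecovery:
    def test_planted_copies_recovered(self, model, template42):
        """>=95% of evolved copies at <=10% divergence are found with exact
        coordinates in genomic context."""
        rng = np.random.default_rng(9)
        n_ok = 0
        n = 40
        for k in range(n):
            ev = evolve_copy(
                template42.sequence,
                rate=rng.uniform(0, 0.10),
                protect_motifs=True,
                protected=template42.protected,
                seed=rng,
            )
            seq = _random_dna(80, rng) + ev.sequence + _random_dna(80, rng)
            gs = GenomicSequence(id=f"g{k}", residues=seq)
            hits = find_d12_stwintrons(gs, model)
            if any(
                h.location.start == 80 and h.location.end == 80 + len(ev.sequence)
                for h in hits
            ):
                n_ok += 1
        assert n_ok / n >= 0.95
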