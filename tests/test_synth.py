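import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from stwinscan.family import global_align
from stwinscan.scanner import find_d12_stwintrons
from stwinscan.seqcore import GenomicSequence, read_fasta
from stwinscan.symmetry import find_palindrome_hits, find_tir
from stwinscan.synth import (
    SimParams,
    TemplateParams,
    build_genome,
    copy_is_splice_valid,
    evolve_copy,
    make_template,
)


class TestMakeTemplate:
    def test_scanner_contract(self, model, template42):
        gs = GenomicSequence(id="t", residues=template42.sequence)
        hits = find_d12_stwintrons(gs, model)
        assert len(hits) == 1
        assert hits[0].location.start == 0
        assert hits[0].location.end == len(template42.sequence)

    def test_starts_ggt(self, template42):
        assert template42.sequence.startswith("GGT")

    def test_tir_contract(self, template42):
        rep = find_tir(template42.sequence)
        assert rep.tir_present
        assert 45 <= rep.arm_length <= 55
        assert rep.arm_identity >= 70.0

    def test_exactly_two_palindromes(self, template42):
        hits = find_palindrome_hits(template42.sequence)
        assert len(hits) == 2
        # 5' copy perfect (W=T), 3' copy imperfect (W=A)
        assert hits[0].observed == "TTTCTAGAAA"
        assert hits[0].w_base == "T"
        assert hits[1].w_base == "A"

    def test_spacer_between_palindromes(self, template42):
        h5, h3 = find_palindrome_hits(template42.sequence)
        assert h3.location.start - h5.location.end == template42.spacer_length
        assert 90 <= template42.spacer_length <= 110

    def test_deterministic(self, model):
        a = make_template(TemplateParams(), model, 5)
        b = make_template(TemplateParams(), model, 5)
        assert a.sequence == b.sequence


class TestEvolveCopy:
    def test_rate_zero_identity(self, template42):
        ev = evolve_copy(template42.sequence, 0.0, seed=1)
        assert ev.sequence == template42.sequence
        assert ev.realised_divergence == 0.0

    def test_protected_copies_stay_valid(self, model, template42):
        rng = np.random.default_rng(9)
        n_valid = 0
        for _ in range(100):
            ev = evolve_copy(
                template42.sequence, 0.1, protect_motifs=True,
                protected=template42.protected, seed=rng,
            )
            n_valid += copy_is_splice_valid(ev.sequence, "full_sister", model)
        assert n_valid >= 95  # mutation can still reroute a parse occasionally

    def test_unprotected_strictly_worse(self, model, template42):
        rng = np.random.default_rng(9)
        n_prot = n_unprot = 0
        for _ in range(60):
            ev_p = evolve_copy(
                template42.sequence, 0.1, protect_motifs=True,
                protected=template42.protected, seed=rng,
            )
            ev_u = evolve_copy(
                template42.sequence, 0.1, protect_motifs=False,
                protected=template42.protected, seed=rng,
            )
            n_prot += copy_is_splice_valid(ev_p.sequence, "full_sister", model)
            n_unprot += copy_is_splice_valid(ev_u.sequence, "full_sister", model)
        assert n_unprot < n_prot

    def test_rate_bounds(self, template42):
        with pytest.raises(ValueError):
            evolve_copy(template42.sequence, 0.6)

    def test_divergence_monotone(self, template42):
        """Mean identity to the template decreases with the rate dial."""
        rates = [0.0, 0.05, 0.1, 0.15, 0.2, 0.3]
        means = []
        for r_i, rate in enumerate(rates):
            rng = np.random.default_rng(1000 + r_i)
            ids = []
            for _ in range(8):
                ev = evolve_copy(
                    template42.sequence, rate, protected=template42.protected, seed=rng
                )
                ids.append(
                    global_align(template42.sequence, ev.sequence).percent_identity
                )
            means.append(np.mean(ids))
        rho, _ = spearmanr(rates, means)
        assert rho < 0


class TestBuildGenome:
    def test_truth_counts(self, sim_genome):
        p = sim_genome.params
        cats = [r.category for r in sim_genome.truth]
        assert cats.count("full_sister") == p.n_full_copies
        assert cats.count("cropped_type1") == p.n_type1
        assert cats.count("cropped_type2") == p.n_type2
        assert cats.count("long_intron") == p.n_long
        assert sum(c.startswith("sheared") for c in cats) == p.n_sheared

    def test_coordinates_match_sequences(self, sim_genome):
        g = sim_genome.genome.residues
        for rec in sim_genome.truth:
            assert g[rec.genome_start : rec.genome_end] == rec.sequence

    def test_seamless_round_trip(self, sim_genome):
        """Deleting every planted element (and background intron) restores
        each pre-insertion gene exactly."""
        g = sim_genome.genome.residues
        gene_feats = {
            f.attributes["ID"]: f.interval
            for f in sim_genome.features
            if f.feature_type == "gene"
        }
        inserts = {}
        for f in sim_genome.features:
            if f.feature_type in ("planted_element", "background_intron"):
                inserts.setdefault(f.attributes["gene"], []).append(f.interval)
        for gid, iv in gene_feats.items():
            seq = g[iv.start : iv.end]
            removed = seq
            for ins in sorted(inserts.get(gid, []), key=lambda x: -x.start):
                a, b = ins.start - iv.start, ins.end - iv.start
                removed = removed[:a] + removed[b:]
            assert removed == sim_genome.pre_insertion_genes[gid]

    def test_type2_products_single_palindrome(self, model):
        sg = build_genome(SimParams(seed=3, n_type2=6, divergence=(0.0, 0.0)), model)
        t2 = [r for r in sg.truth if r.category == "cropped_type2"]
        assert len(t2) == 6
        for rec in t2:
            assert len(find_palindrome_hits(rec.sequence)) == 1

    def test_determinism_byte_identical(self, model, tmp_path):
        a = build_genome(SimParams(seed=11), model)
        b = build_genome(SimParams(seed=11), model)
        assert a.genome.residues == b.genome.residues
        assert a.truth_json() == b.truth_json()
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("genome.fasta", "genes.gff3", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_written_outputs_consistent(self, sim_genome, tmp_path):
        sim_genome.write(tmp_path / "sim")
        back = read_fasta(tmp_path / "sim" / "genome.fasta")
        assert back[0].residues == sim_genome.genome.residues
        truth = json.loads((tmp_path / "sim" / "truth.json").read_text())
        assert len(truth) == len(sim_genome.truth)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SimParams(divergence=(0.0, 1.5))
        with pytest.raises(ValueError):
            SimParams(n_genes=-1)

    def test_zero_planted_no_family_stwintrons(self, model):
        sg = build_genome(
            SimParams(seed=4, n_full_copies=0, n_sheared=0, n_type1=0,
                      n_type2=0, n_long=0, n_genes=6),
            model,
        )
        assert sg.truth == []
        # background can contain chance grammar hits; report only
        from stwinscan.scanner import scan_genome

        res = scan_genome([sg.genome], model, both_strands=False)
        with_two_pals = [
            s
            for s in res.stwintrons
            if len(find_palindrome_hits(
                sg.genome.residues[s.location.start : s.location.end]
            )) >= 2
        ]
        assert with_two_pals == []
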