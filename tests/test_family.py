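import numpy as np
import pytest

from stwinscan.family import (
    FamilyAssignment,
    classify_relative,
    collect_family,
    global_align,
)
from stwinscan.seqcore import GenomicSequence
from stwinscan.synth import (
    _random_dna,
    derive_long,
    derive_type1,
    derive_type2,
    evolve_copy,
    make_sheared,
)


def _nw_score_oracle(a, b, match=2, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Plain affine-gap DP, scores only, written independently."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend, Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


class TestGlobalAlign:
    def test_identical(self):
        aln = global_align("A" * 100, "A" * 100)
        assert aln.percent_identity == 100.0
        assert aln.score == 200

    def test_degapping_restores_inputs(self, rng):
        a = _random_dna(80, rng)
        b = _random_dna(70, rng)
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("ACGT", "")

    @pytest.mark.parametrize("seed", range(5))
    def test_optimal_score_vs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_dna(int(rng.integers(5, 40)), rng)
        b = _random_dna(int(rng.integers(5, 40)), rng)
        aln = global_align(a, b)
        assert aln.score == _nw_score_oracle(a, b)

    def test_substituted_copy_identity(self, rng):
        a = _random_dna(100, rng)
        b = list(a)
        pos = rng.choice(100, size=10, replace=False)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        aln = global_align(a, "".join(b))
        assert aln.percent_identity >= 90.0
        assert aln.score == _nw_score_oracle(a, "".join(b))

    def test_deterministic(self, rng):
        a, b = _random_dna(120, rng), _random_dna(110, rng)
        x = global_align(a, b)
        y = global_align(a, b)
        assert (x.aligned_a, x.aligned_b, x.score) == (y.aligned_a, y.aligned_b, y.score)

    def test_local_blocks_consistent(self, rng):
        a, b = _random_dna(60, rng), _random_dna(60, rng)
        aln = global_align(a, b)
        for blk in aln.local_blocks:
            assert blk.a_end - blk.a_start == blk.b_end - blk.b_start
            assert 0 <= blk.identity <= 100


class TestCollectFamily:
    def test_copies_in_randoms_out(self, model, template42):
        rng = np.random.default_rng(42)
        seed = GenomicSequence(id="seed", residues=template42.sequence)
        cands = [seed]
        for k in range(5):
            ev = evolve_copy(
                template42.sequence, 0.2, protected=template42.protected, seed=rng
            )
            cands.append(GenomicSequence(id=f"copy{k}", residues=ev.sequence))
        for k in range(5):
            cands.append(
                GenomicSequence(id=f"rand{k}", residues=_random_dna(len(template42), rng))
            )
        fam = collect_family(cands, seed, min_identity=55.0)
        assert {m.member_id for m in fam} == {"seed"} | {f"copy{k}" for k in range(5)}
        for m in fam:
            assert m.identity_to_seed >= 55.0

    def test_threshold_above_100_empty(self, template42):
        seed = GenomicSequence(id="seed", residues=template42.sequence)
        assert collect_family([seed], seed, min_identity=101) == []

    def test_empty_candidates(self, template42):
        seed = GenomicSequence(id="seed", residues=template42.sequence)
        assert collect_family([], seed) == []


class TestClassifyRelative:
    def test_verbatim_internal_is_type1(self, model, template42):
        i0, i1 = template42.internal_span
        element = template42.sequence[i0:i1]
        fa = classify_relative("x", element, template42.sequence, template42.stw, model)
        assert fa.category == "cropped_type1"

    def test_type2_construction(self, model, template42):
        seq, _ = derive_type2(template42, model)
        fa = classify_relative("x", seq, template42.sequence, template42.stw, model)
        assert fa.category == "cropped_type2"

    def test_long_intron(self, model, template42):
        seq, _ = derive_long(template42, model)
        fa = classify_relative("x", seq, template42.sequence, template42.stw, model)
        assert fa.category == "long_intron"

    def test_diverged_copy_is_full_sister(self, model, template42):
        rng = np.random.default_rng(7)
        ev = evolve_copy(
            template42.sequence, 0.2, protected=template42.protected, seed=rng
        )
        fa = classify_relative(
            "x", ev.sequence, template42.sequence, template42.stw, model
        )
        assert fa.category == "full_sister"
        assert fa.identity_to_seed >= 55.0

    def test_random_is_unrelated(self, model, template42, rng):
        fa = classify_relative(
            "x", _random_dna(len(template42), rng), template42.sequence,
            template42.stw, model,
        )
        assert fa.category == "unrelated"
        assert fa.identity_to_seed < 55.0

    @pytest.mark.parametrize("which", ["internal", "external"])
    def test_sheared(self, model, template42, which):
        rng = np.random.default_rng(3)
        seq, _ = make_sheared(template42, model, which, rng)
        fa = classify_relative("x", seq, template42.sequence, template42.stw, model)
        assert fa.category == f"sheared_{which}"

    def test_extra_g_attribute_only_on_type2(self):
        with pytest.raises(ValueError):
            FamilyAssignment("x", "full_sister", 80.0, extra_g_subgroup=True)

    def test_extra_g_detected(self, model, template42):
        seq, _ = derive_type2(template42, model)
        # insert a G directly upstream of the 3-nt acceptor
        with_g = seq[:-3] + "G" + seq[-3:]
        fa = classify_relative("x", with_g, template42.sequence, template42.stw, model)
        if fa.category == "cropped_type2":
            assert fa.extra_g_subgroup is True

    def test_category_recovery_rate(self, model, sim_genome):
        """>=90% of planted elements at <=15% divergence classified to the
        planted category from the labelled truth sequences."""
        ok = 0
        for rec in sim_genome.truth:
            fa = classify_relative(
                rec.element_id,
                rec.sequence,
                sim_genome.template.sequence,
                sim_genome.template.stw,
                model,
            )
            ok += fa.category == rec.category
        assert ok / len(sim_genome.truth) >= 0.90
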