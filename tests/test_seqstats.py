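"""Sequence statistics: GC, 3n fractions, PWMs, SNP impact, workhorse tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from exitron_scan import gio, seqstats, synthio
from exitron_scan.seqstats import (Pwm, binomial_test, build_pwm, fraction_3n,
                                   gc_content, mww_test, score_site,
                                   snp_codon_positions, snp_splice_impact)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0), ("ATAT", 0.0), ("GANC", 2 / 3), ("acgt", 0.5),
    ])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNN")


class TestFraction3n:
    def test_simple_lengths(self):
        frac, n3, n = fraction_3n([9, 10, 12])
        assert (frac, n3, n) == (pytest.approx(2 / 3), 2, 3)

    def test_stop_free_rule_removes_members(self):
        # a 9-mer with TAA in frame 0 fails the fixed-frame stop-free rule
        frac, n3, n = fraction_3n([9], sequences=["ATGTAACCC"],
                                  require_stop_free=True, frame=0)
        assert (n3, n) == (0, 1)
        # but counts under "any frame" if another frame is stop-free
        frac, n3, _ = fraction_3n([9], sequences=["ATGTAACCC"],
                                  require_stop_free=True, frame="any")
        assert n3 == 1

    def test_planted_catalog_fraction_equals_config(self):
        cfg = synthio.SynthConfig(n_genes=48, exitron_fraction=1.0,
                                  eix3_fraction=0.458, seed=6)
        _, _, truth = synthio.generate_genome(cfg)
        lengths = [x.length for x in truth.planted_exitrons]
        frac, n3, n = fraction_3n(lengths)
        assert n == 48
        assert n3 == round(48 * 0.458)
        assert frac == pytest.approx(n3 / 48)


def _tiny_sites():
    """5 identical-window introns on a hand-made contig."""
    seqs, introns = [], []
    donors = ["GTAAGTATCA", "GTAAGAATCA", "GTTAGTATCA", "GTAAGTTTCA",
              "GTCAGTATCA"]
    contig = []
    pos = 0
    for d in donors:
        exon = "CAGGCA"          # 6 exonic bases before the donor
        intron = d + "T" * 20 + "TTTCTTTCTTTCAG"  # acceptor window inside
        contig.append(exon + intron + "GCCGCA")
        s = pos + len(exon)
        e = s + len(intron)
        introns.append(("c", s, e, "+"))
        pos += len(exon + intron + "GCCGCA")
    return gio.GenomeSequence({"c": "".join(contig)}), introns


class TestPwm:
    def test_counts_match_hand_tally(self):
        genome, introns = _tiny_sites()
        pwm = build_pwm(introns, genome, "donor", pseudocount=1.0)
        # hand-count the donor windows (3 exonic + 10 intronic bases)
        windows = [genome.fetch("c", s - 3, s + 10) for _, s, _, _ in introns]
        for i in range(13):
            for j, b in enumerate("ACGT"):
                assert pwm.counts[i, j] == sum(w[i] == b for w in windows)

    def test_consensus_achieves_relative_one(self):
        genome, introns = _tiny_sites()
        pwm = build_pwm(introns, genome, "donor")
        assert pwm.relative(pwm.score(pwm.consensus)) == pytest.approx(1.0)
        assert pwm.consensus[3:5] == "GT"

    def test_score_additivity_and_dot_product_oracle(self):
        genome, introns = _tiny_sites()
        pwm = build_pwm(introns, genome, "donor")
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = "".join(rng.choice(list("ACGT"), pwm.width))
            brute = sum(pwm.log_odds[i, "ACGT".index(b)]
                        for i, b in enumerate(w))
            assert pwm.score(w) == pytest.approx(brute, abs=1e-12)
            # additivity over positions
            singles = [pwm.log_odds[i, "ACGT".index(b)]
                       for i, b in enumerate(w)]
            assert pwm.score(w) == pytest.approx(sum(singles), abs=1e-12)

    def test_uniform_training_scores_near_zero(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 20000))
        genome = gio.GenomeSequence({"c": seq})
        introns = [("c", int(p), int(p) + 60, "+")
                   for p in rng.integers(20, 19000, 300)]
        pwm = build_pwm(introns, genome, "donor")
        w = "".join(rng.choice(list("ACGT"), pwm.width))
        scores = [pwm.score("".join(rng.choice(list("ACGT"), pwm.width)))
                  for _ in range(200)]
        assert abs(np.mean(scores)) < 1.0  # ~0 bits in expectation

    def test_minus_strand_windows_are_strand_correct(self, small_study):
        """Training on +/- introns together still centres on GT/AG."""
        introns = [(m.contig, s, e, m.strand) for m in small_study.models
                   for s, e in m.introns]
        assert any(strand == "-" for _, _, _, strand in introns)
        pwm_d = build_pwm(introns, small_study.genome, "donor")
        pwm_a = build_pwm(introns, small_study.genome, "acceptor")
        # intronic +1/+2 of the donor consensus is GT; acceptor ends AG+exon
        assert pwm_d.consensus[3:5] == "GT"
        assert pwm_a.consensus[12:14] == "AG"

    def test_exitrons_score_weaker_than_real_introns(self, small_study):
        """Planted exitron signals are minimal GT/AG, so they score below the
        constitutive-intron consensus sites on average."""
        introns = [(m.contig, s, e, m.strand) for m in small_study.models
                   for s, e in m.introns]
        pwm = build_pwm(introns, small_study.genome, "donor")
        intron_scores = [score_site(pwm, small_study.genome, c, s, e, st)
                         for c, s, e, st in introns]
        x_scores = [score_site(pwm, small_study.genome, x.contig, x.start,
                               x.end, x.strand)
                    for x in small_study.truth.planted_exitrons]
        assert np.mean(x_scores) < np.mean(intron_scores)


class TestSnpImpact:
    def test_delta_equals_full_rescore(self, small_study):
        """Additivity makes the column delta identical to re-scoring a
        mutated genome (exact, not approximate)."""
        genome = small_study.genome
        introns = [(m.contig, s, e, m.strand) for m in small_study.models
                   for s, e in m.introns]
        truth = synthio.TruthSet(
            planted_exitrons=list(small_study.truth.planted_exitrons))
        synthio.inject_snps(truth, small_study.models, genome, snp_rate=40,
                            signal_fraction=0.5, base_seed=4)
        xmap = truth.by_id()
        checked = 0
        for kind in ("donor", "acceptor"):
            pwm = build_pwm(introns, genome, kind)
            for ps in truth.planted_snps:
                x = xmap[ps.exitron_id]
                v = gio.Variant(ps.contig, ps.pos, ps.ref, ps.alt)
                rec = snp_splice_impact(pwm, v, x.start, x.end, x.strand)
                if rec.direction == "outside_signal":
                    continue
                seq = genome[x.contig]
                mutated = gio.GenomeSequence(
                    {x.contig: seq[:ps.pos] + ps.alt + seq[ps.pos + 1:]})
                d_ref = score_site(pwm, genome, x.contig, x.start, x.end,
                                   x.strand)
                d_alt = score_site(pwm, mutated, x.contig, x.start, x.end,
                                   x.strand)
                assert rec.delta == pytest.approx(d_alt - d_ref, abs=1e-12)
                checked += 1
        assert checked >= 5

    def test_donor_plus_one_g_to_a_weakens(self, small_study):
        introns = [(m.contig, s, e, m.strand) for m in small_study.models
                   for s, e in m.introns]
        pwm = build_pwm(introns, small_study.genome, "donor")
        x = next(x for x in small_study.truth.planted_exitrons
                 if x.strand == "+")
        v = gio.Variant(x.contig, x.start, "G", "A")
        rec = snp_splice_impact(pwm, v, x.start, x.end, x.strand)
        assert rec.direction == "weaken" and rec.delta < 0
        assert rec.offset == 1

    def test_ref_equals_alt_is_neutral(self, small_study):
        introns = [(m.contig, s, e, m.strand) for m in small_study.models
                   for s, e in m.introns]
        pwm = build_pwm(introns, small_study.genome, "donor")
        x = next(x for x in small_study.truth.planted_exitrons
                 if x.strand == "+")
        rec = snp_splice_impact(pwm, gio.Variant(x.contig, x.start, "G", "G"),
                                x.start, x.end, x.strand)
        assert rec.direction == "neutral" and rec.delta == 0.0

    def test_outside_window_flagged(self, small_study):
        introns = [(m.contig, s, e, m.strand) for m in small_study.models
                   for s, e in m.introns]
        pwm = build_pwm(introns, small_study.genome, "donor")
        x = small_study.truth.planted_exitrons[0]
        mid = (x.start + x.end) // 2
        ref = small_study.genome.fetch(x.contig, mid, mid + 1)
        rec = snp_splice_impact(pwm, gio.Variant(x.contig, mid, ref, "A"),
                                x.start, x.end, x.strand)
        assert rec.direction == "outside_signal"


class TestCodonPositions:
    def test_biased_planting_detected(self, small_study):
        truth = synthio.TruthSet(
            planted_exitrons=list(small_study.truth.planted_exitrons))
        variants = synthio.inject_snps(truth, small_study.models,
                                       small_study.genome, snp_rate=30,
                                       codon_bias=(0, 0, 1), base_seed=9)
        tally = snp_codon_positions(variants, small_study.models)
        assert (tally.n1, tally.n2) == (0, 0)
        assert tally.n3 == len(variants)
        assert tally.p_value < 0.05

    def test_single_snp_offset_five_is_position_three(self, toy_genome,
                                                      toy_model):
        # CDS offset 5 (0-based) is the third base of the second codon
        pos = 15  # genomic; exon starts at 10 -> offset 5
        ref = toy_genome.fetch("t", pos, pos + 1)
        tally = snp_codon_positions([gio.Variant("t", pos, ref, "C")],
                                    [toy_model])
        assert (tally.n1, tally.n2, tally.n3) == (0, 0, 1)

    def test_uniform_planting_rarely_rejects(self, small_study):
        """Calibration: uniform codon bias yields p > 0.05 in >= 90% of seeds."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            truth = synthio.TruthSet(
                planted_exitrons=list(small_study.truth.planted_exitrons))
            variants = synthio.inject_snps(
                truth, small_study.models, small_study.genome, snp_rate=60,
                codon_bias=(1 / 3, 1 / 3, 1 / 3), base_seed=seed)
            tally = snp_codon_positions(variants, small_study.models)
            ok += tally.p_value > 0.05
        assert ok >= int(0.9 * n_seeds)


def _exact_binomial_p(k, n, p0, alternative):
    """Exact-rational enumeration oracle for the binomial test."""
    p0 = Fraction(p0).limit_denominator(10**6)
    pmf = [Fraction(comb(n, i)) * p0**i * (1 - p0)**(n - i)
           for i in range(n + 1)]
    if alternative == "greater":
        return float(sum(pmf[k:]))
    if alternative == "less":
        return float(sum(pmf[:k + 1]))
    d = pmf[k]
    return float(min(1, sum(q for q in pmf if q <= d)))


class TestWorkhorseTests:
    def test_identical_samples_mww_p_near_one(self):
        res = mww_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.99

    def test_mww_detects_planted_gc_contrast(self, small_study):
        """Directional power check: exitron GC < exon GC at the generator's
        defaults, detected at alpha = 0.05 with n >= 100 per group."""
        cfg = synthio.SynthConfig(n_genes=120, exitron_fraction=1.0, seed=31)
        genome, models, truth = synthio.generate_genome(cfg)
        x_gc, e_gc = [], []
        xmap = {x.gene_id: x for x in truth.planted_exitrons}
        for m in models:
            x = xmap[m.gene_id]
            x_gc.append(gc_content(genome.fetch(x.contig, x.start, x.end)))
            for s, e in m.exons_genomic:
                if not (s <= x.start and x.end <= e):
                    e_gc.append(gc_content(genome.fetch(m.contig, s, e)))
        assert len(x_gc) >= 100 and len(e_gc) >= 100
        res = mww_test(x_gc, e_gc, alternative="less")
        assert res.p_value < 0.05

    def test_binomial_symmetric_case_is_one(self):
        assert binomial_test(5, 10, 0.5).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_binomial_matches_enumeration_oracle(self, alternative):
        for n in (1, 2, 5, 10, 17, 20):
            for p0 in (0.5, 0.25, 0.3, 2 / 3):
                for k in range(0, n + 1, max(1, n // 4)):
                    got = binomial_test(k, n, p0, alternative).p_value
                    want = _exact_binomial_p(k, n, p0, alternative)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_bh_adjust_monotone(self):
        p = [0.001, 0.01, 0.02, 0.5, 0.9]
        q = seqstats.bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()
        assert (q >= np.array(p) - 1e-15).all()


def test_branch_point_best_match_found():
    seq = "A" * 60 + "CTAAT" + "A" * 20 + "TTTTAG" + "C" * 10
    g = gio.GenomeSequence({"c": seq})
    intron_end = 91  # acceptor at the AG
    score, off = seqstats.branch_point_score(g, "c", 0, intron_end, "+")
    assert score == pytest.approx(1.0)  # CTAAT matches CTRAY fully
    assert intron_end + off == 60
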