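import math
from fractions import Fraction

import numpy as np
import pytest

from actghap.gene_model import GenomicInterval, partition_regions
from actghap.synthetic import make_gene_model
from actghap.variant_engine import (
    DEFAULT_THRESHOLDS,
    ClassifiedVariant,
    ContigAlignment,
    HomopolymerContext,
    QVCalibration,
    RawVariant,
    call_variants_from_alignment,
    classify,
    contig_error_probability,
    filter_variants,
    homopolymer_context,
    normalize_variant,
    trim_to_gene_window,
    vqv,
)


def exact_binom_tail(k: int, n: int, p: Fraction) -> Fraction:
    """Independent oracle: exact upper-tail Pr[X >= k] by enumeration."""
    return sum(
        Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i)
        for i in range(k, n + 1)
    )


def leftmost_deletion(reference: str, alt_seq: str, del_len: int, lo: int, hi: int):
    """Oracle: leftmost position where deleting del_len bases from
    reference[lo:hi] reproduces alt_seq."""
    for pos in range(lo, hi - del_len + 1):
        if reference[lo:pos] + reference[pos + del_len : hi] == alt_seq:
            return pos
    return None


class TestCalling:
    def test_identity_contig(self):
        ref = "ACGTACGTACGTACGTACGT"
        aln = ContigAlignment("h", "c", 0, [("M", 20)], ref)
        window = GenomicInterval("c", 2, 18)
        assert call_variants_from_alignment(aln, ref, window) == []

    def test_single_mismatch(self):
        ref = "ACGTACGTACGTACGTACGTA"
        query = ref[:10] + "T" + ref[11:]
        assert ref[10] == "G"
        aln = ContigAlignment("h", "c", 0, [("=", 10), ("X", 1), ("=", 10)], query)
        window = GenomicInterval("c", 0, 21)
        (v,) = call_variants_from_alignment(aln, ref, window)
        assert (v.pos, v.ref, v.alt) == (10, "G", "T")

    def test_homopolymer_indels_left_aligned(self):
        #       0123456789...
        ref = "GGCTGAAAAACTGGC"
        # delete two A's from the run (any two give the same alt string)
        query_del = "GGCTGAAACTGGC"
        aln = ContigAlignment("h", "c", 0, [("=", 7), ("D", 2), ("=", 6)], query_del)
        window = GenomicInterval("c", 0, len(ref))
        (v,) = call_variants_from_alignment(aln, ref, window)
        oracle_pos = leftmost_deletion(ref, query_del, 2, 0, len(ref))
        # leftmost placement (run start at 5) with one anchor base before
        assert oracle_pos == 5
        assert v.pos == oracle_pos - 1
        assert v.ref == ref[v.pos : v.pos + 3]
        assert v.alt == ref[v.pos]

        query_ins = "GGCTGAAAAAACTGGC"
        aln = ContigAlignment("h", "c", 0, [("=", 9), ("I", 1), ("=", 6)], query_ins)
        (v,) = call_variants_from_alignment(aln, ref, window)
        assert v.pos == 4  # anchored just before the run start
        assert (v.ref, v.alt) == ("G", "GA")

    def test_snv_not_shifted(self):
        ref = "AAAACAAAA"
        aln = ContigAlignment(
            "h", "c", 0, [("=", 4), ("X", 1), ("=", 4)], "AAAAGAAAA"
        )
        (v,) = call_variants_from_alignment(
            aln, ref, GenomicInterval("c", 0, 9)
        )
        assert (v.pos, v.ref, v.alt) == (4, "C", "G")

    def test_incomplete_alignment_rejected(self):
        ref = "ACGTACGTACGT"
        aln = ContigAlignment("h", "c", 2, [("M", 8)], ref[2:10])
        with pytest.raises(ValueError, match="does not span"):
            call_variants_from_alignment(aln, ref, GenomicInterval("c", 0, 12))

    def test_normalize_trims_and_shifts(self):
        ref = "GGCTGAAAAACTGGC"
        v = normalize_variant(ref, 8, "AA", "A", contig="c")
        assert (v.pos, v.ref, v.alt) == (4, "GA", "G")
        v = normalize_variant(ref, 3, "TGA", "TCA", contig="c")
        assert (v.pos, v.ref, v.alt) == (4, "G", "C")


class TestTrim:
    def _gene(self):
        model, ref = make_gene_model(seed=3, flank=100)
        return model, ref

    def test_overhang_trimmed_and_exact_unchanged(self):
        model, ref = self._gene()
        wstart, wend = model.start - 60, model.end + 60
        aln = ContigAlignment(
            "h", model.contig, wstart - 30, [("M", wend - wstart + 60)],
            ref[wstart - 30 : wend + 30],
        )
        trimmed = trim_to_gene_window(aln, model, flank=60)
        assert (trimmed.ref_start, trimmed.ref_end) == (wstart, wend)
        assert trimmed.query == ref[wstart:wend]
        again = trim_to_gene_window(trimmed, model, flank=60)
        assert again.cigar == trimmed.cigar
        assert again.query == trimmed.query

    def test_no_overlap_rejected(self):
        model, ref = self._gene()
        aln = ContigAlignment("h", model.contig, 0, [("M", 20)], ref[:20])
        with pytest.raises(ValueError, match="does not overlap"):
            trim_to_gene_window(aln, model, flank=60)

    def test_trim_then_call_commutes(self):
        """Trimming then calling equals calling then position-filtering,
        for variants strictly inside the window."""
        from actghap.synthetic import PanelSpec, haplotype_alignment, make_panel

        model, ref = make_gene_model(seed=9, flank=100)
        spec = PanelSpec(
            n_haploids=4,
            frequency_spectrum=(0.5, 0.5),
            variants_per_level={"C": 1, "G": 1, "U": 1},
            seed=2,
        )
        panel = make_panel(model, spec, ref, flank=60)
        window = panel.window
        for hap in panel.haplotypes[:2]:
            aln = haplotype_alignment(hap, ref, window)
            # widen: embed the window alignment in a larger M context
            wide = ContigAlignment(
                aln.name,
                aln.contig,
                aln.ref_start - 30,
                [("M", 30)] + aln.cigar + [("M", 30)],
                ref[aln.ref_start - 30 : aln.ref_start] + aln.query + ref[window.end : window.end + 30],
            )
            wide_window = GenomicInterval(window.contig, window.start - 30, window.end + 30)
            direct = [
                v.key
                for v in call_variants_from_alignment(wide, ref, wide_window)
                if window.start < v.pos < window.end - 1
            ]
            trimmed = trim_to_gene_window(wide, model, flank=60)
            via_trim = [
                v.key
                for v in call_variants_from_alignment(trimmed, ref, window)
                if window.start < v.pos < window.end - 1
            ]
            assert via_trim == direct


class TestClassify:
    @pytest.fixture()
    def gene(self):
        # contig has 150 bp flanks; partition with 100 so that contig
        # positions outside the analysis window exist
        model, ref = make_gene_model(
            n_exons=2, cds_span=60, utr_spans=(30, 30), seed=21, flank=150
        )
        return model, ref, partition_regions(model, flank=100)

    def _snv(self, model, ref, pos, alt):
        return RawVariant(model.contig, pos, ref[pos], alt)

    def test_missense(self, gene):
        model, ref, part = gene
        # second codon, first position: any base change is non-synonymous
        pos = model.cds[0].start + 3
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[pos]]
        cv = classify(self._snv(model, ref, pos, alt), part, model, ref)
        assert cv.level == "A"
        assert "missense" in cv.flags or "stop_gain" in cv.flags

    def test_synonymous_third_position(self, gene):
        model, ref, part = gene
        from actghap.variant_engine import _translate_codon

        found = False
        for codon_i in range(1, 18):
            pos = model.cds[0].start + codon_i * 3 + 2
            if pos >= model.cds[0].end:
                break
            codon = ref[pos - 2 : pos + 1]
            for alt in "ACGT":
                if alt == ref[pos]:
                    continue
                if _translate_codon(codon[:2] + alt) == _translate_codon(codon):
                    cv = classify(self._snv(model, ref, pos, alt), part, model, ref)
                    assert cv.level == "C"
                    assert cv.flags == frozenset({"synonymous"})
                    found = True
                    break
            if found:
                break
        assert found

    def test_start_loss(self, gene):
        model, ref, part = gene
        pos = model.cds[0].start + 2  # ATG -> ATx
        assert ref[pos] == "G"
        cv = classify(self._snv(model, ref, pos, "A"), part, model, ref)
        assert cv.level == "A"
        assert "start_loss" in cv.flags

    def test_regions(self, gene):
        model, ref, part = gene
        utr5_pos = part.utr5[0].start + 2
        intron_pos = part.introns[0].start + 5
        up_pos = part.upstream.start + 10
        for pos, level in ((utr5_pos, "T"), (intron_pos, "G"), (up_pos, "U")):
            alt = "A" if ref[pos] != "A" else "C"
            cv = classify(self._snv(model, ref, pos, alt), part, model, ref)
            assert cv.level == level
            assert cv.flags == frozenset()

    def test_cds_indel_frameshift_vs_inframe(self, gene):
        model, ref, part = gene
        pos = model.cds[0].start + 5
        ins1 = RawVariant(model.contig, pos, ref[pos], ref[pos] + "A")
        cv = classify(ins1, part, model, ref)
        assert cv.level == "A" and "frameshift" in cv.flags
        ins3 = RawVariant(model.contig, pos, ref[pos], ref[pos] + "ACT")
        cv = classify(ins3, part, model, ref)
        assert cv.level == "A" and "inframe_indel" in cv.flags

    def test_outside_window_rejected(self, gene):
        model, ref, part = gene
        with pytest.raises(ValueError, match="outside"):
            classify(RawVariant(model.contig, 2, ref[2], "A" if ref[2] != "A" else "C"), part, model, ref)

    def test_every_window_base_has_a_level(self, gene):
        model, ref, part = gene
        w = part.window
        levels = {"cds", "utr5", "utr3", "intron", "upstream", "downstream"}
        seen = {part.region_at(pos) for pos in range(w.start, w.end)}
        assert seen <= levels
        assert None not in seen


class TestErrorProbability:
    def _calib(self, qv_ref=30.0, qv_alt=20.0):
        return QVCalibration(
            {
                ("*", "A", 4): qv_ref,
                ("*", "A", 5): qv_alt,
            }
        )

    def test_lower_of_two_qvs(self):
        calib = self._calib(30.0, 20.0)
        ctx = HomopolymerContext("A", 4, 5)
        assert contig_error_probability(calib, ctx, "*") == pytest.approx(1e-2)

    def test_qv_zero_gives_p_one(self):
        calib = QVCalibration({("*", "A", 1): 0.0})
        ctx = HomopolymerContext("A", 1, 1)
        assert contig_error_probability(calib, ctx, "*") == 1.0

    def test_monotone_in_qv(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            q1, q2 = sorted(rng.uniform(0, 60, size=2))
            ctx = HomopolymerContext("A", 4, 5)
            p_low = contig_error_probability(self._calib(q1, q1), ctx, "*")
            p_high = contig_error_probability(self._calib(q2, q2), ctx, "*")
            assert p_high <= p_low

    def test_missing_contig_without_fallback(self):
        calib = QVCalibration({("hap1", "A", 1): 30.0})
        with pytest.raises(ValueError, match="no calibration row"):
            calib.lookup("hap2", "A", 1)

    def test_run_length_clamped_to_max_bin(self):
        calib = QVCalibration({("*", "A", 1): 30.0, ("*", "A", 6): 10.0})
        assert calib.lookup("*", "A", 40) == 10.0
        assert calib.lookup("*", "A", 3) == 30.0


class TestHomopolymerContext:
    def test_snv_run_length_one(self):
        ref = "GGAAAAGG"
        ctx = homopolymer_context(ref, RawVariant("c", 3, "A", "C"))
        assert (ctx.run_length_ref, ctx.run_length_alt) == (1, 1)

    def test_single_base_indel_in_run(self):
        ref = "GGCAAAAGG"  # run of 4 A's at 3..6
        ins = RawVariant("c", 2, "C", "CA")
        ctx = homopolymer_context(ref, ins)
        assert ctx.base == "A"
        assert ctx.run_length_ref == 4
        assert ctx.run_length_alt == 5
        dele = RawVariant("c", 2, "CA", "C")
        ctx = homopolymer_context(ref, dele)
        assert (ctx.run_length_ref, ctx.run_length_alt) == (4, 3)

    def test_mixed_indel_run_one(self):
        ref = "GGCATTAGG"
        ctx = homopolymer_context(ref, RawVariant("c", 2, "C", "CAT"))
        assert (ctx.run_length_ref, ctx.run_length_alt) == (1, 1)


class TestVqv:
    def test_zero_support(self):
        assert vqv(0, 10, 0.5) == 0.0

    def test_two_of_two(self):
        assert vqv(2, 2, 1e-3) == pytest.approx(60.0, rel=1e-9)

    def test_retention_boundaries(self):
        assert vqv(1, 1, 1e-10) == pytest.approx(100.0, rel=1e-12)
        assert vqv(1, 1, 1e-5) == pytest.approx(50.0, rel=1e-12)

    def test_supporting_above_covering_rejected(self):
        with pytest.raises(ValueError):
            vqv(3, 2, 0.1)

    def test_oracle_equivalence_small_covering(self):
        """VQV agrees with exact binomial-tail enumeration, covering <= 12."""
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            k = int(rng.integers(1, n + 1))
            p = Fraction(int(rng.integers(1, 1000)), 10_000)
            expected = -10.0 * math.log10(float(exact_binom_tail(k, n, p)))
            assert vqv(k, n, float(p)) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_p_and_support(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            k = int(rng.integers(1, n))
            p1, p2 = sorted(rng.uniform(1e-6, 1, size=2))
            assert vqv(k, n, p2) <= vqv(k, n, p1) + 1e-9
            assert vqv(k + 1, n, p1) >= vqv(k, n, p1) - 1e-9

    def test_deep_tail_no_underflow(self):
        # 200 supporting contigs at p=1e-4: tail is 1e-800, far below
        # float range; the log-space fallback must still be finite
        q = vqv(200, 200, 1e-4)
        assert q == pytest.approx(8000.0, rel=1e-6)


class TestFilter:
    def _cv(self, level, q):
        return ClassifiedVariant("c", 10, "A", "C", "h", level, frozenset(), vqv=q)

    def test_boundaries_inclusive(self):
        out = filter_variants(
            [self._cv("A", 99.9), self._cv("A", 100.0), self._cv("T", 50.0)]
        )
        assert [v.retained for v in out] == [False, True, True]

    def test_empty(self):
        assert filter_variants([]) == []

    def test_missing_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_variants([self._cv("A", 120.0)], thresholds={"C": 100.0})

    def test_no_filter_mode(self):
        out = filter_variants([self._cv("A", None)])
        assert out[0].retained is True

    def test_order_independent(self):
        vs = [self._cv("A", q) for q in (10.0, 150.0, 99.0, 101.0)]
        a = {v.vqv: v.retained for v in filter_variants(vs)}
        b = {v.vqv: v.retained for v in filter_variants(vs[::-1])}
        assert a == b
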