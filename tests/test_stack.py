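"""GFF3 ingest, Gap-CIGAR projection, classification, coverage, splicing."""

import pytest

from alnkit.fixtures import planted_read_set
from alnkit.seqcore import PROTEIN, Sequence
from alnkit.stack import (
    Gff3Error,
    classify_match_bases,
    coverage_bedgraph,
    coverage_track,
    detect_splice_sites,
    parse_gff3,
    project_alignment,
    render_detail_view,
    sort_features,
    squash_identical_matches,
)


def gff_line(
    seqid="ref1", ftype="nucleotide_match", start=1, end=10, score=".",
    strand="+", attrs="ID=m1;Target=q1 1 10",
):
    return f"{seqid}\tsrc\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}"


class TestParse:
    def test_target_span_parsed(self):
        f = parse_gff3(gff_line(attrs="ID=m1;Target=m1 1 50", end=50))[0]
        assert f.target == ("m1", 1, 50, "+")

    def test_gap_ops_parsed(self):
        f = parse_gff3(
            gff_line(end=17, attrs="ID=m1;Target=q1 1 14;Gap=M8 D3 M6")
        )[0]
        assert f.gap_ops == (("M", 8), ("D", 3), ("M", 6))

    def test_percent_decoding(self):
        f = parse_gff3(gff_line(attrs="ID=m1;Note=a%2Cb"))[0]
        assert f.attributes["Note"] == "a,b"

    def test_unknown_types_retained(self):
        f = parse_gff3(gff_line(ftype="mystery_feature", attrs="ID=x"))[0]
        assert f.type == "mystery_feature"

    def test_start_after_end_reports_line(self):
        text = gff_line() + "\n" + gff_line(start=20, end=10, attrs="ID=bad")
        with pytest.raises(Gff3Error, match="line 2"):
            parse_gff3(text)

    def test_bad_gap_token_reports_line(self):
        with pytest.raises(Gff3Error, match="Gap token"):
            parse_gff3(gff_line(attrs="ID=m1;Target=q1 1 10;Gap=M8 Q3"))

    def test_lenient_mode_skips_bad_lines(self):
        text = gff_line() + "\n" + "only\tthree\tcols"
        feats = parse_gff3(text, strict=False)
        assert len(feats) == 1

    def test_inconsistent_gap_span_rejected(self):
        with pytest.raises(Gff3Error, match="consume"):
            parse_gff3(gff_line(end=5, attrs="ID=m1;Target=q1 1 10;Gap=M10"))


class TestProjection:
    def test_hand_expanded_alignment(self):
        f = parse_gff3(
            gff_line(end=5, attrs="ID=m1;Target=q1 1 4;Gap=M2 D1 M2")
        )[0]
        ma = project_alignment(f)
        assert ma.pairs == ((1, 1), (2, 2), (3, None), (4, 3), (5, 4))

    def test_no_gap_identity_pairing(self):
        f = parse_gff3(gff_line())[0]
        ma = project_alignment(f)
        assert ma.pairs == tuple((i, i) for i in range(1, 11))

    def test_protein_three_to_one_consumption(self):
        f = parse_gff3(
            gff_line(ftype="protein_match", end=12,
                     attrs="ID=p1;Target=pr1 1 4;Gap=M4")
        )[0]
        ma = project_alignment(f)
        assert ma.pairs == ((1, 1), (4, 2), (7, 3), (10, 4))
        assert ma.mode == PROTEIN

    def test_insertion_consumes_target_only(self):
        f = parse_gff3(
            gff_line(end=4, attrs="ID=m1;Target=q1 1 6;Gap=M2 I2 M2")
        )[0]
        ma = project_alignment(f)
        assert ma.pairs == ((1, 1), (2, 2), (None, 3), (None, 4), (3, 5), (4, 6))

    def test_consumption_accounting_invariant(self):
        ref, gff, feats, _ = planted_read_set(n_reads=6, seed=5)
        for f in feats:
            ma = project_alignment(f, ref)
            ref_used = sum(1 for r, _ in ma.pairs if r is not None)
            tgt_used = sum(1 for _, t in ma.pairs if t is not None)
            assert ref_used * ma.ref_unit == f.end - f.start + 1
            tid, tstart, tend, _ = f.target
            assert tgt_used == tend - tstart + 1

    def test_missing_target_rejected(self):
        f = parse_gff3(gff_line(ftype="gene", attrs="ID=g1"))[0]
        with pytest.raises(ValueError, match="Target"):
            project_alignment(f)


class TestClassification:
    def test_exact_and_mismatch_nucleotide(self):
        ref = Sequence("ref1", "ATGGCCAAAT")
        match = Sequence("q1", "ATGGACAAAT")
        f = parse_gff3(gff_line())[0]
        cls = classify_match_bases(project_alignment(f), ref, match)
        assert cls == ["exact"] * 4 + ["mismatch"] + ["exact"] * 5
        # nucleotide mode never yields "conserved"
        assert "conserved" not in cls

    def test_n_is_never_exact(self):
        ref = Sequence("ref1", "AN")
        match = Sequence("q1", "AN")
        f = parse_gff3(gff_line(end=2, attrs="ID=m;Target=q1 1 2"))[0]
        cls = classify_match_bases(project_alignment(f), ref, match)
        assert cls == ["exact", "mismatch"]

    def test_protein_conserved_class(self):
        # codons ATG GCC CTG -> M A L; target M A I: L/I scores +2 -> conserved
        ref = Sequence("ref1", "ATGGCCCTG")
        match = Sequence("pr1", "MAI", PROTEIN)
        f = parse_gff3(
            gff_line(ftype="protein_match", end=9, attrs="ID=p;Target=pr1 1 3")
        )[0]
        cls = classify_match_bases(project_alignment(f), ref, match)
        assert cls == ["exact", "exact", "conserved"]

    def test_indel_classes_and_count_conservation(self):
        ref = Sequence("ref1", "ATGGCC")
        match = Sequence("q1", "ATGC")
        f = parse_gff3(
            gff_line(end=4, attrs="ID=m;Target=q1 1 4;Gap=M2 D1 M1 I1")
        )[0]
        ma = project_alignment(f)
        cls = classify_match_bases(ma, ref, match)
        assert len(cls) == len(ma.pairs)
        assert cls.count("deletion") == 1 and cls.count("insertion") == 1


class TestCoverage:
    def test_interval_overlap(self):
        text = (
            gff_line(start=1, end=5, attrs="ID=a;Target=r1 1 5") + "\n"
            + gff_line(start=3, end=8, attrs="ID=b;Target=r2 1 6")
        )
        track = coverage_track(parse_gff3(text), "ref1", 1, 10)
        assert track.depth == (1, 1, 2, 2, 2, 1, 1, 1, 0, 0)

    def test_no_reads_all_zero(self):
        track = coverage_track([], "ref1", 1, 5)
        assert track.depth == (0,) * 5 and track.total == 0

    def test_deletion_covers_insertion_does_not(self):
        text = gff_line(end=5, attrs="ID=a;Target=q1 1 6;Gap=M2 D2 M1 I3")
        track = coverage_track(parse_gff3(text), "ref1", 1, 8)
        assert track.depth == (1, 1, 1, 1, 1, 0, 0, 0)
        assert sum(track.depth) == 5  # M2 + D2 + M1 reference bases

    def test_matches_planted_truth(self):
        ref, _, feats, truth = planted_read_set(n_reads=8, n_duplicates=2, seed=11)
        track = coverage_track(feats, "ref1", 1, len(ref.residues))
        assert list(track.depth) == truth["expected_depth"]

    def test_bedgraph_runs(self):
        track = coverage_track(
            parse_gff3(gff_line(start=3, end=5, attrs="ID=a;Target=r 1 3")),
            "ref1", 1, 8,
        )
        assert coverage_bedgraph(track) == "ref1\t2\t5\t1\n"

    def test_coverage_invariant_under_squashing(self):
        ref, _, feats, _ = planted_read_set(n_reads=5, n_duplicates=4, seed=2)
        full = coverage_track(feats, "ref1", 1, len(ref.residues))
        squashed = squash_identical_matches(feats)
        mult = {i: c for i, (f, c) in enumerate(squashed)}
        collapsed = coverage_track(
            [f for f, _ in squashed], "ref1", 1, len(ref.residues), mult
        )
        assert full.depth == collapsed.depth


class TestSquashAndSort:
    def test_identical_reads_collapse(self):
        feats = parse_gff3("\n".join([gff_line()] * 3))
        out = squash_identical_matches(feats)
        assert len(out) == 1 and out[0][1] == 3

    def test_distinct_reads_kept(self):
        text = gff_line() + "\n" + gff_line(start=2, end=11, attrs="ID=b;Target=q2 1 10")
        out = squash_identical_matches(parse_gff3(text))
        assert [c for _, c in out] == [1, 1]

    def test_different_gap_not_squashed(self):
        a = gff_line(end=10, attrs="ID=a;Target=q1 1 10;Gap=M10")
        b = gff_line(end=10, attrs="ID=b;Target=q1 1 8;Gap=M4 D2 M4")
        out = squash_identical_matches(parse_gff3(a + "\n" + b))
        assert len(out) == 2

    def test_count_conservation(self):
        _, _, feats, truth = planted_read_set(n_reads=7, n_duplicates=5, seed=9)
        out = squash_identical_matches(feats)
        assert sum(c for _, c in out) == truth["total_reads"]
        assert len(out) == truth["n_distinct"]

    def test_sort_position_and_stability(self):
        text = "\n".join(
            [
                gff_line(start=5, end=14, attrs="ID=a;Target=q1 1 10"),
                gff_line(start=1, end=10, attrs="ID=b;Target=q2 1 10"),
                gff_line(start=5, end=14, attrs="ID=c;Target=q3 1 10"),
            ]
        )
        out = sort_features(parse_gff3(text), "position")
        assert [f.attributes["ID"] for f in out] == ["b", "a", "c"]

    def test_sort_name_case_insensitive(self):
        text = "\n".join(
            [
                gff_line(attrs="ID=1;Target=Beta 1 10"),
                gff_line(attrs="ID=2;Target=alpha 1 10"),
            ]
        )
        out = sort_features(parse_gff3(text), "name")
        assert [f.target[0] for f in out] == ["alpha", "Beta"]

    def test_sort_identity_needs_scores(self):
        feats = parse_gff3(gff_line(score="."))
        with pytest.raises(ValueError, match="score"):
            sort_features(feats, "identity")
        scored = parse_gff3(
            gff_line(score="90.5") + "\n"
            + gff_line(score="99.9", attrs="ID=b;Target=q2 1 10")
        )
        out = sort_features(scored, "identity")
        assert [f.score for f in out] == [99.9, 90.5]


class TestSpliceSites:
    def ref_with_intron(self, donor="GT", acceptor="AG"):
        #        exon1   intron           exon2
        seq = "AAA" + donor + "CCCC" + acceptor + "TTT"
        exons = parse_gff3(
            "r\ts\texon\t1\t3\t.\t+\t.\tID=e1\n"
            f"r\ts\texon\t{len(seq) - 2}\t{len(seq)}\t.\t+\t.\tID=e2"
        )
        return Sequence("r", seq), exons

    def test_canonical_gt_ag(self):
        ref, exons = self.ref_with_intron()
        (site,) = detect_splice_sites(ref, exons)
        assert (site.donor, site.acceptor, site.status) == ("GT", "AG", "canonical")

    def test_ct_ac_on_plus_is_non_canonical(self):
        ref, exons = self.ref_with_intron("CT", "AC")
        (site,) = detect_splice_sites(ref, exons)
        assert site.status == "non_canonical"

    def test_minus_strand_reads_reverse_complement(self):
        # CT..AC on the forward strand is GT..AG on the minus strand
        seq = "AAA" + "CT" + "CCCC" + "AC" + "TTT"
        exons = parse_gff3(
            "r\ts\texon\t1\t3\t.\t-\t.\tID=e1\n"
            "r\ts\texon\t12\t14\t.\t-\t.\tID=e2"
        )
        (site,) = detect_splice_sites(Sequence("r", seq), exons)
        assert (site.donor, site.acceptor, site.status) == ("GT", "AG", "canonical")

    def test_named_variants(self):
        for d, a, status in [("GC", "AG", "gc_ag"), ("AT", "AC", "at_ac")]:
            ref, exons = self.ref_with_intron(d, a)
            (site,) = detect_splice_sites(ref, exons)
            assert site.status == status

    def test_overlapping_exons_rejected(self):
        exons = parse_gff3(
            "r\ts\texon\t1\t6\t.\t+\t.\tID=e1\nr\ts\texon\t4\t9\t.\t+\t.\tID=e2"
        )
        with pytest.raises(ValueError, match="overlap"):
            detect_splice_sites(Sequence("r", "A" * 20), exons)


class TestDetailView:
    def test_stacked_rows_and_glyphs(self):
        ref = Sequence("ref1", "ATGGCCAAAT")
        q = Sequence("q1", "ATGGACAAAT")
        f = parse_gff3(gff_line())[0]
        view = render_detail_view(ref, [(f, q, 2)], 1, 10)
        lines = view.splitlines()
        assert lines[0].endswith("ATGGCCAAAT")
        assert "q1 (x2)" in lines[1]
        assert "~" in lines[1]  # the planted mismatch
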