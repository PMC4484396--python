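"""I/O and coordinate-model tests: round trips, dialects, strand handling."""

import textwrap

import pandas as pd
import pytest

from exitron_scan import gio

# independent per-codon table for the translation oracle
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestGenomeSequence:
    def test_lowercase_normalised_and_fetch(self):
        g = gio.GenomeSequence({"c": "acgtACGT"})
        assert g["c"] == "ACGTACGT"
        assert g.fetch("c", 0, 4) == "ACGT"
        assert g.fetch("c", 0, 4, "-") == "ACGT"[::-1].translate(
            str.maketrans("ACGT", "TGCA"))

    def test_minus_strand_is_reverse_complement(self):
        g = gio.GenomeSequence({"c": "AACCGGTT"})
        assert g.fetch("c", 2, 6, "-") == "CCGG"
        assert g.fetch("c", 0, 3, "-") == "GTT"

    def test_out_of_range_is_error(self):
        g = gio.GenomeSequence({"c": "ACGT"})
        with pytest.raises(IndexError):
            g.fetch("c", 2, 9)

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            gio.GenomeSequence({"c": "ACGU"})

    def test_fasta_round_trip(self, tmp_path):
        g = gio.GenomeSequence({"chrA": "ACGT" * 50, "chrB": "GGCC" * 10})
        path = tmp_path / "g.fa"
        gio.write_genome(g, path)
        g2 = gio.read_genome(path)
        assert g2.contigs == g.contigs
        assert all(g2[c] == g[c] for c in g.contigs)


GFF3_GENE = textwrap.dedent("""\
    ##gff-version 3
    c1\tsrc\tgene\t11\t310\t.\t+\t.\tID=G1
    c1\tsrc\tmRNA\t11\t310\t.\t+\t.\tID=G1.1;Parent=G1
    c1\tsrc\texon\t11\t100\t.\t+\t.\tParent=G1.1
    c1\tsrc\texon\t161\t310\t.\t+\t.\tParent=G1.1
    c1\tsrc\tCDS\t11\t100\t.\t+\t0\tParent=G1.1
    c1\tsrc\tCDS\t161\t310\t.\t+\t0\tParent=G1.1
    """)

GTF_GENE = textwrap.dedent("""\
    c1\tsrc\texon\t11\t100\t.\t+\t.\tgene_id "G1"; transcript_id "G1.1";
    c1\tsrc\texon\t161\t310\t.\t+\t.\tgene_id "G1"; transcript_id "G1.1";
    c1\tsrc\tCDS\t11\t100\t.\t+\t0\tgene_id "G1"; transcript_id "G1.1";
    c1\tsrc\tCDS\t161\t310\t.\t+\t0\tgene_id "G1"; transcript_id "G1.1";
    """)


class TestAnnotation:
    def test_gff3_coordinates_become_half_open(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3_GENE)
        (m,) = gio.read_annotation(p, "gff3")
        assert m.exons_genomic == [(10, 100), (160, 310)]
        assert m.introns == [(100, 160)]
        assert m.cds_length == 240
        assert not m.flags

    def test_gtf_and_gff3_give_identical_models(self, tmp_path):
        p1 = tmp_path / "a.gff3"
        p1.write_text(GFF3_GENE)
        p2 = tmp_path / "a.gtf"
        p2.write_text(GTF_GENE)
        (m1,) = gio.read_annotation(p1, "gff3")
        (m2,) = gio.read_annotation(p2, "gtf")
        assert m1.exons == m2.exons
        assert m1.cds == m2.cds
        assert (m1.strand, m1.contig) == (m2.strand, m2.contig)
        assert m1.gene_id == m2.gene_id

    def test_single_exon_gene_is_intronless(self, tmp_path):
        text = GFF3_GENE.replace("11\t100", "11\t310")
        lines = [l for l in text.splitlines() if "161\t310" not in l]
        p = tmp_path / "s.gff3"
        p.write_text("\n".join(lines) + "\n")
        (m,) = gio.read_annotation(p, "gff3")
        assert m.is_intronless
        assert m.introns == []

    def test_non_mod3_cds_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(GFF3_GENE.replace("161\t310", "161\t309"))
        (m,) = gio.read_annotation(p, "gff3")
        assert "cds_length_not_multiple_of_3" in m.flags

    def test_gff3_round_trip_preserves_coordinates(self, tmp_path, small_study):
        p = tmp_path / "rt.gff3"
        gio.write_annotation(small_study.models, p)
        models2 = gio.read_annotation(p, "gff3")
        orig = {m.transcript_id: m for m in small_study.models}
        assert len(models2) == len(orig)
        for m2 in models2:
            m1 = orig[m2.transcript_id]
            assert m2.exons == m1.exons
            assert m2.cds == m1.cds
            assert m2.strand == m1.strand


class TestSplicedCds:
    def test_plus_strand_is_concatenated_substring(self, toy_genome, toy_model):
        cds = gio.spliced_cds(toy_model, toy_genome)
        s = toy_genome["t"]
        assert cds == s[10:100] + s[160:310]
        assert cds.startswith("ATG") and len(cds) % 3 == 0

    def test_translation_matches_codon_table_oracle(self, small_study):
        for m in small_study.models[:20]:
            cds = gio.spliced_cds(m, small_study.genome)
            expected = "".join(_CODON_TABLE[cds[i:i + 3]]
                               for i in range(0, len(cds), 3))
            assert gio.translate(cds) == expected

    def test_mirror_gene_has_identical_cds(self, small_study):
        """A gene and its reverse-complemented mirror have the same spliced CDS."""
        genome = small_study.genome
        n = genome.lengths["chr1"]
        mirror = gio.GenomeSequence(
            {"chr1": gio.reverse_complement(genome["chr1"])})
        for m in small_study.models[:10]:
            flip = {"+": "-", "-": "+"}[m.strand]
            exons = tuple((n - e, n - s) for s, e in m.exons)
            m2 = gio.TranscriptModel(
                gene_id=m.gene_id, transcript_id=m.transcript_id,
                contig="chr1", strand=flip, exons=exons, cds=exons)
            assert gio.spliced_cds(m2, mirror) == gio.spliced_cds(m, genome)

    def test_cds_offset_strand_aware(self, toy_model):
        assert toy_model.cds_offset_of(10) == 0
        assert toy_model.cds_offset_of(99) == 89
        assert toy_model.cds_offset_of(160) == 90
        minus = gio.TranscriptModel(
            gene_id="g", transcript_id="g.1", contig="t", strand="-",
            exons=((160, 310), (10, 100)), cds=((160, 310), (10, 100)))
        assert minus.cds_offset_of(309) == 0
        assert minus.cds_offset_of(160) == 149
        assert minus.cds_offset_of(99) == 150


class TestTables:
    def test_junction_round_trip_and_empty(self, tmp_path):
        df = pd.DataFrame(
            [("c1", 5, 50, "+", 12, "s")],
            columns=gio.JUNCTION_COLUMNS)
        p = tmp_path / "j.bed"
        gio.write_junctions(df, p)
        back = gio.read_junctions(p, "s")
        assert back.loc[0, "read_count"] == 12
        assert (back.loc[0, "start"], back.loc[0, "end"]) == (5, 50)
        (tmp_path / "empty.bed").write_text("")
        assert len(gio.read_junctions(tmp_path / "empty.bed", "s")) == 0

    def test_coverage_round_trip(self, tmp_path):
        t = gio.CoverageTrack.zeros({"c": 30}, "s")
        t.set("c", 5, 12, 7)
        t.set("c", 12, 20, 3.5)
        p = tmp_path / "c.bg"
        gio.write_coverage(t, p)
        t2 = gio.read_coverage(p, "s", {"c": 30})
        assert (t2.array("c") == t.array("c")).all()

    def test_vcf_round_trip_and_ref_check(self, tmp_path):
        g = gio.GenomeSequence({"c": "ACGTACGTAC"})
        vs = [gio.Variant("c", 3, "T", "A"), gio.Variant("c", 6, "G", "C")]
        p = tmp_path / "v.vcf"
        gio.write_variants(vs, g, p)
        back = gio.read_variants(p, genome=g)
        assert [(v.pos, v.ref, v.alt) for v in back] == [(3, "T", "A"),
                                                         (6, "G", "C")]
        bad = gio.GenomeSequence({"c": "AAAAAAAAAA"})
        with pytest.raises(ValueError, match="REF mismatch"):
            gio.read_variants(p, genome=bad)


class TestCatalog:
    def test_empty_catalog_is_header_only(self, tmp_path):
        paths = gio.write_catalog([], tmp_path / "cat")
        df = gio.read_catalog(paths["tsv"])
        assert len(df) == 0
        assert list(df.columns) == gio.CATALOG_COLUMNS

    def test_round_trip_and_tie_break_order(self, tmp_path, small_study):
        from exitron_scan import discovery

        exitrons, _ = discovery.discover(
            small_study.genome, small_study.models, small_study.junctions,
            small_study.coverage)
        paths = gio.write_catalog(exitrons, tmp_path / "cat")
        df = gio.read_catalog(paths["tsv"])
        assert len(df) == len(exitrons)
        key = df[["contig", "start", "end"]].apply(tuple, axis=1).tolist()
        assert key == sorted(key)
        back = {(r.contig, r.start, r.end) for r in df.itertuples()}
        assert back == {x.interval for x in exitrons}
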