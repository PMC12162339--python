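import pytest

from cytofam import formats_io as fio


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nMKV\n")
        recs = fio.read_fasta(p)
        assert len(recs) == 1 and recs[0].id == "a" and len(recs[0]) == 3

    def test_trailing_stop_stripped(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nMKV*\n")
        assert fio.read_fasta(p)[0].seq == "MKV"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nMKV\n>a\nMKA\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            fio.read_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\n\n>b\nMK\n")
        with pytest.raises(fio.FormatError, match="empty"):
            fio.read_fasta(p)

    def test_roundtrip_byte_identical(self, tmp_path):
        seq = "MKVLWAALLVTFLAGCQA" * 5
        original = tmp_path / "in.fa"
        original.write_text(f">p1 some description\n" + "\n".join(
            seq[i:i + 60] for i in range(0, len(seq), 60)) + "\n>p2\nMKV\n")
        recs = fio.read_fasta(original)
        out = tmp_path / "out.fa"
        fio.write_fasta(recs, out)
        assert out.read_bytes() == original.read_bytes()

    def test_id_is_first_token(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">sp|P29460|IL12B_HUMAN Interleukin-12 subunit beta\nMK\n")
        rec = fio.read_fasta(p)[0]
        assert rec.id == "sp|P29460|IL12B_HUMAN"
        assert rec.description == "Interleukin-12 subunit beta"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff(lines):
    return "##gff-version 3\n" + "\n".join(lines) + "\n"


class TestGff3:
    def test_two_transcript_gene(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(_gff([
            "c1\t.\tgene\t1\t1000\t.\t+\t.\tID=g1;Name=IL12B",
            "c1\t.\tmRNA\t1\t1000\t.\t+\t.\tID=t1;Parent=g1",
            "c1\t.\tmRNA\t1\t1000\t.\t+\t.\tID=t2;Parent=g1",
            "c1\t.\tCDS\t1\t300\t.\t+\t0\tParent=t1",
            "c1\t.\tCDS\t1\t200\t.\t+\t0\tParent=t2",
            "c1\t.\tCDS\t500\t749\t.\t+\t1\tParent=t2",
        ]))
        models, orphans = fio.read_gff3(p)
        assert orphans == 0
        (gm,) = models
        assert gm.symbol == "IL12B" and len(gm.transcripts) == 2
        assert {t.transcript_id: t.cds_length for t in gm.transcripts} == \
            {"t1": 300, "t2": 450}

    def test_orphan_cds_dropped_with_tally(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(_gff([
            "c1\t.\tgene\t1\t300\t.\t+\t.\tID=g1",
            "c1\t.\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1",
            "c1\t.\tCDS\t1\t300\t.\t+\t0\tParent=t1",
            "c1\t.\tCDS\t400\t500\t.\t+\t0\tParent=ghost",
        ]))
        models, orphans = fio.read_gff3(p)
        assert len(models) == 1 and orphans == 1

    def test_minus_strand_transcription_order(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(_gff([
            "c1\t.\tgene\t1\t500\t.\t-\t.\tID=g1",
            "c1\t.\tmRNA\t1\t500\t.\t-\t.\tID=t1;Parent=g1",
            "c1\t.\tCDS\t10\t100\t.\t-\t0\tParent=t1",
            "c1\t.\tCDS\t200\t300\t.\t-\t0\tParent=t1",
        ]))
        (gm,), _ = fio.read_gff3(p)
        segs = gm.transcripts[0].cds_segments
        assert segs == ((200, 300), (10, 100))  # descending = transcription order

    def test_cds_end_before_start_is_error(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(_gff(["c1\t.\tCDS\t300\t100\t.\t+\t0\tParent=t1"]))
        with pytest.raises(fio.FormatError, match="CDS end"):
            fio.read_gff3(p)

    def test_unknown_strand_is_error(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(_gff(["c1\t.\tgene\t1\t10\t.\t?\t.\tID=g1"]))
        with pytest.raises(fio.FormatError, match="strand"):
            fio.read_gff3(p)


# ---------------------------------------------------------------------------
# BUSCO
# ---------------------------------------------------------------------------

class TestBusco:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("# BUSCO\n\tC:95.0%[S:90.0%,D:5.0%],F:2.0%,M:3.0%,n:9226\n")
        s = fio.parse_busco_summary(p)
        assert (s.complete_pct, s.single_pct, s.duplicated_pct,
                s.fragmented_pct, s.missing_pct) == (95.0, 90.0, 5.0, 2.0, 3.0)

    def test_high_missing(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("C:1.0%[S:0.8%,D:0.2%],F:2.0%,M:97.0%\n")
        assert fio.parse_busco_summary(p).missing_pct == 97.0

    def test_malformed_line_is_error(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("Complete: 95%\n")
        with pytest.raises(fio.FormatError):
            fio.parse_busco_summary(p)


# ---------------------------------------------------------------------------
# domtblout
# ---------------------------------------------------------------------------

_DOMTBL_ROW = ("fn3  PF00041.26  91 prot1 - 300 1e-20 55.0 0.0 1 1 "
               "1e-20 1e-20 55.0 0.0 1 91 10 100 10 100 0.98 -")


class TestDomtblout:
    def test_envelope_coordinates(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text("# comment\n" + _DOMTBL_ROW + "\n")
        (h,) = fio.parse_domtblout(p)
        assert (h.protein_id, h.start, h.end) == ("prot1", 10, 100)
        assert h.domain_acc == "PF00041.26"

    def test_version_stripped_key_matches_table(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text(_DOMTBL_ROW + "\n")
        (h,) = fio.parse_domtblout(p)
        assert h.acc_key == "PF00041"
        assert fio.strip_version("PF00041.26") == fio.strip_version("PF00041")

    def test_short_row_is_error(self, tmp_path):
        p = tmp_path / "d.tbl"
        p.write_text("fn3 PF00041.26 91 prot1\n")
        with pytest.raises(fio.FormatError, match="columns"):
            fio.parse_domtblout(p)

    def test_write_parse_roundtrip(self, tmp_path):
        hits = [fio.DomainHit("p1", "PF06328.16", 5, 90, 120.0, 1e-30, "Lep_receptor_Ig"),
                fio.DomainHit("p1", "PF00041.26", 100, 190, 88.0, 1e-20, "fn3")]
        p = tmp_path / "d.tbl"
        fio.write_domtblout(hits, p, {"p1": 320})
        parsed = fio.parse_domtblout(p)
        assert [(h.protein_id, h.acc_key, h.start, h.end) for h in parsed] == \
            [("p1", "PF06328", 5, 90), ("p1", "PF00041", 100, 190)]


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

class TestBlastTab:
    def test_single_row(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("P29460\tENSX1\t29.85\t260\t150\t8\t1\t250\t5\t255\t1e-20\t95.5\n")
        (h,) = fio.parse_blast_tab(p)
        assert h.pct_identity == 29.85 and h.evalue == 1e-20

    def test_evalue_threshold_notation(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("q\ts\t50.00\t100\t50\t0\t1\t100\t1\t100\t1e-5\t40.0\n")
        assert fio.parse_blast_tab(p)[0].evalue == 1e-5

    def test_empty_file(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("")
        assert fio.parse_blast_tab(p) == []

    def test_non_numeric_pident_is_error(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("q\ts\thigh\t100\t0\t0\t1\t100\t1\t100\t1e-9\t40.0\n")
        with pytest.raises(fio.FormatError, match="pident"):
            fio.parse_blast_tab(p)

    def test_write_parse_identity(self, tmp_path):
        hits = [fio.SimilarityHit("q1", "s1", 83.25, 200, 1e-40, 150.0),
                fio.SimilarityHit("q2", "s2", 29.85, 260, 2e-05, 40.5)]
        p = tmp_path / "b.tsv"
        fio.write_blast_tab(hits, p)
        parsed = fio.parse_blast_tab(p)
        for orig, back in zip(hits, parsed):
            assert (orig.query_id, orig.subject_id, orig.pct_identity,
                    orig.evalue, orig.bitscore) == \
                (back.query_id, back.subject_id, back.pct_identity,
                 back.evalue, back.bitscore)


# ---------------------------------------------------------------------------
# Query table
# ---------------------------------------------------------------------------

class TestQueryTable:
    def test_builtin_has_ten_queries(self):
        queries = fio.load_builtin_queries()
        assert len(queries) == 10
        assert len({q.uniprot_acc for q in queries}) == 10

    def test_gp130_domain_set(self):
        q = {q.uniprot_acc: q for q in fio.load_builtin_queries()}["P40189"]
        assert set(q.required_domains) == {"PF00041.26", "PF06328.16", "PF09240.15"}
        assert q.family_side == "receptor"

    def test_p28_is_blast_only(self):
        q = {q.uniprot_acc: q for q in fio.load_builtin_queries()}["Q8NEV9"]
        assert q.required_domains == () and q.blast_only

    def test_blast_only_flags(self):
        flags = {q.gene_symbol: q.blast_only for q in fio.load_builtin_queries()}
        assert {s for s, b in flags.items() if b} == {"IL27", "IL23R", "IL27RA"}

    def test_unknown_family_side_is_error(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("accession\tgene_symbol\tprotein_name\tdomains\tfamily_side\n"
                     "X1\tGENE\tname\t-\tcofactor\n")
        with pytest.raises(fio.FormatError, match="family_side"):
            fio.read_query_table(p)
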