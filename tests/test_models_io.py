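import numpy as np
import pytest

from retroscribe.io import (
    ParseError,
    read_repeats,
    read_transcripts,
    write_repeats_bed,
    write_transcripts_gtf,
)
from retroscribe.models import (
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
    ValidationError,
    ere_class_of,
    ere_subgroup_of,
    exonic_overlap_bp,
)

from .conftest import make_transcript
from .oracles import per_base_overlap_bp


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(-1, 10), (10, 10), (10, 5)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end)

    def test_empty_chrom_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 10)

    def test_overlap_ignores_strand_and_respects_chrom(self):
        a = GenomicInterval("chr1", 100, 200, "+")
        assert a.overlap_bp(GenomicInterval("chr1", 150, 250, "-")) == 50
        assert a.overlap_bp(GenomicInterval("chr2", 150, 250)) == 0


class TestTranscriptModel:
    def test_exons_sorted_on_construction(self):
        t = make_transcript([(300, 400), (100, 200)])
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]

    def test_mixed_strand_exons_rejected(self):
        exons = [
            GenomicInterval("chr1", 0, 100, "+"),
            GenomicInterval("chr1", 200, 300, "-"),
        ]
        with pytest.raises(ValidationError, match="t1"):
            TranscriptModel("t1", "g1", "chr1", "+", exons)

    def test_abutting_exons_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            make_transcript([(0, 100), (100, 200)])

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValidationError, match="CDS"):
            make_transcript([(0, 100), (200, 300)], cds=(50, 150))

    def test_intron_geometry(self):
        t = make_transcript([(0, 100), (200, 300), (400, 500)])
        assert [(i.start, i.end) for i in t.introns()] == [(100, 200), (300, 400)]
        assert t.exonic_length == 300


class TestExonicOverlap:
    @pytest.mark.parametrize(
        "exons,iv,expected",
        [
            ([(100, 200)], (150, 250), 50),
            ([(100, 200)], (300, 400), 0),
            # per-base membership over 0..299: 50 bp in each exon
            ([(0, 100), (200, 300)], (50, 250), 100),
        ],
    )
    def test_examples(self, exons, iv, expected):
        t = make_transcript(exons)
        assert exonic_overlap_bp(t, GenomicInterval("chr1", *iv)) == expected

    def test_agrees_with_per_base_oracle(self, rng):
        """1,000 random small instances vs explicit per-base counting."""
        for _ in range(1000):
            n_ex = rng.integers(1, 4)
            exons, pos = [], 0
            for _ in range(n_ex):
                pos += int(rng.integers(1, 50))
                length = int(rng.integers(1, 100))
                exons.append((pos, pos + length))
                pos += length + 1
            s = int(rng.integers(0, 900))
            iv = (s, s + int(rng.integers(1, 100)))
            t = make_transcript(exons)
            got = exonic_overlap_bp(t, GenomicInterval("chr1", *iv))
            assert got == per_base_overlap_bp(exons, iv, 1100)
            assert got <= min(t.exonic_length, iv[1] - iv[0])


class TestEreTaxonomy:
    @pytest.mark.parametrize(
        "family,name,expected_class,expected_sub",
        [
            ("SINE/Alu", "AluY", "SINE", None),
            ("LTR/ERVL-MaLR", "MSTB", "LTR", "MaLR"),
            ("LTR/ERVK", "HERVK9-int", "LTR", "HERV"),
            ("LINE/L1", "L1PA3", "LINE", None),
            ("Retroposon/SVA", "SVA_D", "SVA", None),
            ("Simple_repeat", "(TA)n", "Other", None),
            ("Low_complexity", "A-rich", "Other", None),
            ("DNA/hAT-Charlie", "MER5A", "Other", None),
        ],
    )
    def test_family_mapping(self, family, name, expected_class, expected_sub):
        assert ere_class_of(family, name) == expected_class
        assert ere_subgroup_of(family, name) == expected_sub

    def test_name_only_fallback(self):
        # BED6 input carries only locus names
        assert ere_class_of(None, "MSTB") == "LTR"
        assert ere_subgroup_of(None, "MSTB") == "MaLR"
        assert ere_class_of(None, "AluSx") == "SINE"
        assert ere_class_of(None, "totally-unknown") == "Other"


class TestReadTranscripts:
    def _write(self, tmp_path, text, name="ann.gtf"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_gtf_coordinates_become_half_open(self, tmp_path):
        gtf = self._write(
            tmp_path,
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n',
        )
        (t,) = read_transcripts(gtf)
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]

    def test_exon_order_in_file_is_irrelevant(self, tmp_path):
        fwd = self._write(
            tmp_path,
            'chr1\tx\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\ttranscript_id "t1";\n',
            "a.gtf",
        )
        rev = self._write(
            tmp_path,
            'chr1\tx\texon\t301\t400\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tx\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n',
            "b.gtf",
        )
        (ta,), (tb,) = read_transcripts(fwd), read_transcripts(rev)
        assert [(e.start, e.end) for e in ta.exons] == [(e.start, e.end) for e in tb.exons]

    def test_mixed_strand_transcript_rejected_by_id(self, tmp_path):
        gtf = self._write(
            tmp_path,
            'chr1\tx\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t-\t.\ttranscript_id "t1";\n',
        )
        with pytest.raises(ValidationError, match="t1"):
            read_transcripts(gtf)

    def test_malformed_record_names_line(self, tmp_path):
        gtf = self._write(tmp_path, "chr1\tonly\tthree\n")
        with pytest.raises(ParseError, match="line 1"):
            read_transcripts(gtf)

    def test_gff3_parent_grouping(self, tmp_path):
        gff = self._write(
            tmp_path,
            "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tx\texon\t101\t200\t.\t+\t.\tParent=t1\n"
            "chr1\tx\texon\t301\t400\t.\t+\t.\tParent=t1\n",
            "ann.gff3",
        )
        (t,) = read_transcripts(gff, dialect="GFF3")
        assert t.gene_id == "g1"
        assert len(t.exons) == 2

    def test_gtf_round_trip_preserves_models(self, tmp_path):
        original = [
            make_transcript([(100, 200), (300, 400)], tid="tA", strand="+"),
            make_transcript([(1000, 1500)], tid="tB", strand="-", cds=None),
            make_transcript([(2000, 2300), (2500, 2900)], tid="tC", cds=(2100, 2700)),
        ]
        path = tmp_path / "rt.gtf"
        write_transcripts_gtf(original, path)
        restored = {t.transcript_id: t for t in read_transcripts(path)}
        for t in original:
            r = restored[t.transcript_id]
            assert [(e.start, e.end) for e in r.exons] == [
                (e.start, e.end) for e in t.exons
            ]
            assert r.strand == t.strand and r.gene_id == t.gene_id
            assert r.cds == t.cds


class TestReadRepeats:
    def test_repeatmasker_out_row(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "   SW   perc perc perc  query     position in query\n"
            "score   div. del. ins.  sequence  begin end (left)\n"
            "\n"
            "  463  11.4  0.0  0.0  chr1  1001  1100  (0)  +  AluY  SINE/Alu  1  100  (0)  1\n"
        )
        (r,) = read_repeats(p, "repeatmasker_out")
        assert (r.interval.start, r.interval.end) == (1000, 1100)
        assert r.ere_class == "SINE"

    def test_bed6_row_with_malr_name(self, tmp_path):
        p = tmp_path / "reps.bed"
        p.write_text("chr1\t500\t600\tMSTB\t0\t+\n")
        (r,) = read_repeats(p, "bed6")
        assert (r.interval.start, r.interval.end) == (500, 600)
        assert r.repeat_name == "MSTB"
        assert r.ere_class == "LTR" and r.subgroup == "MaLR"

    def test_short_row_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t500\n")
        with pytest.raises(ParseError, match="line 1"):
            read_repeats(p, "bed6")

    def test_bed_round_trip(self, tmp_path):
        reps = [
            RepeatFeature(GenomicInterval("chr1", 10, 300, "+"), "LTR12C", "LTR/ERV1"),
            RepeatFeature(GenomicInterval("chr2", 50, 90, "-"), "AluY", "SINE/Alu"),
        ]
        p = tmp_path / "rt.bed"
        write_repeats_bed(reps, p)
        back = read_repeats(p, "bed6")
        assert [(r.interval.start, r.interval.end, r.ere_class) for r in back] == [
            (10, 300, "LTR"), (50, 90, "SINE")
        ]
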