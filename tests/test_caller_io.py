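import pytest

from duocall.caller_io import (
    DepthTrack,
    SomaticCall,
    depth_at,
    normalize_consequence,
    normalize_variant,
    read_annotation_table,
    read_depth_track,
    read_germline_keys,
    read_population_frequencies,
    read_somatic_vcf,
    write_dialect_a_vcf,
)
from duocall.errors import FormatError, InputError, ReferenceMismatchError
from duocall.reference_context import ReferenceSet

VCF_A = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=c1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tS1
c1\t100\trs1\tC\tT\t30\tPASS\t.\tGT:DP:AD\t0/0:55:55,0\t0/1:80:46,34
c1\t200\t.\tA\tT,G\t22\tPASS\t.\tGT:DP:AD\t0/0:40:40,0,0\t0/1:60:30,20,10
c1\t300\t.\tG\t<DEL>\t50\tPASS\t.\tGT:DP:AD\t0/0:40:40,0\t0/1:60:30,30
"""

VCF_B = """##fileformat=VCFv4.2
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="x">
##INFO=<ID=SomaticEVS,Number=1,Type=Float,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=AU,Number=2,Type=Integer,Description="x">
##FORMAT=<ID=CU,Number=2,Type=Integer,Description="x">
##FORMAT=<ID=GU,Number=2,Type=Integer,Description="x">
##FORMAT=<ID=TU,Number=2,Type=Integer,Description="x">
##FILTER=<ID=LowEVS,Description="x">
##contig=<ID=c1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
c1\t100\t.\tC\tT\t.\tPASS\tSOMATIC;SomaticEVS=17.5\tDP:AU:CU:GU:TU\t50:0,0:50,50:0,0:0,0\t40:1,1:33,33:2,2:4,4
c1\t150\t.\tG\tA\t.\tLowEVS\tSOMATIC;SomaticEVS=4.1\tDP:AU:CU:GU:TU\t50:0,0:0,0:50,50:0,0\t30:10,10:0,0:20,20:0,0
"""


@pytest.fixture
def vcf_a(tmp_path):
    path = tmp_path / "a.vcf"
    path.write_text(VCF_A)
    return path


@pytest.fixture
def vcf_b(tmp_path):
    path = tmp_path / "b.vcf"
    path.write_text(VCF_B)
    return path


class TestReadSomaticVcf:
    def test_dialect_a_field_mapping(self, vcf_a):
        calls = read_somatic_vcf(vcf_a, "A", "S1")
        first = calls[0]
        assert first.qual_score == 30
        assert first.tumor_alt_depth == 34
        assert first.tumor_total_depth == 80
        assert first.normal_depth == 55
        assert first.dbsnp_id == "rs1"
        assert first.filter_status == "PASS"

    def test_multiallelic_split(self, vcf_a):
        calls = read_somatic_vcf(vcf_a, "A", "S1")
        at_200 = [c for c in calls if c.pos1 == 200]
        assert [(c.alt_allele, c.tumor_alt_depth) for c in at_200] == [("T", 20), ("G", 10)]
        assert all(c.tumor_total_depth == 60 for c in at_200)

    def test_symbolic_alt_skipped_with_count(self, vcf_a):
        stats = {}
        calls = read_somatic_vcf(vcf_a, "A", "S1", stats=stats)
        assert stats["n_skipped"] == 1
        assert stats["n_alt_alleles"] == len(calls) + stats["n_skipped"]

    def test_dialect_b_tier1_counts(self, vcf_b):
        calls = read_somatic_vcf(vcf_b, "B", "S1")
        first = calls[0]
        assert first.qual_score == 17.5
        assert first.tumor_alt_depth == 4
        assert first.tumor_total_depth == 40
        assert first.normal_depth == 50

    def test_dialect_b_filter_field(self, vcf_b):
        calls = read_somatic_vcf(vcf_b, "B", "S1")
        assert calls[1].filter_status == "LowEVS"
        assert calls[1].qual_score == pytest.approx(4.1)

    def test_missing_tumor_column(self, vcf_a):
        with pytest.raises(InputError, match="tumor sample"):
            read_somatic_vcf(vcf_a, "A", "NOPE")


class TestNormalizeVariant:
    REF = ReferenceSet({"c1": "GGGGGGGGGCACTGACGTAC"})  # pos 10..13 = CACT

    def _call(self, pos1, ref, alt):
        return SomaticCall("S1", "A", "c1", pos1, ref, alt, "PASS", 30.0, 10, 20)

    def test_snv_unchanged(self):
        call = self._call(10, "C", "T")
        assert normalize_variant(call, self.REF) is call

    def test_trim_to_snv(self):
        # REF=AC ALT=AT at pos 11 -> SNV C->T at pos 12
        out = normalize_variant(self._call(11, "AC", "AT"), self.REF)
        assert (out.pos1, out.ref_allele, out.alt_allele) == (12, "C", "T")

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError):
            normalize_variant(self._call(10, "A", "T"), self.REF)

    def test_indel_left_alignment(self):
        # deletion of one G inside the G run: any representation left-aligns to pos 1
        ref = ReferenceSet({"c1": "GGGGGACGT"})
        call = SomaticCall("S1", "A", "c1", 4, "GG", "G", "PASS", 30.0, 10, 20)
        out = normalize_variant(call, ref)
        assert (out.pos1, out.ref_allele, out.alt_allele) == (1, "GG", "G")


class TestRoundTrip:
    def test_dialect_a_roundtrip(self, tmp_path):
        calls = [
            SomaticCall("S1", "A", "c1", 5, "A", "T", "PASS", 31.5, 12, 40, normal_depth=22),
            SomaticCall("S1", "A", "c1", 9, "C", "G", "LowSupport", 8.0, 3, 50, normal_depth=30),
        ]
        path = tmp_path / "rt.vcf"
        write_dialect_a_vcf(calls, path, {"c1": 100}, "S1")
        back = read_somatic_vcf(path, "A", "S1")
        assert back == calls


class TestPopulationFrequencies:
    def test_tsv(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("c1\t50\tC\tT\t0.002\n")
        table = read_population_frequencies(path)
        assert table.get(("c1", 50, "C", "T")) == 0.002
        assert table.get(("c1", 51, "C", "T")) is None

    def test_tsv_with_header(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("contig\tpos1\tref\talt\tmaf\nc1\t50\tC\tT\t0.004\n")
        assert read_population_frequencies(path).get(("c1", 50, "C", "T")) == 0.004

    def test_maf_out_of_range(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("c1\t50\tC\tT\t1.5\n")
        with pytest.raises(FormatError):
            read_population_frequencies(path)

    def test_vcf_af_info(self, tmp_path):
        path = tmp_path / "p.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="x">\n'
            "##contig=<ID=c1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c1\t10\t.\tA\tG\t.\tPASS\tAF=0.25\n"
        )
        assert read_population_frequencies(path).get(("c1", 10, "A", "G")) == pytest.approx(0.25)

    def test_position_mode_lookup(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("c1\t50\tC\tT\t0.002\nc1\t50\tC\tA\t0.01\n")
        table = read_population_frequencies(path)
        assert table.max_at_position("c1", 50) == 0.01


class TestNormalizeConsequence:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Missense variant", "missense_variant"),
            ("Intron variant", "intron_variant"),
            ("3 prime UTR variant", "3_prime_utr_variant"),
            ("Downstream gene variant, rs111534922", "downstream_gene_variant"),
            ("Missense variant, COSV57111433", "missense_variant"),
            ("missense_variant&splice_region_variant", "missense_variant"),
            ("weird thing", "weird_thing"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_consequence(raw) == expected


class TestAnnotationTable:
    def test_read_and_normalize(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "contig\tpos\tref\talt\tgene\tconsequence\tcadd_phred\tpop_freq\n"
            "c1\t10\tA\tG\tGENE1\tMissense variant\t34\t0\n"
            "c1\t20\tC\tT\tGENE2\tIntron variant\t\t0.003%\n"
        )
        table = read_annotation_table(path)
        a = table.get(("c1", 10, "A", "G"))
        assert a.consequence == "missense_variant" and a.cadd_phred == 34
        b = table.get(("c1", 20, "C", "T"))
        assert b.cadd_phred is None
        assert b.population_freq == pytest.approx(0.00003)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("contig\tpos\tref\talt\n")
        with pytest.raises(InputError, match="consequence"):
            read_annotation_table(path)

    def test_unknown_consequence_flagged_other(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "contig\tpos\tref\talt\tgene\tconsequence\tcadd_phred\tpop_freq\n"
            "c1\t10\tA\tG\tG1\tmystery_effect\t1\t0\n"
        )
        rec = read_annotation_table(path).get(("c1", 10, "A", "G"))
        assert rec.consequence == "mystery_effect"
        assert not rec.in_vocabulary


class TestDepthTrack:
    def test_depth_at_basic(self):
        track = DepthTrack([("c1", 0, 100, 15)])
        assert depth_at(track, "c1", 50) == 15
        assert depth_at(track, "c1", 101) == 0
        assert depth_at(track, "c2", 50) == 0

    def test_boundary_half_open(self):
        track = DepthTrack([("c1", 0, 10, 10), ("c1", 10, 20, 20)])
        assert depth_at(track, "c1", 10) == 10  # 0-based offset 9: first interval
        assert depth_at(track, "c1", 11) == 20  # 0-based offset 10: second interval

    def test_read_tsv(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("c1\t0\t100\t15\nc1\t100\t200\t8\n")
        track = read_depth_track(path)
        assert track.depth_at("c1", 150) == 8

    def test_negative_depth_rejected(self):
        with pytest.raises(FormatError):
            DepthTrack([("c1", 0, 10, -1)])


class TestGermlineKeys:
    def test_read(self, tmp_path, tiny_ref):
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=c1,length=25>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "c1\t2\t.\tC\tA\t50\tPASS\t.\tGT\t0/1\n"
        )
        assert read_germline_keys(path, tiny_ref) == {("c1", 2, "C", "A")}


class TestSomaticCallInvariants:
    def test_alt_depth_exceeds_total(self):
        with pytest.raises(InputError):
            SomaticCall("S", "A", "c1", 1, "A", "T", "PASS", 1.0, 10, 5)

    def test_ref_equals_alt(self):
        with pytest.raises(InputError):
            SomaticCall("S", "A", "c1", 1, "A", "A", "PASS", 1.0, 1, 5)
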