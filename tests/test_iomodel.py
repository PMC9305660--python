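"""Domain types, ISCN parsing and multi-modal bundle loading."""

import pytest

from clonefish.cytobands import parse_band
from clonefish.fixtures import table_karyotype_strings, \
    write_patient_fixture
from clonefish.iomodel import CghSegment, Direction, IscnParseError, \
    KaryotypeObservation, Kind, VariantObservation, count_aberrations, \
    infer_der_losses, load_patient, parse_iscn, serialize_iscn

ZW = "​"


class TestParseIscn:
    def test_deletion_token(self):
        (ab,) = parse_iscn("del(5)(q14q33)")
        assert ab.kind == Kind.CNV
        assert ab.cnv_direction == Direction.LOSS
        assert ab.chrom == "5"
        assert ab.region.arm == "q"
        assert ab.region.lo == pytest.approx(1.4)
        assert 3.3 <= ab.region.hi < 3.4

    def test_empty_clone_string(self):
        assert parse_iscn("") == []

    def test_two_translocations_with_zero_width_chars(self):
        abs_ = parse_iscn(f"t(9;20)(q11;q11),{ZW}t(12;22)(p13;q11)")
        assert len(abs_) == 2
        assert all(a.kind == Kind.SV for a in abs_)

    def test_isochromosome_with_multiplier(self):
        (ab,) = parse_iscn("i(8)(q10)x2")
        assert ab.kind == Kind.CNV
        assert ab.cnv_direction == Direction.GAIN
        assert ab.multiplicity == 2

    @pytest.mark.parametrize("token,kind,direction", [
        ("+8", Kind.CNV, Direction.GAIN),
        ("-17", Kind.CNV, Direction.LOSS),
        ("+X", Kind.CNV, Direction.GAIN),
        ("dup(1)(q21q32)", Kind.CNV, Direction.GAIN),
        ("add(18)(q22)", Kind.SV, None),
        ("inv(16)(p13q22)", Kind.SV, None),
        ("ins(9;12)(q34;p12p13)", Kind.SV, None),
        ("+mar1", Kind.SV, None),
        ("der(17)t(13;17)(q21;p12)", Kind.SV, None),
        ("+der(4)t(4;14;11)", Kind.SV, None),
    ])
    def test_token_kinds(self, token, kind, direction):
        (ab,) = parse_iscn(token)
        assert ab.kind == kind
        assert ab.cnv_direction == direction

    def test_ploidy_prefix_consumed(self):
        assert parse_iscn("46,XX") == []
        abs_ = parse_iscn("45,XY,del(5)(q14q33)")
        assert [a.iscn_token for a in abs_] == ["del(5)(q14q33)"]

    def test_unsupported_token_reports_token_and_offset(self):
        with pytest.raises(IscnParseError) as exc:
            parse_iscn("del(5)(q14q33),bogus(3)")
        assert exc.value.token == "bogus(3)"
        assert exc.value.offset == len("del(5)(q14q33),")

    def test_roundtrip_over_cohort_karyotypes(self):
        # total over the supported grammar: every published clone string
        # parses and re-serializes to its cleaned token sequence
        for s in table_karyotype_strings():
            cleaned = "".join(ch for ch in s if not ch.isspace()
                              and ch != ZW)
            assert serialize_iscn(parse_iscn(s)) == cleaned


class TestDerivativeLossInference:
    def test_der17_implies_terminal_17p_loss(self):
        abs_ = parse_iscn("der(17)t(13;17)(q21;p12)")
        (loss,) = infer_der_losses(abs_)
        assert loss.kind == Kind.CNV
        assert loss.cnv_direction == Direction.LOSS
        assert loss.chrom == "17"
        assert loss.region.contains_band("p13.1")   # covers TP53
        assert not loss.region.contains_band("q11")

    def test_balanced_translocation_implies_nothing(self):
        assert infer_der_losses(parse_iscn("t(9;20)(q11;q11)")) == []


class TestObservationInvariants:
    def test_vaf_bounds(self):
        with pytest.raises(ValueError):
            VariantObservation("a", 0, vaf=1.2)

    def test_alt_depth_consistency(self):
        with pytest.raises(ValueError):
            VariantObservation("a", 0, vaf=0.5, depth=100, alt_reads=30)
        VariantObservation("a", 0, vaf=0.3, depth=100, alt_reads=30)

    def test_karyotype_counts(self):
        with pytest.raises(ValueError):
            KaryotypeObservation(0, "+8", metaphases_with=21,
                                 metaphases_total=20)
        with pytest.raises(ValueError):
            KaryotypeObservation(0, "+8", metaphases_with=0,
                                 metaphases_total=0)

    def test_cgh_direction_sign(self):
        with pytest.raises(ValueError):
            CghSegment(0, "5", 100, 200, log2_ratio=0.3,
                       direction=Direction.LOSS)
        CghSegment(0, "5", 100, 200, log2_ratio=-0.3,
                   direction=Direction.LOSS)


class TestLoadPatient:
    def test_patient3_three_aberrations_one_timepoint(self, cohort):
        assert count_aberrations(cohort["3"]) == 3
        assert len(cohort["3"].timepoints) == 1

    def test_patient2_six_variants_plus_two_trisomies(self, cohort):
        assert count_aberrations(cohort["2"]) == 8

    def test_patient1_table_enumerates_ten(self, cohort):
        assert count_aberrations(cohort["1"]) == 10

    def test_patient7_has_no_somatic_variants(self, cohort):
        assert cohort["7"].variant_obs == []
        assert len(cohort["7"].timepoints) == 4

    def test_empty_bundle(self, tmp_path):
        (tmp_path / "config.yaml").write_text(
            "patient: p0\ntimepoints:\n- {label: initial, status: initial}\n")
        (tmp_path / "variants.tsv").write_text(
            "patient\ttimepoint\tgene\thgvs_c\thgvs_p\tvaf_percent\t"
            "depth\talt_reads\n")
        (tmp_path / "karyotype.tsv").write_text(
            "patient\ttimepoint\tclone_iscn\tmetaphases_with\t"
            "metaphases_total\npatient0\t0\t46,XX\t20\t20\n")
        bundle = load_patient(tmp_path)
        assert count_aberrations(bundle) == 0

    def test_unknown_timepoint_rejected(self, tmp_path):
        write_patient_fixture("3", tmp_path)
        with open(tmp_path / "variants.tsv", "a") as fh:
            fh.write("patient3\t9\tNF1\tc.1A>G\t\t10.0\t\t\n")
        with pytest.raises(ValueError, match="unknown time point"):
            load_patient(tmp_path)

    def test_merging_is_idempotent(self, tmp_path):
        d = write_patient_fixture("6", tmp_path)
        a, b = load_patient(d), load_patient(d)
        assert set(a.aberrations) == set(b.aberrations)
        assert [o.vaf for o in a.variant_obs] == [o.vaf for o in b.variant_obs]

    def test_fish_merges_onto_karyotype_aberration(self, tmp_path):
        d = write_patient_fixture("8", tmp_path)
        (d / "fish.tsv").write_text(
            "patient\ttimepoint\tprobe\tnuclei_with\tnuclei_total\n"
            "patient8\t0\t9q22\t102\t200\n")
        bundle = load_patient(d)
        (fobs,) = bundle.fish_obs
        assert fobs.aberration_id == "del(9)(q21q31)"
        assert count_aberrations(bundle) == 11  # merged, nothing new

    def test_cgh_merges_and_checks_direction(self, tmp_path):
        from clonefish.cytobands import band_to_coords
        d = write_patient_fixture("8", tmp_path)
        start, end = band_to_coords("9", parse_band("q25"))
        (d / "cgh.tsv").write_text(
            "chrom\tstart\tend\tlog2_ratio\ttimepoint\n"
            f"9\t{start}\t{end}\t-0.32\t0\n")
        bundle = load_patient(d)
        (seg,) = bundle.cgh_segments
        assert seg.aberration_id == "del(9)(q21q31)"
        # a gain over the same region contradicts the karyotype deletion
        (d / "cgh.tsv").write_text(
            "chrom\tstart\tend\tlog2_ratio\ttimepoint\n"
            f"9\t{start}\t{end}\t0.32\t0\n")
        with pytest.raises(ValueError, match="conflict"):
            load_patient(d)


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="Transcript change">
##INFO=<ID=TP,Number=1,Type=Integer,Description="Time point index">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=1>
##contig=<ID=17>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t115258747\t.\tC\tT\t.\tPASS\tGENE=NRAS;HGVSC=c.35G>A;TP=0;AF=0.30\tAD\t70,30
17\t7577538\t.\tC\tT\t.\tPASS\tGENE=TP53;HGVSC=c.742C>T;TP=0\tAD\t160,40
"""


class TestVcfIngestion:
    def test_af_and_ad_fields(self, tmp_path):
        (tmp_path / "config.yaml").write_text(
            "patient: pv\ntimepoints:\n- {label: initial, status: initial}\n")
        (tmp_path / "variants.vcf").write_text(VCF_TEXT)
        bundle = load_patient(tmp_path)
        assert count_aberrations(bundle) == 2
        by_id = {o.aberration_id: o for o in bundle.variant_obs}
        assert by_id["NRAS:c.35G>A"].vaf == pytest.approx(0.30)
        tp53 = by_id["TP53:c.742C>T"]
        assert tp53.vaf == pytest.approx(0.20)
        assert (tp53.depth, tp53.alt_reads) == (200, 40)
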