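"""Domain types and readers/writers: round-trips, keying, integrity checks."""

from __future__ import annotations

import pytest
import pysam

from famexome.model import (
    FamilyCohort,
    PedigreeMember,
    SequenceRead,
    VariantCall,
    load_pedigree,
    load_site_set,
    load_variant_table,
    write_site_set,
    write_variant_table,
)


def _pedigree_tsv(tmp_path, rows):
    path = tmp_path / "ped.tsv"
    header = "family_id\tmember_id\taffected\tdiagnosis_age\tsequenced\tavailable\n"
    path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestSequenceRead:
    def test_rejects_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            SequenceRead("r", "ACGT", (30, 30))
        with pytest.raises(ValueError):
            SequenceRead("r", "", ())

    def test_rejects_invalid_bases(self):
        with pytest.raises(ValueError):
            SequenceRead("r", "ACXT", (30,) * 4)


class TestVariantCall:
    def test_identity_key_is_chrom_pos_alleles(self):
        a = VariantCall("c1", 100, "A", "G", "SNV", "het", 10, 8, 30.0, 25.0, 50.0)
        b = VariantCall("c1", 100, "A", "G", "SNV", "hom", 1, 1, 1.0, 1.0, 1.0)
        c = VariantCall("c1", 100, "A", "T", "SNV", "het", 10, 8, 30.0, 25.0, 50.0)
        assert a.key == b.key
        assert a.key != c.key

    def test_snv_requires_single_base_alleles(self):
        with pytest.raises(ValueError):
            VariantCall("c1", 100, "AT", "G", "SNV", "het")

    def test_position_must_be_one_based(self):
        with pytest.raises(ValueError):
            VariantCall("c1", 0, "A", "G", "SNV", "het")


class TestVariantTableRoundTrip:
    @pytest.mark.parametrize("suffix", [".vcf", ".tsv"])
    def test_write_then_load_is_identity(self, tmp_path, suffix, small_study):
        calls = small_study.cohorts[0].variant_sets["F1_A"]
        path = tmp_path / f"calls{suffix}"
        write_variant_table(calls, path, sample_id="F1_A")
        assert load_variant_table(path) == calls

    def test_vcf_line_maps_fields_directly(self, tmp_path):
        call = VariantCall(
            "c1", 500, "A", "G", "SNV", "het",
            depth_ref=10, depth_alt=8, phred_ref=200.0, phred_alt=150.0,
            snp_quality=99.0, consequence="nonsynonymous", gene="FANCM",
            db_flags=frozenset({"dbsnp"}),
        )
        path = tmp_path / "one.vcf"
        write_variant_table([call], path)
        (loaded,) = load_variant_table(path)
        assert loaded.depth_ref == 10 and loaded.depth_alt == 8
        assert loaded.zygosity == "het"
        assert loaded == call

    def test_multiallelic_record_splits_per_alt(self, tmp_path):
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">')
        header.formats.add("AD", "R", "Integer", "depths")
        header.formats.add("AQ", "R", "Float", "quals")
        header.contigs.add("c1")
        header.add_sample("S")
        path = tmp_path / "multi.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            rec = vcf.new_record(contig="c1", start=99, alleles=("G", "A", "T"), qual=50)
            rec.samples["S"]["GT"] = (1, 2)
            rec.samples["S"]["AD"] = (4, 6, 7)
            rec.samples["S"]["AQ"] = (40.0, 60.0, 70.0)
            vcf.write(rec)
        calls = load_variant_table(path)
        assert len(calls) == 2
        assert {c.alt_allele for c in calls} == {"A", "T"}
        assert all(c.key[:3] == ("c1", 100, "G") for c in calls)
        assert [c.depth_alt for c in calls] == [6, 7]
        assert all(c.depth_ref == 4 for c in calls)

    def test_missing_evidence_header_is_field_error(self, tmp_path):
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">')
        header.contigs.add("c1")
        header.add_sample("S")
        path = tmp_path / "noad.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            rec = vcf.new_record(contig="c1", start=9, alleles=("A", "C"))
            rec.samples["S"]["GT"] = (0, 1)
            vcf.write(rec)
        with pytest.raises(ValueError, match="AD"):
            load_variant_table(path)

    def test_empty_table_loads_as_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert load_variant_table(path) == []

    def test_missing_per_record_evidence_becomes_none(self, tmp_path):
        call = VariantCall("c1", 5, "A", "G", "SNV", "het", consequence="UTR3")
        path = tmp_path / "sparse.vcf"
        write_variant_table([call], path)
        (loaded,) = load_variant_table(path)
        assert loaded.depth_ref is None and loaded.phred_alt is None


class TestPedigree:
    def test_study_layout_seven_families_eleven_sequenced(self, tmp_path):
        rows = []
        fams = [("A", 2), ("B", 2), ("C", 2), ("D", 2), ("E", 1), ("F", 1), ("G", 1)]
        for fam, n_seq in fams:
            for i in range(n_seq):
                rows.append((fam, f"{fam}{i}", 1, 45, 1, 1))
            rows.append((fam, f"{fam}x", 0, "", 0, 1))
        cohorts = load_pedigree(_pedigree_tsv(tmp_path, rows))
        assert len(cohorts) == 7
        assert sum(len(c.sequenced_ids) for c in cohorts) == 11

    def test_single_member_family_gives_singleton_cohort(self, tmp_path):
        cohorts = load_pedigree(_pedigree_tsv(tmp_path, [("A", "A1", 1, 50, 1, 1)]))
        assert len(cohorts) == 1 and cohorts[0].sequenced_ids == ["A1"]

    def test_member_in_two_families_is_error(self, tmp_path):
        rows = [("A", "m1", 1, 50, 1, 1), ("B", "m1", 1, 50, 1, 1)]
        with pytest.raises(ValueError, match="two families"):
            load_pedigree(_pedigree_tsv(tmp_path, rows))

    def test_duplicate_member_within_family_is_error(self, tmp_path):
        rows = [("A", "m1", 1, 50, 1, 1), ("A", "m1", 1, 50, 1, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            load_pedigree(_pedigree_tsv(tmp_path, rows))

    def test_family_without_sequenced_member_is_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no sequenced"):
            load_pedigree(_pedigree_tsv(tmp_path, [("A", "m1", 1, 50, 0, 1)]))

    def test_more_than_two_sequenced_members_warns_but_loads(self, tmp_path):
        rows = [("A", f"m{i}", 1, 50, 1, 1) for i in range(3)]
        with pytest.warns(UserWarning, match="3 sequenced"):
            cohorts = load_pedigree(_pedigree_tsv(tmp_path, rows))
        assert len(cohorts[0].sequenced_ids) == 3

    def test_diagnosis_age_requires_affected(self):
        with pytest.raises(ValueError):
            PedigreeMember("m", "f", affected=False, diagnosis_age=40.0)

    def test_variant_sets_restricted_to_sequenced_members(self):
        members = [PedigreeMember("m1", "f", True, 40.0, sequenced=True)]
        with pytest.raises(ValueError, match="non-sequenced"):
            FamilyCohort("f", members, {"ghost": []})


class TestSiteSet:
    def test_duplicates_collapse(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("c1\t10\tA\tG\nc1\t10\tA\tG\nc2\t20\tC\tT\n")
        assert len(load_site_set(path, "x")) == 2

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("")
        assert len(load_site_set(path, "x")) == 0

    def test_same_position_different_alt_are_distinct(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("c1\t10\tA\tG\nc1\t10\tA\tT\n")
        sites = load_site_set(path, "x")
        assert len(sites) == 2
        assert ("c1", 10, "A", "G") in sites and ("c1", 10, "A", "C") not in sites

    def test_unparseable_line_errors_with_line_number(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("c1\t10\tA\tG\nc1\tnope\tA\tG\n")
        with pytest.raises(ValueError, match="line 2"):
            load_site_set(path, "x")

    def test_round_trip(self, tmp_path, small_study):
        path = tmp_path / "panel.tsv"
        write_site_set(small_study.control_sites, path)
        assert load_site_set(path, "control_panel").keys == small_study.control_sites.keys
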