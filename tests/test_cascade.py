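"""Allele-balance scores, the filtering cascade, and funnel accounting."""

from __future__ import annotations

import dataclasses
import itertools

import pytest

from famexome.cascade import (
    CascadeConfig,
    consequence_filter,
    depth_score,
    exclude_sites,
    gene_function_filter,
    quality_score,
    run_cascade,
    score_filter_indel,
    score_filter_snv,
    shared_in_family,
    summarize_funnel,
)
from famexome.model import FamilyCohort, PedigreeMember, SiteSet, VariantCall
from _oracles import cascade_bruteforce


def _call(pos=100, chrom="c1", ref="A", alt="G", vtype="SNV", zygosity="het",
          depth_ref=10, depth_alt=10, phred_ref=100.0, phred_alt=100.0,
          snp_quality=60.0, consequence="nonsynonymous", gene="FANCM", db_flags=()):
    return VariantCall(chrom, pos, ref, alt, vtype, zygosity, depth_ref, depth_alt,
                       phred_ref, phred_alt, snp_quality, consequence, gene,
                       frozenset(db_flags))


def _cohort(family_id, variant_sets):
    members = [
        PedigreeMember(m, family_id, affected=True, diagnosis_age=45.0, sequenced=True,
                       available_for_segregation=True)
        for m in variant_sets
    ]
    return FamilyCohort(family_id, members, {m: list(v) for m, v in variant_sets.items()})


class TestScores:
    @pytest.mark.parametrize(
        "depth_alt,depth_ref,expected",
        [(10, 10, 100.0), (21, 10, 210.0), (3, 0, None), (0, 10, 0.0)],
    )
    def test_depth_score_is_percentage_ratio(self, depth_alt, depth_ref, expected):
        assert depth_score(depth_alt, depth_ref) == expected

    @pytest.mark.parametrize(
        "phred_alt,phred_ref,expected",
        [(30.0, 30.0, 100.0), (60.0, 30.0, 200.0), (15.0, 0.0, None), (10.0, None, None)],
    )
    def test_quality_score_is_percentage_ratio(self, phred_alt, phred_ref, expected):
        assert quality_score(phred_alt, phred_ref) == expected


class TestSharedInFamily:
    def test_two_member_family_keeps_only_common_keys(self):
        shared = _call(pos=10)
        cohort = _cohort("f", {"a": [shared, _call(pos=20)], "b": [_call(pos=10), _call(pos=30)]})
        result = shared_in_family(cohort)
        assert [v.key for v in result] == [shared.key]

    def test_evidence_comes_from_index_member(self):
        a_copy = _call(pos=10, depth_alt=15)
        b_copy = _call(pos=10, depth_alt=4)
        cohort = _cohort("f", {"a": [a_copy], "b": [b_copy]})
        assert shared_in_family(cohort)[0].depth_alt == 15
        assert shared_in_family(cohort, index_member="b")[0].depth_alt == 4

    def test_single_member_family_is_identity(self):
        calls = [_call(pos=p) for p in range(1, 101)]
        cohort = _cohort("f", {"solo": calls})
        assert shared_in_family(cohort) == calls


class TestSiteExclusion:
    def test_excludes_matching_key_only(self):
        keep = _call(pos=10, alt="G")
        drop = _call(pos=10, alt="T")
        sites = SiteSet("panel", {drop.key})
        assert exclude_sites([keep, drop], sites) == [keep]

    def test_empty_site_set_is_identity(self):
        calls = [_call(pos=p) for p in (1, 2, 3)]
        assert exclude_sites(calls, SiteSet("empty")) == calls

    def test_exclusions_and_consequence_filter_commute(self):
        calls = [
            _call(pos=1, consequence="synonymous"),
            _call(pos=2, consequence="nonsynonymous", db_flags={"dbsnp"}),
            _call(pos=3, consequence="intronic"),
            _call(pos=4, consequence="UTR3"),
        ]
        panel = SiteSet("panel", {calls[1].key, calls[3].key})
        known = SiteSet("known", {calls[0].key})
        cfg = CascadeConfig()
        stages = [
            lambda vs: exclude_sites(vs, panel),
            lambda vs: exclude_sites(vs, known),
            lambda vs: consequence_filter(vs, cfg),
        ]
        results = set()
        for order in itertools.permutations(stages):
            out = calls
            for stage in order:
                out = stage(out)
            results.add(tuple(v.key for v in out))
        assert len(results) == 1


class TestConsequenceFilter:
    def test_snv_blacklist_drops_silent_and_noncoding(self):
        calls = [
            _call(pos=1, consequence="synonymous"),
            _call(pos=2, consequence="UTR3"),
            _call(pos=3, consequence="nonsynonymous"),
        ]
        kept = consequence_filter(calls)
        assert [v.pos for v in kept] == [2, 3]

    def test_indel_blacklist_lacks_synonymous(self):
        indel = lambda pos, csq: _call(pos=pos, ref="A", alt="AT", vtype="INDEL", consequence=csq)
        kept = consequence_filter([indel(1, "intronic"), indel(2, "synonymous")])
        assert [v.pos for v in kept] == [2]

    def test_missing_consequence_label_is_error(self):
        with pytest.raises(ValueError, match="consequence"):
            consequence_filter([_call(consequence="")])


class TestScoreFilters:
    def test_snv_window_is_inclusive(self):
        at_bounds = _call(depth_ref=10, depth_alt=2, phred_ref=100.0, phred_alt=210.0)
        assert depth_score(at_bounds.depth_alt, at_bounds.depth_ref) == 20.0
        assert score_filter_snv([at_bounds]) == [at_bounds]

    def test_snv_below_window_removed(self):
        low = _call(depth_ref=1000, depth_alt=199, phred_ref=100.0, phred_alt=100.0)
        assert score_filter_snv([low]) == []

    def test_snv_undefined_score_removed(self):
        assert score_filter_snv([_call(depth_ref=0, depth_alt=3)]) == []
        assert score_filter_snv([_call(phred_ref=None)]) == []

    def test_indel_boundary_conditions(self):
        ok = _call(ref="A", alt="AT", vtype="INDEL", depth_ref=3, depth_alt=3,
                   phred_alt=11.0, snp_quality=11.0)
        assert score_filter_indel([ok]) == [ok]
        too_few = dataclasses.replace(ok, depth_alt=2)
        assert score_filter_indel([too_few]) == []
        at_ds_max = dataclasses.replace(ok, depth_ref=10, depth_alt=14)  # DS = 140
        assert score_filter_indel([at_ds_max]) == []
        weak_qual = dataclasses.replace(ok, phred_alt=10.0)
        assert score_filter_indel([weak_qual]) == []


class TestGeneFilter:
    def test_allowlist_membership(self):
        inlist, outlist = _call(gene="FANCM"), _call(pos=2, gene="G0001")
        assert gene_function_filter([inlist, outlist], frozenset({"FANCM"})) == [inlist]

    def test_disabled_filter_is_identity(self):
        calls = [_call(gene="whatever")]
        assert gene_function_filter(calls, None) == calls


class TestFunnelSummary:
    def test_single_family_single_sample_all_percentages_100(self):
        ft = summarize_funnel(
            {"m": 42}, {"fam": (42, 42, 42, 42, 42)}, {"m": "fam"}
        )
        assert ft.averages == [42] * 6
        assert ft.percentages == [100.0] * 6

    def test_counts_must_not_increase_along_stages(self):
        with pytest.raises(ValueError, match="increase"):
            summarize_funnel({"m": 10}, {"fam": (10, 12, 5, 5, 5)}, {"m": "fam"})

    def test_two_member_family_stage_one_is_sample_mean(self):
        ft = summarize_funnel(
            {"a": 10, "b": 20}, {"fam": (6, 4, 2, 1, 1)}, {"a": "fam", "b": "fam"}
        )
        assert ft.per_family_values["fam"][0] == 15.0


class TestRunCascade:
    def test_implanted_variant_survives_and_matches_bruteforce(self, small_study):
        cfg = CascadeConfig(gene_allowlist=small_study.gene_allowlist)
        result = run_cascade(
            small_study.cohorts, small_study.control_sites, small_study.known_sites, cfg
        )
        for cohort in small_study.cohorts:
            fam = cohort.family_id
            got = {v.key for v in result.survivors[fam]}
            expected = cascade_bruteforce(
                cohort, small_study.control_sites, small_study.known_sites, cfg
            )
            assert got == expected
            assert small_study.implants[fam].key in got

    def test_implant_added_to_known_sites_is_excluded(self, small_study):
        cfg = CascadeConfig(gene_allowlist=small_study.gene_allowlist)
        known = SiteSet(
            "dbsnp",
            small_study.known_sites.keys | {v.key for v in small_study.implants.values()},
        )
        result = run_cascade(small_study.cohorts, small_study.control_sites, known, cfg)
        for fam, implant in small_study.implants.items():
            assert implant.key not in {v.key for v in result.survivors[fam]}

    def test_empty_variant_sets_give_zero_counts(self):
        cohort = _cohort("f", {"a": [], "b": []})
        result = run_cascade([cohort], SiteSet("p"), SiteSet("k"))
        assert result.survivors["f"] == []
        assert result.funnel_snv.per_family_values["f"] == [0.0] * 6

    def test_stage_outputs_are_weakly_decreasing_subsets(self, small_study):
        cfg = CascadeConfig(gene_allowlist=small_study.gene_allowlist)
        result = run_cascade(
            small_study.cohorts, small_study.control_sites, small_study.known_sites, cfg
        )
        for funnel in (result.funnel_snv, result.funnel_indel):
            for values in funnel.per_family_values.values():
                assert all(a >= b for a, b in zip(values, values[1:]))

    def test_hom_snvs_are_outside_the_default_snv_funnel(self):
        het = _call(pos=1, zygosity="het")
        hom = _call(pos=2, zygosity="hom")
        cohort = _cohort("f", {"solo": [het, hom]})
        result = run_cascade([cohort], SiteSet("p"), SiteSet("k"))
        assert result.funnel_snv.per_sample_counts["solo"] == 1
        relaxed = run_cascade(
            [_cohort("f", {"solo": [het, hom]})], SiteSet("p"), SiteSet("k"),
            CascadeConfig(het_only=False),
        )
        assert relaxed.funnel_snv.per_sample_counts["solo"] == 2
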