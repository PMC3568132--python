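"""Allele-balance scoring and the six-stage variant-filtering cascade.

Each called variant carries two percentage-scale allele-balance statistics:

* Depth Score ``DS = 100 * depth_alt / depth_ref``
* Quality Score ``QS = 100 * phred_alt / phred_ref``

Either score is *undefined* (not zero) when its reference-allele denominator
is zero or missing; an undefined score can never certify a score filter.
The variant:reference orientation makes a perfectly balanced heterozygote
score 100, and values above 100 (excess variant-allele evidence) are legal —
which is why the SNV acceptance window extends to 210.

The cascade prioritizes rare variants shared within high-risk families:

1. ``detected``            heterozygous SNVs / all INDELs called per sample
2. ``shared_in_family``    present in both sequenced members (two-member
                           families); identity for single-member families
3. ``not_in_control_panel`` absent from the pooled control-panel call set
4. ``not_in_dbsnp``        absent from the known-variant database
5. ``consequence``         functional-consequence blacklist (SNVs drop
                           intronic/intergenic/synonymous; INDELs drop
                           intronic/intergenic only)
6. ``score_and_gene``      score filters plus an optional gene allowlist,
                           accounted as one funnel stage

All sharing and exclusion comparisons are allele-aware, on the key
``(chrom, pos, ref, alt)``.  The funnel summary mirrors the study-style
per-family table: stage-1 value per family is the mean of its sample counts,
later stages are the family's shared/filtered counts; the Average row is the
mean over families rounded half-away-from-zero to integers, and the
Percentage-remaining row divides the rounded stage averages by the rounded
stage-1 average (two decimals, half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import FamilyCohort, Key, ScorePair, SiteSet, VariantCall

__all__ = [
    "STAGES",
    "CascadeConfig",
    "FunnelTable",
    "CascadeResult",
    "depth_score",
    "quality_score",
    "score_pair",
    "shared_in_family",
    "exclude_sites",
    "consequence_filter",
    "score_filter_snv",
    "score_filter_indel",
    "gene_function_filter",
    "summarize_funnel",
    "run_cascade",
]

STAGES = (
    "detected",
    "shared_in_family",
    "not_in_control_panel",
    "not_in_dbsnp",
    "consequence",
    "score_and_gene",
)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and switches of the filtering cascade.

    The SNV window is inclusive on both ends ("between 20 and 210"); the
    INDEL criteria are strict where printed strict (DS < 140, qualities > 10)
    and inclusive for the minimum read support (at least 3 reads per allele).
    ``gene_allowlist=None`` disables the gene-function filter.
    """

    snp_score_low: float = 20.0
    snp_score_high: float = 210.0
    indel_ds_max: float = 140.0
    indel_phred_min: float = 10.0
    indel_snpq_min: float = 10.0
    indel_min_reads_each: int = 3
    consequence_blacklist_snv: frozenset[str] = frozenset(
        {"intronic", "intergenic", "synonymous"}
    )
    consequence_blacklist_indel: frozenset[str] = frozenset({"intronic", "intergenic"})
    gene_allowlist: frozenset[str] | None = None
    het_only: bool = True  # restrict the SNV funnel to heterozygous calls

    def __post_init__(self) -> None:
        if not (0 <= self.snp_score_low <= self.snp_score_high):
            raise ValueError("require 0 <= snp_score_low <= snp_score_high")
        if self.indel_min_reads_each < 0:
            raise ValueError("indel_min_reads_each must be >= 0")


def depth_score(depth_alt: int | None, depth_ref: int | None) -> float | None:
    """DS = 100 * depth_alt / depth_ref; undefined when depth_ref is 0/missing."""
    if depth_ref is None or depth_alt is None or depth_ref == 0:
        return None
    return 100.0 * depth_alt / depth_ref


def quality_score(phred_alt: float | None, phred_ref: float | None) -> float | None:
    """QS = 100 * phred_alt / phred_ref; undefined when phred_ref is 0/missing."""
    if phred_ref is None or phred_alt is None or phred_ref == 0:
        return None
    return 100.0 * phred_alt / phred_ref


def score_pair(call: VariantCall) -> ScorePair:
    return ScorePair(
        ds=depth_score(call.depth_alt, call.depth_ref),
        qs=quality_score(call.phred_alt, call.phred_ref),
    )


def shared_in_family(
    cohort: FamilyCohort,
    index_member: str | None = None,
    variant_sets: Mapping[str, Sequence[VariantCall]] | None = None,
) -> list[VariantCall]:
    """Variants common to all sequenced members of a family.

    For two-member families, a variant is retained iff its allele-aware key
    appears in both members' sets; the retained record (evidence fields
    included) is the *index member's* copy, by default the first sequenced
    member.  Single-member families pass through unchanged.
    """
    sets = variant_sets if variant_sets is not None else cohort.variant_sets
    sequenced = [m for m in cohort.sequenced_ids if m in sets]
    if not sequenced:
        raise ValueError(f"family {cohort.family_id}: no sequenced member with variants")
    if index_member is None:
        index_member = sequenced[0]
    if index_member not in sequenced:
        raise ValueError(f"index member {index_member!r} has no variant set")
    index_calls = list(sets[index_member])
    others = [m for m in sequenced if m != index_member]
    if not others:
        return index_calls
    common: set[Key] | None = None
    for m in others:
        keys = {v.key for v in sets[m]}
        common = keys if common is None else common & keys
    return [v for v in index_calls if v.key in common]


def exclude_sites(variants: Iterable[VariantCall], sites: SiteSet) -> list[VariantCall]:
    """Drop variants whose (chrom, pos, ref, alt) key is in the site set."""
    return [v for v in variants if v.key not in sites]


def consequence_filter(
    variants: Iterable[VariantCall], config: CascadeConfig = CascadeConfig()
) -> list[VariantCall]:
    """Drop variants whose consequence label is blacklisted for their type."""
    out = []
    for v in variants:
        if not v.consequence:
            raise ValueError(f"variant {v.key} has no consequence label")
        blacklist = (
            config.consequence_blacklist_snv
            if v.vtype == "SNV"
            else config.consequence_blacklist_indel
        )
        if v.consequence not in blacklist:
            out.append(v)
    return out


def _snv_scores_pass(v: VariantCall, config: CascadeConfig) -> bool:
    sp = score_pair(v)
    if sp.ds is None or sp.qs is None:
        return False
    return (
        config.snp_score_low <= sp.ds <= config.snp_score_high
        and config.snp_score_low <= sp.qs <= config.snp_score_high
    )


def _indel_scores_pass(v: VariantCall, config: CascadeConfig) -> bool:
    ds = depth_score(v.depth_alt, v.depth_ref)
    if ds is None or not ds < config.indel_ds_max:
        return False
    if v.phred_alt is None or not v.phred_alt > config.indel_phred_min:
        return False
    if v.snp_quality is None or not v.snp_quality > config.indel_snpq_min:
        return False
    if v.depth_ref is None or v.depth_alt is None:
        return False
    return (
        v.depth_ref >= config.indel_min_reads_each
        and v.depth_alt >= config.indel_min_reads_each
    )


def score_filter_snv(
    variants: Iterable[VariantCall], config: CascadeConfig = CascadeConfig()
) -> list[VariantCall]:
    """Keep SNVs with both DS and QS defined and inside the inclusive window."""
    return [v for v in variants if _snv_scores_pass(v, config)]


def score_filter_indel(
    variants: Iterable[VariantCall], config: CascadeConfig = CascadeConfig()
) -> list[VariantCall]:
    """Keep INDELs with DS < max, qualities above minima, and read support."""
    return [v for v in variants if _indel_scores_pass(v, config)]


def gene_function_filter(
    variants: Iterable[VariantCall], allowlist: frozenset[str] | None
) -> list[VariantCall]:
    """Keep variants whose gene is in the allowlist; identity when disabled."""
    if allowlist is None:
        return list(variants)
    return [v for v in variants if v.gene in allowlist]


# ---------------------------------------------------------------------------
# funnel accounting
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class FunnelTable:
    """Per-stage surviving-variant counts with study-table summary rows."""

    stage_labels: tuple[str, ...]
    per_sample_counts: dict[str, int]  # member -> stage-1 count
    per_family_values: dict[str, list[float]]  # family -> value per stage
    family_map: dict[str, str]  # member -> family
    averages_raw: list[float] = field(default_factory=list)
    averages: list[int] = field(default_factory=list)
    percentages: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Study-table layout: one row per family plus summary rows."""
        rows = {fam: list(vals) for fam, vals in sorted(self.per_family_values.items())}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(self.stage_labels))
        df.loc["Average"] = self.averages
        df.loc["Percentage remaining"] = self.percentages
        return df


def summarize_funnel(
    per_sample_counts: Mapping[str, int],
    per_family_counts: Mapping[str, Sequence[float]],
    family_map: Mapping[str, str],
    stage_labels: Sequence[str] = STAGES,
) -> FunnelTable:
    """Build the per-family funnel summary from raw stage counts.

    ``per_sample_counts`` holds the stage-1 (detected) count of every
    sequenced member; ``per_family_counts`` holds each family's counts for
    the later stages in order.  Counts must be weakly decreasing along the
    funnel within each family.
    """
    n_later = len(stage_labels) - 1
    families = sorted(per_family_counts)
    mapped = {family_map[m] for m in per_sample_counts}
    if mapped != set(families):
        raise ValueError("per-sample and per-family inputs cover different families")
    per_family_values: dict[str, list[float]] = {}
    for fam in families:
        samples = [c for m, c in per_sample_counts.items() if family_map[m] == fam]
        later = list(per_family_counts[fam])
        if len(later) != n_later:
            raise ValueError(
                f"family {fam}: expected {n_later} post-detection stage counts, "
                f"got {len(later)}"
            )
        values = [sum(samples) / len(samples), *map(float, later)]
        for prev, cur in zip(values, values[1:]):
            if cur > prev + 1e-9:
                raise ValueError(f"family {fam}: funnel counts increase along stages")
        per_family_values[fam] = values
    averages_raw = [
        sum(per_family_values[f][i] for f in families) / len(families)
        for i in range(len(stage_labels))
    ]
    averages_int = [_round_half_away(a) for a in averages_raw]
    # percentages derive from the rounded integer averages: this convention
    # reproduces every printed summary percentage of the study tables,
    # whereas unrounded intermediates do not (44.285 -> 44.28, not 44.29)
    percentages = [
        _round2(100.0 * a / averages_int[0]) if averages_int[0] else 0.0
        for a in averages_int
    ]
    return FunnelTable(
        stage_labels=tuple(stage_labels),
        per_sample_counts=dict(per_sample_counts),
        per_family_values=per_family_values,
        family_map=dict(family_map),
        averages_raw=averages_raw,
        averages=averages_int,
        percentages=percentages,
    )


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class CascadeResult:
    survivors: dict[str, list[VariantCall]]  # family -> SNV+INDEL survivors
    survivors_snv: dict[str, list[VariantCall]]
    survivors_indel: dict[str, list[VariantCall]]
    funnel_snv: FunnelTable
    funnel_indel: FunnelTable


def _run_one_type(
    cohorts: Sequence[FamilyCohort],
    vtype: str,
    control_sites: SiteSet,
    known_sites: SiteSet,
    config: CascadeConfig,
    index_members: Mapping[str, str] | None,
) -> tuple[dict[str, list[VariantCall]], FunnelTable]:
    per_sample: dict[str, int] = {}
    per_family: dict[str, list[float]] = {}
    family_map: dict[str, str] = {}
    survivors: dict[str, list[VariantCall]] = {}
    for cohort in cohorts:
        sets = {}
        for m in cohort.sequenced_ids:
            calls = cohort.variant_sets.get(m, [])
            if vtype == "SNV" and config.het_only:
                calls = [v for v in calls if v.vtype == "SNV" and v.zygosity == "het"]
            else:
                calls = [v for v in calls if v.vtype == vtype]
            sets[m] = calls
            per_sample[m] = len(calls)
            family_map[m] = cohort.family_id
        index = index_members.get(cohort.family_id) if index_members else None
        shared = shared_in_family(cohort, index_member=index, variant_sets=sets)
        no_panel = exclude_sites(shared, control_sites)
        novel = exclude_sites(no_panel, known_sites)
        functional = consequence_filter(novel, config)
        if vtype == "SNV":
            scored = score_filter_snv(functional, config)
        else:
            scored = score_filter_indel(functional, config)
        final = gene_function_filter(scored, config.gene_allowlist)
        survivors[cohort.family_id] = final
        per_family[cohort.family_id] = [
            len(shared), len(no_panel), len(novel), len(functional), len(final),
        ]
    funnel = summarize_funnel(per_sample, per_family, family_map)
    return survivors, funnel


def run_cascade(
    cohorts: Sequence[FamilyCohort],
    control_sites: SiteSet,
    known_sites: SiteSet,
    config: CascadeConfig = CascadeConfig(),
    index_members: Mapping[str, str] | None = None,
) -> CascadeResult:
    """Run the full filtering cascade over family cohorts.

    SNVs and INDELs are tracked as separate funnels (the SNV funnel counts
    heterozygous calls only when ``config.het_only``).  ``index_members``
    optionally names, per family, the member whose evidence fields represent
    shared variants.
    """
    snv_surv, snv_funnel = _run_one_type(
        cohorts, "SNV", control_sites, known_sites, config, index_members
    )
    indel_surv, indel_funnel = _run_one_type(
        cohorts, "INDEL", control_sites, known_sites, config, index_members
    )
    combined = {
        fam: snv_surv.get(fam, []) + indel_surv.get(fam, [])
        for fam in {c.family_id for c in cohorts}
    }
    return CascadeResult(
        survivors=combined,
        survivors_snv=snv_surv,
        survivors_indel=indel_surv,
        funnel_snv=snv_funnel,
        funnel_indel=indel_funnel,
    )
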