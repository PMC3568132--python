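"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the Fisher oracle
enumerates hypergeometric tables with exact rational arithmetic, and the
cascade oracle evaluates the full filter predicate per variant in a single
pass instead of stage by stage.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

from famexome.cascade import CascadeConfig
from famexome.model import FamilyCohort, SiteSet, VariantCall


@lru_cache(maxsize=None)
def _margin_probs(r1: int, r2: int, c1: int) -> tuple[tuple[int, Fraction], ...]:
    n = r1 + r2
    denom = comb(n, c1)
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    return tuple(
        (k, Fraction(comb(r1, k) * comb(r2, c1 - k), denom)) for k in range(kmin, kmax + 1)
    )


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by rational enumeration (point-probability rule)."""
    probs = dict(_margin_probs(a + b, c + d, a + c))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def _variant_predicate(
    v: VariantCall,
    shared_keys: set,
    control: SiteSet,
    known: SiteSet,
    config: CascadeConfig,
) -> bool:
    if v.key not in shared_keys:
        return False
    if v.key in control or v.key in known:
        return False
    if v.vtype == "SNV":
        if v.consequence in config.consequence_blacklist_snv:
            return False
        if v.depth_ref in (None, 0) or v.depth_alt is None:
            return False
        ds = 100.0 * v.depth_alt / v.depth_ref
        if v.phred_ref in (None, 0) or v.phred_alt is None:
            return False
        qs = 100.0 * v.phred_alt / v.phred_ref
        if not (config.snp_score_low <= ds <= config.snp_score_high):
            return False
        if not (config.snp_score_low <= qs <= config.snp_score_high):
            return False
    else:
        if v.consequence in config.consequence_blacklist_indel:
            return False
        if v.depth_ref in (None, 0) or v.depth_alt is None:
            return False
        if not 100.0 * v.depth_alt / v.depth_ref < config.indel_ds_max:
            return False
        if v.phred_alt is None or v.phred_alt <= config.indel_phred_min:
            return False
        if v.snp_quality is None or v.snp_quality <= config.indel_snpq_min:
            return False
        if v.depth_ref < config.indel_min_reads_each or v.depth_alt < config.indel_min_reads_each:
            return False
    if config.gene_allowlist is not None and v.gene not in config.gene_allowlist:
        return False
    return True


def cascade_bruteforce(
    cohort: FamilyCohort,
    control: SiteSet,
    known: SiteSet,
    config: CascadeConfig,
) -> set:
    """Surviving variant keys of one family by single-pass predicate evaluation."""
    member_keys = []
    for member_id in cohort.sequenced_ids:
        calls = cohort.variant_sets.get(member_id, [])
        keys = set()
        for v in calls:
            if v.vtype == "SNV" and config.het_only and v.zygosity != "het":
                continue
            keys.add((v.key, v.vtype))
        member_keys.append(keys)
    shared_typed = set.intersection(*member_keys) if member_keys else set()
    index_member = cohort.sequenced_ids[0]
    survivors = set()
    for v in cohort.variant_sets.get(index_member, []):
        if v.vtype == "SNV" and config.het_only and v.zygosity != "het":
            continue
        shared_keys = {k for k, t in shared_typed if t == v.vtype}
        if _variant_predicate(v, shared_keys, control, known, config):
            survivors.add(v.key)
    return survivors
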