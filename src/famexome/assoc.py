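"""Rare-variant case-control, segregation and prioritization statistics.

Carrier counts are converted to 2x2 *allele*-count tables under the
rare-variant assumption that every carrier is heterozygous (one variant
allele per carrier, ``2n`` alleles per arm).  Association is tested with the
two-sided Fisher's exact test under the point-probability rule — the p-value
is the sum of hypergeometric probabilities of all tables with the observed
margins that are no more probable than the observed table — which matches
the convention of standard case-control association software.  Effect size
is the cross-product odds ratio with a Woolf (log-scale normal) 95%
confidence interval; zero cells either yield NA or receive the Haldane
continuity correction (+0.5 to every cell), by policy.

Family-level evidence is summarized by the segregation fraction: among
affected relatives available for typing with a known carrier status, the
fraction carrying the candidate variant.  A variant "segregates" when that
fraction reaches one half.  Affected non-carriers with a late diagnosis age
are flagged as candidate phenocopies — sporadic cases inside a high-risk
family that should not count against the family's candidate allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import PedigreeMember

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "SegregationReport",
    "Candidate",
    "allele_table",
    "fisher_exact_two_sided",
    "odds_ratio_ci",
    "associate",
    "maf_screen",
    "segregation",
    "prioritize",
]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 allele counts: a/b variant/reference in cases, c/d in controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both margins (case and control alleles) must be positive")


@dataclass(frozen=True, slots=True)
class AssociationResult:
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    freq_cases: float
    freq_controls: float


def allele_table(
    carriers_cases: int, n_cases: int, carriers_controls: int, n_controls: int
) -> ContingencyTable:
    """Carrier counts to allele counts (heterozygous carriers, 2n alleles)."""
    if carriers_cases > n_cases or carriers_controls > n_controls:
        raise ValueError("carrier count exceeds sample count")
    if min(carriers_cases, n_cases, carriers_controls, n_controls) < 0:
        raise ValueError("counts must be non-negative")
    return ContingencyTable(
        a=carriers_cases,
        b=2 * n_cases - carriers_cases,
        c=carriers_controls,
        d=2 * n_controls - carriers_controls,
    )


def fisher_exact_two_sided(table: ContingencyTable, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p under the point-probability rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability is at most that of the observed table
    (within relative tolerance ``rel_tol`` to absorb floating-point noise).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    rv = hypergeom(n, c1, r1)
    k_min = max(0, r1 - (n - c1))
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = rv.pmf(ks)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(1.0, p)


def odds_ratio_ci(
    table: ContingencyTable, zero_policy: str = "na"
) -> tuple[float | None, float | None, float | None]:
    """Cross-product OR with Woolf 95% CI; zero cells handled by policy.

    ``zero_policy="na"`` returns (None, None, None) for any zero cell;
    ``"haldane"`` adds 0.5 to every cell first.
    """
    if zero_policy not in ("na", "haldane"):
        raise ValueError(f"invalid zero_policy {zero_policy!r}")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if zero_policy == "na":
            return None, None, None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-1.96 * se), or_ * math.exp(1.96 * se)


def associate(table: ContingencyTable, zero_policy: str = "na") -> AssociationResult:
    """Full association summary: OR, Woolf CI, Fisher p, allele frequencies."""
    or_, lo, hi = odds_ratio_ci(table, zero_policy)
    return AssociationResult(
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=fisher_exact_two_sided(table),
        freq_cases=table.a / (table.a + table.b),
        freq_controls=table.c / (table.c + table.d),
    )


def maf_screen(carriers: int, n_individuals: int, threshold: float = 0.01) -> str:
    """Discard a candidate seen in controls at MAF strictly above threshold."""
    if carriers > n_individuals:
        raise ValueError("carriers exceed number of individuals")
    maf = carriers / (2 * n_individuals)
    return "discard" if maf > threshold else "retain"


@dataclass(frozen=True, slots=True)
class SegregationReport:
    carriers_affected: int
    available_affected: int
    fraction: float
    passes: bool
    phenocopy_flags: tuple[str, ...]


def segregation(
    members: Iterable[PedigreeMember],
    age_threshold: float = 70.0,
    min_fraction: float = 0.5,
) -> SegregationReport:
    """Segregation fraction of a candidate variant in a family.

    Considers affected members available for typing whose carrier status is
    known.  The variant segregates when carriers/available >= min_fraction
    (the boundary is inclusive).  Affected non-carriers diagnosed at or
    after ``age_threshold`` years are flagged as candidate phenocopies.
    """
    informative = [
        m
        for m in members
        if m.affected and m.available_for_segregation and m.carrier_status != "unknown"
    ]
    if not informative:
        raise ValueError("no available affected member with known carrier status")
    carriers = sum(m.carrier_status == "carrier" for m in informative)
    fraction = carriers / len(informative)
    phenocopies = tuple(
        m.member_id
        for m in informative
        if m.carrier_status == "non-carrier"
        and m.diagnosis_age is not None
        and m.diagnosis_age >= age_threshold
    )
    return SegregationReport(
        carriers_affected=carriers,
        available_affected=len(informative),
        fraction=fraction,
        passes=fraction >= min_fraction,
        phenocopy_flags=phenocopies,
    )


@dataclass(slots=True)
class Candidate:
    """A candidate variant with its three evidence blocks.

    Missing evidence (None) fails its criterion, except segregation that was
    genuinely not assessable (``segregation_assessable=False``), which does
    not count against the candidate.
    """

    name: str
    association: AssociationResult | None = None
    control_carriers: int | None = None
    damaging: tuple[bool, ...] | None = None  # one flag per predictor
    segregation_report: SegregationReport | None = None
    segregation_assessable: bool = True
    selected: bool | None = None

    @property
    def odds_ratio(self) -> float | None:
        return self.association.odds_ratio if self.association else None


def _is_selected(c: Candidate, or_threshold: float = 2.0) -> bool:
    or_ok = (c.odds_ratio is not None and c.odds_ratio > or_threshold) or (
        c.control_carriers == 0
    )
    damaging_ok = bool(c.damaging) and any(c.damaging)
    if not c.segregation_assessable:
        seg_ok = True
    else:
        seg_ok = c.segregation_report is not None and c.segregation_report.passes
    return or_ok and damaging_ok and seg_ok


def prioritize(candidates: Sequence[Candidate], or_threshold: float = 2.0) -> list[Candidate]:
    """Select and rank candidates.

    Selected iff (OR > threshold OR absent from controls) AND damaging in at
    least one predictor AND (segregation passes or was not assessable).
    Output is ordered selected-first, then by descending OR with NA last.
    """
    ranked = [replace(c, selected=_is_selected(c, or_threshold)) for c in candidates]
    ranked.sort(
        key=lambda c: (
            not c.selected,
            c.odds_ratio is None,
            -(c.odds_ratio or 0.0),
        )
    )
    return ranked
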