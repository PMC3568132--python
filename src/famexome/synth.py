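"""Synthetic-data generators for end-to-end testing of the pipeline.

No deposited sequencing data is required anywhere in the package: these
generators emulate the statistical structure every pipeline stage assumes,
at the magnitudes of the seven-family exome study the pipeline models —
per-sample heterozygous SNV sets of ~26,500–30,700 calls and INDEL sets of
~25,200–36,200 calls, within-family sharing of about 31% of a member's
variants, and database-membership fractions (~82% of background variants in
the pooled control panel, ~87% in the known-variant database) chosen so the
sharing/novelty stages shed variants at roughly the observed rates.

Background variants live on a synthetic coordinate system (chromosomes
``c1``–``c22``, positions above 1000); no reference genome is involved.
A shared variant is one key copied to both sequenced members with
independently drawn evidence fields, matching how the cascade compares
members.  Evidence models give database-member SNVs allele-balance scores
inside [40, 160] on both DS and QS, while artifact calls draw heavy-tailed
score ratios and shallow depths; INDEL calls are a true/artifact mixture
(default 25% true-like) so stringent INDEL criteria retain only a minority
of known calls.  Each generator also emits the ground truth it knows by
construction (read-rule failures, implanted variant keys, carrier
placements), which downstream tests use as oracles.

All generators are pure functions of their :class:`SyntheticConfig`
(seed included): the same config yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .assoc import ContingencyTable, allele_table
from .model import (
    FamilyCohort,
    PedigreeMember,
    SequenceRead,
    SiteSet,
    VariantCall,
    write_pedigree,
    write_site_set,
    write_variant_table,
)
from .readqc import write_fastq

__all__ = [
    "CANDIDATE_GENES",
    "SyntheticConfig",
    "ReadTruth",
    "SimulatedStudy",
    "CaseControlSim",
    "gen_reads",
    "gen_family_cohorts",
    "gen_score_panel",
    "gen_case_control",
    "write_study",
]

#: allowlisted cancer-plausible genes; implanted causal variants draw from here
CANDIDATE_GENES = (
    "FANCM",
    "CHEK2",
    "WNT8A",
    "SLBP",
    "CNTROB",
    "AXIN1",
    "MAPKAP1",
    "TNFSF8",
    "PTPRF",
    "UBA3",
    "TIMP3",
    "S1PR3",
)

_SNV_CONSEQUENCES = (
    ("intronic", 0.44),
    ("intergenic", 0.15),
    ("synonymous", 0.12),
    ("nonsynonymous", 0.20),
    ("UTR3", 0.05),
    ("splicing", 0.02),
    ("stopgain", 0.02),
)
_INDEL_CONSEQUENCES = (
    ("intronic", 0.50),
    ("intergenic", 0.18),
    ("frameshift", 0.17),
    ("UTR3", 0.09),
    ("splicing", 0.06),
)

_POS_SPACE = 50_000_000  # positions per synthetic chromosome
_N_CHROM = 22
_RESERVED_POS_MAX = 1000  # implant positions live below background positions


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of all synthetic generators; identical seed, identical output."""

    seed: int = 0
    # family/variant structure
    family_sizes: tuple[int, ...] = (2, 2, 2, 2, 1, 1, 1)  # sequenced members
    snv_het_range: tuple[int, int] = (26_500, 30_700)  # het SNVs per sample
    indel_range: tuple[int, int] = (25_200, 36_200)  # INDELs per sample
    hom_snv_frac: float = 0.05  # extra hom SNVs on top of the het count
    share_frac: float = 0.31  # within-family background sharing
    frac_in_dbsnp: float = 0.87
    frac_in_control_panel: float = 0.82
    indel_true_frac: float = 0.25  # fraction of INDEL calls with true-like scores
    implant: bool = True  # one causal variant per family
    implant_consequence: str = "nonsynonymous"
    # raw reads
    n_reads: int = 2000
    read_length: int = 78
    n_rate: float = 0.01  # per-position uncalled-base rate
    high_n_frac: float = 0.02  # fraction of reads with a degraded N rate
    high_n_rate: float = 0.20
    poly_frac: float = 0.05  # fraction of mono-base contamination reads
    # case-control cohorts (study-scale carrier counts)
    n_cases: int = 3409
    n_controls: int = 3896
    carriers_cases: int = 10
    carriers_controls: int = 5

    def __post_init__(self) -> None:
        for name in (
            "hom_snv_frac",
            "share_frac",
            "frac_in_dbsnp",
            "frac_in_control_panel",
            "indel_true_frac",
            "n_rate",
            "high_n_frac",
            "high_n_rate",
            "poly_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(s not in (1, 2) for s in self.family_sizes):
            raise ValueError("family sizes must be 1 or 2 sequenced members")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ReadTruth:
    read_id: str
    fails_uncalled: bool
    fails_monobase: bool


def gen_reads(config: SyntheticConfig) -> tuple[list[SequenceRead], list[ReadTruth]]:
    """Simulate raw reads plus a truth table of per-read rule failures.

    Reads are uniform-composition with Bernoulli N placement; a configured
    fraction are mono-base contamination and a further fraction have a
    degraded (high) N rate.  The truth table evaluates both raw-read rules
    directly at generation time and serves as the read-filter oracle.
    """
    rng = np.random.default_rng(config.seed)
    n, length = config.n_reads, config.read_length
    bases = rng.choice(np.array(list("ACGT")), size=(n, length))
    is_poly = rng.random(n) < config.poly_frac
    poly_base = rng.choice(np.array(list("ACGT")), size=n)
    bases[is_poly] = poly_base[is_poly, None]
    n_rates = np.where(
        rng.random(n) < config.high_n_frac, config.high_n_rate, config.n_rate
    )
    n_mask = rng.random((n, length)) < n_rates[:, None]
    bases[n_mask] = "N"
    quals = rng.integers(2, 41, size=(n, length))

    reads, truth = [], []
    for i in range(n):
        seq = "".join(bases[i])
        read = SequenceRead(
            read_id=f"read{i:06d}", bases=seq, quals=tuple(int(q) for q in quals[i])
        )
        n_count = seq.count("N")
        max_frac = max(seq.count(b) for b in "ACGT") / length
        reads.append(read)
        truth.append(
            ReadTruth(
                read_id=read.read_id,
                fails_uncalled=n_count > 5,
                fails_monobase=max_frac > 0.70,
            )
        )
    return reads, truth


# ---------------------------------------------------------------------------
# family cohorts
# ---------------------------------------------------------------------------


def _unique_site_indices(rng: np.random.Generator, k: int) -> np.ndarray:
    """k distinct position codes in [reserved, N_CHROM * POS_SPACE)."""
    lo = _RESERVED_POS_MAX
    hi = _N_CHROM * _POS_SPACE
    out = np.unique(rng.integers(lo, hi, size=int(k * 1.02) + 16))
    while out.size < k:
        more = rng.integers(lo, hi, size=k)
        out = np.unique(np.concatenate([out, more]))
    return rng.permutation(out)[:k]


def _decode_sites(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chrom_idx = codes // _POS_SPACE + 1
    pos = codes % _POS_SPACE + 1
    return chrom_idx, pos


_BASE_ARR = np.array(list("ACGT"))


def _true_evidence(rng: np.random.Generator, k: int):
    depth_ref = rng.integers(8, 26, size=k)
    depth_alt = np.maximum(1, np.rint(depth_ref * rng.uniform(0.5, 1.5, size=k))).astype(int)
    phred_ref = np.round(rng.uniform(100, 400, size=k), 1)
    phred_alt = np.round(phred_ref * rng.uniform(0.5, 1.5, size=k), 1)
    snpq = np.round(rng.uniform(30, 200, size=k), 1)
    return depth_ref, depth_alt, phred_ref, phred_alt, snpq


def _artifact_evidence(rng: np.random.Generator, k: int):
    depth_ref = rng.integers(0, 6, size=k)
    depth_alt = rng.integers(1, 40, size=k)
    phred_ref = np.round(rng.uniform(0, 60, size=k), 1)
    phred_alt = np.round(rng.uniform(0, 400, size=k), 1)
    snpq = np.round(rng.uniform(0, 60, size=k), 1)
    return depth_ref, depth_alt, phred_ref, phred_alt, snpq


def _mixture_evidence(rng: np.random.Generator, true_mask: np.ndarray):
    k = true_mask.size
    t = _true_evidence(rng, k)
    a = _artifact_evidence(rng, k)
    return tuple(np.where(true_mask, ti, ai) for ti, ai in zip(t, a))


@dataclass(slots=True)
class _SitePool:
    """Site-level annotations shared by every copy of a variant key."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    vtype: str
    consequence: np.ndarray
    gene: np.ndarray
    in_dbsnp: np.ndarray
    in_panel: np.ndarray
    true_score: np.ndarray  # evidence class per site


def _make_sites(rng: np.random.Generator, k: int, vtype: str, config: SyntheticConfig) -> _SitePool:
    codes = _unique_site_indices(rng, k)
    chrom_idx, pos = _decode_sites(codes)
    chrom = np.array([f"c{int(c)}" for c in chrom_idx])
    ref_idx = rng.integers(0, 4, size=k)
    ref = _BASE_ARR[ref_idx]
    if vtype == "SNV":
        alt = _BASE_ARR[(ref_idx + rng.integers(1, 4, size=k)) % 4]
        conseq_spec = _SNV_CONSEQUENCES
    else:
        # insertion-style indels: alt = ref base plus 1-3 extra bases
        extra_len = rng.integers(1, 4, size=k)
        extra = rng.integers(0, 4, size=(k, 3))
        alt = np.array(
            [r + "".join(_BASE_ARR[extra[i, : extra_len[i]]]) for i, r in enumerate(ref)]
        )
        conseq_spec = _INDEL_CONSEQUENCES
    labels = np.array([c for c, _ in conseq_spec])
    probs = np.array([p for _, p in conseq_spec])
    consequence = rng.choice(labels, size=k, p=probs / probs.sum())
    gene = np.array([f"G{g:04d}" for g in rng.integers(1, 4000, size=k)])
    gene[consequence == "intergenic"] = ""
    in_dbsnp = rng.random(k) < config.frac_in_dbsnp
    in_panel = rng.random(k) < config.frac_in_control_panel
    if vtype == "SNV":
        true_score = in_dbsnp.copy()
    else:
        true_score = rng.random(k) < config.indel_true_frac
    return _SitePool(chrom, pos, ref, alt, vtype, consequence, gene, in_dbsnp, in_panel, true_score)


def _calls_for_member(
    rng: np.random.Generator, sites: _SitePool, idx: np.ndarray, zygosity: np.ndarray
) -> list[VariantCall]:
    k = idx.size
    dr, da, pr, pa, sq = _mixture_evidence(rng, sites.true_score[idx])
    db_cache: dict[tuple[bool, bool], frozenset[str]] = {
        (False, False): frozenset(),
        (True, False): frozenset({"dbsnp"}),
        (False, True): frozenset({"control_panel"}),
        (True, True): frozenset({"dbsnp", "control_panel"}),
    }
    calls = []
    for j in range(k):
        i = idx[j]
        depth_ref = int(dr[j])
        calls.append(
            VariantCall(
                chrom=str(sites.chrom[i]),
                pos=int(sites.pos[i]),
                ref_allele=str(sites.ref[i]),
                alt_allele=str(sites.alt[i]),
                vtype=sites.vtype,
                zygosity=str(zygosity[j]),
                depth_ref=depth_ref,
                depth_alt=int(da[j]),
                phred_ref=float(pr[j]),
                phred_alt=float(pa[j]),
                snp_quality=float(sq[j]),
                consequence=str(sites.consequence[i]),
                gene=str(sites.gene[i]),
                db_flags=db_cache[(bool(sites.in_dbsnp[i]), bool(sites.in_panel[i]))],
            )
        )
    return calls


def _implant_call(rng: np.random.Generator, fam_index: int, config: SyntheticConfig) -> VariantCall:
    depth_ref = int(rng.integers(10, 20))
    depth_alt = int(max(3, round(depth_ref * rng.uniform(0.7, 1.3))))
    phred_ref = round(float(rng.uniform(150, 300)), 1)
    phred_alt = round(phred_ref * float(rng.uniform(0.7, 1.3)), 1)
    return VariantCall(
        chrom="c13",
        pos=100 + fam_index,  # reserved, below every background position
        ref_allele="C",
        alt_allele="T",
        vtype="SNV",
        zygosity="het",
        depth_ref=depth_ref,
        depth_alt=depth_alt,
        phred_ref=phred_ref,
        phred_alt=phred_alt,
        snp_quality=round(float(rng.uniform(50, 150)), 1),
        consequence=config.implant_consequence,
        gene=CANDIDATE_GENES[fam_index % len(CANDIDATE_GENES)],
        db_flags=frozenset(),
    )


@dataclass(slots=True)
class SimulatedStudy:
    cohorts: list[FamilyCohort]
    control_sites: SiteSet
    known_sites: SiteSet
    implants: dict[str, VariantCall]  # family -> implanted causal variant
    gene_allowlist: frozenset[str]


def gen_family_cohorts(config: SyntheticConfig = SyntheticConfig()) -> SimulatedStudy:
    """Simulate family cohorts, exclusion site sets, and implant truth.

    Per family: a shared background pool (a binomial ``share_frac`` fraction
    of the per-member target count) copied to both sequenced members with
    independent evidence, plus private variants per member; single-member
    families get private variants only.  Database membership is a site
    property, consistent across copies; the pooled control-panel and
    known-variant site sets are the unions of the flagged keys.  When
    ``config.implant`` is set, one causal variant — shared, novel,
    functionally consequential, in an allowlisted gene, with filter-passing
    evidence — is inserted into every sequenced member of each family, and
    recorded in the truth map.
    """
    rng = np.random.default_rng(config.seed)
    cohorts: list[FamilyCohort] = []
    implants: dict[str, VariantCall] = {}
    control_keys: set = set()
    known_keys: set = set()

    for fam_index, size in enumerate(config.family_sizes):
        family_id = f"F{fam_index + 1}"
        member_ids = [f"{family_id}_{chr(ord('A') + i)}" for i in range(size)]
        members = [
            PedigreeMember(
                member_id=mid,
                family_id=family_id,
                affected=True,
                diagnosis_age=float(np.clip(rng.normal(47, 7), 28, 59).round(0)),
                sequenced=True,
                available_for_segregation=True,
            )
            for mid in member_ids
        ]
        # a few additional affected relatives available for segregation only
        for extra in range(int(rng.integers(2, 5))):
            members.append(
                PedigreeMember(
                    member_id=f"{family_id}_R{extra + 1}",
                    family_id=family_id,
                    affected=True,
                    diagnosis_age=float(np.clip(rng.normal(50, 9), 28, 78).round(0)),
                    sequenced=False,
                    available_for_segregation=bool(rng.random() < 0.8),
                )
            )

        variant_sets: dict[str, list[VariantCall]] = {}
        for vtype, count_range in (("SNV", config.snv_het_range), ("INDEL", config.indel_range)):
            targets = rng.integers(count_range[0], count_range[1] + 1, size=size)
            if size == 2:
                n_shared = int(rng.binomial(int(targets.min()), config.share_frac))
            else:
                n_shared = 0
            n_private = targets - n_shared
            n_hom = (
                np.rint(targets * config.hom_snv_frac).astype(int)
                if vtype == "SNV"
                else np.zeros(size, dtype=int)
            )
            total_sites = n_shared + int(n_private.sum()) + int(n_hom.sum())
            sites = _make_sites(rng, total_sites, vtype, config)
            control_keys.update(
                (str(sites.chrom[i]), int(sites.pos[i]), str(sites.ref[i]), str(sites.alt[i]))
                for i in np.flatnonzero(sites.in_panel)
            )
            known_keys.update(
                (str(sites.chrom[i]), int(sites.pos[i]), str(sites.ref[i]), str(sites.alt[i]))
                for i in np.flatnonzero(sites.in_dbsnp)
            )
            cursor = n_shared
            shared_idx = np.arange(0, n_shared)
            for m_i, mid in enumerate(member_ids):
                priv_idx = np.arange(cursor, cursor + int(n_private[m_i]))
                cursor += int(n_private[m_i])
                hom_idx = np.arange(cursor, cursor + int(n_hom[m_i]))
                cursor += int(n_hom[m_i])
                idx = np.concatenate([shared_idx, priv_idx, hom_idx])
                zyg = np.array(
                    ["het"] * (shared_idx.size + priv_idx.size) + ["hom"] * hom_idx.size
                )
                variant_sets.setdefault(mid, []).extend(
                    _calls_for_member(rng, sites, idx, zyg)
                )

        if config.implant:
            implant = _implant_call(rng, fam_index, config)
            implants[family_id] = implant
            for mid in member_ids:
                variant_sets[mid].append(_implant_call(rng, fam_index, config))

        cohorts.append(
            FamilyCohort(family_id=family_id, members=members, variant_sets=variant_sets)
        )

    return SimulatedStudy(
        cohorts=cohorts,
        control_sites=SiteSet("control_panel", control_keys),
        known_sites=SiteSet("dbsnp", known_keys),
        implants=implants,
        gene_allowlist=frozenset(CANDIDATE_GENES),
    )


def gen_score_panel(
    config: SyntheticConfig, n_snv: int = 8000, n_indel: int = 4000
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Control-panel-style call sets with known-membership flags, for calibration."""
    rng = np.random.default_rng(config.seed + 7_654_321)
    out = []
    for vtype, n in (("SNV", n_snv), ("INDEL", n_indel)):
        sites = _make_sites(rng, n, vtype, config)
        idx = np.arange(n)
        zyg = np.array(["het"] * n)
        out.append(_calls_for_member(rng, sites, idx, zyg))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# case-control cohorts
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class CaseControlSim:
    genotypes_cases: np.ndarray  # 0/1 carrier indicator per case
    genotypes_controls: np.ndarray
    table: ContingencyTable


def gen_case_control(config: SyntheticConfig = SyntheticConfig()) -> CaseControlSim:
    """Place exactly the configured carrier counts among case/control arms."""
    rng = np.random.default_rng(config.seed + 11)
    if config.carriers_cases > config.n_cases or config.carriers_controls > config.n_controls:
        raise ValueError("carrier count exceeds arm size")
    cases = np.zeros(config.n_cases, dtype=np.int8)
    cases[rng.choice(config.n_cases, size=config.carriers_cases, replace=False)] = 1
    controls = np.zeros(config.n_controls, dtype=np.int8)
    controls[rng.choice(config.n_controls, size=config.carriers_controls, replace=False)] = 1
    table = allele_table(
        int(cases.sum()), config.n_cases, int(controls.sum()), config.n_controls
    )
    return CaseControlSim(genotypes_cases=cases, genotypes_controls=controls, table=table)


# ---------------------------------------------------------------------------
# writing a simulated study to disk
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, outdir: str | Path, reads=None) -> None:
    """Write a simulated study as text files (pedigree, VCFs, site sets, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(study.cohorts, outdir / "pedigree.tsv")
    for cohort in study.cohorts:
        for member_id, calls in sorted(cohort.variant_sets.items()):
            write_variant_table(calls, outdir / f"{member_id}.vcf", sample_id=member_id)
    write_site_set(study.control_sites, outdir / "control_panel.tsv")
    write_site_set(study.known_sites, outdir / "dbsnp.tsv")
    truth = {
        "implants": {fam: list(v.key) for fam, v in sorted(study.implants.items())},
        "gene_allowlist": sorted(study.gene_allowlist),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    if reads is not None:
        write_fastq(reads, outdir / "reads.fastq")
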