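"""Domain types and file I/O for family-based exome variant prioritization.

The central objects are :class:`VariantCall` (one called variant in one
sample, carrying the per-allele read-depth and Phred-scaled quality evidence
the allele-balance scores are computed from), :class:`FamilyCohort` (a
pedigree together with the variant sets of its sequenced members) and
:class:`SiteSet` (an allele-aware exclusion list such as a known-variant
database or a control-panel call set).

Variants are identified for all filtering purposes by the key
``(chrom, pos, ref_allele, alt_allele)`` with 1-based, fully closed
coordinates as in VCF.  Chromosome labels are opaque strings, so the code is
reference-assembly agnostic.  Indel calls are compared as given, without
left-normalization; callers feeding data from different normalizers should
harmonize representations upstream.

On-disk formats:

* variant tables: a VCF 4.x subset (read and written through pysam) with
  per-allele depths in an AD-style FORMAT field and per-allele Phred quality
  mass in a second FORMAT field, or a flat tab-separated table;
* pedigrees: a FAM-like TSV extended with diagnosis age and availability;
* site sets: a 4-column TSV of (chrom, pos, ref, alt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "Key",
    "SequenceRead",
    "VariantCall",
    "ScorePair",
    "PedigreeMember",
    "FamilyCohort",
    "SiteSet",
    "VcfDialect",
    "load_variant_table",
    "write_variant_table",
    "load_pedigree",
    "write_pedigree",
    "attach_variant_sets",
    "load_site_set",
    "write_site_set",
]

#: identity key of a variant for all sharing/exclusion comparisons
Key = tuple[str, int, str, str]

_BASES = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class SequenceRead:
    """A single sequencing read (mates of a pair are independent reads)."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise ValueError(f"read {self.read_id!r} is empty")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: negative Phred quality")
        if not _BASES.issuperset(self.bases):
            bad = sorted(set(self.bases) - _BASES)
            raise ValueError(f"read {self.read_id!r}: invalid bases {bad}")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(slots=True)
class VariantCall:
    """One called variant in one sample, with its supporting evidence.

    ``depth_ref``/``depth_alt`` are read counts supporting each allele;
    ``phred_ref``/``phred_alt`` are Phred-scaled quality masses per allele;
    ``snp_quality`` is the caller's site quality.  Any evidence field may be
    ``None`` when the caller did not emit it, in which case downstream
    allele-balance scores are undefined rather than zero.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # "SNV" | "INDEL"
    zygosity: str  # "het" | "hom"
    depth_ref: int | None = None
    depth_alt: int | None = None
    phred_ref: float | None = None
    phred_alt: float | None = None
    snp_quality: float | None = None
    consequence: str = ""
    gene: str = ""
    db_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vtype not in ("SNV", "INDEL"):
            raise ValueError(f"invalid vtype {self.vtype!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.vtype == "SNV" and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise ValueError(
                f"SNV at {self.chrom}:{self.pos} must have single-base alleles, "
                f"got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        for name in ("depth_ref", "depth_alt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        self.db_flags = frozenset(self.db_flags)

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True, slots=True)
class ScorePair:
    """Depth Score and Quality Score of a call; ``None`` means undefined."""

    ds: float | None
    qs: float | None

    def __post_init__(self) -> None:
        if self.ds is not None and self.ds < 0:
            raise ValueError("DS must be >= 0 when defined")
        if self.qs is not None and self.qs < 0:
            raise ValueError("QS must be >= 0 when defined")


@dataclass(slots=True)
class PedigreeMember:
    member_id: str
    family_id: str
    affected: bool
    diagnosis_age: float | None = None
    sequenced: bool = False
    available_for_segregation: bool = False
    carrier_status: str = "unknown"  # "carrier" | "non-carrier" | "unknown"

    def __post_init__(self) -> None:
        if self.diagnosis_age is not None and not self.affected:
            raise ValueError(
                f"member {self.member_id!r} has a diagnosis age but is unaffected"
            )
        if self.carrier_status not in ("carrier", "non-carrier", "unknown"):
            raise ValueError(f"invalid carrier_status {self.carrier_status!r}")


@dataclass(slots=True)
class FamilyCohort:
    """A family's pedigree plus the variant sets of its sequenced members."""

    family_id: str
    members: list[PedigreeMember]
    variant_sets: dict[str, list[VariantCall]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = set(self.sequenced_ids)
        extra = set(self.variant_sets) - seq
        if extra:
            raise ValueError(
                f"family {self.family_id}: variant sets for non-sequenced "
                f"members {sorted(extra)}"
            )

    @property
    def sequenced_ids(self) -> list[str]:
        return [m.member_id for m in self.members if m.sequenced]


@dataclass(slots=True)
class SiteSet:
    """An allele-aware set of variant keys used as an exclusion list."""

    label: str
    keys: set[Key] = field(default_factory=set)

    @classmethod
    def from_variants(cls, label: str, variants: Iterable[VariantCall]) -> "SiteSet":
        return cls(label, {v.key for v in variants})

    def __contains__(self, key: Key) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VcfDialect:
    """Names of the FORMAT/INFO fields the VCF subset carries evidence in."""

    depth_field: str = "AD"  # per-allele read depths, Number=R Integer
    quality_field: str = "AQ"  # per-allele Phred quality mass, Number=R Float
    consequence_info: str = "CSQ"
    gene_info: str = "GENE"
    db_info: str = "DBM"


_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "vtype",
    "zygosity",
    "depth_ref",
    "depth_alt",
    "phred_ref",
    "phred_alt",
    "snp_quality",
    "consequence",
    "gene",
    "db_flags",
]


def load_variant_table(
    path: str | Path, dialect: VcfDialect = VcfDialect()
) -> list[VariantCall]:
    """Load a variant table from a VCF-subset or flat-TSV file.

    Multi-allelic VCF records are split into one call per alternate allele.
    Per-record missing depth/quality values yield ``None`` evidence fields
    (scores downstream become undefined, not zero); a file whose header does
    not declare the dialect's evidence fields raises a field error.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return _load_vcf(path, dialect)
    return _load_tsv(path)


def _infer_vtype(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


def _scalar_info(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def _load_vcf(path: Path, dialect: VcfDialect) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for name in (dialect.depth_field, dialect.quality_field):
            if name not in vcf.header.formats:
                raise ValueError(
                    f"{path}: FORMAT field {name!r} not declared in header; "
                    "per-allele evidence is required by the dialect"
                )
        for i, rec in enumerate(vcf, 1):
            try:
                calls.extend(_calls_from_record(rec, dialect))
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"{path}: malformed record #{i}: {exc}") from exc
    return calls


def _info_get(rec, key):
    # pysam raises on keys absent from the header; treat those as unset
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _calls_from_record(rec, dialect: VcfDialect) -> list[VariantCall]:
    if not rec.alts:
        return []
    consequence = _scalar_info(_info_get(rec, dialect.consequence_info))
    gene = _scalar_info(_info_get(rec, dialect.gene_info))
    db_raw = _info_get(rec, dialect.db_info)
    if db_raw is None:
        db_flags: frozenset[str] = frozenset()
    elif isinstance(db_raw, (tuple, list)):
        db_flags = frozenset(db_raw)
    else:
        db_flags = frozenset(str(db_raw).split(","))
    out = []
    sample = rec.samples[0] if rec.samples else None
    ad = sample.get(dialect.depth_field) if sample is not None else None
    aq = sample.get(dialect.quality_field) if sample is not None else None
    gt = sample.get("GT") if sample is not None else None
    for alt_index, alt in enumerate(rec.alts, start=1):
        depth_ref = depth_alt = None
        if ad is not None and ad[0] is not None:
            depth_ref = int(ad[0])
        if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
            depth_alt = int(ad[alt_index])
        # per-allele qualities travel as float32 in htslib; the dialect
        # carries them at <=3 decimals, so round away the widening noise
        phred_ref = phred_alt = None
        if aq is not None and aq[0] is not None:
            phred_ref = round(float(aq[0]), 3)
        if aq is not None and len(aq) > alt_index and aq[alt_index] is not None:
            phred_alt = round(float(aq[alt_index]), 3)
        if gt is not None and tuple(gt) == (alt_index, alt_index):
            zygosity = "hom"
        else:
            zygosity = "het"
        out.append(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alt,
                vtype=_infer_vtype(rec.ref, alt),
                zygosity=zygosity,
                depth_ref=depth_ref,
                depth_alt=depth_alt,
                phred_ref=phred_ref,
                phred_alt=phred_alt,
                snp_quality=None if rec.qual is None else round(float(rec.qual), 3),
                consequence=consequence,
                gene=gene,
                db_flags=db_flags,
            )
        )
    return out


def write_variant_table(
    calls: Sequence[VariantCall],
    path: str | Path,
    sample_id: str = "SAMPLE",
    dialect: VcfDialect = VcfDialect(),
) -> None:
    """Write calls to a single-sample VCF subset or a flat TSV (by suffix)."""
    path = Path(path)
    if path.suffix == ".vcf":
        _write_vcf(calls, path, sample_id, dialect)
    else:
        _write_tsv(calls, path)


def _write_vcf(
    calls: Sequence[VariantCall], path: Path, sample_id: str, dialect: VcfDialect
) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.formats.add(
        dialect.depth_field, "R", "Integer", "Read depth per allele (ref, alt)"
    )
    header.formats.add(
        dialect.quality_field, "R", "Float", "Phred-scaled quality mass per allele"
    )
    header.info.add(dialect.consequence_info, 1, "String", "Functional consequence")
    header.info.add(dialect.gene_info, 1, "String", "Gene symbol")
    header.info.add(dialect.db_info, ".", "String", "Database membership flags")
    for chrom in dict.fromkeys(c.chrom for c in calls):
        header.contigs.add(chrom)
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref_allele, call.alt_allele),
                qual=call.snp_quality,
            )
            if call.consequence:
                rec.info[dialect.consequence_info] = call.consequence
            if call.gene:
                rec.info[dialect.gene_info] = call.gene
            if call.db_flags:
                rec.info[dialect.db_info] = tuple(sorted(call.db_flags))
            smp = rec.samples[sample_id]
            smp["GT"] = (1, 1) if call.zygosity == "hom" else (0, 1)
            if call.depth_ref is not None and call.depth_alt is not None:
                smp[dialect.depth_field] = (call.depth_ref, call.depth_alt)
            if call.phred_ref is not None and call.phred_alt is not None:
                smp[dialect.quality_field] = (call.phred_ref, call.phred_alt)
            vcf.write(rec)


def _load_tsv(path: Path) -> list[VariantCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref_allele),
                alt_allele=str(row.alt_allele),
                vtype=str(row.vtype),
                zygosity=str(row.zygosity),
                depth_ref=None if pd.isna(row.depth_ref) else int(row.depth_ref),
                depth_alt=None if pd.isna(row.depth_alt) else int(row.depth_alt),
                phred_ref=None if pd.isna(row.phred_ref) else float(row.phred_ref),
                phred_alt=None if pd.isna(row.phred_alt) else float(row.phred_alt),
                snp_quality=None if pd.isna(row.snp_quality) else float(row.snp_quality),
                consequence="" if pd.isna(row.consequence) else str(row.consequence),
                gene="" if pd.isna(row.gene) else str(row.gene),
                db_flags=frozenset()
                if pd.isna(row.db_flags) or row.db_flags == ""
                else frozenset(str(row.db_flags).split(",")),
            )
        )
    return calls


def _write_tsv(calls: Sequence[VariantCall], path: Path) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref_allele": c.ref_allele,
            "alt_allele": c.alt_allele,
            "vtype": c.vtype,
            "zygosity": c.zygosity,
            "depth_ref": c.depth_ref,
            "depth_alt": c.depth_alt,
            "phred_ref": c.phred_ref,
            "phred_alt": c.phred_alt,
            "snp_quality": c.snp_quality,
            "consequence": c.consequence,
            "gene": c.gene,
            "db_flags": ",".join(sorted(c.db_flags)),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


def load_pedigree(path: str | Path) -> list[FamilyCohort]:
    """Load a FAM-like pedigree TSV into per-family cohorts.

    Columns: family_id, member_id, affected (0/1), diagnosis_age (may be
    empty), sequenced (0/1), available (0/1).  A member listed twice (in the
    same or different families) is an integrity error; a family with more
    than two sequenced members is accepted with a warning; a family with no
    sequenced member is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "member_id": str})
    required = ["family_id", "member_id", "affected", "diagnosis_age", "sequenced", "available"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {missing}")
    dup = df["member_id"][df["member_id"].duplicated()]
    if not dup.empty:
        families = df.loc[df["member_id"].isin(dup), ["member_id", "family_id"]]
        if families.groupby("member_id")["family_id"].nunique().max() > 1:
            raise ValueError(f"{path}: member(s) {sorted(set(dup))} listed in two families")
        raise ValueError(f"{path}: duplicate member id(s) {sorted(set(dup))} within a family")
    cohorts = []
    for family_id, group in df.groupby("family_id", sort=True):
        members = [
            PedigreeMember(
                member_id=row.member_id,
                family_id=family_id,
                affected=bool(int(row.affected)),
                diagnosis_age=None if pd.isna(row.diagnosis_age) else float(row.diagnosis_age),
                sequenced=bool(int(row.sequenced)),
                available_for_segregation=bool(int(row.available)),
            )
            for row in group.itertuples(index=False)
        ]
        n_seq = sum(m.sequenced for m in members)
        if n_seq == 0:
            raise ValueError(f"{path}: family {family_id} has no sequenced member")
        if n_seq > 2:
            warnings.warn(
                f"family {family_id} has {n_seq} sequenced members; the study design "
                "assumes at most 2",
                stacklevel=2,
            )
        cohorts.append(FamilyCohort(family_id=family_id, members=members))
    return cohorts


def write_pedigree(cohorts: Iterable[FamilyCohort], path: str | Path) -> None:
    rows = [
        {
            "family_id": m.family_id,
            "member_id": m.member_id,
            "affected": int(m.affected),
            "diagnosis_age": m.diagnosis_age,
            "sequenced": int(m.sequenced),
            "available": int(m.available_for_segregation),
        }
        for cohort in cohorts
        for m in cohort.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_variant_sets(
    cohorts: Iterable[FamilyCohort], tables: Mapping[str, list[VariantCall]]
) -> None:
    """Attach per-member variant lists (keyed by member id) to their cohorts."""
    for cohort in cohorts:
        for member_id in cohort.sequenced_ids:
            if member_id in tables:
                cohort.variant_sets[member_id] = tables[member_id]


# ---------------------------------------------------------------------------
# site sets
# ---------------------------------------------------------------------------


def load_site_set(path: str | Path, label: str) -> SiteSet:
    """Load a 4-column (chrom, pos, ref, alt) TSV into a deduplicated SiteSet."""
    keys: set[Key] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, pos_s, ref, alt = parts
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad position {pos_s!r}") from exc
            keys.add((chrom, pos, ref, alt))
    return SiteSet(label=label, keys=keys)


def write_site_set(sites: SiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in sorted(sites.keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
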