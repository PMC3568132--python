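"""Pre-alignment raw-read filters.

Two per-read rules, applied before any alignment, remove common sequencing
artifacts: reads with uncalled bases (N) at more than ``max_uncalled``
positions, and low-complexity reads in which one nucleotide accounts for more
than ``max_mono_fraction`` of the total read length.  Both thresholds are
read strictly ("more than"), so a read sitting exactly on a boundary is kept.
N never counts toward the mono-base numerator but stays in the denominator.

Mates of a read pair are filtered independently; there is no mate rescue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import SequenceRead

__all__ = [
    "DEFAULT_MAX_UNCALLED",
    "DEFAULT_MAX_MONO_FRACTION",
    "ReadFilterStats",
    "ReadFilterResult",
    "count_uncalled",
    "max_base_fraction",
    "filter_reads",
    "read_fastq",
    "write_fastq",
]

DEFAULT_MAX_UNCALLED = 5
DEFAULT_MAX_MONO_FRACTION = 0.70


def count_uncalled(read: SequenceRead) -> int:
    """Number of positions with no base call (N)."""
    return read.bases.count("N")


def max_base_fraction(read: SequenceRead) -> float:
    """Largest fraction of the read length taken by any one of A/C/G/T.

    N is excluded from the numerator but included in the denominator, so an
    all-N read scores 0.
    """
    return max(read.bases.count(b) for b in "ACGT") / read.length


@dataclass(slots=True)
class ReadFilterStats:
    total: int
    removed_uncalled: int  # failed the N-count rule
    removed_monobase: int  # failed the mono-base-fraction rule
    removed_total: int  # failed at least one rule


@dataclass(slots=True)
class ReadFilterResult:
    kept: list[SequenceRead]
    removed: list[SequenceRead]
    stats: ReadFilterStats


def filter_reads(
    reads: Iterable[SequenceRead],
    max_uncalled: int = DEFAULT_MAX_UNCALLED,
    max_mono_fraction: float = DEFAULT_MAX_MONO_FRACTION,
) -> ReadFilterResult:
    """Partition reads into kept/removed under the two raw-read rules.

    A read is removed iff ``count_uncalled > max_uncalled`` or
    ``max_base_fraction > max_mono_fraction``.  A read failing both rules
    counts once toward each per-rule tally and once toward the total.
    Input order is preserved in both output lists.
    """
    kept: list[SequenceRead] = []
    removed: list[SequenceRead] = []
    n_uncalled = n_mono = 0
    for read in reads:
        fail_n = count_uncalled(read) > max_uncalled
        fail_mono = max_base_fraction(read) > max_mono_fraction
        n_uncalled += fail_n
        n_mono += fail_mono
        (removed if fail_n or fail_mono else kept).append(read)
    stats = ReadFilterStats(
        total=len(kept) + len(removed),
        removed_uncalled=n_uncalled,
        removed_monobase=n_mono,
        removed_total=len(removed),
    )
    return ReadFilterResult(kept=kept, removed=removed, stats=stats)


def read_fastq(path: str | Path) -> list[SequenceRead]:
    return [
        SequenceRead(
            read_id=rec.id,
            bases=str(rec.seq).upper(),
            quals=tuple(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Sequence[SequenceRead], path: str | Path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
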