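"""Score-threshold calibration against known-site truth.

The score filters need thresholds.  They are tuned on a control panel of
unrelated reference individuals: calls already present in the known-variant
database are treated as (mostly) true positives, and a grid of candidate
threshold combinations is evaluated for two metrics — the fraction of known
calls retained (``known_retention``) and the total number of calls retained
(``total_retained``).  The chosen combination retains at least the target
fraction of known calls (default 95%) while letting through as few calls
overall as possible, i.e. it trades specificity for a guaranteed floor on
sensitivity.

For SNVs the grid ranges over inclusive (low, high) windows applied to both
DS and QS; for INDELs it ranges over the strict DS ceiling, with the other
stringent INDEL criteria (allele qualities, site quality, minimum read
support) held fixed.  Known calls with an undefined score count as lost —
an undefined score cannot certify any window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cascade import CascadeConfig
from .model import VariantCall

__all__ = ["GridSpec", "CalibrationResult", "calibrate_thresholds"]


@dataclass(frozen=True)
class GridSpec:
    """Threshold grid: (low, high) windows for SNVs, DS ceilings for INDELs."""

    lows: tuple[float, ...] = tuple(range(0, 51, 5))
    highs: tuple[float, ...] = tuple(range(100, 301, 10))
    ds_maxes: tuple[float, ...] = tuple(range(50, 301, 10))

    def __post_init__(self) -> None:
        if not (self.lows and self.highs and self.ds_maxes):
            raise ValueError("grid ranges must be non-empty")


@dataclass(slots=True)
class CalibrationResult:
    vtype: str
    chosen: dict[str, float]
    known_retention: float
    total_retained: int
    grid: list[dict[str, float]]  # thresholds plus both metrics per grid point
    meets_target: bool


def _score_arrays(variants: Sequence[VariantCall]):
    n = len(variants)
    ds = np.full(n, np.nan)
    qs = np.full(n, np.nan)
    phred_alt = np.full(n, np.nan)
    snpq = np.full(n, np.nan)
    depth_ref = np.full(n, -1, dtype=int)
    depth_alt = np.full(n, -1, dtype=int)
    known = np.zeros(n, dtype=bool)
    for i, v in enumerate(variants):
        if v.depth_ref not in (None, 0) and v.depth_alt is not None:
            ds[i] = 100.0 * v.depth_alt / v.depth_ref
        if v.phred_ref not in (None, 0) and v.phred_alt is not None:
            qs[i] = 100.0 * v.phred_alt / v.phred_ref
        if v.phred_alt is not None:
            phred_alt[i] = v.phred_alt
        if v.snp_quality is not None:
            snpq[i] = v.snp_quality
        if v.depth_ref is not None:
            depth_ref[i] = v.depth_ref
        if v.depth_alt is not None:
            depth_alt[i] = v.depth_alt
    return ds, qs, phred_alt, snpq, depth_ref, depth_alt, known


def calibrate_thresholds(
    variants: Sequence[VariantCall],
    vtype: str,
    target_retention: float = 0.95,
    grid_spec: GridSpec = GridSpec(),
    known_flag: str = "dbsnp",
    config: CascadeConfig = CascadeConfig(),
) -> CalibrationResult:
    """Exhaustively evaluate the threshold grid and pick the best point.

    Among grid points with ``known_retention >= target_retention`` the one
    with the smallest ``total_retained`` wins; ties break toward higher
    retention, then toward the lexicographically smallest thresholds.  If no
    point meets the target, the maximum-retention point is returned with
    ``meets_target=False``.
    """
    if not variants:
        raise ValueError("cannot calibrate on an empty variant list")
    if vtype not in ("SNV", "INDEL"):
        raise ValueError(f"invalid vtype {vtype!r}")
    ds, qs, phred_alt, snpq, depth_ref, depth_alt, known = _score_arrays(variants)
    for i, v in enumerate(variants):
        known[i] = known_flag in v.db_flags
    n_known = int(known.sum())
    if n_known == 0:
        raise ValueError(f"no variant carries the known flag {known_flag!r}")

    grid: list[dict[str, float]] = []
    if vtype == "SNV":
        defined = ~np.isnan(ds) & ~np.isnan(qs)
        for low in grid_spec.lows:
            for high in grid_spec.highs:
                if high < low:
                    continue
                retained = defined & (ds >= low) & (ds <= high) & (qs >= low) & (qs <= high)
                grid.append(
                    {
                        "low": float(low),
                        "high": float(high),
                        "known_retention": float(retained[known].sum() / n_known),
                        "total_retained": int(retained.sum()),
                    }
                )
        threshold_keys = ("low", "high")
    else:
        base = (
            ~np.isnan(ds)
            & ~np.isnan(phred_alt)
            & (phred_alt > config.indel_phred_min)
            & ~np.isnan(snpq)
            & (snpq > config.indel_snpq_min)
            & (depth_ref >= config.indel_min_reads_each)
            & (depth_alt >= config.indel_min_reads_each)
        )
        for ds_max in grid_spec.ds_maxes:
            retained = base & (ds < ds_max)
            grid.append(
                {
                    "ds_max": float(ds_max),
                    "known_retention": float(retained[known].sum() / n_known),
                    "total_retained": int(retained.sum()),
                }
            )
        threshold_keys = ("ds_max",)

    feasible = [g for g in grid if g["known_retention"] >= target_retention]
    pool = feasible if feasible else grid
    if feasible:
        best = min(
            pool,
            key=lambda g: (
                g["total_retained"],
                -g["known_retention"],
                tuple(g[k] for k in threshold_keys),
            ),
        )
    else:
        best = max(
            pool,
            key=lambda g: (
                g["known_retention"],
                -g["total_retained"],
                tuple(-g[k] for k in threshold_keys),
            ),
        )
    return CalibrationResult(
        vtype=vtype,
        chosen={k: best[k] for k in threshold_keys},
        known_retention=best["known_retention"],
        total_retained=best["total_retained"],
        grid=grid,
        meets_target=bool(feasible),
    )
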