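"""Somatic-call filtering with per-filter attrition reporting.

Three rules are applied to each call, mirroring common practice for paired
tumor/normal exomes: a minimum read depth in the matched normal, a minimum
ratio of tumor to normal variant allele fraction (to remove germline
leakage), and a population minor-allele-frequency ceiling (to remove common
polymorphisms).  An optional target-region restriction (BED semantics,
0-based half-open) runs first.

Boundary behavior is deliberate: a call at exactly the MAF ceiling is kept
(only strictly greater is removed) and a call at exactly the VAF-ratio
threshold is kept (only strictly smaller is removed).  A call with zero
normal-alt support and any tumor-alt support passes the ratio rule — zero
normal support is the cleanest somatic evidence.

Attrition is attributed to the *first failing* filter in the fixed order
target → depth → ratio → MAF (a zero-tumor-depth record is its own
category), so the report's counts are reproducible.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_model import MutationCall, normalize_chrom

logger = logging.getLogger("clonkit")

__all__ = ["FilterConfig", "FilterReport", "TargetRegions", "apply_filters", "read_bed"]

#: Attribution order; each removed record counts against exactly one category.
FILTER_ORDER = ("target", "zero_tumor_depth", "normal_depth", "vaf_ratio", "pop_maf")


class TargetRegions:
    """Interval set with BED semantics (0-based, half-open) for membership tests."""

    def __init__(self, intervals: Sequence[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end < start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    def contains(self, chrom: str, pos1: int) -> bool:
        """Test a 1-based position against the 0-based half-open intervals."""
        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return False
        pos0 = pos1 - 1
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]


def read_bed(path: str | Path) -> TargetRegions:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return TargetRegions(intervals)


@dataclass
class FilterConfig:
    """Thresholds for the three call filters plus the optional target set."""

    min_normal_depth: int = 20
    vaf_ratio_min: float = 5.0
    max_pop_maf: float = 0.05
    target_regions: TargetRegions | None = None

    def __post_init__(self) -> None:
        if self.min_normal_depth < 0 or self.vaf_ratio_min < 0 or self.max_pop_maf < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    """Attrition accounting: input = retained + Σ removed (first-failing rule)."""

    total_input: int = 0
    total_retained: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in FILTER_ORDER}
    )

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("input", self.total_input)]
        rows += [(f"removed_{k}", self.removed[k]) for k in FILTER_ORDER]
        rows.append(("retained", self.total_retained))
        return rows

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["category", "count"])
            w.writerows(self.as_rows())


def _failing_filter(call: MutationCall, cfg: FilterConfig) -> str | None:
    """Name of the first failing filter, or None if the call is retained."""
    if cfg.target_regions is not None and not cfg.target_regions.contains(
        call.chrom, call.pos
    ):
        return "target"
    if call.tumor_depth == 0:
        return "zero_tumor_depth"
    if call.normal_depth < cfg.min_normal_depth:
        return "normal_depth"
    t_vaf = call.tumor_vaf
    n_vaf = call.normal_vaf if call.normal_depth > 0 else 0.0
    if t_vaf < cfg.vaf_ratio_min * n_vaf:  # n_vaf == 0 can never fail this
        return "vaf_ratio"
    if call.pop_maf is not None and call.pop_maf > cfg.max_pop_maf:
        return "pop_maf"
    return None


def apply_filters(
    calls: Sequence[MutationCall], cfg: FilterConfig | None = None
) -> tuple[list[MutationCall], FilterReport]:
    """Apply the call filters and account for every removal.

    Returns the retained calls (input order preserved) and a
    :class:`FilterReport` whose removal counts are attributed to the first
    failing rule in the order target → depth → VAF ratio → population MAF.
    Applying the filters to their own output removes nothing (idempotence).
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(total_input=len(calls))
    retained: list[MutationCall] = []
    for call in calls:
        reason = _failing_filter(call, cfg)
        if reason is None:
            retained.append(call)
        else:
            report.removed[reason] += 1
    report.total_retained = len(retained)
    logger.info(
        "filters: %d in, %d retained (%s)",
        report.total_input,
        report.total_retained,
        ", ".join(f"{k}={v}" for k, v in report.removed.items() if v),
    )
    return retained, report
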