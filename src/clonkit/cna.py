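"""Arm-level copy-number summaries from segmented log2 ratios.

Per chromosome arm, segment log2 ratios are averaged weighted by the length
of each segment's intersection with the arm (half-open interval arithmetic),
and the arm is called gained or lost when the weighted mean crosses a
threshold.  The defaults of +/-0.2 are common practice for segment-mean
calls; they are configurable because visual genome plots carry no explicit
cutoff.  Arms covered by segments over less than ``min_covered`` of their
length are called neutral and flagged low-coverage.

Fraction of genome altered (FGA) quantifies overall copy-number burden: the
length-weighted fraction of the segment-covered genome whose log2 ratio lies
beyond the gain/loss thresholds.  The concurrent 1q-gain/16q-loss pair — the
hallmark of ER-positive breast cancer — is exposed as a dedicated check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io_model import CopySegment, chrom_sort_key, normalize_chrom

__all__ = [
    "ArmCall",
    "ArmTable",
    "arm_calls",
    "fraction_genome_altered",
    "has_1q_gain_16q_loss",
    "read_arm_table",
    "write_arm_calls",
    "plot_genome",
]


@dataclass
class ArmTable:
    """Chromosome-arm boundaries (1-based inclusive) for a stated genome build."""

    arms: dict[str, tuple[str, int, int]]  # arm -> (chrom, start, end)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for arm, (chrom, start, end) in self.arms.items():
            if start > end:
                raise ValueError(f"arm {arm}: start > end")
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end, arm))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, a1), (s2, e2, a2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"arms {a1} and {a2} overlap on chrom {chrom}")

    def sorted_arms(self) -> list[str]:
        return sorted(
            self.arms, key=lambda a: (chrom_sort_key(self.arms[a][0]), self.arms[a][1])
        )


@dataclass
class ArmCall:
    """Weighted-mean log2 ratio and gain/loss/neutral call for one arm."""

    sample_id: str
    arm: str
    mean_log2: float
    call: str  # gain | loss | neutral
    covered_fraction: float
    low_coverage: bool = False


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    """Overlap length of two half-open intervals."""
    return max(0, min(a1, b1) - max(a0, b0))


def arm_calls(
    segments: Sequence[CopySegment],
    arms: ArmTable,
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
    min_covered: float = 0.5,
) -> list[ArmCall]:
    """Gain/loss/neutral call per (sample, arm) from segment-arm intersections.

    ``mean_log2`` is the intersection-length-weighted mean of segment log2
    ratios over the arm; gain when >= ``gain_threshold``, loss when
    <= ``loss_threshold``.  Under-covered arms are neutral and flagged.
    An empty segment list yields all-neutral, flagged calls.
    """
    samples = sorted({s.sample_id for s in segments}) or [""]
    out: list[ArmCall] = []
    for sample in samples:
        segs = [s for s in segments if s.sample_id == sample]
        for arm in arms.sorted_arms():
            chrom, a_start, a_end = arms.arms[arm]
            chrom = normalize_chrom(chrom)
            a0, a1 = a_start - 1, a_end  # half-open
            arm_len = a1 - a0
            wsum = 0.0
            lsum = 0
            for s in segs:
                if s.chrom != chrom:
                    continue
                s0, s1 = s.half_open()
                ov = _overlap(a0, a1, s0, s1)
                if ov:
                    wsum += ov * s.log2_ratio
                    lsum += ov
            covered = lsum / arm_len
            if lsum == 0 or covered < min_covered:
                out.append(
                    ArmCall(sample, arm, wsum / lsum if lsum else 0.0, "neutral", covered, True)
                )
                continue
            mean = wsum / lsum
            if mean >= gain_threshold:
                call = "gain"
            elif mean <= loss_threshold:
                call = "loss"
            else:
                call = "neutral"
            out.append(ArmCall(sample, arm, mean, call, covered))
    return out


def fraction_genome_altered(
    segments: Sequence[CopySegment],
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
) -> float:
    """Length-weighted fraction of covered genome with |log2| beyond thresholds."""
    total = 0
    altered = 0
    for s in segments:
        total += s.length
        if s.log2_ratio >= gain_threshold or s.log2_ratio <= loss_threshold:
            altered += s.length
    return altered / total if total else 0.0


def has_1q_gain_16q_loss(calls: Sequence[ArmCall], sample_id: str) -> bool:
    """Concurrent 1q gain and 16q loss in one sample's arm calls."""
    mine = {c.arm: c.call for c in calls if c.sample_id == sample_id}
    return mine.get("1q") == "gain" and mine.get("16q") == "loss"


def read_arm_table(path: str | Path) -> ArmTable:
    """Read an arm-boundary TSV (arm, chrom, start, end)."""
    arms: dict[str, tuple[str, int, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ("arm", "chrom", "start", "end"):
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise ValueError(f"arm table {path} missing column {col!r}")
        for row in reader:
            arms[row["arm"]] = (row["chrom"], int(row["start"]), int(row["end"]))
    return ArmTable(arms)


def write_arm_calls(calls: Sequence[ArmCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_id", "arm", "mean_log2", "call", "covered_fraction", "low_coverage"]
        )
        for c in calls:
            w.writerow(
                [
                    c.sample_id,
                    c.arm,
                    f"{c.mean_log2:.4f}",
                    c.call,
                    f"{c.covered_fraction:.4f}",
                    "true" if c.low_coverage else "false",
                ]
            )


def plot_genome(
    segments: Sequence[CopySegment],
    arms: ArmTable,
    sample_id: str,
    path: str | Path,
) -> None:
    """Render a simple genome plot (log2 vs concatenated genomic position).

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chrom_order: list[str] = []
    chrom_len: dict[str, int] = {}
    for chrom, start, end in arms.arms.values():
        c = normalize_chrom(chrom)
        chrom_len[c] = max(chrom_len.get(c, 0), end)
        if c not in chrom_order:
            chrom_order.append(c)
    chrom_order.sort(key=chrom_sort_key)
    offset: dict[str, int] = {}
    run = 0
    for c in chrom_order:
        offset[c] = run
        run += chrom_len[c]

    fig, ax = plt.subplots(figsize=(10, 2.5))
    for s in segments:
        if s.sample_id != sample_id or s.chrom not in offset:
            continue
        x0 = offset[s.chrom] + s.start
        x1 = offset[s.chrom] + s.end
        ax.plot([x0, x1], [s.log2_ratio, s.log2_ratio], lw=2, color="tab:blue")
    for c in chrom_order[1:]:
        ax.axvline(offset[c], color="0.85", lw=0.5)
    ax.axhline(0, color="0.5", lw=0.5)
    ax.set_ylabel("log2 ratio")
    ax.set_title(sample_id)
    ax.set_xticks([offset[c] + chrom_len[c] / 2 for c in chrom_order])
    ax.set_xticklabels(chrom_order, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
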