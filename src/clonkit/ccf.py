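"""Cancer-cell-fraction estimation and clonal/subclonal classification.

Per-mutation CCF is estimated with a flat-prior binomial posterior over a
CCF grid.  The observed tumor alt-read count is modeled as
Binomial(depth, f(c)) where the expected VAF is

    f(c) = purity * multiplicity * c / (purity * cn_tumor + (1 - purity) * cn_normal)

clamped to [0, 1].  Multiplicity (mutant copies per carrying cell) is chosen
from {1, ..., major copy number} by maximizing the binomial likelihood at the
moment estimate of CCF, with ties broken toward the smaller multiplicity
(the more conservative CCF).

"Probability of being clonal" is defined as posterior mass at CCF >= 0.9.  A
mutation is labeled clonal when that probability exceeds 0.5 or when the
lower bound of the 95% credible interval exceeds 0.9.  This grid posterior is
a deliberately simple surrogate for full purity/ploidy-aware karyotype
models; it needs only read counts, purity and local copy number, and it makes
the clonal-probability rule concrete and reproducible.

Mutations falling in segments with total copy number 0 carry no tumor signal
and are flagged unestimable rather than forced onto the grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import CopySegment, MutationCall, SamplePurity

__all__ = ["CCFEstimate", "expected_vaf", "estimate_ccf", "estimate_case", "write_ccf_table"]


@dataclass
class CCFEstimate:
    """Point estimate, 95% credible interval and clonal call for one mutation."""

    ccf_point: float
    ci_low: float
    ci_high: float
    p_clonal: float
    multiplicity: int
    clonal: bool
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable and not (
            self.ci_low <= self.ccf_point <= self.ci_high
        ):
            raise ValueError("credible interval must bracket the point estimate")


def expected_vaf(
    ccf: float,
    purity: float,
    multiplicity: int = 1,
    cn_tumor: int = 2,
    cn_normal: int = 2,
) -> float:
    """Expected variant allele fraction for a mutation at the given CCF.

    Standard relation for a mutation on ``multiplicity`` of ``cn_tumor``
    copies in tumor cells mixed with normal cells of ``cn_normal`` copies at
    the given purity; the result is clamped to [0, 1].
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if cn_tumor < 1:
        raise ValueError("cn_tumor must be >= 1")
    if cn_normal not in (1, 2):
        raise ValueError("cn_normal must be 1 or 2")
    vaf = purity * multiplicity * ccf / (purity * cn_tumor + (1.0 - purity) * cn_normal)
    return float(min(1.0, max(0.0, vaf)))


def _choose_multiplicity(
    t_alt: int,
    depth: int,
    purity: float,
    cn_tumor: int,
    cn_minor: int,
    cn_normal: int,
) -> int:
    """Pick multiplicity in {1..major CN} by likelihood at the moment estimate."""
    major = max(1, cn_tumor - cn_minor)
    if major == 1:
        return 1
    vaf_obs = t_alt / depth
    denom = purity * cn_tumor + (1.0 - purity) * cn_normal
    best_m, best_ll = 1, -np.inf
    for m in range(1, major + 1):
        ccf_star = min(1.0, vaf_obs * denom / (purity * m))
        f = expected_vaf(ccf_star, purity, m, cn_tumor, cn_normal)
        ll = stats.binom.logpmf(t_alt, depth, f)
        if ll > best_ll + 1e-12:  # strict improvement: ties keep the smaller m
            best_m, best_ll = m, ll
    return best_m


def estimate_ccf(
    call: MutationCall,
    purity: SamplePurity,
    segment: CopySegment | None = None,
    grid_step: float = 0.01,
) -> CCFEstimate:
    """Grid-posterior CCF estimate for one mutation.

    The posterior over the grid {grid_step, 2*grid_step, ..., 1} is
    proportional to the binomial likelihood of the tumor alt count under the
    expected VAF at each grid CCF (flat prior).  The point estimate is the
    posterior mode, the interval the 2.5th/97.5th posterior percentiles, and
    ``p_clonal`` the mass at CCF >= 0.9.
    """
    depth = call.tumor_depth
    if depth <= 0:
        raise ValueError("tumor depth must be positive for CCF estimation")
    cn_tumor = segment.cn_total if segment is not None and segment.cn_total is not None else 2
    cn_minor = segment.cn_minor if segment is not None and segment.cn_minor is not None else 1
    if cn_tumor == 0:
        return CCFEstimate(0.0, 0.0, 0.0, 0.0, 1, False, estimable=False)
    cn_normal = 2
    m = _choose_multiplicity(call.t_alt, depth, purity.purity, cn_tumor, cn_minor, cn_normal)

    grid = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    denom = purity.purity * cn_tumor + (1.0 - purity.purity) * cn_normal
    f = np.clip(purity.purity * m * grid / denom, 0.0, 1.0)
    loglik = stats.binom.logpmf(call.t_alt, depth, f)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()

    mode = float(grid[int(np.argmax(post))])
    # midpoint (Hazen) percentile convention: each grid cell contributes half
    # its mass at its own location, which behaves sanely at the CCF=1 boundary
    cdf_mid = np.cumsum(post) - 0.5 * post
    ci_low = float(grid[min(int(np.searchsorted(cdf_mid, 0.025)), len(grid) - 1)])
    ci_high = float(grid[min(int(np.searchsorted(cdf_mid, 0.975)), len(grid) - 1)])
    # grid discreteness can leave the mode a step outside the interval
    ci_low, ci_high = min(ci_low, mode), max(ci_high, mode)
    p_clonal = float(post[grid >= 0.9 - 1e-12].sum())
    clonal = p_clonal > 0.5 or ci_low > 0.9
    return CCFEstimate(mode, ci_low, ci_high, p_clonal, m, clonal)


def _segment_for(
    call: MutationCall, segments: Sequence[CopySegment]
) -> CopySegment | None:
    for s in segments:
        if s.sample_id == call.sample_id and s.chrom == call.chrom:
            if s.start <= call.pos <= s.end:
                return s
    return None


def estimate_case(
    calls: Sequence[MutationCall],
    purities: Mapping[str, SamplePurity],
    segments: Sequence[CopySegment] = (),
    grid_step: float = 0.01,
) -> list[tuple[MutationCall, CCFEstimate]]:
    """Estimate CCF for every call, looking up purity and overlapping segment.

    Raises ``KeyError`` naming the sample when its purity is missing.
    """
    out = []
    for call in calls:
        if call.sample_id not in purities:
            raise KeyError(f"no purity estimate for sample {call.sample_id!r}")
        seg = _segment_for(call, segments)
        out.append((call, estimate_ccf(call, purities[call.sample_id], seg, grid_step)))
    return out


CCF_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "ccf_point",
    "ci_low",
    "ci_high",
    "p_clonal",
    "multiplicity",
    "clonal",
    "estimable",
)


def write_ccf_table(
    results: Sequence[tuple[MutationCall, CCFEstimate]], path: str | Path
) -> None:
    """One row per (sample, variant) with all estimate fields."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CCF_COLUMNS)
        for call, est in results:
            w.writerow(
                [
                    call.sample_id,
                    call.chrom,
                    call.pos,
                    call.ref,
                    call.alt,
                    call.gene,
                    f"{est.ccf_point:.4f}",
                    f"{est.ci_low:.4f}",
                    f"{est.ci_high:.4f}",
                    f"{est.p_clonal:.6f}",
                    est.multiplicity,
                    "true" if est.clonal else "false",
                    "true" if est.estimable else "false",
                ]
            )
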