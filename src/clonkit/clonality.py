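"""Clonality index for pairwise lesion relatedness.

Two lesions sharing an improbable set of somatic mutations are unlikely to
have arisen independently.  For each mutation shared by a pair of samples,
the chance of both samples carrying it independently is the two-trial
binomial probability p^2, where p is the mutation's frequency in a reference
cohort.  The clonality index aggregates over the M shared mutations:

    CI = -log10 prod_m p_m^2 = -2 * sum_m log10 p_m

so rarer shared mutations contribute more, and CI = 0 exactly when nothing
is shared.  The product is evaluated in log space for numerical stability.

Because no universal CI cutoff exists, relatedness is declared against a
permutation null: each sample's mutation count is preserved while its
mutations are re-drawn independently from the frequency catalog (probability
proportional to p), and the pair is called related when the observed CI
exceeds the (1 - alpha) quantile of the null CI distribution.  Frequencies
for mutations absent from the catalog floor at 1e-6, and all frequencies cap
at 0.5, bounding each mutation's CI contribution.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import MutationCall, VariantKey

logger = logging.getLogger("clonkit")

__all__ = [
    "MutationFrequency",
    "FrequencyTable",
    "ClonalityResult",
    "pair_probability",
    "clonality_index",
    "pairwise_clonality",
    "read_frequency_table",
    "write_clonality_table",
]

DEFAULT_FLOOR = 1e-6
DEFAULT_CAP = 0.5


@dataclass(frozen=True)
class MutationFrequency:
    """Reference-cohort frequency of one mutation.

    ``key`` is the genomic identity when known; ``gene``/``protein_change``
    serve as a fallback lookup for catalog entries without coordinates.
    """

    p: float
    key: VariantKey | None = None
    gene: str = ""
    protein_change: str = ""


class FrequencyTable:
    """Frequency lookup with floor/cap, plus the catalog used by the null."""

    def __init__(
        self,
        entries: Sequence[MutationFrequency],
        floor: float = DEFAULT_FLOOR,
        cap: float = DEFAULT_CAP,
    ):
        if not 0 < floor <= cap < 1:
            raise ValueError("need 0 < floor <= cap < 1")
        self.floor = floor
        self.cap = cap
        self.entries = list(entries)
        self._by_key = {e.key: e.p for e in entries if e.key is not None}
        self._by_protein = {
            (e.gene, e.protein_change): e.p
            for e in entries
            if e.gene and e.protein_change
        }

    def _clip(self, p: float) -> float:
        return min(self.cap, max(self.floor, p))

    def lookup(
        self, key: VariantKey, gene: str = "", protein_change: str = ""
    ) -> float:
        """Frequency by exact key, else by (gene, protein change), else floor."""
        if key in self._by_key:
            return self._clip(self._by_key[key])
        if (gene, protein_change) in self._by_protein:
            return self._clip(self._by_protein[(gene, protein_change)])
        return self.floor

    def catalog_probs(self) -> np.ndarray:
        """Clipped frequencies of all catalog entries (for null re-draws)."""
        return np.array([self._clip(e.p) for e in self.entries], dtype=float)


def pair_probability(p: float) -> float:
    """Probability that two samples independently carry a mutation of frequency p.

    Binomial with n = 2 trials and k = 2 successes: p^2.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"frequency must be in (0,1), got {p}")
    return p * p


def clonality_index(
    shared: Sequence[VariantKey],
    freqs: FrequencyTable,
    annotations: Mapping[VariantKey, tuple[str, str]] | None = None,
) -> float:
    """CI = -log10 of the product of pair probabilities over shared mutations.

    Computed as -2 * sum(log10 p_m); the empty set gives 0 (empty product).
    ``annotations`` optionally maps keys to (gene, protein_change) for the
    fallback lookup.
    """
    total = 0.0
    for key in shared:
        gene, pc = (annotations or {}).get(key, ("", ""))
        p = freqs.lookup(key, gene, pc)
        total += -2.0 * math.log10(p)
    return total


@dataclass
class ClonalityResult:
    """Clonality-index comparison of one unordered sample pair."""

    sample_a: str
    sample_b: str
    shared_keys: list[VariantKey]
    ci: float
    related: bool
    null_quantiles: dict[str, float] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.shared_keys)


def _null_ci_distribution(
    n_a: int,
    n_b: int,
    probs: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Null CI values from re-drawing both samples' mutations from the catalog.

    Each permutation draws ``n_a`` (resp. ``n_b``) distinct catalog mutations
    with probability proportional to p, via the exponential-race trick for
    weighted sampling without replacement, then scores the intersection.
    """
    C = len(probs)
    n_a, n_b = min(n_a, C), min(n_b, C)
    contrib = -2.0 * np.log10(probs)
    out = np.empty(n_perm)
    done = 0
    # cap the permutations-x-catalog work array at ~4M entries per chunk
    chunk = max(16, min(chunk, 4_000_000 // max(C, 1)))
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # weighted sampling without replacement: smallest Exp(1)/w win
        race_a = rng.exponential(size=(b, C)) / probs
        race_b = rng.exponential(size=(b, C)) / probs
        idx_a = np.argpartition(race_a, n_a - 1, axis=1)[:, :n_a] if n_a else np.empty((b, 0), int)
        idx_b = np.argpartition(race_b, n_b - 1, axis=1)[:, :n_b] if n_b else np.empty((b, 0), int)
        in_a = np.zeros((b, C), dtype=bool)
        in_b = np.zeros((b, C), dtype=bool)
        rows = np.arange(b)[:, None]
        if n_a:
            in_a[rows, idx_a] = True
        if n_b:
            in_b[rows, idx_b] = True
        out[done : done + b] = ((in_a & in_b) * contrib).sum(axis=1)
        done += b
    return out


def pairwise_clonality(
    calls_by_sample: Mapping[str, Sequence[MutationCall]],
    freqs: FrequencyTable,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[ClonalityResult]:
    """Clonality index and permutation test for every unordered sample pair.

    The null preserves each sample's mutation count and re-draws mutation
    identities from the frequency catalog; ``related`` means the observed CI
    exceeds the (1 - alpha) null quantile.  With ``alpha = 1`` no pair is
    ever called related.  Results are deterministic given the seed.
    """
    samples = list(calls_by_sample)
    if len(samples) < 2:
        raise ValueError("pairwise clonality needs at least 2 samples")
    keysets: dict[str, set[VariantKey]] = {}
    annotations: dict[VariantKey, tuple[str, str]] = {}
    for s, calls in calls_by_sample.items():
        keysets[s] = {c.key for c in calls}
        for c in calls:
            annotations.setdefault(c.key, (c.gene, c.protein_change))
        if not keysets[s]:
            logger.warning("sample %s has no retained mutations", s)

    probs = freqs.catalog_probs()
    results: list[ClonalityResult] = []
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(len(samples) * (len(samples) - 1) // 2)
    pair_i = 0
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            rng = np.random.default_rng(pair_seeds[pair_i])
            pair_i += 1
            shared = sorted(keysets[a] & keysets[b])
            ci = clonality_index(shared, freqs, annotations)
            quantiles: dict[str, float] = {}
            related = False
            if keysets[a] and keysets[b] and len(probs) and alpha < 1:
                null = _null_ci_distribution(
                    len(keysets[a]), len(keysets[b]), probs, n_perm, rng
                )
                thr = float(np.quantile(null, 1.0 - alpha))
                quantiles = {
                    "q50": float(np.quantile(null, 0.5)),
                    "q95": float(np.quantile(null, 0.95)),
                    "threshold": thr,
                    "max": float(null.max()),
                }
                related = ci > thr
            results.append(
                ClonalityResult(a, b, list(shared), ci, related, quantiles)
            )
    return results


def read_frequency_table(path: str | Path, floor: float = DEFAULT_FLOOR, cap: float = DEFAULT_CAP) -> FrequencyTable:
    """Read a frequency catalog TSV (chrom,pos,ref,alt,gene,protein_change,p)."""
    entries: list[MutationFrequency] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "p" not in reader.fieldnames:
            raise ValueError(f"frequency table {path} must have a 'p' column")
        for row in reader:
            key = None
            if row.get("chrom") and row.get("pos"):
                key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            entries.append(
                MutationFrequency(
                    p=float(row["p"]),
                    key=key,
                    gene=row.get("gene", "") or "",
                    protein_change=row.get("protein_change", "") or "",
                )
            )
    return FrequencyTable(entries, floor=floor, cap=cap)


def write_clonality_table(results: Sequence[ClonalityResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_a", "sample_b", "n_shared", "clonality_index", "null_threshold", "related"]
        )
        for r in results:
            w.writerow(
                [
                    r.sample_a,
                    r.sample_b,
                    r.M,
                    f"{r.ci:.4f}",
                    f"{r.null_quantiles.get('threshold', float('nan')):.4f}",
                    "true" if r.related else "false",
                ]
            )
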