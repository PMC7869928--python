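"""Mutational-signature exposure estimation over the 96 trinucleotide channels.

Single-base substitutions are tabulated into the canonical 96 channels
(6 pyrimidine substitution types x 16 flanking contexts), and per-sample
exposures over a signature catalog are estimated by non-negative least
squares on the normalized channel spectrum, followed by a sparsity refit:
signatures receiving less than ``sparsity_floor`` of the total exposure are
dropped and the fit repeated on the survivors.  Exposures sum to 1 and the
Euclidean reconstruction residual is reported.

Signature inference is unstable on very few mutations; samples with fewer
than :data:`LOW_CONFIDENCE_MIN` attributable SNVs are flagged low-confidence
rather than suppressed, since benign lesions in multi-lesion studies often
carry only a handful of mutations.

The bundled default catalog (:func:`default_catalog`) is a SYNTHETIC,
stylized rendering of five well-known signature shapes — SBS1 (CpG
deamination, aging), SBS2/SBS13 (APOBEC: C>T and C>G at TpC), SBS5
(flat, clock-like) and SBS18 (C>A dominated) — constructed from their
qualitative channel structure, not copied from any published matrix.  It is
intended for simulation and testing; analyses of real data should load a
published catalog via ``read_signature_catalog``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .io_model import CHANNELS_96, MutationCall, SignatureCatalog, channel_of

logger = logging.getLogger("clonkit")

__all__ = [
    "ChannelCounts",
    "SignatureExposure",
    "count_channels",
    "fit_exposures",
    "default_catalog",
    "write_exposure_table",
    "LOW_CONFIDENCE_MIN",
]

#: Below this many attributable SNVs an exposure estimate is flagged low-confidence.
LOW_CONFIDENCE_MIN = 5


@dataclass
class ChannelCounts:
    """96-channel SNV counts for one sample (catalog channel order)."""

    sample_id: str
    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError("channel counts must have length 96")
        if np.any(self.counts < 0):
            raise ValueError("channel counts must be non-negative")

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureExposure:
    """Per-sample exposure fractions over a catalog, summing to 1."""

    sample_id: str
    signature_names: tuple[str, ...]
    exposures: np.ndarray
    residual: float
    n_mutations: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if np.any(self.exposures < -1e-12):
            raise ValueError("exposures must be non-negative")
        if self.n_mutations > 0 and abs(self.exposures.sum() - 1.0) > 1e-8:
            raise ValueError("exposures must sum to 1")

    def exposure_of(self, name: str) -> float:
        return float(self.exposures[self.signature_names.index(name)])


def count_channels(calls: Sequence[MutationCall], sample_id: str | None = None) -> ChannelCounts:
    """Tabulate SNVs with valid trinucleotide context into the 96 channels.

    Purine-centered inputs are mapped to the pyrimidine strand; indels and
    records without a usable context are excluded and counted in
    ``n_skipped``.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    sid = sample_id
    for c in calls:
        if sid is None:
            sid = c.sample_id
        label = channel_of(c.ref, c.alt, c.context) if c.context else None
        if label is None:
            skipped += 1
            continue
        counts[CHANNELS_96.index(label)] += 1
    if skipped:
        logger.info("count_channels: skipped %d record(s) without usable context", skipped)
    return ChannelCounts(sid or "", counts, n_skipped=skipped)


def fit_exposures(
    counts: ChannelCounts,
    catalog: SignatureCatalog,
    sparsity_floor: float = 0.05,
) -> SignatureExposure:
    """Non-negative least-squares exposure fit with a sparsity refit.

    Solves min_{e >= 0} || counts/n - S e ||_2, normalizes e to sum to 1,
    zeroes signatures below ``sparsity_floor`` and refits on the remainder.
    Deterministic; raises on a sample with no attributable mutations.
    """
    n = counts.n_mutations
    if n < 1:
        raise ValueError(f"sample {counts.sample_id!r}: no attributable mutations")
    spectrum = counts.counts / n
    active = list(range(catalog.n_signatures))
    while True:
        sub = catalog.matrix[:, active]
        coef, _ = nnls(sub, spectrum)
        total = coef.sum()
        if total <= 0:
            # degenerate: spectrum orthogonal to catalog; spread evenly
            norm = np.full(len(active), 1.0 / len(active))
        else:
            norm = coef / total
        keep = [a for a, w in zip(active, norm) if w >= sparsity_floor]
        if len(keep) == len(active) or not keep:
            break
        active = keep
    exposures = np.zeros(catalog.n_signatures)
    for a, w in zip(active, norm):
        exposures[a] = w
    exposures /= exposures.sum()
    residual = float(np.linalg.norm(spectrum - catalog.matrix[:, active] @ coef))
    return SignatureExposure(
        sample_id=counts.sample_id,
        signature_names=tuple(catalog.signature_names),
        exposures=exposures,
        residual=residual,
        n_mutations=n,
        low_confidence=n < LOW_CONFIDENCE_MIN,
    )


def _context_index(sub: str, five: str, three: str) -> int:
    return CHANNELS_96.index(f"{five}[{sub}]{three}")


def default_catalog() -> SignatureCatalog:
    """SYNTHETIC five-signature catalog (SBS1, SBS2, SBS5, SBS13, SBS18).

    Stylized channel profiles built from each signature's qualitative
    description; see the module docstring.  Deterministic and
    column-stochastic by construction.
    """
    bases = "ACGT"
    mat = np.zeros((96, 5))

    # SBS1: C>T at NpCpG (CpG deamination), sharp
    col = np.full(96, 0.15 / 96)
    for five in bases:
        col[_context_index("C>T", five, "G")] += 0.85 / 4
    mat[:, 0] = col

    # SBS2: C>T at TpCpN (APOBEC)
    col = np.full(96, 0.08 / 96)
    for three in bases:
        col[_context_index("C>T", "T", three)] += 0.92 / 4
    mat[:, 1] = col

    # SBS5: flat, clock-like, mild preference for C>T and T>C
    col = np.full(96, 1.0)
    for five in bases:
        for three in bases:
            col[_context_index("C>T", five, three)] = 1.8
            col[_context_index("T>C", five, three)] = 1.6
    mat[:, 2] = col / col.sum()

    # SBS13: C>G at TpCpN (APOBEC)
    col = np.full(96, 0.08 / 96)
    for three in bases:
        col[_context_index("C>G", "T", three)] += 0.92 / 4
    mat[:, 3] = col

    # SBS18: C>A dominated (reactive oxygen damage), broad over contexts
    col = np.full(96, 0.10 / 96)
    for five in bases:
        for three in bases:
            col[_context_index("C>A", five, three)] += 0.90 / 16
    mat[:, 4] = col

    mat /= mat.sum(axis=0, keepdims=True)
    return SignatureCatalog(
        signature_names=("SBS1", "SBS2", "SBS5", "SBS13", "SBS18"), matrix=mat
    )


def write_exposure_table(
    exposures: Sequence[SignatureExposure], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        names = exposures[0].signature_names if exposures else ()
        w.writerow(["sample_id", "n_mutations", "residual", "low_confidence", *names])
        for e in exposures:
            w.writerow(
                [
                    e.sample_id,
                    e.n_mutations,
                    f"{e.residual:.6f}",
                    "true" if e.low_confidence else "false",
                    *[f"{x:.4f}" for x in e.exposures],
                ]
            )
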