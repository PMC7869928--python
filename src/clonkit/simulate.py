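"""Synthetic multi-lesion cases with known truth, and the JuP3 case fixture.

The generator emulates the structure of a multi-lesion breast case in which
a benign proliferative lesion (juvenile papillomatosis, JP) coexists with
DCIS and invasive carcinoma: a clonal trunk of mutations shared by every
lesion (including one hotspot driver such as PIK3CA E542K), branch mutations
shared by a lesion subset, private subclonal mutations, binomial read-count
noise at the configured purity and depth, trinucleotide contexts drawn from
per-lesion signature mixtures, and carcinoma-only 1q-gain/16q-loss segments.
Every quantity a downstream stage estimates is recorded in :class:`SimTruth`
so recovery can be scored exactly.

Mutations live on a toy genome (22 chromosomes of 10 Mb, arms split at the
midpoint) so that cross-case coordinate collisions are quantifiable.  Trunk
and branch mutations have true CCF 1 in their carrying lesions; private
mutations draw CCF ~ Uniform(0.2, 1).  Tumor depth is Poisson(mean_depth)
and alt counts Binomial(depth, expected VAF); matched normals are Poisson
depth with zero alt reads (plus an optional contamination rate).

``load_jup3_fixture`` packages the mutations named in the study narrative
for case JuP3 — the trio shared by all components (PIK3CA E542K hotspot,
CES1 S12A, SMG1 R420Q), a 29-mutation DCIS+IDC branch including ARID1A
(truncating), KMT2C, PIK3CB, NUP93 E14K and PIK3C2A, a DCIS-private STAG2
truncation and an IDC-private FGF12 missense — with SYNTHETIC read counts,
depths and CCFs: only the mutation identities and their sharing pattern
follow the published case, and unnamed branch mutations carry synthetic
placeholder gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ccf import expected_vaf
from .clonality import FrequencyTable, MutationFrequency
from .cna import ArmTable
from .io_model import (
    CopySegment,
    MutationCall,
    SamplePurity,
    SignatureCatalog,
    VariantKey,
    write_mutation_table,
    write_purity_table,
    write_segments,
)
from .signatures import default_catalog

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimCase",
    "simulate_case",
    "preset",
    "toy_arm_table",
    "jup3_arm_table",
    "load_jup3_fixture",
    "jup3_fixture_segments",
    "jup3_fixture_purities",
    "frequency_catalog_for",
]

TOY_CHROM_LENGTH = 10_000_000
TOY_CHROMS = tuple(str(c) for c in range(1, 23))

_EFFECT_PROBS = {
    "nonsynonymous": 0.65,
    "synonymous": 0.25,
    "truncating": 0.05,
    "splice": 0.02,
    "other": 0.03,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def toy_arm_table() -> ArmTable:
    """p/q arms of the toy genome (each chromosome 10 Mb, split at 5 Mb)."""
    half = TOY_CHROM_LENGTH // 2
    arms = {}
    for c in TOY_CHROMS:
        arms[f"{c}p"] = (c, 1, half)
        arms[f"{c}q"] = (c, half + 1, TOY_CHROM_LENGTH)
    return ArmTable(arms)


@dataclass
class SimConfig:
    """Configuration of one simulated multi-lesion case.

    ``branches`` maps a lesion subset (tuple of lesion names) to the number
    of mutations shared by exactly that subset; ``private_sizes`` gives each
    lesion's private mutation count.  ``signature_weights`` are per-lesion
    mixtures over the catalog's signatures.
    """

    case_id: str
    lesions: tuple[str, ...]
    trunk_size: int = 3
    branches: dict[tuple[str, ...], int] = dc_field(default_factory=dict)
    private_sizes: dict[str, int] = dc_field(default_factory=dict)
    purity: dict[str, float] = dc_field(default_factory=dict)
    mean_depth: float = 150.0
    signature_weights: dict[str, np.ndarray] = dc_field(default_factory=dict)
    cn_events: dict[str, list[tuple[str, float]]] = dc_field(default_factory=dict)
    contamination: float = 0.0
    hotspot_driver: tuple[str, str] = ("PIK3CA", "E542K")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= len(self.lesions) or len(self.lesions) > 8:
            raise ValueError("a case needs 2-8 lesions")
        if self.trunk_size < 1:
            raise ValueError("trunk_size must be >= 1 (it carries the driver)")
        for subset in self.branches:
            if not set(subset) < set(self.lesions):
                raise ValueError(
                    f"branch subset {subset} must be a proper subset of the lesions"
                )
            if len(subset) < 2:
                raise ValueError("branch subsets must contain >= 2 lesions")
        for lesion in self.lesions:
            self.private_sizes.setdefault(lesion, 0)
            self.purity.setdefault(lesion, 0.6)
        for w in self.signature_weights.values():
            w = np.asarray(w, float)
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("signature weights must sum to 1")


@dataclass
class SimTruth:
    """Ground truth sufficient to score every downstream stage."""

    ccf: dict[tuple[str, VariantKey], float]
    edge: dict[VariantKey, frozenset[str]]
    signature: dict[VariantKey, str]
    purity: dict[str, float]
    cn_events: dict[str, list[tuple[str, float]]]
    related_pairs: set[frozenset[str]]


@dataclass
class SimCase:
    """One simulated case: tables the pipeline reads plus the truth."""

    case_id: str
    calls_by_lesion: dict[str, list[MutationCall]]
    segments: list[CopySegment]
    purities: dict[str, SamplePurity]
    truth: SimTruth

    def all_calls(self) -> list[MutationCall]:
        return [c for calls in self.calls_by_lesion.values() for c in calls]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mutation_table(self.all_calls(), outdir / f"{self.case_id}.mutations.tsv")
        write_segments(self.segments, outdir / f"{self.case_id}.segments.tsv")
        write_purity_table(self.purities, outdir / f"{self.case_id}.purity.tsv")


def _draw_channel(rng: np.random.Generator, catalog: SignatureCatalog, weights: np.ndarray) -> tuple[int, str]:
    sig_idx = int(rng.choice(catalog.n_signatures, p=weights))
    chan = int(rng.choice(96, p=catalog.matrix[:, sig_idx]))
    return chan, catalog.signature_names[sig_idx]


def _channel_to_alleles(chan_label: str) -> tuple[str, str, str]:
    # "A[C>T]G" -> ref C, alt T, context ACG
    five, rest = chan_label[0], chan_label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


def simulate_case(cfg: SimConfig, catalog: SignatureCatalog | None = None) -> SimCase:
    """Simulate one case with full ground truth; deterministic given the seed."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(cfg.seed)
    lesions = list(cfg.lesions)
    default_w = np.full(catalog.n_signatures, 1.0 / catalog.n_signatures)

    # plan: (carrying lesions, ccf per lesion)
    plans: list[tuple[tuple[str, ...], dict[str, float]]] = []
    plans.append((tuple(lesions), {l: 1.0 for l in lesions}))  # trunk w/ driver
    for _ in range(cfg.trunk_size - 1):
        plans.append((tuple(lesions), {l: 1.0 for l in lesions}))
    for subset, size in cfg.branches.items():
        for _ in range(size):
            plans.append((tuple(subset), {l: 1.0 for l in subset}))
    for lesion in lesions:
        for _ in range(cfg.private_sizes[lesion]):
            plans.append(((lesion,), {lesion: float(rng.uniform(0.2, 1.0))}))

    used_pos: set[tuple[str, int]] = set()
    truth_ccf: dict[tuple[str, VariantKey], float] = {}
    truth_edge: dict[VariantKey, frozenset[str]] = {}
    truth_sig: dict[VariantKey, str] = {}
    calls_by_lesion: dict[str, list[MutationCall]] = {l: [] for l in lesions}

    for mut_i, (carriers, ccf_map) in enumerate(plans):
        while True:
            chrom = str(rng.choice(TOY_CHROMS))
            pos = int(rng.integers(1, TOY_CHROM_LENGTH + 1))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                break
        weights = np.asarray(
            cfg.signature_weights.get(carriers[0], default_w), float
        )
        chan, sig_name = _draw_channel(rng, catalog, weights)
        ref, alt, context = _channel_to_alleles(
            catalog.channel_labels[chan]
        )
        if mut_i == 0:
            gene, protein_change = cfg.hotspot_driver
            effect, hotspot = "nonsynonymous", True
        else:
            gene = f"{cfg.case_id}_G{mut_i:04d}"
            codon = int(rng.integers(1, 1000))
            protein_change = (
                f"{_AA[rng.integers(len(_AA))]}{codon}{_AA[rng.integers(len(_AA))]}"
            )
            effect = str(
                rng.choice(list(_EFFECT_PROBS), p=list(_EFFECT_PROBS.values()))
            )
            hotspot = False
        key = VariantKey(chrom, pos, ref, alt)
        truth_edge[key] = frozenset(f"{cfg.case_id}-{l}" for l in carriers)
        truth_sig[key] = sig_name
        for lesion in carriers:
            ccf = ccf_map[lesion]
            truth_ccf[(f"{cfg.case_id}-{lesion}", key)] = ccf
            f = expected_vaf(ccf, cfg.purity[lesion], 1, 2, 2)
            depth = max(1, int(rng.poisson(cfg.mean_depth)))
            t_alt = int(rng.binomial(depth, f))
            n_depth = max(1, int(rng.poisson(cfg.mean_depth)))
            n_alt = int(rng.binomial(n_depth, cfg.contamination)) if cfg.contamination else 0
            calls_by_lesion[lesion].append(
                MutationCall(
                    sample_id=f"{cfg.case_id}-{lesion}",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    protein_change=protein_change,
                    effect=effect,
                    t_ref=depth - t_alt,
                    t_alt=t_alt,
                    n_ref=n_depth - n_alt,
                    n_alt=n_alt,
                    pop_maf=None,
                    context=context,
                    hotspot=hotspot,
                )
            )

    segments = _segments_for(cfg)
    purities = {
        f"{cfg.case_id}-{l}": SamplePurity(f"{cfg.case_id}-{l}", cfg.purity[l])
        for l in lesions
    }
    truth = SimTruth(
        ccf=truth_ccf,
        edge=truth_edge,
        signature=truth_sig,
        purity={f"{cfg.case_id}-{l}": cfg.purity[l] for l in lesions},
        cn_events=dict(cfg.cn_events),
        related_pairs={
            frozenset({f"{cfg.case_id}-{a}", f"{cfg.case_id}-{b}"})
            for i, a in enumerate(lesions)
            for b in lesions[i + 1 :]
        },
    )
    # rename calls dict to full sample ids
    calls = {f"{cfg.case_id}-{l}": calls_by_lesion[l] for l in lesions}
    return SimCase(cfg.case_id, calls, segments, purities, truth)


def _segments_for(cfg: SimConfig) -> list[CopySegment]:
    """One segment per toy-genome arm per lesion, flat except configured events."""
    arms = toy_arm_table()
    out: list[CopySegment] = []
    for lesion in cfg.lesions:
        events = dict(cfg.cn_events.get(lesion, []))
        sample = f"{cfg.case_id}-{lesion}"
        for arm, (chrom, start, end) in arms.arms.items():
            log2 = events.get(arm, 0.0)
            if log2 > 0:
                cn_total, cn_minor = 3, 1
            elif log2 < 0:
                cn_total, cn_minor = 1, 0
            else:
                cn_total, cn_minor = 2, 1
            out.append(
                CopySegment(sample, chrom, start, end, log2, cn_total, cn_minor)
            )
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def preset(name: str, seed: int = 0) -> list[SimConfig]:
    """Named study conditions.

    ``jup3_like``: one case of three lesions (JP, DCIS, IDC) with a
    3-mutation clonal trunk carrying the PIK3CA E542K driver, a 29-mutation
    DCIS+IDC branch, private mutations sized so the benign lesion totals 9
    mutations, aging-dominant signature mixture in JP versus APOBEC-dominant
    in the carcinomas, and 1q-gain/16q-loss only in the carcinoma lesions.

    ``null_pair``: two unrelated two-lesion cases drawn independently from
    the toy genome; cross-case sample pairs share no true mutations.
    """
    if name == "jup3_like":
        return [
            SimConfig(
                case_id="SIM3",
                lesions=("JP", "DCIS", "IDC"),
                trunk_size=3,
                branches={("DCIS", "IDC"): 29},
                private_sizes={"JP": 6, "DCIS": 10, "IDC": 12},
                purity={"JP": 0.7, "DCIS": 0.6, "IDC": 0.6},
                mean_depth=150.0,
                signature_weights={
                    # order: SBS1, SBS2, SBS5, SBS13, SBS18
                    "JP": np.array([0.02, 0.20, 0.76, 0.01, 0.01]),
                    "DCIS": np.array([0.02, 0.55, 0.35, 0.05, 0.03]),
                    "IDC": np.array([0.02, 0.64, 0.26, 0.05, 0.03]),
                },
                cn_events={
                    "DCIS": [("1q", 0.4), ("16q", -0.4)],
                    "IDC": [("1q", 0.4), ("16q", -0.4)],
                },
                seed=seed,
            )
        ]
    if name == "null_pair":
        common = dict(
            trunk_size=3,
            private_sizes={"A": 5, "B": 5},
            purity={"A": 0.6, "B": 0.6},
            mean_depth=150.0,
        )
        return [
            SimConfig(case_id="NULL1", lesions=("A", "B"), seed=seed * 2 + 1, **common),
            SimConfig(case_id="NULL2", lesions=("A", "B"), seed=seed * 2 + 2, **common),
        ]
    raise ValueError(f"unknown preset {name!r}")


def frequency_catalog_for(
    cases: Sequence[SimCase],
    n_background: int = 500,
    hotspot_p: float = 0.02,
    somatic_p: float = 1e-4,
    seed: int = 0,
) -> FrequencyTable:
    """A reference-cohort frequency table covering the cases' mutations.

    Hotspot drivers are common in cohorts (default p = 0.02); other somatic
    mutations are rare (default p = 1e-4).  ``n_background`` additional
    catalog-only entries give the permutation null something to draw.
    """
    rng = np.random.default_rng(seed)
    entries: list[MutationFrequency] = []
    seen: set[VariantKey] = set()
    for case in cases:
        for calls in case.calls_by_lesion.values():
            for c in calls:
                if c.key in seen:
                    continue
                seen.add(c.key)
                entries.append(
                    MutationFrequency(
                        p=hotspot_p if c.hotspot else somatic_p,
                        key=c.key,
                        gene=c.gene,
                        protein_change=c.protein_change,
                    )
                )
    for i in range(n_background):
        chrom = str(rng.choice(TOY_CHROMS))
        pos = int(rng.integers(1, TOY_CHROM_LENGTH + 1))
        entries.append(
            MutationFrequency(
                p=float(rng.uniform(1e-5, 1e-3)),
                key=VariantKey(chrom, pos, "C", "T"),
                gene=f"BG{i:04d}",
                protein_change="",
            )
        )
    return FrequencyTable(entries)


# ---------------------------------------------------------------------------
# JuP3 case fixture (mutation identities from the published narrative;
# read counts, depths and contexts SYNTHETIC)
# ---------------------------------------------------------------------------

_JUP3_SAMPLES = ("JuP3-JP", "JuP3-DCIS", "JuP3-IDC")

# (gene, protein_change, effect, chrom, pos, ref, alt, hotspot)
_JUP3_SHARED = [
    ("PIK3CA", "E542K", "nonsynonymous", "3", 178936082, "G", "A", True),
    ("CES1", "S12A", "nonsynonymous", "16", 55862704, "A", "C", False),
    ("SMG1", "R420Q", "nonsynonymous", "16", 18899543, "C", "T", False),
]

_JUP3_BRANCH_NAMED = [
    ("ARID1A", "Q586*", "truncating", "1", 27092814, "C", "T", False),
    ("KMT2C", "P331L", "nonsynonymous", "7", 151945071, "G", "A", False),
    ("PIK3CB", "A552V", "nonsynonymous", "3", 138413320, "G", "A", False),
    ("NUP93", "E14K", "nonsynonymous", "16", 56764612, "G", "A", False),
    ("PIK3C2A", "R86H", "nonsynonymous", "11", 17125456, "C", "T", False),
]

_JUP3_DCIS_PRIVATE = [("STAG2", "R614*", "truncating", "X", 123195650, "C", "T", False)]
_JUP3_IDC_PRIVATE = [("FGF12", "G141R", "nonsynonymous", "3", 191860916, "C", "T", False)]

#: SYNTHETIC per-lesion purities for the fixture (the study reports none).
JUP3_PURITY = {"JuP3-JP": 0.7, "JuP3-DCIS": 0.6, "JuP3-IDC": 0.6}
_JUP3_DEPTH = 120


def _jup3_records() -> list[tuple[tuple, tuple[str, ...], dict[str, float]]]:
    """(mutation spec, carrying samples, ccf per sample) for every fixture row."""
    rows: list[tuple[tuple, tuple[str, ...], dict[str, float]]] = []
    for spec in _JUP3_SHARED:
        rows.append((spec, _JUP3_SAMPLES, {s: 1.0 for s in _JUP3_SAMPLES}))
    branch_samples = ("JuP3-DCIS", "JuP3-IDC")
    for spec in _JUP3_BRANCH_NAMED:
        ccf = {s: 1.0 for s in branch_samples}
        if spec[0] == "PIK3C2A":  # subclonal in DCIS, dominant in IDC
            ccf = {"JuP3-DCIS": 0.3, "JuP3-IDC": 1.0}
        rows.append((spec, branch_samples, ccf))
    # unnamed branch mutations: SYNTHETIC placeholders bringing the DCIS+IDC
    # branch to 29 mutations (mix of synonymous and nonsynonymous)
    rng = np.random.default_rng(20200521)
    for i in range(29 - len(_JUP3_BRANCH_NAMED)):
        chrom = str(rng.choice(TOY_CHROMS))
        pos = int(rng.integers(1, TOY_CHROM_LENGTH + 1))
        effect = "synonymous" if i % 3 == 0 else "nonsynonymous"
        spec = (f"SYNBR{i:02d}", f"A{100 + i}G", effect, chrom, pos, "C", "T", False)
        rows.append((spec, branch_samples, {s: 1.0 for s in branch_samples}))
    for spec in _JUP3_DCIS_PRIVATE:
        rows.append((spec, ("JuP3-DCIS",), {"JuP3-DCIS": 1.0}))
    for spec in _JUP3_IDC_PRIVATE:
        rows.append((spec, ("JuP3-IDC",), {"JuP3-IDC": 1.0}))
    # a few SYNTHETIC private mutations per lesion so each has private branch mass
    privates = {"JuP3-JP": 6, "JuP3-DCIS": 2, "JuP3-IDC": 2}
    j = 0
    for sample, n in privates.items():
        for _ in range(n):
            chrom = str(rng.choice(TOY_CHROMS))
            pos = int(rng.integers(1, TOY_CHROM_LENGTH + 1))
            effect = "synonymous" if j % 4 == 0 else "nonsynonymous"
            spec = (f"SYNPR{j:02d}", f"L{50 + j}F", effect, chrom, pos, "T", "G", False)
            rows.append((spec, (sample,), {sample: 1.0}))
            j += 1
    return rows


def load_jup3_fixture() -> dict[str, list[MutationCall]]:
    """Mutation tables for the JP, DCIS and IDC components of case JuP3.

    Mutation identities and the sharing pattern follow the published case
    narrative; read counts, depths, CCFs and trinucleotide contexts are
    SYNTHETIC (generated deterministically at documented depth 120).
    """
    rng = np.random.default_rng(31337)
    catalog = default_catalog()
    mix = np.array([0.05, 0.40, 0.45, 0.05, 0.05])  # case-level context mixture
    calls: dict[str, list[MutationCall]] = {s: [] for s in _JUP3_SAMPLES}
    for (gene, pc, effect, chrom, pos, ref, alt, hotspot), samples, ccfs in _jup3_records():
        chan, _ = _draw_channel(rng, catalog, mix)
        _, _, context = _channel_to_alleles(catalog.channel_labels[chan])
        # keep the stated ref/alt; the context is synthetic and only needs to
        # be a valid trinucleotide, so re-center it on the (pyrimidine) ref
        pyr_ref = ref if ref in "CT" else {"G": "C", "A": "T"}[ref]
        context = context[0] + pyr_ref + context[2]
        for sample in samples:
            purity = JUP3_PURITY[sample]
            f = expected_vaf(ccfs[sample], purity, 1, 2, 2)
            depth = max(1, int(rng.poisson(_JUP3_DEPTH)))
            # the fixture encodes its stated CCFs exactly: alt reads are the
            # expected count at this depth, not a noisy draw (the simulator
            # is the place for read-count noise)
            t_alt = int(round(depth * f))
            n_depth = max(1, int(rng.poisson(_JUP3_DEPTH)))
            calls[sample].append(
                MutationCall(
                    sample_id=sample,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    protein_change=pc,
                    effect=effect,
                    t_ref=depth - t_alt,
                    t_alt=t_alt,
                    n_ref=n_depth,
                    n_alt=0,
                    pop_maf=None,
                    context=context,
                    hotspot=hotspot,
                )
            )
    return calls


def jup3_arm_table() -> ArmTable:
    """Approximate arm boundaries for the chromosomes the fixture touches."""
    return ArmTable(
        {
            "1p": ("1", 1, 125_000_000),
            "1q": ("1", 125_000_001, 249_000_000),
            "3p": ("3", 1, 91_000_000),
            "3q": ("3", 91_000_001, 198_000_000),
            "7p": ("7", 1, 60_000_000),
            "7q": ("7", 60_000_001, 159_000_000),
            "11p": ("11", 1, 53_000_000),
            "11q": ("11", 53_000_001, 135_000_000),
            "16p": ("16", 1, 36_000_000),
            "16q": ("16", 36_000_001, 90_000_000),
            "Xp": ("X", 1, 61_000_000),
            "Xq": ("X", 61_000_001, 155_000_000),
        }
    )


def jup3_fixture_segments() -> list[CopySegment]:
    """SYNTHETIC segment profiles: carcinoma lesions carry 1q+ / 16q-, JP is flat."""
    arms = jup3_arm_table()
    out: list[CopySegment] = []
    for sample in _JUP3_SAMPLES:
        carcinoma = sample != "JuP3-JP"
        for arm, (chrom, start, end) in arms.arms.items():
            log2 = 0.0
            cn_total, cn_minor = 2, 1
            if carcinoma and arm == "1q":
                log2, cn_total, cn_minor = 0.4, 3, 1
            elif carcinoma and arm == "16q":
                log2, cn_total, cn_minor = -0.4, 1, 0
            out.append(CopySegment(sample, chrom, start, end, log2, cn_total, cn_minor))
    return out


def jup3_fixture_purities() -> dict[str, SamplePurity]:
    return {s: SamplePurity(s, p) for s, p in JUP3_PURITY.items()}
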