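"""Domain types and tabular I/O for somatic-call pipelines.

The atomic record is :class:`MutationCall` — one somatic variant observed in
one sample, with tumor/normal read counts and annotations.  Mutations are
matched across samples of a case by :class:`VariantKey` (chrom, pos, ref,
alt); this identity underlies the shared/private distinction used by the
clonality index and the phylogeny.

Coordinate conventions: mutation positions and segment start/end are 1-based
inclusive in all files (MAF convention).  Segment arithmetic elsewhere in the
package converts to half-open internally; this module is the single place
where the file convention is defined.  Chromosome labels are normalized by
stripping a leading ``chr``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("clonkit")

__all__ = [
    "MutationCall",
    "VariantKey",
    "CopySegment",
    "SamplePurity",
    "SignatureCatalog",
    "HotspotList",
    "TableFormatError",
    "EFFECTS",
    "CHANNELS_96",
    "normalize_chrom",
    "chrom_sort_key",
    "read_mutation_table",
    "write_mutation_table",
    "read_segments",
    "write_segments",
    "read_purity_table",
    "write_purity_table",
    "read_signature_catalog",
    "write_signature_catalog",
    "read_hotspot_list",
    "annotate_hotspots",
]


class TableFormatError(ValueError):
    """An input table violates its format contract (missing column, bad row)."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Functional effect classes carried by a mutation record.
EFFECTS = ("nonsynonymous", "synonymous", "truncating", "splice", "other")

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: Canonical 96-channel ordering: the 6 pyrimidine substitution types in
#: alphabetical order, each expanded over the 16 flanking-base contexts in
#: alphabetical order (COSMIC-style labels such as ``A[C>T]G``).
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 32 pyrimidine-centered trinucleotide contexts (central base C or T).
PYRIMIDINE_CONTEXTS = frozenset(
    f"{five}{mid}{three}" for five in _BASES for mid in ("C", "T") for three in _BASES
)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix from a chromosome label."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Canonical chromosome order 1..22, X, Y, then others lexicographically."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    if c == "X":
        return (0, 23, "")
    if c == "Y":
        return (0, 24, "")
    return (1, 0, c)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantKey:
    """Genomic identity of a mutation; equality defines 'the same mutation'."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __lt__(self, other: "VariantKey") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class MutationCall:
    """One somatic variant in one sample, with read counts and annotations.

    ``pop_maf`` and ``context`` may be ``None`` when unavailable; records
    without a context are simply skipped by signature tabulation.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    effect: str = "other"
    t_ref: int = 0
    t_alt: int = 0
    n_ref: int = 0
    n_alt: int = 0
    pop_maf: float | None = None
    context: str | None = None
    hotspot: bool = False

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect class {self.effect!r}")
        for name in ("t_ref", "t_alt", "n_ref", "n_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pop_maf is not None and not 0.0 <= self.pop_maf <= 1.0:
            raise ValueError(f"pop_maf out of [0,1]: {self.pop_maf}")
        if self.context is not None:
            ctx = self.context.upper()
            if len(ctx) != 3 or any(b not in _COMPLEMENT for b in ctx):
                raise ValueError(f"malformed trinucleotide context {self.context!r}")
            # store on the pyrimidine strand
            if ctx not in PYRIMIDINE_CONTEXTS:
                ctx = revcomp_context(ctx)
            self.context = ctx

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_depth(self) -> int:
        return self.t_ref + self.t_alt

    @property
    def normal_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def tumor_vaf(self) -> float | None:
        d = self.tumor_depth
        return self.t_alt / d if d > 0 else None

    @property
    def normal_vaf(self) -> float | None:
        d = self.normal_depth
        return self.n_alt / d if d > 0 else None

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass
class CopySegment:
    """A copy-number segment (1-based inclusive coordinates as read from file)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    cn_total: int | None = None
    cn_minor: int | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if (
            self.cn_total is not None
            and self.cn_minor is not None
            and self.cn_minor > self.cn_total
        ):
            raise ValueError("cn_minor exceeds cn_total")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def half_open(self) -> tuple[int, int]:
        """(start0, end0) with 0-based half-open semantics."""
        return self.start - 1, self.end


@dataclass
class SamplePurity:
    """Tumor purity (and ploidy) for one sample; inputs, never inferred here."""

    sample_id: str
    purity: float
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


@dataclass
class SignatureCatalog:
    """96-channel column-stochastic signature matrix.

    Rows follow :data:`CHANNELS_96`; each column is one signature's channel
    probability vector and sums to 1.
    """

    signature_names: tuple[str, ...]
    matrix: np.ndarray
    channel_labels: tuple[str, ...] = CHANNELS_96

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.signature_names)):
            raise ValueError(
                f"catalog matrix must be 96 x {len(self.signature_names)}, "
                f"got {self.matrix.shape}"
            )
        if tuple(self.channel_labels) != CHANNELS_96:
            raise ValueError("catalog channels must follow the canonical 96 ordering")
        if np.any(self.matrix < 0):
            raise ValueError("catalog entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            bad = [self.signature_names[i] for i in np.where(np.abs(sums - 1) > 1e-8)[0]]
            raise ValueError(f"catalog columns do not sum to 1: {bad}")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)


_CODON_RE = re.compile(r"[A-Za-z*]*?(\d+)")


def _codon_of(protein_change: str) -> str | None:
    """Extract the codon number from a protein change like ``E542K`` → ``542``."""
    m = _CODON_RE.search(protein_change or "")
    return m.group(1) if m else None


@dataclass
class HotspotList:
    """Set of (gene, codon-or-protein-change) hotspot entries.

    Gene matching is case-sensitive; the second element may be either a full
    protein change (``E542K``) or a bare codon number (``542``).
    """

    entries: frozenset[tuple[str, str]] = frozenset()

    def matches(self, gene: str, protein_change: str) -> bool:
        if (gene, protein_change) in self.entries:
            return True
        codon = _codon_of(protein_change)
        return codon is not None and (gene, codon) in self.entries


# ---------------------------------------------------------------------------
# Mutation-table I/O
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "effect",
    "t_ref",
    "t_alt",
    "n_ref",
    "n_alt",
    "pop_maf",
    "context",
    "hotspot",
)

_REQUIRED_MAF_COLUMNS = MUTATION_COLUMNS[:5] + ("t_ref", "t_alt", "n_ref", "n_alt")


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def read_mutation_table(
    path: str | Path,
    dialect: str = "maf_like",
    *,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[MutationCall]:
    """Read somatic mutation calls from a MAF-style TSV or a VCF.

    Rows with unparseable coordinates or alleles are rejected; their line
    numbers are reported in a single warning and the remainder is returned.
    For the ``vcf`` dialect only the first alternate allele of multi-allelic
    records is used (skipped alleles are counted in a warning), and the file
    must carry tumor and normal sample columns with allelic depths (``AD``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maf_like":
        return _read_maf_like(path)
    if dialect == "vcf":
        return _read_vcf(path, tumor_sample, normal_sample)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_maf_like(path: Path) -> list[MutationCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("empty mutation table: %s", path)
            return []
        for col in _REQUIRED_MAF_COLUMNS:
            if col not in reader.fieldnames:
                raise TableFormatError(f"missing required column {col!r} in {path}")
        calls: list[MutationCall] = []
        bad_lines: list[int] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                calls.append(_row_to_call(row))
            except (ValueError, KeyError):
                bad_lines.append(lineno)
        if bad_lines:
            logger.warning(
                "%s: rejected %d unparseable row(s) at line(s) %s",
                path,
                len(bad_lines),
                bad_lines,
            )
        if not calls and not bad_lines:
            logger.warning("mutation table %s contains no records", path)
        return calls


def _row_to_call(row: dict[str, str]) -> MutationCall:
    pop_maf = row.get("pop_maf", "")
    context = row.get("context", "")
    return MutationCall(
        sample_id=row["sample_id"],
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        gene=row.get("gene", "") or "",
        protein_change=row.get("protein_change", "") or "",
        effect=row.get("effect", "") or "other",
        t_ref=int(row["t_ref"]),
        t_alt=int(row["t_alt"]),
        n_ref=int(row["n_ref"]),
        n_alt=int(row["n_alt"]),
        pop_maf=float(pop_maf) if pop_maf not in ("", None, "NA") else None,
        context=context if context not in ("", None, "NA") else None,
        hotspot=str(row.get("hotspot", "")).strip().lower() in ("1", "true", "yes"),
    )


def _read_vcf(path: Path, tumor_sample: str, normal_sample: str) -> list[MutationCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for needed in (tumor_sample, normal_sample):
        if needed not in samples:
            raise TableFormatError(
                f"VCF {path} lacks required sample column {needed!r} "
                f"(has {samples})"
            )
    it = samples.index(tumor_sample)
    inn = samples.index(normal_sample)
    calls: list[MutationCall] = []
    skipped_alleles = 0
    for rec in vcf:
        if not rec.ALT:
            continue
        skipped_alleles += max(0, len(rec.ALT) - 1)
        ad = rec.format("AD")
        if ad is None:
            raise TableFormatError(f"VCF {path} lacks allelic-depth (AD) fields")
        t_ref, t_alt = int(ad[it][0]), int(ad[it][1])
        n_ref, n_alt = int(ad[inn][0]), int(ad[inn][1])
        calls.append(
            MutationCall(
                sample_id=tumor_sample,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                t_ref=t_ref,
                t_alt=t_alt,
                n_ref=n_ref,
                n_alt=n_alt,
            )
        )
    if skipped_alleles:
        logger.warning(
            "%s: used first ALT only; skipped %d additional allele(s)",
            path,
            skipped_alleles,
        )
    return calls


def write_mutation_table(calls: Sequence[MutationCall], path: str | Path) -> None:
    """Write calls as a MAF-style TSV under the fixed column order (round-trip safe)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MUTATION_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.chrom,
                    c.pos,
                    c.ref,
                    c.alt,
                    c.gene,
                    c.protein_change,
                    c.effect,
                    c.t_ref,
                    c.t_alt,
                    c.n_ref,
                    c.n_alt,
                    _fmt_float(c.pop_maf),
                    c.context or "",
                    "true" if c.hotspot else "false",
                ]
            )


# ---------------------------------------------------------------------------
# Segment / purity / catalog / hotspot I/O
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ("sample_id", "chrom", "start", "end", "log2_ratio", "cn_total", "cn_minor")


def read_segments(path: str | Path) -> list[CopySegment]:
    """Read copy-number segments; overlapping segments within a sample/chromosome
    are a format error naming the offending pair."""
    path = Path(path)
    segs: list[CopySegment] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        for col in ("sample_id", "chrom", "start", "end", "log2_ratio"):
            if col not in reader.fieldnames:
                raise TableFormatError(f"missing required column {col!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                cn_total = row.get("cn_total", "")
                cn_minor = row.get("cn_minor", "")
                segs.append(
                    CopySegment(
                        sample_id=row["sample_id"],
                        chrom=row["chrom"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        log2_ratio=float(row["log2_ratio"]),
                        cn_total=int(cn_total) if cn_total not in ("", None, "NA") else None,
                        cn_minor=int(cn_minor) if cn_minor not in ("", None, "NA") else None,
                    )
                )
            except ValueError as exc:
                raise TableFormatError(f"{path} line {lineno}: {exc}") from exc
    _check_segment_overlaps(segs)
    return segs


def _check_segment_overlaps(segs: Iterable[CopySegment]) -> None:
    by_group: dict[tuple[str, str], list[CopySegment]] = {}
    for s in segs:
        by_group.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), group in by_group.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise TableFormatError(
                    f"overlapping segments for sample {sample} chrom {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_segments(segs: Sequence[CopySegment], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SEGMENT_COLUMNS)
        for s in segs:
            writer.writerow(
                [
                    s.sample_id,
                    s.chrom,
                    s.start,
                    s.end,
                    _fmt_float(s.log2_ratio),
                    "" if s.cn_total is None else s.cn_total,
                    "" if s.cn_minor is None else s.cn_minor,
                ]
            )


def read_purity_table(path: str | Path) -> dict[str, SamplePurity]:
    path = Path(path)
    out: dict[str, SamplePurity] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        for col in ("sample_id", "purity"):
            if col not in reader.fieldnames:
                raise TableFormatError(f"missing required column {col!r} in {path}")
        for row in reader:
            ploidy = row.get("ploidy", "")
            out[row["sample_id"]] = SamplePurity(
                sample_id=row["sample_id"],
                purity=float(row["purity"]),
                ploidy=float(ploidy) if ploidy not in ("", None) else 2.0,
            )
    return out


def write_purity_table(purities: dict[str, SamplePurity], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "purity", "ploidy"])
        for p in purities.values():
            writer.writerow([p.sample_id, _fmt_float(p.purity), _fmt_float(p.ploidy)])


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a 96-row, COSMIC-style signature catalog TSV.

    The first column holds channel labels (``A[C>T]G`` form); remaining
    columns are signatures.  Rows may appear in any order and are mapped to
    the canonical channel ordering.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise TableFormatError(
            f"catalog {path} is missing {len(missing)} channel(s), e.g. {sorted(missing)[:3]}"
        )
    df = df.loc[list(CHANNELS_96)]
    return SignatureCatalog(
        signature_names=tuple(df.columns), matrix=df.to_numpy(dtype=float)
    )


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        catalog.matrix,
        index=list(CHANNELS_96),
        columns=list(catalog.signature_names),
    ).to_csv(path, sep="\t", index_label="channel")


def read_hotspot_list(path: str | Path) -> HotspotList:
    """Read a two-column TSV (gene, codon-or-protein-change)."""
    entries = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return HotspotList()
        for row in reader:
            if len(row) < 2:
                continue
            entries.add((row[0], row[1]))
    return HotspotList(frozenset(entries))


def annotate_hotspots(
    calls: Sequence[MutationCall], hotspots: HotspotList
) -> list[MutationCall]:
    """Return copies of the calls with the ``hotspot`` flag set from the list.

    A record is flagged when (gene, protein_change) or (gene, codon) matches
    an entry; no other field changes.
    """
    return [
        replace(c, hotspot=hotspots.matches(c.gene, c.protein_change)) for c in calls
    ]


def revcomp_context(context: str) -> str:
    """Reverse-complement a trinucleotide context string."""
    return "".join(_COMPLEMENT[b] for b in reversed(context))


def channel_of(ref: str, alt: str, context: str) -> str | None:
    """Map an SNV with its trinucleotide context to one of the 96 channels.

    Purine-centered inputs are reverse-complemented onto the pyrimidine
    strand.  Returns ``None`` for indels or malformed contexts.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    # the stored context may sit on either strand; orient it to the pyrimidine ref
    if context[1] != ref:
        context = revcomp_context(context)
        if context[1] != ref:
            return None
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return label if label in _CHANNEL_INDEX else None
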