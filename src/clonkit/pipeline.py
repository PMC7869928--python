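"""Pipeline orchestration: filter → CCF → clonality index → tree → signatures → CNA.

A :class:`PipelineConfig` (loadable from YAML) names the input tables and
stage parameters; :func:`run_pipeline` executes the stages in order, writes
every stage's TSV plus the Newick tree into the output directory, and
returns a :class:`CaseReport` that is also rendered as a human-readable
markdown summary.  All randomness flows from the single config seed, and
identical config + inputs yield identical outputs.  Stage failures are
re-raised with the stage name attached.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import ccf as ccf_mod
from . import clonality as clon_mod
from . import cna as cna_mod
from . import filters as filt_mod
from . import io_model
from . import phylogeny as phylo_mod
from . import signatures as sig_mod

logger = logging.getLogger("clonkit")

__all__ = ["PipelineConfig", "CaseReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Input paths and stage parameters; round-trips through YAML."""

    mutations: str
    purity: str
    output_dir: str
    segments: str | None = None
    catalog: str | None = None
    hotspots: str | None = None
    frequencies: str | None = None
    arm_table: str | None = None
    target_bed: str | None = None
    min_normal_depth: int = 20
    vaf_ratio_min: float = 5.0
    max_pop_maf: float = 0.05
    grid_step: float = 0.01
    n_perm: int = 10_000
    alpha: float = 0.05
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(**data)


@dataclass
class CaseReport:
    """Structured summary of one pipeline run."""

    mutation_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    clonal_hotspots: list[dict[str, Any]] = field(default_factory=list)
    pairwise: list[dict[str, Any]] = field(default_factory=list)
    newick: str = ""
    exposures: dict[str, dict[str, float]] = field(default_factory=dict)
    arm_events: dict[str, list[str]] = field(default_factory=dict)
    fga: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = ["# Case summary", "", "## Per-lesion mutation counts", ""]
        lines.append("| sample | total | nonsynonymous | synonymous |")
        lines.append("|---|---|---|---|")
        for s, c in self.mutation_counts.items():
            lines.append(
                f"| {s} | {c['total']} | {c['nonsynonymous']} | {c['synonymous']} |"
            )
        lines += ["", "## Clonal hotspot drivers", ""]
        if self.clonal_hotspots:
            for h in self.clonal_hotspots:
                lines.append(
                    f"- {h['gene']} {h['protein_change']} in {h['sample_id']} "
                    f"(CCF {h['ccf']:.2f}, clonal={h['clonal']})"
                )
        else:
            lines.append("- none detected")
        lines += ["", "## Pairwise clonality", ""]
        lines.append("| pair | shared | CI | related |")
        lines.append("|---|---|---|---|")
        for p in self.pairwise:
            lines.append(
                f"| {p['sample_a']} vs {p['sample_b']} | {p['n_shared']} "
                f"| {p['ci']:.2f} | {p['related']} |"
            )
        if self.newick:
            lines += ["", "## Phylogeny", "", "```", self.newick, "```"]
        if self.exposures:
            lines += ["", "## Signature exposures", ""]
            names = list(next(iter(self.exposures.values())))
            lines.append("| sample | " + " | ".join(names) + " |")
            lines.append("|" + "---|" * (len(names) + 1))
            for s, e in self.exposures.items():
                lines.append(
                    f"| {s} | " + " | ".join(f"{e[n]:.2f}" for n in names) + " |"
                )
        if self.arm_events or self.fga:
            lines += ["", "## Copy number", ""]
            for s, events in self.arm_events.items():
                ev = ", ".join(events) if events else "none"
                lines.append(f"- {s}: arm events: {ev}; FGA {self.fga.get(s, 0.0):.3f}")
        if self.warnings:
            lines += ["", "## Warnings", ""]
            lines += [f"- {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> CaseReport:
    """Run the full analysis for one case and write all outputs.

    Stages: filtering (with attrition report), CCF estimation and clonal
    classification, pairwise clonality index with permutation null,
    mutation-presence phylogeny, signature exposures and arm-level CNA
    summary.  Stages whose optional inputs are absent are skipped with a
    warning in the report.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = CaseReport()

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    # --- load inputs -------------------------------------------------------
    try:
        stage("load")
        calls = io_model.read_mutation_table(cfg.mutations)
        purities = io_model.read_purity_table(cfg.purity)
        segments = io_model.read_segments(cfg.segments) if cfg.segments else []
        if cfg.hotspots:
            calls = io_model.annotate_hotspots(
                calls, io_model.read_hotspot_list(cfg.hotspots)
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    if not calls:
        report.warnings.append("no input mutations; empty report")
        (outdir / "summary.md").write_text(report.to_markdown())
        return report

    # --- filters -----------------------------------------------------------
    try:
        stage("filter")
        fcfg = filt_mod.FilterConfig(
            min_normal_depth=cfg.min_normal_depth,
            vaf_ratio_min=cfg.vaf_ratio_min,
            max_pop_maf=cfg.max_pop_maf,
            target_regions=filt_mod.read_bed(cfg.target_bed) if cfg.target_bed else None,
        )
        retained, frep = filt_mod.apply_filters(calls, fcfg)
        frep.write_tsv(outdir / "filter_report.tsv")
        io_model.write_mutation_table(retained, outdir / "retained.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc

    by_sample: dict[str, list[io_model.MutationCall]] = {}
    for c in retained:
        by_sample.setdefault(c.sample_id, []).append(c)
    for s, sc in by_sample.items():
        report.mutation_counts[s] = {
            "total": len(sc),
            "nonsynonymous": sum(c.effect in ("nonsynonymous", "truncating", "splice") for c in sc),
            "synonymous": sum(c.effect == "synonymous" for c in sc),
        }

    # --- CCF ---------------------------------------------------------------
    ccf_lookup: dict[tuple[str, io_model.VariantKey], float] = {}
    try:
        stage("ccf")
        results = ccf_mod.estimate_case(retained, purities, segments, cfg.grid_step)
        ccf_mod.write_ccf_table(results, outdir / "ccf.tsv")
        for call, est in results:
            ccf_lookup[(call.sample_id, call.key)] = est.ccf_point
            if call.hotspot and est.clonal:
                report.clonal_hotspots.append(
                    {
                        "sample_id": call.sample_id,
                        "gene": call.gene,
                        "protein_change": call.protein_change,
                        "ccf": est.ccf_point,
                        "clonal": est.clonal,
                    }
                )
    except Exception as exc:  # noqa: BLE001
        raise StageError("ccf", exc) from exc

    # --- clonality index ---------------------------------------------------
    if len(by_sample) >= 2:
        try:
            stage("clonality")
            if cfg.frequencies:
                freqs = clon_mod.read_frequency_table(cfg.frequencies)
            else:
                # A fallback catalog holding only the observed mutations would
                # let the permutation null re-draw them constantly, making
                # chance overlap look common; pad it with rare background
                # entries sized like an exome-wide opportunity space (roughly
                # one rare-variant slot per gene) so null overlap of rare
                # variants is correspondingly rare.
                entries = [
                    clon_mod.MutationFrequency(
                        p=0.02 if c.hotspot else 1e-4,
                        key=c.key,
                        gene=c.gene,
                        protein_change=c.protein_change,
                    )
                    for c in retained
                ]
                entries += [
                    clon_mod.MutationFrequency(
                        p=1e-4,
                        key=io_model.VariantKey("1", 1_000_000_000 + i, "C", "T"),
                        gene=f"BG{i:04d}",
                        protein_change="",
                    )
                    for i in range(20_000)
                ]
                freqs = clon_mod.FrequencyTable(entries)
                report.warnings.append(
                    "no frequency table given; built one from observed mutations "
                    "plus 20000 synthetic background entries"
                )
            pairs = clon_mod.pairwise_clonality(
                by_sample, freqs, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha
            )
            clon_mod.write_clonality_table(pairs, outdir / "clonality.tsv")
            for r in pairs:
                report.pairwise.append(
                    {
                        "sample_a": r.sample_a,
                        "sample_b": r.sample_b,
                        "n_shared": r.M,
                        "ci": r.ci,
                        "related": r.related,
                    }
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("clonality", exc) from exc

        # --- phylogeny -----------------------------------------------------
        try:
            stage("tree")
            pm = phylo_mod.build_presence_matrix(by_sample, ccf=ccf_lookup)
            tree = phylo_mod.infer_tree(pm)
            phylo_mod.write_newick(tree, outdir / "tree.nwk")
            phylo_mod.write_edge_assignments(tree, outdir / "tree_edges.tsv")
            report.newick = phylo_mod.newick_string(tree)
        except Exception as exc:  # noqa: BLE001
            raise StageError("tree", exc) from exc
    else:
        report.warnings.append("single sample: clonality and phylogeny skipped")

    # --- signatures --------------------------------------------------------
    try:
        stage("signatures")
        catalog = (
            io_model.read_signature_catalog(cfg.catalog)
            if cfg.catalog
            else sig_mod.default_catalog()
        )
        exposures = []
        for s, sc in by_sample.items():
            counts = sig_mod.count_channels(sc, sample_id=s)
            if counts.n_mutations == 0:
                report.warnings.append(f"{s}: no attributable SNVs for signatures")
                continue
            exp = sig_mod.fit_exposures(counts, catalog)
            exposures.append(exp)
            report.exposures[s] = {
                n: float(v) for n, v in zip(exp.signature_names, exp.exposures)
            }
            if exp.low_confidence:
                report.warnings.append(
                    f"{s}: signature exposure from only {exp.n_mutations} mutations"
                )
        if exposures:
            sig_mod.write_exposure_table(exposures, outdir / "exposures.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("signatures", exc) from exc

    # --- CNA summary -------------------------------------------------------
    if segments and cfg.arm_table:
        try:
            stage("cna")
            arms = cna_mod.read_arm_table(cfg.arm_table)
            calls_arm = cna_mod.arm_calls(
                segments, arms, cfg.gain_threshold, cfg.loss_threshold
            )
            cna_mod.write_arm_calls(calls_arm, outdir / "arm_calls.tsv")
            for s in sorted({seg.sample_id for seg in segments}):
                events = [
                    f"{c.arm}{'+' if c.call == 'gain' else '-'}"
                    for c in calls_arm
                    if c.sample_id == s and c.call != "neutral"
                ]
                report.arm_events[s] = events
                report.fga[s] = cna_mod.fraction_genome_altered(
                    [seg for seg in segments if seg.sample_id == s],
                    cfg.gain_threshold,
                    cfg.loss_threshold,
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("cna", exc) from exc
    else:
        report.warnings.append("segments or arm table missing: CNA summary skipped")

    (outdir / "summary.md").write_text(report.to_markdown())
    return report
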