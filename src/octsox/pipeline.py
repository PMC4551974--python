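"""End-to-end orchestration: scan -> background -> link -> compare.

One declarative config drives the whole analysis and every output is
written as TSV next to a run manifest (parameters, seed, input checksums)
so that a run can be reproduced byte-for-byte from the manifest plus the
inputs.  Stages are independent: disabling the expression stage leaves
the scan and linking outputs untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .motifs import default_motifs, load_motifs
from .peaks import (
    extract_windows,
    positional_distribution,
    read_peaks,
    scan_windows,
    select_background,
)
from .expression import (
    assign_peaks_to_genes,
    assignments_frame,
    average_condition,
    class_gene_sets,
    compare_conditions,
    read_expression,
    read_tss,
    scatter_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Parameter defaults are the values of the analysis this package
    re-implements: 100-bp summit windows, a 50 kb TSS radius, a
    background floor of 5 expression units and a 2-fold threshold.
    """

    genome: str | None = None
    peaks: str | None = None
    tss: str | None = None
    expression: str | None = None
    motifs: str | None = None  # None -> packaged composite words
    outdir: str = "octsox_out"

    width: int = 100
    strands: str = "both"
    max_distance: int = 50_000
    floor: float = 5.0
    threshold: float = 2.0
    gc_tolerance: float = 0.02
    n_background: int = 0
    bin_width: int = 5
    seed: int = 0
    summit_from_midpoint: bool = False

    sample_groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    reference_condition: str | None = None

    def params(self) -> dict:
        d = dataclasses.asdict(self)
        d["sample_groups"] = {k: list(v) for k, v in self.sample_groups.items()}
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file into a validated :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return validate_config(PipelineConfig(**raw))


def validate_config(config: PipelineConfig, require_genome: bool = True) -> PipelineConfig:
    """Validate every invariant at once; raise with the full error list."""
    errors: list[str] = []
    if config.width <= 0 or config.width % 2:
        errors.append(f"width must be a positive even number, got {config.width}")
    if config.strands not in ("forward", "both"):
        errors.append(f"strands must be 'forward' or 'both', got {config.strands!r}")
    if config.max_distance < 0:
        errors.append("max_distance must be non-negative")
    if config.floor <= 0:
        errors.append("floor must be positive")
    if config.threshold <= 1:
        errors.append(f"fold threshold must exceed 1, got {config.threshold}")
    if not 0 < config.gc_tolerance <= 1:
        errors.append("gc_tolerance must lie in (0, 1]")
    if config.n_background < 0:
        errors.append("n_background must be non-negative")
    if config.bin_width <= 0 or (config.width % config.bin_width):
        errors.append(f"bin_width must divide width, got {config.bin_width}")
    if require_genome:
        for name in ("genome", "peaks"):
            if getattr(config, name) is None:
                errors.append(f"required path {name!r} is missing")
            elif not Path(getattr(config, name)).exists():
                errors.append(f"{name} path does not exist: {getattr(config, name)}")
    if config.expression is not None and not config.sample_groups:
        errors.append("expression stage enabled but sample_groups is empty")
    if config.sample_groups and config.reference_condition is not None:
        if config.reference_condition not in config.sample_groups:
            errors.append(
                f"reference_condition {config.reference_condition!r} not in sample_groups"
            )
    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    return config


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _open_genome(path: str):
    import pyfaidx

    return pyfaidx.Fasta(path, sequence_always_upper=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage and write the report bundle.

    Returns a dict with the in-memory results (count table, distributions,
    assignments, comparisons, summary) and the output paths.  Any stage
    failure is re-raised with the stage name prepended.
    """
    validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motifs = load_motifs(config.motifs) if config.motifs else default_motifs()
    results: dict = {}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        stage("scan")
        genome = _open_genome(config.genome)
        peaks = read_peaks(config.peaks, summit_from_midpoint=config.summit_from_midpoint)
        windows = extract_windows(genome, peaks, config.width)
        logger.info("scan: %d peaks, %d scannable windows", len(peaks), len(windows))
        table = scan_windows(windows, motifs, strands=config.strands)
        results["counts"] = table
        table.to_frame().to_csv(outdir / "counts.tsv", sep="\t", index=False)
        table.hits_frame().to_csv(outdir / "hits.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage scan: {exc}") from exc

    try:
        stage("background")
        bg_table = None
        if config.n_background > 0:
            bg_windows = select_background(
                genome, peaks, config.n_background, width=config.width,
                gc_tolerance=config.gc_tolerance, seed=config.seed,
            )
            bg_table = scan_windows(bg_windows, motifs, strands=config.strands)
        dist_frames = []
        for m in motifs:
            dist = positional_distribution(
                table.hits[m.name], width=config.width, bin_width=config.bin_width,
                motif_name=m.name,
            )
            if bg_table is not None:
                bg_dist = positional_distribution(
                    bg_table.hits[m.name], width=config.width,
                    bin_width=config.bin_width, motif_name=m.name,
                )
                dist.background_counts = bg_dist.counts
            dist_frames.append(dist.to_frame())
        results["background"] = bg_table
        dist_df = pd.concat(dist_frames, ignore_index=True)
        results["distribution"] = dist_df
        dist_df.to_csv(outdir / "distribution.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage background: {exc}") from exc

    if config.tss is not None:
        try:
            stage("link")
            tss = read_tss(config.tss)
            peak_classes: dict[str, set[str]] = {}
            for m_name, hs in table.hits.items():
                for h in hs:
                    peak_classes.setdefault(h.peak_id, set()).add(m_name)
            assignments = assign_peaks_to_genes(
                peaks, tss, peak_classes, max_distance=config.max_distance
            )
            results["assignments"] = assignments
            results["gene_sets"] = class_gene_sets(assignments)
            assignments_frame(assignments).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
            logger.info("link: %d assignments, %d genes in >=1 class",
                        len(assignments), len(set().union(*results["gene_sets"].values()) if results["gene_sets"] else set()))
        except Exception as exc:
            raise RuntimeError(f"stage link: {exc}") from exc

    if config.expression is not None:
        try:
            stage("compare")
            if "assignments" not in results:
                raise ValueError("expression stage requires a TSS table for linking")
            expr = read_expression(config.expression)
            means = average_condition(expr, config.sample_groups)
            ref = config.reference_condition or list(config.sample_groups)[0]
            summaries = []
            scatter_frames = []
            comparisons = {}
            for cond in config.sample_groups:
                if cond == ref:
                    continue
                comps = compare_conditions(
                    means[cond], means[ref], floor=config.floor, threshold=config.threshold
                )
                comparisons[cond] = comps
                for cls_name, genes in sorted(results["gene_sets"].items()):
                    present = {g for g in genes if g in means.index}
                    df, counts = scatter_table(present, comps)
                    df.insert(0, "condition", cond)
                    df.insert(1, "motif_class", cls_name)
                    scatter_frames.append(df)
                    summaries.append(
                        {"condition": cond, "motif_class": cls_name, "n_genes": len(present), **counts}
                    )
            results["comparisons"] = comparisons
            summary_df = pd.DataFrame(summaries)
            results["summary"] = summary_df
            summary_df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
            if scatter_frames:
                pd.concat(scatter_frames, ignore_index=True).to_csv(
                    outdir / "scatter.tsv", sep="\t", index=False
                )
        except Exception as exc:
            raise RuntimeError(f"stage compare: {exc}") from exc

    manifest = {
        "octsox_version": __version__,
        "parameters": config.params(),
        "inputs": {
            name: {"path": getattr(config, name), "md5": _md5(getattr(config, name))}
            for name in ("genome", "peaks", "tss", "expression", "motifs")
            if getattr(config, name) is not None
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    ranked = sorted(table.totals.items(), key=lambda kv: kv[1], reverse=True)
    lines = [
        "Composite motif abundance in summit windows",
        f"windows scanned: {table.n_windows} (width {config.width} bp, strands {config.strands})",
        "",
        "rank\tmotif\ttotal_occurrences\twindows_with_hit",
    ]
    for rank, (name, total) in enumerate(ranked, start=1):
        lines.append(f"{rank}\t{name}\t{total}\t{table.windows_with_hit[name]}")
    if "summary" in results and len(results["summary"]):
        lines += ["", "fold-change classification (vs reference):",
                  results["summary"].to_string(index=False)]
    report = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(report)
    results["report"] = report
    results["outdir"] = outdir
    return results
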