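"""Synthetic genomes, peak sets, TSS tables and expression matrices.

Every pipeline stage is testable without external downloads: this module
plants concrete expansions of the composite motif words into summit
windows of a random genome, links a configurable fraction of genes to
motif-bearing summits, and simulates linear-scale expression with planted
fold effects plus multiplicative log-normal noise.  Ground truth for every
planting is emitted alongside the data.

In *strict* mode the genome is rejection-sampled so that the only motif
occurrences anywhere are the planted ones; scan counts then recover the
planting counts exactly.  In non-strict mode chance occurrences remain at
the analytic background rate.

The default configuration mirrors the study conditions this package
re-implements: 3,798 summit windows of 100 bp with 554 Hoxb1-like, 47
Utf1-like and 26 Fgf4-like plantings, a 50 kb TSS linking radius, a
background floor of 5 expression units and a 2-fold change threshold,
with reference/mutant replicate counts of 2/2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    DegenerateMotif,
    default_motifs,
    encode,
    reverse_complement,
    scan_sequence,
)
from .peaks import Peak
from .expression import TSSRecord

__all__ = [
    "GeneratorConfig",
    "PlantedMotif",
    "SyntheticTruth",
    "generate_genome",
    "plant_peaks",
    "generate_tss",
    "generate_expression",
    "generate_dataset",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedMotif:
    peak_id: str
    motif_name: str
    offset: int  # 0-based within the summit window
    strand: str
    expansion: str  # concrete sequence matching the class pattern


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generators, keyed for recovery tests."""

    planted: dict[str, PlantedMotif | None] = field(default_factory=dict)
    gene_links: dict[str, list[str]] = field(default_factory=dict)
    gene_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def planted_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pm in self.planted.values():
            if pm is not None:
                counts[pm.motif_name] = counts.get(pm.motif_name, 0) + 1
        return counts


@dataclass
class GeneratorConfig:
    """All knobs for one reproducible synthetic dataset."""

    n_peaks: int = 3798
    plant_counts: Mapping[str, int] = field(
        default_factory=lambda: {"Hoxb1-like": 554, "Utf1-like": 47, "Fgf4-like": 26}
    )
    width: int = 100
    gap: int = 100  # motif-free spacing between adjacent windows
    gc: float = 0.5
    strict: bool = True
    tail: int = 120_000  # peak-free genome tail hosting unlinked genes
    n_genes: int = 300
    link_fraction: float = 0.7
    max_distance: int = 50_000
    effect_fraction: float = 0.25
    fold_range: tuple[float, float] = (2.5, 6.0)
    noise_sd: float = 0.1
    replicates: Mapping[str, int] = field(
        default_factory=lambda: {"SWT": 2, "S113": 2, "S98_102": 3}
    )
    reference_condition: str = "SWT"
    floor: float = 5.0
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie strictly between 0 and 1")
        if any(c < 0 for c in self.plant_counts.values()):
            raise ValueError("plant counts must be non-negative")
        if sum(self.plant_counts.values()) > self.n_peaks:
            raise ValueError("cannot plant more motifs than peaks")
        if self.reference_condition not in self.replicates:
            raise ValueError("replicates must include the reference condition")

    @property
    def genome_length(self) -> int:
        return self.n_peaks * (self.width + self.gap) + self.tail


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_base_probs(gc))


def generate_genome(
    length: int, gc: float = 0.5, seed: int = 0, chrom: str = "chr1"
) -> dict[str, str]:
    """An i.i.d. random genome with P(G)+P(C) = gc, split evenly.

    Returns a mapping chromosome name -> sequence.  Seeded and
    reproducible: the same arguments always give the same sequence.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    return {chrom: _random_bases(rng, length, gc).tobytes().decode("ascii")}


def _scrub_motifs(
    arr: np.ndarray, motifs: Sequence[DegenerateMotif], rng: np.random.Generator, gc: float
) -> None:
    """Resample bases until no motif occurs anywhere on either strand."""
    seq_view = arr  # uint8 ASCII
    for _ in range(50):
        dirty = False
        seq = seq_view.tobytes().decode("ascii")
        for m in motifs:
            for h in scan_sequence(m, seq, strands="both"):
                seq_view[h.offset : h.offset + m.length] = _random_bases(rng, m.length, gc)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("failed to scrub chance motif occurrences from genome")


def _sample_expansion(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    """One concrete sequence drawn uniformly over the pattern's expansions."""
    return "".join(sorted(s)[rng.integers(len(s))] for s in motif.allowed)


def plant_peaks(
    genome: dict[str, str],
    config: GeneratorConfig,
    motifs: Sequence[DegenerateMotif] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Peak], dict[str, str], SyntheticTruth]:
    """Write planted motif expansions into evenly spaced summit windows.

    Each planted peak receives one uniformly sampled concrete expansion of
    its class pattern at a random in-window offset and strand (a
    minus-strand planting writes the reverse complement).  In strict mode
    the whole genome is first scrubbed of chance occurrences and every
    planted window is rejection-sampled until scanning it (plus a
    motif-length flank) finds exactly the planted hit and nothing else.

    Returns the peak list, the modified genome and the truth table.
    """
    if motifs is None:
        motifs = default_motifs()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    motif_by_name = {m.name: m for m in motifs}
    for name in config.plant_counts:
        if name not in motif_by_name:
            raise KeyError(f"plant_counts references unknown motif {name!r}")

    chrom = config.chrom
    arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8).copy()
    width, gap = config.width, config.gap
    slot = width + gap
    if config.n_peaks * slot > arr.size:
        raise ValueError("genome too short for the requested number of peaks")

    if config.strict:
        _scrub_motifs(arr, motifs, rng, config.gc)

    # class label per peak, shuffled
    labels: list[str | None] = []
    for name, count in config.plant_counts.items():
        labels.extend([name] * count)
    labels.extend([None] * (config.n_peaks - len(labels)))
    labels = [labels[i] for i in rng.permutation(len(labels))]

    lmax = max(m.length for m in motifs)
    peaks: list[Peak] = []
    truth = SyntheticTruth()
    for i, label in enumerate(labels):
        win_start = i * slot + gap // 2
        win_end = win_start + width
        summit = win_start + width // 2
        peak_id = f"peak_{i:05d}"
        peaks.append(Peak(peak_id=peak_id, chrom=chrom, start=win_start, end=win_end, summit=summit))
        if label is None:
            truth.planted[peak_id] = None
            continue
        m = motif_by_name[label]
        expansion = _sample_expansion(m, rng)
        offset = int(rng.integers(0, width - m.length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        written = expansion if strand == "+" else reverse_complement(expansion)
        for attempt in range(200):
            arr[win_start + offset : win_start + offset + m.length] = np.frombuffer(
                written.encode("ascii"), dtype=np.uint8
            )
            if not config.strict:
                break
            lo = max(0, win_start - (lmax - 1))
            hi = min(arr.size, win_end + (lmax - 1))
            region = arr[lo:hi].tobytes().decode("ascii")
            hits = [
                (mm.name, lo + h.offset, h.strand)
                for mm in motifs
                for h in scan_sequence(mm, region, strands="both")
            ]
            if hits == [(m.name, win_start + offset, strand)]:
                break
            # chance occurrence created at a junction: resample the
            # window's non-planted bases (and the offset) and try again
            offset = int(rng.integers(0, width - m.length + 1))
            fresh = _random_bases(rng, width, config.gc)
            fresh[offset : offset + m.length] = np.frombuffer(written.encode("ascii"), dtype=np.uint8)
            arr[win_start:win_end] = fresh
        else:
            raise RuntimeError(f"could not plant {label} in {peak_id} within the attempt budget")
        truth.planted[peak_id] = PlantedMotif(
            peak_id=peak_id, motif_name=label, offset=offset, strand=strand, expansion=expansion
        )
    return peaks, {chrom: arr.tobytes().decode("ascii")}, truth


def generate_tss(
    peaks: Sequence[Peak],
    truth: SyntheticTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[TSSRecord]:
    """Place gene TSSs: a ``link_fraction`` of genes within the linking
    radius of a motif-bearing summit, the rest in the peak-free genome
    tail beyond it.

    Updates ``truth.gene_links`` with the intended peak of every linked
    gene.  Raises when the tail is too short to host unlinked genes.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    motif_peaks = [p for p in peaks if truth.planted.get(p.peak_id) is not None]
    n_linked = int(round(config.link_fraction * config.n_genes))
    if n_linked and not motif_peaks:
        raise ValueError("cannot link genes: no motif-bearing peaks planted")
    last_summit = max((p.summit for p in peaks), default=0)
    tail_lo = last_summit + config.max_distance + 1
    tail_hi = config.genome_length - 1
    if config.n_genes - n_linked > 0 and tail_hi - tail_lo < 1000:
        raise ValueError("genome tail too small to host unlinked genes")
    records: list[TSSRecord] = []
    for g in range(config.n_genes):
        gene_id = f"gene_{g:04d}"
        if g < n_linked:
            p = motif_peaks[rng.integers(len(motif_peaks))]
            delta = int(rng.integers(-config.max_distance, config.max_distance + 1))
            tss = min(max(p.summit + delta, 0), tail_lo - 1)
            truth.gene_links[gene_id] = [p.peak_id]
        else:
            tss = int(rng.integers(tail_lo, tail_hi + 1))
            truth.gene_links[gene_id] = []
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(TSSRecord(gene_id=gene_id, chrom=config.chrom, tss=tss, strand=strand))
    return records


def generate_expression(
    tss: Sequence[TSSRecord],
    truth: SyntheticTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Linear-scale expression with planted fold effects and noise.

    Baselines are drawn log-uniformly in [2^5, 2^10] (well above the
    background floor).  An ``effect_fraction`` of motif-linked genes is
    given a fold effect drawn from ``fold_range`` (direction random) in
    one randomly chosen non-reference condition; all samples then receive
    multiplicative log-normal noise with standard deviation ``noise_sd``
    in natural-log units.  Updates ``truth.gene_effects``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    conds = list(config.replicates)
    alt_conds = [c for c in conds if c != config.reference_condition]
    linked = [r.gene_id for r in tss if truth.gene_links.get(r.gene_id)]
    n_eff = int(round(config.effect_fraction * len(linked)))
    affected = [linked[i] for i in rng.permutation(len(linked))[:n_eff]]
    lo, hi = config.fold_range
    if lo < 1 or hi < lo:
        raise ValueError("fold_range must satisfy 1 <= lo <= hi")
    for gene in affected:
        fold = float(rng.uniform(lo, hi))
        if rng.random() < 0.5:
            fold = 1.0 / fold
        cond = alt_conds[rng.integers(len(alt_conds))] if alt_conds else config.reference_condition
        truth.gene_effects[gene] = {cond: fold}

    columns = [f"{c}_{r + 1}" for c in conds for r in range(config.replicates[c])]
    data = np.empty((len(tss), len(columns)))
    for gi, rec in enumerate(tss):
        baseline = 2.0 ** rng.uniform(5, 10)
        effects = truth.gene_effects.get(rec.gene_id, {})
        ci = 0
        for c in conds:
            mean = baseline * effects.get(c, 1.0)
            for _ in range(config.replicates[c]):
                noise = np.exp(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 1.0
                data[gi, ci] = mean * noise
                ci += 1
    if (data <= 0).any():
        raise ValueError("generated non-positive expression value")
    return pd.DataFrame(data, index=[r.gene_id for r in tss], columns=columns).rename_axis("gene_id")


def generate_dataset(
    config: GeneratorConfig, outdir: str | Path | None = None
) -> dict[str, object]:
    """Run all generators off one config; optionally write files.

    Returns a dict with keys ``genome`` (chrom -> str), ``peaks``,
    ``tss``, ``expression`` (DataFrame), ``truth`` and, when ``outdir``
    is given, ``paths``.  Identical configs produce byte-identical
    outputs.
    """
    motifs = default_motifs()
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config.genome_length, config.gc, seed=config.seed, chrom=config.chrom)
    peaks, genome, truth = plant_peaks(genome, config, motifs=motifs, rng=rng)
    tss = generate_tss(peaks, truth, config)
    expr = generate_expression(tss, truth, config)
    out: dict[str, object] = {
        "genome": genome, "peaks": peaks, "tss": tss, "expression": expr, "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "peaks": outdir / "peaks.tsv",
            "tss": outdir / "tss.tsv",
            "expression": outdir / "expression.tsv",
            "truth_peaks": outdir / "truth_peaks.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
        }
        write_fasta(genome, paths["genome"])
        pd.DataFrame(
            [(p.chrom, p.start, p.end, p.peak_id, p.summit) for p in peaks]
        ).to_csv(paths["peaks"], sep="\t", header=False, index=False)
        pd.DataFrame(
            [(r.gene_id, r.chrom, r.tss, r.strand) for r in tss],
            columns=["gene_id", "chrom", "tss", "strand"],
        ).to_csv(paths["tss"], sep="\t", index=False)
        expr.to_csv(paths["expression"], sep="\t")
        pd.DataFrame(
            [
                (pid, pm.motif_name, pm.offset, pm.strand, pm.expansion)
                for pid, pm in truth.planted.items()
                if pm is not None
            ],
            columns=["peak_id", "motif", "offset", "strand", "expansion"],
        ).to_csv(paths["truth_peaks"], sep="\t", index=False)
        pd.DataFrame(
            [
                (
                    g,
                    ",".join(truth.gene_links.get(g, [])),
                    ";".join(f"{c}:{f:.6g}" for c, f in truth.gene_effects.get(g, {}).items()),
                )
                for g in (r.gene_id for r in tss)
            ],
            columns=["gene_id", "linked_peaks", "effects"],
        ).to_csv(paths["truth_genes"], sep="\t", index=False)
        out["paths"] = paths
    return out


def write_fasta(genome: Mapping[str, str], path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
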