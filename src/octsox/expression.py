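"""Peak-to-gene linking and fold-change classification of expression.

Motif-bearing peaks are assigned to genes whose transcription start site
(TSS) lies within a maximum summit-to-TSS distance (50 kb by default,
boundary-inclusive, strand-agnostic).  Per-gene condition means are taken
on the linear scale, raised to a background floor (5 expression units by
default), and classified up / down / unchanged against a fold threshold
(2-fold by default).  No statistical test is applied: classification is
purely fold-change based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import Peak

__all__ = [
    "TSSRecord",
    "GeneMotifAssignment",
    "ConditionComparison",
    "read_tss",
    "read_expression",
    "assign_peaks_to_genes",
    "class_gene_sets",
    "average_condition",
    "compare_conditions",
    "scatter_table",
    "assignments_frame",
]


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: TSS must be >= 0")


@dataclass(frozen=True)
class GeneMotifAssignment:
    """A gene linked to a peak by summit-to-TSS distance.

    ``motif_classes`` lists the composite classes with at least one
    occurrence in the peak's summit window (possibly empty for
    motif-free peaks).
    """

    gene_id: str
    peak_id: str
    distance: int
    motif_classes: frozenset[str]


@dataclass(frozen=True)
class ConditionComparison:
    """Floored condition means and the resulting fold-change class."""

    gene_id: str
    mean_a: float
    mean_b: float
    ratio: float
    fc_class: str
    log2_a: float
    log2_b: float


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table: gene_id, chrom, tss, strand (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: TSS table needs columns {sorted(required)}")
    strand = df["strand"] if "strand" in df.columns else "+"
    return [
        TSSRecord(gene_id=str(r.gene_id), chrom=str(r.chrom), tss=int(r.tss),
                  strand=str(getattr(r, "strand", "+")))
        for r in df.itertuples(index=False)
    ]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a linear-scale expression matrix (gene rows, sample columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: expression values must be non-negative (linear scale)")
    return df


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    tss: Sequence[TSSRecord],
    peak_motif_classes: Mapping[str, frozenset[str] | set[str]],
    max_distance: int = 50_000,
    confidence_filter: Callable[[Peak], bool] | None = None,
) -> list[GeneMotifAssignment]:
    """Assign every qualifying peak to every gene within ``max_distance``.

    Distance is |summit - TSS|, absolute and boundary-inclusive; gene
    strand is ignored.  A peak may serve several genes and a gene may
    collect several peaks.  ``confidence_filter`` defaults to pass-all
    (the high-confidence criterion of the source peak set is not
    restated here, so confidence is pluggable).
    """
    if not tss:
        raise ValueError("TSS table is empty")
    if confidence_filter is not None:
        peaks = [p for p in peaks if confidence_filter(p)]
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for ps in by_chrom.values():
        ps.sort(key=lambda p: p.summit)
    out: list[GeneMotifAssignment] = []
    for rec in tss:
        ps = by_chrom.get(rec.chrom, [])
        summits = np.array([p.summit for p in ps])
        if summits.size == 0:
            continue
        lo = np.searchsorted(summits, rec.tss - max_distance, side="left")
        hi = np.searchsorted(summits, rec.tss + max_distance, side="right")
        for p in ps[lo:hi]:
            out.append(
                GeneMotifAssignment(
                    gene_id=rec.gene_id,
                    peak_id=p.peak_id,
                    distance=abs(p.summit - rec.tss),
                    motif_classes=frozenset(peak_motif_classes.get(p.peak_id, frozenset())),
                )
            )
    return out


def class_gene_sets(assignments: Iterable[GeneMotifAssignment]) -> dict[str, set[str]]:
    """Map each motif class to the genes with >=1 assigned peak of it.

    Classes are not mutually exclusive: one gene can appear in several
    sets, and a motif-free assignment contributes to none.
    """
    sets: dict[str, set[str]] = {}
    for a in assignments:
        for cls in a.motif_classes:
            sets.setdefault(cls, set()).add(a.gene_id)
    return sets


def average_condition(
    matrix: pd.DataFrame, sample_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Arithmetic per-gene mean on the linear scale, per condition.

    Raises ``KeyError`` naming any sample absent from the matrix.
    """
    means = {}
    for cond, samples in sample_groups.items():
        missing = [s for s in samples if s not in matrix.columns]
        if missing:
            raise KeyError(f"condition {cond!r}: samples not in matrix: {missing}")
        means[cond] = matrix[list(samples)].mean(axis=1)
    return pd.DataFrame(means)


def compare_conditions(
    means_a: pd.Series,
    means_b: pd.Series,
    floor: float = 5.0,
    threshold: float = 2.0,
) -> list[ConditionComparison]:
    """Classify per-gene fold change of condition A against reference B.

    Each mean is first raised to ``floor`` if below it (values under the
    floor are treated as background), then ``ratio = a / b`` is classed
    up if ratio >= threshold, down if ratio <= 1/threshold, else
    unchanged.  log2 values are computed from the floored means.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if (means_a < 0).any() or (means_b < 0).any():
        raise ValueError("negative expression value")
    genes = means_a.index.intersection(means_b.index)
    out = []
    for g in genes:
        a = max(float(means_a[g]), floor)
        b = max(float(means_b[g]), floor)
        ratio = a / b
        if ratio >= threshold:
            cls = "up"
        elif ratio <= 1.0 / threshold:
            cls = "down"
        else:
            cls = "unchanged"
        out.append(
            ConditionComparison(
                gene_id=str(g), mean_a=a, mean_b=b, ratio=ratio, fc_class=cls,
                log2_a=float(np.log2(a)), log2_b=float(np.log2(b)),
            )
        )
    return out


def scatter_table(
    gene_set: Iterable[str], comparisons: Sequence[ConditionComparison]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict comparisons to a gene set; return rows plus class counts.

    The table carries (mean_b, mean_a, fc_class) per gene -- the data
    behind a pairwise scatter plot; rendering is left to the caller.
    An empty gene set gives an empty table with zero counts; genes
    absent from the comparisons are an error.
    """
    gene_set = set(gene_set)
    by_gene = {c.gene_id: c for c in comparisons}
    missing = sorted(gene_set - by_gene.keys())
    if missing:
        raise KeyError(f"genes not present in comparisons: {missing}")
    rows = [
        (g, by_gene[g].mean_b, by_gene[g].mean_a, by_gene[g].ratio, by_gene[g].fc_class)
        for g in sorted(gene_set)
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "mean_ref", "mean_alt", "ratio", "fc_class"])
    counts = {cls: int((df["fc_class"] == cls).sum()) for cls in ("up", "down", "unchanged")}
    return df, counts


def assignments_frame(assignments: Sequence[GeneMotifAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.gene_id, a.peak_id, a.distance, ",".join(sorted(a.motif_classes)))
            for a in assignments
        ],
        columns=["gene_id", "peak_id", "distance", "motif_classes"],
    )
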