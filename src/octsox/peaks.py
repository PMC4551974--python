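"""Summit-centred window extraction, motif counting and background matching.

ChIP-seq peaks are consumed as given (BED convention, 0-based half-open,
with an absolute summit position).  Each peak contributes one fixed-width
window centred on its summit -- 100 bp by default -- and motif occurrences
are counted inside those windows.  A GC- and length-matched background set
can be sampled from the same genome, excluding peak windows, to put the
positional distributions in context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .motifs import DegenerateMotif, MotifHit, encode, scan_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Window",
    "MotifCountTable",
    "PositionalDistribution",
    "read_peaks",
    "extract_window",
    "extract_windows",
    "scan_windows",
    "scan_peaks",
    "positional_distribution",
    "select_background",
    "gc_fraction",
]


@dataclass(frozen=True)
class Peak:
    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"peak {self.peak_id}: start must be < end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.peak_id}: summit outside [start, end)")


@dataclass(frozen=True)
class Window:
    """A summit-centred, fixed-width genomic window and its sequence."""

    peak_id: str
    chrom: str
    win_start: int
    win_end: int
    seq: str

    @property
    def width(self) -> int:
        return self.win_end - self.win_start


@dataclass
class MotifCountTable:
    """Per-class occurrence totals, motif-positive window counts and hits."""

    n_windows: int
    totals: dict[str, int]
    windows_with_hit: dict[str, int]
    hits: dict[str, list[MotifHit]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": list(self.totals),
                "total_occurrences": [self.totals[m] for m in self.totals],
                "windows_with_hit": [self.windows_with_hit[m] for m in self.totals],
                "n_windows": self.n_windows,
            }
        )

    def hits_frame(self) -> pd.DataFrame:
        rows = [
            (h.peak_id, h.motif_name, h.offset, h.summit_offset, h.strand, h.matched_seq)
            for hs in self.hits.values()
            for h in hs
        ]
        return pd.DataFrame(
            rows, columns=["peak_id", "motif", "offset", "summit_offset", "strand", "matched_seq"]
        )


@dataclass
class PositionalDistribution:
    motif_name: str
    bin_edges: np.ndarray
    counts: np.ndarray
    background_counts: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        bg = (
            self.background_counts
            if self.background_counts is not None
            else np.zeros_like(self.counts)
        )
        return pd.DataFrame(
            {
                "motif": self.motif_name,
                "bin_lo": self.bin_edges[:-1].astype(int),
                "bin_hi": self.bin_edges[1:].astype(int),
                "count": self.counts,
                "background_count": bg,
            }
        )


def read_peaks(path: str | Path, summit_from_midpoint: bool = False) -> list[Peak]:
    """Read a BED-like peak table.

    Columns: chrom, start, end, peak_id[, summit].  ``summit`` is an
    absolute 0-based position; when the column is absent (or
    ``summit_from_midpoint`` is set) the interval midpoint is used.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: need at least 4 columns (chrom, start, end, peak_id)")
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end, peak_id = str(row[0]), int(row[1]), int(row[2]), str(row[3])
        if df.shape[1] >= 5 and not summit_from_midpoint:
            summit = int(row[4])
        else:
            summit = (start + end) // 2
        peaks.append(Peak(peak_id=peak_id, chrom=chrom, start=start, end=end, summit=summit))
    return peaks


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] upper-cased.

    ``genome`` may be a pyfaidx.Fasta or a plain mapping chrom -> str.
    """
    try:
        rec = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in genome") from None
    if isinstance(rec, str):
        return rec[start:end].upper()
    return str(rec[start:end]).upper()


def _chrom_len(genome, chrom: str) -> int:
    rec = genome[chrom]
    return len(rec)


def extract_window(genome, peak: Peak, width: int = 100) -> Window | None:
    """Extract the ``width``-bp window centred on the peak summit.

    Returns None (with a logged warning) when the window would run past a
    chromosome boundary: windows are skipped rather than truncated so that
    every scanned window has identical length.  An unknown chromosome is
    an error.
    """
    if width % 2:
        raise ValueError("window width must be even")
    half = width // 2
    win_start = peak.summit - half
    win_end = peak.summit + half
    clen = _chrom_len(genome, peak.chrom)
    if win_start < 0 or win_end > clen:
        logger.warning(
            "peak %s: window [%d, %d) outside chromosome %s (length %d); skipped",
            peak.peak_id, win_start, win_end, peak.chrom, clen,
        )
        return None
    seq = _fetch(genome, peak.chrom, win_start, win_end)
    return Window(peak_id=peak.peak_id, chrom=peak.chrom, win_start=win_start, win_end=win_end, seq=seq)


def extract_windows(genome, peaks: Sequence[Peak], width: int = 100) -> list[Window]:
    windows = [extract_window(genome, p, width) for p in peaks]
    return [w for w in windows if w is not None]


def scan_windows(
    windows: Sequence[Window],
    motifs: Sequence[DegenerateMotif],
    strands: str = "both",
) -> MotifCountTable:
    """Count motif occurrences per class over pre-extracted windows."""
    if not windows:
        raise ValueError("no scannable windows")
    totals = {m.name: 0 for m in motifs}
    with_hit = {m.name: 0 for m in motifs}
    hits: dict[str, list[MotifHit]] = {m.name: [] for m in motifs}
    for w in windows:
        for m in motifs:
            hs = scan_sequence(m, w.seq, strands=strands, peak_id=w.peak_id)
            totals[m.name] += len(hs)
            if hs:
                with_hit[m.name] += 1
            hits[m.name].extend(hs)
    return MotifCountTable(n_windows=len(windows), totals=totals, windows_with_hit=with_hit, hits=hits)


def scan_peaks(
    genome,
    peaks: Sequence[Peak],
    motifs: Sequence[DegenerateMotif],
    width: int = 100,
    strands: str = "both",
) -> MotifCountTable:
    """Extract summit windows and count composite motifs per class.

    Both the total occurrence count and the number of motif-positive
    windows are reported for every class; boundary-clipped peaks are
    skipped with a warning.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    windows = extract_windows(genome, peaks, width)
    if not windows:
        raise ValueError("no scannable windows (all peaks clipped at chromosome boundaries?)")
    return scan_windows(windows, motifs, strands=strands)


def positional_distribution(
    hits: Iterable[MotifHit],
    width: int = 100,
    bin_width: int = 5,
    motif_name: str = "",
) -> PositionalDistribution:
    """Histogram of hit-centre positions relative to the window centre.

    Bins are half-open over [-width/2, +width/2), except the last bin
    which is closed, matching numpy's histogram convention.
    """
    if width % bin_width:
        raise ValueError(f"bin_width {bin_width} must divide width {width}")
    half = width // 2
    offsets = np.array([h.summit_offset for h in hits], dtype=float)
    if offsets.size and (np.abs(offsets) > half).any():
        raise ValueError("summit_offset outside [-width/2, +width/2]")
    edges = np.arange(-half, half + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(offsets, bins=edges)
    return PositionalDistribution(motif_name=motif_name, bin_edges=edges, counts=counts)


def gc_fraction(seq: str) -> float:
    enc = encode(seq)
    return float(((enc == 1) | (enc == 2)).mean())


def select_background(
    genome,
    peaks: Sequence[Peak],
    n_regions: int,
    width: int = 100,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    max_attempts_factor: int = 2000,
) -> list[Window]:
    """Seeded GC- and length-matched background windows avoiding peaks.

    Candidate windows are drawn uniformly over the genome (chromosomes
    weighted by length), rejected if they overlap any peak summit window,
    contain a non-ACGT base, or have a GC fraction farther than
    ``gc_tolerance`` from the pooled GC of the peak windows.  A tolerance
    of 1.0 reduces to uniform non-overlapping sampling.  Raises if the
    attempt budget (``max_attempts_factor * n_regions``) is exhausted,
    reporting the shortfall.
    """
    rng = np.random.default_rng(seed)
    peak_windows = extract_windows(genome, peaks, width)
    if not peak_windows:
        raise ValueError("no peak windows to match background against")
    target_gc = gc_fraction("".join(w.seq for w in peak_windows))

    trees: dict[str, IntervalTree] = {}
    for w in peak_windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.win_start, w.win_end)

    chroms = sorted(genome.keys()) if hasattr(genome, "keys") else [r.name for r in genome]
    lengths = np.array([_chrom_len(genome, c) for c in chroms], dtype=float)
    usable = lengths - width
    if (usable <= 0).all():
        raise ValueError("genome too short to host background windows")
    weights = np.clip(usable, 0, None)
    weights /= weights.sum()

    chosen: list[Window] = []
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    budget = max_attempts_factor * n_regions
    for _ in range(budget):
        if len(chosen) >= n_regions:
            break
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        start = int(rng.integers(0, int(usable[ci]) + 1))
        end = start + width
        if chrom in trees and trees[chrom].overlap(start, end):
            continue
        if occupied[chrom].overlap(start, end):
            continue
        seq = _fetch(genome, chrom, start, end)
        if (encode(seq) == 4).any():
            continue
        if abs(gc_fraction(seq) - target_gc) > gc_tolerance:
            continue
        occupied[chrom].addi(start, end)
        chosen.append(Window(peak_id=f"bg_{len(chosen)}", chrom=chrom, win_start=start, win_end=end, seq=seq))
    if len(chosen) < n_regions:
        raise RuntimeError(
            f"could only place {len(chosen)} of {n_regions} background windows "
            f"within the attempt budget (target GC {target_gc:.3f} +/- {gc_tolerance})"
        )
    return chosen
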