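"""Degenerate DNA motif model and exact word matching.

The OCT4-SOX2 composite elements scanned throughout this package are
degenerate IUPAC "words": each position of the pattern admits a fixed
subset of {A, C, G, T} and a subject sequence matches only if every
position falls inside its subset.  There is no scoring, no mismatch
tolerance and no position-weight matrix -- a window either contains the
word or it does not.  Three composite classes are bundled as defaults:

* ``Hoxb1-like``  ``HWTTSWNATGYWDWD``   (SOX and OCT half-sites juxtaposed)
* ``Utf1-like``   ``HWTTSWNATGYWDGD``   (one position stricter: W -> G)
* ``Fgf4-like``   ``HWTTSWNNNNATGYWDWD`` (three-nucleotide spacer)

The Hoxb1- and Utf1-like words are provably disjoint (their position-14
subsets do not intersect), so a concrete 15-mer can never be counted in
both classes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "DegenerateMotif",
    "MotifHit",
    "compile_iupac",
    "reverse_complement",
    "matches_at",
    "scan_sequence",
    "patterns_disjoint",
    "expected_hit_rate",
    "load_motifs",
    "default_motifs",
]

#: IUPAC nucleotide codes mapped to the base subsets they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte -> base index lookup; anything that is not an upper/lowercase ACGT
# maps to column 4, which no motif position ever allows.
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as base indices (A,C,G,T -> 0..3, other -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class DegenerateMotif:
    """A named IUPAC pattern compiled to per-position allowed-base sets.

    ``allowed_matrix`` is an (L, 5) boolean table over base indices; the
    fifth column (ambiguous/unknown subject base) is always False so that
    windows containing N can never match.
    """

    name: str
    pattern: str
    allowed: tuple[frozenset[str], ...]
    allowed_matrix: np.ndarray = field(repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.pattern)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a scanned window.

    ``matched_seq`` is always the window subsequence read on the forward
    strand, even for minus-strand hits.  ``summit_offset`` is the signed
    distance from the window centre to the hit's centre nucleotide
    (``offset + L//2 - window_length//2``).
    """

    peak_id: str
    motif_name: str
    offset: int
    strand: str
    matched_seq: str
    summit_offset: int


def compile_iupac(pattern: str, name: str = "") -> DegenerateMotif:
    """Compile an IUPAC degenerate pattern into a :class:`DegenerateMotif`.

    Raises ``ValueError`` naming the first offending position (1-based) if
    the pattern is empty or contains a non-IUPAC character.  Input case is
    ignored; the stored pattern is upper-case.
    """
    if not pattern:
        raise ValueError("motif pattern must be non-empty")
    pattern = pattern.upper()
    allowed: list[frozenset[str]] = []
    for pos, ch in enumerate(pattern, start=1):
        try:
            allowed.append(IUPAC_SETS[ch])
        except KeyError:
            raise ValueError(
                f"invalid IUPAC symbol {ch!r} at position {pos} of pattern {pattern!r}"
            ) from None
    matrix = np.zeros((len(pattern), 5), dtype=bool)
    for i, s in enumerate(allowed):
        for b in s:
            matrix[i, _BASE_INDEX[b]] = True
    return DegenerateMotif(
        name=name or pattern, pattern=pattern, allowed=tuple(allowed), allowed_matrix=matrix
    )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string (case-insensitive).

    Ambiguity codes are rejected: subject sequences handed to the scanner
    are expected to be concrete.
    """
    seq = seq.upper()
    if any(c not in _BASE_INDEX for c in seq):
        bad = next(c for c in seq if c not in _BASE_INDEX)
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def matches_at(motif: DegenerateMotif, seq: str, offset: int) -> bool:
    """True iff ``seq[offset:offset+L]`` matches the motif position-wise.

    Positions holding a non-ACGT base never match.  An offset that does not
    leave room for the full motif is an error, not a non-match.
    """
    L = motif.length
    if offset < 0 or offset + L > len(seq):
        raise ValueError(
            f"offset {offset} out of range for motif length {L} on sequence of length {len(seq)}"
        )
    window = encode(seq[offset : offset + L])
    return bool(motif.allowed_matrix[np.arange(L), window].all())


def _forward_offsets(motif: DegenerateMotif, enc: np.ndarray) -> np.ndarray:
    """All offsets where the motif matches the encoded forward strand."""
    L = motif.length
    n = enc.size
    if n < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    ok = motif.allowed_matrix[np.arange(L), windows].all(axis=1)
    return np.flatnonzero(ok)


def scan_sequence(
    motif: DegenerateMotif,
    seq: str,
    strands: str = "both",
    peak_id: str = "",
    window_length: int | None = None,
) -> list[MotifHit]:
    """Scan every offset of ``seq`` for the motif.

    Overlapping occurrences are all reported.  A minus-strand hit at offset
    ``k`` means the reverse complement of ``seq[k:k+L]`` matches.  Hits are
    sorted by (offset, strand) with '+' before '-' and are unique per
    (offset, strand).  A sequence shorter than the motif yields no hits.

    ``window_length`` only affects the ``summit_offset`` bookkeeping and
    defaults to ``len(seq)``.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = seq.upper()
    L = motif.length
    wlen = len(seq) if window_length is None else window_length
    enc = encode(seq)
    found: list[tuple[int, str]] = [(int(k), "+") for k in _forward_offsets(motif, enc)]
    if strands == "both":
        # complement of index i is 3 - i; unknown (4) stays unknown
        rc = np.where(enc == 4, 4, 3 - enc)[::-1].astype(np.uint8)
        for k in _forward_offsets(motif, rc):
            found.append((len(seq) - L - int(k), "-"))
    found = sorted(set(found), key=lambda t: (t[0], t[1]))
    return [
        MotifHit(
            peak_id=peak_id,
            motif_name=motif.name,
            offset=k,
            strand=s,
            matched_seq=seq[k : k + L],
            summit_offset=k + L // 2 - wlen // 2,
        )
        for k, s in found
    ]


def patterns_disjoint(a: DegenerateMotif, b: DegenerateMotif) -> bool:
    """True iff no concrete sequence can match both equal-length patterns.

    This holds exactly when some position has an empty intersection of
    allowed sets.  Unequal lengths are rejected: length-heterogeneous
    classes cannot collide at the same offset anyway and must be handled
    by the caller.
    """
    if a.length != b.length:
        raise ValueError(
            f"patterns_disjoint requires equal lengths ({a.name}: {a.length}, {b.name}: {b.length})"
        )
    return any(not (sa & sb) for sa, sb in zip(a.allowed, b.allowed))


def expected_hit_rate(motif: DegenerateMotif, base_probs: Sequence[float]) -> float:
    """Probability that one random offset matches on one strand.

    Under an i.i.d. background with per-base probabilities ``base_probs``
    (ordered A, C, G, T) the match probability is the product over
    positions of the summed probabilities of the allowed bases.
    """
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must be four non-negative values summing to 1")
    rate = 1.0
    for s in motif.allowed:
        rate *= sum(p[_BASE_INDEX[b]] for b in s)
    return float(rate)


def load_motifs(path: str | Path) -> list[DegenerateMotif]:
    """Read motifs from a two-column TSV (name, IUPAC pattern).

    Lines starting with '#' and blank lines are skipped.
    """
    motifs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        motifs.append(compile_iupac(parts[1], name=parts[0]))
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def default_motifs() -> list[DegenerateMotif]:
    """The three packaged OCT4-SOX2 composite words."""
    ref = importlib.resources.files("octsox").joinpath("data/composite_motifs.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_motifs(path)
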