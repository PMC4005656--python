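"""Per-promoter sequence properties.

All features are computed on the coding strand of a window centered on the
promoter anchor (default half-width 100, length 201): G+C percentage, CpG
observed/expected ratio, best TATA-box match under a uniform or
per-promoter background model, base-shuffled controls and upstream
cross-species identity.  Non-ACGT letters are N and are excluded from all
composition denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cage_io import BASES, IdentityTrack, PositionCountMatrix, clean_sequence

__all__ = [
    "SequenceWindow",
    "MotifScore",
    "extract_window",
    "reverse_complement",
    "gc_percent",
    "cpg_oe",
    "pcm_log_odds",
    "tata_best_score",
    "shuffle_window",
    "identity_upstream",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODE = {b: i for i, b in enumerate(BASES)}  # A0 C1 G2 T3; N -> 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceWindow:
    """A coding-strand sequence of length 2w+1 centered on an anchor."""

    sequence: str
    contig: str
    anchor: int
    strand: str
    w: int

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.w + 1:
            raise ValueError("window length must be 2w+1")


def extract_window(
    genome: Mapping[str, str], contig: str, anchor: int, strand: str, w: int = 100
) -> SequenceWindow:
    """Extract the +/- w window around an anchor on its coding strand.

    Minus-strand windows are reverse-complemented so that position w is the
    anchor base and smaller indices are upstream.  Bases beyond the contig
    ends are padded with N.
    """
    seq = genome[contig]
    lo, hi = anchor - w, anchor + w + 1
    core = seq[max(lo, 0) : min(hi, len(seq))]
    padded = "N" * max(0, -lo) + core + "N" * max(0, hi - len(seq))
    padded = clean_sequence(padded)
    if strand == "-":
        padded = reverse_complement(padded)
    return SequenceWindow(sequence=padded, contig=contig, anchor=anchor, strand=strand, w=w)


def _seq_of(window: SequenceWindow | str) -> str:
    return window.sequence if isinstance(window, SequenceWindow) else clean_sequence(window)


def gc_percent(window: SequenceWindow | str) -> float:
    """Percent G+C among non-N bases."""
    seq = _seq_of(window)
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        raise ValueError("window has no non-N bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def cpg_oe(window: SequenceWindow | str, method: str = "gc") -> float:
    """Observed/expected CpG dinucleotides.

    Observed is the overlapping count of "CG" on the coding strand.  The
    default expectation derives from %G+C alone: (L-1) * (gc/2)^2, with
    L the number of non-N bases (so appending N runs leaves the ratio
    unchanged).  ``method="cxg"`` instead uses the product of the actual C
    and G frequencies, (L-1) * (nC/L) * (nG/L).  Returns NaN when the
    window contains no G or C.
    """
    seq = _seq_of(window)
    n_c = seq.count("C")
    n_g = seq.count("G")
    length = sum(seq.count(b) for b in BASES)
    if length < 2:
        raise ValueError("window too short for dinucleotides")
    observed = seq.count("CG")
    if method == "gc":
        gc = (n_c + n_g) / length
        expected = (length - 1) * (gc / 2.0) ** 2
    elif method == "cxg":
        expected = (length - 1) * (n_c / length) * (n_g / length)
    else:
        raise ValueError(f"unknown method {method!r}")
    if expected == 0.0:
        return float("nan")
    return observed / expected


@dataclass(frozen=True)
class MotifScore:
    """Best motif match in a window: log2-odds score, offset, background."""

    score: float
    offset: int
    background: str


def pcm_log_odds(
    pcm: PositionCountMatrix, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-position log2-odds scores s_k(x) from a position count matrix.

    s_k(x) = log2[(c_kx + 1) / (sum_y c_ky + 4)] - log2(b_x), i.e. +1
    pseudocount per cell against the given background base probabilities
    (uniform 1/4 by default).  Returns shape (K, 5); the fifth column is
    the score assigned to N, the column minimum (a conservative choice so
    that runs of N never create a spurious best match).
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    c = pcm.counts.astype(float)
    probs = (c + 1.0) / (c.sum(axis=1, keepdims=True) + 4.0)
    lo = np.log2(probs) - np.log2(background)
    return np.column_stack([lo, lo.min(axis=1)])


def _window_background(seq: str) -> np.ndarray:
    """Base frequencies of the window with +1 pseudocount per base."""
    counts = np.array([seq.count(b) for b in BASES], dtype=float)
    return (counts + 1.0) / (counts.sum() + 4.0)


def tata_best_score(
    window: SequenceWindow | str,
    pcm: PositionCountMatrix,
    background: str = "uniform",
) -> MotifScore:
    """Highest-scoring motif match in the window, coding strand only.

    The best match is reported no matter how weak, so scores from windows
    lacking a true TATA box reflect the best random match.  ``background``
    is either "uniform" (b_x = 1/4) or "per_promoter" (the window's own
    base frequencies with +1 pseudocount per base); a per-promoter
    background down-weights TATA-like matches in AT-rich windows.
    """
    seq = _seq_of(window)
    K = pcm.length
    if len(seq) < K:
        raise ValueError("window shorter than motif")
    if background == "uniform":
        lo = pcm_log_odds(pcm)
    elif background == "per_promoter":
        lo = pcm_log_odds(pcm, _window_background(seq))
    else:
        raise ValueError(f"unknown background {background!r}")
    codes = np.fromiter((_CODE.get(ch, 4) for ch in seq), dtype=np.int8, count=len(seq))
    windows = np.lib.stride_tricks.sliding_window_view(codes, K)
    scores = lo[np.arange(K), windows].sum(axis=1)
    best = int(np.argmax(scores))
    return MotifScore(score=float(scores[best]), offset=best, background=background)


def shuffle_window(
    window: SequenceWindow | str, rng: np.random.Generator
) -> SequenceWindow | str:
    """Uniform random permutation of the window's bases.

    Base composition is conserved exactly, so shuffled windows serve as
    composition-matched controls for motif scores.
    """
    seq = _seq_of(window)
    shuffled = "".join(np.array(list(seq))[rng.permutation(len(seq))])
    if isinstance(window, SequenceWindow):
        return SequenceWindow(
            sequence=shuffled,
            contig=window.contig,
            anchor=window.anchor,
            strand=window.strand,
            w=window.w,
        )
    return shuffled


def identity_upstream(
    track: IdentityTrack, contig: str, anchor: int, strand: str, span: int = 100
) -> float:
    """Mean per-base identity over the span immediately 5' of the anchor.

    Strand-aware: for '+' the span is [anchor - span, anchor); for '-' it
    is (anchor, anchor + span].  The anchor base itself is excluded.
    Unaligned (uncovered) bases count in the denominator, so a promoter
    with no alignment scores 0%.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    if strand == "+":
        return track.mean_identity(contig, anchor - span, anchor)
    return track.mean_identity(contig, anchor + 1, anchor + span + 1)
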