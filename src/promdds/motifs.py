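"""IUPAC consensus scanning and lightweight positional consensus extraction.

This stands in for a full motif-discovery suite: it scans promoter windows
for degenerate consensus patterns (e.g. the TATA-box around −32…−24) and
extracts a simple consensus by sliding a fixed-width frame over a window,
scoring each frame by information content against a zero-order background
estimated from the input sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dds import position_to_index
from .sequences import PromoterRecord

#: the 15 IUPAC nucleotide codes → allowed bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_CODES.items()}


class MotifError(ValueError):
    """Invalid pattern or scan geometry."""


@dataclass(frozen=True)
class IupacConsensus:
    """A degenerate nucleotide consensus (default TATA-box widths are 6–8)."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise MotifError("empty consensus pattern")
        bad = [c for c in pat if c not in IUPAC_CODES]
        if bad:
            raise MotifError(f"invalid IUPAC character(s) {bad} in {pat!r}")

    @property
    def width(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifPresenceReport:
    """How many sequences carry the motif anywhere in the search window."""

    n_sequences: int
    n_with_match: int
    window: tuple[int, int]
    pattern: str

    @property
    def fraction(self) -> float:
        return self.n_with_match / self.n_sequences if self.n_sequences else 0.0


def _as_seqs(sequences: Iterable) -> list[str]:
    return [
        s.sequence if isinstance(s, PromoterRecord) else str(s).upper()
        for s in sequences
    ]


def iupac_match(pattern: str | IupacConsensus, seq: str, offset: int) -> bool:
    """True iff ``seq[offset:offset+width]`` matches the consensus exactly."""
    cons = pattern if isinstance(pattern, IupacConsensus) else IupacConsensus(pattern)
    seq = seq.upper()
    if offset < 0 or offset + cons.width > len(seq):
        raise MotifError(
            f"offset {offset} with width {cons.width} exceeds sequence of length {len(seq)}"
        )
    return all(b in IUPAC_CODES[c] for c, b in zip(cons.pattern, seq[offset:]))


def motif_presence(
    sequences: Iterable,
    pattern: str | IupacConsensus,
    window: tuple[int, int] = (-32, -24),
    upstream: int = 80,
) -> MotifPresenceReport:
    """Count sequences matching the consensus with its 5′ end anywhere in
    ``window`` (TSS-relative, inclusive); each sequence counts at most once."""
    cons = pattern if isinstance(pattern, IupacConsensus) else IupacConsensus(pattern)
    seqs = _as_seqs(sequences)
    if not seqs:
        raise ValueError("no sequences to scan")
    lo, hi = window
    offsets = [position_to_index(p, upstream) for p in range(lo, hi + 1) if p != 0]
    seq_len = len(seqs[0])
    if min(offsets) < 0 or max(offsets) + cons.width > seq_len:
        raise MotifError(
            f"window {window} (width {cons.width}) does not fit in {seq_len}-nt sequences"
        )
    n_match = sum(
        1 for s in seqs if any(iupac_match(cons, s, off) for off in offsets)
    )
    return MotifPresenceReport(
        n_sequences=len(seqs), n_with_match=n_match, window=window, pattern=cons.pattern
    )


def _column_code(freqs: np.ndarray, coverage: float = 0.75) -> str:
    """Smallest IUPAC code whose bases cover ≥ ``coverage`` of the column."""
    order = np.argsort(freqs)[::-1]
    bases, total = [], 0.0
    for i in order:
        bases.append("ACGT"[i])
        total += freqs[i]
        if total >= coverage:
            break
    return _SET_TO_CODE[frozenset(bases)]


def consensus_from_window(
    sequences: Iterable,
    window: tuple[int, int] = (-40, -15),
    width: int = 6,
    upstream: int = 80,
    coverage: float = 0.75,
) -> tuple[IupacConsensus, int, pd.DataFrame]:
    """Extract a width-``width`` consensus from the most informative frame.

    Slides the frame over all 5′ starts inside ``window`` and keeps the one
    maximizing summed column information content relative to a zero-order
    (mononucleotide) background estimated from the input.  Returns the
    consensus, its TSS-relative 5′ start, and per-column base frequencies.
    """
    seqs = _as_seqs(sequences)
    if len(seqs) < 2:
        raise ValueError("consensus extraction needs at least two sequences")
    seq_len = len(seqs[0])
    if any(len(s) != seq_len for s in seqs):
        raise ValueError("sequences must share one length")
    arr = np.array([list(s) for s in seqs])
    base_idx = {b: i for i, b in enumerate("ACGT")}
    # zero-order background from the whole input
    bg = np.array([np.mean(arr == b) for b in "ACGT"])
    if bg.sum() == 0:
        raise ValueError("degenerate input: no ACGT bases")
    bg = np.clip(bg / bg.sum(), 1e-9, None)

    lo, hi = window
    starts = [p for p in range(lo, hi + 1) if p != 0]
    best: tuple[float, int, np.ndarray] | None = None
    for start in starts:
        j0 = position_to_index(start, upstream)
        if j0 < 0 or j0 + width > seq_len:
            continue
        freqs = np.zeros((width, 4))
        for k in range(width):
            col = arr[:, j0 + k]
            for b, i in base_idx.items():
                freqs[k, i] = np.mean(col == b)
        p = np.clip(freqs, 1e-9, None)
        ic = float(np.sum(p * np.log2(p / bg)))
        if best is None or ic > best[0]:
            best = (ic, start, freqs)
    if best is None:
        raise MotifError(f"no width-{width} frame fits inside window {window}")
    _, start, freqs = best
    pattern = "".join(_column_code(freqs[k], coverage) for k in range(width))
    freq_df = pd.DataFrame(freqs, columns=list("ACGT"))
    freq_df.insert(0, "position", [p for p in range(start, start + width + 1) if p != 0][:width])
    return IupacConsensus(pattern), start, freq_df
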