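"""Synthetic promoter and toy-genome generators.

These fixtures emulate the statistical structure of archaeal core
promoters at desk scale: i.i.d. background at a chosen GC content with
degenerate sequence elements (TATA-box, BRE, PPE) planted at fixed
TSS-relative positions with chosen probabilities.  They exist so every
downstream stage — encoding, classification, explanation, scanning — can
be exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dds import CORE_PROMOTER_LENGTH, position_to_index
from .motifs import IUPAC_CODES
from .sequences import PromoterRecord, reverse_complement


@dataclass(frozen=True)
class PlantedElement:
    """A degenerate element planted at a fixed TSS-relative 5′ position."""

    pattern: str
    position: int  # TSS-relative 5' start, no-zero convention
    probability: float = 1.0

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        bad = [c for c in pat if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {bad} in {pat!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"planting probability {self.probability} outside [0, 1]")

    @property
    def width(self) -> int:
        return len(self.pattern)


def default_elements() -> tuple[PlantedElement, ...]:
    """Archaeal-style core-promoter architecture: a purine BRE at −33/−32,
    an AT-rich TATA-box at −31…−26, and an AT PPE at −11/−10."""
    return (
        PlantedElement("RR", -33, 0.5),
        PlantedElement("TTTAWA", -31, 0.8),
        PlantedElement("WW", -11, 0.5),
    )


@dataclass(frozen=True)
class PromoterModelSpec:
    """Geometry and composition of the synthetic promoter model."""

    length: int = CORE_PROMOTER_LENGTH
    gc_fraction: float = 0.5
    elements: tuple[PlantedElement, ...] = field(default_factory=default_elements)
    upstream: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        spans = []
        for el in self.elements:
            j0 = position_to_index(el.position, self.upstream)
            j1 = j0 + el.width
            if j0 < 0 or j1 > self.length:
                raise ValueError(
                    f"element {el.pattern!r} at {el.position} falls outside the "
                    f"{self.length}-nt window"
                )
            spans.append((j0, j1, el.pattern))
        spans.sort()
        for (a0, a1, pa), (b0, b1, pb) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"planted elements {pa!r} and {pb!r} overlap")


def _sample_background(rng: np.random.Generator, n: int, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=(n, length), p=probs)


def _sample_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        sorted(IUPAC_CODES[c])[rng.integers(len(IUPAC_CODES[c]))] for c in pattern
    )


def generate_promoters(
    spec: PromoterModelSpec,
    n: int,
    seed: int | None = None,
    id_prefix: str = "syn",
) -> list[PromoterRecord]:
    """Draw ``n`` synthetic promoter records (label 1, origin synthetic).

    Background bases are i.i.d. at the spec's GC fraction; each element is
    planted independently with its probability, each IUPAC code sampled
    uniformly over its allowed bases.  Deterministic under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mat = _sample_background(rng, n, spec.length, spec.gc_fraction)
    for el in spec.elements:
        j0 = position_to_index(el.position, spec.upstream)
        for i in range(n):
            if rng.random() < el.probability:
                mat[i, j0 : j0 + el.width] = list(_sample_iupac(rng, el.pattern))
    return [
        PromoterRecord(
            id=f"{id_prefix}_{i:05d}",
            sequence="".join(mat[i]),
            label=1,
            origin="synthetic",
        )
        for i in range(n)
    ]


def generate_annotated_genome(
    n_genes: int,
    intergenic_length: int,
    spec: PromoterModelSpec,
    seed: int = 0,
    contig_id: str = "synthetic_contig",
) -> tuple[dict[str, str], pd.DataFrame, list[PromoterRecord]]:
    """Build a single-contig toy genome with ``n_genes`` embedded promoters.

    Each gene's −80…+20 window is a :func:`generate_promoters` draw embedded
    verbatim (reverse-complemented for minus-strand genes, alternating
    strands), separated by i.i.d. intergenic filler.  Returns the contig,
    a 1-based TSS table that round-trips through window extraction, and the
    planted windows themselves.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if intergenic_length < 0:
        raise ValueError("intergenic length must be non-negative")
    downstream = spec.length - spec.upstream
    if downstream < 1:
        raise ValueError("window geometry leaves no downstream bases")
    rng = np.random.default_rng(seed)
    windows = generate_promoters(spec, n_genes, seed=int(rng.integers(2**31)), id_prefix="gene")
    parts: list[str] = []
    rows = []
    pos = 0  # 0-based running coordinate
    for i, win in enumerate(windows):
        filler = "".join(_sample_background(rng, 1, intergenic_length, spec.gc_fraction)[0]) if intergenic_length else ""
        parts.append(filler)
        pos += len(filler)
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            parts.append(win.sequence)
            tss_1based = pos + spec.upstream + 1
        else:
            parts.append(reverse_complement(win.sequence))
            tss_1based = pos + downstream
        rows.append(
            {"contig": contig_id, "tss_1based": tss_1based, "strand": strand, "id": win.id}
        )
        pos += spec.length
    # trailing filler so minus-strand upstream regions never touch the edge
    parts.append("".join(_sample_background(rng, 1, max(intergenic_length, 1), spec.gc_fraction)[0]))
    genome = {contig_id: "".join(parts)}
    return genome, pd.DataFrame(rows), windows
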