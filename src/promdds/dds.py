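"""DNA duplex-stability (DDS) encoding of nucleotide sequences.

A sequence of length L is slid over with two-nucleotide windows and each
dinucleotide stack is replaced by its nearest-neighbor free energy
(kcal/mol, negative = more stable duplex).  The canonical core-promoter
window of 100 nt (−80…+20 around the TSS, no position 0) therefore maps
to a fixed-length vector of 99 features, one per dinucleotide, each
labeled by the TSS-relative coordinate of its 5′ base.

The free-energy table is data, not code: the default shipped table is the
unified nearest-neighbor ΔG°37 parameter set, and any 16-entry table can
be substituted from a plain config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in DNA_ALPHABET for b in DNA_ALPHABET)

#: length of the canonical core-promoter window (−80…+20, TSS = +1)
CORE_PROMOTER_LENGTH = 100
#: number of dinucleotide features for the canonical window
N_CORE_FEATURES = CORE_PROMOTER_LENGTH - 1

DEFAULT_TABLE_RESOURCE = "unified_nn_dg37.txt"


class TableFormatError(ValueError):
    """A DDS table file could not be parsed or validated."""


class EncodingError(ValueError):
    """A sequence could not be encoded (bad base, bad length)."""


class DimensionError(ValueError):
    """Inputs with incompatible shapes/lengths."""


# ---------------------------------------------------------------------------
# coordinate convention: TSS-relative positions skip 0; the core promoter
# spans -80..-1, +1..+20 and feature j carries the 5' position of its
# dinucleotide (-80..+19 skipping 0).
# ---------------------------------------------------------------------------

def tss_positions(start: int, n: int) -> np.ndarray:
    """``n`` consecutive TSS-relative coordinates from ``start``, skipping 0.

    >>> tss_positions(-3, 5).tolist()
    [-3, -2, -1, 1, 2]
    """
    if start == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    out = np.empty(n, dtype=int)
    p = start
    for i in range(n):
        out[i] = p
        p += 1
        if p == 0:
            p = 1
    return out


def core_feature_positions(upstream: int = 80) -> np.ndarray:
    """Position labels of the 99 canonical core-promoter features."""
    return tss_positions(-upstream, N_CORE_FEATURES)


def position_to_index(position: int, upstream: int = 80) -> int:
    """Map a TSS-relative coordinate (no zero) to a 0-based window index."""
    if position == 0:
        raise ValueError("position 0 does not exist in the no-zero convention")
    return position + upstream if position < 0 else position + upstream - 1


@dataclass(frozen=True)
class DinucleotideTable:
    """Free energies (kcal/mol) for the 16 dinucleotide stacks."""

    values: dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(DINUCLEOTIDES):
            missing = sorted(set(DINUCLEOTIDES) - keys)
            extra = sorted(keys - set(DINUCLEOTIDES))
            raise TableFormatError(
                f"table must define exactly the 16 ACGT dinucleotides; "
                f"missing={missing}, extra={extra}"
            )
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise TableFormatError(f"non-finite value for {k!r}: {v}")

    def __getitem__(self, dinucleotide: str) -> float:
        return self.values[dinucleotide]

    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    def as_lookup(self) -> dict[str, float]:
        return dict(self.values)


def load_dds_table(path: str | Path) -> DinucleotideTable:
    """Parse a DDS table config file (``AA: -1.00`` lines, ``#`` comments)."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise TableFormatError(f"{path}:{lineno}: expected 'XY: value', got {raw!r}")
        key, _, val = line.partition(":")
        key = key.strip().upper()
        if len(key) != 2 or any(b not in DNA_ALPHABET for b in key):
            raise TableFormatError(
                f"{path}:{lineno}: {key!r} is not an ACGT dinucleotide"
            )
        if key in values:
            raise TableFormatError(f"{path}:{lineno}: duplicate entry for {key!r}")
        try:
            values[key] = float(val.strip())
        except ValueError as exc:
            raise TableFormatError(
                f"{path}:{lineno}: non-numeric value {val.strip()!r}"
            ) from exc
    if len(values) != 16:
        raise TableFormatError(
            f"{path}: expected 16 dinucleotide entries, found {len(values)}"
        )
    return DinucleotideTable(values=values, source_label=str(path))


def default_table() -> DinucleotideTable:
    """The shipped unified nearest-neighbor ΔG°37 table."""
    with resources.as_file(
        resources.files("promdds.data").joinpath(DEFAULT_TABLE_RESOURCE)
    ) as p:
        table = load_dds_table(p)
    return DinucleotideTable(values=table.values, source_label="unified NN dG37 (shipped)")


@dataclass(frozen=True)
class FeatureVector:
    """DDS features of one sequence plus their TSS-relative position labels."""

    values: np.ndarray
    position_labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "position_labels", np.asarray(self.position_labels, dtype=int))
        if self.values.shape != self.position_labels.shape:
            raise DimensionError("values and position_labels differ in length")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FeatureMatrix:
    """n × m DDS feature matrix with shared position labels and row ids."""

    values: np.ndarray
    position_labels: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "position_labels", np.asarray(self.position_labels, dtype=int))
        object.__setattr__(self, "ids", tuple(self.ids))
        if self.values.ndim != 2:
            raise DimensionError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.ids):
            raise DimensionError("row count does not match number of ids")
        if self.values.shape[0] and self.values.shape[1] != self.position_labels.size:
            raise DimensionError("column count does not match position labels")

    @property
    def n_sequences(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(p) for p in self.position_labels])
        df.insert(0, "id", list(self.ids))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Profile:
    """Mean DDS per position (kcal/mol) over a set of sequences."""

    values: np.ndarray
    position_labels: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "position_labels", np.asarray(self.position_labels, dtype=int))
        if self.values.size != self.position_labels.size:
            raise DimensionError("profile values and position labels differ in length")
        if self.n_sequences < 1:
            raise ValueError("a profile needs at least one contributing sequence")

    def peak_position(self) -> int:
        """TSS-relative position of the least-negative (least stable) mean."""
        return int(self.position_labels[int(np.argmax(self.values))])


def encode_sequence(
    seq: str,
    table: DinucleotideTable | None = None,
    tss_offset: int = -80,
    ambiguous: str = "strict",
) -> FeatureVector:
    """Encode ``seq`` as DDS features via two-nucleotide sliding windows.

    ``tss_offset`` is the TSS-relative coordinate of the first base (no-zero
    convention).  ``ambiguous`` is ``"strict"`` (reject non-ACGT bases) or
    ``"mean"`` (substitute the table mean for any dinucleotide touching an
    ambiguous base).
    """
    if table is None:
        table = default_table()
    seq = seq.upper()
    L = len(seq)
    if L < 2:
        raise EncodingError(f"sequence of length {L} has no dinucleotides")
    lookup = table.as_lookup()
    mean_value = table.mean()
    values = np.empty(L - 1, dtype=float)
    for j in range(L - 1):
        dinuc = seq[j : j + 2]
        try:
            values[j] = lookup[dinuc]
        except KeyError:
            if ambiguous == "mean":
                values[j] = mean_value
            else:
                bad = j if seq[j] not in DNA_ALPHABET else j + 1
                raise EncodingError(
                    f"ambiguous base {seq[bad]!r} at sequence position {bad}"
                ) from None
    labels = tss_positions(tss_offset, L - 1)
    return FeatureVector(values=values, position_labels=labels)


def encode_batch(
    records: Sequence,
    table: DinucleotideTable | None = None,
    tss_offset: int = -80,
    ambiguous: str = "strict",
) -> FeatureMatrix:
    """Encode equal-length :class:`PromoterRecord`-like objects row by row."""
    if table is None:
        table = default_table()
    records = list(records)
    if not records:
        return FeatureMatrix(
            values=np.empty((0, 0)), position_labels=np.empty(0, dtype=int), ids=()
        )
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        ref = len(records[0].sequence)
        offenders = [r.id for r in records if len(r.sequence) != ref]
        raise DimensionError(
            f"mixed sequence lengths {sorted(lengths)}; offending ids: {offenders[:10]}"
        )
    rows = [encode_sequence(r.sequence, table, tss_offset, ambiguous) for r in records]
    return FeatureMatrix(
        values=np.vstack([fv.values for fv in rows]),
        position_labels=rows[0].position_labels,
        ids=tuple(r.id for r in records),
    )


def mean_profile(matrix: FeatureMatrix) -> Profile:
    """Longitudinal DDS profile: per-position arithmetic mean of a matrix."""
    if matrix.n_sequences == 0:
        raise ValueError("cannot profile an empty feature matrix")
    return Profile(
        values=matrix.values.mean(axis=0),
        position_labels=matrix.position_labels,
        n_sequences=matrix.n_sequences,
    )


def profile_correlation(p1, p2) -> float:
    """Pearson correlation between two longitudinal profiles (or series)."""
    a = np.asarray(p1.values if isinstance(p1, Profile) else p1, dtype=float)
    b = np.asarray(p2.values if isinstance(p2, Profile) else p2, dtype=float)
    if a.size != b.size:
        raise DimensionError(f"profile lengths differ: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("correlation needs at least two positions")
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        raise ValueError("correlation undefined: a profile has zero variance")
    return float(np.corrcoef(a, b)[0, 1])
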