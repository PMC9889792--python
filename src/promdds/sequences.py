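"""Sequence records, FASTA/TSV I/O, TSS-anchored window extraction, and
shuffled negative-control construction.

The exchange formats are deliberately plain: FASTA for sequences, a TSV of
(contig, tss_1based, strand, id) for transcription start sites, and a TSV of
(id, label, origin, sequence) for labeled datasets.  TSS positions are
1-based in files (the convention of transcriptome maps) and converted to
0-based half-open genomic coordinates internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dds import DimensionError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")

ORIGINS = ("observed", "shuffled", "synthetic", "scanned")


class BoundaryError(ValueError):
    """A requested genomic window falls off the end of its contig."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    """A (candidate) promoter sequence with optional label and coordinates.

    ``coords`` are 0-based half-open on the forward strand:
    (contig, start, end, strand).
    """

    id: str
    sequence: str
    label: int | None = None
    origin: str = "observed"
    coords: tuple[str, int, int, str] | None = None
    parent_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; expected one of {ORIGINS}")
        if self.origin == "shuffled" and self.parent_id is None:
            raise ValueError("shuffled records must record a parent id")
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass(frozen=True)
class LabeledDataset:
    """Balanced promoter/non-promoter training set."""

    records: tuple[PromoterRecord, ...]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "label": [r.label for r in self.records],
                "origin": [r.origin for r in self.records],
                "sequence": [r.sequence for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, origin: str = "observed") -> list[PromoterRecord]:
    """Read FASTA into records; ids are the first whitespace token, unique."""
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(PromoterRecord(id=rec.id, sequence=str(rec.seq), origin=origin))
    if not records:
        warnings.warn(f"no records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Contig id → uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


TSS_COLUMNS = ("contig", "tss_1based", "strand", "id")


def read_tss_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TSS table {path} lacks columns {sorted(missing)}")
    return df[list(TSS_COLUMNS)]


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(TSS_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# core-promoter window extraction
# ---------------------------------------------------------------------------

def extract_core_promoter(
    genome: Mapping[str, str],
    contig: str,
    tss_1based: int,
    strand: str,
    upstream: int = 80,
    downstream: int = 20,
    record_id: str | None = None,
) -> PromoterRecord:
    """Extract the −upstream…+downstream window around a TSS, 5′→3′.

    The TSS is +1 under the no-zero convention, so the window covers
    ``upstream`` bases before the TSS and ``downstream`` bases from the TSS
    on; its length is always ``upstream + downstream``.  Minus-strand
    windows are reverse-complemented.  Returned coordinates are 0-based
    half-open on the forward strand.
    """
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not in genome")
    seq = genome[contig]
    t0 = tss_1based - 1  # 0-based TSS
    if strand == "+":
        start, end = t0 - upstream, t0 + downstream
    elif strand == "-":
        start, end = t0 - downstream + 1, t0 + upstream + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0 or end > len(seq):
        raise BoundaryError(
            f"window [{start}, {end}) off contig {contig!r} of length {len(seq)}"
        )
    window = seq[start:end]
    if strand == "-":
        window = reverse_complement(window)
    rid = record_id or f"{contig}:{tss_1based}:{strand}"
    return PromoterRecord(
        id=rid, sequence=window, origin="observed", coords=(contig, start, end, strand)
    )


def extract_batch(
    genome: Mapping[str, str],
    tss_table: pd.DataFrame,
    upstream: int = 80,
    downstream: int = 20,
) -> tuple[list[PromoterRecord], list[str]]:
    """Extract windows for every TSS row, skipping (and logging) boundary hits."""
    out: list[PromoterRecord] = []
    skipped: list[str] = []
    for row in tss_table.itertuples(index=False):
        try:
            out.append(
                extract_core_promoter(
                    genome, row.contig, int(row.tss_1based), row.strand,
                    upstream, downstream, record_id=str(row.id),
                )
            )
        except BoundaryError as exc:
            logger.warning("skipping %s: %s", row.id, exc)
            skipped.append(str(row.id))
    return out, skipped


# ---------------------------------------------------------------------------
# shuffled negatives and balanced datasets
# ---------------------------------------------------------------------------

def _mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Doublet-preserving shuffle via a random Eulerian walk on the
    dinucleotide transition graph (Altschul–Erickson construction)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random last-exit edge toward the sink for each non-sink vertex,
    # retrying until those edges form a tree into the sink (Euler condition)
    vertices = list(edges)
    for _ in range(1000):
        last_exit = {}
        for v in vertices:
            if v == last:
                continue
            last_exit[v] = edges[v][rng.integers(len(edges[v]))]
        # connectivity check: every vertex reaches the sink via last-exit edges
        ok = True
        for v in last_exit:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_exit:
                    ok = False
                    break
                seen.add(cur)
                cur = last_exit[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    pools: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_exit:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v in last_exit:
            rest.append(last_exit[v])
        pools[v] = rest
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_negative(
    record: PromoterRecord,
    seed: int | np.random.Generator = 0,
    mode: str = "mono",
) -> PromoterRecord:
    """A shuffled, label-0 negative control of ``record``.

    ``mode="mono"`` permutes single bases uniformly (default, preserving
    mononucleotide composition); ``mode="dinuc"`` preserves dinucleotide
    composition as well.
    """
    if not record.sequence:
        raise ValueError("cannot shuffle an empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "mono":
        shuffled = _mononucleotide_shuffle(record.sequence, rng)
    elif mode == "dinuc":
        shuffled = _dinucleotide_shuffle(record.sequence, rng)
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return PromoterRecord(
        id=f"{record.id}|shuffled",
        sequence=shuffled,
        label=0,
        origin="shuffled",
        parent_id=record.id,
    )


def build_labeled_dataset(
    positives: Sequence[PromoterRecord],
    seed: int = 0,
    mode: str = "mono",
) -> LabeledDataset:
    """Pair every positive with one shuffled negative (1:1 class balance)."""
    positives = list(positives)
    if not positives:
        raise ValueError("need at least one positive record")
    lengths = {len(r.sequence) for r in positives}
    if len(lengths) > 1:
        offenders = [r.id for r in positives if len(r.sequence) != len(positives[0].sequence)]
        raise DimensionError(
            f"positives have mixed lengths {sorted(lengths)}; ids: {offenders[:10]}"
        )
    rng = np.random.default_rng(seed)
    records: list[PromoterRecord] = []
    for rec in positives:
        records.append(replace(rec, label=1))
        records.append(shuffle_negative(rec, rng, mode=mode))
    return LabeledDataset(records=tuple(records))


def at_percentage(sequences: str | Iterable) -> float:
    """Percentage of A+T among ACGT bases, over one or many sequences."""
    if isinstance(sequences, str):
        seqs = [sequences]
    else:
        seqs = [s.sequence if isinstance(s, PromoterRecord) else str(s) for s in sequences]
    at = acgt = 0
    for s in seqs:
        s = s.upper()
        at += s.count("A") + s.count("T")
        acgt += sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no ACGT bases to compute AT percentage from")
    return 100.0 * at / acgt
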