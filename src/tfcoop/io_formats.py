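"""Sequence/interval I/O and fixed-width regulatory window construction.

The package works on four kinds of regulatory regions (promoters of mRNAs,
lncRNAs and pri-miRNAs, and enhancers), all represented as fixed-width
windows centered on an anchor position: the annotated transcription start
site for promoters, or the enhancer interval mid-point.  Coordinates are
BED-style 0-based half-open everywhere; a window of flank ``f`` around
anchor ``a`` is ``[a - f, a + f)`` and therefore exactly ``2 f`` bp wide.

Windows are never reverse-complemented for minus-strand anchors: every
feature computed downstream (two-strand motif scanning, reverse-complement
collapsed composition) is strand-symmetric, so the reference orientation is
kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

ROLES = ("mRNA_promoter", "lncRNA_promoter", "primiRNA_promoter", "enhancer")

#: chromosome name -> uppercase nucleotide string over {A, C, G, T, N}
GenomeSequences = dict

_ALPHABET = frozenset("ACGTN")
_STRANDS = frozenset("+-.")


@dataclass(frozen=True)
class Interval:
    """A BED record: 0-based, half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RegulatoryWindow:
    """A fixed-width window with its sequence and regulatory role."""

    interval: Interval
    sequence: str
    role: str
    anchor: int

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"window {self.interval.name}: sequence length "
                f"{len(self.sequence)} != interval width {len(self.interval)}"
            )

    @property
    def id(self) -> str:
        return self.interval.name


def read_fasta(path) -> GenomeSequences:
    """Read a multi-record FASTA into a ``{name: sequence}`` mapping.

    Sequences are uppercased; characters outside A/C/G/T/N are rejected.
    """
    path = Path(path)
    genome: GenomeSequences = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if not name:
            raise ValueError(f"{path}: FASTA record with empty header")
        if name in genome:
            raise ValueError(f"{path}: duplicate FASTA record {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty FASTA record {name!r}")
        bad = set(seq) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"{path}: record {name!r} contains invalid character "
                f"{seq[pos]!r} at sequence position {pos + 1}"
            )
        genome[name] = seq
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: GenomeSequences, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list:
    """Read BED3+/BED6 into :class:`Interval` records.

    Missing name columns are auto-filled with ``.``; a missing strand is
    recorded as ``.``.  Malformed records raise with their line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start ({start}) >= end ({end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            intervals.append(Interval(chrom, start, end, name, strand))
    return intervals


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def _anchor_position(iv: Interval, one_based: bool) -> int:
    # 1-bp intervals are point anchors (TSS tables); wider intervals use
    # their integer mid-point (enhancers).
    if len(iv) == 1:
        return iv.start - 1 if one_based else iv.start
    return iv.midpoint


def make_windows(
    anchors: Sequence[Interval],
    genome: GenomeSequences,
    flank: int = 500,
    role: str = "mRNA_promoter",
    anchors_are_one_based: bool = False,
) -> list:
    """Build ``[anchor - flank, anchor + flank)`` windows around anchors.

    Windows that would extend past either chromosome end are dropped (and
    logged), as are windows whose sequence is entirely N.  Duplicate
    windows (identical chrom/start/end/role) are deduplicated.

    Raises if any anchor lies on a chromosome absent from the genome.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    missing = sorted({iv.chrom for iv in anchors} - set(genome))
    if missing:
        raise KeyError(f"anchor chromosomes absent from genome: {missing}")
    windows: list[RegulatoryWindow] = []
    seen: set[tuple] = set()
    n_dropped = 0
    for i, iv in enumerate(anchors):
        anchor = _anchor_position(iv, anchors_are_one_based)
        start, end = anchor - flank, anchor + flank
        chrom_seq = genome[iv.chrom]
        if start < 0 or end > len(chrom_seq):
            n_dropped += 1
            logger.debug(
                "dropping window %s:%d-%d (outside chromosome of length %d)",
                iv.chrom, start, end, len(chrom_seq),
            )
            continue
        key = (iv.chrom, start, end, role)
        if key in seen:
            continue
        seen.add(key)
        seq = chrom_seq[start:end]
        if set(seq) == {"N"}:
            n_dropped += 1
            logger.warning("dropping all-N window %s:%d-%d", iv.chrom, start, end)
            continue
        name = iv.name if iv.name != "." else f"{iv.chrom}:{start}-{end}"
        windows.append(
            RegulatoryWindow(
                interval=Interval(iv.chrom, start, end, name, iv.strand),
                sequence=seq,
                role=role,
                anchor=anchor,
            )
        )
    if n_dropped:
        logger.info("make_windows: dropped %d/%d anchors", n_dropped, len(anchors))
    return windows


def intersect_labels(windows: Sequence[RegulatoryWindow], peaks: Sequence[Interval]):
    """Boolean vector: window overlaps >= 1 peak by >= 1 bp (half-open).

    This is the positive/negative labeling rule for ChIP-seq experiments:
    a regulatory sequence intersecting at least one binding region is a
    positive example.
    """
    import numpy as np

    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end)
    labels = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows):
        tree = trees.get(w.interval.chrom)
        if tree is not None and tree.overlap(w.interval.start, w.interval.end):
            labels[i] = True
    return labels
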