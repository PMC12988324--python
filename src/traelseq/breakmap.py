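"""Single-base break mapping and copy-number-aware UMI deduplication.

TrAEL-seq reads begin at the free 3' end of the captured strand, so after
alignment each read is reduced to the single base at its 5'-most position
in read orientation -- the last nucleotide 5' of the strand break.  PCR
duplicates are removed with a dual-key scheme:

* high-quality (uniquely mapping) reads are deduplicated by mapped break
  position, strand and UMI, so independent molecules at the same position
  with different UMIs survive, and identical molecules at different copies
  of a repeat are NOT collapsed (the "copy-number-aware" property);
* low-MAPQ (multi-mapping) reads cannot be trusted positionally, so only
  the UMI is used -- but an 8-nt UMI has only 4^8 = 65,536 combinations,
  fewer than a typical library, so the first 10 bases of the read sequence
  are appended to the UMI to enlarge the key space.

Deduplication is per sample; within a duplicate group the survivor is the
first read in coordinate-sorted order (ties broken by read name), which
makes the operation deterministic and idempotent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pysam

from traelseq.readproc import umi_from_read_name

BREAK_COLUMNS = ["chrom", "pos", "strand", "mapq", "umi", "sample", "t_class"]


def umi_keyspace(length: int = 8, alphabet: Sequence[str] = "ACGT") -> int:
    """Number of distinct UMIs of the given length over the DNA alphabet.

    For the standard 8-nt UMI this is 4^8 = 65,536 -- smaller than a typical
    library, which is why low-MAPQ deduplication augments the UMI with read
    sequence.
    """
    if length < 1:
        raise ValueError("UMI length must be >= 1")
    distinct = len(set(alphabet))
    return distinct ** length


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read with its UMI, in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mapq: int
    umi: str
    seq: str
    sample: str = "sample"
    name: str = ""
    t_class: str = "T"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class BreakRecord:
    """One deduplicated break observation at single-base resolution."""

    chrom: str
    pos: int  # 0-based coordinate of the break-adjacent base
    strand: str
    mapq: int
    umi: str
    sample: str = "sample"
    t_class: str = "T"


@dataclass(frozen=True)
class DedupPolicy:
    """Keys and thresholds of the dual deduplication scheme.

    Reads with ``mapq > hq_threshold`` use the position-aware key
    (chrom, 5'-end position, strand, UMI); reads with
    ``mapq <= hq_threshold`` use (UMI, first ``prefix_length`` bases of the
    read sequence).
    """

    hq_threshold: int = 20
    prefix_length: int = 10

    def __post_init__(self) -> None:
        if self.prefix_length < 1:
            raise ValueError("prefix_length must be >= 1")
        if self.hq_threshold < 0:
            raise ValueError("hq_threshold must be >= 0")

    def is_hq(self, read: AlignedRead) -> bool:
        return read.mapq > self.hq_threshold

    def hq_key(self, read: AlignedRead) -> tuple:
        pos = read.start if read.strand == "+" else read.end - 1
        return (read.sample, read.chrom, pos, read.strand, read.umi)

    def lq_key(self, read: AlignedRead) -> tuple:
        return (read.sample, read.umi, read.seq[: self.prefix_length].upper())


def reduce_to_break(read: AlignedRead) -> BreakRecord:
    """Reduce an alignment to the single base 5' of the strand break.

    For a forward read that is the lowest aligned coordinate; for a reverse
    read, the highest (``end - 1``).
    """
    pos = read.start if read.strand == "+" else read.end - 1
    return BreakRecord(
        chrom=read.chrom,
        pos=pos,
        strand=read.strand,
        mapq=read.mapq,
        umi=read.umi,
        sample=read.sample,
        t_class=read.t_class,
    )


@dataclass
class DedupStats:
    input: int = 0
    retained: int = 0
    duplicates_hq: int = 0
    duplicates_lq: int = 0

    @property
    def duplicates(self) -> int:
        return self.duplicates_hq + self.duplicates_lq


def _sort_key(read: AlignedRead) -> tuple:
    return (read.chrom, read.start, read.end, read.name)


def deduplicate(
    reads: Iterable[AlignedRead], policy: DedupPolicy = DedupPolicy()
) -> tuple[list[AlignedRead], DedupStats]:
    """Remove PCR duplicates under the dual-key policy.

    Returns the retained reads (coordinate-sorted) and class-wise counts.
    The survivor within each duplicate group is the first read in
    coordinate-sorted order, read name breaking ties, so the result is
    deterministic for any input order and idempotent.
    """
    stats = DedupStats()
    seen_hq: set[tuple] = set()
    seen_lq: set[tuple] = set()
    retained: list[AlignedRead] = []
    for read in sorted(reads, key=_sort_key):
        stats.input += 1
        if not read.umi:
            raise ValueError(f"read {read.name!r} at {read.chrom}:{read.start} has no UMI")
        if policy.is_hq(read):
            key = policy.hq_key(read)
            if key in seen_hq:
                stats.duplicates_hq += 1
                continue
            seen_hq.add(key)
        else:
            key = policy.lq_key(read)
            if key in seen_lq:
                stats.duplicates_lq += 1
                continue
            seen_lq.add(key)
        retained.append(read)
        stats.retained += 1
    return retained, stats


def filter_by_mapq(
    records: Iterable[BreakRecord], min_mapq: int = 20, enabled: bool = True
) -> list[BreakRecord]:
    """Keep records with ``mapq >= min_mapq``; identity when disabled.

    The filter is switched off for analyses of multi-copy regions, where
    reads are legitimately low-MAPQ.
    """
    records = list(records)
    if not enabled:
        return records
    return [r for r in records if r.mapq >= min_mapq]


# --- SAM/BAM and BED plumbing -------------------------------------------------


def read_alignments(
    path: str | os.PathLike,
    sample: str = "sample",
    t_class: str = "T",
    umi_tag: str | None = None,
) -> list[AlignedRead]:
    """Load mapped reads from SAM/BAM; UMI from the read-name suffix.

    If ``umi_tag`` is given (e.g. ``"RX"``), the UMI is taken from that tag
    instead of the read name.  Unmapped reads are skipped.
    """
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if umi_tag is not None:
                umi = str(aln.get_tag(umi_tag))
            else:
                umi = umi_from_read_name(aln.query_name)
            reads.append(
                AlignedRead(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    umi=umi,
                    seq=aln.query_sequence or "",
                    sample=sample,
                    name=aln.query_name,
                    t_class=t_class,
                )
            )
    return reads


def breaks_to_frame(records: Iterable[BreakRecord]) -> pd.DataFrame:
    """Tabulate break records (columns chrom, pos, strand, mapq, umi, sample, t_class)."""
    return pd.DataFrame(
        [(r.chrom, r.pos, r.strand, r.mapq, r.umi, r.sample, r.t_class) for r in records],
        columns=BREAK_COLUMNS,
    )


def write_breaks_bed(records: Iterable[BreakRecord], path: str | os.PathLike) -> None:
    """Write break records as BED6 (name=UMI, score=MAPQ), sorted."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.umi}\t{r.mapq}\t{r.strand}\n")


def read_breaks_bed(path: str | os.PathLike, sample: str = "sample") -> list[BreakRecord]:
    """Read break records from the BED6 written by :func:`write_breaks_bed`."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, name, score, strand = line.split("\t")[:6]
            records.append(
                BreakRecord(
                    chrom=chrom,
                    pos=int(start),
                    strand=strand,
                    mapq=int(score),
                    umi=name,
                    sample=sample,
                )
            )
    return records
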