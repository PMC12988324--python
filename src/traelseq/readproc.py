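"""Parsing and demultiplexing of raw multiplexed TrAEL-seq reads.

The multiplexed TrAEL-seq adaptor places an inline 4-nt sample index at the
ligation junction followed by an 8-nt random UMI, so every raw read starts

    [8 nt UMI][4 nt barcode][poly-T run][genomic insert]

The poly-T run comes from the terminal-transferase A-tail on the broken 3'
end; DNA-derived reads therefore carry at least one T at the first
post-barcode position, while reads with no leading T ("noT" class) are
candidate RNA-derived molecules and are kept as a separate QC channel.

This module parses that layout, assigns reads to samples (tolerating a
configurable number of barcode mismatches with a unique-best rule), trims
the poly-T run, and writes per-sample T / noT FASTQ files.  The UMI is
carried in the read identifier (suffix after ``_``, as in ``umi_tools``) so
downstream SAM/BAM stages can recover it without non-standard fields.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import pandas as pd

UNASSIGNED = "UNASSIGNED"
UMI_SEPARATOR = "_"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadLayout:
    """Geometry of the multiplexed TrAEL-seq read start.

    Parameters
    ----------
    umi_length : int
        Number of random nucleotides at the read start (default 8).
    barcode_length : int
        Length of the inline sample index that follows the UMI (default 4).
    min_remaining_length : int
        Reads whose insert (after poly-T trimming) is shorter than this are
        discarded as unmappable (default 20).
    barcode_mismatch_tolerance : int
        Maximum Hamming distance for barcode rescue (default 1); a read is
        assigned only if a single barcode is the unique best match within
        this tolerance.
    """

    umi_length: int = 8
    barcode_length: int = 4
    min_remaining_length: int = 20
    barcode_mismatch_tolerance: int = 1

    def __post_init__(self) -> None:
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if self.min_remaining_length < 1:
            raise ValueError("min_remaining_length must be >= 1")
        if not 0 <= self.barcode_mismatch_tolerance < self.barcode_length:
            raise ValueError("tolerance must be in [0, barcode_length)")

    @property
    def header_length(self) -> int:
        return self.umi_length + self.barcode_length


@dataclass
class BarcodeTable:
    """Sample barcodes as listed on the adaptor strand.

    The adaptors are ligated such that sequencing reads traverse the index
    on the complementary strand, so with the default orientation
    ``reverse_complement_in_read`` the in-read barcode is the reverse
    complement of the adaptor-strand index (adaptor ``GACT`` is read as
    ``AGTC``).  ``as_adaptor`` disables the flip for dialects that list
    in-read sequences directly.
    """

    entries: list[tuple[str, str]]
    orientation: str = "reverse_complement_in_read"

    def __post_init__(self) -> None:
        if self.orientation not in ("as_adaptor", "reverse_complement_in_read"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for name, bc in self.entries:
            if set(bc.upper()) - set("ACGT"):
                raise ValueError(f"barcode {bc!r} for {name!r} is not plain DNA")

    @property
    def in_read(self) -> dict[str, str]:
        """Mapping sample name -> barcode sequence as it appears in reads."""
        if self.orientation == "reverse_complement_in_read":
            return {name: reverse_complement(bc.upper()) for name, bc in self.entries}
        return {name: bc.upper() for name, bc in self.entries}

    def validate_separability(self, tolerance: int) -> None:
        """Check barcodes are pairwise separable at the given tolerance.

        With the unique-best assignment rule, pairwise Hamming distance
        >= 2 * tolerance guarantees a read is never assigned to the wrong
        sample: an observed barcode equidistant from two entries is left
        UNASSIGNED rather than guessed.  (Distance > 2 * tolerance would
        additionally guarantee every read with <= tolerance errors is
        rescued; the standard six-plex set contains pairs at distance 2,
        so only the misassignment-safety condition is enforced.)
        """
        seqs = list(self.in_read.items())
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = hamming(seqs[i][1], seqs[j][1])
                if d < 2 * tolerance:
                    raise ValueError(
                        f"barcodes {seqs[i][0]} and {seqs[j][0]} are Hamming-{d} "
                        f"apart; not separable at tolerance {tolerance}"
                    )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, orientation: str = "reverse_complement_in_read") -> "BarcodeTable":
        """Load a 2-column TSV (index_name, adaptor_barcode); '#' comments allowed."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"barcode table line has <2 columns: {line!r}")
                entries.append((fields[0], fields[1]))
        return cls(entries=entries, orientation=orientation)


@dataclass
class ParsedRead:
    """One raw read decomposed into UMI, sample, poly-T run and insert."""

    umi: str
    sample: str
    polyT_run: int
    t_class: str  # "T" or "noT"
    insert: str
    insert_quality: str


def match_barcode(observed: str, table: BarcodeTable, tolerance: int) -> str:
    """Assign a barcode to a sample; UNASSIGNED when no unique best match.

    A read is assigned to the sample whose in-read barcode has the smallest
    Hamming distance to the observed field, provided that distance is within
    the tolerance and no second barcode ties for best.
    """
    best_name = UNASSIGNED
    best_d = tolerance + 1
    tied = False
    for name, bc in table.in_read.items():
        d = hamming(observed.upper(), bc)
        if d < best_d:
            best_name, best_d, tied = name, d, False
        elif d == best_d:
            tied = True
    if tied or best_d > tolerance:
        return UNASSIGNED
    return best_name


def parse_read(
    raw_sequence: str,
    raw_quality: str,
    layout: ReadLayout,
    table: BarcodeTable,
) -> ParsedRead | None:
    """Decompose one raw read; return None for reads too short to use.

    The first ``umi_length`` bases are the UMI, the next ``barcode_length``
    the in-read sample index, then the maximal run of literal T is trimmed
    and the remainder is the genomic insert (quality sliced identically).
    Reads whose insert ends up shorter than ``min_remaining_length`` are
    discarded (None).
    """
    seq = raw_sequence.upper()
    if len(seq) < layout.header_length + layout.min_remaining_length:
        return None
    umi = seq[: layout.umi_length]
    barcode = seq[layout.umi_length : layout.header_length]
    sample = match_barcode(barcode, table, layout.barcode_mismatch_tolerance)
    i = layout.header_length
    while i < len(seq) and seq[i] == "T":
        i += 1
    polyt = i - layout.header_length
    insert = raw_sequence[i:]
    quality = raw_quality[i:]
    if len(insert) < layout.min_remaining_length:
        return None
    return ParsedRead(
        umi=umi,
        sample=sample,
        polyT_run=polyt,
        t_class="T" if polyt >= 1 else "noT",
        insert=insert,
        insert_quality=quality,
    )


def _open_text(path: str | os.PathLike, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) records from a FASTQ file (.gz ok).

    Raises ValueError naming the record number on malformed input.
    """
    with _open_text(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record {record} in {path}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record {record} in {path}: sequence/quality length mismatch"
                )
            yield header[1:].rstrip("\n").split()[0], seq, qual


@dataclass
class DemuxResult:
    """Outputs of demultiplexing: file paths plus accounting."""

    outputs: dict[str, tuple[str, str]]  # sample -> (fastq_T path, fastq_noT path)
    unassigned_path: str
    summary: pd.DataFrame
    polyt_histogram: pd.DataFrame
    total: int
    assigned: int
    unassigned: int
    discarded: int


def demultiplex_fastq(
    fastq_in: str | os.PathLike,
    layout: ReadLayout,
    table: BarcodeTable,
    out_dir: str | os.PathLike,
    gzip_out: bool = False,
) -> DemuxResult:
    """Split a multiplexed FASTQ into per-sample T / noT files.

    Every input read lands in exactly one of: a sample's T file, a sample's
    noT file, the unassigned file, or the discarded tally (too short).  The
    UMI is appended to each emitted read identifier.  A summary TSV, a
    poly-T run-length histogram and a JSON parameter sidecar are written to
    ``out_dir``.
    """
    table.validate_separability(layout.barcode_mismatch_tolerance)
    os.makedirs(out_dir, exist_ok=True)
    ext = ".fastq.gz" if gzip_out else ".fastq"

    handles: dict[tuple[str, str], TextIO] = {}
    outputs: dict[str, tuple[str, str]] = {}
    for name, _ in table.entries:
        t_path = os.path.join(out_dir, f"{name}_T{ext}")
        not_path = os.path.join(out_dir, f"{name}_noT{ext}")
        handles[(name, "T")] = _open_text(t_path, "wt")
        handles[(name, "noT")] = _open_text(not_path, "wt")
        outputs[name] = (t_path, not_path)
    unassigned_path = os.path.join(out_dir, f"unassigned{ext}")
    un_handle = _open_text(unassigned_path, "wt")

    counts: dict[tuple[str, str], int] = {}
    polyt_hist: dict[int, int] = {}
    total = assigned = unassigned = discarded = 0
    try:
        for name, seq, qual in read_fastq(fastq_in):
            total += 1
            parsed = parse_read(seq, qual, layout, table)
            if parsed is None:
                discarded += 1
                continue
            polyt_hist[parsed.polyT_run] = polyt_hist.get(parsed.polyT_run, 0) + 1
            out_name = f"{name}{UMI_SEPARATOR}{parsed.umi}"
            if parsed.sample == UNASSIGNED:
                unassigned += 1
                un_handle.write(f"@{out_name}\n{parsed.insert}\n+\n{parsed.insert_quality}\n")
                continue
            assigned += 1
            key = (parsed.sample, parsed.t_class)
            counts[key] = counts.get(key, 0) + 1
            handles[key].write(f"@{out_name}\n{parsed.insert}\n+\n{parsed.insert_quality}\n")
    finally:
        for fh in handles.values():
            fh.close()
        un_handle.close()

    rows = []
    for name, _ in table.entries:
        t = counts.get((name, "T"), 0)
        n = counts.get((name, "noT"), 0)
        rows.append({"sample": name, "reads": t + n, "T": t, "noT": n})
    rows.append({"sample": UNASSIGNED, "reads": unassigned, "T": 0, "noT": 0})
    rows.append({"sample": "discarded", "reads": discarded, "T": 0, "noT": 0})
    summary = pd.DataFrame(rows)
    hist = pd.DataFrame(
        sorted(polyt_hist.items()), columns=["polyT_run", "reads"]
    ) if polyt_hist else pd.DataFrame(columns=["polyT_run", "reads"])

    summary.to_csv(os.path.join(out_dir, "demux_summary.tsv"), sep="\t", index=False)
    hist.to_csv(os.path.join(out_dir, "polyT_histogram.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "demux_params.json"), "w") as fh:
        json.dump(
            {
                "fastq_in": str(fastq_in),
                "umi_length": layout.umi_length,
                "barcode_length": layout.barcode_length,
                "min_remaining_length": layout.min_remaining_length,
                "barcode_mismatch_tolerance": layout.barcode_mismatch_tolerance,
                "orientation": table.orientation,
                "total": total,
                "assigned": assigned,
                "unassigned": unassigned,
                "discarded": discarded,
            },
            fh,
            indent=2,
        )

    return DemuxResult(
        outputs=outputs,
        unassigned_path=unassigned_path,
        summary=summary,
        polyt_histogram=hist,
        total=total,
        assigned=assigned,
        unassigned=unassigned,
        discarded=discarded,
    )


def umi_from_read_name(name: str) -> str:
    """Recover the UMI carried in a read identifier (suffix after '_')."""
    if UMI_SEPARATOR not in name:
        raise ValueError(f"read name {name!r} carries no UMI suffix")
    return name.rsplit(UMI_SEPARATOR, 1)[1]
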