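"""Stranded windowed count tracks and replication fork directionality.

RFD is computed per window from break-read polarity as

    RFD = (R - F) / (R + F)

where R and F are reverse- and forward-strand read counts.  TrAEL-seq
captures leading-strand 3' ends, so rightward-moving forks yield
reverse-strand reads: RFD = +1 means all forks in the window move
left -> right, -1 all right -> left.  The conventional display uses 20 kb
windows spaced every 2 kb (sliding), while read-density profiling uses
non-overlapping 50 kb windows.

Read-count normalization follows the multiplexing design: samples pooled
into one multiplexed set share every processing step, so their relative
read counts are biologically meaningful and must not be rescaled
individually.  Comparisons *across* sets therefore use a single scalar per
set that equalizes set totals while preserving within-set ratios.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from traelseq.breakmap import BreakRecord, breaks_to_frame

TRACK_COLUMNS = ["chrom", "start", "end", "R", "F"]


@dataclass(frozen=True)
class BinningScheme:
    """Sliding-window binning: window k covers [k*step, k*step + window).

    ``window_size == step`` gives non-overlapping tiles; the default RFD
    scheme (20 kb windows every 2 kb) is sliding, so each break lands in
    ``window_size / step`` windows.
    """

    window_size: int = 20_000
    step: int = 2_000

    def __post_init__(self) -> None:
        if not self.window_size >= self.step >= 1:
            raise ValueError("require window_size >= step >= 1")

    def n_windows(self, chrom_length: int) -> int:
        # every window whose start lies within the chromosome
        return max(1, -(-chrom_length // self.step))  # ceil

    def window_span(self, k: int, chrom_length: int) -> tuple[int, int]:
        start = k * self.step
        return start, min(start + self.window_size, chrom_length)

    def windows_for(self, pos: int) -> range:
        """Window indices k with k*step <= pos < k*step + window_size."""
        lo = max(0, (pos - self.window_size) // self.step + 1)
        hi = pos // self.step
        return range(lo, hi + 1)


def count_breaks(
    records: Iterable[BreakRecord] | pd.DataFrame,
    scheme: BinningScheme,
    genome_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Count breaks per window and strand.

    Returns a DataFrame with one row per window per chromosome
    (chrom, start, end, R, F); windows are anchored at coordinate 0 and the
    final partial window is kept.  A record beyond the chromosome end is a
    hard error.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = breaks_to_frame(records)
    pieces = []
    for chrom, length in genome_sizes.items():
        sub = frame[frame["chrom"] == chrom]
        if len(sub) and (sub["pos"].max() >= length or sub["pos"].min() < 0):
            bad = sub.loc[(sub["pos"] >= length) | (sub["pos"] < 0), "pos"].iloc[0]
            raise ValueError(f"break at {chrom}:{bad} outside chromosome of length {length}")
        n = scheme.n_windows(length)
        counts = {s: np.zeros(n, dtype=np.int64) for s in "+-"}
        for strand in "+-":
            pos = sub.loc[sub["strand"] == strand, "pos"].to_numpy()
            if len(pos) == 0:
                continue
            if scheme.window_size == scheme.step:
                np.add.at(counts[strand], pos // scheme.step, 1)
            else:
                for p in pos:
                    ks = scheme.windows_for(int(p))
                    counts[strand][ks.start : min(ks.stop, n)] += 1
        starts = np.arange(n) * scheme.step
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + scheme.window_size, length),
                    "R": counts["-"],
                    "F": counts["+"],
                }
            )
        )
    unknown = set(frame["chrom"]) - set(genome_sizes)
    if unknown:
        raise ValueError(f"records on chromosomes missing from genome_sizes: {sorted(unknown)}")
    if not pieces:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(pieces, ignore_index=True)


def compute_rfd(counts: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Add an ``rfd`` column: (R - F) / (R + F), NaN below ``min_reads``."""
    out = counts.copy()
    total = out["R"] + out["F"]
    with np.errstate(invalid="ignore", divide="ignore"):
        rfd = (out["R"] - out["F"]) / total
    rfd[total < max(min_reads, 1)] = np.nan
    out["rfd"] = rfd
    return out


def normalize_sets(
    sample_totals: Mapping[str, float], sets: Mapping[str, str]
) -> dict[str, float]:
    """Per-set scale factors equalizing multiplexed-set totals.

    ``sets`` maps sample -> set name.  Each set receives one factor
    (mean set total / set total); all samples in a set share it, so
    within-set count ratios are untouched.  Returns sample -> factor.
    """
    set_totals: dict[str, float] = {}
    for sample, total in sample_totals.items():
        if sample not in sets:
            raise ValueError(f"sample {sample!r} not assigned to a multiplexed set")
        set_totals[sets[sample]] = set_totals.get(sets[sample], 0.0) + float(total)
    for name, tot in set_totals.items():
        if tot <= 0:
            raise ValueError(f"multiplexed set {name!r} has no reads")
    mean_total = float(np.mean(list(set_totals.values())))
    factors = {name: mean_total / tot for name, tot in set_totals.items()}
    return {sample: factors[sets[sample]] for sample in sample_totals}


def write_bedgraph(
    track: pd.DataFrame, value_column: str, path: str | os.PathLike
) -> None:
    """Write one column of a windowed track as a 4-decimal bedGraph.

    Rows with missing values are omitted; intervals are emitted sorted.
    """
    sub = track.dropna(subset=[value_column]).sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(
            sub["chrom"], sub["start"], sub["end"], sub[value_column]
        ):
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:.4f}\n")


def read_bedgraph(path: str | os.PathLike, value_column: str = "value") -> pd.DataFrame:
    """Read a bedGraph file into (chrom, start, end, <value_column>)."""
    return pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", value_column],
        comment="#",
        dtype={"chrom": str},
    )


def write_tracks(
    counts_with_rfd: pd.DataFrame, prefix: str | os.PathLike
) -> dict[str, str]:
    """Write F and R count bedGraphs plus (when present) the RFD bedGraph.

    Returns the mapping of track name to file path.
    """
    paths = {}
    for name, col in (("F", "F"), ("R", "R")):
        path = f"{prefix}.{name}.bedgraph"
        write_bedgraph(counts_with_rfd, col, path)
        paths[name] = path
    if "rfd" in counts_with_rfd.columns:
        path = f"{prefix}.rfd.bedgraph"
        write_bedgraph(counts_with_rfd, "rfd", path)
        paths["rfd"] = path
    return paths


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Load a 2-column chromosome sizes TSV."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes
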