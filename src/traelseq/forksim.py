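"""Replication-fork simulator emitting TrAEL-seq-structured data.

The model: a genome with defined initiation zones (IZs).  In each simulated
cell every IZ fires with probability ``efficiency`` at a truncated-Normal
time, placing an origin uniformly within the zone.  Forks move outward at a
position-dependent speed v(x) > 0, and every position is replicated by
whichever fork arrives first (arrival-time sweep); an unfired IZ is
replicated passively by an incoming fork, and converging forks define
termination points.  Every position is replicated exactly once per cell.

TrAEL-seq captures the leading-strand 3' end of a fork, so the expected
read density at x is proportional to the fork residence time 1/v(x)
(slower forks spend longer per base and are sampled more often), and read
strand reports fork direction: rightward forks yield reverse-strand reads,
leftward forks forward-strand reads.  Reads are drawn directly from the
residence-time density (equivalent in expectation to snapshot sampling of
fork positions, and far cheaper); a tiny explicit snapshot sampler is kept
as an independent check.

Emission layers reproduce the read structure of the multiplexed protocol
(8-nt UMI + 4-nt inline barcode + poly-T + genomic insert), PCR duplicates
with identical UMI and position, a minority "noT" (RNA-like) fraction, and
ready-made coordinate-sorted alignments that bypass mapping.  Truth labels
accompany every read so each pipeline stage can be scored exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from traelseq.readproc import ReadLayout, BarcodeTable, UMI_SEPARATOR, reverse_complement
from traelseq.rfdtracks import BinningScheme

RIGHT, LEFT = 1, -1  # fork directions; rightward -> reverse-strand read

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class InitiationZone:
    """One replication initiation zone with firing parameters.

    ``efficiency`` is the per-cell firing probability; ``firing_time`` and
    ``firing_spread`` parameterize a Normal firing-time distribution
    truncated at zero (arbitrary time units -- only ratios of time to
    1/v matter).
    """

    chrom: str
    start: int
    end: int
    efficiency: float = 0.9
    firing_time: float = 1.0
    firing_spread: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.start >= self.end:
            raise ValueError("IZ start must be < end")

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2


SpeedFunction = Callable[[str, np.ndarray], np.ndarray]


def constant_speed(v0: float = 1000.0) -> SpeedFunction:
    """Uniform fork speed v(x) = v0 (bp per time unit)."""

    def v(chrom: str, x: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(x, dtype=float), v0)

    return v


def distance_step_speed(
    centres: Mapping[str, Sequence[int]],
    v_near: float = 1000.0,
    factor: float = 2.0,
    threshold: float = 1_000_000.0,
) -> SpeedFunction:
    """Speed that steps from v_near to factor*v_near beyond ``threshold``
    bp from the nearest IZ centre -- the shape behind declining TrAEL-seq
    read density with distance from initiation zones."""

    sorted_centres = {c: np.sort(np.asarray(p, dtype=float)) for c, p in centres.items()}

    def v(chrom: str, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cs = sorted_centres.get(chrom)
        if cs is None or len(cs) == 0:
            return np.full_like(x, v_near * factor)
        idx = np.searchsorted(cs, x)
        left = cs[np.clip(idx - 1, 0, len(cs) - 1)]
        right = cs[np.clip(idx, 0, len(cs) - 1)]
        d = np.minimum(np.abs(x - left), np.abs(x - right))
        return np.where(d > threshold, v_near * factor, v_near)

    return v


def region_scaled_speed(
    base: SpeedFunction,
    regions: Mapping[str, Sequence[tuple[int, int]]],
    residence_factor: float = 1.2,
) -> SpeedFunction:
    """Scale residence time by ``residence_factor`` inside the regions.

    Residence time is 1/v, so the speed inside each region is divided by
    the factor; used e.g. to plant slower forks in transcribed gene bodies.
    """

    def v(chrom: str, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.asarray(base(chrom, x), dtype=float).copy()
        for start, end in regions.get(chrom, ()):  # few regions expected
            inside = (x >= start) & (x < end)
            out[inside] /= residence_factor
        return out

    return v


@dataclass
class _ChromGrid:
    """Discretized speed field of one chromosome."""

    centres: np.ndarray  # grid-cell centre coordinates
    widths: np.ndarray  # grid-cell widths (last may be partial)
    v: np.ndarray  # speed at cell centres
    rho: np.ndarray  # residence time density 1/v
    time: np.ndarray  # cumulative travel time from 0 to each cell centre


@dataclass
class ForkModel:
    """Ground-truth replication model used to generate synthetic data.

    Parameters
    ----------
    genome : mapping chrom -> length in bp.
    izs : initiation zones (non-overlapping within a chromosome).
    speed : v(chrom, x) in bp per time unit, strictly positive.
    n_cells : cells in the simulated population.
    capture_rate : expected captured (pre-duplication) reads per cell.
    duplicate_rate : probability a molecule gains one PCR duplicate copy.
    noT_fraction : fraction of reads emitted without the leading poly-T
        (RNA-like class).
    grid : resolution in bp of the arrival-time sweep and density sampling.
    """

    genome: dict[str, int]
    izs: list[InitiationZone]
    speed: SpeedFunction = field(default_factory=constant_speed)
    n_cells: int = 100
    capture_rate: float = 1000.0
    duplicate_rate: float = 0.0
    noT_fraction: float = 0.0
    grid: int = 1000
    _grids: dict[str, _ChromGrid] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[InitiationZone]] = {}
        for iz in self.izs:
            if iz.chrom not in self.genome:
                raise ValueError(f"IZ on unknown chromosome {iz.chrom!r}")
            if iz.end > self.genome[iz.chrom]:
                raise ValueError(f"IZ {iz} beyond chromosome end")
            by_chrom.setdefault(iz.chrom, []).append(iz)
        for chrom, zones in by_chrom.items():
            zones = sorted(zones, key=lambda z: z.start)
            for a, b in zip(zones, zones[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping IZs on {chrom}: {a} / {b}")

    def grid_for(self, chrom: str) -> _ChromGrid:
        if chrom not in self._grids:
            length = self.genome[chrom]
            n = -(-length // self.grid)
            starts = np.arange(n) * self.grid
            widths = np.minimum(starts + self.grid, length) - starts
            centres = starts + widths / 2.0
            v = np.asarray(self.speed(chrom, centres), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"speed must be positive everywhere on {chrom}")
            rho = 1.0 / v
            # cumulative travel time from coordinate 0 to each cell centre
            time = np.cumsum(widths * rho) - widths * rho / 2.0
            self._grids[chrom] = _ChromGrid(centres, widths, v, rho, time)
        return self._grids[chrom]

    def iz_centres(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {c: [] for c in self.genome}
        for iz in self.izs:
            out[iz.chrom].append(iz.centre)
        return {c: np.sort(np.array(v, dtype=int)) for c, v in out.items()}


@dataclass
class CellChromMap:
    """Replication outcome of one chromosome in one cell."""

    origins: list[tuple[float, float]]  # (position, firing time)
    direction: np.ndarray  # per grid cell: RIGHT or LEFT
    terminations: list[float]  # coordinates where converging forks met


CellReplicationMap = dict[str, CellChromMap]


def _sample_origins(
    model: ForkModel, chrom: str, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Fire origins on one chromosome; resample until at least one fires."""
    zones = [iz for iz in model.izs if iz.chrom == chrom]
    if not zones:
        raise ValueError(f"no initiation zones on chromosome {chrom!r}")
    while True:
        origins = []
        for iz in zones:
            if rng.random() <= iz.efficiency:
                pos = rng.uniform(iz.start, iz.end)
                t = rng.normal(iz.firing_time, iz.firing_spread) if iz.firing_spread > 0 else iz.firing_time
                while t < 0:  # truncated-Normal firing time
                    t = rng.normal(iz.firing_time, iz.firing_spread)
                origins.append((pos, t))
        if origins:
            return origins


def simulate_cell(model: ForkModel, rng: np.random.Generator) -> CellReplicationMap:
    """Replicate the genome once: origins, fork directions, terminations.

    For each grid position the replicating fork is the one arriving first,
    arrival(x) = tau_k + |T(x) - T(x_k)| with T the cumulative travel time
    integral of 1/v.  Direction switches from rightward to leftward mark
    termination points; coverage is complete by construction.
    """
    cell: CellReplicationMap = {}
    for chrom in model.genome:
        grid = model.grid_for(chrom)
        origins = _sample_origins(model, chrom, rng)
        arrivals = np.empty((len(origins), len(grid.centres)))
        for i, (pos, tau) in enumerate(origins):
            t0 = float(np.interp(pos, grid.centres, grid.time))
            arrivals[i] = tau + np.abs(grid.time - t0)
        winner = np.argmin(arrivals, axis=0)
        origin_pos = np.array([p for p, _ in origins])
        direction = np.where(grid.centres >= origin_pos[winner], RIGHT, LEFT).astype(np.int8)
        flips = np.nonzero((direction[:-1] == RIGHT) & (direction[1:] == LEFT))[0]
        terminations = [float((grid.centres[i] + grid.centres[i + 1]) / 2.0) for i in flips]
        cell[chrom] = CellChromMap(origins=origins, direction=direction, terminations=terminations)
    return cell


def simulate_population(model: ForkModel, rng: np.random.Generator) -> list[CellReplicationMap]:
    """Simulate ``model.n_cells`` independent cells."""
    return [simulate_cell(model, rng) for _ in range(model.n_cells)]


def _density_tables(model: ForkModel):
    """Flattened genome-wide residence-time sampling distribution."""
    chroms = list(model.genome)
    chrom_idx, cell_idx, weights = [], [], []
    for ci, chrom in enumerate(chroms):
        grid = model.grid_for(chrom)
        w = grid.rho * grid.widths
        chrom_idx.append(np.full(len(w), ci))
        cell_idx.append(np.arange(len(w)))
        weights.append(w)
    chrom_idx = np.concatenate(chrom_idx)
    cell_idx = np.concatenate(cell_idx)
    weights = np.concatenate(weights)
    return chroms, chrom_idx, cell_idx, weights / weights.sum()


def _random_umis(n: int, rng: np.random.Generator, length: int = 8) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in _BASES[codes]])


READ_COLUMNS = [
    "read_id", "sample", "cell", "chrom", "pos", "strand",
    "direction", "umi", "is_duplicate", "t_class",
]


def sample_reads(
    model: ForkModel,
    rng: np.random.Generator,
    population: list[CellReplicationMap] | None = None,
    n_reads: int | None = None,
    sample: str = "sample",
) -> pd.DataFrame:
    """Draw truth-labelled break reads from the residence-time density.

    Read positions are sampled with probability density proportional to
    1/v(x); each read is attributed to a random cell whose local fork
    direction fixes the read strand (rightward fork -> reverse strand).
    PCR duplicates are appended as clones with identical UMI and position;
    a ``noT_fraction`` of reads is labelled RNA-like.  With ``n_reads``
    unset, the total is Poisson(n_cells * capture_rate).
    """
    if population is None:
        population = simulate_population(model, rng)
    if n_reads is None:
        n_reads = int(rng.poisson(model.n_cells * model.capture_rate))
    chroms, chrom_idx, cell_idx, probs = _density_tables(model)
    draw = rng.choice(len(probs), size=n_reads, p=probs)
    cells = rng.integers(0, len(population), size=n_reads)
    rows_chrom = chrom_idx[draw]
    rows_cell = cell_idx[draw]

    pos = np.empty(n_reads, dtype=np.int64)
    direction = np.empty(n_reads, dtype=np.int8)
    for ci, chrom in enumerate(chroms):
        mask = rows_chrom == ci
        if not mask.any():
            continue
        grid = model.grid_for(chrom)
        starts = grid.centres - grid.widths / 2.0
        offs = rng.random(mask.sum()) * grid.widths[rows_cell[mask]]
        pos[mask] = np.minimum(
            (starts[rows_cell[mask]] + offs).astype(np.int64), model.genome[chrom] - 1
        )
        dirs = np.stack([population[c][chrom].direction for c in range(len(population))])
        direction[mask] = dirs[cells[mask], rows_cell[mask]]

    frame = pd.DataFrame(
        {
            "read_id": [f"read{i:08d}" for i in range(n_reads)],
            "sample": sample,
            "cell": cells,
            "chrom": np.array(chroms, dtype=object)[rows_chrom],
            "pos": pos,
            "strand": np.where(direction == RIGHT, "-", "+"),
            "direction": direction,
            "umi": _random_umis(n_reads, rng),
            "is_duplicate": False,
            "t_class": np.where(rng.random(n_reads) < model.noT_fraction, "noT", "T"),
        }
    )
    if model.duplicate_rate > 0:
        dup = frame[rng.random(n_reads) < model.duplicate_rate].copy()
        dup["is_duplicate"] = True
        dup["read_id"] = dup["read_id"] + "dup"
        frame = pd.concat([frame, dup], ignore_index=True)
    return frame[READ_COLUMNS]


def truth_rfd(
    model: ForkModel,
    population: list[CellReplicationMap],
    scheme: BinningScheme,
) -> pd.DataFrame:
    """Ground-truth RFD per window: residence-weighted mean fork direction.

    Equals 2*P(rightward) - 1 when speed is uniform; with variable speed
    each position is weighted by its expected read density 1/v.
    """
    pieces = []
    for chrom, length in model.genome.items():
        grid = model.grid_for(chrom)
        mean_dir = np.mean(
            [cell[chrom].direction for cell in population], axis=0
        )
        weights = grid.rho * grid.widths
        n = scheme.n_windows(length)
        rfd = np.full(n, np.nan)
        starts = np.arange(n) * scheme.step
        for k in range(n):
            lo, hi = scheme.window_span(k, length)
            mask = (grid.centres >= lo) & (grid.centres < hi)
            if mask.any():
                rfd[k] = np.average(mean_dir[mask], weights=weights[mask])
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + scheme.window_size, length),
                    "rfd": rfd,
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def snapshot_sample_reads(
    model: ForkModel,
    rng: np.random.Generator,
    population: list[CellReplicationMap],
    n_timepoints: int = 50,
) -> pd.DataFrame:
    """Explicit time-snapshot sampler (slow; independent check).

    At each of ``n_timepoints`` uniformly spaced times within each cell's
    S phase, records the positions of all active forks.  The aggregated
    position distribution converges to the residence-time density used by
    :func:`sample_reads`.
    """
    rows = []
    for ci, cell in enumerate(population):
        for chrom in model.genome:
            grid = model.grid_for(chrom)
            cmap = cell[chrom]
            arrivals = np.empty((len(cmap.origins), len(grid.centres)))
            for i, (pos, tau) in enumerate(cmap.origins):
                t0 = float(np.interp(pos, grid.centres, grid.time))
                arrivals[i] = tau + np.abs(grid.time - t0)
            arrival = arrivals.min(axis=0)
            t_end = arrival.max()
            t_start = min(tau for _, tau in cmap.origins)
            for t in np.linspace(t_start, t_end, n_timepoints, endpoint=False):
                # a fork sits wherever the replication boundary is at time t:
                # cells already replicated next to cells not yet replicated
                done = arrival <= t
                edges = np.nonzero(done[:-1] != done[1:])[0]
                for e in edges:
                    direction = cmap.direction[e] if done[e] else cmap.direction[e + 1]
                    frontier = e if done[e] else e + 1
                    rows.append(
                        {
                            "cell": ci,
                            "chrom": chrom,
                            "pos": int(grid.centres[frontier]),
                            "direction": int(direction),
                        }
                    )
    return pd.DataFrame(rows)


# --- emission of sequencing-format outputs -----------------------------------


def load_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load chromosome sequences from a FASTA file (uppercased strings)."""
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fasta:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def random_genome_sequences(
    genome: Mapping[str, int], rng: np.random.Generator
) -> dict[str, str]:
    """I.i.d. random nucleotide sequence for each chromosome."""
    return {
        chrom: "".join(_BASES[rng.integers(0, 4, size=length)])
        for chrom, length in genome.items()
    }


def write_genome_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def emit_fastq(
    reads: pd.DataFrame,
    sequences: Mapping[str, str],
    layout: ReadLayout,
    table: BarcodeTable,
    rng: np.random.Generator,
    fastq_path: str | os.PathLike,
    truth_path: str | os.PathLike | None = None,
    read_length: int = 60,
    polyt_p: float = 0.5,
) -> pd.DataFrame:
    """Write raw multiplexed FASTQ (UMI + barcode + poly-T + insert) + truth.

    The insert is the reverse complement of the forward-strand sequence
    ending at the break for reverse-strand reads, and the forward-strand
    sequence starting at the break for forward-strand reads, so alignment
    recovers the break coordinate exactly.  Poly-T length is drawn from
    1 + Geometric (mean 2); noT reads get no poly-T and a non-T first
    insert base (mutated if the genomic base is T).  Reads running off a
    chromosome end are truncated and flagged in the truth table.
    """
    in_read = table.in_read
    unknown = set(reads["sample"]) - set(in_read)
    if unknown:
        raise ValueError(f"reads reference samples missing from barcode table: {sorted(unknown)}")
    truth_rows = []
    with open(fastq_path, "w") as fh:
        for row in reads.itertuples(index=False):
            seq = sequences[row.chrom]
            if row.t_class == "noT":
                polyt = 0
            else:
                polyt = int(rng.geometric(polyt_p))
            insert_len = read_length - layout.header_length - polyt
            insert_len = max(insert_len, layout.min_remaining_length)
            truncated = False
            if row.strand == "-":
                lo = row.pos - insert_len + 1
                if lo < 0:
                    lo, truncated = 0, True
                insert = reverse_complement(seq[lo : row.pos + 1])
            else:
                hi = row.pos + insert_len
                if hi > len(seq):
                    hi, truncated = len(seq), True
                insert = seq[row.pos : hi]
            if row.t_class == "noT" and insert[:1] == "T":
                insert = rng.choice(["A", "C", "G"]) + insert[1:]
            if len(insert) < layout.min_remaining_length:
                # molecule ran off the chromosome end: the sequencer keeps
                # reading into downstream adaptor; pad so read length holds
                insert = insert + "A" * (layout.min_remaining_length - len(insert))
            full = row.umi + in_read[row.sample] + "T" * polyt + insert
            qual = "I" * len(full)
            fh.write(f"@{row.read_id}\n{full}\n+\n{qual}\n")
            truth_rows.append(
                {
                    "read_id": row.read_id,
                    "sample": row.sample,
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "strand": row.strand,
                    "is_duplicate": row.is_duplicate,
                    "t_class": row.t_class,
                    "polyT_run": polyt,
                    "truncated": truncated,
                }
            )
    truth = pd.DataFrame(truth_rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def _pseudo_sequence(chrom: str, pos: int, strand: str, length: int) -> str:
    """Deterministic position-keyed stand-in read sequence (synthetic).

    Used when no genome FASTA accompanies the alignments; duplicates (same
    position and strand) share it while distinct molecules differ, which is
    all the sequence-augmented low-MAPQ dedup key needs.
    """
    rng = np.random.default_rng(abs(hash((chrom, pos, strand))) % (2**31))
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def emit_alignments(
    reads: pd.DataFrame,
    genome: Mapping[str, int],
    rng: np.random.Generator,
    sam_path: str | os.PathLike,
    multicopy_fraction: float = 0.0,
    read_length: int = 50,
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Write coordinate-sorted SAM at truth coordinates (bypasses mapping).

    MAPQ follows a two-component model: unique reads get 42, a configurable
    ``multicopy_fraction`` gets a value drawn uniformly from 0..20 so both
    deduplication paths are exercised.  PCR duplicate pairs share MAPQ and
    coordinates.  The UMI rides in the read name (readproc convention).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(length)} for chrom, length in genome.items()],
    }
    chrom_ids = {chrom: i for i, chrom in enumerate(genome)}

    base_ids = reads["read_id"].str.removesuffix("dup")
    unique_ids = base_ids.unique()
    lowq = dict(
        zip(
            unique_ids,
            rng.random(len(unique_ids)) < multicopy_fraction,
        )
    )
    mapq_low = dict(zip(unique_ids, rng.integers(0, 21, size=len(unique_ids))))

    entries = []
    for row, base in zip(reads.itertuples(index=False), base_ids):
        length = min(read_length, genome[row.chrom])
        if row.strand == "+":
            start = min(int(row.pos), genome[row.chrom] - length)
        else:
            start = max(int(row.pos) - length + 1, 0)
        if sequences is not None:
            # SAM stores the forward-strand sequence for both orientations
            seq = sequences[row.chrom][start : start + length]
        else:
            seq = _pseudo_sequence(row.chrom, start, row.strand, length)
        mapq = int(mapq_low[base]) if lowq[base] else 42
        entries.append(
            (
                chrom_ids[row.chrom],
                start,
                f"{row.read_id}{UMI_SEPARATOR}{row.umi}",
                row.strand,
                mapq,
                seq,
                length,
            )
        )
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for ref_id, start, name, strand, mapq, seq, length in entries:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.reference_id = ref_id
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = f"{length}M"
            a.flag = 16 if strand == "-" else 0
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            out.write(a)
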