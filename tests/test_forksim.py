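"""Replication-fork simulator: geometry, sampling laws, emission formats."""

import numpy as np
import pandas as pd
import pysam
import pytest
import scipy.stats

from traelseq import forksim
from traelseq.breakmap import read_alignments, reduce_to_break, deduplicate
from traelseq.forksim import (
    ForkModel,
    InitiationZone,
    LEFT,
    RIGHT,
    constant_speed,
    distance_step_speed,
    emit_alignments,
    emit_fastq,
    random_genome_sequences,
    region_scaled_speed,
    sample_reads,
    simulate_cell,
    simulate_population,
    snapshot_sample_reads,
    truth_rfd,
)
from traelseq.readproc import BarcodeTable, ReadLayout, reverse_complement
from traelseq.rfdtracks import BinningScheme
from tests.conftest import ADAPTOR_BARCODES


def point_origin_model(length=2_000_000, centre=1_000_000, **kw):
    """One near-point, fully efficient origin with deterministic firing."""
    defaults = dict(n_cells=5, capture_rate=100.0)
    defaults.update(kw)
    return ForkModel(
        genome={"chr1": length},
        izs=[InitiationZone("chr1", centre - 500, centre + 500, efficiency=1.0,
                            firing_time=1.0, firing_spread=0.0)],
        **defaults,
    )


class TestSimulateCell:
    def test_single_origin_geometry(self):
        model = point_origin_model()
        cell = simulate_cell(model, np.random.default_rng(1))["chr1"]
        grid = model.grid_for("chr1")
        x0 = cell.origins[0][0]
        assert (cell.direction[grid.centres > x0 + model.grid] == RIGHT).all()
        assert (cell.direction[grid.centres < x0 - model.grid] == LEFT).all()
        assert cell.terminations == []

    def test_two_equal_origins_terminate_at_midpoint(self):
        model = ForkModel(
            genome={"chr1": 4_000_000},
            izs=[
                InitiationZone("chr1", 999_500, 1_000_500, 1.0, 1.0, 0.0),
                InitiationZone("chr1", 2_999_500, 3_000_500, 1.0, 1.0, 0.0),
            ],
        )
        cell = simulate_cell(model, np.random.default_rng(2))["chr1"]
        assert len(cell.terminations) == 1
        midpoint = (cell.origins[0][0] + cell.origins[1][0]) / 2
        assert cell.terminations[0] == pytest.approx(midpoint, abs=2 * model.grid)

    def test_staggered_firing_displaces_termination(self):
        """tau2 = tau1 + delta at constant v moves the meeting point
        v * delta / 2 toward the later origin (closed form)."""
        v0, delta = 1000.0, 400.0
        model = ForkModel(
            genome={"chr1": 4_000_000},
            izs=[
                InitiationZone("chr1", 999_500, 1_000_500, 1.0, 1.0, 0.0),
                InitiationZone("chr1", 2_999_500, 3_000_500, 1.0, 1.0 + delta, 0.0),
            ],
            speed=constant_speed(v0),
        )
        cell = simulate_cell(model, np.random.default_rng(3))["chr1"]
        x1, x2 = cell.origins[0][0], cell.origins[1][0]
        expected = (x1 + x2) / 2 + v0 * delta / 2
        assert cell.terminations[0] == pytest.approx(expected, abs=2 * model.grid)

    def test_full_coverage_no_gaps(self):
        """Every grid position is replicated by exactly one fork direction."""
        model = ForkModel(
            genome={"chr1": 3_000_000},
            izs=[
                InitiationZone("chr1", 400_000, 500_000, 0.5),
                InitiationZone("chr1", 1_400_000, 1_500_000, 0.5),
                InitiationZone("chr1", 2_400_000, 2_500_000, 0.5),
            ],
        )
        for seed in range(5):
            cell = simulate_cell(model, np.random.default_rng(seed))["chr1"]
            assert np.isin(cell.direction, [RIGHT, LEFT]).all()
            assert len(cell.direction) == len(model.grid_for("chr1").centres)

    def test_passive_replication_of_unfired_iz(self):
        model = ForkModel(
            genome={"chr1": 2_000_000},
            izs=[
                InitiationZone("chr1", 499_000, 501_000, 1.0, 1.0, 0.0),
                # never fires; must be replicated by the incoming fork
                InitiationZone("chr1", 1_499_000, 1_501_000, 1e-9, 1.0, 0.0),
            ],
        )
        cell = simulate_cell(model, np.random.default_rng(4))["chr1"]
        assert len(cell.origins) == 1
        grid = model.grid_for("chr1")
        assert (cell.direction[grid.centres > 1_400_000] == RIGHT).all()

    def test_determinism_under_fixed_seed(self):
        model = point_origin_model()
        a = simulate_cell(model, np.random.default_rng(9))["chr1"]
        b = simulate_cell(model, np.random.default_rng(9))["chr1"]
        assert a.origins == b.origins
        assert np.array_equal(a.direction, b.direction)


class TestSampleReads:
    def test_uniform_speed_gives_uniform_positions(self):
        model = point_origin_model(n_cells=10)
        rng = np.random.default_rng(5)
        pop = simulate_population(model, rng)
        reads = sample_reads(model, rng, population=pop, n_reads=20_000)
        counts, _ = np.histogram(reads["pos"], bins=np.arange(0, 2_050_000, 50_000))
        p = scipy.stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_read_density_follows_inverse_speed(self):
        """v doubled on the right half halves the read density there."""

        def v(chrom, x):
            return np.where(np.asarray(x) < 1_000_000, 1000.0, 2000.0)

        model = point_origin_model(speed=v, n_cells=5)
        rng = np.random.default_rng(6)
        pop = simulate_population(model, rng)
        reads = sample_reads(model, rng, population=pop, n_reads=30_000)
        left = (reads["pos"] < 1_000_000).sum()
        right = len(reads) - left
        ratio = right / left
        assert ratio == pytest.approx(0.5, abs=0.03)

    def test_polarity_right_of_lone_origin(self):
        model = point_origin_model()
        rng = np.random.default_rng(7)
        pop = simulate_population(model, rng)
        reads = sample_reads(model, rng, population=pop, n_reads=5_000)
        right = reads[reads["pos"] > 1_100_000]
        assert (right["strand"] == "-").all()  # rightward forks -> reverse reads
        left = reads[reads["pos"] < 900_000]
        assert (left["strand"] == "+").all()

    def test_duplicates_clone_umi_and_position(self):
        model = point_origin_model(duplicate_rate=0.3)
        rng = np.random.default_rng(8)
        reads = sample_reads(model, rng, n_reads=2_000)
        dups = reads[reads["is_duplicate"]]
        assert len(dups) > 0
        originals = reads.set_index("read_id")
        for row in dups.itertuples(index=False):
            src = originals.loc[row.read_id.removesuffix("dup")]
            assert src["umi"] == row.umi and src["pos"] == row.pos

    def test_not_fraction_labelled(self):
        model = point_origin_model(noT_fraction=0.05)
        rng = np.random.default_rng(9)
        reads = sample_reads(model, rng, n_reads=10_000)
        frac = (reads["t_class"] == "noT").mean()
        lo, hi = scipy.stats.binom.interval(0.999, 10_000, 0.05)
        assert lo / 10_000 <= frac <= hi / 10_000

    def test_agrees_with_snapshot_sampler(self):
        """Residence-time sampling matches the explicit time-snapshot
        sampler's position distribution on a tiny two-speed genome."""

        def v(chrom, x):
            return np.where(np.asarray(x) < 100_000, 500.0, 1000.0)

        model = ForkModel(
            genome={"chr1": 200_000},
            izs=[InitiationZone("chr1", 0, 1000, 1.0, 1.0, 0.0)],
            speed=v,
            n_cells=20,
            grid=500,
        )
        rng = np.random.default_rng(10)
        pop = simulate_population(model, rng)
        fast = sample_reads(model, rng, population=pop, n_reads=20_000)
        snap = snapshot_sample_reads(model, rng, pop, n_timepoints=400)
        f_left = (fast["pos"] < 100_000).mean()
        s_left = (snap["pos"] < 100_000).mean()
        # slow half holds 2/3 of residence time
        assert f_left == pytest.approx(2 / 3, abs=0.02)
        assert s_left == pytest.approx(2 / 3, abs=0.02)


class TestTruthRfd:
    def test_lone_origin_truth_track(self):
        model = point_origin_model(n_cells=10)
        rng = np.random.default_rng(11)
        pop = simulate_population(model, rng)
        track = truth_rfd(model, pop, BinningScheme(20_000, 20_000))
        left = track[track["end"] <= 990_000]
        right = track[track["start"] >= 1_010_000]
        assert (left["rfd"] == -1).all()
        assert (right["rfd"] == 1).all()


class TestEmissions:
    def _reads_and_sequences(self, n_reads=200, **model_kw):
        model = point_origin_model(**model_kw)
        rng = np.random.default_rng(12)
        pop = simulate_population(model, rng)
        reads = sample_reads(model, rng, population=pop, n_reads=n_reads, sample="index1")
        sequences = random_genome_sequences(model.genome, rng)
        return model, rng, reads, sequences

    def test_fastq_insert_matches_genome_slice(self, tmp_path, layout, barcode_table):
        model, rng, reads, sequences = self._reads_and_sequences()
        fq = tmp_path / "sim.fastq"
        truth = emit_fastq(reads, sequences, layout, barcode_table, rng, fq,
                           read_length=60)
        with open(fq) as fh:
            records = fh.read().splitlines()
        seqs = {records[i].lstrip("@"): records[i + 1] for i in range(0, len(records), 4)}
        genome = sequences["chr1"]
        checked = 0
        for row in truth.itertuples(index=False):
            if row.truncated or row.t_class == "noT":
                continue
            raw = seqs[row.read_id]
            insert = raw[12 + row.polyT_run:]
            if row.strand == "-":
                expected = reverse_complement(genome[row.pos - len(insert) + 1 : row.pos + 1])
            else:
                expected = genome[row.pos : row.pos + len(insert)]
            assert insert == expected
            checked += 1
        assert checked > 100

    def test_fastq_not_reads_have_no_leading_t(self, tmp_path, layout, barcode_table):
        model, rng, reads, sequences = self._reads_and_sequences(noT_fraction=0.5)
        fq = tmp_path / "sim.fastq"
        truth = emit_fastq(reads, sequences, layout, barcode_table, rng, fq)
        with open(fq) as fh:
            records = fh.read().splitlines()
        seqs = {records[i].lstrip("@"): records[i + 1] for i in range(0, len(records), 4)}
        nots = truth[truth["t_class"] == "noT"]
        assert len(nots) > 0
        for row in nots.itertuples(index=False):
            assert row.polyT_run == 0
            assert seqs[row.read_id][12] != "T"

    def test_fastq_duplicates_identical(self, tmp_path, layout, barcode_table):
        model = point_origin_model(duplicate_rate=0.5)
        rng = np.random.default_rng(13)
        reads = sample_reads(model, rng, n_reads=200, sample="index1")
        sequences = random_genome_sequences(model.genome, rng)
        truth = emit_fastq(reads, sequences, layout, barcode_table, rng,
                           tmp_path / "sim.fastq")
        dups = truth[truth["is_duplicate"]]
        by_id = truth.set_index("read_id")
        assert len(dups) > 0
        for row in dups.itertuples(index=False):
            src = by_id.loc[row.read_id.removesuffix("dup")]
            assert (src["chrom"], src["pos"], src["strand"]) == (row.chrom, row.pos, row.strand)

    def test_alignments_round_trip_breaks_exactly(self, tmp_path):
        model, rng, reads, sequences = self._reads_and_sequences(n_reads=500)
        sam = tmp_path / "sim.sam"
        emit_alignments(reads, model.genome, rng, sam, sequences=sequences)
        aligned = read_alignments(sam, sample="index1")
        recovered = {
            r.name.rsplit("_", 1)[0]: reduce_to_break(r) for r in aligned
        }
        assert len(recovered) == len(reads)
        for row in reads.itertuples(index=False):
            rec = recovered[row.read_id]
            assert (rec.chrom, rec.pos, rec.strand) == (row.chrom, row.pos, row.strand)

    def test_alignments_sorted_and_valid(self, tmp_path):
        model, rng, reads, sequences = self._reads_and_sequences(n_reads=300)
        sam = tmp_path / "sim.sam"
        emit_alignments(reads, model.genome, rng, sam)
        with pysam.AlignmentFile(str(sam)) as fh:
            assert fh.header["HD"]["SO"] == "coordinate"
            positions = [a.reference_start for a in fh]
        assert positions == sorted(positions)

    def test_mapq_mixture_fraction(self, tmp_path):
        model, rng, reads, _ = self._reads_and_sequences(n_reads=2_000)
        sam = tmp_path / "sim.sam"
        emit_alignments(reads, model.genome, rng, sam, multicopy_fraction=0.3)
        with pysam.AlignmentFile(str(sam)) as fh:
            mapqs = np.array([a.mapping_quality for a in fh])
        assert set(np.unique(mapqs)) <= set(range(21)) | {42}
        frac_low = (mapqs <= 20).mean()
        lo, hi = scipy.stats.binom.interval(0.999, len(mapqs), 0.3)
        assert lo / len(mapqs) <= frac_low <= hi / len(mapqs)

    def test_dedup_recovers_unique_molecules(self, tmp_path):
        """PCR duplicates injected by the simulator are exactly removed."""
        model = point_origin_model(duplicate_rate=0.4)
        rng = np.random.default_rng(14)
        reads = sample_reads(model, rng, n_reads=1_000, sample="index1")
        sam = tmp_path / "sim.sam"
        emit_alignments(reads, model.genome, rng, sam, multicopy_fraction=0.2)
        aligned = read_alignments(sam, sample="index1")
        retained, stats = deduplicate(aligned)
        n_unique = (~reads["is_duplicate"]).sum()
        # hq duplicates are exact; lq dedup can additionally merge distinct
        # molecules that collide in (UMI, prefix) space -- rare here
        assert abs(stats.retained - n_unique) <= 0.01 * n_unique
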