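# Methods

## The measurement model

TrAEL-seq ligates an adaptor to free single-stranded 3′ DNA ends. In
proliferating cells the dominant such end is the 3′ terminus of the
replication-fork leading strand, so each deduplicated read is treated as one
observation of one fork in one cell. Three consequences drive everything in
this package:

1. **Position.** The first aligned base 5′ of the strand break (read 5′ end)
   is the fork's leading-strand terminus at capture time; all quantitation
   is done on this single base.
2. **Strand.** A rightward-moving fork's leading strand is the reverse
   (Crick) strand template product, so rightward forks yield reverse-strand
   reads and leftward forks forward-strand reads. Replication fork
   directionality per window is RFD = (R − F)/(R + F) ∈ [−1, +1], +1 meaning
   all forks move left→right.
3. **Density.** Every base replicates exactly once per cell cycle, so in an
   unsynchronized population the number of captured ends per unit length is
   proportional to the time a fork spends there — the residence time
   1/v(x). Uniform speed ⇒ uniform density; elevated density ⇒ slower or
   pausing forks. This is the identity the profiling module and the
   simulator are built on.

## Read structure and demultiplexing

Reads are `[8 nt UMI][4 nt barcode][poly-T run][insert]`. The barcode is the
ligation-junction sample index; because reads traverse the adaptor on the
complementary strand, the in-read barcode is by default the reverse
complement of the adaptor-strand index (a configuration switch covers
dialects that list in-read sequences). Assignment uses a unique-best
Hamming rule with tolerance 1: a read is assigned only if exactly one
barcode is nearest within tolerance; ties go to UNASSIGNED. The standard
six-plex index set contains pairs at Hamming distance 2, which with this
rule can never cause *mis*assignment (a 1-error read equidistant from two
barcodes is left unassigned), so the table validator enforces pairwise
distance ≥ 2·tolerance rather than the stricter > 2·tolerance that would
also guarantee every 1-error read is rescued.

Poly-T trimming removes the maximal run of literal T after the barcode; at
least one trimmed T marks the read as DNA-derived ("T" class), none as
"noT" (candidate RNA-derived; kept as a separate channel, not discarded).
A strict literal run is reproducible and conservative; it can consume
genomic T/A bases adjacent to the tail, an ambiguity inherent to A-tailing
chemistry rather than to the implementation. Inserts shorter than 20 nt
after trimming are discarded as unmappable (configurable). The UMI travels
as a read-name suffix after `_`, keeping all downstream files standard
FASTQ/SAM.

## Deduplication

Two key functions, switched on mapping quality with boundary 20:

* MAPQ > 20 (unique mappers): key = (sample, chromosome, break position,
  strand, UMI). Position in the key is what makes the scheme copy-number
  aware: identical molecules mapped to different repeat copies survive.
* MAPQ ≤ 20 (multi-mappers): position is untrustworthy, so key = (sample,
  UMI, first 10 read bases). The sequence prefix augments the 4⁸ = 65,536
  UMI states, which alone are fewer than the molecules in a library.

Records at exactly MAPQ 20 are deduplicated with the sequence key but
retained by the downstream analysis filter (MAPQ ≥ 20); both thresholds are
independently configurable, which reconciles the two conventions without a
gap. The survivor in each duplicate group is the first read in
coordinate-sorted order with read-name tie-break — an arbitrary but
deterministic choice that makes deduplication idempotent and exactly
reproducible; the test suite checks equality with a brute-force group-by.
Low-MAPQ keys are held genome-wide in a hash set; UMIs are matched exactly
(no error-correction networks), matching the exact-key semantics of the
position-aware class.

## RFD tracks and normalization

Windows are anchored at coordinate 0 per chromosome, 0-based half-open,
final partial window kept. The display convention is 20-kb windows every
2 kb (each break lands in 10 windows); profiling uses non-overlapping 50-kb
tiles. RFD is computed directly on the −1..+1 scale. Windows with fewer
than `min_reads` (default 1) breaks are missing, not zero: a window with no
data has no directionality estimate, and missing windows are omitted from
bedGraph output.

Within a multiplexed set no per-sample normalization is applied — samples
in one pool share every enzymatic and amplification step, so their relative
read counts are informative. Across sets, one scalar per set rescales each
set's total to the mean set total, preserving within-set ratios to machine
precision.

## Initiation-zone segmentation

The segmenter is a deliberately small, self-contained stand-in for
published RFD-based HMM origin callers, operating on increments
Δrfd_k = rfd_{k+1} − rfd_k of a non-overlapping RFD track:

* States UP, DOWN, FLAT; Gaussian emissions with tied means (+μ, −μ, 0) and
  shared σ; sticky transitions with self-probability p_stay = 0.99 and the
  remainder split equally.
* Decoding is exact Viterbi in log space with a uniform initial
  distribution and a deterministic tie-break toward FLAT (tests verify
  equality with exhaustive 3ⁿ enumeration up to n = 12, including missing
  values).
* Missing increments emit the FLAT mean under every state with σ inflated
  10×: effectively state-neutral, they keep the chain connected across
  coverage gaps without driving switches.
* Maximal UP runs of ≥ `min_zone_bins` (default 3) become IZ calls, DOWN
  runs TZ calls; the zone centre is the midpoint. Negating the track swaps
  IZ and TZ exactly.

**Parameter estimation.** μ is initialized from the increment-distribution
tails (half the spread between the mean top and bottom deciles) and refined
by up to 20 hard-assignment EM sweeps: assign each increment to the nearest
of (0, +μ, −μ), update μ from the assigned UP/DOWN values and σ from pooled
residuals. Two couplings are intentionally avoided, both found to be
failure modes rather than refinements. Coupling estimation to the sticky
transitions (classic full EM) lets 3–5-bin transition ramps absorb into
FLAT, inflating σ until the decoder returns FLAT everywhere. Soft
posterior-weighted means over the marginal distribution over-weight the
steepest increments, biasing μ high; since an increment decodes UP only
when it exceeds μ/2, ramp shoulders then drop out and UP runs fragment
below the length filter. The hard nearest-mean rule estimates exactly the
quantity the decoder thresholds on and converges to the mean of all
transition increments.

**Known limitation.** Viterbi is a point estimate: when a ramp shoulder
sits near the μ/2 boundary, a 2-bin UP run and a 3-bin run can be almost
equally probable, and the length filter then discards the zone. At the
noise level studied in the validation scenario (increment noise σ = μ/4,
200-kb zones, 50-kb bins) this loses ~2% of zones at some random seeds.
Zone width must span ≥ `min_zone_bins` of the chosen binning for a zone to
be callable at all — segment at bins several times smaller than the
expected zone width. Concordance with any specific external caller is
qualitative only; external IZ BED files are accepted as a bypass.

## Distance profiles, stratification, AUC, metaplots

The window table counts breaks in non-overlapping 50-kb tiles, flags
windows whose count is outside median ± 5·MAD (raw median absolute
deviation) or which overlap user exclusion intervals (copy-number variants,
peri-centromeres), and records the distance d from the window midpoint to
the nearest feature centre. Flagged windows are excluded from statistics
but kept in the table for accounting.

The distance profile groups unflagged windows by floor(d / 100 kb) and
reports mean count, Student-t CI half-width (level 0.95 by default; some
published workflows report 96%, so the level is a parameter) and n per bin,
truncated at 3 Mb where mammalian-genome bins become too sparse for a
useful interval (2 Mb for earliest-zone analyses). With a feature subset
(e.g. the earliest-replicating 5% of zones, supplied as a user score —
deriving replication timing is out of scope), d is measured to the subset,
and windows lying closer to a non-subset feature can be excluded.

Stratification flags windows at or above the (1 − f) quantile (type-7
interpolation) of an external score, ties at the threshold dropped. AUC
comparisons integrate the profile trapezoidally over a distance range and
compare replicate groups by paired t-test (replicate time courses are
matched; Welch's test is the unpaired option).

Gene metaplots convert counts to per-bp densities in 20 fixed-width flank
bins per side (±100 kb) and a gene body rescaled to 20 bins, reverse
minus-strand genes, average within score-quantile strata (default 0–40,
40–70, 70–90, 90–100%), and rescale each stratum's profile so the outer
halves of the two flanks average 1 — making the body level directly a fold
enrichment. Genes shorter than one bp per body bin, or whose flanks leave
the chromosome (which would read as depressed background), are skipped and
tallied.

## The simulator

The simulator defines the ground truth the pipeline is validated against.

* **Genome**: named chromosomes with lengths; sequences either random
  i.i.d. nucleotides or a user FASTA.
* **Origin firing**: per cell, each IZ fires with probability e_i; the
  origin position is uniform in the zone (initiation is zone-like, not a
  point), the firing time Normal(τ_i, spread) truncated at 0. Chromosomes
  with no fired origin are resampled — conditioning on ≥ 1 origin per
  chromosome per S phase.
* **Replication sweep**: on a 1-kb grid, cumulative travel time
  T(x) = ∫ dx′/v(x′); a fork from origin (x_k, τ_k) reaches x at
  τ_k + |T(x) − T(x_k)|; each position is replicated by the first-arriving
  fork. This yields per-position direction, passive replication of unfired
  zones, and termination points where a rightward and leftward fork meet —
  full coverage with no position replicated twice, by construction.
* **Read sampling**: positions are drawn with density ∝ 1/v(x)
  (residence-time sampling), each read attributed to a random cell whose
  local fork direction sets the strand. This is equivalent in expectation
  to explicitly sampling fork positions at random times — a slow snapshot
  sampler is kept and tested against it on a small two-speed genome — but
  orders of magnitude cheaper. PCR duplicates are appended as clones
  (probability `duplicate_rate`, identical UMI and position); a
  `noT_fraction` of reads is emitted without poly-T and with a non-T first
  insert base.
* **Emission**: FASTQ reads rebuild the full layout (UMI + in-read barcode
  + poly-T with length ~ 1 + Geometric(0.5), mean 2 — tail lengths are not
  otherwise constrained — + insert read 3′→5′ from the break, so reverse
  for rightward forks); molecules running off a chromosome end are padded
  (adaptor read-through) and flagged in the truth table. Alignment
  emission bypasses mapping, writing coordinate-sorted SAM at truth
  coordinates with MAPQ 42 for unique reads and a configurable multi-copy
  fraction drawn uniformly from 0–20, exercising both deduplication paths.
* **Truth tracks**: per-window truth RFD is the residence-weighted mean
  fork direction across cells; planted zones, per-read labels (cell,
  position, direction, duplicate status, class) accompany all output.

What the simulator does **not** emulate: sequence-context break hotspots,
fork stalling/reversal dynamics (a stalling agent can be approximated by
editing v(x) near early zones), double-strand-break signals, mapping
ambiguity (multi-copy MAPQ is assigned, not caused by repeats), base-call
errors, and barcode corruption (tests corrupt barcodes explicitly where
needed). Passing tests therefore demonstrate correctness of the
computational pipeline under the stated replication model, not robustness
to alignment artefacts or library chemistry beyond that model.

## Validation scenarios and problem sizes

Chosen so the full suite runs in well under a minute per scenario while
keeping per-window counts in the regime the statistics assume:

* RFD reconstruction: 10 Mb, five 40-kb zones at 2-Mb spacing, efficiency
  1, 50 cells, 100,000 reads (≈200 per 20-kb window); Pearson r against
  truth RFD > 0.95, windows beside isolated origins exactly ±1.
* Zone recovery: 12.5 Mb, ten 200-kb zones at 1.25-Mb spacing, 200 cells,
  50-kb bins, Gaussian RFD noise calibrated so increment noise is μ/4.
* Fork-speed readout: four 4-Mb chromosomes with central zones, v stepping
  1000 → 2000 bp/time at d = 1 Mb, 20 cells, 60,000 reads per replicate,
  four replicates; far/near density ratio 0.5 within summed 95% CIs, with
  a uniform-speed control at ratio 1. "Flat within CI" is assessed by this
  same near/far contrast — testing every bin against a grand mean at 95%
  would fail by multiplicity even under the null.
* Stratification null: the same variable-speed genome with an independent
  uniform score; dropping the top 75% leaves each profile bin within
  overlapping 95% CIs of the full profile.
* Gene metaplot: 10 Mb, forty 60-kb genes, residence time ×1.2 planted in
  the top-decile gene bodies; recovered body/flank ratio 1.2 (±0.05 at
  300,000 reads).

Units: genomic coordinates in bp (0-based half-open); fork speed in bp per
arbitrary time unit — only the product of speed and firing-time scale
matters, so τ ≈ 1 time unit with v ≈ 1000 bp/unit puts origin spacing and
S-phase duration in a realistic ratio for the megabase zone spacings used.
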