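"""Read-density profiling around initiation zones and genes.

In an unsynchronized population every base replicates exactly once per cell
cycle, so if replisomes moved at a uniform speed the density of replication
forks -- and hence of TrAEL-seq reads -- would be uniform along the genome.
Regions of elevated read density are therefore regions where forks pause
more or move more slowly.  This module implements the quantitations built
on that null:

* read counts summed in non-overlapping 50-kb windows, with robust
  flagging of aberrant windows (CNVs, peri-centromeres) and optional
  exclusion intervals;
* mean read count as a function of distance from the nearest initiation
  zone centre (100-kb distance bins, t-based confidence interval, n per
  bin, truncation at 3 Mb; optionally restricted to a feature subset such
  as the earliest-replicating zones, excluding windows nearer to other
  zones);
* stratified re-profiling after dropping the most-transcribed windows;
* area-under-curve comparisons between replicate groups by t-test;
* stranded gene metaplots with scaled bodies and per-profile background
  normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from traelseq.breakmap import BreakRecord, breaks_to_frame
from traelseq.rfdtracks import BinningScheme, count_breaks

PROFILE_COLUMNS = ["bin_start", "bin_end", "mean", "ci_half", "n"]


def _records_frame(records: Iterable[BreakRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return breaks_to_frame(records)


def nearest_distance(
    chroms: Sequence[str], positions: np.ndarray, centres: Mapping[str, Sequence[int]]
) -> np.ndarray:
    """Distance from each (chrom, position) to the nearest feature centre.

    NaN for positions on chromosomes without any feature.
    """
    sorted_centres = {c: np.sort(np.asarray(v, dtype=float)) for c, v in centres.items()}
    out = np.full(len(positions), np.nan)
    chroms = np.asarray(chroms)
    for chrom in np.unique(chroms):
        cs = sorted_centres.get(chrom)
        if cs is None or len(cs) == 0:
            continue
        mask = chroms == chrom
        x = np.asarray(positions, dtype=float)[mask]
        idx = np.searchsorted(cs, x)
        left = cs[np.clip(idx - 1, 0, len(cs) - 1)]
        right = cs[np.clip(idx, 0, len(cs) - 1)]
        out[mask] = np.minimum(np.abs(x - left), np.abs(x - right))
    return out


def _overlaps_any(
    chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> np.ndarray:
    hit = np.zeros(len(chroms), dtype=bool)
    for chrom, ivs in intervals.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        for lo, hi in ivs:
            hit[mask] |= (starts[mask] < hi) & (ends[mask] > lo)
    return hit


def build_window_table(
    records: Iterable[BreakRecord] | pd.DataFrame,
    scheme: BinningScheme,
    genome_sizes: Mapping[str, int],
    feature_centres: Mapping[str, Sequence[int]],
    exclusion: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    mad_k: float = 5.0,
) -> pd.DataFrame:
    """Per-window read counts with distance-to-feature and aberrance flags.

    Requires a non-overlapping scheme (step == window).  Windows whose
    count lies outside median +/- ``mad_k`` * MAD, or which overlap the
    exclusion intervals, or which lie on a chromosome without features, are
    flagged (``flagged`` column) but kept in the table.
    """
    if scheme.step != scheme.window_size:
        raise ValueError("window table requires non-overlapping windows (step == window)")
    if not any(len(v) for v in feature_centres.values()):
        raise ValueError("no feature centres supplied")
    counts = count_breaks(_records_frame(records), scheme, genome_sizes)
    table = counts.copy()
    table["count"] = table["R"] + table["F"]
    table["midpoint"] = (table["start"] + table["end"]) // 2
    table["d"] = nearest_distance(
        table["chrom"].to_numpy(), table["midpoint"].to_numpy(), feature_centres
    )
    med = float(table["count"].median())
    mad = float((table["count"] - med).abs().median())
    aberrant = (table["count"] - med).abs() > mad_k * mad
    excluded = np.zeros(len(table), dtype=bool)
    if exclusion:
        excluded = _overlaps_any(
            table["chrom"].to_numpy(),
            table["start"].to_numpy(),
            table["end"].to_numpy(),
            exclusion,
        )
    table["flagged"] = aberrant | excluded | table["d"].isna()
    return table.drop(columns=["R", "F"])


def distance_profile(
    table: pd.DataFrame,
    max_dist: float = 3_000_000.0,
    bin_size: int = 100_000,
    level: float = 0.95,
    feature_subset: Mapping[str, Sequence[int]] | None = None,
    exclude_nearer_other: bool = False,
) -> pd.DataFrame:
    """Mean read count per distance bin from the nearest feature centre.

    Unflagged windows are grouped by floor(d / bin_size); each reported bin
    carries the mean count, the t-based confidence half-width at ``level``
    and the number of windows.  Bins beyond ``max_dist`` are truncated and
    empty bins are omitted.  With ``feature_subset`` the distance is
    measured to the subset (e.g. the earliest-replicating initiation
    zones); ``exclude_nearer_other`` additionally drops windows that lie
    closer to a feature outside the subset than to any subset member.
    """
    sub = table.loc[~table["flagged"]].copy()
    d = sub["d"].to_numpy(dtype=float)
    if feature_subset is not None:
        d_sub = nearest_distance(
            sub["chrom"].to_numpy(), sub["midpoint"].to_numpy(), feature_subset
        )
        keep = ~np.isnan(d_sub)
        if exclude_nearer_other:
            keep &= ~(d < d_sub)  # nearest overall feature outside the subset
        sub, d = sub.loc[keep], d_sub[keep]
    keep = d < max_dist
    sub, d = sub.loc[keep], d[keep]
    bins = (d // bin_size).astype(int)
    rows = []
    for b in np.unique(bins):
        vals = sub.loc[bins == b, "count"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            tq = scipy.stats.t.ppf(0.5 + level / 2.0, n - 1)
            ci = float(tq * vals.std(ddof=1) / np.sqrt(n))
        else:
            ci = np.nan
        rows.append(
            {
                "bin_start": int(b) * bin_size,
                "bin_end": (int(b) + 1) * bin_size,
                "mean": mean,
                "ci_half": ci,
                "n": n,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def stratify_windows(
    table: pd.DataFrame, scores: pd.Series | np.ndarray, drop_top_fraction: float
) -> pd.DataFrame:
    """Flag the top-scoring fraction of unflagged windows.

    ``scores`` aligns with the table rows (e.g. PRO-seq read counts per
    window as a nascent-transcription proxy).  Windows at or above the
    (1 - drop_top_fraction) quantile (linear/type-7 interpolation) are
    flagged; ties at the threshold are dropped.
    """
    if not 0 <= drop_top_fraction < 1:
        raise ValueError("drop_top_fraction must be in [0, 1)")
    out = table.copy()
    if drop_top_fraction == 0:
        return out
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(table):
        raise ValueError("scores must align with the window table")
    if np.isnan(scores[~table["flagged"].to_numpy()]).any():
        raise ValueError("score missing for an unflagged window")
    active = ~out["flagged"].to_numpy()
    threshold = np.quantile(scores[active], 1.0 - drop_top_fraction)
    out.loc[active & (scores >= threshold), "flagged"] = True
    return out


def profile_auc(profile: pd.DataFrame, dist_range: tuple[float, float]) -> float:
    """Trapezoidal area under the mean profile over a distance range.

    Bin centres within [lo, hi) form the integration grid.
    """
    lo, hi = dist_range
    centres = (profile["bin_start"] + profile["bin_end"]) / 2.0
    mask = (centres >= lo) & (centres < hi)
    if mask.sum() < 2:
        raise ValueError("AUC needs at least 2 profile bins inside the range")
    return float(np.trapezoid(profile.loc[mask, "mean"], x=centres[mask]))


def auc_compare(
    profiles_a: Sequence[pd.DataFrame],
    profiles_b: Sequence[pd.DataFrame],
    dist_range: tuple[float, float],
    paired: bool = True,
) -> dict:
    """Compare replicate profile groups by AUC over a distance range.

    Returns per-replicate AUCs, the t statistic and the two-sided p value;
    paired t-test when the groups are matched replicates (default),
    otherwise Welch's unpaired test.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need >= 2 replicate profiles per group")
    if paired and len(profiles_a) != len(profiles_b):
        raise ValueError("paired comparison requires equal group sizes")
    auc_a = [profile_auc(p, dist_range) for p in profiles_a]
    auc_b = [profile_auc(p, dist_range) for p in profiles_b]
    if paired:
        stat = scipy.stats.ttest_rel(auc_a, auc_b)
    else:
        stat = scipy.stats.ttest_ind(auc_a, auc_b, equal_var=False)
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "t": float(stat.statistic),
        "p": float(stat.pvalue),
        "paired": paired,
    }


@dataclass
class MetaplotResult:
    """Per-stratum gene metaplot.

    ``profiles`` maps a stratum label to its mean read-density profile
    (reads per bp, background-normalized so the outer flank halves average
    1).  ``bin_centres_rel`` gives, per bin, the position relative to the
    gene: negative bp upstream, [0, 1) scaled body, then bp downstream
    offset by 1.
    """

    profiles: dict[str, np.ndarray]
    n_genes: dict[str, int]
    flank_bins: int
    body_bins: int
    flank: int
    skipped: int

    def body_flank_ratio(self, stratum: str) -> float:
        """Mean body density over mean outer-flank density for a stratum."""
        prof = self.profiles[stratum]
        f, b = self.flank_bins, self.body_bins
        outer = np.r_[prof[: f // 2], prof[-(f // 2):]]
        body = prof[f : f + b]
        return float(body.mean() / outer.mean())


def gene_metaplot(
    records: Iterable[BreakRecord] | pd.DataFrame,
    genes: pd.DataFrame,
    strata: Sequence[tuple[float, float]] = ((0.0, 0.4), (0.4, 0.7), (0.7, 0.9), (0.9, 1.0)),
    flank: int = 100_000,
    flank_bins: int = 20,
    body_bins: int = 20,
    genome_sizes: Mapping[str, int] | None = None,
) -> MetaplotResult:
    """Average read density over genes +/- flank, stratified by a score.

    ``genes`` needs columns chrom, start, end, strand and score (the
    expression proxy used for stratification; quantile bands over the
    score define the strata).  Per gene, read counts are converted to
    densities in fixed-width flank bins and a body rescaled to
    ``body_bins`` bins; minus-strand genes are reversed so 5'->3' runs
    left to right.  Each stratum's mean profile is normalized so that the
    outer halves of the two flanks average 1 (background = 1), making the
    gene-body elevation directly readable as a fold enrichment.  Genes
    shorter than one bp per body bin are skipped and tallied.
    """
    needed = {"chrom", "start", "end", "strand", "score"}
    if needed - set(genes.columns):
        raise ValueError(f"genes table needs columns {sorted(needed)}")
    frame = _records_frame(records)
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in frame.groupby("chrom")
    }
    pct = genes["score"].rank(method="average", pct=True).to_numpy()

    total_bins = 2 * flank_bins + body_bins
    sums = {i: np.zeros(total_bins) for i in range(len(strata))}
    counts = {i: 0 for i in range(len(strata))}
    skipped = 0
    fb_width = flank / flank_bins

    for g, p in zip(genes.itertuples(index=False), pct):
        stratum = None
        for i, (lo, hi) in enumerate(strata):
            if (lo < p <= hi) or (p <= hi and lo == 0.0):
                stratum = i
                break
        if stratum is None:
            continue
        length = g.end - g.start
        if length < body_bins:
            skipped += 1
            continue
        if g.start - flank < 0 or (
            genome_sizes is not None and g.end + flank > genome_sizes.get(g.chrom, np.inf)
        ):
            # a flank leaving the chromosome would read as depressed
            # background and distort the normalization
            skipped += 1
            continue
        pos = pos_by_chrom.get(g.chrom, np.empty(0))
        edges = np.concatenate(
            [
                g.start - flank + np.arange(flank_bins) * fb_width,
                g.start + np.arange(body_bins) * (length / body_bins),
                g.end + np.arange(flank_bins + 1) * fb_width,
            ]
        )
        hits = np.searchsorted(pos, edges)
        density = np.diff(hits) / np.diff(edges)
        if g.strand == "-":
            density = density[::-1]
        sums[stratum] += density
        counts[stratum] += 1

    profiles: dict[str, np.ndarray] = {}
    n_genes: dict[str, int] = {}
    for i, (lo, hi) in enumerate(strata):
        label = f"{int(lo * 100)}-{int(hi * 100)}%"
        if counts[i] == 0:
            continue
        mean = sums[i] / counts[i]
        outer = np.r_[mean[: flank_bins // 2], mean[-(flank_bins // 2):]]
        background = outer.mean()
        profiles[label] = mean / background if background > 0 else mean
        n_genes[label] = counts[i]
    return MetaplotResult(
        profiles=profiles,
        n_genes=n_genes,
        flank_bins=flank_bins,
        body_bins=body_bins,
        flank=flank,
        skipped=skipped,
    )
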