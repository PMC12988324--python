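"""Initiation-zone segmentation of RFD tracks with a 3-state Gaussian HMM.

Replication initiation zones (IZs) appear as ascending transitions of the
RFD track (forks diverge from the zone), termination zones (TZs) as
descending transitions, and uniformly-traversed regions are flat.  The
segmenter therefore works on per-window RFD increments

    drfd_k = rfd_{k+1} - rfd_k

with hidden states UP, DOWN and FLAT, Gaussian emissions with means
(+mu, -mu, 0) and a shared sigma, and a sticky transition matrix
(self-transition probability ``p_stay``).  Decoding is exact Viterbi in log
space with a deterministic tie-break toward FLAT; maximal UP runs of at
least ``min_zone_bins`` become IZ calls and DOWN runs TZ calls.

This is a self-contained functional equivalent of published RFD-based HMM
origin callers; externally produced IZ BED files can be supplied to the
profiling stage instead whenever bit-compatibility with a specific caller
matters.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STATES = ("FLAT", "UP", "DOWN")  # FLAT first so argmax ties resolve to FLAT
FLAT, UP, DOWN = 0, 1, 2

MISSING_SIGMA_INFLATION = 10.0


@dataclass
class SegmentationModel:
    """Sticky 3-state Gaussian HMM over RFD increments.

    Parameters
    ----------
    mu : float
        Emission mean magnitude of the UP (+mu) and DOWN (-mu) states.
    sigma : float
        Shared emission standard deviation.
    p_stay : float
        Self-transition probability (default 0.99); the two cross
        transitions share the remainder equally.

    Missing increments (NaN) are treated as FLAT-neutral observations:
    they emit the FLAT mean under every state with sigma inflated 10x,
    which keeps the chain connected across coverage gaps without letting
    them drive state switches.
    """

    mu: float
    sigma: float
    p_stay: float = 0.99

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.sigma > 0):
            raise ValueError("mu and sigma must be positive")
        if not 0 < self.p_stay < 1:
            raise ValueError("p_stay must be in (0, 1)")

    @property
    def means(self) -> np.ndarray:
        return np.array([0.0, self.mu, -self.mu])

    @property
    def log_transition(self) -> np.ndarray:
        p_move = (1.0 - self.p_stay) / 2.0
        mat = np.full((3, 3), p_move)
        np.fill_diagonal(mat, self.p_stay)
        return np.log(mat)

    def log_emissions(self, increments: np.ndarray) -> np.ndarray:
        """(n, 3) log emission densities; NaN observations are FLAT-neutral."""
        x = np.asarray(increments, dtype=float)
        missing = np.isnan(x)
        obs = np.where(missing, 0.0, x)
        sigma = np.where(missing, self.sigma * MISSING_SIGMA_INFLATION, self.sigma)
        diff = obs[:, None] - self.means[None, :]
        return -0.5 * (diff / sigma[:, None]) ** 2 - np.log(sigma)[:, None] - 0.5 * math.log(2 * math.pi)

    # -- parameter estimation -------------------------------------------------

    @classmethod
    def estimate(
        cls,
        increments: np.ndarray,
        p_stay: float = 0.99,
        tail_quantile: float = 0.90,
        baum_welch_iterations: int = 20,
    ) -> "SegmentationModel":
        """Estimate (mu, sigma) from data; p_stay is held fixed.

        mu is initialized from the tails of the increment distribution
        (half the spread between the mean upper and lower ``tail_quantile``
        tails) and refined by up to ``baum_welch_iterations`` hard-
        assignment EM sweeps over the marginal increments: each value is
        assigned to the nearest of the tied means (0, +mu, -mu), mu is
        re-estimated from the assigned UP/DOWN values and sigma from the
        pooled residuals.  Two couplings are deliberately avoided:

        * the sticky transition matrix takes no part in estimation --
          otherwise short transition ramps absorb into FLAT during
          fitting, sigma inflates, and nothing is ever decoded as UP/DOWN;
        * soft (posterior-weighted) responsibilities are not used for the
          means -- they let the steepest increments dominate, biasing mu
          above the typical ramp increment so ramp shoulders (which decode
          as UP only when they exceed mu/2) fall back to FLAT.

        The hard nearest-mean rule matches the quantity that matters at
        decoding time and converges to the mean of all transition
        increments.
        """
        x = np.asarray(increments, dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 3:
            raise ValueError("need at least 3 finite increments to estimate parameters")
        hi = x[x >= np.quantile(x, tail_quantile)]
        lo = x[x <= np.quantile(x, 1.0 - tail_quantile)]
        mu = max(float((hi.mean() - lo.mean()) / 2.0), 1e-3)
        sigma = max(float(np.std(x)), 1e-6)
        for _ in range(baum_welch_iterations):
            means = np.array([0.0, mu, -mu])
            assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
            n_moving = (assign != FLAT).sum()
            if n_moving == 0:
                break
            new_mu = float((x[assign == UP].sum() - x[assign == DOWN].sum()) / n_moving)
            sigma = max(float(np.sqrt(np.mean((x - means[assign]) ** 2))), 1e-6)
            if new_mu <= 0:
                break
            if abs(new_mu - mu) < 1e-10:
                mu = new_mu
                break
            mu = new_mu
        return cls(mu=mu, sigma=sigma, p_stay=p_stay)


def delta_rfd(rfd: Sequence[float] | pd.Series) -> np.ndarray:
    """First differences of an RFD series; NaN neighbours propagate NaN."""
    x = np.asarray(rfd, dtype=float)
    if len(x) < 2:
        return np.empty(0)
    return x[1:] - x[:-1]


def viterbi_segment(
    increments: Sequence[float], model: SegmentationModel
) -> np.ndarray:
    """Maximum-probability state path over the increments.

    Log-space dynamic programming; uniform initial distribution; ties are
    broken deterministically toward FLAT (then UP before DOWN).  Returns an
    array of state indices (see :data:`STATES`); empty input gives an empty
    path.
    """
    x = np.asarray(increments, dtype=float)
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=int)
    log_b = model.log_emissions(x)
    log_a = model.log_transition
    score = np.full((n, 3), -np.inf)
    back = np.zeros((n, 3), dtype=int)
    score[0] = log_b[0] - math.log(3)
    for t in range(1, n):
        cand = score[t - 1][:, None] + log_a  # cand[i, j]: from i to j
        back[t] = np.argmax(cand, axis=0)  # first max -> FLAT on ties
        score[t] = cand[back[t], np.arange(3)] + log_b[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(score[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def brute_force_segment(
    increments: Sequence[float], model: SegmentationModel
) -> np.ndarray:
    """Exhaustive maximum-probability path (3^n enumeration, n <= 14).

    Independent check of the Viterbi recursion on tiny instances; uses the
    same tie-break (lexicographically smallest path among maxima, with
    FLAT = 0 ordered first).
    """
    x = np.asarray(increments, dtype=float)
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=int)
    if n > 14:
        raise ValueError("brute force is only for tiny instances")
    log_b = model.log_emissions(x)
    log_a = model.log_transition
    best_path, best_score = None, -np.inf
    for code in range(3 ** n):
        path, c = [], code
        for _ in range(n):
            path.append(c % 3)
            c //= 3
        score = log_b[0, path[0]] - math.log(3)
        for t in range(1, n):
            score += log_a[path[t - 1], path[t]] + log_b[t, path[t]]
        if score > best_score + 1e-12:
            best_path, best_score = path, score
        elif abs(score - best_score) <= 1e-12 and path < best_path:
            best_path = path
    return np.array(best_path, dtype=int)


@dataclass(frozen=True)
class ZoneCall:
    """A contiguous initiation (IZ) or termination (TZ) zone."""

    chrom: str
    start: int
    end: int
    type: str  # "IZ" or "TZ"
    centre: int
    mean_delta: float


def call_zones(
    path: np.ndarray,
    increments: Sequence[float],
    bin_width: int,
    chrom: str = "chr1",
    min_zone_bins: int = 3,
    offset: int = 0,
) -> list[ZoneCall]:
    """Turn a decoded state path into IZ/TZ interval calls.

    Path element k describes the bin [offset + k*bin_width,
    offset + (k+1)*bin_width).  Maximal UP runs of >= ``min_zone_bins``
    become IZs, DOWN runs TZs; centre is the interval midpoint rounded
    down.  Output is coordinate-sorted.
    """
    x = np.asarray(increments, dtype=float)
    calls: list[ZoneCall] = []
    i = 0
    n = len(path)
    while i < n:
        state = path[i]
        j = i
        while j < n and path[j] == state:
            j += 1
        if state in (UP, DOWN) and j - i >= min_zone_bins:
            start = offset + i * bin_width
            end = offset + j * bin_width
            vals = x[i:j]
            mean_delta = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else 0.0
            calls.append(
                ZoneCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    type="IZ" if state == UP else "TZ",
                    centre=(start + end) // 2,
                    mean_delta=mean_delta,
                )
            )
        i = j
    return calls


def segment_rfd_track(
    rfd_track: pd.DataFrame,
    min_zone_bins: int = 3,
    p_stay: float = 0.99,
    model: SegmentationModel | None = None,
) -> list[ZoneCall]:
    """Segment a non-overlapping RFD track (columns chrom/start/end/rfd).

    One shared emission model is estimated across chromosomes (unless
    given); decoding and zone calling run per chromosome.
    """
    if {"chrom", "start", "end", "rfd"} - set(rfd_track.columns):
        raise ValueError("rfd_track needs columns chrom, start, end, rfd")
    per_chrom = []
    all_increments = []
    for chrom, sub in rfd_track.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        widths = (sub["end"] - sub["start"]).to_numpy()
        bin_width = int(widths[0]) if len(widths) else 0
        inc = delta_rfd(sub["rfd"].to_numpy())
        per_chrom.append((str(chrom), int(sub["start"].iloc[0]), bin_width, inc))
        all_increments.append(inc)
    if model is None:
        model = SegmentationModel.estimate(np.concatenate(all_increments), p_stay=p_stay)
    calls: list[ZoneCall] = []
    for chrom, offset, bin_width, inc in per_chrom:
        path = viterbi_segment(inc, model)
        calls.extend(
            call_zones(path, inc, bin_width, chrom=chrom, min_zone_bins=min_zone_bins, offset=offset)
        )
    return sorted(calls, key=lambda z: (z.chrom, z.start))


def write_zones_bed(calls: Sequence[ZoneCall], path: str | os.PathLike) -> None:
    """Write zone calls as BED6 (name=IZ|TZ, score=1000*|mean drfd| clipped)."""
    with open(path, "w") as fh:
        for z in sorted(calls, key=lambda z: (z.chrom, z.start)):
            score = min(1000, int(round(1000 * abs(z.mean_delta))))
            fh.write(f"{z.chrom}\t{z.start}\t{z.end}\t{z.type}\t{score}\t.\n")


def read_zones_bed(path: str | os.PathLike) -> list[ZoneCall]:
    """Read IZ/TZ calls from BED (columns 4+ optional; default type IZ)."""
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            ztype = fields[3] if len(fields) > 3 and fields[3] in ("IZ", "TZ") else "IZ"
            calls.append(
                ZoneCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    type=ztype,
                    centre=(start + end) // 2,
                    mean_delta=0.0,
                )
            )
    return calls
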