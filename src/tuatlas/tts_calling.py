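"""Calling RNA 3' termini from term-seq coverage.

Each library is screened with a one-sided Poisson test against a *dynamic*
lambda: for every candidate position the expected rate is taken as the
largest of the strand-specific genome-wide mean, the replicon-wide mean,
and local means over a ladder of windows (13, 51, 251, 501 and 1,001 bp by
default) centred on the position.  Using the maximum makes the test
conservative near pileups and in locally busy regions.  P values are
BH-adjusted per library across the tested positions, and a position must
recur in at least two biological replicates to become a preliminary 3'
terminus for a condition.

The identical machinery is applied to RppH-untreated 5'-end coverage to
call 5'-monophosphoryl sites (see :mod:`tuatlas.end_integration`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import STRANDS, EndCoverageTrack, SiteCall

DEFAULT_WINDOWS = (13, 51, 251, 501, 1001)


@dataclass(frozen=True)
class DynamicLambdaSpec:
    """Configuration of the dynamic-lambda ladder.

    Windows must be odd so that "centred on the tested position" is
    symmetric; window means include the tested position's own count and
    count zeros, with truncation at replicon ends (the denominator is the
    number of in-range positions).
    """

    window_sizes: tuple = DEFAULT_WINDOWS
    include_replicon_mean: bool = True
    include_genome_mean: bool = True
    include_center: bool = True

    def __post_init__(self) -> None:
        if any(w % 2 == 0 or w < 1 for w in self.window_sizes):
            raise ValueError("window sizes must be odd positive integers")


def poisson_tail_p(x: int, lam: float):
    """Upper-tail probability P(X >= x) for X ~ Poisson(lam).

    Vectorized over ``x``/``lam``; equals ``1 - CDF(x - 1)`` computed via
    the survival function (no catastrophic cancellation for large x).
    """
    x_arr = np.asarray(x)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be > 0")
    if np.any(x_arr < 0) or not np.issubdtype(x_arr.dtype, np.integer):
        if np.any(np.asarray(x_arr, dtype=float) % 1 != 0) or np.any(x_arr < 0):
            raise ValueError("x must be a non-negative integer")
    p = stats.poisson.sf(x_arr - 1, lam_arr)
    if np.isscalar(x) and np.isscalar(lam):
        return float(p)
    return p


def _window_means(arr: np.ndarray, window: int, include_center: bool = True) -> np.ndarray:
    """Mean count in a `window`-bp window centred on each position.

    Truncated at array ends: the denominator is the number of positions
    actually inside the array.
    """
    half = window // 2
    n = arr.size
    csum = np.concatenate(([0], np.cumsum(arr, dtype=np.float64)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    total = csum[hi + 1] - csum[lo]
    denom = (hi - lo + 1).astype(np.float64)
    if not include_center:
        total = total - arr
        denom = denom - 1.0
        denom[denom <= 0] = 1.0
    return total / denom


def dynamic_lambda(
    track: EndCoverageTrack,
    key: tuple,
    spec: DynamicLambdaSpec = DynamicLambdaSpec(),
) -> float:
    """Dynamic lambda at one (replicon, position, strand) key (max rule)."""
    replicon_id, position, strand = key
    arr = track.get(replicon_id, strand)
    if not (1 <= position <= arr.size):
        raise ValueError(f"position {position} outside {replicon_id}")
    cands = []
    if spec.include_genome_mean:
        cands.append(track.strand_mean(strand))
    if spec.include_replicon_mean:
        cands.append(track.replicon_strand_mean(replicon_id, strand))
    for w in spec.window_sizes:
        cands.append(float(_window_means(arr, w, spec.include_center)[position - 1]))
    return max(cands)


def nonzero_percentile_cutoff(track: EndCoverageTrack, percentile: float = 95.0) -> float:
    """Percentile (linear interpolation) of the library's nonzero counts,
    pooled over both strands and all replicons."""
    vals = track.nonzero_values()
    if vals.size == 0:
        return float("inf")
    return float(np.percentile(vals, percentile))


def call_three_prime_ends(
    track: EndCoverageTrack,
    spec: DynamicLambdaSpec = DynamicLambdaSpec(),
    percentile: float = 95.0,
    fdr_threshold: float = 0.05,
    site_kind: str = "prelim_3prime",
) -> list:
    """Per-library screen: candidate positions are those with a count
    strictly greater than the 95th percentile of all nonzero counts; each
    is tested one-sided against its dynamic lambda and BH-adjusted across
    the library's tested positions.  Returns calls with FDR < threshold.
    """
    if track.total() == 0:
        warnings.warn(f"library {track.library_id}: all-zero track, no sites called")
        return []
    cutoff = nonzero_percentile_cutoff(track, percentile)
    keys, xs, lams = [], [], []
    for replicon_id in sorted(track.lengths):
        for strand in STRANDS:
            arr = track.get(replicon_id, strand)
            cand = np.flatnonzero(arr > cutoff)
            if cand.size == 0:
                continue
            genome_mean = track.strand_mean(strand) if spec.include_genome_mean else 0.0
            rep_mean = (
                track.replicon_strand_mean(replicon_id, strand)
                if spec.include_replicon_mean
                else 0.0
            )
            lam = np.full(cand.size, max(genome_mean, rep_mean))
            for w in spec.window_sizes:
                wm = _window_means(arr, w, spec.include_center)[cand]
                lam = np.maximum(lam, wm)
            for i, c in enumerate(cand):
                keys.append((replicon_id, int(c) + 1, strand))
            xs.append(arr[cand])
            lams.append(lam)
    if not keys:
        return []
    x = np.concatenate(xs)
    lam = np.concatenate(lams)
    pvals = poisson_tail_p(x, lam)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    sites = []
    for (replicon_id, pos, strand), xi, pi, qi in zip(keys, x, pvals, fdr):
        if qi < fdr_threshold:
            sites.append(
                SiteCall(
                    replicon_id=replicon_id, position=pos, strand=strand,
                    site_kind=site_kind, p_value=float(pi), fdr=float(qi),
                    mean_signal=float(xi),
                )
            )
    return sites


def combine_replicates(
    per_sample_sites: list,
    min_replicates: int = 2,
    site_kind: str = "prelim_3prime",
    condition_id: str | None = None,
) -> list:
    """Exact-position, same-strand replicate consensus within a condition.

    ``per_sample_sites`` is a list (one entry per biological replicate) of
    site lists.  A position is retained when called in at least
    ``min_replicates`` replicates; no +/-1 fuzziness is applied.
    """
    if len(per_sample_sites) < 2 and min_replicates > 1:
        raise ValueError(
            "need >=2 replicate site lists (or set min_replicates=1 explicitly)"
        )
    tally: dict[tuple, list] = {}
    for sample in per_sample_sites:
        for s in sample:
            tally.setdefault(s.key, []).append(s)
    out = []
    for key in sorted(tally):
        calls = tally[key]
        if len(calls) < min_replicates:
            continue
        replicon_id, pos, strand = key
        out.append(
            SiteCall(
                replicon_id=replicon_id, position=pos, strand=strand,
                site_kind=site_kind,
                p_value=max(c.p_value for c in calls),
                fdr=max(c.fdr for c in calls),
                mean_signal=float(np.mean([c.mean_signal for c in calls])),
                conditions_detected=(
                    frozenset([condition_id]) if condition_id else frozenset()
                ),
            )
        )
    return out


def call_termini_for_condition(
    tracks: list,
    spec: DynamicLambdaSpec = DynamicLambdaSpec(),
    percentile: float = 95.0,
    fdr_threshold: float = 0.05,
    min_replicates: int = 2,
    site_kind: str = "prelim_3prime",
    condition_id: str | None = None,
) -> list:
    """Full per-condition pipeline: per-replicate Poisson screen, then the
    >=2-replicate consensus."""
    per_sample = [
        call_three_prime_ends(t, spec, percentile, fdr_threshold, site_kind)
        for t in tracks
    ]
    cond = condition_id or (tracks[0].condition_id if tracks else None)
    return combine_replicates(per_sample, min_replicates, site_kind, cond)
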