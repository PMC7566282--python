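"""TSS identification from RppH-treated vs untreated 5'-end coverage.

A true TSS carries a 5'-triphosphate and can only be adapter-ligated after
RppH treatment, so it shows a sharp excess of 5'-end counts in treated
over untreated libraries.  Per condition the pipeline is:

1. prefilter candidate positions (zero filter, then a 95th-percentile
   filter on replicate-averaged treated counts);
2. a per-position one-sided negative-binomial exceedance test of treated
   over untreated counts, with median-of-ratios size factors, run in both
   a paired (replicate-blocked) and an unpaired design, BH-adjusted per
   design across all tested positions of the condition;
3. a position is a TSS when either design gives FDR < 0.05 (and the fold
   change is positive);
4. runs of adjacent called positions are resolved into one primary TSS
   (highest replicate-averaged treated coverage) plus secondary TSSs;
5. condition catalogs are merged (secondaries dropped; conditions counted)
   and thinned for promoter modelling (15-bp rule) or coalesced into
   promoters (10-bp rule).

The NB test is a Wald test with a pooled method-of-moments dispersion; it
is an exceedance test in the same spirit as a DESeq2 contrast with
``altHypothesis="greater"``, not a bit-exact replication of any external
engine (acceptance is planted-signal recovery and FDR control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import STRANDS, EndCoverageTrack, SiteCall

DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Prefiltering
# ---------------------------------------------------------------------------


def zero_filter_positions(treated: list, untreated: list) -> list:
    """Positions with a nonzero count in at least one library of the
    condition (treated or untreated) — the survivor set on which size
    factors and the pooled dispersion are estimated."""
    lengths = treated[0].lengths
    keys = []
    for replicon_id in sorted(lengths):
        for strand in STRANDS:
            nonzero = np.zeros(lengths[replicon_id], dtype=bool)
            for t in treated + untreated:
                nonzero |= t.get(replicon_id, strand) > 0
            keys.extend(
                (replicon_id, int(i) + 1, strand) for i in np.flatnonzero(nonzero)
            )
    return keys


def prefilter_positions(
    treated: list,
    untreated: list,
    percentile: float = 95.0,
    prefilter_source: str = "treated",
) -> list:
    """Candidate positions for one condition.

    A position survives when (a) it has a nonzero count in at least one
    library of the condition (treated or untreated) and (b) its
    replicate-averaged treated count is >= the `percentile` percentile
    (linear interpolation) of the averaged counts over positions surviving
    (a), pooled across replicons.  With ``prefilter_source="all"`` the
    averaged count in (b) is taken over all libraries instead.

    Returns sorted ``(replicon, position, strand)`` keys.
    """
    if len(treated) < 2 or len(untreated) < 2:
        raise ValueError("need >=2 treated and >=2 untreated replicate tracks")
    lengths = treated[0].lengths
    source = treated if prefilter_source == "treated" else treated + untreated
    keys, avgs = [], []
    for replicon_id in sorted(lengths):
        for strand in STRANDS:
            nonzero = np.zeros(lengths[replicon_id], dtype=bool)
            for t in treated + untreated:
                nonzero |= t.get(replicon_id, strand) > 0
            idx = np.flatnonzero(nonzero)
            if idx.size == 0:
                continue
            avg = np.mean([t.get(replicon_id, strand)[idx] for t in source], axis=0)
            keys.extend((replicon_id, int(i) + 1, strand) for i in idx)
            avgs.append(avg)
    if not keys:
        warnings.warn("no nonzero positions in condition; empty candidate set")
        return []
    avg_all = np.concatenate(avgs)
    cutoff = np.percentile(avg_all, percentile)
    return [k for k, a in zip(keys, avg_all) if a >= cutoff]


def counts_matrix(candidates: list, tracks: list) -> np.ndarray:
    """(n_candidates x n_libraries) count matrix at candidate keys."""
    mat = np.empty((len(candidates), len(tracks)), dtype=np.int64)
    groups: dict[tuple, tuple] = {}
    for i, (replicon_id, pos, strand) in enumerate(candidates):
        rows, idx = groups.setdefault((replicon_id, strand), ([], []))
        rows.append(i)
        idx.append(pos - 1)
    for (replicon_id, strand), (rows, idx) in groups.items():
        rows_a, idx_a = np.asarray(rows), np.asarray(idx)
        for j, t in enumerate(tracks):
            mat[rows_a, j] = t.get(replicon_id, strand)[idx_a]
    return mat


# ---------------------------------------------------------------------------
# Negative-binomial exceedance test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExceedanceResult:
    """Per-position treated-vs-untreated test result for one condition."""

    key: tuple  # (replicon, position, strand)
    log2_fold: float
    p_value_paired: float
    p_value_unpaired: float
    fdr_paired: float
    fdr_unpaired: float
    mean_treated_norm: float


def median_of_ratios_size_factors(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over a count matrix (columns are
    libraries), with a positive-count geometric-mean reference.

    The reference for each row is ``exp(sum(log K_ij > 0) / n_libraries)``
    and each library's factor is the median of its positive-count ratios
    to that reference.  On an all-positive matrix this is the classic
    median-of-ratios estimator; on sparse per-position 5'-end matrices it
    avoids restricting the reference to the (signal-biased) rows where
    every library is nonzero.
    """
    mat = np.asarray(mat, dtype=float)
    n_libs = mat.shape[1]
    pos = mat > 0
    any_pos = pos.any(axis=1)
    if not np.any(any_pos):
        raise ValueError("count matrix is all zero; cannot estimate size factors")
    with np.errstate(divide="ignore"):
        logs = np.where(pos, np.log(np.where(pos, mat, 1.0)), 0.0)
    ref = np.exp(logs.sum(axis=1) / n_libs)
    sf = np.empty(n_libs)
    for j in range(n_libs):
        use = pos[:, j] & any_pos
        if not np.any(use):
            raise ValueError(
                f"library column {j} has all-zero counts; cannot estimate a "
                "size factor"
            )
        sf[j] = np.median(mat[use, j] / ref[use])
    return sf


def pooled_dispersion(
    mat: np.ndarray, sf: np.ndarray, groups: list, min_mean: float = 1.0
) -> float:
    """Pooled method-of-moments NB dispersion (variance = m + a*m^2).

    Per-row, per-group estimates ``(v - m)/m^2`` on the normalized scale
    are averaged (negative estimates clipped to zero) over rows whose
    group mean is at least ``min_mean`` — below that the moment estimator
    carries no information.  Floored at a small positive value.
    """
    norm = mat / sf[None, :]
    ests = []
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m >= min_mean
        if not np.any(ok):
            ok = m > 0
        a = (v[ok] - m[ok]) / m[ok] ** 2
        ests.append(a)
    allests = np.concatenate(ests) if ests else np.array([])
    if allests.size == 0:
        return DISPERSION_FLOOR
    pooled = float(np.mean(np.clip(allests, 0.0, None)))
    return max(pooled, DISPERSION_FLOOR)


def _group_rate_and_var(mat, sf, alpha):
    """Rate q = sum(K)/sum(s) per row (continuity-floored at half a count)
    plus a delta-method variance of log(q) under NB(mu = s*q,
    var = mu + alpha*mu^2)."""
    S = sf.sum()
    q = mat.sum(axis=1) / S
    q_eff = np.maximum(q, 0.5 / S)
    mu = sf[None, :] * q_eff[:, None]
    var_q = (mu + alpha * mu**2).sum(axis=1) / S**2
    return q, q_eff, var_q / q_eff**2


def test_end_exceedance(
    candidates: list,
    treated_mat: np.ndarray,
    untreated_mat: np.ndarray,
    pairing: list | None = None,
    background_mats: tuple | None = None,
) -> list:
    """One-sided (treated greater) NB exceedance test at candidate positions.

    Size factors are median-of-ratios over the joint treated+untreated
    matrix; the dispersion is a pooled method-of-moments estimate.  Two
    designs are computed: *unpaired* (Wald test on group rates) and
    *paired* (one-sample t test on per-replicate normalized log ratios,
    i.e. replicate as a blocking factor).  BH adjustment is applied per
    design across all tested positions.  ``pairing`` gives, for each
    replicate pair, the (treated_column, untreated_column) indices;
    defaults to positional pairing.

    ``background_mats`` — an optional ``(treated, untreated)`` matrix pair
    over a wider, selection-free position set (typically the zero-filter
    survivors) — is used for size factors and the pooled dispersion;
    estimating them on the percentile-selected candidates alone would let
    the treated-count selection bias leak into the normalization.
    """
    n_t, n_u = treated_mat.shape[1], untreated_mat.shape[1]
    if n_t < 2 or n_u < 2:
        raise ValueError("need >=2 treated and >=2 untreated libraries")
    if len(candidates) == 0:
        return []
    if background_mats is not None:
        est = np.hstack([np.asarray(m) for m in background_mats])
    else:
        est = np.hstack([treated_mat, untreated_mat])
    sf = median_of_ratios_size_factors(est)
    sf_t, sf_u = sf[:n_t], sf[n_t:]
    alpha = pooled_dispersion(
        est, sf, [list(range(n_t)), list(range(n_t, n_t + n_u))]
    )

    # unpaired Wald test on log rates
    q_t, qe_t, vlog_t = _group_rate_and_var(treated_mat, sf_t, alpha)
    q_u, qe_u, vlog_u = _group_rate_and_var(untreated_mat, sf_u, alpha)
    se = np.sqrt(vlog_t + vlog_u)
    z = (np.log(qe_t) - np.log(qe_u)) / se
    p_unpaired = stats.norm.sf(z)

    # paired design: replicate-blocked log-ratio t test.  The empirical SE
    # is floored by the NB delta-method SE so that degenerate replicate
    # agreement (e.g. counts (1,1,1) vs (0,0,0)) cannot yield p ~ 0.
    if pairing is None:
        if n_t != n_u:
            raise ValueError("positional pairing requires equal library numbers")
        pairing = [(j, j) for j in range(n_t)]
    d = np.stack(
        [
            np.log((treated_mat[:, jt] + 0.5) / sf_t[jt])
            - np.log((untreated_mat[:, ju] + 0.5) / sf_u[ju])
            for jt, ju in pairing
        ],
        axis=1,
    )
    npairs = d.shape[1]
    dm = d.mean(axis=1)
    ds = d.std(axis=1, ddof=1)
    var_pair = np.zeros(len(candidates))
    for jt, ju in pairing:
        mu_t = sf_t[jt] * qe_t
        mu_u = sf_u[ju] * qe_u
        var_pair += (mu_t + alpha * mu_t**2) / (mu_t + 0.5) ** 2
        var_pair += (mu_u + alpha * mu_u**2) / (mu_u + 0.5) ** 2
    se_model = np.sqrt(var_pair / npairs**2)
    se_emp = ds / np.sqrt(npairs)
    se_paired = np.maximum(se_emp, se_model)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se_paired > 0, dm / se_paired, 0.0)
    p_paired = stats.t.sf(tstat, df=npairs - 1)

    _, fdr_unpaired, _, _ = multipletests(p_unpaired, method="fdr_bh")
    _, fdr_paired, _, _ = multipletests(p_paired, method="fdr_bh")

    log2_fold = np.log2(qe_t / qe_u)
    results = [
        ExceedanceResult(
            key=candidates[i],
            log2_fold=float(log2_fold[i]),
            p_value_paired=float(p_paired[i]),
            p_value_unpaired=float(p_unpaired[i]),
            fdr_paired=float(fdr_paired[i]),
            fdr_unpaired=float(fdr_unpaired[i]),
            mean_treated_norm=float(q_t[i]),
        )
        for i in range(len(candidates))
    ]
    return results


# ---------------------------------------------------------------------------
# Condition-level calling and catalog refinement
# ---------------------------------------------------------------------------


def call_tss_for_condition(
    results: list,
    fdr_threshold: float = 0.05,
    condition_id: str | None = None,
) -> list:
    """TSS calls: FDR < threshold in the paired or unpaired design (or
    both), with a positive fold change."""
    conds = frozenset([condition_id]) if condition_id else frozenset()
    sites = []
    for r in results:
        if r.log2_fold <= 0:
            continue
        if min(r.fdr_paired, r.fdr_unpaired) >= fdr_threshold:
            continue
        replicon_id, pos, strand = r.key
        sites.append(
            SiteCall(
                replicon_id=replicon_id, position=pos, strand=strand,
                site_kind="tss_primary",
                p_value=min(r.p_value_paired, r.p_value_unpaired),
                fdr=min(r.fdr_paired, r.fdr_unpaired),
                mean_signal=r.mean_treated_norm,
                conditions_detected=conds,
            )
        )
    return sites


def call_condition(
    treated: list,
    untreated: list,
    condition_id: str,
    fdr_threshold: float = 0.05,
    percentile: float = 95.0,
    prefilter_source: str = "treated",
) -> list:
    """Full per-condition TSS calling: prefilter, NB exceedance test with
    zero-filter-based normalization, union calling, adjacency resolution."""
    survivors = zero_filter_positions(treated, untreated)
    candidates = prefilter_positions(treated, untreated, percentile, prefilter_source)
    if not candidates:
        return []
    background = (
        counts_matrix(survivors, treated),
        counts_matrix(survivors, untreated),
    )
    results = test_end_exceedance(
        candidates,
        counts_matrix(candidates, treated),
        counts_matrix(candidates, untreated),
        background_mats=background,
    )
    called = call_tss_for_condition(results, fdr_threshold, condition_id)
    return resolve_adjacent_tss(called)


def _is_upstream(pos_a: int, pos_b: int, strand: str) -> bool:
    return pos_a < pos_b if strand == "+" else pos_a > pos_b


def resolve_adjacent_tss(sites: list, treated_mean: dict | None = None) -> list:
    """Resolve maximal runs of contiguous same-strand TSS calls.

    Within each run the position with the highest replicate-averaged
    treated coverage (``treated_mean`` maps site key to that value;
    defaults to the site's ``mean_signal``) becomes the primary TSS and
    the rest become secondary; ties go to the strand-aware upstream-most
    position.
    """

    def coverage(s: SiteCall) -> float:
        if treated_mean is not None:
            return treated_mean[s.key]
        return s.mean_signal

    out = []
    by_strand: dict[tuple, list] = {}
    for s in sites:
        by_strand.setdefault((s.replicon_id, s.strand), []).append(s)
    for (replicon_id, strand), group in sorted(by_strand.items()):
        group = sorted(group, key=lambda s: s.position)
        run: list = []
        for s in group + [None]:
            if s is not None and (not run or s.position == run[-1].position + 1):
                run.append(s)
                continue
            # close the run
            best = run[0]
            for cand in run[1:]:
                if coverage(cand) > coverage(best) or (
                    coverage(cand) == coverage(best)
                    and _is_upstream(cand.position, best.position, strand)
                ):
                    best = cand
            for member in run:
                kind = "tss_primary" if member is best else "tss_secondary"
                out.append(member.with_kind(kind))
            run = [s] if s is not None else []
    return sorted(out, key=lambda s: (s.replicon_id, s.position, s.strand))


def merge_conditions(per_condition: list) -> list:
    """Merge per-condition catalogs: secondary TSSs are removed first, then
    the number of detecting conditions is counted per remaining position.
    ``mean_signal`` of the merged site is the maximum per-condition
    normalized treated mean (used later for coalescing)."""
    tally: dict[tuple, list] = {}
    for catalog in per_condition:
        for s in catalog:
            if s.site_kind != "tss_primary":
                continue
            tally.setdefault(s.key, []).append(s)
    merged = []
    for key in sorted(tally):
        calls = tally[key]
        replicon_id, pos, strand = key
        conds: set = set()
        for c in calls:
            conds |= c.conditions_detected
        merged.append(
            SiteCall(
                replicon_id=replicon_id, position=pos, strand=strand,
                site_kind="tss_primary",
                p_value=min(c.p_value for c in calls),
                fdr=min(c.fdr for c in calls),
                mean_signal=max(c.mean_signal for c in calls),
                conditions_detected=frozenset(conds),
            )
        )
    return merged


def n_conditions(site: SiteCall) -> int:
    return len(site.conditions_detected)


def refine_for_promoter_model(sites: list, window: int = 15) -> list:
    """Thin a merged catalog so no two retained same-strand sites lie
    within `window` bp: iteratively keep the site detected under the most
    conditions (ties: strand-aware upstream-most) and remove its
    same-strand neighbours within the window."""

    def priority(s: SiteCall):
        # more conditions first; then upstream-most in transcript orientation
        upstream_rank = s.position if s.strand == "+" else -s.position
        return (-n_conditions(s), s.replicon_id, s.strand, upstream_rank)

    remaining = sorted(sites, key=priority)
    kept: list = []
    removed: set = set()
    for s in remaining:
        if s.key in removed:
            continue
        kept.append(s)
        for other in remaining:
            if other.key in removed or other is s:
                continue
            if (
                other.replicon_id == s.replicon_id
                and other.strand == s.strand
                and abs(other.position - s.position) <= window
            ):
                removed.add(other.key)
    return sorted(kept, key=lambda s: (s.replicon_id, s.position, s.strand))


def coalesce_tss(sites: list, window: int = 10) -> list:
    """Coalesce TSSs within `window` bp into single promoters, assigned to
    the position with the highest TSS-seq read count (``mean_signal``).
    Greedy by descending count: the highest-count unassigned site seeds a
    cluster absorbing all same-strand sites within the window."""

    def priority(s: SiteCall):
        upstream_rank = s.position if s.strand == "+" else -s.position
        return (-s.mean_signal, s.replicon_id, s.strand, upstream_rank)

    ordered = sorted(sites, key=priority)
    assigned: set = set()
    promoters = []
    for s in ordered:
        if s.key in assigned:
            continue
        promoters.append(s)
        for other in ordered:
            if other.key in assigned:
                continue
            if (
                other.replicon_id == s.replicon_id
                and other.strand == s.strand
                and abs(other.position - s.position) <= window
            ):
                assigned.add(other.key)
    return sorted(promoters, key=lambda s: (s.replicon_id, s.position, s.strand))


# ---------------------------------------------------------------------------
# Validation against independent reference sites
# ---------------------------------------------------------------------------


def rotate_positions(positions, genome_length: int, fraction: float = 0.25):
    """Rotate 1-based positions around a (circular) replicon by a quarter
    turn — the randomized control used for validation."""
    shift = int(round(genome_length * fraction))
    return [((p - 1 + shift) % genome_length) + 1 for p in positions]


def validate_against_reference(
    catalog: list,
    reference: list,
    genome_length: int,
    mode: str = "distance",
    regions: list | None = None,
):
    """Compare the catalog with independently known sites.

    ``distance`` mode: per-reference distance to the nearest called TSS,
    for the real catalog and for a control catalog rotated a quarter turn
    around the replicon, plus a two-sided Wilcoxon signed-rank p value on
    the paired distances.  ``contained_in_regions`` mode: TSS counts per
    reference region for real vs rotated.
    """
    if not catalog:
        raise ValueError("empty catalog")
    positions = np.array(sorted(s.position for s in catalog))
    rotated = np.array(sorted(rotate_positions(positions.tolist(), genome_length)))

    if mode == "distance":
        def nearest(ref, arr):
            i = np.searchsorted(arr, ref)
            best = np.inf
            for j in (i - 1, i):
                if 0 <= j < arr.size:
                    best = min(best, abs(int(arr[j]) - ref))
            return best

        d_real = np.array([nearest(r, positions) for r in reference], dtype=float)
        d_rot = np.array([nearest(r, rotated) for r in reference], dtype=float)
        if np.all(d_real == d_rot):
            p = 1.0
        else:
            stat = stats.wilcoxon(d_real, d_rot, zero_method="wilcox")
            p = float(stat.pvalue)
        return {
            "median_real": float(np.median(d_real)),
            "median_rotated": float(np.median(d_rot)),
            "distances_real": d_real,
            "distances_rotated": d_rot,
            "p_value": p,
        }
    elif mode == "contained_in_regions":
        if regions is None:
            raise ValueError("regions required for contained_in_regions mode")
        counts_real = [
            int(np.sum((positions >= lo) & (positions <= hi))) for lo, hi in regions
        ]
        counts_rot = [
            int(np.sum((rotated >= lo) & (rotated <= hi))) for lo, hi in regions
        ]
        cr, cb = np.array(counts_real, float), np.array(counts_rot, float)
        if np.all(cr == cb):
            p = 1.0
        else:
            p = float(stats.wilcoxon(cr, cb, zero_method="wilcox").pvalue)
        return {
            "counts_real": counts_real,
            "counts_rotated": counts_rot,
            "p_value": p,
        }
    raise ValueError(f"unknown mode {mode!r}")
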