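import itertools

import numpy as np
import pytest

from tuatlas import synthetic_data as sd
from tuatlas import tss_calling
from tuatlas.core_io import EndCoverageTrack, SiteCall
from tuatlas.tss_calling import test_end_exceedance as nb_exceedance_test
from tuatlas.tss_calling import (
    ExceedanceResult,
    call_tss_for_condition,
    coalesce_tss,
    counts_matrix,
    median_of_ratios_size_factors,
    merge_conditions,
    prefilter_positions,
    refine_for_promoter_model,
    resolve_adjacent_tss,
    validate_against_reference,
)


def tracks_from_matrix(values, kind, lengths={"chr": 200}):
    """values: {(pos, strand): [per-replicate counts]}."""
    n_reps = len(next(iter(values.values())))
    tracks = []
    for r in range(n_reps):
        t = EndCoverageTrack(f"{kind}{r}", "c1", f"r{r}", kind, lengths)
        for (pos, strand), counts in values.items():
            t.set_count("chr", strand, pos, counts[r])
        tracks.append(t)
    return tracks


class TestPrefilter:
    def test_percentile_cutoff_on_1_to_100(self):
        # averaged treated counts 1..100: linear-interpolation 95th
        # percentile is 95.05, so positions with averages 96..100 pass
        values = {(i, "+"): [i, i] for i in range(1, 101)}
        treated = tracks_from_matrix(values, "tss_treated")
        untreated = tracks_from_matrix({(1, "+"): [0, 0]}, "tss_untreated")
        cand = prefilter_positions(treated, untreated)
        assert sorted(pos for _, pos, _ in cand) == [96, 97, 98, 99, 100]

    def test_untreated_only_positions_survive_zero_filter_not_percentile(self):
        treated = tracks_from_matrix({(10, "+"): [100, 100]}, "tss_treated")
        untreated = tracks_from_matrix({(20, "+"): [5, 5]}, "tss_untreated")
        cand = prefilter_positions(treated, untreated)
        # position 20 survives (a) but its treated average 0 is below the
        # cutoff set by position 10
        assert ("chr", 10, "+") in cand and ("chr", 20, "+") not in cand

    def test_all_zero_tracks_give_empty_candidates(self):
        treated = tracks_from_matrix({(1, "+"): [0, 0]}, "tss_treated")
        untreated = tracks_from_matrix({(1, "+"): [0, 0]}, "tss_untreated")
        with pytest.warns(UserWarning):
            assert prefilter_positions(treated, untreated) == []


class TestExceedance:
    def test_proportional_libraries_have_size_factor_ratio_two(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20, size=300) + 1
        mat = np.stack([base, 2 * base], axis=1)
        sf = median_of_ratios_size_factors(mat)
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-9)

    def test_identical_columns_are_null(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(30, size=400)
        mat = np.stack([col, col, col], axis=1)
        cands = [("chr", i + 1, "+") for i in range(400)]
        res = nb_exceedance_test(cands, mat, mat)
        assert max(abs(r.log2_fold) for r in res) < 1e-9
        assert not any(
            min(r.fdr_paired, r.fdr_unpaired) < 0.05 for r in res
        )

    def test_all_zero_library_raises_naming_size_factor_problem(self):
        mat_t = np.ones((50, 2), dtype=int)
        mat_u = np.zeros((50, 2), dtype=int)
        mat_u[:, 0] = 1
        with pytest.raises(ValueError, match="size factor"):
            nb_exceedance_test([("chr", i, "+") for i in range(50)], mat_t, mat_u)

    def test_planted_signal_detected_with_high_power(self):
        # treated NB mean 200 vs untreated mean 2, dispersion 0.1, 3+3
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n_null = 500
            t = sd.nb_draw(rng, np.full((n_null + 1, 3), 5.0), 0.1)
            u = sd.nb_draw(rng, np.full((n_null + 1, 3), 5.0), 0.1)
            t[0] = sd.nb_draw(rng, np.full(3, 200.0), 0.1)
            u[0] = sd.nb_draw(rng, np.full(3, 2.0), 0.1)
            cands = [("chr", i + 1, "+") for i in range(n_null + 1)]
            res = nb_exceedance_test(cands, t, u)
            if min(res[0].fdr_paired, res[0].fdr_unpaired) < 0.05:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_direction_gate_blocks_negative_fold(self):
        r = ExceedanceResult(("chr", 1, "+"), -1.0, 0.001, 0.001, 0.01, 0.01, 5.0)
        assert call_tss_for_condition([r]) == []

    def test_either_design_suffices(self):
        r1 = ExceedanceResult(("chr", 1, "+"), 2.0, 0.001, 0.5, 0.01, 0.2, 5.0)
        r2 = ExceedanceResult(("chr", 2, "+"), 2.0, 0.5, 0.5, 0.2, 0.2, 5.0)
        called = call_tss_for_condition([r1, r2])
        assert [s.position for s in called] == [1]


def site(pos, strand="+", kind="tss_primary", signal=10.0, conds=("c1",)):
    return SiteCall("chr", pos, strand, kind, 0.001, 0.01, signal,
                    frozenset(conds))


class TestAdjacentResolution:
    def test_run_resolved_to_highest_coverage(self):
        sites = [site(100, signal=10), site(101, signal=40), site(102, signal=12)]
        out = resolve_adjacent_tss(sites)
        kinds = {s.position: s.site_kind for s in out}
        assert kinds == {100: "tss_secondary", 101: "tss_primary",
                         102: "tss_secondary"}

    def test_isolated_site_is_primary(self):
        out = resolve_adjacent_tss([site(500)])
        assert out[0].site_kind == "tss_primary"

    def test_tie_goes_to_strand_aware_upstream(self):
        out_plus = resolve_adjacent_tss([site(10, signal=7), site(11, signal=7)])
        assert {s.position for s in out_plus if s.site_kind == "tss_primary"} == {10}
        out_minus = resolve_adjacent_tss(
            [site(10, "-", signal=7), site(11, "-", signal=7)]
        )
        assert {s.position for s in out_minus if s.site_kind == "tss_primary"} == {11}

    def test_never_two_adjacent_primaries_on_random_catalogs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            positions = sorted(rng.choice(60, size=25, replace=False))
            sites = [site(int(p) + 1, signal=float(rng.integers(1, 50)))
                     for p in positions]
            out = resolve_adjacent_tss(sites)
            prim = sorted(s.position for s in out if s.site_kind == "tss_primary")
            assert all(b - a > 1 for a, b in zip(prim, prim[1:]))
            assert len(out) == len(sites)


class TestMergeAndRefine:
    def test_condition_counting(self):
        cats = [[site(100, conds=(f"c{i}",))] for i in range(3)]
        cats.append([site(200, conds=("c9",))])
        merged = merge_conditions(cats)
        n = {s.position: len(s.conditions_detected) for s in merged}
        assert n == {100: 3, 200: 1}

    def test_secondary_records_removed_before_counting(self):
        cats = [
            [site(100, conds=("c1",))],
            [site(100, kind="tss_secondary", conds=("c2",))],
        ]
        merged = merge_conditions(cats)
        assert len(merged) == 1
        assert merged[0].conditions_detected == frozenset({"c1"})

    def test_disjoint_catalogs_concatenate(self):
        cats = [[site(100)], [site(300)], [site(500)]]
        assert len(merge_conditions(cats)) == 3

    def test_refine_keeps_most_conditions_then_upstream(self):
        sites = [
            site(100, conds=("a", "b", "c")),
            site(110, conds=("a",)),
            site(130, conds=("a",)),
        ]
        out = refine_for_promoter_model(sites, window=15)
        assert sorted(s.position for s in out) == [100, 130]

    def test_refine_tie_upstream_most(self):
        sites = [site(100, conds=("a", "b")), site(112, conds=("c", "d"))]
        out = refine_for_promoter_model(sites, window=15)
        assert [s.position for s in out] == [100]

    def test_refine_agrees_with_exhaustive_subset_oracle(self):
        # oracle: among all maximal subsets with pairwise spacing > 15,
        # take the one whose sorted priority key sequence is lexicographically
        # smallest (priority: more conditions, then upstream-most)
        rng = np.random.default_rng(7)
        window = 15
        for _ in range(30):
            n = int(rng.integers(4, 11))
            positions = sorted(rng.choice(80, size=n, replace=False).tolist())
            sites = [
                site(p + 1, conds=tuple(f"c{j}" for j in range(rng.integers(1, 4))))
                for p in positions
            ]

            def key(s):
                return (-len(s.conditions_detected), s.position)

            def feasible(subset):
                pos = sorted(s.position for s in subset)
                return all(b - a > window for a, b in zip(pos, pos[1:]))

            best = None
            for r in range(1, n + 1):
                for combo in itertools.combinations(sites, r):
                    if not feasible(combo):
                        continue
                    # maximality: no site outside combo can be added
                    if any(
                        feasible(list(combo) + [s])
                        for s in sites
                        if s not in combo
                    ):
                        continue
                    sig = tuple(sorted(key(s) for s in combo))
                    if best is None or sig < best[0]:
                        best = (sig, set(s.position for s in combo))
            got = {s.position for s in refine_for_promoter_model(sites, window)}
            assert got == best[1]


class TestCoalescing:
    def test_cluster_assigned_to_highest_count(self):
        out = coalesce_tss([site(200, signal=50), site(208, signal=9)], window=10)
        assert [s.position for s in out] == [200]

    def test_distance_eleven_stays_separate(self):
        out = coalesce_tss([site(200, signal=5), site(211, signal=9)], window=10)
        assert sorted(s.position for s in out) == [200, 211]

    def test_idempotence_on_random_catalogs(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            sites = [
                site(int(p) + 1, signal=float(rng.integers(1, 100)))
                for p in rng.choice(150, size=30, replace=False)
            ]
            once = coalesce_tss(sites)
            assert coalesce_tss(once) == once


class TestReferenceValidation:
    def test_identical_catalog_has_zero_median_distance(self):
        catalog = [site(p) for p in (100, 900, 2500)]
        res = validate_against_reference(catalog, [100, 900, 2500], 10000)
        assert res["median_real"] == 0.0

    def test_nearest_distance_is_symmetric(self):
        catalog = [site(87), site(113)]
        res = validate_against_reference(catalog, [100], 10000)
        assert res["median_real"] == 13.0

    def test_enriched_catalog_beats_rotated_control(self):
        rng = np.random.default_rng(21)
        L = 100_000
        refs = sorted(rng.choice(L, size=50, replace=False).tolist())
        catalog = [site(int(r + rng.integers(-5, 6))) for r in refs]
        res = validate_against_reference(catalog, refs, L)
        assert res["median_real"] < res["median_rotated"]
        assert res["p_value"] < 0.01

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            validate_against_reference([], [100], 1000)
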