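"""Enrichment engine: running sum, permutation null, p-values, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gseaconcord import (
    GseaParams,
    RankedList,
    SimulationConfig,
    bh_adjust,
    build_ranked_list,
    enrichment_score,
    generate_dataset,
    leading_edge,
    nominal_pvalue,
    permutation_null,
    run_gsea,
)
from gseaconcord.gsea import frame_to_results, results_to_frame
from tests.test_correlations import _make_profile


def es_oracle(stats, hit_positions, p):
    """Exhaustive running-sum evaluation at every position (independent of
    the implementation's candidate-position shortcut)."""
    n = len(stats)
    hits = set(hit_positions)
    absw = [abs(s) ** p for s in stats]
    nr = 0.0
    for i in range(n):
        if i in hits:
            nr += absw[i]
    if nr == 0:
        absw = [1.0] * n
        nr = float(len(hits))
    best, best_pos = 0.0, 0
    cum_hit, cum_miss = 0.0, 0
    rs = []
    for i in range(n):
        if i in hits:
            cum_hit += absw[i]
        else:
            cum_miss += 1
        val = cum_hit / nr - cum_miss / (n - len(hits))
        rs.append(val)
        if abs(val) > abs(best):
            best, best_pos = val, i + 1
    return best, best_pos, rs


def _ranked(stats):
    genes = tuple(f"g{i:03d}" for i in range(len(stats)))
    return RankedList(genes=genes, stats=np.asarray(stats, dtype=float))


class TestRankedList:
    def test_sorted_by_signed_rho_descending(self):
        prof = _make_profile([0.9, -0.2, 0.5])
        rl = build_ranked_list(prof)
        assert rl.genes == ("g0", "g2", "g1")

    def test_equal_rho_breaks_ties_lexicographically(self):
        prof = _make_profile([0.5, 0.5, -0.1])
        rl = build_ranked_list(prof)
        assert rl.genes == ("g0", "g1", "g2")
        assert build_ranked_list(prof).genes == rl.genes

    def test_invalid_genes_excluded(self):
        prof = _make_profile([0.9, np.nan, 0.5])
        assert "g1" not in build_ranked_list(prof).genes

    def test_matches_sort_oracle_on_random_profile(self):
        rng = np.random.default_rng(2)
        rhos = list(rng.uniform(-1, 1, size=100))
        rl = build_ranked_list(_make_profile(rhos))
        expected = tuple(
            sorted((f"g{i}" for i in range(100)), key=lambda g: (-rhos[int(g[1:])], g))
        )
        assert rl.genes == expected

    def test_fewer_than_two_valid_genes_rejected(self):
        with pytest.raises(ValueError):
            build_ranked_list(_make_profile([0.5, np.nan]))


class TestEnrichmentScore:
    def test_single_top_hit_scores_plus_one(self):
        rl = _ranked([3.0, 2.0, 1.0, 0.5])
        es, peak, _ = enrichment_score(rl, ["g000"], p=0)
        assert es == pytest.approx(1.0) and peak == 1

    def test_single_bottom_hit_scores_minus_one(self):
        rl = _ranked([3.0, 2.0, 1.0, 0.5])
        es, peak, _ = enrichment_score(rl, ["g003"], p=0)
        assert es == pytest.approx(-1.0) and peak == 3

    def test_ten_gene_instance_matches_oracle_both_weights(self):
        stats = [10.0, 9, 8, 7, 6, 5, 4, 3, 2, 1]
        rl = _ranked(stats)
        members = ["g001", "g004", "g008"]  # ranked positions 2, 5, 9 (1-based)
        for p in (0, 1):
            es, peak, rs = enrichment_score(rl, members, p=p)
            o_es, o_peak, o_rs = es_oracle(stats, [1, 4, 8], p)
            assert es == pytest.approx(o_es, abs=1e-12)
            assert peak == o_peak
            np.testing.assert_allclose(rs, o_rs, atol=1e-12)

    def test_random_instances_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(4, 50))
            k = int(rng.integers(1, n))
            stats = np.sort(rng.normal(size=n))[::-1]
            rl = _ranked(stats)
            pos = sorted(rng.choice(n, size=k, replace=False).tolist())
            members = [rl.genes[i] for i in pos]
            for p in (0, 1):
                es, peak, _ = enrichment_score(rl, members, p=p)
                o_es, o_peak, _ = es_oracle(stats.tolist(), pos, p)
                assert es == pytest.approx(o_es, abs=1e-12)
                assert peak == o_peak

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.data())
    def test_es_bounded_and_running_sum_closes_at_zero(self, data):
        n = data.draw(st.integers(4, 40))
        k = data.draw(st.integers(1, n - 1))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=n))[::-1]
        rl = _ranked(stats)
        pos = sorted(rng.choice(n, size=k, replace=False).tolist())
        es, _, rs = enrichment_score(rl, [rl.genes[i] for i in pos], p=0)
        assert -1.0 <= es <= 1.0
        assert rs[-1] == pytest.approx(0.0, abs=1e-9)  # hit mass equals miss mass

    def test_reversed_list_negates_es_at_p_zero(self):
        rng = np.random.default_rng(11)
        stats = np.sort(rng.normal(size=30))[::-1]
        rl = _ranked(stats)
        pos = sorted(rng.choice(30, size=7, replace=False).tolist())
        es, peak, _ = enrichment_score(rl, [rl.genes[i] for i in pos], p=0)
        rev = RankedList(
            genes=tuple(reversed(rl.genes)), stats=-stats[::-1]
        )
        es_r, peak_r, _ = enrichment_score(
            rev, [rl.genes[i] for i in pos], p=0
        )
        assert es_r == pytest.approx(-es, abs=1e-12)
        assert peak_r == 30 - peak

    def test_empty_intersection_rejected(self):
        rl = _ranked([1.0, 0.5, -0.5])
        with pytest.raises(ValueError, match="empty intersection"):
            enrichment_score(rl, ["absent"], p=1)

    def test_whole_universe_set_rejected(self):
        rl = _ranked([1.0, 0.5, -0.5])
        with pytest.raises(ValueError, match="entire universe"):
            enrichment_score(rl, list(rl.genes), p=1)

    def test_all_zero_member_stats_fall_back_to_unweighted(self):
        rl = _ranked([1.0, 0.5, 0.0, 0.0, -0.5])
        with pytest.warns(UserWarning, match="unweighted"):
            es, _, _ = enrichment_score(rl, ["g002", "g003"], p=1)
        es0, _, _ = enrichment_score(rl, ["g002", "g003"], p=0)
        assert es == es0


class TestLeadingEdge:
    def test_positive_es_takes_hits_up_to_peak(self):
        rl = _ranked(np.linspace(5, 1, 8))
        hits = ["g000", "g002", "g006"]
        assert leading_edge(rl, hits, es=0.5, peak_index=3) == ("g000", "g002")

    def test_negative_es_takes_hits_from_peak_on(self):
        rl = _ranked(np.linspace(5, -5, 10))
        hits = ["g001", "g007", "g008"]
        assert leading_edge(rl, hits, es=-0.4, peak_index=8) == ("g007", "g008")

    def test_zero_es_has_empty_leading_edge(self):
        rl = _ranked([2.0, 1.0, -1.0])
        assert leading_edge(rl, ["g000"], es=0.0, peak_index=1) == ()

    def test_matches_recomputed_peak_prefix_suffix(self):
        rng = np.random.default_rng(3)
        stats = np.sort(rng.normal(size=50))[::-1]
        rl = _ranked(stats)
        for _ in range(30):
            pos = sorted(rng.choice(50, size=int(rng.integers(2, 20)), replace=False).tolist())
            members = [rl.genes[i] for i in pos]
            es, peak, _ = enrichment_score(rl, members, p=1)
            le = leading_edge(rl, members, es, peak)
            if es > 0:
                expected = tuple(rl.genes[i] for i in pos if i + 1 <= peak)
            else:
                expected = tuple(rl.genes[i] for i in pos if i + 1 >= peak)
            assert le == expected


class TestPermutationNull:
    def test_same_seed_gives_identical_null(self):
        rl = _ranked(np.linspace(1, -1, 40))
        params = GseaParams(n_permutations=50, seed=9)
        n1 = permutation_null(rl, [5, 10], params)
        n2 = permutation_null(rl, [5, 10], params)
        for k in (5, 10):
            np.testing.assert_array_equal(n1[k], n2[k])

    def test_single_permutation_gives_one_sample_per_size(self):
        rl = _ranked(np.linspace(1, -1, 20))
        null = permutation_null(rl, [3, 7], GseaParams(n_permutations=1, seed=0))
        assert null[3].shape == (1,) and null[7].shape == (1,)

    def test_oversized_set_rejected(self):
        rl = _ranked(np.linspace(1, -1, 10))
        with pytest.raises(ValueError, match="smaller than the universe"):
            permutation_null(rl, [10], GseaParams(n_permutations=5, seed=0))

    def test_null_mean_near_zero_on_symmetric_list(self):
        rl = _ranked(np.linspace(1, -1, 101))
        null = permutation_null(
            rl, [8], GseaParams(n_permutations=2000, weight_exponent=0, seed=1)
        )[8]
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se

    def test_null_matches_direct_scoring_of_same_subsets(self):
        # the vectorized batch path must agree with the scalar scorer
        rl = _ranked(np.sort(np.random.default_rng(5).normal(size=30))[::-1])
        params = GseaParams(n_permutations=20, weight_exponent=1, seed=4)
        null = permutation_null(rl, [6], params)[6]
        rng = np.random.default_rng(4)
        keys = rng.random((20, 30))
        pos = np.argpartition(keys, 5, axis=1)[:, :6]
        pos.sort(axis=1)
        direct = [
            enrichment_score(rl, [rl.genes[i] for i in row], p=1)[0] for row in pos
        ]
        np.testing.assert_array_equal(null, np.asarray(direct))


class TestNominalPvalue:
    def test_observed_exceeding_all_same_sign_nulls(self):
        null = np.concatenate([np.full(999, 0.1), [-0.5]])
        assert nominal_pvalue(0.9, null) == pytest.approx(1 / 1000)

    def test_weak_observation_gets_p_one(self):
        null = np.array([0.5, 0.6, 0.7])
        assert nominal_pvalue(0.01, null) == pytest.approx(1.0)

    def test_counting_matches_brute_force_on_hand_built_null(self):
        null = np.array(
            [0.1, 0.2, -0.3, 0.4, -0.5, 0.6, -0.7, 0.8, -0.9, 0.15,
             0.25, -0.35, 0.45, -0.55, 0.65, -0.75, 0.85, -0.95, 0.05, -0.05]
        )
        for es in (0.5, -0.5, 0.95, -0.01):
            same = [v for v in null if (v >= 0) == (es >= 0) or v == 0]
            expected = (1 + sum(1 for v in same if abs(v) >= abs(es))) / (1 + len(same))
            assert nominal_pvalue(es, null) == pytest.approx(expected)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=100)
        for es in rng.normal(size=50):
            p = nominal_pvalue(es, null)
            assert 0 < p <= 1


def bh_oracle(pvals):
    """Quadratic-time BH: q_i = min over j with p_j >= p_i of p_j*m/rank_j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [None] * m
    best = float("inf")
    for idx in range(m - 1, -1, -1):
        i = order[idx]
        best = min(best, pvals[i] * m / (idx + 1))
        q[i] = min(best, 1.0)
    return q


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_quadratic_oracle_and_statsmodels(self, pvals):
        q = bh_adjust(pvals)
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


@pytest.fixture(scope="module")
def powered_dataset():
    return generate_dataset(
        SimulationConfig(
            n_genes=600,
            n_sets=30,
            set_size_range=(10, 25),
            n_carcinoid=80,
            n_lcnec=20,
            effect_size=2.0,
            seed=21,
        )
    )


class TestRunGsea:
    def test_planted_set_attains_smallest_q(self, powered_dataset):
        ds = powered_dataset
        results = run_gsea(
            ds.expression, ds.phenotypes, "mitotic_rate", ds.gene_sets,
            GseaParams(n_permutations=300, seed=3),
        )
        best = min(results, key=lambda r: (r.fdr_q, r.nominal_p))
        truly_up = set(ds.sets_with_status("shared")) | set(ds.sets_with_status("a_only"))
        assert best.set_name in truly_up
        assert best.fdr_q < 0.10

    def test_identical_seed_identical_tables(self, powered_dataset):
        ds = powered_dataset
        params = GseaParams(n_permutations=100, seed=8)
        f1 = results_to_frame(
            run_gsea(ds.expression, ds.phenotypes, "ki67", ds.gene_sets, params)
        )
        f2 = results_to_frame(
            run_gsea(ds.expression, ds.phenotypes, "ki67", ds.gene_sets, params)
        )
        pd.testing.assert_frame_equal(f1, f2)

    def test_disjoint_set_excluded_from_results(self, powered_dataset):
        from gseaconcord.io import GeneSet, GeneSetCollection

        ds = powered_dataset
        sets = dict(ds.gene_sets.sets)
        sets["GHOST"] = GeneSet("not in universe", ("NOPE1", "NOPE2"))
        results = run_gsea(
            ds.expression, ds.phenotypes, "ki67", GeneSetCollection(sets=sets),
            GseaParams(n_permutations=20, seed=0),
        )
        assert "GHOST" not in {r.set_name for r in results}

    def test_all_sets_filtered_is_error(self, powered_dataset):
        from gseaconcord.io import GeneSet, GeneSetCollection

        ds = powered_dataset
        ghost = GeneSetCollection(sets={"G": GeneSet("d", ("NOPE",))})
        with pytest.raises(ValueError, match="filtered"):
            run_gsea(ds.expression, ds.phenotypes, "ki67", ghost,
                     GseaParams(n_permutations=10, seed=0))

    def test_sample_mode_runs_and_is_deterministic(self, powered_dataset):
        ds = powered_dataset
        small = ds.gene_sets.subset(ds.gene_sets.set_names[:5])
        params = GseaParams(n_permutations=10, permutation_mode="sample", seed=2)
        r1 = run_gsea(ds.expression, ds.phenotypes, "ki67", small, params)
        r2 = run_gsea(ds.expression, ds.phenotypes, "ki67", small, params)
        assert [x.nominal_p for x in r1] == [x.nominal_p for x in r2]
        assert all(0 < x.nominal_p <= 1 for x in r1)

    def test_result_table_round_trip(self, powered_dataset):
        ds = powered_dataset
        results = run_gsea(
            ds.expression, ds.phenotypes, "ki67", ds.gene_sets,
            GseaParams(n_permutations=30, seed=1),
        )
        back = frame_to_results(results_to_frame(results))
        assert [r.set_name for r in back] == [r.set_name for r in results]
        assert [r.leading_edge for r in back] == [r.leading_edge for r in results]
        np.testing.assert_allclose(
            [r.es for r in back], [r.es for r in results]
        )
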