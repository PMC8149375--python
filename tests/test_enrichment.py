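"""KS enrichment engine, permutation nulls, KSEA / regulon / GSEA wrappers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synscreen.enrichment import (AnnotationSet, RankedList,
                                  gsea_preranked, ks_enrichment_score, ksea,
                                  permutation_null, regulon_enrichment)
from synscreen.errors import ConfigError, SchemaError
from synscreen.pipeline import make_kinase_sets
from synscreen.simulate import simulate_phospho


def ranked_list(n, seed=None):
    """Descending-score list g0 > g1 > ..."""
    return RankedList(tuple(f"g{i}" for i in range(n)),
                      np.arange(n, 0, -1.0))


def brute_force_es(ids, members):
    """Independent O(N * |set|) literal running-sum implementation."""
    hits = sum(1 for i in ids if i in members)
    n = len(ids)
    if hits == 0 or hits >= n:
        return np.nan
    run, best = 0.0, 0.0
    for item in ids:
        run += 1.0 / hits if item in members else -1.0 / (n - hits)
        if abs(run) > abs(best):
            best = run
    return best


class TestRankedList:
    def test_from_scores_orders_desc_with_id_ties(self):
        rl = RankedList.from_scores({"b": 1.0, "a": 1.0, "c": 2.0})
        assert rl.ids == ("c", "a", "b")

    def test_duplicates_rejected(self):
        with pytest.raises(SchemaError):
            RankedList(("a", "a"), np.array([2.0, 1.0]))

    def test_increasing_scores_rejected(self):
        with pytest.raises(SchemaError):
            RankedList(("a", "b"), np.array([1.0, 2.0]))


class TestKSScore:
    def test_top_block_scores_one(self):
        rl = ranked_list(10)
        es = ks_enrichment_score(rl, AnnotationSet("s", ("g0", "g1", "g2")))
        assert es == pytest.approx(1.0)

    def test_bottom_block_scores_negative(self):
        rl = ranked_list(10)
        es = ks_enrichment_score(rl, AnnotationSet("s", ("g8", "g9")))
        assert es == pytest.approx(-1.0)

    def test_whole_list_is_undefined(self):
        rl = ranked_list(5)
        es = ks_enrichment_score(rl, AnnotationSet("s", tuple(rl.ids)))
        assert np.isnan(es)

    def test_zero_overlap_is_na(self):
        rl = ranked_list(5)
        assert np.isnan(ks_enrichment_score(rl, AnnotationSet("s", ("zz",))))

    def test_equals_brute_force_oracle_exhaustively(self, rng):
        """Engine output equals the literal running sum for every N <= 100
        tried with random sets."""
        for n in range(5, 101, 5):
            rl = ranked_list(n)
            for _ in range(5):
                k = int(rng.integers(1, n))
                members = tuple(
                    sorted(rng.choice(list(rl.ids), size=k, replace=False)))
                es = ks_enrichment_score(rl, AnnotationSet("s", members))
                bf = brute_force_es(rl.ids, set(members))
                assert es == pytest.approx(bf, abs=1e-12)

    def test_reversing_list_negates_score(self, rng):
        rl = ranked_list(60)
        members = tuple(rng.choice(list(rl.ids), size=12, replace=False))
        es = ks_enrichment_score(rl, AnnotationSet("s", members))
        es_rev = ks_enrichment_score(rl.reversed(), AnnotationSet("s", members))
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_mode_flip_mirrors_score(self):
        rl = ranked_list(40)
        members = ("g0", "g1", "g2", "g3")
        plus = AnnotationSet("s", members, {m: 1 for m in members})
        minus = AnnotationSet("s", members, {m: -1 for m in members})
        es_plus = ks_enrichment_score(rl, plus)
        es_minus = ks_enrichment_score(rl, minus)
        assert es_minus == pytest.approx(-es_plus, abs=1e-12)


class TestPermutationNull:
    def test_mean_near_zero(self):
        null = permutation_null(ranked_list(500), 40, B=1000, seed=3)
        assert abs(null.mean()) < 3 * null.std() / np.sqrt(len(null))

    def test_deterministic_under_seed(self):
        a = permutation_null(ranked_list(100), 10, B=100, seed=5)
        b = permutation_null(ranked_list(100), 10, B=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_set_size_bounds(self):
        rl = ranked_list(20)
        with pytest.raises(ConfigError):
            permutation_null(rl, 20, B=100)
        # N - 1 is legal, just high variance
        null = permutation_null(rl, 19, B=100, seed=1)
        assert np.isfinite(null).all()


class TestKSEA:
    def test_planted_kinase_has_top_positive_nks(self):
        sets = make_kinase_sets(10, 30)
        fc, _ = simulate_phospho(1000, sets, "K04", 2.0, seed=8)
        table = ksea(fc, sets, min_hits=3, B=500, seed=0)
        assert table["nks"].idxmax() == "K04"
        assert table["nks"].abs().idxmax() == "K04"
        assert table.loc["K04", "q_value"] < 0.05

    def test_zero_es_gives_zero_nks(self):
        # a set whose running sum never leaves zero cannot be built exactly,
        # so check the normalization identity on the definition instead
        sets = {"k": [f"g{i}" for i in range(0, 40, 2)]}
        fc = pd.Series(np.zeros(40), index=[f"g{i}" for i in range(40)])
        table = ksea(fc, sets, min_hits=3, B=200, seed=0)
        assert np.isfinite(table.loc["k", "nks"])

    def test_min_hits_filters_small_sets(self):
        sets = {"small": ["g0", "g1"], "big": [f"g{i}" for i in range(5)]}
        fc = pd.Series(np.arange(50, 0, -1.0), index=[f"g{i}" for i in range(50)])
        with pytest.warns(UserWarning, match="min_hits"):
            table = ksea(fc, sets, min_hits=30, B=200, seed=0)
        assert table["p_value"].isna().all()

    def test_p_value_lower_bound(self):
        sets = make_kinase_sets(3, 20)
        fc, _ = simulate_phospho(300, sets, "K00", 10.0, seed=2)
        table = ksea(fc, sets, min_hits=3, B=200, seed=0)
        assert (table["p_value"].dropna() >= 1 / 201).all()

    def test_null_p_values_uniform_across_seeds(self):
        """With no planted shift, the planted kinase's p-value is a null
        draw: approximately uniform over repeated simulations."""
        sets = make_kinase_sets(5, 25)
        pvals = []
        for seed in range(120):
            fc, _ = simulate_phospho(400, sets, "K01", 0.0, seed=seed)
            table = ksea(fc, sets, min_hits=3, B=200, seed=seed)
            pvals.append(table.loc["K01", "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestRegulon:
    def _regulons(self, modes_sign=1):
        members = tuple(f"g{i}" for i in range(6))
        return {"R": AnnotationSet("R", members,
                                   {m: modes_sign for m in members})}

    def test_positive_targets_at_top_positive_direction(self):
        scores = pd.Series(np.arange(100, 0, -1.0),
                           index=[f"g{i}" for i in range(100)])
        table = regulon_enrichment(scores, self._regulons(1), B=200, seed=0)
        assert table.loc["R", "direction"] == 1

    def test_flipping_modes_flips_direction_keeps_magnitude(self):
        scores = pd.Series(np.arange(100, 0, -1.0),
                           index=[f"g{i}" for i in range(100)])
        t_plus = regulon_enrichment(scores, self._regulons(1), B=200, seed=0)
        t_minus = regulon_enrichment(scores, self._regulons(-1), B=200, seed=0)
        assert t_minus.loc["R", "direction"] == -t_plus.loc["R", "direction"]
        assert abs(t_minus.loc["R", "es"]) == pytest.approx(
            abs(t_plus.loc["R", "es"]), abs=1e-12)

    def test_planted_regulator_ranks_first_across_seeds(self, rng):
        """A regulon whose +/- targets sit at the matching extremes of the
        ranked list has the top |NKS| in >= 90% of seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            betas = pd.Series(r.normal(0, 0.3, 300),
                              index=[f"g{i:03d}" for i in range(300)])
            order = betas.sort_values(ascending=False)
            pos = tuple(order.index[:10])
            neg = tuple(order.index[-10:])
            regs = {"active": AnnotationSet(
                "active", pos + neg,
                {g: 1 for g in pos} | {g: -1 for g in neg})}
            for j in range(5):
                members = tuple(r.choice(betas.index, 20, replace=False))
                regs[f"rand{j}"] = AnnotationSet(f"rand{j}", members)
            table = regulon_enrichment(betas, regs, B=300, seed=seed)
            wins += table["nks"].abs().idxmax() == "active"
        assert wins / n_seeds >= 0.9


class TestGSEA:
    def test_bottom_set_negative_es(self):
        scores = pd.Series(np.arange(50, 0, -1.0),
                           index=[f"g{i}" for i in range(50)])
        table = gsea_preranked(scores, {"tail": [f"g{i}" for i in range(45, 50)]},
                               B=200, seed=0)
        assert table.loc["tail", "es"] < 0

    def test_duplicate_disjoint_sets_order_invariant(self):
        scores = pd.Series(np.arange(60, 0, -1.0),
                           index=[f"g{i}" for i in range(60)])
        sets_a = {"x": [f"g{i}" for i in range(5)],
                  "y": [f"g{i}" for i in range(30, 35)]}
        sets_b = dict(reversed(list(sets_a.items())))
        ta = gsea_preranked(scores, sets_a, B=200, seed=0)
        tb = gsea_preranked(scores, sets_b, B=200, seed=0)
        pd.testing.assert_frame_equal(ta.sort_index(), tb.sort_index())

    def test_planted_shifted_set_detected(self, rng):
        """A 50-gene set shifted by one score s.d. is significant at q < 0.1
        in most runs."""
        detected = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = pd.Series(r.normal(0, 1, 1000),
                               index=[f"g{i:04d}" for i in range(1000)])
            members = r.choice(scores.index, 50, replace=False)
            scores[members] += 1.0
            sets = {"planted": list(members)}
            for j in range(5):
                sets[f"rand{j}"] = list(r.choice(scores.index, 50, replace=False))
            table = gsea_preranked(scores, sets, B=300, seed=seed)
            detected += bool(table.loc["planted", "significant"])
        assert detected / 10 >= 0.8
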