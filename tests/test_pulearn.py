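"""Bagging-SVM PU scoring, baseline selection and the cross-validation protocols."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncrank._util import rank_auc
from lncrank.features import FeatureStore
from lncrank.pulearn import (
    BaggingConfig,
    SVMGridConfig,
    SVMParams,
    _bagged_scores,
    bagging_score,
    baseline_selection,
    lodocv_auc,
    loocv_auc,
    rank_unlabeled,
)

LINEAR = SVMParams("linear", 0)


def planted_store(n_diseases=6, n_lncrnas=8, seed=0):
    """A store whose co-expression block linearly separates planted pairs."""
    rng = np.random.default_rng(seed)
    diseases = tuple(f"d{i}" for i in range(n_diseases))
    lncrnas = tuple(f"l{i}" for i in range(n_lncrnas))
    store = FeatureStore(
        diseases=diseases,
        lncrnas=lncrnas,
        v_chr=rng.uniform(size=(n_diseases, 5)),
        v_path=rng.uniform(size=(n_diseases, 3)),
        seq_kmers=rng.uniform(size=(n_lncrnas, 4)),
        profiles=rng.uniform(size=(n_lncrnas, 4)),
        coexp=rng.normal(0, 0.05, size=(n_diseases, n_lncrnas, 3)),
    )
    return store


def plant(store, pairs, value=1.0):
    d_idx = {d: i for i, d in enumerate(store.diseases)}
    l_idx = {l: i for i, l in enumerate(store.lncrnas)}
    for d, l in pairs:
        store.coexp[d_idx[d], l_idx[l]] = value


def all_pairs(store):
    return [(d, l) for d in store.diseases for l in store.lncrnas]


class TestBaggingScore:
    def setup_method(self):
        self.store = planted_store()
        pairs = all_pairs(self.store)
        self.positives = pairs[::7][:6]
        plant(self.store, self.positives)
        self.unlabeled = [p for p in pairs if p not in set(self.positives)]

    def test_single_round_scores_equal_decision_values(self):
        config = BaggingConfig(v=1, seed=3)
        scores = bagging_score(self.store, self.positives, self.unlabeled, LINEAR, 7, config)
        in_bag = scores["n"] == 0
        assert in_bag.sum() == len(self.positives)  # R = |PO| pairs were in the bag
        assert (scores.loc[~in_bag, "n"] == 1).all()
        assert np.allclose(scores.loc[~in_bag, "score"], scores.loc[~in_bag, "f"])
        assert scores.loc[in_bag, "score"].isna().all()

    def test_fixed_seed_is_deterministic(self):
        config = BaggingConfig(v=5, seed=42)
        s1 = bagging_score(self.store, self.positives, self.unlabeled, LINEAR, 7, config)
        s2 = bagging_score(self.store, self.positives, self.unlabeled, LINEAR, 7, config)
        pd.testing.assert_frame_equal(s1, s2)

    def test_out_of_bag_accounting(self):
        v, r = 6, 10
        config = BaggingConfig(v=v, r=r, seed=0)
        scores = bagging_score(self.store, self.positives, self.unlabeled, LINEAR, 7, config)
        assert (scores["n"] <= v).all()
        assert scores["n"].sum() == v * (len(self.unlabeled) - r)

    def test_full_coverage_when_bag_leaves_one_out(self):
        config = BaggingConfig(v=3, r=len(self.unlabeled) - 1, seed=1)
        scores = bagging_score(self.store, self.positives, self.unlabeled, LINEAR, 7, config)
        assert scores["n"].sum() == 3  # one out-of-bag pair per round

    def test_planted_pairs_outscore_noise(self):
        # hide two planted pairs among the unlabeled: they should score high
        hidden = all_pairs(self.store)[1::7][:4]
        plant(self.store, hidden)
        unlabeled = [p for p in all_pairs(self.store) if p not in set(self.positives)]
        scores = bagging_score(
            self.store, self.positives, unlabeled, LINEAR, 7, BaggingConfig(v=10, seed=5)
        )
        scored = scores.dropna(subset=["score"]).set_index(["disease_id", "lncrna_id"])
        hidden_mean = scored.loc[[p for p in hidden if p in scored.index], "score"].mean()
        noise_mean = scored.drop(index=[p for p in hidden if p in scored.index])["score"].mean()
        assert hidden_mean > noise_mean

    def test_oversized_bag_rejected(self):
        config = BaggingConfig(v=1, r=10**6, seed=0)
        with pytest.raises(ValueError, match="bootstrap size"):
            bagging_score(self.store, self.positives, self.unlabeled, LINEAR, 7, config)


class TestBaselineSelection:
    def test_single_grid_point_returned(self):
        store = planted_store()
        pairs = all_pairs(store)
        positives = pairs[::5][:8]
        plant(store, positives)
        unlabeled = [p for p in pairs if p not in set(positives)]
        grid = SVMGridConfig(kernels=("linear",), c_exps=(2,))
        result = baseline_selection(store, positives, unlabeled, grid, [7], repeats=2, seed=0)
        assert result.params == SVMParams("linear", 2)
        assert result.feature_type == 7

    def test_separable_fixture_reaches_high_f1(self):
        store = planted_store(n_diseases=8, n_lncrnas=10)
        pairs = all_pairs(store)
        positives = pairs[::4][:15]
        plant(store, positives, value=2.0)
        unlabeled = [p for p in pairs if p not in set(positives)]
        grid = SVMGridConfig(kernels=("linear",), c_exps=(0, 4))
        result = baseline_selection(store, positives, unlabeled, grid, [7], repeats=3, seed=1)
        assert result.f1_table["mean_f1"].max() > 0.9

    def test_tie_breaks_toward_grid_order(self):
        # constant features make every grid point equally (un)informative
        store = planted_store()
        store.coexp[:] = 0.0
        object.__setattr__(store, "v_chr", np.ones_like(store.v_chr))
        object.__setattr__(store, "v_path", np.ones_like(store.v_path))
        object.__setattr__(store, "seq_kmers", np.ones_like(store.seq_kmers))
        object.__setattr__(store, "profiles", np.ones_like(store.profiles))
        pairs = all_pairs(store)
        positives = pairs[:6]
        unlabeled = pairs[6:]
        grid = SVMGridConfig(kernels=("linear",), c_exps=(-2, 3))
        result = baseline_selection(store, positives, unlabeled, grid, [0, 1], repeats=2, seed=0)
        assert result.params == SVMParams("linear", -2)
        assert result.feature_type == 0

    def test_insufficient_unlabeled_rejected(self):
        store = planted_store()
        pairs = all_pairs(store)
        with pytest.raises(ValueError, match="unlabeled"):
            baseline_selection(store, pairs[:30], pairs[30:32], SVMGridConfig(), [0], repeats=1)


class TestCrossValidation:
    def make_problem(self, seed=0):
        store = planted_store(n_diseases=8, n_lncrnas=10, seed=seed)
        pairs = all_pairs(store)
        rng = np.random.default_rng(seed)
        pos_idx = rng.choice(len(pairs), size=14, replace=False)
        positives = [pairs[i] for i in sorted(pos_idx)]
        plant(store, positives, value=1.5)
        unlabeled = [p for p in pairs if p not in set(positives)]
        return store, positives, unlabeled

    def test_loocv_recovers_planted_signal(self):
        store, po, un = self.make_problem()
        res = loocv_auc(store, po, un, LINEAR, 7, BaggingConfig(v=5, seed=2))
        assert res.auc > 0.9
        assert res.held_out_scores.size == len(po)

    def test_loocv_requires_two_positives(self):
        store, po, un = self.make_problem()
        with pytest.raises(ValueError, match="at least 2"):
            loocv_auc(store, po[:1], un, LINEAR, 7)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        aucs = [rank_auc(rng.uniform(size=50), rng.uniform(size=500)) for _ in range(50)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_lodocv_mean_is_mean_of_table(self):
        store, po, un = self.make_problem(seed=3)
        res = lodocv_auc(store, po, un, LINEAR, 7, BaggingConfig(v=5, seed=1))
        assert res.mean_auc == pytest.approx(res.per_disease.mean())
        assert (res.per_disease > 0.5).mean() > 0.5  # majority of diseases recovered

    def test_lodocv_skips_disease_without_kept_positives(self, caplog):
        import logging

        store = planted_store()
        pairs = all_pairs(store)
        positives = [p for p in pairs if p[0] == store.diseases[0]][:4]
        plant(store, positives)
        unlabeled = [p for p in pairs if p not in set(positives)]
        with caplog.at_level(logging.WARNING, logger="lncrank"):
            res = lodocv_auc(store, positives, unlabeled, LINEAR, 7, BaggingConfig(v=2, seed=0))
        assert res.per_disease.empty


class TestRankUnlabeled:
    def make_scores(self):
        return pd.DataFrame(
            {
                "disease_id": ["d1", "d2", "d1", "d3", "d1"],
                "lncrna_id": ["l1", "l2", "l3", "l1", "l2"],
                "f": [0.9, 0.5, 0.1, 0.5, 0.0],
                "n": [1, 1, 1, 1, 0],
                "score": [0.9, 0.5, 0.1, 0.5, np.nan],
            }
        )

    def test_descending_order(self):
        ranked = rank_unlabeled(self.make_scores())
        assert ranked["score"].tolist() == [0.9, 0.5, 0.5, 0.1]

    def test_ties_break_lexicographically(self):
        ranked = rank_unlabeled(self.make_scores())
        tied = ranked[ranked["score"] == 0.5]
        assert tied["disease_id"].tolist() == ["d2", "d3"]

    def test_per_disease_top_extraction(self):
        ranked = rank_unlabeled(self.make_scores(), disease="d1", top=1)
        assert len(ranked) == 1
        assert ranked.iloc[0]["lncrna_id"] == "l1"

    def test_unscored_pairs_excluded(self):
        ranked = rank_unlabeled(self.make_scores())
        assert len(ranked) == 4
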