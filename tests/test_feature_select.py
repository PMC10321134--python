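"""Booster importance ranking, union selection rule, correlation pruning."""

import numpy as np
import pandas as pd
import pytest

from oedl.containers import int_to_labels, make_feature_table
from oedl.feature_select import (
    LEAFWISE_GAIN,
    SECONDORDER_WEIGHT,
    ImportanceRanking,
    fuse_features,
    prune_correlated,
    rank_importance,
    select_union_topk,
)


def _rank(scores: dict) -> ImportanceRanking:
    return ImportanceRanking("leafwise_gain", pd.Series(scores, dtype=float))


def _table_from(X, names, modality="radiomics"):
    df = pd.DataFrame(X, columns=names)
    df.index = [f"s{i}" for i in range(len(df))]
    return make_feature_table(df, modality, "continuous")


@pytest.fixture(scope="module")
def planted_single():
    """One informative feature among 99 noise features, effect 2 SD."""
    rng = np.random.default_rng(0)
    n = 400
    y = rng.integers(0, 3, n)
    X = rng.normal(0, 1, (n, 100))
    X[:, 37] += y * 2.0
    names = [f"f{i:03d}" for i in range(100)]
    return _table_from(X, names), pd.Series(int_to_labels(y)), "f037"


class TestRankImportance:
    @pytest.mark.parametrize("method", [LEAFWISE_GAIN, SECONDORDER_WEIGHT])
    def test_single_informative_feature_ranked_first(self, method, planted_single):
        table, labels, name = planted_single
        labels = labels.set_axis(table.data.index)
        # univariate AUC oracle confirms it is the only separating feature
        from sklearn.metrics import roc_auc_score
        y01 = (labels == "C").astype(int).to_numpy()
        aucs = [roc_auc_score(y01, table.data[c]) for c in table.feature_names]
        assert table.feature_names[int(np.argmax(np.abs(np.array(aucs) - 0.5)))] == name
        rank = rank_importance(table, labels, method, seed=0)
        assert rank.order[0] == name

    def test_duplicated_informative_pair_outranks_noise(self, planted_single):
        table, labels, name = planted_single
        labels = labels.set_axis(table.data.index)
        dup = table.data.copy()
        dup["f037_copy"] = dup[name]
        t2 = _table_from(dup.to_numpy(), list(dup.columns))
        rank = rank_importance(t2, labels, LEAFWISE_GAIN, seed=0)
        pair_score = rank.scores[name] + rank.scores["f037_copy"]
        noise_max = rank.scores.drop([name, "f037_copy"]).max()
        assert pair_score > noise_max

    def test_all_noise_scores_within_permutation_null(self):
        rng = np.random.default_rng(3)
        n = 200
        y = pd.Series(int_to_labels(rng.integers(0, 3, n)))
        table = _table_from(rng.normal(0, 1, (n, 20)), [f"f{i}" for i in range(20)])
        y = y.set_axis(table.data.index)
        observed = rank_importance(table, y, LEAFWISE_GAIN, seed=0).scores.max()
        null_maxima = []
        for rep in range(5):
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=table.data.index)
            null_maxima.append(rank_importance(table, y_perm, LEAFWISE_GAIN, seed=rep).scores.max())
        # observed max should look like a draw from the permutation null
        assert observed <= 2.0 * max(null_maxima)

    def test_single_class_rejected(self, planted_single):
        table, _, _ = planted_single
        ones = pd.Series(["A"] * table.n_samples, index=table.data.index)
        with pytest.raises(ValueError):
            rank_importance(table, ones, LEAFWISE_GAIN)


class TestUnionTopK:
    def test_identical_rankings_give_top_pool(self):
        scores = {f"f{i:02d}": 60 - i for i in range(60)}
        res = select_union_topk(_rank(scores), _rank(scores), k_pool=50, k_head=10)
        assert set(res.selected) == {f"f{i:02d}" for i in range(50)}

    def test_disjoint_pools_give_heads_only(self):
        a = {f"a{i:02d}": 100 - i for i in range(60)}
        b = {f"b{i:02d}": 100 - i for i in range(60)}
        both = {**a, **{k: 0.0 for k in b}}
        other = {**b, **{k: 0.0 for k in a}}
        res = select_union_topk(_rank(both), _rank(other), k_pool=50, k_head=10)
        assert len(res.selected) == 20
        assert {p for p in res.provenance.values()} == {"top10_methodA", "top10_methodB"}

    def test_hand_enumerated_toy(self):
        """60 features; brute-force set algebra fixes the expected output."""
        rng = np.random.default_rng(1)
        names = [f"f{i:02d}" for i in range(60)]
        sa = dict(zip(names, rng.permutation(60).astype(float)))
        sb = dict(zip(names, rng.permutation(60).astype(float)))
        ra, rb = _rank(sa), _rank(sb)
        k_pool, k_head = 20, 5
        top = lambda s, k: set(sorted(s, key=lambda f: -s[f])[:k])
        expected = (top(sa, k_pool) & top(sb, k_pool)) | top(sa, k_head) | top(sb, k_head)
        res = select_union_topk(ra, rb, k_pool=k_pool, k_head=k_head)
        assert set(res.selected) == expected

    def test_symmetric_up_to_provenance(self):
        rng = np.random.default_rng(2)
        names = [f"f{i}" for i in range(30)]
        sa = dict(zip(names, rng.permutation(30).astype(float)))
        sb = dict(zip(names, rng.permutation(30).astype(float)))
        r1 = select_union_topk(_rank(sa), _rank(sb), 20, 5)
        r2 = select_union_topk(_rank(sb), _rank(sa), 20, 5)
        assert set(r1.selected) == set(r2.selected)

    def test_head_larger_than_pool_rejected(self):
        s = _rank({"a": 1.0, "b": 0.5})
        with pytest.raises(ValueError):
            select_union_topk(s, s, k_pool=5, k_head=6)


class TestPruneCorrelated:
    def test_duplicate_keeps_higher_importance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        table = _table_from(np.column_stack([x, x, rng.normal(0, 1, 100)]),
                            ["low", "high", "other"])
        ranking = _rank({"low": 1.0, "high": 5.0, "other": 3.0})
        res = prune_correlated(table, ["low", "high", "other"], ranking)
        assert "high" in res.selected and "low" not in res.selected
        assert res.dropped_pairs[0][0] == "low"

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(1)
        table = _table_from(rng.normal(0, 1, (200, 4)), list("abcd"))
        ranking = _rank({"a": 4, "b": 3, "c": 2, "d": 1})
        res = prune_correlated(table, list("abcd"), ranking)
        assert res.selected == list("abcd")

    def test_matches_brute_force_greedy_on_toy(self):
        """5 features with a planted correlation structure."""
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 500)
        X = np.column_stack([
            base,
            base + rng.normal(0, 0.1, 500),   # r ~ 0.995 with 0
            rng.normal(0, 1, 500),
            base + rng.normal(0, 1.5, 500),   # r ~ 0.55 with 0
            -base + rng.normal(0, 0.1, 500),  # r ~ -0.995 with 0
        ])
        names = list("vwxyz")
        table = _table_from(X, names)
        ranking = _rank(dict(zip(names, [5.0, 4.0, 3.0, 2.0, 1.0])))
        res = prune_correlated(table, names, ranking, threshold=0.9)
        # brute-force greedy in importance order
        corr = np.corrcoef(X, rowvar=False)
        kept = []
        for idx in range(5):
            if all(abs(corr[idx, j]) <= 0.9 for j in kept):
                kept.append(idx)
        assert res.selected == [names[i] for i in kept]
        # invariant: no surviving pair exceeds the threshold
        sel = [names.index(s) for s in res.selected]
        for i in sel:
            for j in sel:
                if i != j:
                    assert abs(corr[i, j]) <= 0.9

    def test_constant_column_rejected(self):
        table = _table_from(np.column_stack([np.ones(10), np.arange(10)]), ["c", "v"])
        with pytest.raises(ValueError, match="variance_filter"):
            prune_correlated(table, ["c", "v"], _rank({"c": 1.0, "v": 2.0}))


class TestFuse:
    def test_column_counts(self):
        rng = np.random.default_rng(0)
        clin = _table_from(rng.normal(0, 1, (20, 17)),
                           [f"c{i}" for i in range(17)], modality="clinical")
        rad = _table_from(rng.normal(0, 1, (20, 19)), [f"r{i}" for i in range(19)])
        fused = fuse_features(clin, rad)
        assert len(fused.feature_names) == 36
        assert fused.n_samples == 20

    def test_alignment_by_sample_id(self):
        rng = np.random.default_rng(1)
        clin = _table_from(rng.normal(0, 1, (10, 3)), ["c0", "c1", "c2"], "clinical")
        rad = _table_from(rng.normal(0, 1, (10, 2)), ["r0", "r1"])
        shuffled = rad.subset_samples(list(reversed(list(rad.sample_ids))))
        a = fuse_features(clin, rad)
        b = fuse_features(clin, shuffled)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_id_mismatch_lists_offenders(self):
        rng = np.random.default_rng(2)
        clin = _table_from(rng.normal(0, 1, (4, 2)), ["c0", "c1"], "clinical")
        rad = _table_from(rng.normal(0, 1, (5, 2)), ["r0", "r1"])
        with pytest.raises(ValueError, match="s4"):
            fuse_features(clin, rad)
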