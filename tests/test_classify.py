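"""Splits, balancing, RF/CNN training contracts, evaluation and statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nucleoprofile.classify import (
    DensityBinning,
    TrainConfig,
    balance_classes,
    compare_models,
    confluency_score,
    embed,
    evaluate,
    evaluate_by_density,
    finetune,
    split_by_well,
    train_cnn,
    train_rf,
)


def _records(n_per_well, wells):
    rows = []
    for w in wells:
        for i in range(n_per_well):
            rows.append({"well": w})
    return pd.DataFrame(rows, index=[f"{w}_{i}" for w in wells for i in range(n_per_well)])


class TestSplit:
    def test_ten_equal_wells_split_631(self):
        recs = _records(20, [f"w{i}" for i in range(10)])
        split = split_by_well(recs, seed=3)
        sets = split.well_sets()
        assert (len(sets["train"]), len(sets["val"]), len(sets["test"])) == (6, 1, 3)

    def test_no_well_in_two_subsets(self):
        recs = _records(5, [f"w{i}" for i in range(7)])
        sets = split_by_well(recs, seed=1).well_sets()
        assert not (sets["train"] & sets["val"])
        assert not (sets["train"] & sets["test"])
        assert not (sets["val"] & sets["test"])

    def test_deterministic(self):
        recs = _records(5, [f"w{i}" for i in range(9)])
        a = split_by_well(recs, seed=5)
        b = split_by_well(recs, seed=5)
        assert a.assignment == b.assignment

    def test_too_few_wells(self):
        with pytest.raises(ValueError):
            split_by_well(_records(5, ["a", "b"]))

    def test_strata_balance_subsets(self):
        wells = [f"w{i}" for i in range(12)]
        recs = _records(10, wells)
        strata = {w: ("A" if i % 2 else "B") for i, w in enumerate(wells)}
        sets = split_by_well(recs, seed=2, strata=strata).well_sets()
        for subset in sets.values():
            kinds = {strata[w] for w in subset}
            assert kinds == {"A", "B"}


class TestBalance:
    def _labels(self, counts):
        items = []
        for cls, n in counts.items():
            items += [(f"{cls}{i}", cls) for i in range(n)]
        return pd.Series(dict(items))

    def test_downsample_to_minority(self):
        labels = self._labels({"A": 100, "B": 60})
        kept = balance_classes(labels.index, labels, seed=0)
        vc = labels.loc[kept].value_counts()
        assert vc["A"] == vc["B"] == 60

    def test_already_balanced_counts_unchanged(self):
        labels = self._labels({"A": 30, "B": 30})
        kept = balance_classes(labels.index, labels, seed=0)
        assert labels.loc[kept].value_counts().tolist() == [30, 30]

    def test_three_classes(self):
        labels = self._labels({"A": 30, "B": 20, "C": 10})
        kept = balance_classes(labels.index, labels, seed=0)
        assert sorted(labels.loc[kept].value_counts()) == [10, 10, 10]

    def test_single_class_rejected(self):
        labels = self._labels({"A": 10})
        with pytest.raises(ValueError):
            balance_classes(labels.index, labels)


class TestRandomForest:
    def test_importances_sum_to_one_and_top_feature(self, rng):
        n = 300
        informative = np.r_[rng.normal(0, 1, n // 2), rng.normal(5, 1, n // 2)]
        X = pd.DataFrame(
            {"info": informative, "junk1": rng.normal(0, 1, n), "junk2": rng.normal(0, 1, n)}
        )
        y = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=X.index)
        model, imp = train_rf(X, y, n_trees=30, seed=0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.idxmax() == "info"

    def test_nan_features_named(self, rng):
        X = pd.DataFrame({"ok": rng.normal(0, 1, 10), "bad": [np.nan] * 10})
        y = pd.Series(["a", "b"] * 5, index=X.index)
        with pytest.raises(ValueError, match="bad"):
            train_rf(X, y)

    def test_shuffled_labels_give_chance_f(self, rng):
        n = 600
        X = pd.DataFrame(rng.normal(0, 1, (n, 8)), columns=[f"f{i}" for i in range(8)])
        y = pd.Series(rng.permutation(["a", "b"] * (n // 2)), index=X.index)
        model, _ = train_rf(X.iloc[: n // 2], y.iloc[: n // 2], n_trees=30, seed=0)
        rep = evaluate(model, X.iloc[n // 2 :], y.iloc[n // 2 :])
        assert rep.macro_f == pytest.approx(0.5, abs=0.1)

    def test_leakage_assertion(self, rng):
        X = pd.DataFrame({"f": rng.normal(0, 1, 10)})
        y = pd.Series(["a", "b"] * 5, index=X.index)
        with pytest.raises(ValueError, match="overlap"):
            train_rf(X, y, train_wells={"w1", "w2"}, test_wells={"w2"})


def _separable_crops(rng, n_per_class=40, P=21):
    """Tiny synthetic crop set: class differs by a bright central square."""
    X, y = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = rng.normal(0, 0.3, (2, P, P))
            size = 3 if cls == 0 else 7
            img[:, P // 2 - size : P // 2 + size, P // 2 - size : P // 2 + size] += 2.0
            X.append(img)
            y.append(f"c{cls}")
    return np.stack(X), np.array(y)


class TestCnn:
    cfg = TrainConfig(epochs=6, batch_size=32, lr0=2e-3, min_per_class=1, seed=0)

    def test_learns_separable_crops(self, rng):
        X, y = _separable_crops(rng)
        Xt, yt = _separable_crops(np.random.default_rng(99))
        cfg = TrainConfig(epochs=8, batch_size=32, lr0=2e-3, min_per_class=1,
                          seed=0, input_channels=2)
        model, log = train_cnn(X, y, cfg, Xt[:20], yt[:20])
        rep = evaluate(model, Xt, yt)
        assert rep.macro_f >= 0.95
        assert len(log) == 8 and {"loss", "val_acc", "lr"} <= set(log.columns)

    def test_same_seed_identical_metrics(self, rng):
        X, y = _separable_crops(rng, n_per_class=12)
        cfg = TrainConfig(epochs=2, batch_size=16, min_per_class=1, seed=7, input_channels=2)
        _, log1 = train_cnn(X, y, cfg)
        _, log2 = train_cnn(X, y, cfg)
        assert log1.equals(log2)

    def test_inconsistent_shapes_rejected(self, rng):
        ragged = np.empty(2, dtype=object)
        ragged[0] = rng.normal(0, 1, (2, 9, 9))
        ragged[1] = rng.normal(0, 1, (2, 7, 7))
        cfg = TrainConfig(min_per_class=1, input_channels=2)
        with pytest.raises(ValueError):
            train_cnn(ragged, np.array(["a", "b"]), cfg)

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (4, 2, 9, 9))
        with pytest.raises(ValueError):
            train_cnn(X, np.array(["a"] * 4), TrainConfig(min_per_class=1, input_channels=2))

    def test_embedding_probe(self, rng):
        X, y = _separable_crops(rng, n_per_class=30)
        cfg = TrainConfig(epochs=6, batch_size=32, lr0=2e-3, min_per_class=1,
                          seed=1, input_channels=2)
        model, _ = train_cnn(X, y, cfg)
        Xt, yt = _separable_crops(np.random.default_rng(5), n_per_class=25)
        E = embed(model, Xt)
        assert E.shape[0] == len(Xt)
        # 1-NN in embedding space separates the classes
        from sklearn.neighbors import KNeighborsClassifier

        knn = KNeighborsClassifier(1).fit(embed(model, X), y)
        assert (knn.predict(E) == yt).mean() >= 0.9

    def test_finetune_contracts(self, rng):
        X, y = _separable_crops(rng, n_per_class=12)
        cfg = TrainConfig(epochs=2, batch_size=16, min_per_class=1, seed=0, input_channels=2)
        model, _ = train_cnn(X, y, cfg)
        same, log = finetune(model, X[:0], y[:0], cfg)
        assert np.allclose(same.predict_logits(X[:4]), model.predict_logits(X[:4]))
        with pytest.raises(ValueError):
            finetune(model, X[:4], np.array(["new"] * 4), cfg)

    def test_finetune_adapts_to_shifted_distribution(self, rng):
        X, y = _separable_crops(rng, n_per_class=30)
        cfg = TrainConfig(epochs=6, batch_size=32, lr0=2e-3, min_per_class=1,
                          seed=0, input_channels=2)
        model, _ = train_cnn(X, y, cfg)
        # brightness-shifted replicate
        X2, y2 = _separable_crops(np.random.default_rng(3), n_per_class=30)
        X2 = X2 * 0.3 - 1.0
        before = evaluate(model, X2, y2).macro_f
        tuned, _ = finetune(model, X2[::2], y2[::2], cfg)
        after = evaluate(tuned, X2[1::2], y2[1::2]).macro_f
        assert after >= before


class TestEvaluate:
    def test_closed_form_binary_counts(self):
        class Fixed:
            def predict(self, X):
                return np.array(["p"] * 10 + ["n"] * 10)

        y = np.array(["p"] * 9 + ["n"] + ["p"] + ["n"] * 9)
        rep = evaluate(Fixed(), np.zeros((20, 1)), y, class_order=["n", "p"])
        i = rep.classes.index("p")
        assert rep.precision[i] == pytest.approx(0.9)
        assert rep.recall[i] == pytest.approx(0.9)
        assert rep.f1[i] == pytest.approx(0.9)

    def test_perfect_predictions(self):
        class Echo:
            def predict(self, X):
                return X[:, 0]

        y = np.array(["a", "b", "a", "b"])
        rep = evaluate(Echo(), y[:, None], y)
        assert rep.macro_f == 1.0
        assert np.all(rep.confusion == np.array([[2, 0], [0, 2]]))

    def test_all_one_class_predictor(self):
        class Const:
            def predict(self, X):
                return np.array(["a"] * len(X))

        y = np.array(["a", "b"] * 10)
        rep = evaluate(Const(), np.zeros((20, 1)), y)
        assert rep.macro_f == pytest.approx(1 / 3)  # per-class F1 (2/3, 0)

    def test_empty_test_set_rejected(self):
        class Const:
            def predict(self, X):
                return np.array([])

        with pytest.raises(ValueError):
            evaluate(Const(), np.zeros((0, 1)), np.array([]))

    def test_macro_f_matches_brute_force(self, rng):
        """Macro F equals hand-averaged per-class F1 on random predictions."""
        for _ in range(100):
            classes = ["a", "b", "c"]
            y = rng.choice(classes, 60)
            pred = rng.choice(classes, 60)

            class Fixed:
                def predict(self, X, _p=pred):
                    return _p

            rep = evaluate(Fixed(), np.zeros((60, 1)), y, class_order=classes)
            f1s = []
            for c in classes:
                tp = np.sum((pred == c) & (y == c))
                fp = np.sum((pred == c) & (y != c))
                fn = np.sum((pred != c) & (y == c))
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            assert rep.macro_f == pytest.approx(np.mean(f1s), abs=1e-12)


class TestDensity:
    def test_confluency_extremes(self):
        assert confluency_score(np.zeros((10, 10), dtype=int)) == 0.0
        assert confluency_score(np.ones((10, 10), dtype=int)) == 100.0

    def test_scores_increase_with_density(self):
        from nucleoprofile.simulate import SceneConfig, density_series

        cfg = SceneConfig(field_size=(384, 384), overlap_policy="crowded", seed=2)
        series = density_series(cfg, [4, 18, 45])
        scores = [confluency_score(t.cells_mask) for _, t in series]
        assert scores[0] < scores[1] < scores[2]

    def test_bin_edges_half_open(self):
        b = DensityBinning()
        assert b.labels[b.assign([95.0])[0]] == "80-95"
        assert b.labels[b.assign([95.1])[0]] == "95-100"
        assert b.labels[b.assign([100.0])[0]] == "95-100"
        assert b.labels[b.assign([20.0])[0]] == "0-20"

    def test_insufficient_bins_flagged(self):
        class Const:
            def predict(self, X):
                return np.array(["a"] * len(X))

        y = np.array(["a", "b"] * 20)
        dens = np.full(40, 50.0)  # everything in one bin
        rep = evaluate_by_density(Const(), np.zeros((40, 1)), y, dens)
        per = rep.per_bin.set_index("bin")
        assert not per.loc["40-60", "insufficient"]
        assert per.loc["0-20", "insufficient"] and np.isnan(per.loc["0-20", "macro_f"])

    def test_invalid_edges(self):
        with pytest.raises(ValueError):
            DensityBinning(edges=(0.0, 50.0, 40.0, 100.0))


class TestMannWhitney:
    def test_exact_p_by_enumeration(self):
        """U=0 and p=0.1 for [1,2,3] vs [4,5,6], verified by enumerating all
        20 assignments of the six values into two groups of three."""
        a, b = [1, 2, 3], [4, 5, 6]
        u, p = compare_models(a, b)
        assert u == 0.0
        pooled = a + b
        observed_u = 0  # wins of group-a values over group-b values
        count_extreme = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u_combo = sum(x > yv for x in ga for yv in gb)
            total += 1
            # two-sided: as or more extreme than min(U, n1*n2-U) = 0
            if min(u_combo, 9 - u_combo) <= min(observed_u, 9 - observed_u):
                count_extreme += 1
        assert total == 20
        assert p == pytest.approx(count_extreme / total)
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        u, p = compare_models([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_symmetric_under_swap(self):
        _, p1 = compare_models([0.91, 0.93, 0.92, 0.95], [0.85, 0.86, 0.84, 0.83])
        _, p2 = compare_models([0.85, 0.86, 0.84, 0.83], [0.91, 0.93, 0.92, 0.95])
        assert p1 == pytest.approx(p2)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_models([1, 2], [3, 4, 5])
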