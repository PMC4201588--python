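import math
from statistics import mean, variance

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccva import (
    ExpressionMatrix,
    LabelledExpression,
    SimulationConfig,
    balanced_design,
    fscore,
    load_model,
    models_equal,
    predict,
    save_model,
    select_features,
    simulate,
    train_margin,
    train_rank_pairs,
)


def fscore_oracle(pos, neg):
    """Direct evaluation of the F-score formula with stdlib statistics."""
    m_pos, m_neg = mean(pos), mean(neg)
    m_all = mean(list(pos) + list(neg))
    denom = variance(pos) + variance(neg)
    num = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    return math.inf if denom == 0 else num / denom


class TestFscore:
    def test_hand_derived_value(self):
        assert fscore([1, 2, 3], [4, 5, 6]) == 2.25

    def test_equal_means_give_zero(self):
        assert fscore([1.0, 3.0], [0.0, 4.0]) == 0.0

    def test_zero_denominator_is_infinite(self):
        assert fscore([2.0, 2.0], [5.0, 5.0]) == math.inf

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            fscore([1.0], [2.0, 3.0])

    def test_matches_oracle_on_many_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 12, size=2)
            pos = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n1)
            neg = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n2)
            expected = fscore_oracle(list(pos), list(neg))
            got = fscore(pos, neg)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance_exact_small_integers(self):
        # integer inputs keep the arithmetic exact in binary floating point
        base = fscore([1, 2, 3], [4, 5, 6])
        assert fscore([3, 5, 7], [9, 11, 13]) == base  # a=2, b=1
        assert fscore([-2, -4, -6], [-8, -10, -12]) == base  # a=-2

    @given(
        pos=st.lists(st.integers(-50, 50), min_size=2, max_size=8),
        neg=st.lists(st.integers(-50, 50), min_size=2, max_size=8),
        a=st.sampled_from([-4, -1, 2, 8]),
        b=st.integers(-20, 20),
    )
    def test_affine_invariance_property(self, pos, neg, a, b):
        f0 = fscore(pos, neg)
        f1 = fscore([a * x + b for x in pos], [a * x + b for x in neg])
        if math.isinf(f0):
            assert math.isinf(f1)
        else:
            assert f1 == pytest.approx(f0, rel=1e-9)


class TestSelectFeatures:
    def _data(self):
        # g000 separates P from Q perfectly; g001 weakly; g002 noise
        genes = ("g000", "g001", "g002")
        values = np.array(
            [
                [0.0, 0.1, 0.2, 5.0, 5.1, 5.2],
                [0.0, 1.0, 2.0, 1.5, 2.5, 3.5],
                [1.0, -1.0, 0.5, -0.5, 1.0, -1.0],
            ]
        )
        labels = np.array(["P", "P", "P", "Q", "Q", "Q"], dtype=object)
        return LabelledExpression(genes, values, labels)

    def test_top_gene_always_included(self):
        assert select_features(self._data(), 1) == ["g000"]

    def test_k_equal_n_genes_returns_all_sorted_by_score(self):
        feats = select_features(self._data(), 3)
        assert set(feats) == {"g000", "g001", "g002"}
        assert feats[0] == "g000"

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            select_features(self._data(), 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_signature_genes_on_simulated_data(self, seed):
        cfg = SimulationConfig(
            n_genes=200,
            study_design=balanced_design(2, ("A", "B"), 15),
            signature_size=20,
            effect_size=3.0,
            study_effect_sd=0.0,
            heterogeneity_sd=0.0,
            noise_sd=1.0,
            seed=seed,
        )
        ds, sigs = simulate(cfg)
        selected = select_features(ds, 20)
        truth = sigs["A"] | sigs["B"]
        assert sum(g in truth for g in selected) / len(selected) >= 0.8


class TestMarginClassifier:
    def _separable(self):
        genes = ("g1", "g2")
        values = np.array(
            [
                [0.0, 0.2, 0.1, 3.0, 3.2, 3.1],
                [1.0, 1.1, 0.9, -1.0, -1.1, -0.9],
            ]
        )
        labels = np.array(["L", "L", "L", "R", "R", "R"], dtype=object)
        return LabelledExpression(genes, values, labels)

    def test_separable_clusters_classified_perfectly(self):
        data = self._separable()
        model = train_margin(data, ["g1", "g2"], cost=1.0)
        m = ExpressionMatrix(data.gene_ids, tuple(f"s{i}" for i in range(6)), data.values)
        assert list(predict(model, m)) == list(data.labels)

    def test_three_phenotypes_give_three_discriminants(self):
        rng = np.random.default_rng(0)
        genes = tuple(f"g{i}" for i in range(4))
        centers = {"A": 0.0, "B": 5.0, "C": 10.0}
        cols, labels = [], []
        for lab, c in centers.items():
            for _ in range(4):
                cols.append(rng.normal(c, 0.3, 4))
                labels.append(lab)
        data = LabelledExpression(genes, np.column_stack(cols), np.array(labels, dtype=object))
        model = train_margin(data, list(genes))
        assert len(model.discriminants) == 3
        assert {(d.class_a, d.class_b) for d in model.discriminants} == {
            ("A", "B"),
            ("A", "C"),
            ("B", "C"),
        }

    def test_tiny_phenotype_rejected_by_name(self):
        genes = ("g1",)
        values = np.array([[0.0, 1.0, 2.0]])
        labels = np.array(["A", "A", "B"], dtype=object)
        with pytest.raises(ValueError, match="'B'"):
            train_margin(LabelledExpression(genes, values, labels), ["g1"])

    def test_gene_row_order_irrelevant_to_predictions(self):
        data = self._separable()
        model = train_margin(data, ["g1", "g2"])
        ids = tuple(f"s{i}" for i in range(6))
        m = ExpressionMatrix(data.gene_ids, ids, data.values)
        m_flip = ExpressionMatrix(("g2", "g1"), ids, data.values[::-1, :])
        assert list(predict(model, m)) == list(predict(model, m_flip))

    def test_model_json_round_trip(self, tmp_path):
        model = train_margin(self._separable(), ["g1", "g2"])
        save_model(model, tmp_path / "m.json")
        assert models_equal(model, load_model(tmp_path / "m.json"))


def delta_oracle(values, labels, cls, gi, gj):
    """Exhaustive counting of P(x_i < x_j | class) - P(x_i < x_j | rest)."""
    in_c = [k for k, l in enumerate(labels) if l == cls]
    out_c = [k for k, l in enumerate(labels) if l != cls]
    p_in = sum(values[gi, k] < values[gj, k] for k in in_c) / len(in_c)
    p_out = sum(values[gi, k] < values[gj, k] for k in out_c) / len(out_c)
    return p_in - p_out


class TestRankPairClassifier:
    def test_hand_counted_delta(self):
        # pair ordered in 4/5 of class-c samples and 1/5 of the rest
        genes = ("ga", "gb")
        values = np.array(
            [
                # c samples                 rest
                [0, 0, 0, 0, 9, 9, 9, 9, 0, 9],
                [5, 5, 5, 5, 5, 5, 5, 5, 5, 5],
            ],
            dtype=float,
        )
        labels = np.array(["c"] * 5 + ["d"] * 5, dtype=object)
        data = LabelledExpression(genes, values, labels)
        model = train_rank_pairs(data, 1)
        (gi, gj, delta) = model.pairs["c"][0]
        assert (gi, gj) == ("ga", "gb")
        assert delta == pytest.approx(0.6)
        assert delta == delta_oracle(values, labels, "c", 0, 1)

    def test_deltas_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        n_genes, n = 8, 14
        genes = tuple(f"g{i}" for i in range(n_genes))
        values = rng.normal(size=(n_genes, n))
        labels = np.array(["A"] * 7 + ["B"] * 7, dtype=object)
        data = LabelledExpression(genes, values, labels)
        model = train_rank_pairs(data, 3)
        for cls, plist in model.pairs.items():
            gene_row = {g: i for i, g in enumerate(genes)}
            for gi, gj, delta in plist:
                assert delta == pytest.approx(
                    delta_oracle(values, labels, cls, gene_row[gi], gene_row[gj])
                )
                assert delta > 0

    def test_pairs_are_gene_disjoint_within_phenotype(self):
        rng = np.random.default_rng(6)
        genes = tuple(f"g{i}" for i in range(10))
        data = LabelledExpression(
            genes,
            rng.normal(size=(10, 12)),
            np.array(["A"] * 6 + ["B"] * 6, dtype=object),
        )
        model = train_rank_pairs(data, 4)
        for plist in model.pairs.values():
            used = [g for gi, gj, _ in plist for g in (gi, gj)]
            assert len(used) == len(set(used)) == 8

    def test_perfect_pair_accepted_first_with_delta_one(self):
        genes = ("g1", "g2", "g3")
        values = np.array(
            [
                [0, 0, 0, 9, 9, 9],
                [5, 5, 5, 5, 5, 5],
                [1, 2, 0, 1, 0, 2],
            ],
            dtype=float,
        )
        labels = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        model = train_rank_pairs(LabelledExpression(genes, values, labels), 1)
        assert model.pairs["A"][0] == ("g1", "g2", 1.0)

    def test_tie_broken_lexicographically(self):
        # two disjoint pairs with identical |delta|: (g1,g2) and (g3,g4)
        genes = ("g1", "g2", "g3", "g4")
        values = np.array(
            [
                [0, 0, 9, 9],
                [5, 5, 5, 5],
                [0, 0, 9, 9],
                [5, 5, 5, 5],
            ],
            dtype=float,
        )
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        model = train_rank_pairs(LabelledExpression(genes, values, labels), 1)
        assert model.pairs["A"][0][:2] == ("g1", "g2")

    def test_insufficient_disjoint_pairs_rejected(self):
        genes = ("g1", "g2")
        values = np.random.default_rng(0).normal(size=(2, 8))
        labels = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
        with pytest.raises(ValueError, match="pairs"):
            train_rank_pairs(LabelledExpression(genes, values, labels), 2)

    def test_predictions_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(7)
        genes = tuple(f"g{i}" for i in range(10))
        data = LabelledExpression(
            genes,
            rng.normal(size=(10, 16)),
            np.array(["A"] * 8 + ["B"] * 8, dtype=object),
        )
        model = train_rank_pairs(data, 3)
        ids = tuple(f"s{i}" for i in range(6))
        raw = rng.normal(size=(10, 6))
        m = ExpressionMatrix(genes, ids, raw)
        # a different strictly increasing transform per sample
        warped = np.column_stack(
            [np.exp(raw[:, j]) * (j + 1) + j for j in range(6)]
        )
        m_warp = ExpressionMatrix(genes, ids, warped)
        assert list(predict(model, m)) == list(predict(model, m_warp))

    def test_missing_model_gene_named(self):
        genes = ("g1", "g2", "g3", "g4")
        values = np.random.default_rng(1).normal(size=(4, 8))
        labels = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
        model = train_rank_pairs(LabelledExpression(genes, values, labels), 1)
        needed = model.genes_used()
        keep = [g for g in genes if g != needed[0]]
        m = ExpressionMatrix(tuple(keep), ("s1",), np.zeros((len(keep), 1)))
        with pytest.raises(ValueError, match=needed[0]):
            predict(model, m)

    def test_sample_satisfying_all_pairs_of_one_class_wins(self):
        model_pairs = {
            "A": (("g1", "g2", 0.8),),
            "B": (("g2", "g1", 0.7),),
        }
        from ccva.classifiers import RankPairModel

        model = RankPairModel(model_pairs, ("A", "B"))
        m = ExpressionMatrix(("g1", "g2"), ("s1",), np.array([[0.0], [1.0]]))
        assert list(predict(model, m)) == ["A"]

    def test_predict_independent_of_sample_order(self):
        rng = np.random.default_rng(8)
        genes = tuple(f"g{i}" for i in range(6))
        data = LabelledExpression(
            genes,
            rng.normal(size=(6, 10)),
            np.array(["A"] * 5 + ["B"] * 5, dtype=object),
        )
        model = train_rank_pairs(data, 2)
        ids = tuple(f"s{i}" for i in range(5))
        vals = rng.normal(size=(6, 5))
        m = ExpressionMatrix(genes, ids, vals)
        rev = ExpressionMatrix(genes, ids[::-1], vals[:, ::-1])
        assert list(predict(model, m)) == list(predict(model, rev))[::-1]
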