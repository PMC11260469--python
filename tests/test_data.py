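"""Dataset container, splits, categories, cliffs and subset selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from helpers import make_dataset
from utrxfer.data import (ActivityCliffPair, DataSplit, ExpressionDataset,
                          StrengthCategories, categorize, find_activity_cliffs,
                          per_context_split, select_training_subset,
                          strength_categories, stratified_split)


class TestExpressionDataset:
    def test_duplicate_ids_rejected(self):
        frame = pd.DataFrame({
            "id": ["a", "a"], "sequence": ["ACGT", "ACGG"],
            "context": "A", "mu": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unique"):
            ExpressionDataset(frame)

    def test_bad_alphabet_rejected(self):
        frame = pd.DataFrame({
            "id": ["a"], "sequence": ["ACGX"], "context": "A", "mu": [1.0]})
        with pytest.raises(ValueError, match="non-ACGT"):
            ExpressionDataset(frame)

    def test_tsv_roundtrip(self, tmp_path, toy_dataset):
        path = tmp_path / "data.tsv"
        toy_dataset.to_tsv(path)
        loaded = ExpressionDataset.from_tsv(path)
        assert loaded.ids == toy_dataset.ids
        np.testing.assert_allclose(loaded.mu, toy_dataset.mu, atol=1e-4)

    def test_fasta_pairing(self, tmp_path, toy_dataset):
        from utrxfer.synthetic import write_library
        tsv, fasta = tmp_path / "d.tsv", tmp_path / "d.fasta"
        write_library(toy_dataset, tsv, fasta)
        frame = toy_dataset.frame.drop(columns=["sequence"])
        frame.to_csv(tmp_path / "noseq.tsv", sep="\t", index=False)
        loaded = ExpressionDataset.from_tsv(tmp_path / "noseq.tsv",
                                            fasta_path=fasta)
        assert list(loaded.frame["sequence"]) == \
            list(toy_dataset.frame["sequence"])


class TestStratifiedSplit:
    def test_hundred_records_give_80_10_10(self):
        ds = make_dataset(np.linspace(0, 10, 100))
        split = stratified_split(ds, seed=1)
        assert (len(split.train_ids), len(split.val_ids),
                len(split.test_ids)) == (80, 10, 10)

    def test_partition_property(self):
        ds = make_dataset(np.random.default_rng(3).normal(5, 2, 137))
        split = stratified_split(ds, seed=2)
        assert split.all_ids == set(ds.ids)
        assert len(split.train_ids) + len(split.val_ids) + \
            len(split.test_ids) == 137

    def test_bimodal_class_balance_preserved(self):
        """Two point masses 50/50: each subset's class balance stays
        within 5% of 50/50."""
        mu = np.array([0.0] * 50 + [10.0] * 50)
        ds = make_dataset(mu)
        split = stratified_split(ds, seed=4)
        mu_by_id = dict(zip(ds.ids, ds.mu))
        for ids in (split.train_ids, split.val_ids, split.test_ids):
            frac = np.mean([mu_by_id[i] > 5 for i in ids])
            assert abs(frac - 0.5) <= 0.05

    def test_reproducible(self):
        ds = make_dataset(np.random.default_rng(5).normal(5, 2, 60))
        assert stratified_split(ds, seed=9) == stratified_split(ds, seed=9)

    def test_empty_dataset_rejected(self):
        ds = make_dataset([1.0, 2.0])
        with pytest.raises(ValueError):
            stratified_split(ExpressionDataset(ds.frame.iloc[:0]), seed=0)


class TestPerContextSplit:
    def _multi_context(self, sizes):
        frames = []
        offset = 0
        for ctx, n in sizes.items():
            ds = make_dataset(np.linspace(1, 9, n), context=ctx,
                              seed=hash(ctx) % 1000)
            f = ds.frame.copy()
            f["id"] = [f"{ctx}{i:04d}" for i in range(n)]
            frames.append(f)
            offset += n
        return ExpressionDataset(pd.concat(frames, ignore_index=True))

    def test_sizes_follow_contract(self):
        ds = self._multi_context({"p62": 62, "p59": 59, "p111": 111})
        splits = per_context_split(ds, seed=0)
        assert set(splits) == {"p62", "p111"}     # 59 < 60 dropped
        s62 = splits["p62"]
        assert (len(s62.train_ids), len(s62.val_ids), len(s62.test_ids)) \
            == (12, 20, 30)
        s111 = splits["p111"]
        assert (len(s111.train_ids), len(s111.val_ids), len(s111.test_ids)) \
            == (61, 20, 30)

    def test_test_set_covers_mu_range(self):
        ds = self._multi_context({"p100": 100})
        split = per_context_split(ds, seed=1)["p100"]
        mu_by_id = dict(zip(ds.ids, ds.mu))
        test_mu = sorted(mu_by_id[i] for i in split.test_ids)
        # balanced selection spans the range, not just the dense middle
        assert test_mu[0] <= np.percentile(ds.mu, 10)
        assert test_mu[-1] >= np.percentile(ds.mu, 90)


class TestStrengthCategories:
    def test_quantile_range_quarter_width(self):
        # a 1%-99% range of 6.4 gives the published-style width of 1.6;
        # for linspace(0, M, 100) the interpolated 1-99% range is 0.9801 M
        mu = np.linspace(0, 6.4 / 0.9801, 100)
        ds = make_dataset(mu)
        cats = strength_categories(ds)
        assert cats.width == pytest.approx((cats.q99 - cats.q1) / 4)
        assert cats.q99 - cats.q1 == pytest.approx(6.4, abs=0.01)
        assert cats.width == pytest.approx(1.6, abs=0.01)

    def test_simple_boundaries(self):
        cats = StrengthCategories(q1=0.0, q99=4.0)
        assert cats.width == 1.0
        assert cats.boundaries == (1.0, 2.0, 3.0)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(8)
        mu = rng.normal(5, 2, 300)
        a, b = 2.5, -1.0
        w1 = strength_categories(make_dataset(mu)).width
        w2 = strength_categories(make_dataset(a * mu + b)).width
        assert w2 == pytest.approx(a * w1, rel=1e-9)

    def test_constant_mu_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            strength_categories(make_dataset([3.0, 3.0, 3.0]))

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        mu = rng.normal(5, 2, 100)
        c1 = strength_categories(make_dataset(mu))
        c2 = strength_categories(make_dataset(mu[rng.permutation(100)]))
        assert c1.q1 == pytest.approx(c2.q1)
        assert c1.q99 == pytest.approx(c2.q99)


class TestCategorize:
    cats = StrengthCategories(q1=0.0, q99=4.0)

    @pytest.mark.parametrize("value,label", [
        (0.5, "weak"),
        (3.9, "strong"),
        (-2.0, "weak"),           # below range
        (9.0, "strong"),          # above range
        (1.0, "medium weak"),     # boundary tie goes upward
        (2.0, "medium strong"),
        (3.0, "strong"),
    ])
    def test_labels(self, value, label):
        assert categorize(value, self.cats) == label


class TestActivityCliffs:
    def test_constructed_cliff_found(self):
        records = [("a", "AAAA", 2.5), ("b", "AAAT", 6.5)]
        pairs = find_activity_cliffs(records)
        assert len(pairs) == 1
        assert pairs[0].id_weak == "a" and pairs[0].id_strong == "b"

    def test_identical_sequences_never_pair(self):
        records = [("a", "AAAA", 2.5), ("b", "AAAA", 6.5)]
        assert find_activity_cliffs(records) == []

    def test_unequal_lengths_never_pair(self):
        records = [("a", "AAAA", 2.5), ("b", "AAAAT", 6.5)]
        assert find_activity_cliffs(records) == []

    def test_matches_brute_force_oracle(self):
        """Pair set equals an O(n^2) all-pairs Hamming scan on random
        9-mers with random expression values."""
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        records = [(f"s{i}", "".join(bases[rng.integers(0, 4, 9)]),
                    float(rng.uniform(0, 9))) for i in range(120)]
        got = {(p.id_weak, p.id_strong)
               for p in find_activity_cliffs(records)}
        expected = set()
        for (i1, s1, m1), (i2, s2, m2) in itertools.combinations(records, 2):
            if sum(a != b for a, b in zip(s1, s2)) == 1:
                if m1 < 3.0 and m2 > 6.0:
                    expected.add((i1, i2))
                elif m2 < 3.0 and m1 > 6.0:
                    expected.add((i2, i1))
        assert got == expected


class TestSelectTrainingSubset:
    def test_whole_dataset_any_strategy(self, toy_dataset):
        for strategy in ("random", "uniform_truth"):
            ids = select_training_subset(toy_dataset, len(toy_dataset),
                                         strategy=strategy, seed=0)
            assert set(ids) == set(toy_dataset.ids)

    def test_uniform_truth_one_per_decile(self):
        ds = make_dataset(np.arange(1.0, 101.0))
        ids = select_training_subset(ds, 10, strategy="uniform_truth", seed=0)
        mu_by_id = dict(zip(ds.ids, ds.mu))
        deciles = sorted(int((mu_by_id[i] - 1.0) // 10) for i in ids)
        assert deciles == list(range(10))

    def test_perfect_predictor_equals_truth_strategy(self, toy_dataset):
        class Oracle:
            pass
        # a callable stand-in cannot be used (predictor goes through the
        # model API), so check the contract with values instead: the
        # uniform_predicted path with predictions equal to mu must give
        # the same selection as uniform_truth with the same seed.
        from utrxfer import data as data_mod
        ids_truth = select_training_subset(toy_dataset, 10,
                                           strategy="uniform_truth", seed=3)
        captured = {}

        class FakeModel:
            spec = None

        def fake_predict(model, seqs, ids=None):
            from utrxfer.model import Prediction
            mu = dict(zip(toy_dataset.frame["sequence"], toy_dataset.mu))
            return [Prediction(i, mu[s]) for i, s in zip(ids, seqs)]

        import utrxfer.model
        original = utrxfer.model.predict_mean
        utrxfer.model.predict_mean = fake_predict
        try:
            ids_pred = select_training_subset(
                toy_dataset, 10, strategy="uniform_predicted",
                predictor=FakeModel(), seed=3)
        finally:
            utrxfer.model.predict_mean = original
        assert ids_pred == ids_truth

    def test_missing_predictor_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="predictor"):
            select_training_subset(toy_dataset, 5,
                                   strategy="uniform_predicted", seed=0)

    def test_oversized_request_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            select_training_subset(toy_dataset, 101, seed=0)

    def test_random_reproducible(self, toy_dataset):
        a = select_training_subset(toy_dataset, 20, seed=6)
        b = select_training_subset(toy_dataset, 20, seed=6)
        assert a == b


def test_datasplit_disjointness_enforced():
    with pytest.raises(ValueError, match="disjoint"):
        DataSplit(train_ids=["a", "b"], val_ids=["b"], test_ids=["c"])


def test_datasplit_save_load_roundtrip(tmp_path):
    split = DataSplit(train_ids=["a", "b"], val_ids=["c"], test_ids=["d", "e"])
    split.save(tmp_path / "split")
    assert DataSplit.load(tmp_path / "split") == split
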