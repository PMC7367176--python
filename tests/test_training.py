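import numpy as np
import pytest

from _oracles import brute_auroc
from clipbind.seq_io import NamedSequence
from clipbind.training import (
    TrainConfig,
    cv_auroc,
    evaluate_auroc,
    make_cv_folds,
    rnacompete_classes,
    split_80_10_10,
    train_model,
)
from conftest import random_rna


def labelled(residues_list, label):
    return [
        NamedSequence(f"{'p' if label else 'n'}{i}", r, label=label)
        for i, r in enumerate(residues_list)
    ]


def tiny_dataset(rng, n_per_class=24, length=14):
    """Separable toy data: positives carry a UGUGU core."""
    pos = []
    for i in range(n_per_class):
        r = list(random_rna(rng, length))
        off = int(rng.integers(0, length - 5 + 1))
        r[off : off + 5] = "UGUGU"
        pos.append(NamedSequence(f"p{i}", "".join(r), label=1))
    neg = labelled(
        ["".join(rng.choice(list("AC"), size=length)) for _ in range(n_per_class)], 0
    )
    return pos, neg


def tiny_cfg(**kw):
    defaults = dict(
        max_epochs=5, hidden_size=4, filter_sizes=(3, 4), batch_size=16, seed=1
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSplit:
    def test_100_per_class_gives_80_10_10_per_class(self):
        pos = labelled(["ACGU"] * 100, 1)
        neg = labelled(["UUUU"] * 100, 0)
        tr, va, te = split_80_10_10(pos, neg, seed=0)
        assert (len(tr), len(va), len(te)) == (160, 20, 20)
        for part in (tr, va, te):
            labels = [s.label for s in part]
            assert labels.count(0) == labels.count(1)

    def test_105_per_class_floor_rounding(self):
        pos = labelled(["ACGU"] * 105, 1)
        neg = labelled(["UUUU"] * 105, 0)
        tr, va, te = split_80_10_10(pos, neg, seed=0)
        assert (len(tr), len(va), len(te)) == (170, 20, 20)

    def test_deterministic_and_partitioning(self):
        pos = labelled([random_rna(np.random.default_rng(i), 8) for i in range(30)], 1)
        neg = labelled([random_rna(np.random.default_rng(100 + i), 8) for i in range(30)], 0)
        a = split_80_10_10(pos, neg, seed=5)
        b = split_80_10_10(pos, neg, seed=5)
        assert [[s.id for s in part] for part in a] == [
            [s.id for s in part] for part in b
        ]
        ids = [s.id for part in a for s in part]
        assert sorted(ids) == sorted([s.id for s in pos + neg])

    def test_tiny_class_warns(self):
        pos = labelled(["ACGU"] * 5, 1)
        neg = labelled(["UUUU"] * 20, 0)
        with pytest.warns(UserWarning, match="too small"):
            split_80_10_10(pos, neg, seed=0)


class TestFolds:
    def test_bins_partition_and_roles(self):
        plan = make_cv_folds(20, seed=0)
        assert sorted(len(b) for b in plan.bins) == [2] * 10
        all_test = np.concatenate([plan.fold(k)[2] for k in range(10)])
        assert sorted(all_test) == list(range(20))
        all_val = np.concatenate([plan.fold(k)[1] for k in range(10)])
        assert sorted(all_val) == list(range(20))

    def test_every_index_trains_exactly_eight_times(self):
        plan = make_cv_folds(35, seed=3)
        counts = np.zeros(35, int)
        for k in range(10):
            train, _, _ = plan.fold(k)
            counts[train] += 1
        assert np.all(counts == 8)

    def test_too_few_items_error(self):
        with pytest.raises(ValueError):
            make_cv_folds(9, seed=0)


class TestAuroc:
    def test_perfect_and_tied(self):
        assert evaluate_auroc([0.9, 0.8], [1, 0]) == 1.0
        assert evaluate_auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate_auroc([0.1, 0.9], [1, 1])

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert evaluate_auroc(scores, labels) == pytest.approx(
                brute_auroc(list(scores), list(labels))
            )


class TestTrainModel:
    def test_zero_epochs_returns_initialization(self):
        rng = np.random.default_rng(0)
        pos, neg = tiny_dataset(rng, n_per_class=6)
        cfg = tiny_cfg(max_epochs=0)
        from clipbind.network import ModelParams

        init = ModelParams.initialize(
            cfg.filter_sizes, cfg.hidden_size, np.random.default_rng(cfg.seed)
        )
        bundle, history = train_model(pos[:4] + neg[:4], pos[4:] + neg[4:], cfg)
        assert history == []
        for a, b in zip(
            bundle.params.to_arrays().values(), init.to_arrays().values()
        ):
            np.testing.assert_array_equal(a, b)

    def test_learns_separable_data(self):
        rng = np.random.default_rng(4)
        pos, neg = tiny_dataset(rng, n_per_class=30)
        train = pos[:22] + neg[:22]
        val = pos[22:] + neg[22:]
        cfg = tiny_cfg(max_epochs=12, seed=2)
        bundle, history = train_model(train, val, cfg)
        assert bundle.metadata["best_metric"] > 0.5
        assert history[-1]["epoch"] <= 12
        # loss decreases on average over the first epochs
        losses = [h["train_loss"] for h in history[:5]]
        assert losses[-1] < losses[0]

    def test_patience_halts_when_metric_cannot_improve(self):
        # zero learning rate: parameters never move, so the metric improves
        # only on the first epoch; training must stop patience epochs later
        rng = np.random.default_rng(5)
        pos, neg = tiny_dataset(rng, n_per_class=8)
        cfg = tiny_cfg(max_epochs=10, patience=2, adam_alpha=0.0)
        _, history = train_model(pos[:6] + neg[:6], pos[6:] + neg[6:], cfg)
        assert len(history) == 1 + 2

    def test_single_class_validation_errors(self):
        rng = np.random.default_rng(6)
        pos, neg = tiny_dataset(rng, n_per_class=6)
        with pytest.raises(ValueError):
            train_model(pos[:4] + neg[:4], pos[4:], tiny_cfg())

    def test_output_weight_stays_fixed_after_training(self):
        rng = np.random.default_rng(7)
        pos, neg = tiny_dataset(rng, n_per_class=8)
        bundle, _ = train_model(
            pos[:6] + neg[:6], pos[6:] + neg[6:], tiny_cfg(max_epochs=3)
        )
        assert bundle.params.output_weight == 1.0

    def test_identical_seed_reproduces_history_and_parameters(self):
        rng = np.random.default_rng(8)
        pos, neg = tiny_dataset(rng, n_per_class=10)
        args = (pos[:7] + neg[:7], pos[7:] + neg[7:], tiny_cfg(max_epochs=4, seed=9))
        b1, h1 = train_model(*args)
        b2, h2 = train_model(*args)
        assert h1 == h2
        for a, b in zip(
            b1.params.to_arrays().values(), b2.params.to_arrays().values()
        ):
            np.testing.assert_array_equal(a, b)


class TestCV:
    def test_pooled_predictions_cover_every_input_once(self):
        rng = np.random.default_rng(9)
        pos, neg = tiny_dataset(rng, n_per_class=10, length=10)
        cfg = tiny_cfg(max_epochs=1, batch_size=8)
        auroc, bundles = cv_auroc(pos, neg, cfg)
        assert len(bundles) == 10
        assert 0.0 <= auroc <= 1.0
        # each fold's test bin is disjoint and together they cover everything
        plan = make_cv_folds(10, cfg.seed)
        covered = np.concatenate([plan.fold(k)[2] for k in range(10)])
        assert sorted(covered) == list(range(10))

    def test_perfect_scorer_pools_to_auroc_one(self, monkeypatch):
        # scores equal to the true labels by construction: the pooled
        # AUROC must be exactly 1 regardless of fold structure
        rng = np.random.default_rng(10)
        pos, neg = tiny_dataset(rng, n_per_class=12, length=10)

        def label_oracle(seqs, params, max_length, chunk=256):
            return np.array([0.9 if s.label == 1 else 0.1 for s in seqs])

        monkeypatch.setattr("clipbind.training.batch_predict", label_oracle)
        cfg = tiny_cfg(max_epochs=1, batch_size=8, seed=3)
        auroc, _ = cv_auroc(pos, neg, cfg)
        assert auroc == 1.0


class TestRnacompete:
    def test_top_and_bottom(self):
        vals = {f"k{i}": float(i) for i in range(1, 11)}
        pos, neg = rnacompete_classes(vals, n=2)
        assert pos == ["k10", "k9"]
        assert set(neg) == {"k1", "k2"}

    def test_full_partition_and_disjointness(self):
        rng = np.random.default_rng(11)
        vals = {f"k{i}": float(v) for i, v in enumerate(rng.random(2000))}
        pos, neg = rnacompete_classes(vals, n=1000)
        assert len(pos) == len(neg) == 1000
        assert not (set(pos) & set(neg))
        assert set(pos) | set(neg) == set(vals)
        assert min(vals[k] for k in pos) >= max(vals[k] for k in neg)

    def test_too_few_items_error(self):
        with pytest.raises(ValueError):
            rnacompete_classes({"a": 1.0, "b": 2.0}, n=1000)
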