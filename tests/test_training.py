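import math

import numpy as np
import pytest

from grmine.classifier import HeadConfig, score_batch
from grmine.embeddings import EmbeddingBackend
from grmine.evaluation import roc_auc
from grmine.io_formats import ProteinRecord
from grmine.synthetic import SyntheticConfig, gen_protein_families
from grmine.training import (
    DatasetSplit,
    TrainConfig,
    clip_gradients,
    lr_at,
    make_split,
    subsample_negatives,
    train,
    weighted_loss,
)


def _label_of(records):
    return {r.protein_id: r.label for r in records}


@pytest.fixture(scope="module")
def corpus():
    cfg = SyntheticConfig(n_gr_types=10, seqs_per_type=30)
    records, _ = gen_protein_families(cfg)
    return records


class TestMakeSplit:

    def test_holdout_never_in_training(self, corpus):
        split = make_split(corpus, {"T08", "T09"}, seed=1)
        labels = _label_of(corpus)
        assert not any(labels[i] in ("gr:T08", "gr:T09") for i in split.train_ids)

    def test_holdout_even_val_test_split(self, corpus):
        split = make_split(corpus, {"T08"}, seed=1)
        labels = _label_of(corpus)
        in_val = sum(labels[i] == "gr:T08" for i in split.val_ids)
        in_test = sum(labels[i] == "gr:T08" for i in split.test_ids)
        assert in_val == in_test == 15

    def test_odd_holdout_count_extra_to_validation(self):
        records = [
            ProteinRecord(f"p{i}", "ACDEF", label="gr:odd") for i in range(11)
        ] + [ProteinRecord(f"n{i}", "ACDEF", label="tf") for i in range(10)]
        split = make_split(records, {"odd"}, seed=0)
        labels = _label_of(records)
        assert sum(labels[i] == "gr:odd" for i in split.val_ids) == 6
        assert sum(labels[i] == "gr:odd" for i in split.test_ids) == 5

    def test_known_type_80_10_10(self, corpus):
        split = make_split(corpus, set(), seed=2)
        labels = _label_of(corpus)
        for t in range(10):
            lab = f"gr:T{t:02d}"
            n_train = sum(labels[i] == lab for i in split.train_ids)
            total = sum(1 for r in corpus if r.label == lab)
            assert abs(n_train / total - 0.8) <= 1 / total

    def test_negatives_stratified_8_1_1(self, corpus):
        split = make_split(corpus, set(), seed=2)
        labels = _label_of(corpus)
        for cat in ("tf", "other:random"):
            total = sum(1 for r in corpus if r.label == cat)
            n_val = sum(labels[i] == cat for i in split.val_ids)
            n_test = sum(labels[i] == cat for i in split.test_ids)
            assert abs(n_val - 0.1 * total) <= 1
            assert abs(n_test - 0.1 * total) <= 1

    def test_deterministic_and_partition(self, corpus):
        s1 = make_split(corpus, {"T09"}, seed=3)
        s2 = make_split(corpus, {"T09"}, seed=3)
        assert (s1.train_ids, s1.val_ids, s1.test_ids) == (s2.train_ids, s2.val_ids, s2.test_ids)
        all_ids = s1.train_ids | s1.val_ids | s1.test_ids
        assert len(all_ids) == len(corpus)

    def test_small_holdout_type_rejected(self):
        records = [
            ProteinRecord(f"p{i}", "ACDEF", label="gr:tiny") for i in range(9)
        ]
        with pytest.raises(ValueError, match="< 10"):
            make_split(records, {"tiny"}, seed=0)

    def test_unknown_label_rejected(self):
        records = [ProteinRecord("p", "ACD", label="unknown")]
        with pytest.raises(ValueError, match="unknown label"):
            make_split(records, set(), seed=0)


class TestSchedule:
    def test_warmup_ramp(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == 0.0
        assert lr_at(1000, cfg) == pytest.approx(1e-6)
        assert lr_at(500, cfg) == pytest.approx(5e-7)
        assert lr_at(10_000, cfg) == pytest.approx(1e-6)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())


class TestWeightedLoss:
    def test_uninformative_scores_give_ln2(self):
        n = 6
        loss = weighted_loss(np.full(n, 0.5), np.array([0, 1] * 3), np.ones(n))
        assert loss == pytest.approx(math.log(2))

    def test_tf_weight_equals_duplication(self):
        s, y = 0.3, 0
        weighted = weighted_loss(
            np.array([0.9, s]), np.array([1, y]), np.array([1.0, 5.0])
        )
        duplicated = weighted_loss(
            np.array([0.9] + [s] * 5),
            np.array([1] + [y] * 5),
            np.ones(6),
        )
        assert weighted == pytest.approx(duplicated)

    def test_hand_case(self):
        # y=(1,0), s=(0.9,0.2), w=(1,5) -> (-ln 0.9 - 5 ln 0.8) / 6
        loss = weighted_loss(
            np.array([0.9, 0.2]), np.array([1, 0]), np.array([1.0, 5.0])
        )
        assert loss == pytest.approx((-math.log(0.9) - 5 * math.log(0.8)) / 6)

    def test_extreme_scores_clamped_not_error(self):
        loss = weighted_loss(np.array([1.0, 0.0]), np.array([0, 1]), np.ones(2))
        assert np.isfinite(loss) and loss > 10

    def test_raising_tf_weight_increases_misclassified_tf_loss(self):
        scores = np.array([0.9, 0.8])   # second item: TF negative, misclassified
        labels = np.array([1, 0])
        losses = [
            weighted_loss(scores, labels, np.array([1.0, w])) for w in (1, 2, 5, 10)
        ]
        assert all(a < b for a, b in zip(losses, losses[1:]))


class TestSubsample:
    def test_deterministic(self):
        pool = [f"n{i}" for i in range(1000)]
        assert subsample_negatives(pool, 100, epoch=1, seed=1) == subsample_negatives(
            pool, 100, epoch=1, seed=1
        )

    def test_epochs_draw_different_subsets(self):
        pool = [f"n{i}" for i in range(1000)]
        for seed in range(10):
            a = set(subsample_negatives(pool, 100, epoch=1, seed=seed))
            b = set(subsample_negatives(pool, 100, epoch=2, seed=seed))
            assert a != b

    def test_full_pool(self):
        pool = [f"n{i}" for i in range(20)]
        assert sorted(subsample_negatives(pool, 20, epoch=3, seed=0)) == sorted(pool)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError):
            subsample_negatives(["a"], 2, epoch=0, seed=0)


class TestClip:
    def test_within_norm_unchanged(self):
        g = {"w": np.array([3.0, 4.0])}  # norm 5
        assert np.array_equal(clip_gradients(g, 100.0)["w"], g["w"])

    def test_scaled_to_max_norm(self):
        g = {"w": np.array([120.0, 160.0])}  # norm 200
        clipped = clip_gradients(g, 100.0)
        norm = np.linalg.norm(clipped["w"])
        assert norm == pytest.approx(100.0)

    def test_zero_gradients_unchanged(self):
        g = {"w": np.zeros(3)}
        assert np.array_equal(clip_gradients(g, 100.0)["w"], np.zeros(3))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            clip_gradients({"w": np.array([np.nan])}, 100.0)


def _toy_backend(dim=16):
    """Separable toy embeddings: 'K'-rows point one way, 'D'-rows the other."""
    rng = np.random.default_rng(0)
    noise = {ch: rng.standard_normal(dim) * 0.1 for ch in "ACDEFGHIKLMNPQRSTVWYX^"}

    def embed_fn(seq):
        rows = []
        for ch in seq:
            base = 1.0 if ch == "K" else (-1.0 if ch == "D" else 0.0)
            rows.append(np.full(dim, base) + noise[ch])
        return np.array(rows)

    return EmbeddingBackend("toy", dim, embed_fn)


@pytest.fixture(scope="module")
def toy_task():
    rng = np.random.default_rng(5)
    records = []
    for i in range(20):
        seq = "".join(rng.choice(list("KKKACEF"), size=12))
        records.append(ProteinRecord(f"pos{i}", seq, label="gr:X"))
    for i in range(20):
        seq = "".join(rng.choice(list("DDDACEF"), size=12))
        records.append(ProteinRecord(f"neg{i}", seq, label="other:r"))
    return records, _toy_backend()


class TestTrainLoop:

    def test_linearly_separable_task_reaches_perfect_auc(self, toy_task):
        records, backend = toy_task
        split = make_split(records, set(), seed=0)
        head = HeadConfig(
            input_dim=16, model_dim=16, n_layers=1, n_heads=2, head_dim=8,
            ffn_dim=16, dropout=0.0, max_len=32,
        )
        cfg = TrainConfig(lr=3e-3, warmup_batches=5, batch_size=8, epochs=20, seed=0)
        params, history = train(records, backend, cfg, split, head)
        by_id = {r.protein_id: r for r in records}
        test = [by_id[i] for i in sorted(split.test_ids)]
        scores = dict(score_batch(params, backend, test))
        y = np.array([1 if by_id[i].is_gr else 0 for i in sorted(split.test_ids)])
        s = np.array([scores[i] for i in sorted(split.test_ids)])
        assert roc_auc(s, y) == 1.0
        # loss decreases on average over training
        losses = [h["train_loss"] for h in history]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_zero_epochs_returns_init(self, toy_task):
        records, backend = toy_task
        split = make_split(records, set(), seed=0)
        head = HeadConfig(
            input_dim=16, model_dim=16, n_layers=1, n_heads=2, head_dim=8,
            ffn_dim=16, dropout=0.0, max_len=32,
        )
        params, history = train(
            records, backend, TrainConfig(epochs=0), split, head
        )
        assert history == []
        assert params.fingerprint() is not None

    def test_backend_frozen_through_training(self, toy_task):
        records, backend = toy_task
        before = backend.embed(records[0].sequence).copy()
        split = make_split(records, set(), seed=0)
        head = HeadConfig(
            input_dim=16, model_dim=16, n_layers=1, n_heads=2, head_dim=8,
            ffn_dim=16, dropout=0.0, max_len=32,
        )
        train(records, backend, TrainConfig(lr=1e-3, warmup_batches=2, epochs=2, batch_size=8), split, head)
        assert np.array_equal(backend.embed(records[0].sequence), before)

    def test_held_out_leak_rejected(self, toy_task):
        records, backend = toy_task
        split = make_split(records, set(), seed=0)
        leaky = DatasetSplit(
            train_ids=split.train_ids, val_ids=split.val_ids,
            test_ids=split.test_ids, held_out_types=frozenset({"X"}),
        )
        head = HeadConfig(
            input_dim=16, model_dim=16, n_layers=1, n_heads=2, head_dim=8,
            ffn_dim=16, dropout=0.0, max_len=32,
        )
        with pytest.raises(ValueError, match="leak"):
            train(records, backend, TrainConfig(epochs=1), leaky, head)
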