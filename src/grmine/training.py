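"""Dataset splitting and the GR-head training protocol.

Key features of the protocol: whole GR types can be held out of training
to measure generalisation to unseen regulator families (held-out types are
split 50/50 between validation and test); known types are split 80/10/10
per type and negatives 8:1:1 within each negative category; negatives are
re-subsampled every epoch so the head sees a rotating sample of the (much
larger) negative pool; non-GR transcription factors act as hard negatives
with a five-fold sample weight in the training loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classifier import HeadConfig, HeadParams, forward_batch, init_head, loss_and_grads
from .embeddings import EmbeddingBackend
from .evaluation import roc_auc
from .io_formats import ProteinRecord

_SCORE_EPS = 1e-7


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test protein-id sets with held-out GR types."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]
    held_out_types: frozenset[str]

    def __post_init__(self) -> None:
        if self.train_ids & self.val_ids or self.train_ids & self.test_ids or self.val_ids & self.test_ids:
            raise ValueError("train/val/test id sets must be disjoint")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are the reference protocol for corpus-scale training
    (learning rate 1e-6 with a 1,000-batch linear warm-up, gradient norm
    clip 100, decoupled weight decay 0.1, five-fold TF hard-negative
    weight). Desk-scale runs pass an explicit config with a larger
    learning rate and a short warm-up.
    """

    lr: float = 1e-6
    warmup_batches: int = 1000
    clip_norm: float = 100.0
    weight_decay: float = 0.1
    tf_weight: float = 5.0
    neg_per_pos: float = 1.0
    batch_size: int = 32
    epochs: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.clip_norm, self.neg_per_pos) <= 0:
            raise ValueError("lr, clip_norm and neg_per_pos must be positive")
        if self.weight_decay < 0 or self.warmup_batches < 0:
            raise ValueError("weight_decay and warmup_batches must be >= 0")
        if self.tf_weight < 1:
            raise ValueError("tf_weight must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def _negative_category(label: str) -> str | None:
    if label == "tf":
        return "tf"
    if label.startswith("other:"):
        return label
    return None


def _split_three_way(ids: list[str], rng: np.random.Generator) -> tuple[list[str], list[str], list[str]]:
    """Shuffle and split 8:1:1; rounding keeps val/test within one of 10%."""
    ids = list(ids)
    rng.shuffle(ids)
    n = len(ids)
    n_val = round(n * 0.1)
    n_test = round(n * 0.1)
    return ids[n_val + n_test :], ids[:n_val], ids[n_val : n_val + n_test]


def make_split(
    records: Sequence[ProteinRecord],
    holdout_types: Iterable[str],
    seed: int = 0,
) -> DatasetSplit:
    """Type-aware train/val/test partition.

    Held-out GR types (each needing >= 10 sequences) go 50/50 to
    validation and test, never to training; an odd count sends the extra
    sequence to validation. Remaining GR types split 80/10/10 per type;
    negatives split 8:1:1 stratified within each negative category.
    Deterministic for a fixed seed.
    """
    holdout = set(holdout_types)
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for rec in records:
        if rec.is_gr:
            key = f"gr:{rec.gr_type}"
        else:
            cat = _negative_category(rec.label)
            if cat is None:
                raise ValueError(
                    f"protein {rec.protein_id}: unknown label {rec.label!r}"
                )
            key = f"neg:{cat}"
        by_group.setdefault(key, []).append(rec.protein_id)

    present_types = {k[3:] for k in by_group if k.startswith("gr:")}
    missing = holdout - present_types
    if missing:
        raise ValueError(f"held-out GR types absent from records: {sorted(missing)}")

    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for key in sorted(by_group):
        ids = sorted(by_group[key])
        if key.startswith("gr:") and key[3:] in holdout:
            if len(ids) < 10:
                raise ValueError(
                    f"held-out type {key[3:]!r} has {len(ids)} sequences (< 10)"
                )
            rng.shuffle(ids)
            half = (len(ids) + 1) // 2  # odd count: extra sequence to validation
            val += ids[:half]
            test += ids[half:]
        else:
            tr, va, te = _split_three_way(ids, rng)
            train += tr
            val += va
            test += te
    return DatasetSplit(
        train_ids=frozenset(train),
        val_ids=frozenset(val),
        test_ids=frozenset(test),
        held_out_types=frozenset(holdout),
    )


def lr_at(step: int, config: TrainConfig) -> float:
    """Linear warm-up: 0 at step 0, ``lr`` at ``warmup_batches``, flat after."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if config.warmup_batches == 0 or step >= config.warmup_batches:
        return config.lr
    return config.lr * step / config.warmup_batches


def weighted_loss(
    scores: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> float:
    """Weighted mean binary cross-entropy.

    ``-sum(w_i * (y_i ln s_i + (1 - y_i) ln(1 - s_i))) / sum(w_i)`` with
    scores clamped to [1e-7, 1 - 1e-7].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (scores.shape == labels.shape == weights.shape):
        raise ValueError("scores, labels and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    s = np.clip(scores, _SCORE_EPS, 1.0 - _SCORE_EPS)
    ll = labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)
    return float(-(weights * ll).sum() / weights.sum())


def subsample_negatives(
    pool: Iterable[str], n: int, epoch: int, seed: int = 0
) -> list[str]:
    """Draw ``n`` ids without replacement, deterministic per (seed, epoch)."""
    pool = sorted(pool)
    if n > len(pool):
        raise ValueError(f"cannot draw {n} from a pool of {len(pool)}")
    rng = np.random.default_rng([seed, epoch])
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def clip_gradients(
    grads: Mapping[str, np.ndarray], max_norm: float = 100.0
) -> dict[str, np.ndarray]:
    """Global-L2-norm gradient clipping; a no-op when already within bound."""
    total = 0.0
    for g in grads.values():
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite gradient entries")
        total += float((g * g).sum())
    norm = math.sqrt(total)
    if norm <= max_norm:
        return dict(grads)
    scale = max_norm / norm
    return {k: g * scale for k, g in grads.items()}


def global_grad_norm(grads: Mapping[str, np.ndarray]) -> float:
    return math.sqrt(sum(float((g * g).sum()) for g in grads.values()))


# ---------------------------------------------------------------------------
# training loop


def _sample_weight(rec: ProteinRecord, tf_weight: float) -> float:
    return tf_weight if rec.label == "tf" else 1.0


class _AdamW:
    """Adaptive-gradient optimizer with decoupled weight decay.

    Biases and normalisation parameters are excluded from decay, the
    usual convention.
    """

    def __init__(self, params: HeadParams, weight_decay: float):
        self.m = {k: np.zeros_like(v) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.tensors.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.weight_decay = weight_decay

    @staticmethod
    def _decays(key: str) -> bool:
        return not (key.endswith(".b") or key.endswith(".g") or key == "out.b")

    def step(self, params: HeadParams, grads: Mapping[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / b1c
            v_hat = self.v[key] / b2c
            p = params.tensors[key]
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay and self._decays(key):
                p -= lr * self.weight_decay * p


def _embed_records(
    backend: EmbeddingBackend, records: Sequence[ProteinRecord], max_len: int
) -> dict[str, np.ndarray]:
    return {r.protein_id: backend.embed(r.sequence[:max_len]) for r in records}


def _grouped_loss_grads(
    params: HeadParams,
    mats: list[np.ndarray],
    labels: np.ndarray,
    weights: np.ndarray,
    train_mode: bool,
    rng: np.random.Generator | None,
):
    """Loss + grads for a possibly mixed-length batch (grouped by length)."""
    from .classifier import backward_batch

    by_len: dict[int, list[int]] = {}
    for i, m in enumerate(mats):
        by_len.setdefault(m.shape[0], []).append(i)
    probs = np.zeros(len(mats))
    caches = []
    for length, idxs in sorted(by_len.items()):
        x = np.stack([mats[i] for i in idxs])
        p, cache = forward_batch(params, x, train_mode=train_mode, rng=rng)
        probs[idxs] = p
        caches.append((idxs, cache))
    p_clip = np.clip(probs, _SCORE_EPS, 1.0 - _SCORE_EPS)
    w_sum = weights.sum()
    loss = float(
        -(weights * (labels * np.log(p_clip) + (1 - labels) * np.log(1 - p_clip))).sum()
        / w_sum
    )
    dlogits = weights * (p_clip - labels) / w_sum
    grads: dict[str, np.ndarray] | None = None
    for idxs, cache in caches:
        g = backward_batch(params, cache, dlogits[idxs])
        if grads is None:
            grads = g
        else:
            for k in grads:
                grads[k] += g[k]
    assert grads is not None
    return loss, grads, probs


def _eval_scores(
    params: HeadParams, emb: dict[str, np.ndarray], ids: Sequence[str]
) -> np.ndarray:
    by_len: dict[int, list[int]] = {}
    for i, pid in enumerate(ids):
        by_len.setdefault(emb[pid].shape[0], []).append(i)
    out = np.zeros(len(ids))
    for _length, idxs in sorted(by_len.items()):
        x = np.stack([emb[ids[i]] for i in idxs])
        p, _ = forward_batch(params, x, train_mode=False)
        out[idxs] = p
    return out


def train(
    records: Sequence[ProteinRecord],
    backend: EmbeddingBackend,
    config: TrainConfig,
    split: DatasetSplit,
    head_config: HeadConfig | None = None,
) -> tuple[HeadParams, list[dict]]:
    """Train the GR head on a frozen backend.

    Per epoch the batch pool is rebuilt from every positive training
    sequence plus a fresh negative subsample (``neg_per_pos`` negatives per
    positive, capped at the pool size). Optimisation is AdamW with the
    linear warm-up schedule, global-norm gradient clipping, and the
    TF-weighted cross-entropy. History records per-epoch train/val loss
    and validation AUC; the returned parameters are the best-val-AUC
    checkpoint.
    """
    by_id = {r.protein_id: r for r in records}
    train_recs = [by_id[i] for i in sorted(split.train_ids)]
    val_recs = [by_id[i] for i in sorted(split.val_ids)]
    pos_train = [r for r in train_recs if r.is_gr]
    neg_train = [r for r in train_recs if not r.is_gr]
    if not pos_train:
        raise ValueError("no positive (GR) sequences in the training split")
    if not val_recs:
        raise ValueError("validation set is empty")
    bad_types = {r.gr_type for r in pos_train} & set(split.held_out_types)
    if bad_types:
        raise ValueError(f"held-out types leaked into training: {sorted(bad_types)}")

    if head_config is None:
        head_config = HeadConfig(input_dim=backend.dim)
    if head_config.input_dim != backend.dim:
        raise ValueError("head input_dim must match backend dim")

    params = init_head(head_config, seed=config.seed)
    history: list[dict] = []
    if config.epochs == 0:
        return params, history

    emb = _embed_records(backend, train_recs + val_recs, head_config.max_len)
    val_ids = [r.protein_id for r in val_recs]
    val_labels = np.array([1.0 if r.is_gr else 0.0 for r in val_recs])

    optimizer = _AdamW(params, config.weight_decay)
    rng = np.random.default_rng([config.seed, 797])
    best_auc, best_params = -np.inf, params.copy()
    step = 0
    for epoch in range(1, config.epochs + 1):
        n_neg = min(int(round(config.neg_per_pos * len(pos_train))), len(neg_train))
        neg_ids = subsample_negatives(
            [r.protein_id for r in neg_train], n_neg, epoch, config.seed
        )
        epoch_recs = pos_train + [by_id[i] for i in neg_ids]
        order = rng.permutation(len(epoch_recs))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = [epoch_recs[i] for i in order[lo : lo + config.batch_size]]
            mats = [emb[r.protein_id] for r in batch]
            labels = np.array([1.0 if r.is_gr else 0.0 for r in batch])
            weights = np.array([_sample_weight(r, config.tf_weight) for r in batch])
            loss, grads, _ = _grouped_loss_grads(
                params, mats, labels, weights, train_mode=True, rng=rng
            )
            grads = clip_gradients(grads, config.clip_norm)
            step += 1
            optimizer.step(params, grads, lr_at(step, config))
            losses.append(loss)
        val_scores = _eval_scores(params, emb, val_ids)
        val_loss = weighted_loss(val_scores, val_labels, np.ones_like(val_labels))
        if val_labels.min() == val_labels.max():
            val_auc = float("nan")
        else:
            val_auc = roc_auc(val_scores, val_labels)
        history.append(
            dict(
                epoch=epoch,
                n_pos=len(pos_train),
                n_neg=n_neg,
                train_loss=float(np.mean(losses)),
                val_loss=val_loss,
                val_auc=val_auc,
            )
        )
        if not math.isnan(val_auc) and val_auc > best_auc:
            best_auc, best_params = val_auc, params.copy()
    return best_params, history
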