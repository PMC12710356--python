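"""Shared fixtures: the default synthetic bundle, its scan results, and a
trained desk-scale classifier (session-scoped; training runs once)."""

from __future__ import annotations

import numpy as np
import pytest

from grmine.classifier import HeadConfig, score_batch
from grmine.config import PipelineConfig
from grmine.embeddings import kmer_stub_backend
from grmine.pipeline import scan_bundle
from grmine.synthetic import SyntheticConfig, gen_fixture
from grmine.training import TrainConfig, make_split, train

HOLDOUT_TYPES = ["T06", "T07"]

# desk-scale head + schedule used wherever the full protocol is exercised
DESK_HEAD = dict(model_dim=64, n_layers=2, n_heads=8, head_dim=8, ffn_dim=64, max_len=256)
DESK_TRAIN = dict(lr=1e-3, warmup_batches=20, batch_size=32, seed=0)


@pytest.fixture(scope="session")
def bundle():
    return gen_fixture(SyntheticConfig())


@pytest.fixture(scope="session")
def backend():
    return kmer_stub_backend(k=3, dim=32, seed=0)


@pytest.fixture(scope="session")
def scan_records(bundle):
    """Tier-filtered hits of every motif over every gene window at p<=1e-4."""
    motifs = [bundle.motifs[t] for t in sorted(bundle.motifs)]
    records, qc = scan_bundle(bundle.genomes, bundle.genes, motifs, PipelineConfig())
    return records, qc


@pytest.fixture(scope="session")
def split(bundle):
    return make_split(bundle.proteins, HOLDOUT_TYPES, seed=0)


@pytest.fixture(scope="session")
def trained_model(bundle, backend, split):
    """A 2-layer / dim-64 head trained on the fixture (seen types only)."""
    head = HeadConfig(input_dim=backend.dim, dropout=0.4, **DESK_HEAD)
    config = TrainConfig(epochs=12, **DESK_TRAIN)
    params, history = train(bundle.proteins, backend, config, split, head)
    return params, history


@pytest.fixture(scope="session")
def test_scores(bundle, backend, split, trained_model):
    """Eval-mode scores of the test split, keyed by protein id."""
    params, _ = trained_model
    by_id = {p.protein_id: p for p in bundle.proteins}
    records = [by_id[i] for i in sorted(split.test_ids)]
    return dict(score_batch(params, backend, records)), records
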