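"""End-to-end orchestration: simulate -> train -> predict -> scan ->
regulon -> network -> evaluate, with TSV artifacts at every stage."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classifier, evaluation, motif_scan, regulon, training
from .config import PipelineConfig
from .embeddings import kmer_stub_backend
from .io_formats import (
    GeneRecord,
    MotifModel,
    ProteinRecord,
    TaxonomyLineage,
    write_edges_tsv,
)
from .synthetic import FixtureBundle, SyntheticConfig, gen_fixture

log = logging.getLogger("grmine")


def make_backend(pconf: PipelineConfig):
    if pconf.backend == "stub":
        return kmer_stub_backend(k=pconf.backend_k, dim=pconf.backend_dim, seed=pconf.seed)
    if pconf.backend == "esm2":  # optional plug-in; requires fair-esm at runtime
        from .esm_adapter import esm2_backend

        return esm2_backend()
    raise ValueError(f"unknown backend {pconf.backend!r}")


def head_config_from(pconf: PipelineConfig, input_dim: int) -> classifier.HeadConfig:
    return classifier.HeadConfig(
        input_dim=input_dim,
        model_dim=pconf.model_dim,
        n_layers=pconf.n_layers,
        n_heads=pconf.n_heads,
        head_dim=pconf.head_dim,
        ffn_dim=pconf.ffn_dim,
        dropout=pconf.dropout,
        max_len=pconf.max_len,
    )


def train_config_from(pconf: PipelineConfig) -> training.TrainConfig:
    return training.TrainConfig(
        lr=pconf.lr,
        warmup_batches=pconf.warmup_batches,
        clip_norm=pconf.clip_norm,
        weight_decay=pconf.weight_decay,
        tf_weight=pconf.tf_weight,
        neg_per_pos=pconf.neg_per_pos,
        batch_size=pconf.batch_size,
        epochs=pconf.epochs,
        threshold=pconf.threshold,
        seed=pconf.seed,
    )


def scan_bundle(
    genomes: Mapping[str, Mapping[str, str]],
    genes: Sequence[GeneRecord],
    motifs: Sequence[MotifModel],
    pconf: PipelineConfig,
):
    """Scan every genome's gene windows with every motif (tiers applied)."""
    rules = motif_scan.TierRules(
        p_threshold=pconf.p_threshold,
        short_motif_width=pconf.short_motif_width,
        symmetry_threshold=pconf.symmetry_threshold,
    )
    all_records, qc_rows = [], []
    for genome_id in sorted(genomes):
        contigs = genomes[genome_id]
        genome_genes = [g for g in genes if g.genome_id == genome_id]
        records, qc = motif_scan.scan_genes(
            contigs, genome_genes, motifs,
            window=pconf.window, pseudocount=pconf.pseudocount, rules=rules,
        )
        all_records += records
        qc_rows = qc  # identical per genome; keep the last
    return all_records, qc_rows


def hits_table(hit_records) -> pd.DataFrame:
    rows = [
        dict(
            genome_id=gene.genome_id, gene_id=gene.gene_id,
            family_label=gene.family_label, motif_id=hit.motif_id,
            gr_type=gr_type, offset=hit.offset, strand=hit.strand,
            score=hit.score, pvalue=hit.pvalue,
        )
        for hit, gene, gr_type in hit_records
    ]
    return pd.DataFrame(
        rows,
        columns=["genome_id", "gene_id", "family_label", "motif_id", "gr_type",
                 "offset", "strand", "score", "pvalue"],
    )


def run_pipeline(
    out_dir: str | Path,
    pconf: PipelineConfig,
    syn_config: SyntheticConfig | None = None,
    holdout_types: Sequence[str] | None = None,
) -> dict:
    """Run every stage on a synthetic fixture; write artifacts; return summary."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn_config = syn_config or SyntheticConfig(seed=pconf.seed)
    bundle = gen_fixture(syn_config)
    log.info("stage=simulate n_proteins=%d n_genes=%d n_planted=%d",
             len(bundle.proteins), len(bundle.genes), len(bundle.truth.planted_sites))

    # --- train + predict
    backend = make_backend(pconf)
    types = syn_config.gr_types()
    holdout = list(holdout_types) if holdout_types is not None else types[-2:]
    split = training.make_split(bundle.proteins, holdout, seed=pconf.seed)
    head_config = head_config_from(pconf, backend.dim)
    params, history = training.train(
        bundle.proteins, backend, train_config_from(pconf), split, head_config
    )
    for row in history:
        log.info("stage=train epoch=%d n_pos=%d n_neg=%d loss=%.4f val_auc=%.4f",
                 row["epoch"], row["n_pos"], row["n_neg"], row["train_loss"], row["val_auc"])
    classifier.save_checkpoint(out / "model.npz", params, backend.name, backend.dim)

    by_id = {p.protein_id: p for p in bundle.proteins}
    test_recs = [by_id[i] for i in sorted(split.test_ids)]
    scores = dict(classifier.score_batch(params, backend, test_recs))
    pd.DataFrame(
        [
            dict(protein_id=pid, score=s, call=int(s >= pconf.threshold))
            for pid, s in scores.items()
        ]
    ).to_csv(out / "predictions.tsv", sep="\t", index=False)

    reports = evaluation.stratified_report(
        scores, {i: bundle.labels[i] for i in scores}, holdout, pconf.threshold
    )
    evaluation.report_table(reports).to_csv(out / "metrics.tsv", sep="\t")
    log.info("stage=evaluate all_auc=%s holdout_auc=%s",
             reports["all-all"].auc, reports["holdout-all"].auc)

    # --- scan + regulon + network
    motifs = [bundle.motifs[t] for t in sorted(bundle.motifs)]
    hit_records, qc_rows = scan_bundle(bundle.genomes, bundle.genes, motifs, pconf)
    hits_table(hit_records).to_csv(out / "hits.tsv", sep="\t", index=False)
    pd.DataFrame(qc_rows).to_csv(out / "motif_qc.tsv", sep="\t", index=False)

    calls = regulon.call_targets(hit_records, bundle.genes)
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(out / "calls.tsv", sep="\t", index=False)
    prevalence = regulon.genus_prevalence(calls, bundle.lineages)
    cores = regulon.core_targets(
        prevalence, pconf.min_frac, pconf.min_genera, pconf.fallback_k
    )
    core_rows = [
        dict(gr_type=ct.gr_type, family_label=e.family_label, tier=e.tier,
             genera=",".join(e.genera), prevalences=",".join(f"{p:.3f}" for p in e.prevalences))
        for ct in cores.values() for e in ct.entries
    ]
    pd.DataFrame(core_rows).to_csv(out / "core_targets.tsv", sep="\t", index=False)

    network = regulon.build_network(calls, bundle.truth.gr_gene_map)
    write_edges_tsv(network, out / "network_edges.tsv")
    stats, hubs = regulon.network_stats(network, top_k=pconf.fallback_k)
    stats.to_csv(out / "network_stats.tsv", sep="\t", index=False)
    log.info("stage=network n_edges=%d hubs=%s", network.number_of_edges(), hubs)

    summary = dict(
        n_proteins=len(bundle.proteins),
        n_genes=len(bundle.genes),
        n_planted_sites=len(bundle.truth.planted_sites),
        n_hits=len(hit_records),
        n_calls=len(calls),
        n_edges=network.number_of_edges(),
        all_auc=reports["all-all"].auc,
        holdout_auc=reports["holdout-all"].auc,
        hubs=hubs,
        elapsed_s=round(time.time() - t0, 2),
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
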