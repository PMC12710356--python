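"""Target-gene calling, hierarchical core regulons, and GR-GR networks.

A surviving motif hit in a gene's promoter window makes that gene a
candidate target of the motif's regulator. Core targets are defined
hierarchically: (i) a gene family called in >= 50% of a genus's genomes is
a genus-level core target; (ii) families passing (i) in two or more genera
are cross-genus core targets; (iii) when no family passes (ii), the top
five families by overall genome prevalence stand in. A directed GR-GR
edge A -> B records every (genome, gene) event where A is predicted to
regulate a gene encoding a type-B regulator; self-loops are legal (many
regulators repress their own gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import GeneRecord, TaxonomyLineage
from .motif_scan import MotifHit

CORE_TIERS = ("genus_core", "cross_genus_core", "top5_fallback")


@dataclass(frozen=True)
class TargetCall:
    """One predicted GR -> gene regulation event."""

    gr_type: str
    genome_id: str
    gene_id: str
    family_label: str
    n_hits: int
    best_pvalue: float

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise ValueError("a TargetCall needs at least one hit")


@dataclass(frozen=True)
class CoreEntry:
    family_label: str
    tier: str
    genera: tuple[str, ...]
    prevalences: tuple[float, ...]


@dataclass(frozen=True)
class CoreTargets:
    """Hierarchical core-regulon entries for one GR type."""

    gr_type: str
    entries: tuple[CoreEntry, ...]

    def families(self, tier: str | None = None) -> list[str]:
        return [
            e.family_label for e in self.entries if tier is None or e.tier == tier
        ]


def call_targets(
    hit_records: Sequence[tuple[MotifHit, GeneRecord, str]],
    genes: Sequence[GeneRecord] | None = None,
) -> list[TargetCall]:
    """Aggregate surviving hits into one call per (GR type, genome, gene)."""
    known = {g.gene_id for g in genes} if genes is not None else None
    acc: dict[tuple[str, str, str], dict] = {}
    for hit, gene, gr_type in hit_records:
        if known is not None and gene.gene_id not in known:
            raise ValueError(f"hit references unknown gene {gene.gene_id!r}")
        key = (gr_type, gene.genome_id, gene.gene_id)
        slot = acc.setdefault(
            key, dict(family=gene.family_label, n=0, best=1.0)
        )
        slot["n"] += 1
        slot["best"] = min(slot["best"], hit.pvalue)
    return [
        TargetCall(
            gr_type=k[0], genome_id=k[1], gene_id=k[2],
            family_label=v["family"], n_hits=v["n"], best_pvalue=v["best"],
        )
        for k, v in sorted(acc.items())
    ]


def calls_from_hits_table(hits: pd.DataFrame) -> list[TargetCall]:
    """Rebuild target calls from an exported hits table (one row per hit)."""
    calls = []
    grouped = hits.groupby(["gr_type", "genome_id", "gene_id"], sort=True)
    for (gr, genome, gene), sub in grouped:
        calls.append(
            TargetCall(
                gr_type=str(gr), genome_id=str(genome), gene_id=str(gene),
                family_label=str(sub["family_label"].iloc[0]),
                n_hits=len(sub), best_pvalue=float(sub["pvalue"].min()),
            )
        )
    return calls


def genus_prevalence(
    calls: Sequence[TargetCall],
    lineages: Mapping[str, TaxonomyLineage],
    genomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-genus fraction of genomes in which each family is called.

    The denominator is the number of genomes of that genus in the analysed
    genome set (``genomes``, defaulting to every genome with a lineage) —
    genomes without calls still count.
    """
    genome_set = set(genomes) if genomes is not None else set(lineages)
    for call in calls:
        if call.genome_id not in lineages:
            raise ValueError(f"genome {call.genome_id!r} missing from lineage table")
    genus_size: dict[str, int] = {}
    for gid in genome_set:
        if gid not in lineages:
            raise ValueError(f"genome {gid!r} missing from lineage table")
        genus = lineages[gid].genus
        genus_size[genus] = genus_size.get(genus, 0) + 1
    called: dict[tuple[str, str, str], set[str]] = {}
    for call in calls:
        genus = lineages[call.genome_id].genus
        called.setdefault((call.gr_type, genus, call.family_label), set()).add(
            call.genome_id
        )
    rows = [
        dict(
            gr_type=gr, genus=genus, family_label=family,
            n_called=len(gids), n_genomes=genus_size[genus],
            fraction=len(gids) / genus_size[genus],
        )
        for (gr, genus, family), gids in sorted(called.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["gr_type", "genus", "family_label", "n_called", "n_genomes", "fraction"],
    )


def core_targets(
    prevalence: pd.DataFrame,
    min_frac: float = 0.5,
    min_genera: int = 2,
    fallback_k: int = 5,
) -> dict[str, CoreTargets]:
    """Hierarchical core-target assignment per GR type.

    Families at fraction >= ``min_frac`` (inclusive) in a genus are
    genus-level core; those qualifying in >= ``min_genera`` genera are
    cross-genus core. Only when a GR has no cross-genus core at all, the
    top ``fallback_k`` families by overall genome prevalence (ties broken
    lexicographically) are emitted as the fallback tier.
    """
    out: dict[str, CoreTargets] = {}
    if prevalence.empty:
        return out
    for gr_type, sub in prevalence.groupby("gr_type", sort=True):
        entries: list[CoreEntry] = []
        qualifying = sub[sub["fraction"] >= min_frac]
        by_family = {
            fam: fsub.sort_values("genus")
            for fam, fsub in qualifying.groupby("family_label", sort=True)
        }
        has_cross = False
        for fam, fsub in by_family.items():
            tier = "cross_genus_core" if len(fsub) >= min_genera else "genus_core"
            has_cross = has_cross or tier == "cross_genus_core"
            entries.append(
                CoreEntry(
                    family_label=fam,
                    tier=tier,
                    genera=tuple(fsub["genus"]),
                    prevalences=tuple(fsub["fraction"]),
                )
            )
        if not has_cross:
            # overall prevalence: called genomes / all genomes, over every genus
            overall = (
                sub.groupby("family_label")
                .apply(
                    lambda f: f["n_called"].sum() / f["n_genomes"].sum(),
                    include_groups=False,
                )
                .sort_index()
            )
            top = overall.sort_values(ascending=False, kind="stable").head(fallback_k)
            for fam in top.index:
                fsub = sub[sub["family_label"] == fam].sort_values("genus")
                entries.append(
                    CoreEntry(
                        family_label=fam,
                        tier="top5_fallback",
                        genera=tuple(fsub["genus"]),
                        prevalences=tuple(fsub["fraction"]),
                    )
                )
        out[str(gr_type)] = CoreTargets(gr_type=str(gr_type), entries=tuple(entries))
    return out


def putative_gr_support(
    calls: Sequence[TargetCall],
    min_targets: int = 10,
    min_genomes: int = 2,
) -> tuple[bool, dict]:
    """Support rule for a putative regulator from its target calls.

    True iff the candidate has >= ``min_targets`` distinct (genome, gene)
    targets in total and calls span >= ``min_genomes`` distinct genomes.
    """
    targets = {(c.genome_id, c.gene_id) for c in calls}
    per_genome: dict[str, int] = {}
    for genome, _gene in targets:
        per_genome[genome] = per_genome.get(genome, 0) + 1
    supported = len(targets) >= min_targets and len(per_genome) >= min_genomes
    evidence = dict(
        n_targets=len(targets),
        n_genomes=len(per_genome),
        per_genome=dict(sorted(per_genome.items())),
    )
    return supported, evidence


def build_network(
    calls: Sequence[TargetCall],
    gr_gene_map: Mapping[tuple[str, str], str],
    scope: Iterable[str] | None = None,
) -> nx.DiGraph:
    """Directed GR-GR graph from target calls.

    ``gr_gene_map`` maps (genome_id, gene_id) -> GR type encoded by that
    gene. An edge A -> B carries ``support`` = number of (genome, gene)
    call events where A targets a type-B-encoding gene within the scope's
    genomes (scope=None means all). Nodes include every GR type encoded in
    scope even when isolated.
    """
    scope_set = set(scope) if scope is not None else None
    graph = nx.DiGraph()
    for (genome, _gene), gr_type in gr_gene_map.items():
        if scope_set is None or genome in scope_set:
            graph.add_node(gr_type)
    for call in calls:
        if scope_set is not None and call.genome_id not in scope_set:
            continue
        encoded = gr_gene_map.get((call.genome_id, call.gene_id))
        if encoded is None:
            continue
        if graph.has_edge(call.gr_type, encoded):
            graph[call.gr_type][encoded]["support"] += 1
        else:
            graph.add_edge(call.gr_type, encoded, support=1)
    return graph


def network_stats(network: nx.DiGraph, top_k: int = 5) -> tuple[pd.DataFrame, list[str]]:
    """Per-node degree table and top-k hubs by support-weighted total degree.

    Ranking is deterministic: weighted degree descending, then node name.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rows = []
    for node in network.nodes:
        w_in = sum(d["support"] for _, _, d in network.in_edges(node, data=True))
        w_out = sum(d["support"] for _, _, d in network.out_edges(node, data=True))
        rows.append(
            dict(
                node=node,
                in_degree=network.in_degree(node),
                out_degree=network.out_degree(node),
                weighted_in=w_in,
                weighted_out=w_out,
                weighted_degree=w_in + w_out,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["node", "in_degree", "out_degree", "weighted_in", "weighted_out", "weighted_degree"],
    )
    if not table.empty:
        table = table.sort_values(
            ["weighted_degree", "node"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    hubs = list(table["node"].head(top_k)) if not table.empty else []
    return table, hubs


def gr_type_counts(
    presence: Mapping[str, set[str]],
    lineages: Mapping[str, TaxonomyLineage],
    rank: str,
) -> pd.DataFrame:
    """Distinct GR types per taxon at a rank (union over the taxon's genomes)."""
    probe = TaxonomyLineage("probe")
    probe.rank(rank)  # validates the rank name
    union: dict[str, set[str]] = {}
    for genome, types in presence.items():
        if genome not in lineages:
            raise ValueError(f"genome {genome!r} missing from lineage table")
        taxon = lineages[genome].rank(rank)
        union.setdefault(taxon, set()).update(types)
    rows = [
        dict(taxon=taxon, n_gr_types=len(types))
        for taxon, types in sorted(union.items())
    ]
    return pd.DataFrame(rows, columns=["taxon", "n_gr_types"])
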