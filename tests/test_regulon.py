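import numpy as np
import pandas as pd
import pytest

from grmine.io_formats import GeneRecord, TaxonomyLineage
from grmine.motif_scan import MotifHit
from grmine.regulon import (
    TargetCall,
    build_network,
    call_targets,
    core_targets,
    genus_prevalence,
    gr_type_counts,
    network_stats,
    putative_gr_support,
)


def _hit(window_id, pvalue=1e-5, offset=0):
    return MotifHit(window_id, "m", offset, "+", 10.0, pvalue)


def _gene(gene_id, genome="g1", family=""):
    return GeneRecord(gene_id, genome, "ctg", 1000, 1300, "+", family_label=family)


class TestCallTargets:
    def test_hits_aggregated_per_gene(self):
        gene = _gene("geneA", family="famA")
        records = [
            (_hit("g1:geneA", 1e-5, 3), gene, "GRx"),
            (_hit("g1:geneA", 1e-7, 40), gene, "GRx"),
            (_hit("g1:geneA", 1e-6, 80), gene, "GRx"),
        ]
        (call,) = call_targets(records, [gene])
        assert call.n_hits == 3
        assert call.best_pvalue == 1e-7
        assert call.family_label == "famA"

    def test_no_hits_no_calls(self):
        assert call_targets([], []) == []

    def test_two_genes_sharing_region_two_calls(self):
        # two genes whose (untrimmed) windows overlap, one hit supporting each
        left = GeneRecord("gL", "g1", "ctg", 500, 800, "-")
        right = GeneRecord("gR", "g1", "ctg", 1000, 1300, "+")
        records = [
            (_hit("g1:gL", 1e-5, 10), left, "GRx"),
            (_hit("g1:gR", 1e-5, 350), right, "GRx"),
        ]
        calls = call_targets(records, [left, right])
        assert {c.gene_id for c in calls} == {"gL", "gR"}

    def test_unknown_gene_rejected(self):
        gene = _gene("ghost")
        with pytest.raises(ValueError, match="ghost"):
            call_targets([(_hit("g1:ghost"), gene, "GRx")], [_gene("real")])


def _lineages(genus_of):
    """genus_of: {genome: genus}"""
    return {
        g: TaxonomyLineage(g, genus=genus, phylum="Ph") for g, genus in genus_of.items()
    }


def _call(gr, genome, gene, family):
    return TargetCall(gr, genome, gene, family, 1, 1e-5)


class TestGenusPrevalence:
    def test_half_called(self):
        lin = _lineages({f"g{i}": "GenA" for i in range(4)})
        calls = [_call("X", "g0", "a", "famF"), _call("X", "g1", "a", "famF")]
        table = genus_prevalence(calls, lin)
        assert table.iloc[0]["fraction"] == 0.5

    def test_single_genome_genus(self):
        lin = _lineages({"g0": "GenSolo"})
        table = genus_prevalence([_call("X", "g0", "a", "famF")], lin)
        assert table.iloc[0]["fraction"] == 1.0

    def test_hand_tally_two_genera(self):
        lin = _lineages(
            {"a1": "GenA", "a2": "GenA", "a3": "GenA", "b1": "GenB", "b2": "GenB", "b3": "GenB"}
        )
        calls = [
            _call("X", "a1", "g", "famP"), _call("X", "a2", "g", "famP"),
            _call("X", "b1", "g", "famP"),
            _call("X", "b1", "h", "famQ"), _call("X", "b2", "h", "famQ"), _call("X", "b3", "h", "famQ"),
        ]
        table = genus_prevalence(calls, lin).set_index(["genus", "family_label"])
        assert table.loc[("GenA", "famP"), "fraction"] == pytest.approx(2 / 3)
        assert table.loc[("GenB", "famP"), "fraction"] == pytest.approx(1 / 3)
        assert table.loc[("GenB", "famQ"), "fraction"] == 1.0

    def test_missing_lineage_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            genus_prevalence([_call("X", "nope", "a", "f")], _lineages({"g0": "GenA"}))


class TestCoreTargets:
    def _prevalence(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gr_type", "genus", "family_label", "n_called", "n_genomes", "fraction"],
        )

    def test_two_genera_cross_genus_core(self):
        prev = self._prevalence([
            ("X", "GenA", "famF", 3, 5, 0.6),
            ("X", "GenB", "famF", 7, 10, 0.7),
        ])
        cores = core_targets(prev)
        (entry,) = cores["X"].entries
        assert entry.tier == "cross_genus_core"
        assert entry.genera == ("GenA", "GenB")

    def test_boundary_half_inclusive(self):
        prev = self._prevalence([
            ("X", "GenA", "famF", 2, 4, 0.5),
            ("X", "GenB", "famF", 2, 4, 0.5),
        ])
        cores = core_targets(prev)
        assert cores["X"].families("cross_genus_core") == ["famF"]

    def test_fallback_top5_by_overall_prevalence(self):
        rows = [("X", "GenA", f"fam{i}", i, 10, i / 10) for i in range(1, 5)]
        rows += [("X", "GenB", "fam9", 1, 10, 0.1)]
        prev = self._prevalence(rows)  # nothing reaches 0.5 anywhere
        cores = core_targets(prev, fallback_k=3)
        fallback = cores["X"].families("top5_fallback")
        assert fallback == ["fam4", "fam3", "fam2"]

    def test_single_genus_qualifier_stays_genus_core_and_triggers_fallback(self):
        prev = self._prevalence([
            ("X", "GenA", "famF", 3, 5, 0.6),
            ("X", "GenA", "famG", 1, 5, 0.2),
        ])
        cores = core_targets(prev, fallback_k=5)
        assert cores["X"].families("genus_core") == ["famF"]
        assert cores["X"].families("cross_genus_core") == []
        # fallback path emits top families including the genus-level qualifier
        assert "famF" in cores["X"].families("top5_fallback")

    def test_fallback_tie_break_lexicographic(self):
        prev = self._prevalence([
            ("X", "GenA", "famB", 2, 10, 0.2),
            ("X", "GenA", "famA", 2, 10, 0.2),
            ("X", "GenA", "famC", 2, 10, 0.2),
        ])
        cores = core_targets(prev, fallback_k=2)
        assert cores["X"].families("top5_fallback") == ["famA", "famB"]

    def test_empty_prevalence_empty_result(self):
        assert core_targets(self._prevalence([])) == {}

    def test_cross_genus_entries_replay_tier_one(self):
        rng = np.random.default_rng(0)
        rows = []
        for gr in ("X", "Y"):
            for genus in ("GenA", "GenB", "GenC"):
                for fam in range(6):
                    n = int(rng.integers(0, 5))
                    rows.append((gr, genus, f"fam{fam}", n, 4, n / 4))
        prev = self._prevalence(rows)
        cores = core_targets(prev)
        for ct in cores.values():
            for entry in ct.entries:
                if entry.tier == "cross_genus_core":
                    assert len(entry.genera) >= 2
                    assert all(p >= 0.5 for p in entry.prevalences)


class TestPutativeGrSupport:
    @pytest.mark.parametrize(
        "n_targets,n_genomes,expected",
        [(9, 1, False), (9, 2, False), (10, 1, False), (10, 2, True)],
    )
    def test_threshold_truth_table(self, n_targets, n_genomes, expected):
        calls = []
        for i in range(n_targets):
            genome = f"g{i % n_genomes}"
            calls.append(_call("X", genome, f"gene{i}", f"fam{i}"))
        supported, evidence = putative_gr_support(calls)
        assert supported is expected
        assert evidence["n_targets"] == n_targets
        assert evidence["n_genomes"] == n_genomes

    def test_monotone_in_added_calls(self):
        calls = [_call("X", f"g{i % 2}", f"gene{i}", f"f{i}") for i in range(10)]
        assert putative_gr_support(calls)[0]
        more = calls + [_call("X", "g5", "extra", "f")]
        assert putative_gr_support(more)[0]

    def test_duplicate_targets_counted_once(self):
        calls = [_call("X", "g0", "geneA", "f")] * 5 + [_call("X", "g1", "geneB", "f")] * 5
        supported, evidence = putative_gr_support(calls)
        assert evidence["n_targets"] == 2
        assert not supported


class TestBuildNetwork:
    def test_self_loop(self):
        calls = [_call("LexA", "g1", "lexA_gene", "fam_lexA")]
        net = build_network(calls, {("g1", "lexA_gene"): "LexA"})
        assert net.has_edge("LexA", "LexA")
        assert net["LexA"]["LexA"]["support"] == 1

    def test_no_gr_targets_edgeless_with_nodes(self):
        calls = [_call("X", "g1", "plain_gene", "fam")]
        net = build_network(calls, {("g1", "other_gene"): "Y"})
        assert net.number_of_edges() == 0
        assert "Y" in net.nodes

    def test_three_genome_hand_fixture(self):
        gr_map = {}
        calls = []
        for genome in ("g1", "g2", "g3"):
            gr_map[(genome, "geneA")] = "A"
            gr_map[(genome, "geneB")] = "B"
            calls.append(_call("A", genome, "geneB", "famB"))  # A -> B everywhere
        calls.append(_call("B", "g2", "geneA", "famA"))        # B -> A once
        net = build_network(calls, gr_map)
        assert net["A"]["B"]["support"] == 3
        assert net["B"]["A"]["support"] == 1
        assert set(net.edges) == {("A", "B"), ("B", "A")}

    def test_scope_filters_genomes(self):
        gr_map = {("g1", "geneB"): "B", ("g2", "geneB"): "B"}
        calls = [_call("A", "g1", "geneB", "famB"), _call("A", "g2", "geneB", "famB")]
        net = build_network(calls, gr_map, scope={"g1"})
        assert net["A"]["B"]["support"] == 1

    def test_support_conservation(self):
        rng = np.random.default_rng(1)
        gr_map = {(f"g{i}", f"gr_gene{j}"): f"GR{j}" for i in range(3) for j in range(4)}
        calls = []
        for i in range(40):
            genome = f"g{rng.integers(3)}"
            gene = f"gr_gene{rng.integers(6)}"  # some genes are not GR genes
            calls.append(_call(f"GR{rng.integers(4)}", genome, gene, "f"))
        # dedupe: one call per (gr, genome, gene)
        seen = {}
        for c in calls:
            seen[(c.gr_type, c.genome_id, c.gene_id)] = c
        calls = list(seen.values())
        net = build_network(calls, gr_map)
        total_support = sum(d["support"] for _, _, d in net.edges(data=True))
        on_gr_genes = sum(1 for c in calls if (c.genome_id, c.gene_id) in gr_map)
        assert total_support == on_gr_genes


class TestNetworkStats:
    def test_star_center_is_top_hub(self):
        calls = [_call("C", "g1", f"gene{i}", "f") for i in range(5)]
        gr_map = {("g1", f"gene{i}"): f"N{i}" for i in range(5)}
        net = build_network(calls, gr_map)
        _, hubs = network_stats(net, top_k=1)
        assert hubs == ["C"]

    def test_empty_network(self):
        import networkx as nx

        table, hubs = network_stats(nx.DiGraph(), top_k=3)
        assert table.empty and hubs == []

    def test_tie_break_lexicographic(self):
        calls = [_call("A", "g1", "geneB", "f"), _call("B", "g1", "geneA", "f")]
        gr_map = {("g1", "geneA"): "A", ("g1", "geneB"): "B"}
        net = build_network(calls, gr_map)
        table, hubs = network_stats(net, top_k=2)
        assert hubs == ["A", "B"]

    def test_invalid_top_k(self):
        import networkx as nx

        with pytest.raises(ValueError):
            network_stats(nx.DiGraph(), top_k=0)


class TestGrTypeCounts:
    def test_union_within_genus(self):
        lin = _lineages({"A": "Gen1", "B": "Gen1"})
        presence = {"A": {"X", "Y"}, "B": {"Y", "Z"}}
        table = gr_type_counts(presence, lin, "genus")
        assert table.loc[table["taxon"] == "Gen1", "n_gr_types"].item() == 3

    def test_two_phyla_manual_union(self):
        lin = {
            "A": TaxonomyLineage("A", phylum="Ph1"),
            "B": TaxonomyLineage("B", phylum="Ph1"),
            "C": TaxonomyLineage("C", phylum="Ph2"),
        }
        presence = {"A": {"X"}, "B": {"X", "Y"}, "C": {"Z"}}
        table = gr_type_counts(presence, lin, "phylum").set_index("taxon")
        assert table.loc["Ph1", "n_gr_types"] == 2
        assert table.loc["Ph2", "n_gr_types"] == 1

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            gr_type_counts({}, {}, "kingdom")
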