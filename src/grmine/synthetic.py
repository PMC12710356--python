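"""Synthetic fixture generator with known ground truth.

Emulates the statistical structure of a real GR discovery study at desk
scale: GR protein families share a learnable common core (with
type-specific conserved blocks), non-GR transcription factors act as hard
negatives carrying a degraded copy of the core, random proteins act as
easy negatives, and small genomes carry motif instances planted at known
positions inside promoter windows of designated target-gene families.
Every generated object is recorded in a truth registry so each pipeline
stage can be scored against what was planted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import (
    DNA,
    GeneRecord,
    MotifModel,
    ProteinRecord,
    TaxonomyLineage,
    write_fasta,
    write_gff_genes,
    write_labels,
    write_lineages,
    write_meme_motifs,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generated fixture.

    Defaults give 8 GR types x 30 sequences against 60 TF hard negatives
    and 180 random negatives, and 3 genomes x 200 genes with every
    designated binding site planted (plant_prob 1) as the motif consensus.
    """

    n_gr_types: int = 8
    seqs_per_type: int = 30
    n_tf_neg: int = 60
    n_random_neg: int = 180
    protein_len: int = 120
    gr_core_len: int = 40
    type_block_len: int = 20
    core_mutation_rate: float = 0.05
    tf_core_degradation: float = 0.5
    motif_width_min: int = 10
    motif_width_max: int = 14
    motif_concentration: float = 0.1
    n_genomes: int = 3
    genes_per_genome: int = 200
    gene_len: int = 300
    targets_per_type: int = 6
    plant_prob: float = 1.0
    plant_mode: str = "consensus"   # or "sample"
    window: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_gr_types, self.seqs_per_type, self.n_genomes, self.genes_per_genome) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_tf_neg < 0 or self.n_random_neg < 0:
            raise ValueError("negative counts must be >= 0")
        if self.gr_core_len + self.type_block_len >= self.protein_len:
            raise ValueError("gr_core_len + type_block_len must be < protein_len")
        for frac in (self.core_mutation_rate, self.tf_core_degradation, self.plant_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.motif_width_min < 4 or self.motif_width_max < self.motif_width_min:
            raise ValueError("invalid motif width range")
        if self.plant_mode not in ("consensus", "sample"):
            raise ValueError("plant_mode must be 'consensus' or 'sample'")
        if self.genes_per_genome < self.n_gr_types:
            raise ValueError("need at least one gene per GR type")

    def gr_types(self) -> list[str]:
        return [f"T{i:02d}" for i in range(self.n_gr_types)]


@dataclass
class PlantedSite:
    genome_id: str
    gene_id: str
    motif_id: str
    gr_type: str
    offset: int       # 0-based within the strand-corrected upstream window
    strand: str
    instance: str


@dataclass
class SyntheticTruth:
    """Ground truth for everything the generator emitted."""

    labels: dict[str, str]
    planted_sites: list[PlantedSite]
    true_regulons: dict[str, dict[str, list[str]]]   # gr_type -> genome -> gene ids
    cross_edges: dict[tuple[str, str], int]          # (src GR, dst GR) -> support
    gr_gene_map: dict[tuple[str, str], str]          # (genome, gene) -> encoded GR


@dataclass(frozen=True)
class RegulonDesign:
    """Which gene families each GR type regulates, incl. GR-encoding genes."""

    targets: dict[str, tuple[str, ...]]              # gr_type -> family labels
    gr_gene_family: dict[str, str]                   # gr_type -> its gene's family

    def designed_edges(self) -> set[tuple[str, str]]:
        fam_to_gr = {fam: gr for gr, fam in self.gr_gene_family.items()}
        return {
            (src, fam_to_gr[fam])
            for src, fams in self.targets.items()
            for fam in fams
            if fam in fam_to_gr
        }


def gen_motif(width: int, concentration: float, seed: int, motif_id: str = "motif", gr_type: str = "NA") -> MotifModel:
    """Random PWM with Dirichlet(concentration) columns, deterministic per seed.

    Low concentration gives information-rich (near-degenerate) columns.
    """
    if width < 4:
        raise ValueError("motif width must be >= 4")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(4, concentration), size=width).T
    return MotifModel(motif_id=motif_id, gr_type=gr_type, prob_matrix=cols)


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    n_mut = int(round(rate * len(chars)))
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        chars[pos] = _AA[rng.integers(len(_AA))]
    return "".join(chars)


def _place_blocks(rng: np.random.Generator, blocks: list[str], total_len: int) -> str:
    """Blocks in order with random filler gaps, padded to total_len."""
    filler = total_len - sum(len(b) for b in blocks)
    cuts = np.sort(rng.integers(0, filler + 1, size=len(blocks)))
    out, prev = [], 0
    for cut, block in zip(cuts, blocks):
        out.append(_random_aa(rng, cut - prev))
        out.append(block)
        prev = cut
    out.append(_random_aa(rng, filler - prev))
    return "".join(out)


def gen_protein_families(config: SyntheticConfig) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Labeled protein corpus: GR families, TF hard negatives, random negatives.

    Every GR sequence carries the shared core (point-mutated at
    ``core_mutation_rate``) plus its type's conserved block; TF negatives
    carry the core with ``tf_core_degradation`` of its positions
    randomised; random negatives are uniform filler.
    """
    rng = np.random.default_rng([config.seed, 11])
    core = _random_aa(rng, config.gr_core_len)
    type_blocks = {
        t: _random_aa(rng, config.type_block_len) for t in config.gr_types()
    }
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}

    for t in config.gr_types():
        for i in range(config.seqs_per_type):
            seq = _place_blocks(
                rng,
                [_mutate(rng, core, config.core_mutation_rate), type_blocks[t]],
                config.protein_len,
            )
            pid = f"GR_{t}_{i:03d}"
            records.append(ProteinRecord(pid, seq, label=f"gr:{t}"))
            labels[pid] = f"gr:{t}"
    for i in range(config.n_tf_neg):
        degraded = _mutate(rng, core, config.tf_core_degradation)
        seq = _place_blocks(rng, [degraded], config.protein_len)
        pid = f"TF_{i:03d}"
        records.append(ProteinRecord(pid, seq, label="tf"))
        labels[pid] = "tf"
    for i in range(config.n_random_neg):
        pid = f"RAND_{i:03d}"
        records.append(ProteinRecord(pid, _random_aa(rng, config.protein_len), label="other:random"))
        labels[pid] = "other:random"
    return records, labels


def gen_motif_set(config: SyntheticConfig) -> dict[str, MotifModel]:
    """One motif per GR type; widths cycle through the configured range."""
    motifs: dict[str, MotifModel] = {}
    span = config.motif_width_max - config.motif_width_min + 1
    for i, t in enumerate(config.gr_types()):
        width = config.motif_width_min + (i % span)
        motifs[t] = gen_motif(
            width,
            config.motif_concentration,
            seed=int(np.random.default_rng([config.seed, 23, i]).integers(2**31)),
            motif_id=f"{t}__bs",
            gr_type=t,
        )
    return motifs


def default_regulon_design(config: SyntheticConfig) -> RegulonDesign:
    """Deterministic regulon design: disjoint target-family sets per GR,
    ring-shaped cross-regulation (each type targets the gene of the next),
    and a self-loop on the first type."""
    types = config.gr_types()
    gr_gene_family = {t: f"fam_gr_{t}" for t in types}
    n_plain = config.targets_per_type - 1  # one slot goes to a GR gene
    targets: dict[str, tuple[str, ...]] = {}
    for i, t in enumerate(types):
        fams = [f"fam_{i * n_plain + j:03d}" for j in range(n_plain)]
        fams.append(gr_gene_family[types[(i + 1) % len(types)]])
        if i == 0:
            fams.append(gr_gene_family[t])  # self-regulation
        targets[t] = tuple(fams)
    return RegulonDesign(targets=targets, gr_gene_family=gr_gene_family)


_GENERA = ["Alphagenus", "Betagenus", "Gammagenus", "Deltagenus"]
_PHYLA = {"Alphagenus": "PhylumA", "Betagenus": "PhylumA",
          "Gammagenus": "PhylumB", "Deltagenus": "PhylumB"}


def _lineage_for(genome_id: str, index: int) -> TaxonomyLineage:
    genus = _GENERA[index % len(_GENERA)]
    phylum = _PHYLA[genus]
    return TaxonomyLineage(
        genome_id=genome_id,
        genus=genus,
        family=f"{genus}aceae",
        order=f"{phylum}ales",
        class_rank=f"{phylum}ia",
        phylum=phylum,
        domain="Bacteria",
    )


def gen_genomes(
    config: SyntheticConfig,
    motifs: Mapping[str, MotifModel],
    design: RegulonDesign,
) -> tuple[dict[str, dict[str, str]], list[GeneRecord], dict[str, TaxonomyLineage], SyntheticTruth]:
    """Genomes with planted binding sites and full truth registry.

    Genes are laid out non-overlapping with 2x-window gaps so upstream
    windows never overlap; the first ``n_gr_types`` genes of each genome
    encode the GR proteins themselves. For each designed (GR, target
    family) pair a motif instance is planted at a uniform offset of the
    target's strand-corrected upstream window with probability
    ``plant_prob``.
    """
    rng = np.random.default_rng([config.seed, 47])
    window, gene_len = config.window, config.gene_len
    pitch = gene_len + 2 * window + 10
    types = config.gr_types()

    genomes: dict[str, dict[str, str]] = {}
    genes: list[GeneRecord] = []
    lineages: dict[str, TaxonomyLineage] = {}
    truth = SyntheticTruth(
        labels={}, planted_sites=[], true_regulons={t: {} for t in types},
        cross_edges={}, gr_gene_map={},
    )
    fam_to_gr = {fam: gr for gr, fam in design.gr_gene_family.items()}

    for g_idx in range(config.n_genomes):
        genome_id = f"genome_{g_idx:02d}"
        contig_id = f"ctg_{genome_id}"
        lineages[genome_id] = _lineage_for(genome_id, g_idx)
        contig_len = window + config.genes_per_genome * pitch
        contig = rng.choice(list(DNA), size=contig_len)

        genome_genes: list[GeneRecord] = []
        fam_of_gene: dict[str, str] = {}
        for j in range(config.genes_per_genome):
            start = window + j * pitch + window
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{genome_id}_g{j:04d}"
            if j < config.n_gr_types:
                family = design.gr_gene_family[types[j]]
                truth.gr_gene_map[(genome_id, gene_id)] = types[j]
            else:
                family = f"fam_{j - config.n_gr_types:03d}"
            rec = GeneRecord(
                gene_id=gene_id, genome_id=genome_id, contig_id=contig_id,
                start=start, end=end, strand=strand, family_label=family,
            )
            genome_genes.append(rec)
            fam_of_gene[gene_id] = family

        by_family: dict[str, list[GeneRecord]] = {}
        for rec in genome_genes:
            by_family.setdefault(rec.family_label, []).append(rec)

        occupied: dict[str, list[tuple[int, int]]] = {}
        for t in types:
            motif = motifs[t]
            width = motif.width
            for fam in design.targets[t]:
                for rec in by_family.get(fam, []):
                    if rng.random() >= config.plant_prob:
                        continue
                    if config.plant_mode == "consensus":
                        instance = motif.consensus
                    else:
                        instance = "".join(
                            DNA[rng.choice(4, p=motif.prob_matrix[:, j])]
                            for j in range(width)
                        )
                    taken = occupied.setdefault(rec.gene_id, [])
                    offset = None
                    for _attempt in range(20):
                        cand = int(rng.integers(0, window - width + 1))
                        if all(cand + width <= lo or cand >= hi for lo, hi in taken):
                            offset = cand
                            break
                    if offset is None:
                        continue
                    taken.append((offset, offset + width))
                    # map window offset to genomic coordinates
                    if rec.strand == "+":
                        gpos = rec.start - window + offset
                        contig[gpos : gpos + width] = list(instance)
                    else:
                        gpos = rec.end + window - offset - width
                        rc = instance.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                        contig[gpos : gpos + width] = list(rc)
                    truth.planted_sites.append(
                        PlantedSite(
                            genome_id=genome_id, gene_id=rec.gene_id,
                            motif_id=motif.motif_id, gr_type=t,
                            offset=offset, strand="+", instance=instance,
                        )
                    )
                    truth.true_regulons[t].setdefault(genome_id, []).append(rec.gene_id)
                    if fam in fam_to_gr:
                        edge = (t, fam_to_gr[fam])
                        truth.cross_edges[edge] = truth.cross_edges.get(edge, 0) + 1

        genomes[genome_id] = {contig_id: "".join(contig)}
        genes += genome_genes
    return genomes, genes, lineages, truth


@dataclass
class FixtureBundle:
    """In-memory fixture: everything the pipeline stages consume."""

    config: SyntheticConfig
    proteins: list[ProteinRecord]
    labels: dict[str, str]
    motifs: dict[str, MotifModel]
    design: RegulonDesign
    genomes: dict[str, dict[str, str]]
    genes: list[GeneRecord]
    lineages: dict[str, TaxonomyLineage]
    truth: SyntheticTruth


def gen_fixture(config: SyntheticConfig | None = None) -> FixtureBundle:
    """Generate the full in-memory fixture for one config (deterministic)."""
    config = config or SyntheticConfig()
    proteins, labels = gen_protein_families(config)
    motifs = gen_motif_set(config)
    design = default_regulon_design(config)
    genomes, genes, lineages, truth = gen_genomes(config, motifs, design)
    truth.labels = labels
    return FixtureBundle(
        config=config, proteins=proteins, labels=labels, motifs=motifs,
        design=design, genomes=genomes, genes=genes, lineages=lineages, truth=truth,
    )


def gen_full_fixture(config: SyntheticConfig | None = None, out_dir: str | Path = "fixture", force: bool = False) -> FixtureBundle:
    """Write the fixture bundle to disk in the pipeline's standard formats.

    Emits proteins.fasta + labels.tsv, motifs.meme, per-genome FASTA/GFF,
    lineages.tsv, gr_gene_map.tsv and a truth.json manifest. Bit-identical
    across runs with the same config.
    """
    config = config or SyntheticConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    bundle = gen_fixture(config)

    write_fasta([(p.protein_id, p.sequence) for p in bundle.proteins], out / "proteins.fasta")
    write_labels(bundle.labels, out / "labels.tsv")
    write_meme_motifs([bundle.motifs[t] for t in sorted(bundle.motifs)], out / "motifs.meme")
    write_lineages(
        [bundle.lineages[g] for g in sorted(bundle.lineages)], out / "lineages.tsv"
    )
    for genome_id in sorted(bundle.genomes):
        contigs = bundle.genomes[genome_id]
        write_fasta(sorted(contigs.items()), out / f"{genome_id}.fasta")
        write_gff_genes(
            [g for g in bundle.genes if g.genome_id == genome_id],
            out / f"{genome_id}.gff",
        )
    with open(out / "gr_gene_map.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tgr_type\n")
        for (genome, gene), gr in sorted(bundle.truth.gr_gene_map.items()):
            fh.write(f"{genome}\t{gene}\t{gr}\n")

    manifest = dict(
        config=asdict(config),
        n_proteins=len(bundle.proteins),
        n_genes=len(bundle.genes),
        n_planted_sites=len(bundle.truth.planted_sites),
        planted_sites=[asdict(s) for s in bundle.truth.planted_sites],
        cross_edges=[
            dict(source=s, target=d, support=n)
            for (s, d), n in sorted(bundle.truth.cross_edges.items())
        ],
        labels=bundle.labels,
    )
    (out / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundle


def bundle_checksums(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a written fixture (determinism checks)."""
    out = Path(out_dir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file()
    }
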