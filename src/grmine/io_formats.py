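"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; conversion from
the 1-based inclusive GFF convention happens here and only here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

TAXON_RANKS = ("genus", "family", "order", "class_rank", "phylum", "domain")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Six-rank lineage for one genome; unknown ranks carry "NA"."""

    genome_id: str
    genus: str = "NA"
    family: str = "NA"
    order: str = "NA"
    class_rank: str = "NA"
    phylum: str = "NA"
    domain: str = "NA"

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")

    def rank(self, name: str) -> str:
        if name == "class":  # common alias
            name = "class_rank"
        if name not in TAXON_RANKS:
            raise ValueError(f"unknown taxonomic rank: {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with 0-based half-open coordinates on its contig.

    ``family_label`` is the orthology/gene-family key used for cross-genome
    prevalence; it defaults to the gene's own ID when no family is annotated.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    family_label: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.family_label:
            object.__setattr__(self, "family_label", self.gene_id)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a coarse pipeline label.

    Labels follow the scheme ``gr:<type>`` for global regulators,
    ``tf`` for non-GR transcription factors (hard negatives),
    ``other:<category>`` for generic negatives, and ``unknown``.
    """

    protein_id: str
    sequence: str
    genome_id: str = "NA"
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid residues {sorted(bad)}"
            )

    @property
    def is_gr(self) -> bool:
        return self.label.startswith("gr:")

    @property
    def gr_type(self) -> str | None:
        return self.label[3:] if self.is_gr else None


@dataclass
class MotifModel:
    """A nucleotide binding motif: 4 x width probability matrix (rows A,C,G,T)."""

    motif_id: str
    gr_type: str
    prob_matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.prob_matrix = np.asarray(self.prob_matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.prob_matrix.ndim != 2 or self.prob_matrix.shape[0] != 4:
            raise ValueError("prob_matrix must be 4 x width")
        if self.width < 1:
            raise ValueError("motif width must be >= 1")
        if np.any(self.prob_matrix < 0) or np.any(self.background < 0):
            raise ValueError("motif probabilities must be non-negative")
        if not np.allclose(self.prob_matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.prob_matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.prob_matrix.argmax(axis=0))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]``, order kept.

    Raises ``ValueError`` on an empty file or on sequence data appearing
    before any header line.
    """
    path = Path(path)
    text = path.read_text()
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if not stripped:
        raise ValueError(f"empty FASTA file: {path}")
    if not stripped[0].startswith(">"):
        raise ValueError(f"{path}: sequence data before first FASTA header")
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 subset (gene rows only)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff_genes(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Read "gene" rows from a GFF3-dialect file as :class:`GeneRecord` objects.

    GFF 1-based inclusive [start, end] becomes 0-based half-open
    [start-1, end). Only feature type ``gene`` is consumed; attributes use
    ``ID`` and the optional ``family`` tag (falling back to the gene ID).
    ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{line_no}: expected 9 GFF columns")
        contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
        if ftype != "gene":
            continue
        start, end = int(start_s), int(end_s)
        if start > end:
            raise ValueError(f"{path}:{line_no}: start > end")
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{line_no}: invalid strand {strand!r}")
        attrs = _parse_gff_attributes(attrs_s)
        gene_id = attrs.get("ID", f"gene_{line_no}")
        if gene_id in seen:
            raise ValueError(f"{path}:{line_no}: duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=contig,
                start=start - 1,
                end=end,
                strand=strand,
                family_label=attrs.get("family", ""),
                product=attrs.get("product", ""),
            )
        )
    return genes


def write_gff_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene records back to the GFF3 subset dialect (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};family={g.family_label}"
        if g.product:
            attrs += f";product={g.product}"
        lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "grmine",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motifs


def read_meme_motifs(path: str | Path) -> list[MotifModel]:
    """Read motifs from a MEME minimal-format file.

    Probability rows are returned in column order A, C, G, T; a missing
    background line yields the uniform background. Motif IDs of the form
    ``<gr_type>__<n>`` (or a plain name) set ``gr_type`` to the part before
    the separator.
    """
    # parsed directly (not via Bio.motifs "minimal"): that parser rescales
    # frequencies through integer counts (nsites), which loses precision
    # and silently renormalises defective columns
    path = Path(path)
    lines = path.read_text().splitlines()
    bg = np.full(4, 0.25)
    out: list[MotifModel] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            bg = np.array([freqs[b] for b in DNA])
            bg = bg / bg.sum()
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"motif {name}: missing probability matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: missing probability matrix")
            # pull w= from the matrix header line
            tokens = lines[i].replace("=", " = ").split()
            width = int(tokens[tokens.index("w") + 2])
            if width < 1:
                raise ValueError(f"motif {name}: width must be >= 1")
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(v) for v in lines[i].split()])
            mat = np.array(rows).T  # file rows are positions; we store 4 x width
            if mat.shape[0] != 4:
                raise ValueError(f"motif {name}: expected 4 columns per position")
            sums = mat.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                raise ValueError(
                    f"motif {name}: probability columns must sum to 1 (got {sums})"
                )
            mat = mat / sums  # renormalise residual float noise
            out.append(
                MotifModel(
                    motif_id=name, gr_type=name.split("__")[0],
                    prob_matrix=mat, background=bg.copy(),
                )
            )
        i += 1
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def write_meme_motifs(motif_list: Sequence[MotifModel], path: str | Path) -> None:
    """Write motifs in MEME minimal format (frequencies at 6 decimals)."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    if motif_list:
        bg = motif_list[0].background
        lines += [
            "Background letter frequencies",
            " ".join(f"{b} {p:.5f}" for b, p in zip(DNA, bg)),
            "",
        ]
    for m in motif_list:
        lines.append(f"MOTIF {m.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0"
        )
        for j in range(m.width):
            col = m.prob_matrix[:, j]
            col = col / col.sum()
            lines.append(" ".join(f"{p:.6f}" for p in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# TSV tables


def read_lineages(path: str | Path) -> dict[str, TaxonomyLineage]:
    """Read a lineage TSV (genome_id + six rank columns) keyed by genome."""
    out: dict[str, TaxonomyLineage] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].rstrip("\n").split("\t")
    expected = ["genome_id", "genus", "family", "order", "class_rank", "phylum", "domain"]
    if header != expected:
        raise ValueError(f"lineage header must be {expected}, got {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        lin = TaxonomyLineage(*fields)
        if lin.genome_id in out:
            raise ValueError(f"duplicate genome_id {lin.genome_id!r} in lineage table")
        out[lin.genome_id] = lin
    return out


def write_lineages(lineages: Iterable[TaxonomyLineage], path: str | Path) -> None:
    rows = ["\t".join(["genome_id", *TAXON_RANKS])]
    for lin in lineages:
        rows.append(
            "\t".join([lin.genome_id, *(getattr(lin, r) for r in TAXON_RANKS)])
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a protein label TSV (protein_id <TAB> label)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("protein_id\t"):
            continue
        protein_id, label = line.rstrip("\n").split("\t")
        out[protein_id] = label
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    lines = ["protein_id\tlabel"]
    lines += [f"{pid}\t{lab}" for pid, lab in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_edges_tsv(network, path: str | Path) -> None:
    """Write a directed GR-GR network as a deterministic edge TSV.

    Header ``source<TAB>target<TAB>support``; rows sorted by (source, target).
    """
    lines = ["source\ttarget\tsupport"]
    edges = sorted(network.edges(data="support"))
    for src, dst, support in edges:
        lines.append(f"{src}\t{dst}\t{support}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edges_tsv(path: str | Path):
    """Read an edge TSV back into a directed graph (inverse of write_edges_tsv)."""
    import networkx as nx

    graph = nx.DiGraph()
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "source\ttarget\tsupport":
        raise ValueError(f"{path}: missing edge TSV header")
    for line in lines[1:]:
        if not line.strip():
            continue
        src, dst, support = line.rstrip("\n").split("\t")
        graph.add_edge(src, dst, support=int(support))
    return graph
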