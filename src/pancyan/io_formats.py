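"""Domain types and on-disk formats.

The package works with three kinds of artifacts:

* sequences — plain FASTA (nucleotide genomes, protein queries);
* gene annotations — either standard GFF3 or a 9-column TSV dialect
  (``gene_id, genome_id, contig_id, start, end, strand, protein,
  categories, product``) defined here because upstream annotation is out
  of scope and protein sequences plus functional-category labels must
  travel with the coordinates;
* tabular reports — TSV presence/absence matrices and Newick dendrograms.

Coordinates are 1-based inclusive everywhere (GFF3 native); a gene
annotated [100, 399] spans exactly 300 bases.  All readers and writers
are mutual inverses on valid inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO
from scipy.cluster.hierarchy import to_tree

from .errors import (
    AnnotationFormatError,
    ConfigError,
    DuplicateIdError,
    EmptyFileError,
    FastaFormatError,
    MatrixFormatError,
    MissingFileError,
)

logger = logging.getLogger("pancyan")

NUCLEOTIDES = frozenset("ACGTN")

ANNOTATION_COLUMNS = (
    "gene_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "protein",
    "categories",
    "product",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """One genome: an identifier plus named nucleotide contigs.

    Contigs are stored uppercase over the alphabet {A, C, G, T, N} in
    insertion order.
    """

    genome_id: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if not self.contigs:
            raise ValueError(f"genome {self.genome_id!r} has no contigs")
        clean: dict[str, str] = {}
        for cid, seq in self.contigs.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {cid!r} of {self.genome_id!r} is empty")
            if not set(seq) <= NUCLEOTIDES:
                bad = sorted(set(seq) - NUCLEOTIDES)
                raise ValueError(
                    f"contig {cid!r} of {self.genome_id!r} contains non-ACGTN "
                    f"symbols: {bad}"
                )
            clean[cid] = seq
        self.contigs = clean

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene, 1-based inclusive coordinates, stranded."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""
    categories: frozenset[str] = frozenset()
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationFormatError(
                f"{self.gene_id}: start {self.start} < 1 (coordinates are 1-based)"
            )
        if self.end < self.start:
            raise AnnotationFormatError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationFormatError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if not isinstance(self.categories, frozenset):
            object.__setattr__(self, "categories", frozenset(self.categories))

    @property
    def length(self) -> int:
        """Gene span in bp (inclusive coordinates)."""
        return self.end - self.start + 1


@dataclass
class Dendrogram:
    """Rooted binary merge tree: a SciPy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise DuplicateIdError("duplicate leaf labels in dendrogram")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All analysis thresholds in one place.

    Defaults are the values used throughout the species-level analyses:
    70% protein identity for family clustering, a 96% ANI species cutoff
    (95% is the common alternative preset and must be set explicitly),
    ANIb-style 1020 bp fragments accepted at 30% identity / 70% coverage,
    and 50% identity / 80% coverage for marker-gene homolog screening.
    """

    family_identity_threshold: float = 0.70
    ani_species_cutoff: float = 96.0
    fragment_length: int = 1020
    fragment_min_identity: float = 30.0
    fragment_min_coverage: float = 0.70
    screen_min_identity: float = 50.0
    screen_min_coverage: float = 80.0
    s_pos: int = 0
    s_neg: int = 0
    n_permutations: int = 100
    rng_seed: int = 0
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    protein_matrix: str = "BLOSUM62"
    seed_kmer: int = 15
    seed_stride: int = 4
    min_seed_hits: int = 2
    accessory_distance: str = "jaccard"
    linkage_method: str = "average"
    min_category_size: int = 2

    def __post_init__(self) -> None:
        checks = [
            (0 < self.family_identity_threshold <= 1, "family_identity_threshold in (0,1]"),
            (0 <= self.ani_species_cutoff <= 100, "ani_species_cutoff in [0,100]"),
            (self.fragment_length >= 100, "fragment_length >= 100"),
            (0 <= self.fragment_min_identity <= 100, "fragment_min_identity in [0,100]"),
            (0 < self.fragment_min_coverage <= 1, "fragment_min_coverage in (0,1]"),
            (0 < self.screen_min_identity <= 100, "screen_min_identity in (0,100]"),
            (0 < self.screen_min_coverage <= 100, "screen_min_coverage in (0,100]"),
            (self.s_pos >= 0 and self.s_neg >= 0, "s_pos/s_neg non-negative"),
            (self.n_permutations >= 1, "n_permutations >= 1"),
            (self.seed_kmer >= 4, "seed_kmer >= 4"),
            (self.seed_stride >= 1, "seed_stride >= 1"),
            (self.min_seed_hits >= 1, "min_seed_hits >= 1"),
            (self.min_category_size >= 1, "min_category_size >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"configuration violates: {msg}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        if not os.path.exists(path):
            raise MissingFileError(str(path))
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, return_descriptions: bool = False):
    """Read a FASTA file into an insertion-ordered ``{id: sequence}`` map.

    Sequences are uppercased.  Header text after the first whitespace is
    the description, returned separately when requested.
    """
    if not os.path.exists(path):
        raise MissingFileError(str(path))
    with open(path) as fh:
        head = fh.read(1)
        while head and head.isspace():
            head = fh.read(1)
    if not head:
        raise EmptyFileError(str(path))
    if head != ">":
        raise FastaFormatError(f"{path}: does not start with '>'")
    seqs: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
        desc = rec.description
        descriptions[rec.id] = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
    if not seqs:
        raise EmptyFileError(str(path))
    if return_descriptions:
        return seqs, descriptions
    return seqs


def write_fasta(seqs: Mapping[str, str], path, descriptions: Mapping[str, str] | None = None,
                width: int = 70) -> None:
    """Write sequences as FASTA, 70 columns per line, insertion order."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            desc = descriptions.get(sid, "")
            header = f">{sid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations (TSV dialect and GFF3)
# ---------------------------------------------------------------------------

def write_annotations(annotations: Iterable[GeneAnnotation], path) -> None:
    """Write the 9-column TSV annotation table (header included)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.gene_id,
                        a.genome_id,
                        a.contig_id,
                        str(a.start),
                        str(a.end),
                        a.strand,
                        a.protein,
                        ";".join(sorted(a.categories)),
                        a.product,
                    ]
                )
                + "\n"
            )


def _annotations_from_tsv(path) -> list[GeneAnnotation]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_COLUMNS:
            missing = set(ANNOTATION_COLUMNS) - set(header)
            raise AnnotationFormatError(
                f"{path}: bad header; missing columns {sorted(missing)}"
                if missing
                else f"{path}: columns out of order: {header}"
            )
        out = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(ANNOTATION_COLUMNS):
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected {len(ANNOTATION_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            (gene_id, genome_id, contig_id, start, end, strand, protein,
             categories, product) = parts
            cats = frozenset(c for c in categories.split(";") if c)
            out.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    protein=protein,
                    categories=cats,
                    product=product,
                )
            )
    return out


def _annotations_from_gff3(path, genome_id: str | None) -> list[GeneAnnotation]:
    from gffutils.feature import feature_from_line

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: GFF3 rows need 9 tab-separated columns"
                )
            feat = feature_from_line(line)
            if feat.featuretype not in ("gene", "CDS"):
                continue
            attrs = feat.attributes
            if "ID" not in attrs:
                raise AnnotationFormatError(f"{path}:{lineno}: gene row without ID")
            gid = attrs["ID"][0]
            gnm = attrs["genome_id"][0] if "genome_id" in attrs else genome_id
            if gnm is None:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: no genome_id attribute and no genome_id "
                    "argument given"
                )
            cats = frozenset(
                c for c in attrs["categories"][0].split(";") if c
            ) if "categories" in attrs else frozenset()
            out.append(
                GeneAnnotation(
                    gene_id=gid,
                    genome_id=gnm,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    protein=attrs["protein"][0] if "protein" in attrs else "",
                    categories=cats,
                    product=attrs["product"][0] if "product" in attrs else "",
                )
            )
    return out


def read_annotations(path, dialect: str = "tsv",
                     genome_id: str | None = None) -> list[GeneAnnotation]:
    """Read gene annotations from the TSV dialect or standard GFF3.

    GFF3 files carry no genome column; supply ``genome_id`` or put a
    ``genome_id=`` attribute on each row.  Unknown attributes are ignored.
    """
    if not os.path.exists(path):
        raise MissingFileError(str(path))
    if dialect == "tsv":
        return _annotations_from_tsv(path)
    if dialect == "gff3":
        return _annotations_from_gff3(path, genome_id)
    raise ConfigError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Presence/absence matrix
# ---------------------------------------------------------------------------

def write_matrix(matrix, path) -> None:
    """Write a genomes x families boolean matrix as TSV (cells 0/1).

    First column is ``genome_id``; the header row lists family ids.
    """
    df = matrix.df if hasattr(matrix, "df") else matrix
    with open(path, "w") as fh:
        fh.write("\t".join(["genome_id", *(str(c) for c in df.columns)]) + "\n")
        for gid, row in df.iterrows():
            fh.write("\t".join([str(gid), *("1" if v else "0" for v in row)]) + "\n")


def read_matrix(path):
    """Inverse of :func:`write_matrix`; returns a PresenceAbsenceMatrix."""
    import pandas as pd

    from .pangenome import PresenceAbsenceMatrix

    if not os.path.exists(path):
        raise MissingFileError(str(path))
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "genome_id":
            raise MatrixFormatError(f"{path}: first column must be genome_id")
        families = header[1:]
        ncol = len(header)
        genomes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise MatrixFormatError(f"{path}:{lineno}: ragged row")
            for cell in parts[1:]:
                if cell not in ("0", "1"):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: non-binary cell {cell!r}"
                    )
            genomes.append(parts[0])
            rows.append([cell == "1" for cell in parts[1:]])
    df = pd.DataFrame(rows, index=genomes, columns=families, dtype=bool)
    return PresenceAbsenceMatrix(df)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_string(tree: Dendrogram) -> str:
    """Serialize a merge tree as ultrametric Newick.

    Leaf-to-root distance equals the merge height of the root; each
    branch length is the parent's merge height minus the child's (leaves
    sit at height 0).
    """
    root = to_tree(tree.linkage)
    labels = tree.labels

    def render(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{round(parent_height, 10)}"
        inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
        if parent_height is None:
            return f"({inner})"
        return f"({inner}):{round(parent_height - node.dist, 10)}"

    inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
    return f"({inner});"


def write_newick(tree: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
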