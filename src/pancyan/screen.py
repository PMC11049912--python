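"""Marker-gene homolog screening and anchor-cluster co-occurrence mining.

Screening asks a presence/absence question per genome: does any protein
in the genome align to the marker query at >= 50% identity over >= 80%
of the query?  Co-occurrence mining then asks which gene families track
a marker-defined genome subset: a candidate family must be present in at
least ``|anchor| - s_pos`` anchor genomes and in at most ``s_neg``
non-anchor genomes.  ``s_pos = s_neg = 0`` is full stringency (present
in exactly the anchor subset); relaxing either parameter can only grow
the candidate set.  Candidate genes that are gene-order neighbors are
reported as adjacent pairs — physical linkage of co-occurring genes is
corroborating evidence that they travel together.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .errors import AlignmentInputError, DegenerateInputError, PancyanError
from .io_formats import GeneAnnotation, RunConfig
from .pairwise import align_global
from .pangenome import PresenceAbsenceMatrix

logger = logging.getLogger("pancyan")


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    genome_id: str
    gene_id: str
    identity: float
    coverage: float
    is_best: bool = False


def search_homologs(query: str, proteomes: list[GeneAnnotation],
                    min_identity: float = 50.0, min_coverage: float = 80.0,
                    config: RunConfig | None = None,
                    query_id: str = "query") -> list[HomologHit]:
    """Threshold screen of one protein query against annotated proteomes.

    Coverage is query coverage (fraction of the query inside the aligned
    region).  The best hit per genome carries ``is_best``; ties resolve
    by identity, then coverage, then gene id.  The result is sorted and
    independent of input iteration order.
    """
    if not query:
        raise AlignmentInputError("empty query protein")
    if not proteomes:
        raise DegenerateInputError("empty proteome set")
    if not (0 < min_identity <= 100 and 0 < min_coverage <= 100):
        raise ValueError("thresholds must be in (0, 100]")
    config = config or RunConfig()
    hits: list[HomologHit] = []
    for a in sorted(proteomes, key=lambda a: (a.genome_id, a.gene_id)):
        if not a.protein:
            continue
        # a target shorter than coverage*query can never satisfy coverage
        if 100.0 * len(a.protein) / len(query) < min_coverage:
            continue
        res = align_global(query, a.protein, config=config, protein=True,
                           query_id=query_id, target_id=a.gene_id)
        if res.identity >= min_identity and res.query_coverage >= min_coverage:
            hits.append(HomologHit(query_id, a.genome_id, a.gene_id,
                                   res.identity, res.query_coverage))
    best: dict[str, HomologHit] = {}
    for h in hits:
        b = best.get(h.genome_id)
        if b is None or (h.identity, h.coverage, b.gene_id) > (b.identity, b.coverage, h.gene_id):
            best[h.genome_id] = h
    return [
        HomologHit(h.query_id, h.genome_id, h.gene_id, h.identity, h.coverage,
                   is_best=(best[h.genome_id].gene_id == h.gene_id))
        for h in hits
    ]


def presence_profile(queries: dict[str, str], proteomes: list[GeneAnnotation],
                     min_identity: float = 50.0, min_coverage: float = 80.0,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Markers x genomes boolean presence table (a Fig.-style grid).

    A cell is true when the marker has >= 1 qualifying homolog in that
    genome.
    """
    if not queries:
        raise DegenerateInputError("no marker queries")
    genomes = sorted({a.genome_id for a in proteomes})
    table = pd.DataFrame(False, index=list(queries), columns=genomes)
    for qid, qseq in queries.items():
        for h in search_homologs(qseq, proteomes, min_identity, min_coverage,
                                 config, query_id=qid):
            table.loc[qid, h.genome_id] = True
    return table


# ---------------------------------------------------------------------------
# gene neighborhoods
# ---------------------------------------------------------------------------

def gene_neighborhood(gene_id: str, annotations: list[GeneAnnotation],
                      window: int = 5,
                      family_of_gene: dict[str, str] | None = None
                      ) -> list[tuple[str, str, str | None]]:
    """Up to ``window`` genes on each side of a gene, same contig.

    Returns coordinate-ordered ``(gene_id, strand, family_id)`` triples
    (the focal gene excluded), truncated at contig ends.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    focal = [a for a in annotations if a.gene_id == gene_id]
    if not focal:
        raise KeyError(f"unknown gene {gene_id!r}")
    f = focal[0]
    contig_genes = sorted(
        (a for a in annotations
         if a.genome_id == f.genome_id and a.contig_id == f.contig_id),
        key=lambda a: a.start,
    )
    idx = next(i for i, a in enumerate(contig_genes) if a.gene_id == gene_id)
    fam = family_of_gene or {}
    picked = contig_genes[max(0, idx - window):idx] + \
        contig_genes[idx + 1:idx + 1 + window]
    return [(a.gene_id, a.strand, fam.get(a.gene_id)) for a in picked]


@dataclass(frozen=True)
class ContextComparison:
    shared_fraction: float
    same_organization: bool


def compare_contexts(nbh_a, nbh_b) -> ContextComparison:
    """Order-insensitive Jaccard of neighborhood family sets, plus an
    organization flag.

    ``same_organization`` is true when the shared families occur in the
    same relative order with the same strand pattern in both
    neighborhoods, reading either neighborhood in either direction — a
    cluster assembled on the opposite strand is the same organization.
    """
    fams_a = [f for _, _, f in nbh_a if f is not None]
    fams_b = [f for _, _, f in nbh_b if f is not None]
    set_a, set_b = set(fams_a), set(fams_b)
    union = set_a | set_b
    shared = set_a & set_b
    fraction = 1.0 if not union else len(shared) / len(union)

    def signature(nbh, flip: bool):
        entries = [(f, s) for _, s, f in nbh if f in shared]
        if flip:
            entries = [(f, "+" if s == "-" else "-") for f, s in reversed(entries)]
        return tuple(entries)

    fwd = signature(nbh_a, False)
    same = fwd == signature(nbh_b, False) or fwd == signature(nbh_b, True)
    return ContextComparison(shared_fraction=fraction, same_organization=same)


# ---------------------------------------------------------------------------
# anchor-cluster co-occurrence
# ---------------------------------------------------------------------------

def find_anchor_genomes(matrix: PresenceAbsenceMatrix,
                        marker_families: list[str] | set[str]) -> set[str]:
    """Genomes that contain ALL marker families."""
    markers = sorted(set(marker_families))
    if not markers:
        raise DegenerateInputError("empty marker family set")
    unknown = [m for m in markers if m not in matrix.df.columns]
    if unknown:
        raise PancyanError(f"unknown marker families: {unknown}")
    mask = matrix.df[markers].all(axis=1)
    return set(matrix.df.index[mask])


@dataclass
class CooccurrenceReport:
    """Families tracking an anchor genome subset at stated stringency.

    Every candidate satisfies
    ``anchor_presence >= |anchor| - s_pos`` and
    ``non_anchor_presence <= s_neg``; marker families are flagged in the
    table rather than removed.
    """

    anchor_genomes: set[str]
    s_pos: int
    s_neg: int
    marker_families: set[str]
    table: pd.DataFrame  # index family, cols anchor_presence/non_anchor_presence/is_marker
    adjacent_pairs: set[frozenset]

    @property
    def candidate_families(self) -> set[str]:
        return set(self.table.index)


def core_specific_genes(matrix: PresenceAbsenceMatrix,
                        anchor_genomes: set[str] | list[str],
                        s_pos: int = 0, s_neg: int = 0,
                        annotations: list[GeneAnnotation] | None = None,
                        family_of_gene: dict[str, str] | None = None,
                        marker_families: set[str] | None = None
                        ) -> CooccurrenceReport:
    """Core-specific genes of the anchor subset (co-occurrence mining).

    With ``annotations`` + ``family_of_gene`` supplied, candidate
    families whose member genes are immediate gene-order neighbors in
    some genome are reported as adjacent pairs.
    """
    anchor = set(anchor_genomes)
    all_genomes = set(matrix.genome_ids)
    if not anchor:
        raise DegenerateInputError("anchor genome set is empty")
    if not anchor < all_genomes:
        raise DegenerateInputError(
            "anchor set must be a strict subset of all genomes "
            "(the complement test is vacuous otherwise)"
        )
    if s_pos < 0 or s_neg < 0:
        raise ValueError("s_pos and s_neg must be non-negative")
    inside = matrix.df.loc[sorted(anchor)].sum(axis=0)
    outside = matrix.df.loc[sorted(all_genomes - anchor)].sum(axis=0)
    keep = (inside >= len(anchor) - s_pos) & (outside <= s_neg)
    fids = sorted(matrix.df.columns[keep])
    markers = set(marker_families or ())
    table = pd.DataFrame(
        {
            "anchor_presence": inside[fids].astype(int),
            "non_anchor_presence": outside[fids].astype(int),
            "is_marker": [f in markers for f in fids],
        },
        index=pd.Index(fids, name="family_id"),
    )
    adjacent: set[frozenset] = set()
    if annotations is not None and family_of_gene is not None and fids:
        cand = set(fids)
        by_contig: dict[tuple[str, str], list[GeneAnnotation]] = defaultdict(list)
        for a in annotations:
            by_contig[(a.genome_id, a.contig_id)].append(a)
        for genes in by_contig.values():
            genes.sort(key=lambda a: a.start)
            for prev, cur in zip(genes, genes[1:]):
                fa, fb = family_of_gene.get(prev.gene_id), family_of_gene.get(cur.gene_id)
                if fa in cand and fb in cand and fa != fb:
                    adjacent.add(frozenset((fa, fb)))
    logger.info(
        "co-occurrence at s_pos=%d s_neg=%d: %d candidates (%d markers)",
        s_pos, s_neg, len(fids), int(table["is_marker"].sum()),
    )
    return CooccurrenceReport(anchor, s_pos, s_neg, markers, table, adjacent)
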