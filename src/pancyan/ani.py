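"""Fragment-based Average Nucleotide Identity and species delineation.

The ANIb convention is followed: the query genome is cut into
consecutive non-overlapping 1020 bp fragments, each fragment is searched
in the target with seeded banded alignment, and fragments are accepted
when they align at >= 30% identity over >= 70% of their length.
Directional ANI is the mean identity over accepted fragments; the
symmetric ANI of a pair is the mean of the two directions.  Genomes are
assigned to the same species cluster when their symmetric ANI reaches
the configured cutoff (default 96%; 95% is the common alternative and
must be set explicitly in the configuration).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import DuplicateIdError, UndefinedDistanceError
from .io_formats import Dendrogram, GenomeRecord, RunConfig
from .pairwise import KmerIndex, align_local_seeded

logger = logging.getLogger("pancyan")


@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    genome_id: str
    contig_id: str
    offset: int  # 0-based offset within the contig
    sequence: str


@dataclass
class AniMatrix:
    """Directional and symmetric ANI over an ordered genome set.

    Undefined pairs (no accepted fragments) are NaN.  The diagonal is
    exactly 100 and the symmetric matrix equals its transpose by
    construction.
    """

    genome_ids: list[str]
    directional: pd.DataFrame
    symmetric: pd.DataFrame
    fragment_counts: pd.DataFrame


def fragment_genome(genome: GenomeRecord, fragment_length: int = 1020) -> list[Fragment]:
    """Cut every contig into consecutive non-overlapping windows.

    A trailing remainder shorter than ``fragment_length`` is discarded.
    """
    frags = []
    for cid, seq in genome.contigs.items():
        for i in range(0, len(seq) - fragment_length + 1, fragment_length):
            frags.append(
                Fragment(
                    fragment_id=f"{cid}:{i}",
                    genome_id=genome.genome_id,
                    contig_id=cid,
                    offset=i,
                    sequence=seq[i:i + fragment_length],
                )
            )
    return frags


def _target_index(genome: GenomeRecord, config: RunConfig) -> KmerIndex:
    # contigs joined with N-runs so no seed spans a contig boundary
    joined = ("N" * config.seed_kmer).join(genome.contigs.values())
    return KmerIndex(joined, config.seed_kmer)


def compute_ani(query: GenomeRecord, target: GenomeRecord,
                config: RunConfig | None = None,
                index: KmerIndex | None = None,
                with_count: bool = False):
    """Directional ANI of ``query`` against ``target`` (percent).

    Returns NaN when no fragment is accepted.  With ``with_count`` the
    number of accepted fragments is returned as well.  A prebuilt target
    index may be passed to amortize indexing over many queries.
    """
    config = config or RunConfig()
    if index is None:
        index = _target_index(target, config)
    identities = []
    for frag in fragment_genome(query, config.fragment_length):
        res = align_local_seeded(
            frag.sequence,
            index.target,
            k=config.seed_kmer,
            stride=config.seed_stride,
            min_seed_hits=config.min_seed_hits,
            index=index,
        )
        if res is None:
            continue
        if (res.identity >= config.fragment_min_identity
                and res.query_coverage >= 100.0 * config.fragment_min_coverage):
            identities.append(res.identity)
    ani = float(np.mean(identities)) if identities else math.nan
    if with_count:
        return ani, len(identities)
    return ani


def ani_matrix(genomes: list[GenomeRecord],
               config: RunConfig | None = None) -> AniMatrix:
    """All-pairs directional and symmetric ANI."""
    config = config or RunConfig()
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate genome ids in ANI input")
    if len(ids) < 2:
        raise ValueError("ANI matrix needs at least 2 genomes")
    directional = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    counts = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    indices = {g.genome_id: _target_index(g, config) for g in genomes}
    for q in genomes:
        for t in genomes:
            if q.genome_id == t.genome_id:
                directional.loc[q.genome_id, t.genome_id] = 100.0
                continue
            ani, n = compute_ani(q, t, config, index=indices[t.genome_id],
                                 with_count=True)
            directional.loc[q.genome_id, t.genome_id] = ani
            counts.loc[q.genome_id, t.genome_id] = n
    symmetric = (directional + directional.T) / 2.0
    np.fill_diagonal(symmetric.values, 100.0)
    logger.info("ANI matrix over %d genomes (fragment length %d)",
                len(ids), config.fragment_length)
    return AniMatrix(ids, directional, symmetric, counts)


@dataclass
class SpeciesAssignment:
    clusters: list[list[str]]  # size-sorted, each lexicographic
    outliers: list[str]        # singleton components
    cutoff: float


def assign_species(matrix: AniMatrix, cutoff: float = 96.0) -> SpeciesAssignment:
    """Species clusters = connected components of the >= cutoff graph.

    Undefined (NaN) pairs contribute no edge.  Singleton components are
    flagged as outliers.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.genome_ids)
    sym = matrix.symmetric
    for i, a in enumerate(matrix.genome_ids):
        for b in matrix.genome_ids[i + 1:]:
            v = sym.loc[a, b]
            if not math.isnan(v) and v >= cutoff:
                g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    outliers = [c[0] for c in comps if len(c) == 1]
    return SpeciesAssignment(clusters=comps, outliers=outliers, cutoff=cutoff)


def ani_dendrogram(matrix: AniMatrix,
                   config: RunConfig | None = None) -> Dendrogram:
    """Average-linkage clustering on distance = 100 - symmetric ANI."""
    config = config or RunConfig()
    sym = matrix.symmetric.values
    if np.isnan(sym).any():
        raise UndefinedDistanceError(
            "undefined ANI pairs; replace NaN with a floor distance before "
            "building the dendrogram"
        )
    dist = 100.0 - sym
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard against float asymmetry
    z = linkage(squareform(dist, checks=False), method=config.linkage_method)
    return Dendrogram(z, list(matrix.genome_ids))
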