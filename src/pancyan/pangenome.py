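"""Ortholog families, pan-genome partitioning, and Heap's-law openness.

Protein-coding genes are grouped into ortholog families by single-linkage
clustering: an edge joins two proteins whose pairwise identity reaches
the threshold (default 70%), and families are the connected components
of that graph.  Families present in every genome form the core genome;
families confined to one genome are singletons (strain-specific); the
rest are dispensable.  Dispensable plus singleton families constitute
the accessory genome.

Openness is assessed by rarefaction: genomes are added in random orders
and the mean number of new families contributed at each step N is fitted
to the power law ``n_new = kappa * N^(-alpha)`` on log-log scale (step 1
is excluded — it counts mean genome size, not discovery).  ``alpha < 1``
marks an open pan-genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError
from .io_formats import Dendrogram, GeneAnnotation, RunConfig
from .pairwise import align_global

logger = logging.getLogger("pancyan")


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Percent of ``count`` in ``total``, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# family table and presence/absence matrix
# ---------------------------------------------------------------------------

@dataclass
class FamilyTable:
    """Ortholog families: family id -> list of (genome_id, gene_id)."""

    families: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for fid, members in self.families.items():
            if not members:
                raise ValueError(f"empty family {fid!r}")
            for m in members:
                if m in seen:
                    raise ValueError(f"gene {m} appears in more than one family")
                seen.add(m)

    def carriers(self, family_id: str) -> set[str]:
        return {g for g, _ in self.families[family_id]}

    def family_of_gene(self) -> dict[str, str]:
        return {
            gene: fid
            for fid, members in self.families.items()
            for _, gene in members
        }

    @property
    def n_families(self) -> int:
        return len(self.families)


@dataclass
class PresenceAbsenceMatrix:
    """Genomes x families boolean matrix (a genome is a carrier when it
    holds >= 1 member gene; paralogs do not add columns)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.astype(bool)
        if (self.df.sum(axis=0) < 1).any() and self.df.shape[1] > 0:
            empty = list(self.df.columns[self.df.sum(axis=0) < 1])
            raise ValueError(f"families with no carrier: {empty[:5]}")

    @classmethod
    def from_family_table(cls, table: FamilyTable,
                          genome_ids: list[str]) -> "PresenceAbsenceMatrix":
        fids = list(table.families)
        data = np.zeros((len(genome_ids), len(fids)), dtype=bool)
        gidx = {g: i for i, g in enumerate(genome_ids)}
        for j, fid in enumerate(fids):
            for g in table.carriers(fid):
                data[gidx[g], j] = True
        return cls(pd.DataFrame(data, index=genome_ids, columns=fids))

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.df.columns)

    def accessory(self) -> "PresenceAbsenceMatrix":
        """Columns not present in every genome (core removed)."""
        keep = self.df.columns[~self.df.all(axis=0)]
        return PresenceAbsenceMatrix(self.df[keep])


# ---------------------------------------------------------------------------
# single-linkage family clustering
# ---------------------------------------------------------------------------

def _cannot_reach_threshold(a: str, b: str) -> bool:
    """Conservative prefilter for the all-pairs identity graph.

    Only same-length-scale pairs (length ratio >= 0.8) may be skipped,
    and only when their unit-cost edit distance exceeds half the longer
    length — far beyond what any pair at the clustering threshold can
    produce.  Length-discordant pairs are always fully aligned.
    """
    la, lb = len(a), len(b)
    lo, hi = (la, lb) if la < lb else (lb, la)
    if lo / hi < 0.8:
        return False
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return d > 0.5 * hi


def cluster_families(proteins: list[GeneAnnotation],
                     identity_threshold: float = 0.70,
                     config: RunConfig | None = None,
                     prefilter: bool = True) -> FamilyTable:
    """Single-linkage ortholog families over all annotated proteins.

    An edge joins two proteins whose semi-global identity reaches
    ``identity_threshold``; families are connected components, so every
    member is within threshold of at least one other member.  The output
    is invariant to input order (members are sorted internally) and, by
    construction of the prefilter, to whether the prefilter is enabled.
    """
    if not proteins:
        raise DegenerateInputError("cluster_families: empty protein set")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    config = config or RunConfig()
    annots = sorted(proteins, key=lambda a: (a.genome_id, a.gene_id))
    keys = [(a.genome_id, a.gene_id) for a in annots]
    seqs = [a.protein for a in annots]
    if any(not s for s in seqs):
        raise ValueError("annotation without protein sequence")
    g = nx.Graph()
    g.add_nodes_from(range(len(annots)))
    thr = identity_threshold * 100.0
    for i in range(len(annots)):
        si = seqs[i]
        for j in range(i + 1, len(annots)):
            sj = seqs[j]
            if prefilter and _cannot_reach_threshold(si, sj):
                continue
            res = align_global(si, sj, config=config, protein=True)
            if res.identity >= thr:
                g.add_edge(i, j)
    comps = sorted(
        (sorted(c, key=lambda i: keys[i]) for c in nx.connected_components(g)),
        key=lambda c: keys[c[0]],
    )
    families = {
        f"FAM{n:05d}": [keys[i] for i in comp]
        for n, comp in enumerate(comps, start=1)
    }
    logger.info("clustered %d proteins into %d families at %.0f%% identity",
                len(annots), len(families), thr)
    return FamilyTable(families)


# ---------------------------------------------------------------------------
# core / dispensable / singleton partition
# ---------------------------------------------------------------------------

@dataclass
class PanPartition:
    """Per-family core/dispensable/singleton labels with summary counts.

    Percentages are over the family total, rounded half-up to one
    decimal place.
    """

    labels: dict[str, str]
    n_core: int
    n_dispensable: int
    n_singleton: int

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_dispensable + self.n_singleton

    @property
    def pct_core(self) -> float:
        return percentage(self.n_core, self.n_total)

    @property
    def pct_dispensable(self) -> float:
        return percentage(self.n_dispensable, self.n_total)

    @property
    def pct_singleton(self) -> float:
        return percentage(self.n_singleton, self.n_total)

    @classmethod
    def from_counts(cls, n_core: int, n_dispensable: int,
                    n_singleton: int) -> "PanPartition":
        """Summary arithmetic over already-counted families."""
        return cls({}, n_core, n_dispensable, n_singleton)


def partition(families: FamilyTable, genome_ids: list[str]) -> PanPartition:
    """Label every family core / dispensable / singleton.

    Core = carriers are all genomes; singleton = exactly one carrier;
    dispensable = anything in between.  With fewer than 3 genomes the
    dispensable class is empty by definition and the partition is
    refused.
    """
    if len(genome_ids) < 3:
        raise DegenerateInputError("partition requires >= 3 genomes")
    all_genomes = set(genome_ids)
    labels = {}
    for fid in families.families:
        c = families.carriers(fid)
        if c == all_genomes:
            labels[fid] = "core"
        elif len(c) == 1:
            labels[fid] = "singleton"
        else:
            labels[fid] = "dispensable"
    counts = {k: sum(1 for v in labels.values() if v == k)
              for k in ("core", "dispensable", "singleton")}
    return PanPartition(labels, counts["core"], counts["dispensable"],
                        counts["singleton"])


def shared_cluster_count(matrix: PresenceAbsenceMatrix,
                         subset: set[str] | list[str]) -> int:
    """Families present in every genome of ``subset`` and in no other."""
    subset = set(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = subset - set(matrix.genome_ids)
    if unknown:
        raise KeyError(f"unknown genome ids: {sorted(unknown)}")
    inside = matrix.df.loc[sorted(subset)]
    outside = matrix.df.loc[[g for g in matrix.genome_ids if g not in subset]]
    mask = inside.all(axis=0)
    if len(outside):
        mask &= ~outside.any(axis=0)
    return int(mask.sum())


# ---------------------------------------------------------------------------
# rarefaction and Heap's law
# ---------------------------------------------------------------------------

@dataclass
class RarefactionResult:
    """Per-permutation and mean pan-genome growth curves."""

    pan_sizes: np.ndarray   # (n_permutations, n_genomes) cumulative pan size
    new_counts: np.ndarray  # (n_permutations, n_genomes) new families per step

    @property
    def mean_pan(self) -> np.ndarray:
        return self.pan_sizes.mean(axis=0)

    @property
    def mean_new(self) -> np.ndarray:
        return self.new_counts.mean(axis=0)


def rarefaction(matrix: PresenceAbsenceMatrix, n_permutations: int = 100,
                rng_seed: int = 0, exhaustive: bool = False) -> RarefactionResult:
    """Pan-genome size and new-family counts along random genome orders.

    With ``exhaustive`` every one of the G! orderings is walked instead
    of sampling (only sensible for small G); ``n_permutations`` is then
    ignored.
    """
    import itertools

    G = len(matrix.genome_ids)
    if G < 3:
        raise DegenerateInputError("rarefaction requires >= 3 genomes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    data = matrix.df.values
    if exhaustive:
        orders = [np.array(p) for p in itertools.permutations(range(G))]
    else:
        orders = [rng.permutation(G) for _ in range(n_permutations)]
    pan = np.zeros((len(orders), G), dtype=np.int64)
    new = np.zeros((len(orders), G), dtype=np.int64)
    for p, order in enumerate(orders):
        seen = np.zeros(data.shape[1], dtype=bool)
        for step, gi in enumerate(order):
            added = data[gi] & ~seen
            seen |= data[gi]
            new[p, step] = added.sum()
            pan[p, step] = seen.sum()
    return RarefactionResult(pan, new)


@dataclass
class HeapsFit:
    """Power-law fit ``n_new(N) = kappa * N^(-alpha)`` of mean discovery."""

    kappa: float
    alpha: float
    rms_log_residual: float
    n_points: int

    @property
    def open_pangenome(self) -> bool:
        return self.alpha < 1.0


def fit_heaps(rar: RarefactionResult) -> HeapsFit:
    """Least squares on log(mean new counts) vs log(N), N >= 2.

    Step 1 is excluded: its count is the mean genome size, not a
    discovery count.  Steps whose mean count is zero carry no log-scale
    information and are dropped; if fewer than two informative steps
    remain the fit is undefined and an error is raised.
    """
    mean_new = rar.mean_new
    steps = np.arange(1, len(mean_new) + 1)
    mask = (steps >= 2) & (mean_new > 0)
    if mask.sum() < 2:
        raise DegenerateInputError(
            "Heap's fit undefined: fewer than 2 steps with positive mean "
            "new-family counts beyond step 1"
        )
    x = np.log(steps[mask])
    y = np.log(mean_new[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return HeapsFit(
        kappa=float(np.exp(intercept)),
        alpha=float(-slope),
        rms_log_residual=float(np.sqrt(np.mean(resid ** 2))),
        n_points=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# accessory-profile clustering and strain-specific regions
# ---------------------------------------------------------------------------

def accessory_dendrogram(matrix: PresenceAbsenceMatrix,
                         partition_labels: PanPartition | None = None,
                         config: RunConfig | None = None) -> Dendrogram:
    """Average-linkage Jaccard clustering of genome accessory profiles.

    Core columns are removed first (via ``partition_labels`` when given,
    otherwise any all-true column).  A genome whose accessory vector is
    empty has no defined Jaccard distance and is refused.
    """
    config = config or RunConfig()
    if partition_labels is not None:
        keep = [f for f in matrix.family_ids
                if partition_labels.labels.get(f) != "core"]
        acc = PresenceAbsenceMatrix(matrix.df[keep]) if keep else None
    else:
        acc = matrix.accessory()
    if acc is None or acc.df.shape[1] == 0:
        raise DegenerateInputError("no accessory families to cluster on")
    zero = acc.df.sum(axis=1) == 0
    if zero.any():
        raise DegenerateInputError(
            f"genomes with empty accessory profile: {list(acc.df.index[zero])}; "
            "drop them or cluster on the full matrix"
        )
    condensed = pdist(acc.df.values, metric="jaccard")
    z = linkage(condensed, method=config.linkage_method)
    return Dendrogram(z, list(acc.df.index))


@dataclass(frozen=True)
class SingletonRun:
    """A maximal run of consecutive strain-specific genes on one contig."""

    genome_id: str
    contig_id: str
    gene_ids: tuple[str, ...]
    start: int
    end: int

    @property
    def length(self) -> int:
        return len(self.gene_ids)


def locate_strain_specific(families: FamilyTable, pan: PanPartition,
                           annotations: list[GeneAnnotation], genome_id: str,
                           min_run: int = 2) -> list[SingletonRun]:
    """Maximal gene-order runs of singleton-family genes in one genome.

    Genes are sorted by coordinate per contig; a run is a block of
    consecutive genes (gene-order adjacency, intergenic distance is not
    considered) all belonging to singleton families.  Runs shorter than
    ``min_run`` are dropped.
    """
    mine = [a for a in annotations if a.genome_id == genome_id]
    if not mine:
        raise KeyError(f"unknown genome {genome_id!r}")
    fam_of = families.family_of_gene()
    runs: list[SingletonRun] = []
    for contig in sorted({a.contig_id for a in mine}):
        genes = sorted((a for a in mine if a.contig_id == contig),
                       key=lambda a: a.start)
        current: list[GeneAnnotation] = []
        for a in genes + [None]:
            is_single = (
                a is not None
                and pan.labels.get(fam_of.get(a.gene_id)) == "singleton"
            )
            if is_single:
                current.append(a)
            else:
                if len(current) >= min_run:
                    runs.append(
                        SingletonRun(
                            genome_id=genome_id,
                            contig_id=contig,
                            gene_ids=tuple(g.gene_id for g in current),
                            start=current[0].start,
                            end=current[-1].end,
                        )
                    )
                current = []
    return runs
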