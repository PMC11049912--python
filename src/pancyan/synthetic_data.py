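"""Synthetic pan-genomes with planted ground truth.

The generator emulates the statistical structure of a single-species
bacterial genome collection so that every downstream stage — ANI, family
clustering, partitioning, rarefaction, co-occurrence mining, enrichment
— can be tested against a known answer:

* a core of families present in every genome, dispensable families on
  uniformly random subsets (2..G-1 genomes), and Poisson-distributed
  strain-specific singletons;
* per-genome sequence divergence ``d``: every gene (and intergenic
  spacer) is an independently mutated copy of an ancestral sequence, so
  identities and ANI are analytically predictable (no indels — copies
  are positionally alignable);
* a contiguous 8-gene anchor cluster (``anchorA``..``anchorH``) present
  in a chosen genome subset, with ``anchorA`` upstream of and divergently
  oriented to the co-directional ``anchorB``-``anchorH`` block — the
  arrangement of the nitrilase cluster *nit1C* (*nitA* regulator +
  *nitBCDEFGH*);
* planted accessory families confined exactly to the anchor subset (some
  adjacent in the gene order) and confounder families that leak into a
  few non-anchor genomes;
* one functional-category label enriched in a designated gene set by
  odds multiplication over a 20-letter COG-like background.

Genomes are emitted as one contig each, genes separated by intergenic
spacers.  Spacers descend from ancestral spacers and are dropped
together with their gene, so genomes with identical family content stay
colinear — the property the positional-divergence oracles rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import GeneAnnotation, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
#: 20-letter COG-like functional category alphabet
CATEGORY_ALPHABET = tuple("JAKLBDYVTMNZWUOCGREF")


@dataclass
class SimParams:
    """Study conditions for one simulated species.

    Defaults mirror the shape of a ~18-genome species collection with a
    7-genome anchor subset and two extra co-occurring genes (one
    adjacent pair), scaled to desk-size family counts.  ``divergence``
    0.02 puts within-species ANI near 96%.
    """

    n_genomes: int = 18
    n_core_families: int = 60
    n_dispensable_families: int = 90
    singleton_rate: float = 8.0
    gene_length_mean: int = 250  # codons
    gene_length_sd: int = 30
    divergence: float = 0.02
    anchor_subset_size: int = 7
    n_planted_cooccurring: int = 2
    adjacent_pairs: int = 1
    n_confounders: int = 3
    leak_count: int = 2
    enriched_label: str = "K"
    enriched_target_size: int = 60
    enrichment_factor: float = 6.0
    intergenic_mean: int = 120
    singleton_placement: str = "random"  # "random" | "block"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        G = self.n_genomes
        if G < 3:
            raise ValueError("need at least 3 genomes")
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if self.anchor_subset_size and not 2 <= self.anchor_subset_size < G:
            raise ValueError("anchor subset must hold 2..G-1 genomes")
        if self.leak_count >= G - self.anchor_subset_size:
            raise ValueError("leak_count must be < number of non-anchor genomes")
        if 2 * self.adjacent_pairs > self.n_planted_cooccurring:
            raise ValueError("adjacent_pairs exceed planted co-occurring families")
        if self.singleton_placement not in ("random", "block"):
            raise ValueError("singleton_placement must be 'random' or 'block'")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger written alongside every simulated dataset."""

    family_of_gene: dict[str, str]
    partition_of_family: dict[str, str]
    carriers: dict[str, set[str]]
    anchor_genomes: set[str]
    planted_cooccurring: set[str]
    confounder_families: dict[str, set[str]]
    enriched_label: str
    enriched_genes: set[str]


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def mutate_sequence(seq: str, d: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``d``.

    A substituted base becomes one of the three other bases, uniformly.
    Length is preserved; non-ACGT symbols are left untouched.
    """
    if not 0 <= d < 1:
        raise ValueError("d must be in [0, 1)")
    if not seq or d == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[arr == b] = i
    mask = (rng.random(arr.shape[0]) < d) & (code >= 0)
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        arr[mask] = _BASES[(code[mask] + shift) % 4]
    return arr.tobytes().decode()


def _random_gene(rng: np.random.Generator, mean: int, sd: int) -> str:
    n_codons = max(30, int(round(rng.normal(mean, sd))))
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate_coding(seq: str, d: float, rng: np.random.Generator) -> str:
    """Mutate a coding sequence, reverting any codon mutated into a stop."""
    out = mutate_sequence(seq, d, rng)
    if d == 0:
        return out
    codons = [out[i:i + 3] for i in range(0, len(out), 3)]
    changed = False
    for j, c in enumerate(codons):
        if c in _STOPS:
            codons[j] = seq[3 * j:3 * j + 3]
            changed = True
    return "".join(codons) if changed else out


def translate(nt: str) -> str:
    return str(Seq(nt).translate())


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


# ---------------------------------------------------------------------------
# anchor cluster
# ---------------------------------------------------------------------------

_ANCHOR_NAMES = tuple("anchor" + x for x in "ABCDEFGH")


def _anchor_ancestral(rng: np.random.Generator, params: SimParams):
    """Ancestral sequences and strands of the 8-gene anchor cluster.

    ``anchorA`` (the regulator) sits first and on the opposite strand to
    the co-directional ``anchorB``..``anchorH`` block.
    """
    genes = []
    for name in _ANCHOR_NAMES:
        strand = "-" if name == "anchorA" else "+"
        genes.append((name, _random_gene(rng, params.gene_length_mean,
                                         params.gene_length_sd), strand))
    return genes


def generate_anchor_cluster(rng: np.random.Generator,
                            params: SimParams | None = None):
    """Lay the anchor cluster on a bare contig.

    Returns ``(annotations, gene_sequences)``: eight non-overlapping,
    ordered genes (``anchorA`` first, on '-'; the rest on '+') with
    intergenic spacers, plus each gene's coding-strand sequence.
    """
    params = params or SimParams()
    genes = _anchor_ancestral(rng, params)
    annotations: list[GeneAnnotation] = []
    seqs: dict[str, str] = {}
    pos = 1
    for name, nt, strand in genes:
        spacer = max(20, int(rng.poisson(params.intergenic_mean)))
        annotations.append(
            GeneAnnotation(
                gene_id=name,
                genome_id="anchor",
                contig_id="anchor_c1",
                start=pos,
                end=pos + len(nt) - 1,
                strand=strand,
                protein=translate(nt),
                product=f"anchor cluster gene {name[-1]}",
            )
        )
        seqs[name] = nt
        pos += len(nt) + spacer
    return annotations, seqs


# ---------------------------------------------------------------------------
# whole pan-genome
# ---------------------------------------------------------------------------

def _category_probs(factor: float, label: str) -> tuple[np.ndarray, np.ndarray]:
    base = np.full(len(CATEGORY_ALPHABET), 1.0 / len(CATEGORY_ALPHABET))
    li = CATEGORY_ALPHABET.index(label)
    p = base[li]
    boosted = base.copy()
    boosted[li] = factor * p / (factor * p + 1 - p)
    rest = 1.0 - boosted[li]
    others = np.delete(np.arange(len(base)), li)
    boosted[others] = base[others] / base[others].sum() * rest
    return base, boosted


def generate_pangenome(params: SimParams):
    """Generate genomes, annotations and the truth ledger.

    Fully reproducible from ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    G = params.n_genomes
    genome_ids = [f"g{i:02d}" for i in range(1, G + 1)]
    anchor_genomes = sorted(
        rng.choice(genome_ids, size=params.anchor_subset_size, replace=False)
    ) if params.anchor_subset_size else []
    non_anchor = [g for g in genome_ids if g not in anchor_genomes]

    # --- family roster -----------------------------------------------------
    carriers: dict[str, set[str]] = {}
    strands: dict[str, str] = {}
    ancestral: dict[str, str] = {}

    core_ids = [f"CORE{i:04d}" for i in range(1, params.n_core_families + 1)]
    disp_ids = [f"DISP{i:04d}" for i in range(1, params.n_dispensable_families + 1)]
    cooc_ids = [f"COOC{i:04d}" for i in range(1, params.n_planted_cooccurring + 1)]
    conf_ids = [f"CONF{i:04d}" for i in range(1, params.n_confounders + 1)]

    for fid in core_ids:
        carriers[fid] = set(genome_ids)
    for fid in disp_ids:
        size = int(rng.integers(2, G))  # uniform 2..G-1
        carriers[fid] = set(rng.choice(genome_ids, size=size, replace=False))
    for fid in cooc_ids:
        carriers[fid] = set(anchor_genomes)
    confounder_families: dict[str, set[str]] = {}
    for fid in conf_ids:
        leaks = set(rng.choice(non_anchor, size=params.leak_count, replace=False))
        carriers[fid] = set(anchor_genomes) | leaks
        confounder_families[fid] = leaks

    anchor_fids = []
    if params.anchor_subset_size:
        for name, nt, strand in _anchor_ancestral(rng, params):
            fid = "ANCH_" + name[-1]
            anchor_fids.append(fid)
            carriers[fid] = set(anchor_genomes)
            strands[fid] = strand
            ancestral[fid] = nt

    for fid in core_ids + disp_ids + cooc_ids + conf_ids:
        ancestral[fid] = _random_gene(rng, params.gene_length_mean,
                                      params.gene_length_sd)
        strands[fid] = "+" if rng.random() < 0.5 else "-"

    # --- ancestral chromosome layout --------------------------------------
    # units are placed contiguously: the anchor block is one unit, each
    # designated co-occurring pair is one unit
    units: list[list[str]] = [[f] for f in core_ids + disp_ids + conf_ids]
    paired = cooc_ids[: 2 * params.adjacent_pairs]
    for i in range(0, len(paired), 2):
        units.append([paired[i], paired[i + 1]])
    units.extend([[f] for f in cooc_ids[2 * params.adjacent_pairs:]])
    order = rng.permutation(len(units))
    unit_layout: list[list[str]] = [units[ui] for ui in order]
    if anchor_fids:
        slot = int(rng.integers(0, len(unit_layout) + 1))
        unit_layout.insert(slot, anchor_fids)
    layout = [fid for unit in unit_layout for fid in unit]

    spacer_after = {
        fid: _random_dna(rng, max(20, int(rng.poisson(params.intergenic_mean))))
        for fid in layout
    }

    # --- per-genome assembly (categories assigned afterwards) -------------
    plans = []  # (genome_id, [(fid, nt, strand, spacer)])
    family_of_gene: dict[str, str] = {}
    for gid in genome_ids:
        # blocks preserve planted contiguity: singletons may only land
        # between blocks, never inside the anchor cluster or a pair
        blocks: list[list[list]] = []
        for unit in unit_layout:
            block = []
            for fid in unit:
                if gid not in carriers[fid]:
                    continue
                nt = _mutate_coding(ancestral[fid], params.divergence, rng)
                spacer = mutate_sequence(spacer_after[fid], params.divergence, rng)
                block.append([fid, nt, strands[fid], spacer])
            if block:
                blocks.append(block)
        n_single = int(rng.poisson(params.singleton_rate))
        singles = []
        for j in range(n_single):
            fid = f"SING_{gid}_{j:03d}"
            carriers[fid] = {gid}
            nt = _random_gene(rng, params.gene_length_mean, params.gene_length_sd)
            spacer = _random_dna(rng, max(20, int(rng.poisson(params.intergenic_mean))))
            singles.append([fid, nt, "+" if rng.random() < 0.5 else "-", spacer])
        if singles:
            if params.singleton_placement == "block":
                at = int(rng.integers(0, len(blocks) + 1))
                blocks.insert(at, singles)
            else:
                for s in singles:
                    at = int(rng.integers(0, len(blocks) + 1))
                    blocks.insert(at, [s])
        entries = [e for block in blocks for e in block]
        plans.append((gid, entries))

    # --- enriched gene set -------------------------------------------------
    all_gene_keys = []
    for gid, entries in plans:
        for serial, entry in enumerate(entries, start=1):
            all_gene_keys.append(f"{gid}_{serial:04d}")
    n_target = min(params.enriched_target_size, len(all_gene_keys))
    enriched_genes = set(
        rng.choice(all_gene_keys, size=n_target, replace=False)
    ) if params.enriched_label else set()
    base_p, boosted_p = _category_probs(params.enrichment_factor,
                                        params.enriched_label or "J")

    # --- emit genomes + annotations ----------------------------------------
    genomes: list[GenomeRecord] = []
    annotations: list[GeneAnnotation] = []
    for gid, entries in plans:
        parts: list[str] = []
        pos = 1
        for serial, (fid, nt, strand, spacer) in enumerate(entries, start=1):
            gene_id = f"{gid}_{serial:04d}"
            family_of_gene[gene_id] = fid
            probs = boosted_p if gene_id in enriched_genes else base_p
            label = CATEGORY_ALPHABET[int(rng.choice(len(CATEGORY_ALPHABET), p=probs))]
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    genome_id=gid,
                    contig_id=f"{gid}_c1",
                    start=pos,
                    end=pos + len(nt) - 1,
                    strand=strand,
                    protein=translate(nt),
                    categories=frozenset({label}),
                    product=fid,
                )
            )
            parts.append(nt if strand == "+" else revcomp(nt))
            parts.append(spacer)
            pos += len(nt) + len(spacer)
        genomes.append(GenomeRecord(gid, {f"{gid}_c1": "".join(parts)}))

    partition = {
        fid: ("core" if len(c) == G else "singleton" if len(c) == 1 else "dispensable")
        for fid, c in carriers.items()
    }
    truth = SyntheticTruth(
        family_of_gene=family_of_gene,
        partition_of_family=partition,
        carriers=carriers,
        anchor_genomes=set(anchor_genomes),
        planted_cooccurring=set(cooc_ids),
        confounder_families=confounder_families,
        enriched_label=params.enriched_label,
        enriched_genes=enriched_genes,
    )
    return genomes, annotations, truth


# ---------------------------------------------------------------------------
# small purpose-built genome sets for ANI experiments
# ---------------------------------------------------------------------------

def star_genomes(length: int, divergences: dict[str, float],
                 rng_seed: int = 0) -> list[GenomeRecord]:
    """Genomes radiating from one ancestor, each at its own divergence.

    Expected pairwise mismatch fraction between genomes at divergences
    d1 and d2 is ``d1 + d2 - (4/3) d1 d2`` (independent substitutions).
    """
    rng = np.random.default_rng(rng_seed)
    ancestor = _random_dna(rng, length)
    return [
        GenomeRecord(gid, {f"{gid}_c1": mutate_sequence(ancestor, d, rng)})
        for gid, d in divergences.items()
    ]


def clade_genomes(length: int, n_per_clade: int, clade_divergence: float,
                  within_divergence: float, n_clades: int = 2,
                  rng_seed: int = 0) -> dict[str, list[GenomeRecord]]:
    """Two-level radiation: clade ancestors from a root, genomes from each.

    Returns ``{clade_id: [GenomeRecord, ...]}``; within-clade pairs are
    closer than between-clade pairs whenever ``clade_divergence`` exceeds
    ``within_divergence``.
    """
    rng = np.random.default_rng(rng_seed)
    root = _random_dna(rng, length)
    out: dict[str, list[GenomeRecord]] = {}
    for c in range(n_clades):
        cid = f"clade{c + 1}"
        anc = mutate_sequence(root, clade_divergence, rng)
        out[cid] = [
            GenomeRecord(f"{cid}_g{i + 1}",
                         {f"{cid}_g{i + 1}_c1": mutate_sequence(anc, within_divergence, rng)})
            for i in range(n_per_clade)
        ]
    return out
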