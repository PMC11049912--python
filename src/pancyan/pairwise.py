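"""Pairwise alignment primitives shared by ANI, clustering, and screening.

Two aligners are exposed:

* :func:`align_global` — optimal global alignment with free terminal gaps
  (semi-global), affine gap penalties, nucleotide +1/-1 scoring or a
  protein substitution matrix (BLOSUM62 by default).
* :func:`align_local_seeded` — k-mer seeded, banded alignment of a short
  fragment inside a long target; this is the workhorse of fragment-based
  ANI and deliberately returns ``None`` when no seed diagonal exists.

Identity is defined as matches over *internal* alignment columns:
internal gaps count in the denominator, terminal overhangs do not.  Query
coverage is the fraction of query residues inside the internal region.
Both conventions are stated here once and used everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentInputError
from .io_formats import NUCLEOTIDES, RunConfig

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/coverage summary of one pairwise alignment."""

    query_id: str
    target_id: str
    matches: int
    alignment_columns: int
    query_aligned: int
    identity: float
    query_coverage: float
    score: float
    target_coverage: float = 0.0

    def __post_init__(self) -> None:
        assert 0 <= self.identity <= 100
        assert 0 <= self.query_coverage <= 100
        assert self.matches <= self.alignment_columns


@lru_cache(maxsize=16)
def _make_aligner(protein: bool, match: float, mismatch: float,
                  gap_open: float, gap_extend: float, matrix_name: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if protein:
        aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free terminal gaps: global alignment degrades gracefully to overlap
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _is_protein(seq: str) -> bool:
    return not set(seq) <= NUCLEOTIDES


def align_global(a: str, b: str, config: RunConfig | None = None,
                 protein: bool | None = None,
                 query_id: str = "query", target_id: str = "target") -> AlignmentResult:
    """Semi-global alignment of ``a`` (query) against ``b`` (target).

    Tie-breaking between co-optimal alignments is resolved by the
    aligner's canonical traceback order, which is deterministic.
    """
    if not a or not b:
        raise AlignmentInputError("align_global requires non-empty sequences")
    config = config or RunConfig()
    if protein is None:
        protein = _is_protein(a) or _is_protein(b)
    if protein != (_is_protein(a) or _is_protein(b)) and protein is False:
        raise AlignmentInputError("non-nucleotide symbols with protein=False")
    aligner = _make_aligner(
        protein,
        config.match_score,
        config.mismatch_score,
        config.gap_open,
        config.gap_extend,
        config.protein_matrix,
    )
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    n = len(sa)
    i0 = 0
    while i0 < n and (sa[i0] == "-" or sb[i0] == "-"):
        i0 += 1
    i1 = n
    while i1 > i0 and (sa[i1 - 1] == "-" or sb[i1 - 1] == "-"):
        i1 -= 1
    columns = i1 - i0
    if columns == 0:
        return AlignmentResult(query_id, target_id, 0, 0, 0, 0.0, 0.0, aln.score, 0.0)
    matches = sum(1 for x, y in zip(sa[i0:i1], sb[i0:i1]) if x == y and x != "-")
    query_aligned = sum(1 for x in sa[i0:i1] if x != "-")
    target_aligned = sum(1 for x in sb[i0:i1] if x != "-")
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        matches=matches,
        alignment_columns=columns,
        query_aligned=query_aligned,
        identity=100.0 * matches / columns,
        query_coverage=100.0 * query_aligned / len(a),
        score=float(aln.score),
        target_coverage=100.0 * target_aligned / len(b),
    )


class KmerIndex:
    """Exact k-mer position index over one nucleotide sequence.

    Positions per k-mer are capped so a low-complexity target cannot
    blow up seeding; the cap is far above anything a 15-mer reaches in
    genomes of the sizes handled here.
    """

    def __init__(self, target: str, k: int, max_positions: int = 64) -> None:
        if k < 4:
            raise AlignmentInputError("k-mer size must be >= 4")
        self.target = target
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            kmer = target[i:i + k]
            hits = index.setdefault(kmer, [])
            if len(hits) < max_positions:
                hits.append(i)
        self._index = index

    def diagonal_votes(self, fragment: str, stride: int = 1) -> dict[int, int]:
        """Count seed hits per diagonal (target offset minus query offset)."""
        votes: dict[int, int] = {}
        k = self.k
        for i in range(0, len(fragment) - k + 1, stride):
            for pos in self._index.get(fragment[i:i + k], ()):
                d = pos - i
                votes[d] = votes.get(d, 0) + 1
        return votes


def _expand_cigar(cigar: str) -> str:
    """Extended CIGAR to one op character per alignment column."""
    return "".join(op * int(count) for count, op in _CIGAR_RE.findall(cigar))


# per-column scores for best-segment extraction: matches must outweigh
# noise (random nucleotide alignments run at ~50-55% matches, which
# scores negative here), so segments do not extend into unrelated flanks
_SEGMENT_SCORE = {"=": 1.0, "X": -2.0, "M": -2.0, "I": -3.0, "D": -3.0}


def _best_segment(ops: str) -> tuple[int, int, float]:
    """Maximum-scoring contiguous run of alignment columns (Kadane)."""
    best_score = cur = 0.0
    best = (0, 0)
    start = 0
    for i, op in enumerate(ops):
        cur += _SEGMENT_SCORE[op]
        if cur <= 0:
            cur = 0.0
            start = i + 1
        elif cur > best_score:
            best_score = cur
            best = (start, i + 1)
    return best[0], best[1], best_score


def align_local_seeded(fragment: str, target: str, k: int = 15,
                       stride: int = 1, min_seed_hits: int = 1,
                       index: KmerIndex | None = None,
                       query_id: str = "fragment",
                       target_id: str = "target") -> AlignmentResult | None:
    """Locate and align ``fragment`` inside ``target`` via k-mer seeding.

    Shared k-mers vote for diagonals; the best-supported diagonal is
    realigned in a padded band with edit-distance alignment, and the
    maximum-scoring contiguous segment of that alignment is reported
    (a local alignment: a fragment that is only partly homologous to
    the target yields a segment with query coverage < 100%).  Returns
    ``None`` when no diagonal collects at least ``min_seed_hits`` seeds
    — unrelated sequences fall out here, mimicking a search tool
    reporting no significant hit.

    A prebuilt :class:`KmerIndex` over ``target`` may be supplied to
    amortize indexing across many fragments.
    """
    if not fragment or not target:
        raise AlignmentInputError("empty sequence")
    if k > len(fragment):
        raise AlignmentInputError(
            f"k={k} larger than fragment length {len(fragment)}"
        )
    if index is None:
        index = KmerIndex(target, k)
    votes = index.diagonal_votes(fragment, stride=stride)
    if not votes:
        return None
    best_diag, nhits = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    if nhits < min_seed_hits:
        return None
    pad = 30 + len(fragment) // 20
    lo = max(0, best_diag - pad)
    hi = min(len(target), best_diag + len(fragment) + pad)
    window = target[lo:hi]
    res = edlib.align(fragment, window, mode="HW", task="path")
    ops = _expand_cigar(res["cigar"])
    s0, s1, score = _best_segment(ops)
    if s1 == s0:
        return None
    seg = ops[s0:s1]
    matches = seg.count("=")
    columns = len(seg)
    query_aligned = columns - seg.count("D")
    target_aligned = columns - seg.count("I")
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        matches=matches,
        alignment_columns=columns,
        query_aligned=query_aligned,
        identity=100.0 * matches / columns,
        query_coverage=100.0 * query_aligned / len(fragment),
        score=score,
        target_coverage=100.0 * target_aligned / len(target),
    )
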