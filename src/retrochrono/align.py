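"""Pairwise alignment helpers shared by the detection, clustering and dating
stages.

All nucleotide comparisons use global alignment with free end gaps (terminal
overhangs are not penalised and never counted as aligned sites); identity and
divergence are computed over gap-free aligned columns only.
"""

from __future__ import annotations

from typing import NamedTuple

from Bio import Align
from Bio.Align import substitution_matrices


class PairwiseStats(NamedTuple):
    identity: float  # matches / gap-free aligned columns
    aligned_sites: int  # gap-free aligned columns
    matches: int
    coverage_a: float  # gap-free aligned columns / len(a)
    coverage_b: float
    score: float


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    # free end gaps: local-like ends, global core
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 spelling
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_NT_ALIGNER = _nt_aligner()


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_PROT_ALIGNER = _protein_aligner()


def _count_block_matches(a: str, b: str, aligned) -> tuple[int, int]:
    """Matches and total columns over the gap-free aligned blocks."""
    matches = 0
    total = 0
    for (ta, tb), (qa, qb) in zip(aligned[0], aligned[1]):
        total += tb - ta
        sub_a = a[ta:tb]
        sub_b = b[qa:qb]
        matches += sum(x == y for x, y in zip(sub_a, sub_b))
    return matches, total


def align_pair(a: str, b: str) -> PairwiseStats:
    """Global free-end-gap alignment of two nucleotide sequences."""
    if not a or not b:
        return PairwiseStats(0.0, 0, 0, 0.0, 0.0, 0.0)
    alignment = _NT_ALIGNER.align(a, b)[0]
    matches, total = _count_block_matches(a, b, alignment.aligned)
    identity = matches / total if total else 0.0
    return PairwiseStats(
        identity=identity,
        aligned_sites=total,
        matches=matches,
        coverage_a=total / len(a),
        coverage_b=total / len(b),
        score=alignment.score,
    )


def divergence(a: str, b: str) -> tuple[float, int]:
    """Observed proportion of mismatched sites (p) and the number of gap-free
    aligned columns, under global free-end-gap alignment."""
    stats = align_pair(a, b)
    if stats.aligned_sites == 0:
        return 0.0, 0
    p = 1.0 - stats.matches / stats.aligned_sites
    return p, stats.aligned_sites


class ProteinHit(NamedTuple):
    score: float
    query_start: int  # on the translated frame, aa coordinates
    query_end: int
    ref_start: int
    ref_end: int
    identity: float


def align_protein_local(query: str, ref: str) -> ProteinHit | None:
    """Best local alignment of a translated frame against a protein reference.

    Returns None for empty inputs or a non-positive best score.
    """
    if not query or not ref:
        return None
    try:
        best = _PROT_ALIGNER.align(query, ref)[0]
    except (ValueError, IndexError):  # letters outside the matrix alphabet
        return None
    if best.score <= 0:
        return None
    blocks = best.aligned
    matches, total = _count_block_matches(query, ref, blocks)
    return ProteinHit(
        score=float(best.score),
        query_start=int(blocks[0][0][0]),
        query_end=int(blocks[0][-1][1]),
        ref_start=int(blocks[1][0][0]),
        ref_end=int(blocks[1][-1][1]),
        identity=matches / total if total else 0.0,
    )
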