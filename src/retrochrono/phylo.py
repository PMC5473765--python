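"""Neighbor-joining trees on RT sequences and nearest-seed lineage calls.

Distances are uncorrected pairwise p-distances on aligned sequences
(amino-acid by default).  NJ uses the Q criterion with standard branch-length
formulas; ties break to the smallest label-index pair and negative branch
lengths are clamped at zero with the deficit recorded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import align_pair, divergence
from .ioutils import revcomp


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class UnrootedTree:
    root: TreeNode  # arbitrary internal node used for serialization
    labels: list[str]
    clamped_deficit: float = 0.0  # total negative branch length clamped to 0

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(
                f"{render(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner}){node.name}"

        return render(self.root) + ";"

    def total_branch_length(self) -> float:
        total = 0.0

        def walk(node: TreeNode):
            nonlocal total
            for child, length in node.children:
                total += length
                walk(child)

        walk(self.root)
        return total

    def leaf_names(self) -> list[str]:
        names = []

        def walk(node: TreeNode):
            if node.is_leaf():
                names.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return names


# ---------------------------------------------------------------------------
# RT extraction and alignment


def extract_rt(internal: str, rt_hit) -> tuple[str, bool]:
    """Translate the RT hit's interval in its frame/strand.

    Returns (protein, clean) where ``clean`` is False when the translation
    contains internal stop codons.
    """
    if rt_hit.domain != "RT":
        raise ValueError("hit is not an RT hit")
    sub = internal[rt_hit.start : rt_hit.end]
    if rt_hit.strand == "-":
        sub = revcomp(sub)
    sub = sub[: len(sub) - len(sub) % 3]
    protein = str(Seq(sub).translate())
    clean = "*" not in protein.rstrip("*")
    return protein, clean


def align_sequences(seqs: Mapping[str, str]) -> dict[str, str]:
    """Center-star progressive multiple alignment (greedy guide).

    The center is the sequence with the highest summed pairwise identity;
    every other sequence is aligned to it and gaps are merged.  Exact for
    gap-free inputs of equal length; adequate as a guide alignment elsewhere.
    """
    labels = sorted(seqs)
    if len(labels) < 2:
        return {label: seqs[label] for label in labels}
    if len({len(seqs[label]) for label in labels}) == 1:
        return {label: seqs[label] for label in labels}  # already flush

    sums = {}
    for a in labels:
        sums[a] = sum(
            align_pair(seqs[a], seqs[b]).identity for b in labels if b != a
        )
    center = max(labels, key=lambda l: (sums[l], l))

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5

    center_seq = seqs[center]
    # rows as lists of columns; center gap structure merged across alignments
    center_cols = list(center_seq)
    rows: dict[str, list[str]] = {center: list(center_seq)}
    for label in labels:
        if label == center:
            continue
        alignment = aligner.align(center_seq, seqs[label])[0]
        a_center, a_other = str(alignment[0]), str(alignment[1])
        # merge: walk existing columns and the new alignment simultaneously
        merged_center: list[str] = []
        new_rows: dict[str, list[str]] = {k: [] for k in rows}
        new_row: list[str] = []
        i = j = 0  # i over center_cols, j over a_center
        while i < len(center_cols) or j < len(a_center):
            old = center_cols[i] if i < len(center_cols) else None
            new = a_center[j] if j < len(a_center) else None
            if old == "-" and new != "-":
                merged_center.append("-")
                for k in rows:
                    new_rows[k].append(rows[k][i])
                new_row.append("-")
                i += 1
            elif new == "-" and old != "-":
                merged_center.append("-")
                for k in rows:
                    new_rows[k].append("-")
                new_row.append(a_other[j])
                j += 1
            else:
                merged_center.append(old if old is not None else "-")
                for k in rows:
                    new_rows[k].append(rows[k][i] if i < len(center_cols) else "-")
                new_row.append(a_other[j] if j < len(a_center) else "-")
                i += 1
                j += 1
        center_cols = merged_center
        rows = new_rows
        rows[label] = new_row
    width = len(center_cols)
    return {label: "".join(row).ljust(width, "-") for label, row in rows.items()}


def p_distance_matrix(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Uncorrected pairwise distances: mismatches / gap-free shared columns.

    Pairs with no gap-free shared columns get distance NaN (degenerate,
    flagged for the caller)."""
    labels = sorted(aligned)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(aligned[label]) for label in labels}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    arrays = {
        label: np.frombuffer(aligned[label].encode("ascii"), dtype=np.uint8)
        for label in labels
    }
    gap = ord("-")
    n = len(labels)
    matrix = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = arrays[labels[i]], arrays[labels[j]]
        shared = (a != gap) & (b != gap)
        total = int(shared.sum())
        if total == 0:
            matrix[i, j] = matrix[j, i] = float("nan")
            continue
        mism = int(((a != b) & shared).sum())
        matrix[i, j] = matrix[j, i] = mism / total
    if np.isnan(matrix).any():
        raise ValueError("all-gap overlap between some pair: distances undefined")
    return DistanceMatrix(labels=labels, matrix=matrix)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Canonical NJ: minimize Q = (n-2) d(i,j) - r_i - r_j, join, update with
    the standard reduction formulas; final three nodes join at one internal
    vertex, giving an unrooted (trifurcating-root) tree."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    size = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m - 1):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i][j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        vi = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i][j] - vi
        new = TreeNode(
            children=[(nodes[i], clamp(vi)), (nodes[j], clamp(vj))]
        )
        # grow the matrix with the new node's row
        new_index = size
        size += 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_index][k] = d[k][new_index] = 0.5 * (d[i][k] + d[j][k] - d[i][j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    bi = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    bj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    bk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    root = TreeNode(
        children=[
            (nodes[i], clamp(bi)),
            (nodes[j], clamp(bj)),
            (nodes[k], clamp(bk)),
        ]
    )
    return UnrootedTree(root=root, labels=list(dm.labels), clamped_deficit=deficit)


# ---------------------------------------------------------------------------
# lineage assignment and display filtering


def assign_lineages(
    rt_seqs: Mapping[str, str],
    lineage_seeds: Mapping[str, Sequence[str] | str],
    tie_tolerance: float = 1e-9,
) -> dict[str, str]:
    """Nearest-seed lineage call by minimum p-distance; exact ties are
    reported as 'unassigned'."""
    if not lineage_seeds:
        raise ValueError("no lineage seed sequences supplied")
    seeds: list[tuple[str, str]] = []
    for lineage, entries in sorted(lineage_seeds.items()):
        entries = [entries] if isinstance(entries, str) else list(entries)
        for seq in entries:
            seeds.append((lineage, seq))
    out = {}
    for label in sorted(rt_seqs):
        dists: dict[str, float] = {}
        for lineage, seed in seeds:
            p, sites = divergence(rt_seqs[label], seed)
            if sites == 0:
                continue
            dists[lineage] = min(dists.get(lineage, math.inf), p)
        if not dists:
            out[label] = "unassigned"
            continue
        ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ranked) > 1 and ranked[1][1] - ranked[0][1] <= tie_tolerance:
            out[label] = "unassigned"
        else:
            out[label] = ranked[0][0]
    return out


def filter_redundant(
    seqs: Mapping[str, str], max_identity: float = 0.99
) -> dict[str, str]:
    """Greedy display filtering: drop sequences >= max_identity to a kept one.

    Never applied to analysis outputs, only to what gets drawn."""
    kept: dict[str, str] = {}
    for label in sorted(seqs):
        redundant = any(
            align_pair(seqs[label], other).identity >= max_identity
            for other in kept.values()
        )
        if not redundant:
            kept[label] = seqs[label]
    return kept
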