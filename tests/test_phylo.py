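import itertools

import dendropy
import numpy as np
import pytest

from retrochrono import synth
from retrochrono.ioutils import revcomp
from retrochrono.phylo import (
    DistanceMatrix,
    align_sequences,
    assign_lineages,
    extract_rt,
    filter_redundant,
    neighbor_joining,
    p_distance_matrix,
)
from retrochrono.taxonomy import DomainHit, scan_domains


def random_protein(rng, n):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, len(aa), n))


def mutate_protein(seq, frac, rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = list(seq)
    for i in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
        alternatives = aa.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


# ---------------------------------------------------------------------------
# oracle: enumerate unrooted topologies + least-squares branch fit


def enumerate_topologies(labels):
    """All unrooted binary topologies as edge lists over leaf/internal ids."""
    if len(labels) == 3:
        yield [(labels[0], "i0"), (labels[1], "i0"), (labels[2], "i0")]
        return
    for smaller in enumerate_topologies(labels[:-1]):
        new_leaf = labels[-1]
        for k, (u, v) in enumerate(smaller):
            hub = f"i{len(smaller)}"
            edges = [e for i, e in enumerate(smaller) if i != k]
            edges += [(u, hub), (v, hub), (new_leaf, hub)]
            yield edges


def tree_paths(edges, leaves):
    """Leaf-to-leaf path (as edge index sets) for least-squares fitting."""
    adjacency = {}
    for idx, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, idx))
        adjacency.setdefault(v, []).append((u, idx))
    paths = {}
    for a, b in itertools.combinations(leaves, 2):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if node == b:
                paths[(a, b)] = used
                break
            for nxt, edge_idx in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [edge_idx]))
    return paths


def best_ls_topology(dm: DistanceMatrix):
    """Brute force: the topology (with fitted branch lengths) minimizing SSE."""
    leaves = dm.labels
    index = {label: i for i, label in enumerate(leaves)}
    best = None
    for edges in enumerate_topologies(list(leaves)):
        paths = tree_paths(edges, leaves)
        pairs = sorted(paths)
        design = np.zeros((len(pairs), len(edges)))
        target = np.zeros(len(pairs))
        for row, (a, b) in enumerate(pairs):
            for edge_idx in paths[(a, b)]:
                design[row, edge_idx] = 1.0
            target[row] = dm.matrix[index[a], index[b]]
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        sse = float(((design @ coef - target) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, edges, coef)
    return best


def canonical_split(side, leaves):
    """A bipartition and its complement are the same split; keep the side
    not containing the lexicographically smallest leaf."""
    side = frozenset(side)
    anchor = min(leaves)
    return frozenset(leaves - side) if anchor in side else side


def splits_from_edges(edges, leaves):
    out = set()
    adjacency = {}
    for idx, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, idx))
        adjacency.setdefault(v, []).append((u, idx))
    for idx, (u, v) in enumerate(edges):
        side = set()
        stack = [u]
        seen = {v, u}
        while stack:
            node = stack.pop()
            if node in leaves:
                side.add(node)
            for nxt, eidx in adjacency.get(node, []):
                if eidx != idx and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < len(leaves) - 1:
            out.add(canonical_split(side, frozenset(leaves)))
    return out


def splits_from_newick(newick, leaves):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.parent_node is None:
            continue
        side = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        if 1 < len(side) < len(leaves) - 1:
            out.add(canonical_split(side, frozenset(leaves)))
    return out


def random_additive_matrix(labels, rng):
    """Distances from a random unrooted binary tree with positive branches."""
    topologies = list(enumerate_topologies(list(labels)))
    edges = topologies[rng.integers(0, len(topologies))]
    lengths = rng.uniform(0.5, 3.0, len(edges))
    paths = tree_paths(edges, labels)
    n = len(labels)
    matrix = np.zeros((n, n))
    index = {label: i for i, label in enumerate(labels)}
    for (a, b), edge_idxs in paths.items():
        dist = sum(lengths[i] for i in edge_idxs)
        matrix[index[a], index[b]] = matrix[index[b], index[a]] = dist
    return DistanceMatrix(list(labels), matrix), edges, lengths


class TestPDistance:
    def test_identical_pair(self):
        dm = p_distance_matrix({"a": "MKLV", "b": "MKLV"})
        assert dm.matrix[0, 1] == 0.0

    def test_one_in_ten(self):
        dm = p_distance_matrix({"a": "AAAAAAAAAA", "b": "AAAAAAAAAC"})
        assert dm.matrix[0, 1] == pytest.approx(0.1)

    def test_gap_columns_excluded(self):
        dm = p_distance_matrix({"a": "AA--AA", "b": "AACCAA"})
        assert dm.matrix[0, 1] == 0.0

    def test_all_gap_overlap_flagged(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "AA--", "b": "--AA"})

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "AAA"})

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "AAA", "b": "AAAA"})


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        tree = neighbor_joining(dm)
        # three-point solution: a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 4
        lengths = {child.name: length for child, length in tree.root.children}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(4.0)}

    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,C:4,D:5) -> additive matrix
        dm = DistanceMatrix(["A", "B", "C", "D"], np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float))
        tree = neighbor_joining(dm)
        assert splits_from_newick(tree.to_newick(), dm.labels) == {
            canonical_split({"A", "B"}, frozenset(dm.labels))
        }
        assert tree.total_branch_length() == pytest.approx(15.0)
        assert tree.clamped_deficit == 0.0

    def test_zero_matrix_star_tree(self):
        dm = DistanceMatrix(list("ABCD"), np.zeros((4, 4)))
        tree = neighbor_joining(dm)
        assert tree.total_branch_length() == 0.0

    @pytest.mark.parametrize("n", [5, 6])
    def test_additive_recovery_matches_enumeration_oracle(self, n):
        labels = [f"t{i}" for i in range(n)]
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            dm, true_edges, _ = random_additive_matrix(labels, rng)
            tree = neighbor_joining(dm)
            sse, oracle_edges, _ = best_ls_topology(dm)
            assert sse < 1e-12  # matrix is additive
            nj_splits = splits_from_newick(tree.to_newick(), labels)
            assert nj_splits == splits_from_edges(oracle_edges, set(labels))
            assert nj_splits == splits_from_edges(true_edges, set(labels))

    def test_branch_lengths_exact_on_additive_input(self):
        labels = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(11)
        dm, _, lengths = random_additive_matrix(labels, rng)
        tree = neighbor_joining(dm)
        assert tree.total_branch_length() == pytest.approx(lengths.sum())

    def test_label_order_invariance(self):
        labels = [f"t{i}" for i in range(6)]
        rng = np.random.default_rng(12)
        dm, _, _ = random_additive_matrix(labels, rng)
        total = neighbor_joining(dm).total_branch_length()
        perm = [3, 1, 5, 0, 4, 2]
        dm2 = DistanceMatrix(
            [labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        assert neighbor_joining(dm2).total_branch_length() == pytest.approx(total)

    def test_newick_round_trip(self):
        labels = [f"t{i}" for i in range(7)]
        rng = np.random.default_rng(13)
        dm, _, _ = random_additive_matrix(labels, rng)
        tree = neighbor_joining(dm)
        reparsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert sorted(l.taxon.label for l in reparsed.leaf_node_iter()) == labels
        total = sum(e.length or 0 for e in reparsed.preorder_edge_iter())
        assert total == pytest.approx(tree.total_branch_length())

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestExtractRt:
    def test_planted_rt_recovered_verbatim(self, fresh_genome):
        el = fresh_genome.truth[0]
        internal = fresh_genome.sequence[
            el.realized_coords["ltr5"][1] : el.realized_coords["ltr3"][0]
        ]
        hits = scan_domains(internal, synth.domain_references())
        rt_hit = next(h for h in hits if h.domain == "RT")
        protein, clean = extract_rt(internal, rt_hit)
        assert clean
        assert protein == synth.family_domain_proteins("fresh")["RT"]

    def test_minus_strand_translation(self, fresh_genome):
        el = fresh_genome.truth[0]
        internal = fresh_genome.sequence[
            el.realized_coords["ltr5"][1] : el.realized_coords["ltr3"][0]
        ]
        flipped = revcomp(internal)
        hits = scan_domains(flipped, synth.domain_references())
        rt_hit = next(h for h in hits if h.domain == "RT")
        assert rt_hit.strand == "-"
        protein, clean = extract_rt(flipped, rt_hit)
        assert clean
        assert protein == synth.family_domain_proteins("fresh")["RT"]

    def test_non_rt_hit_rejected(self):
        hit = DomainHit(domain="PR", start=0, end=30, score=10, frame=0, strand="+")
        with pytest.raises(ValueError):
            extract_rt("ACG" * 100, hit)


class TestAlignSequences:
    def test_gap_free_equal_length_passthrough(self):
        seqs = {"a": "MKLV", "b": "MRLV", "c": "MKLI"}
        assert align_sequences(seqs) == seqs

    def test_center_star_handles_indel(self):
        seqs = {"a": "MKKKLVVE", "b": "MKKKVVE", "c": "MKKKLVVE"}
        aligned = align_sequences(seqs)
        widths = {len(s) for s in aligned.values()}
        assert len(widths) == 1
        assert aligned["b"].replace("-", "") == "MKKKVVE"


class TestLineages:
    def test_exact_seed_match(self):
        rng = np.random.default_rng(1)
        seed_seq = random_protein(rng, 100)
        out = assign_lineages({"x": seed_seq}, {"Tat": [seed_seq]})
        assert out["x"] == "Tat"

    def test_equidistant_tie_unassigned(self):
        out = assign_lineages({"x": "AAAA"}, {"L1": ["AAAC"], "L2": ["AAAG"]})
        assert out["x"] == "unassigned"

    def test_mutated_seeds_fully_recovered(self):
        rng = np.random.default_rng(2)
        seeds = {f"L{i}": [random_protein(rng, 120)] for i in range(4)}
        queries = {}
        truth = {}
        for lineage, (seed_seq,) in seeds.items():
            for copy in range(5):
                name = f"{lineage}_{copy}"
                queries[name] = mutate_protein(seed_seq, 0.10, rng)
                truth[name] = lineage
        out = assign_lineages(queries, seeds)
        assert out == truth

    def test_no_seeds_unavailable(self):
        with pytest.raises(ValueError):
            assign_lineages({"x": "AAAA"}, {})


class TestRedundancyFilter:
    def test_identical_dropped(self):
        seqs = {"a": "MKLVMKLV", "b": "MKLVMKLV", "c": "WWWWYYYY"}
        kept = filter_redundant(seqs)
        assert set(kept) == {"a", "c"}

    def test_distinct_kept(self):
        rng = np.random.default_rng(3)
        seqs = {"a": random_protein(rng, 50), "b": random_protein(rng, 50)}
        assert set(filter_redundant(seqs)) == {"a", "b"}
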