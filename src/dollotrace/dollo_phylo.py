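"""Dollo parsimony tree inference from binary presence/absence characters.

Under Dollo parsimony each derived state (an insertion) arises exactly once
on the tree and may be lost any number of times.  With the tree polarized by
a hypothetical all-absent ancestor, the minimal cost of one character is

    cost = 1 (the single gain, on the edge entering the MRCA of present
              leaves) + the number of edges leaving the spanning subtree of
              present leaves into subtrees with no present leaf,

or 0 for an all-absent character.

Search machinery: an exact exhaustive search for up to 8 taxa, and a
heuristic search (random-addition stepwise insertion followed by
nearest-neighbor-interchange hill climbing, 50 replicates by default) for
larger matrices.  Clade support comes from bootstrap resampling of matrix
columns, mapped onto the best tree as rooted-clade frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .core import PresenceMatrix, ValidationError, character_masks
from .tree import Tree, TreeNode

__all__ = [
    "dollo_character_cost",
    "brute_force_dollo_cost",
    "dollo_tree_length",
    "dollo_score",
    "DolloScore",
    "exhaustive_search",
    "heuristic_search",
    "bootstrap_support",
    "rf_distance",
]

EXHAUSTIVE_MAX_TAXA = 8
BRUTE_FORCE_MAX_INTERNAL = 12


# ------------------------------------------------------------ mask evaluator
def _topology_arrays(topo) -> tuple[np.ndarray, np.ndarray]:
    """Postorder leaf-set bitmasks and parent indices for a nested-tuple
    topology over leaf indices.  The ingroup root is the last node; its
    parent (the hypothetical ancestor) is encoded as -1."""
    leafsets: list[int] = []
    parent: list[int] = []

    def rec(t) -> int:
        if not isinstance(t, tuple):
            leafsets.append(1 << t)
            parent.append(-1)
            return len(leafsets) - 1
        a = rec(t[0])
        b = rec(t[1])
        leafsets.append(leafsets[a] | leafsets[b])
        parent.append(-1)
        idx = len(leafsets) - 1
        parent[a] = idx
        parent[b] = idx
        return idx

    rec(topo)
    return np.array(leafsets, dtype=np.uint64), np.array(parent, dtype=np.int64)


def _masks_length(
    leafsets: np.ndarray, parent: np.ndarray, masks: np.ndarray
) -> tuple[int, np.ndarray]:
    """Total Dollo length and per-character costs for one topology.

    For a character with present-leaf bitmask m:
      on[v]   — subtree of v contains a present leaf;
      T       — number of nodes whose subtree contains *all* present leaves
                (the MRCA plus its strict ancestors, which each shed exactly
                one on->off edge that is not a loss);
      E0      — edges from an on node into an off subtree.
    cost = 1 + (E0 - (T - 1)) = E0 - T + 2 for non-empty characters.
    """
    ls = leafsets[:, None]
    m = masks[None, :]
    on = (ls & m) != 0
    T = ((ls & m) == m).sum(axis=0)
    nonroot = parent >= 0
    E0 = (on[parent[nonroot]] & ~on[nonroot]).sum(axis=0)
    costs = np.where(masks != 0, E0 - T + 2, 0)
    return int(costs.sum()), costs


def _topology_length(topo, masks: np.ndarray) -> int:
    leafsets, parent = _topology_arrays(topo)
    return _masks_length(leafsets, parent, masks)[0]


def _tree_arrays(tree: Tree) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Leaf-set bitmasks and parent indices for a (possibly non-binary) Tree."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    leaf_bit: dict[str, int] = {}
    leafsets = np.zeros(len(nodes), dtype=np.uint64)
    parent = np.full(len(nodes), -1, dtype=np.int64)
    for i, node in enumerate(nodes):
        if node.is_leaf:
            bit = len(leaf_bit)
            leaf_bit[node.name] = bit
            leafsets[i] = np.uint64(1 << bit)
        else:
            acc = np.uint64(0)
            for child in node.children:
                acc |= leafsets[index[id(child)]]
            leafsets[i] = acc
        if node.parent is not None:
            parent[index[id(node)]] = index[id(node.parent)]
    return leafsets, parent, leaf_bit


def _character_mask(
    character: Mapping[str, int], leaf_bit: dict[str, int]
) -> np.uint64:
    missing = [name for name in leaf_bit if name not in character]
    if missing:
        raise ValidationError(
            f"character vector is missing leaves: {sorted(missing)}"
        )
    mask = 0
    for name, bit in leaf_bit.items():
        if character[name]:
            mask |= 1 << bit
    return np.uint64(mask)


# -------------------------------------------------------------- single costs
def dollo_character_cost(tree: Tree, character: Mapping[str, int]) -> int:
    """Minimal number of state changes for one binary character under Dollo
    parsimony (exactly one 0->1 gain, any number of 1->0 losses), with the
    hypothetical ancestor above the root fixed at state 0."""
    leafsets, parent, leaf_bit = _tree_arrays(tree)
    mask = _character_mask(character, leaf_bit)
    total, _ = _masks_length(leafsets, parent, np.array([mask], dtype=np.uint64))
    return total


def brute_force_dollo_cost(tree: Tree, character: Mapping[str, int]) -> int:
    """Verification oracle: enumerate every internal-node state assignment
    (hypothetical ancestor fixed at 0), discard assignments with more than
    one 0->1 edge, and return the minimal number of changed edges.

    Refuses trees with more than 12 internal nodes (combinatorial guard).
    """
    internals = tree.internal_nodes()
    if len(internals) > BRUTE_FORCE_MAX_INTERNAL:
        raise ValidationError(
            f"brute force limited to {BRUTE_FORCE_MAX_INTERNAL} internal nodes"
        )
    leaf_names = set(tree.leaf_names())
    missing = leaf_names - set(character)
    if missing:
        raise ValidationError(f"character vector is missing leaves: {sorted(missing)}")
    if not any(character[n] for n in leaf_names):
        return 0

    internal_index = {id(n): i for i, n in enumerate(internals)}
    edges: list[tuple[TreeNode, TreeNode]] = [
        (n.parent, n) for n in tree.postorder() if n.parent is not None
    ]

    def state(node: TreeNode, assignment) -> int:
        if node.is_leaf:
            return int(character[node.name])
        return assignment[internal_index[id(node)]]

    best: Optional[int] = None
    for assignment in product((0, 1), repeat=len(internals)):
        changes = 0
        gains = 0
        # edge from the hypothetical ancestor (state 0) into the root
        root_state = state(tree.root, assignment)
        if root_state == 1:
            changes += 1
            gains += 1
        for parent_node, child in edges:
            ps, cs = state(parent_node, assignment), state(child, assignment)
            if ps != cs:
                changes += 1
                if cs == 1:
                    gains += 1
        if gains > 1:
            continue
        if best is None or changes < best:
            best = changes
    assert best is not None  # the all-zero assignment is always admissible
    return best


# ------------------------------------------------------------- matrix scores
@dataclass
class DolloScore:
    """Total tree length with its per-character decomposition.

    For each character: ``gains`` is 1 when the character is present in at
    least one taxon (it arises exactly once) and 0 otherwise; ``losses`` is
    the number of 1->0 edges in the minimal reconstruction.
    """

    total_length: int
    gains: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        if self.total_length != int(self.gains.sum() + self.losses.sum()):
            raise ValidationError("Dollo score decomposition does not add up")


def dollo_tree_length(tree: Tree, matrix: PresenceMatrix) -> int:
    return dollo_score(tree, matrix).total_length


def dollo_score(tree: Tree, matrix: PresenceMatrix) -> DolloScore:
    """Score a tree against a presence matrix."""
    leafsets, parent, leaf_bit = _tree_arrays(tree)
    if set(leaf_bit) != set(matrix.samples):
        raise ValidationError("tree leaves do not match matrix samples")
    # reorder matrix bits to the tree's leaf numbering
    bits = matrix.values != 0
    masks = np.zeros(matrix.n_loci, dtype=np.uint64)
    for row, sample in enumerate(matrix.samples):
        masks |= bits[row].astype(np.uint64) << np.uint64(leaf_bit[sample])
    total, costs = _masks_length(leafsets, parent, masks)
    gains = (masks != 0).astype(np.int64)
    losses = costs - gains
    return DolloScore(total_length=total, gains=gains, losses=losses)


# -------------------------------------------------------------- tree search
def _canonical_masks(matrix: PresenceMatrix) -> tuple[list[str], np.ndarray]:
    """Character bitmasks over alphabetically ordered samples, so search
    results do not depend on matrix row order."""
    samples = sorted(matrix.samples)
    reordered = PresenceMatrix(matrix.df.loc[samples])
    return samples, character_masks(reordered)


def _all_topologies(n: int) -> Iterator:
    """Every rooted binary topology over leaf indices 0..n-1 ((2n-3)!! trees),
    generated by inserting each new leaf on every edge plus above the root."""

    def insert_everywhere(topo, leaf) -> Iterator:
        yield (topo, leaf)
        if isinstance(topo, tuple):
            left, right = topo
            for new_left in insert_everywhere(left, leaf):
                yield (new_left, right)
            for new_right in insert_everywhere(right, leaf):
                yield (left, new_right)

    def rec(k: int) -> Iterator:
        if k == 1:
            yield 0
            return
        for smaller in rec(k - 1):
            yield from insert_everywhere(smaller, k - 1)

    if n < 1:
        raise ValidationError("need at least one taxon")
    yield from rec(n)


def _nni_neighbors(topo) -> list:
    """All nearest-neighbor-interchange rearrangements of a rooted binary
    topology (two per internal edge)."""
    out = []
    if not isinstance(topo, tuple):
        return out
    left, right = topo
    if isinstance(left, tuple):
        a, b = left
        out.append(((a, right), b))
        out.append(((b, right), a))
    if isinstance(right, tuple):
        c, d = right
        out.append((c, (left, d)))
        out.append((d, (c, left)))
    for nl in _nni_neighbors(left):
        out.append((nl, right))
    for nr in _nni_neighbors(right):
        out.append((left, nr))
    return out


def _greedy_addition(order: Sequence[int], masks: np.ndarray) -> tuple:
    """Stepwise insertion: add taxa in the given order, each at the edge
    (or above the root) minimizing Dollo length; first best kept on ties."""
    topo = int(order[0])
    for leaf in order[1:]:
        leaf = int(leaf)
        best_topo, best_len = None, None
        for candidate in _insert_positions(topo, leaf):
            length = _topology_length(candidate, masks)
            if best_len is None or length < best_len:
                best_topo, best_len = candidate, length
        topo = best_topo
    return topo


def _insert_positions(topo, leaf) -> Iterator:
    yield (topo, leaf)
    if isinstance(topo, tuple):
        left, right = topo
        for nl in _insert_positions(left, leaf):
            yield (nl, right)
        for nr in _insert_positions(right, leaf):
            yield (left, nr)


def _prunings(topo) -> Iterator[tuple]:
    """Yield (pruned subtree, remainder) for every prunable edge."""
    if not isinstance(topo, tuple):
        return
    left, right = topo
    yield left, right
    yield right, left
    for sub, rest in _prunings(left):
        yield sub, (rest, right)
    for sub, rest in _prunings(right):
        yield sub, (left, rest)


def _spr_neighbors(topo) -> Iterator[tuple]:
    """Subtree prune-and-regraft rearrangements (a superset of NNI)."""
    for sub, rest in _prunings(topo):
        yield from _insert_positions(rest, sub)


def _hill_climb(topo, masks: np.ndarray, use_spr: bool = True) -> tuple[tuple, int]:
    """Steepest-descent NNI until stuck; then, optionally, scan SPR
    rearrangements (first improvement) and resume NNI.  Deterministic:
    neighbors are generated in a fixed order and ties keep the first."""
    current_len = _topology_length(topo, masks)
    while True:
        best_topo, best_len = None, current_len
        for neighbor in _nni_neighbors(topo):
            length = _topology_length(neighbor, masks)
            if length < best_len:
                best_topo, best_len = neighbor, length
        if best_topo is not None:
            topo, current_len = best_topo, best_len
            continue
        if not use_spr:
            return topo, current_len
        for neighbor in _spr_neighbors(topo):
            length = _topology_length(neighbor, masks)
            if length < current_len:
                topo, current_len = neighbor, length
                break
        else:
            return topo, current_len


def _search_masks(
    masks: np.ndarray,
    n_taxa: int,
    replicates: int,
    rng: np.random.Generator,
    use_spr: bool = True,
) -> tuple[tuple, int]:
    best_topo, best_len = None, None
    for _ in range(replicates):
        order = rng.permutation(n_taxa)
        start = _greedy_addition(order, masks)
        topo, length = _hill_climb(start, masks, use_spr=use_spr)
        if best_len is None or length < best_len:
            best_topo, best_len = topo, length
    return best_topo, best_len


def exhaustive_search(matrix: PresenceMatrix) -> tuple[list[Tree], int]:
    """Enumerate all rooted binary topologies (hypothetical ancestor above)
    and return every topology attaining the minimal total Dollo length.

    Exact but factorial: refuses more than 8 taxa.
    """
    n = matrix.n_samples
    if n > EXHAUSTIVE_MAX_TAXA:
        raise ValidationError(
            f"exhaustive search limited to {EXHAUSTIVE_MAX_TAXA} taxa, got {n}"
        )
    if n < 2:
        raise ValidationError("exhaustive search requires at least 2 taxa")
    samples, masks = _canonical_masks(matrix)
    best_len: Optional[int] = None
    best: list = []
    for topo in _all_topologies(n):
        length = _topology_length(topo, masks)
        if best_len is None or length < best_len:
            best_len, best = length, [topo]
        elif length == best_len:
            best.append(topo)
    trees = [Tree.from_topology(t, samples) for t in best]
    return trees, best_len


def heuristic_search(
    matrix: PresenceMatrix, replicates: int = 50, seed: int = 0
) -> tuple[Tree, int]:
    """Heuristic Dollo parsimony search.

    Each replicate draws a random taxon-addition order from the seeded RNG,
    builds a starting tree by greedy stepwise insertion, then hill-climbs
    through NNI rearrangements, escaping NNI-local optima with SPR moves.
    The best-length tree over all replicates is returned; on ties the first
    tree attaining the best length is kept.  Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    n = matrix.n_samples
    if n < 4:
        raise ValidationError("heuristic search requires at least 4 taxa")
    samples, masks = _canonical_masks(matrix)
    rng = np.random.default_rng(seed)
    topo, length = _search_masks(masks, n, replicates, rng)
    return Tree.from_topology(topo, samples), length


def bootstrap_support(
    matrix: PresenceMatrix,
    best_tree: Tree,
    replicates: int = 100,
    seed: int = 0,
    search_replicates: int = 10,
) -> Tree:
    """Column-bootstrap clade support mapped onto the best tree.

    Each replicate resamples loci (matrix columns) with replacement to the
    original matrix size and re-runs the search (NNI-only hill climbing, the
    customary lighter setting for bootstrap replicates); the support of each
    rooted ingroup clade of the best tree is the fraction of replicate trees
    containing it.  Replicate ``r`` uses seed ``seed + r`` for both the
    resampling and the search.  Returns an annotated copy of the best tree.
    """
    if set(best_tree.leaf_names()) != set(matrix.samples):
        raise ValidationError("best tree leaves do not match matrix samples")
    samples, masks = _canonical_masks(matrix)
    n_loci = masks.shape[0]
    n = len(samples)

    clade_counts: dict[frozenset[str], int] = {}
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        resampled = masks[rng.integers(0, n_loci, n_loci)]
        topo, _ = _search_masks(resampled, n, search_replicates, rng, use_spr=False)
        rep_tree = Tree.from_topology(topo, samples)
        for clade in rep_tree.clades():
            clade_counts[clade] = clade_counts.get(clade, 0) + 1

    annotated = best_tree.copy()
    node_clades = annotated.node_clades()
    for node in annotated.postorder():
        if node.is_leaf:
            continue
        node.support = clade_counts.get(node_clades[id(node)], 0) / replicates
    return annotated


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Rooted Robinson–Foulds distance: the size of the symmetric difference
    of the two trees' ingroup clade sets.  Requires identical leaf sets."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValidationError("trees have different leaf sets")
    return len(t1.clades() ^ t2.clades())
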