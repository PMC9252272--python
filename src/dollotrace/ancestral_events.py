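"""Map each locus's single gain and all losses onto tree branches.

Once the tree is fixed, the minimal Dollo reconstruction of a binary
character is fully determined: the gain sits on the edge entering the MRCA
of the present leaves, and a loss sits on every edge leaving the spanning
subtree of present leaves into a subtree with no present leaf.  Aggregating
over loci, keyed by TE family, gives the per-branch activity table behind
branch-annotated trees and family-by-branch heatmaps.

Branches are identified by the node the edge enters (see
:meth:`dollotrace.tree.Tree.assign_branch_ids`); the edge from the
hypothetical all-absent ancestor into the ingroup root is the reportable
branch ``"root"``, which collects gains of characters present in every
sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .core import PresenceMatrix, ValidationError
from .tree import Tree, TreeNode

__all__ = [
    "reconstruct_character_events",
    "branch_event_table",
    "family_branch_heatmap_matrix",
    "BranchEventTable",
]


@dataclass
class BranchEventTable:
    """Per-branch, per-family counts of reconstructed gains and losses.

    ``gains`` and ``losses`` are DataFrames indexed by branch id (preorder
    tree order) with one column per TE family.  Counts are untransformed;
    the log10(count + 1) view lives in :func:`family_branch_heatmap_matrix`.
    """

    gains: pd.DataFrame
    losses: pd.DataFrame
    branch_order: list[str]
    branch_clades: dict[str, frozenset[str]]

    @property
    def total_gains(self) -> int:
        return int(self.gains.to_numpy().sum())

    @property
    def total_losses(self) -> int:
        return int(self.losses.to_numpy().sum())

    @property
    def total_events(self) -> int:
        return self.total_gains + self.total_losses

    def gains_by_branch(self) -> pd.Series:
        return self.gains.sum(axis=1)

    def gains_by_family(self) -> pd.Series:
        return self.gains.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Flat export: one row per branch, gain/loss columns per family plus
        totals."""
        out = pd.concat(
            {
                "gains": self.gains,
                "losses": self.losses,
            },
            axis=1,
        )
        out.columns = [f"{kind}:{family}" for kind, family in out.columns]
        out.insert(0, "total_losses", self.losses.sum(axis=1))
        out.insert(0, "total_gains", self.gains.sum(axis=1))
        out.index.name = "branch"
        return out


def _present_leaf_set(character) -> frozenset[str]:
    if isinstance(character, Mapping):
        return frozenset(name for name, state in character.items() if state)
    return frozenset(character)


def reconstruct_character_events(
    tree: Tree, character
) -> tuple[str, frozenset[str]]:
    """Place one character's gain and losses on branches of the tree.

    ``character`` is either a mapping leaf -> {0,1} or an iterable of the
    present leaves.  Returns ``(gain_branch_id, loss_branch_ids)``.  The
    number of losses plus one equals the character's Dollo cost.
    """
    present = _present_leaf_set(character)
    if not present:
        raise ValidationError("cannot reconstruct events for an all-absent character")
    leaf_names = set(tree.leaf_names())
    unknown = present - leaf_names
    if unknown:
        raise ValidationError(f"character names unknown leaves: {sorted(unknown)}")
    if tree.root.branch_id is None:
        tree.assign_branch_ids()

    mrca = tree.mrca(present)
    clades = tree.node_clades()
    losses: set[str] = set()
    stack: list[TreeNode] = [mrca]
    while stack:
        node = stack.pop()
        for child in node.children:
            if clades[id(child)] & present:
                stack.append(child)
            else:
                losses.add(child.branch_id)
    return mrca.branch_id, frozenset(losses)


def branch_event_table(
    tree: Tree,
    matrix: PresenceMatrix,
    locus_families: Optional[Mapping[str, str]] = None,
) -> BranchEventTable:
    """Aggregate per-character reconstructions into a branch x family table.

    ``locus_families`` maps locus id -> family; by default families are
    parsed from the canonical locus identifiers.  Every matrix column
    contributes exactly one gain, so total gains equal the column count.
    """
    if set(tree.leaf_names()) != set(matrix.samples):
        raise ValidationError("tree leaves do not match matrix samples")
    if locus_families is None:
        locus_families = matrix.family_map()
    missing = [lid for lid in matrix.locus_ids if lid not in locus_families]
    if missing:
        raise ValidationError(f"loci without family annotation: {missing[:3]}")

    if tree.root.branch_id is None:
        tree.assign_branch_ids()
    branch_order = tree.branch_ids()
    families = sorted(set(locus_families[lid] for lid in matrix.locus_ids))
    fam_index = {f: j for j, f in enumerate(families)}
    branch_index = {b: i for i, b in enumerate(branch_order)}

    gains = np.zeros((len(branch_order), len(families)), dtype=np.int64)
    losses = np.zeros_like(gains)
    presence = matrix.presence_sets()
    for lid, present in zip(matrix.locus_ids, presence):
        gain_branch, loss_branches = reconstruct_character_events(tree, present)
        j = fam_index[locus_families[lid]]
        gains[branch_index[gain_branch], j] += 1
        for branch in loss_branches:
            losses[branch_index[branch], j] += 1

    table = BranchEventTable(
        gains=pd.DataFrame(gains, index=branch_order, columns=families),
        losses=pd.DataFrame(losses, index=branch_order, columns=families),
        branch_order=branch_order,
        branch_clades=tree.branch_clades(),
    )
    if table.total_gains != matrix.n_loci:
        raise ValidationError("gain conservation violated")  # pragma: no cover
    return table


def family_branch_heatmap_matrix(table: BranchEventTable) -> pd.DataFrame:
    """log10(gains + 1) per family (rows) per branch (columns).

    Rows are sorted by total gains per family across branches, descending,
    ties broken alphabetically; columns follow tree branch order.
    """
    if table.gains.size == 0:
        raise ValidationError("empty branch event table")
    per_family = table.gains.T  # families x branches
    totals = per_family.sum(axis=1)
    order = sorted(per_family.index, key=lambda f: (-totals[f], f))
    shaped = per_family.loc[order, table.branch_order]
    return np.log10(shaped + 1)
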