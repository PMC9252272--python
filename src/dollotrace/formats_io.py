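"""Readers and writers for the standard formats the pipeline touches.

BED6 for TE insertion calls, tab-separated tables for presence/absence
matrices and per-window read counts, Newick for trees, YAML for the genome
configuration (re-exported from :mod:`dollotrace.core`).

All readers reject malformed records rather than silently repairing them.
"""

from __future__ import annotations

import io
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

from .core import (
    FormatError,
    GenomeConfig,
    PresenceMatrix,
    TEInsertionCall,
    ValidationError,
    parse_region,
)
from .tree import Tree, TreeNode

__all__ = [
    "read_te_bed",
    "write_te_bed",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_window_table",
    "write_window_table",
    "GenomeConfig",
    "parse_region",
]

DEFAULT_FAMILY_DELIMITER = "|"


# --------------------------------------------------------------------- BED6
def read_te_bed(
    path,
    sample_id: str,
    family_delimiter: str = DEFAULT_FAMILY_DELIMITER,
) -> list[TEInsertionCall]:
    """Read one sample's nonreference TE calls from a 6-column BED file.

    The TE family is the substring of the name column before
    ``family_delimiter`` (detectors commonly pack ``family|detail`` into the
    name).  Coordinates stay 0-based half-open.  Malformed lines raise
    :class:`FormatError` naming the line number; they are never skipped.
    """
    calls: list[TEInsertionCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            family = name.split(family_delimiter, 1)[0]
            try:
                calls.append(
                    TEInsertionCall(
                        sample_id=sample_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        family=family,
                        strand=strand,
                        support=score,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_te_bed(
    calls: Iterable[TEInsertionCall],
    path,
    family_delimiter: str = DEFAULT_FAMILY_DELIMITER,
    detail: str = "nonref",
) -> None:
    """Write calls as BED6 with ``family|detail`` in the name column."""
    with open(path, "w") as fh:
        for call in calls:
            name = f"{call.family}{family_delimiter}{detail}"
            fh.write(
                f"{call.chrom}\t{call.start}\t{call.end}\t{name}\t"
                f"{call.support}\t{call.strand}\n"
            )


# ------------------------------------------------------------ presence matrix
def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    """Write the binary matrix as TSV: rows = samples, columns = locus ids."""
    matrix.df.to_csv(path, sep="\t", index_label="sample")


def read_presence_matrix(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return PresenceMatrix(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ------------------------------------------------------------------- newick
def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if not label:
            raise FormatError("newick tree contains an unnamed leaf")
        return TreeNode(name=label)
    node = TreeNode(children=[_from_dendropy(c) for c in dnode.child_nodes()])
    label = dnode.label or (dnode.taxon.label if dnode.taxon else None)
    if label:
        try:
            node.support = float(label)
        except ValueError:
            node.annotations["label"] = label
    return node


def read_newick(path_or_string) -> Tree:
    """Read a Newick tree.

    Internal node labels are interpreted as bootstrap support when numeric,
    otherwise kept verbatim in ``node.annotations['label']``.  If the file's
    root has a single child (an explicit hypothetical-ancestor root), the
    tree is re-anchored at that child; the ancestor stays implicit.
    Non-binary trees are accepted; search operations check ``is_binary``.
    """
    if isinstance(path_or_string, str) and "(" in path_or_string:
        src = {"data": path_or_string}
    else:
        src = {"path": str(path_or_string)}
    try:
        dtree = dendropy.Tree.get(schema="newick", suppress_internal_node_taxa=True, **src)
    except Exception as exc:
        raise FormatError(f"could not parse newick input: {exc}") from exc
    seed = dtree.seed_node
    children = seed.child_nodes()
    if len(children) == 1:
        seed = children[0]
    return Tree(_from_dendropy(seed))


def newick_string(tree: Tree, include_support: bool = True) -> str:
    """Serialize a tree to Newick, deterministically (stored child order)."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(render(c) for c in node.children)
        label = ""
        if include_support and node.support is not None:
            label = format(node.support, "g")
        elif node.annotations.get("label"):
            label = str(node.annotations["label"])
        return f"({inner}){label}"

    return render(tree.root) + ";"


def write_newick(tree: Tree, path, include_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree, include_support=include_support) + "\n")


# -------------------------------------------------------------- window tables
WINDOW_COLUMNS = ["chrom", "start", "end", "count", "gc", "mappability"]


def read_window_table(path) -> pd.DataFrame:
    """Read a per-window read-count table (TSV).

    Required columns: chrom, start, end, count, gc, mappability; optional
    downstream columns (ratio, cn, status) are carried through if present.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: window table missing columns {missing}")
    if ((df["gc"] < 0) | (df["gc"] > 1)).any():
        raise FormatError(f"{path}: gc must lie in [0, 1]")
    if ((df["mappability"] < 0) | (df["mappability"] > 1)).any():
        raise FormatError(f"{path}: mappability must lie in [0, 1]")
    return df


def write_window_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
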