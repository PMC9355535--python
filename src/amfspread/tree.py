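"""Rooted support trees over OTU leaves.

Trees arrive as Newick produced by an ML pipeline with bootstrap supports
printed as internal-node labels (the common RAxML dialect).  ``SupportTree``
wraps a :class:`dendropy.Tree` and enforces the contract the collapsing
algorithm relies on: unique leaf labels, supports within [0, 100], and an
explicit root.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy

from .model import FormatError, ValidationError


@dataclass
class SupportTree:
    """A rooted tree whose internal nodes may carry bootstrap support.

    Supports live in ``node.support`` (float in [0, 100] or None when the
    input carried no label).  ``reference_leaves`` flags database reference
    sequences interleaved among the OTUs; clades containing them are never
    collapsible (the polyphyly guard).
    """

    tree: dendropy.Tree
    reference_leaves: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_leaves", frozenset(self.reference_leaves))
        labels = self.leaf_labels()
        seen: set[str] = set()
        dups: set[str] = set()
        for lab in labels:
            if lab in seen:
                dups.add(lab)
            seen.add(lab)
        if dups:
            raise ValidationError(f"duplicate leaf label(s) in tree: {sorted(dups)}")
        unknown_refs = self.reference_leaves - seen
        if unknown_refs:
            raise ValidationError(
                f"reference leaves not present in tree: {sorted(unknown_refs)}"
            )
        for node in self.tree.preorder_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None and not (0.0 <= sup <= 100.0):
                raise ValidationError(f"support value {sup} outside [0, 100]")

    def leaf_labels(self) -> list[str]:
        out = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is not None:
                out.append(leaf.taxon.label)
            elif leaf.label is not None:
                out.append(leaf.label)
            else:
                raise FormatError("tree contains an unlabeled leaf")
        return out

    @property
    def otu_leaves(self) -> list[str]:
        """Leaf labels that are candidate OTUs (not flagged references)."""
        return [lab for lab in self.leaf_labels() if lab not in self.reference_leaves]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _attach_supports(tree: dendropy.Tree) -> None:
    """Interpret internal-node labels as bootstrap supports."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.support = None
            continue
        label = node.label
        if label is None or label == "":
            node.support = None
            continue
        try:
            node.support = float(label)
        except ValueError as exc:
            raise FormatError(
                f"internal-node label {label!r} is not parseable as a support value"
            ) from exc


def read_support_tree(
    path_or_handle,
    reference_leaves: frozenset[str] | set[str] = frozenset(),
) -> SupportTree:
    """Read a rooted Newick tree with internal-node support labels.

    The root must be a bifurcation; a basal polytomy is treated as an
    unrooted tree and rejected (root the tree on an outgroup upstream).
    Unlabeled internal nodes carry absent support, which the collapse rules
    treat as "retain".
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse-error types
        if "DuplicateTaxon" in type(exc).__name__:
            raise ValidationError(f"duplicate leaf label(s) in tree: {exc}") from exc
        raise FormatError(f"could not parse Newick input: {exc}") from exc
    nchild = len(tree.seed_node.child_nodes())
    if nchild != 2:
        raise ValidationError(
            f"tree root has {nchild} children; input looks unrooted. "
            "Root the tree (e.g. on an outgroup) before analysis."
        )
    _attach_supports(tree)
    return SupportTree(tree=tree, reference_leaves=frozenset(reference_leaves))


def support_tree_from_string(newick: str, **kwargs) -> SupportTree:
    """Convenience wrapper for building a SupportTree from a Newick string."""
    return read_support_tree(_io.StringIO(newick), **kwargs)
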