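"""Thin wrapper around dendropy trees with bootstrap supports and leaf flags.

Internal node labels in the Newick source are interpreted as bootstrap
supports in [0, 100] (ultrafast-bootstrap convention).  A missing label is
recorded as missing support, never as zero.
"""

from __future__ import annotations

from typing import Optional, Set

import dendropy


class TreeParseError(ValueError):
    pass


class Tree:
    """Rooted phylogenetic tree over protein ids.

    ``is_reference_spt`` and ``has_colocalized_accessories`` leaf flags are
    attached after construction via :meth:`flag_leaves` and drive clade
    gating in :mod:`sphingolink.screen`.
    """

    def __init__(self, dtree: dendropy.Tree, midpoint_rooted: bool = False):
        self._t = dtree
        self.midpoint_rooted = midpoint_rooted
        self.reference_spt: Set[str] = set()
        self.colocalized: Set[str] = set()
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise TreeParseError("duplicate leaf names in tree")

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, force_rooted: Optional[bool] = None) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeParseError(f"malformed newick: {exc}") from exc
        midpointed = False
        root = dtree.seed_node
        n_children = len(root.child_nodes())
        rooted = force_rooted if force_rooted is not None else (n_children == 2)
        if not rooted and n_children > 2:
            dtree.reroot_at_midpoint(update_bipartitions=False)
            midpointed = True
        dtree.is_rooted = True
        return cls(dtree, midpoint_rooted=midpointed)

    # -- basics --------------------------------------------------------
    def leaf_names(self) -> list:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self._t.leaf_nodes())

    def supports(self) -> list:
        """Supports of internal (non-root, non-leaf) nodes; None when absent."""
        out = []
        for nd in self._t.preorder_node_iter():
            if nd.is_leaf() or nd is self._t.seed_node:
                continue
            out.append(self.node_support(nd))
        return out

    @staticmethod
    def node_support(node) -> Optional[float]:
        lbl = node.label
        if lbl is None or lbl == "":
            return None
        try:
            val = float(lbl)
        except ValueError:
            return None
        if not (0 <= val <= 100):
            raise TreeParseError(f"bootstrap support {val} outside [0, 100]")
        return val

    def flag_leaves(self, reference_spt=(), colocalized=()):
        leaves = set(self.leaf_names())
        for name in reference_spt:
            if name not in leaves:
                raise ValueError(f"reference leaf {name!r} absent from tree")
        self.reference_spt = set(reference_spt)
        self.colocalized = set(colocalized) & leaves
        return self

    # -- clade navigation (used by the Spt gating rule) ----------------
    def mrca(self, leaf_names) -> "dendropy.Node":
        taxa = [lf.taxon for lf in self._t.leaf_node_iter()
                if lf.taxon.label in set(leaf_names)]
        if not taxa:
            raise ValueError("no matching leaves for MRCA")
        if len(taxa) == 1:
            return [lf for lf in self._t.leaf_node_iter() if lf.taxon in taxa][0]
        return self._t.mrca(taxa=taxa)

    @staticmethod
    def clade_leaves(node) -> Set[str]:
        if node.is_leaf():
            return {node.taxon.label}
        return {lf.taxon.label for lf in node.leaf_iter()}

    @property
    def root(self):
        return self._t.seed_node

    def as_newick(self) -> str:
        return self._t.as_string(schema="newick", suppress_rooting=True).strip()
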