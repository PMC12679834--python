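"""Project per-target gene statuses onto a phylogeny (dendrogram semantics).

A leaf carries its target's PseudoIndex and mutation set. An internal node
carries the *maximum* PseudoIndex of its descendants and the set of mutations
*shared by all* of its matched descendant leaves. These are presentation
semantics for reading erosion along a tree, not ancestral-state inference: a
max says "something this eroded exists below here", an intersection says
"every sampled descendant carries this exact lesion".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import dendropy

from .config import TreeConfig
from .index import GeneStatus
from .mutations import MutationKey

log = logging.getLogger(__name__)


class NoOverlapError(ValueError):
    pass


@dataclass
class AnnotatedTree:
    tree: dendropy.Tree
    leaf_status: dict[str, GeneStatus]
    missing_leaves: list[str] = field(default_factory=list)

    @property
    def root_index(self) -> int:
        return self.tree.seed_node.pseudoindex

    @property
    def root_shared(self) -> set[MutationKey]:
        return self.tree.seed_node.shared


def _keys_match(a: MutationKey, b: MutationKey, tol: int) -> bool:
    return a.kind == b.kind and a.exon_index == b.exon_index and abs(a.cds_pos - b.cds_pos) <= tol


def _intersect(sets: list[set[MutationKey]], tol: int) -> set[MutationKey]:
    if not sets:
        return set()
    if tol == 0:
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out
    # positional slack: keep a key from the first set if every other set has a
    # within-tolerance counterpart (asymmetric by construction; documented).
    out = set()
    for key in sets[0]:
        if all(any(_keys_match(key, other, tol) for other in s) for s in sets[1:]):
            out.add(key)
    return out


def annotate_tree(
    newick: str,
    statuses: list[GeneStatus],
    label_map: dict[str, str] | None = None,
    tree_cfg: TreeConfig | None = None,
) -> AnnotatedTree:
    """Fill per-node PseudoIndex (max) and shared mutation sets (intersection).

    ``label_map`` translates leaf labels to target ids before matching. Leaves
    without a matching target are marked missing and excluded from both the
    max and the intersection. Raises :class:`NoOverlapError` when no leaf
    matches any result.
    """
    if tree_cfg is None:
        tree_cfg = TreeConfig()
    by_target = {s.target_id: s for s in statuses}
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    if len(tree.seed_node.child_nodes()) > 2:
        has_lengths = all(
            e.length is not None for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        )
        if has_lengths:
            log.info("input tree looks unrooted (basal polytomy); midpoint-rooting")
            tree.reroot_at_midpoint(update_bipartitions=False)
        else:
            log.info("input tree has a basal polytomy and no branch lengths; keeping as-is")

    leaf_status: dict[str, GeneStatus] = {}
    missing: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else (leaf.label or "")
        target = (label_map or {}).get(label, label)
        status = by_target.get(target)
        if status is None:
            missing.append(label)
            leaf.missing = True
            leaf.pseudoindex = None
            leaf.shared = set()
        else:
            leaf_status[label] = status
            leaf.missing = False
            leaf.pseudoindex = status.pseudoindex
            leaf.shared = {e.key for e in status.events}
    if not leaf_status:
        raise NoOverlapError("no overlap between tree leaf labels and result target ids")
    if missing:
        log.warning("%d tree leaves have no matching target: %s", len(missing), missing)

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        children = [c for c in node.child_nodes() if not c.missing]
        if not children:
            node.missing = True
            node.pseudoindex = None
            node.shared = set()
            continue
        node.missing = False
        node.pseudoindex = max(c.pseudoindex for c in children)
        node.shared = _intersect([c.shared for c in children], tree_cfg.pos_tolerance)
    return AnnotatedTree(tree=tree, leaf_status=leaf_status, missing_leaves=missing)


def export_annotated(atree: AnnotatedTree) -> tuple[str, str]:
    """Serialize to (NHX-annotated newick, JSON sidecar with full shared sets).

    The newick carries per-node ``pseudoindex`` and ``shared_n`` NHX tags and
    re-parses with dendropy; the sidecar lists every node (preorder ids) with
    its full shared mutation set and subtended leaves.
    """
    nodes = []
    for i, node in enumerate(atree.tree.preorder_node_iter()):
        node._ps_id = i
        if not node.missing:
            node.annotations.add_new("pseudoindex", node.pseudoindex)
            node.annotations.add_new("shared_n", len(node.shared))
        leaves = sorted(
            (lf.taxon.label if lf.taxon else lf.label or "") for lf in node.leaf_iter()
        )
        nodes.append(
            {
                "node_id": i,
                "is_leaf": node.is_leaf(),
                "leaves": leaves,
                "missing": bool(node.missing),
                "pseudoindex": node.pseudoindex,
                "shared_mutations": [
                    {"kind": k.kind, "exon_index": k.exon_index, "cds_pos": k.cds_pos}
                    for k in sorted(node.shared)
                ] if not node.missing else [],
            }
        )
    newick = atree.tree.as_string(
        schema="newick", suppress_annotations=False, annotations_as_nhx=True,
        suppress_rooting=True,
    )
    sidecar = json.dumps(
        {"missing_leaves": atree.missing_leaves, "nodes": nodes},
        indent=2, sort_keys=True,
    )
    return newick, sidecar
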