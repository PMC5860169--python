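"""Distance-tree inference and taxonomy-aware tree assessment.

Trees are held as :class:`dendropy.Tree` objects; branch support values live
in a per-node ``support`` attribute (integer percent) which the Newick writer
emits as internal node labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import UsageError
from .gbdp import DistanceMatrix

INF = math.inf


# --------------------------------------------------------------------------
# Neighbour joining


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining with the Studier-Keppler Q criterion.

    Negative branch-length estimates are clamped to zero.  Ties in Q are
    broken by the lexicographically smallest pair of cluster labels (each
    cluster is identified by its smallest member label), making the topology
    deterministic.  With fewer than three taxa a trivial two-leaf tree is
    returned with the single distance split evenly.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 2:
        raise UsageError("neighbour joining needs at least two taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        return node

    if n == 2:
        d = float(matrix.values[0, 1])
        a, b = leaf(labels[0]), leaf(labels[1])
        a.edge.length = b.edge.length = max(0.0, d / 2.0)
        tree.seed_node.add_child(a)
        tree.seed_node.add_child(b)
        tree.is_rooted = True
        return tree

    # active clusters: index -> (node, min member label)
    nodes: dict[int, dendropy.Node] = {i: leaf(labels[i]) for i in range(n)}
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): float(matrix.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    next_idx = n

    def d(i: int, j: int) -> float:
        return dist[frozenset((i, j))]

    while len(active) > 3:
        N = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (N - 2) * d(i, j) - r[i] - r[j]
                lab = tuple(sorted((minlab[i], minlab[j])))
                key = (q, lab)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = d(i, j) - li
        u = dendropy.Node()
        ni, nj_ = nodes.pop(i), nodes.pop(j)
        ni.edge.length = max(0.0, li)
        nj_.edge.length = max(0.0, lj)
        u.add_child(ni)
        u.add_child(nj_)
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((next_idx, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active.discard(i)
        active.discard(j)
        active.add(next_idx)
        nodes[next_idx] = u
        minlab[next_idx] = min(minlab[i], minlab[j])
        next_idx += 1

    i, j, k = sorted(active, key=lambda x: minlab[x])
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    center = tree.seed_node
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].edge.length = max(0.0, ln)
        center.add_child(nodes[idx])
    tree.is_rooted = False
    _collapse_zero_internal_edges(tree)
    return tree


def _collapse_zero_internal_edges(tree: dendropy.Tree) -> None:
    """Suppress internal edges of length zero, producing multifurcations.

    A zero-length internal edge carries no distance signal, so the split it
    induces is not supported by the matrix; collapsing it makes the output
    for e.g. an all-zero matrix a star tree rather than an arbitrary
    resolution of it.
    """
    for node in list(tree.postorder_internal_node_iter()):
        if node.parent_node is None:
            continue
        if (node.edge.length or 0.0) == 0.0:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)


# --------------------------------------------------------------------------
# Midpoint rooting


def _leaf_paths(tree: dendropy.Tree):
    """Per-leaf path (list of nodes up to the seed) and cumulative lengths."""
    parent = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            parent[child] = node
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    paths = {}
    for lf in leaves:
        chain = [lf]
        while chain[-1] in parent:
            chain.append(parent[chain[-1]])
        paths[lf] = chain
    return leaves, paths


def _edge_len(node: dendropy.Node) -> float:
    return node.edge.length or 0.0


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties are broken by the lexicographically smallest (sorted) leaf-label
    pair.  If every branch length is zero the root is placed on the edge
    above the lexicographically smallest leaf.
    """
    tree = tree.clone(depth=1)
    leaves, paths = _leaf_paths(tree)
    if len(leaves) < 2:
        tree.is_rooted = True
        return tree

    best = None  # ((-dist, leafpair), leaf_a, leaf_b)
    for ia in range(len(leaves)):
        for ib in range(ia + 1, len(leaves)):
            la, lb = leaves[ia], leaves[ib]
            pa, pb = paths[la], paths[lb]
            seen = {id(nd): k for k, nd in enumerate(pa)}
            for kb, nd in enumerate(pb):
                if id(nd) in seen:
                    ka = seen[id(nd)]
                    break
            dist = sum(_edge_len(x) for x in pa[:ka]) + sum(
                _edge_len(x) for x in pb[:kb]
            )
            pair = tuple(sorted((la.taxon.label, lb.taxon.label)))
            key = (-dist, pair)
            if best is None or key < best[0]:
                best = (key, la, lb, ka, kb, dist)
    _, la, lb, ka, kb, dmax = best

    if dmax <= 0:
        target = min(leaves, key=lambda nd: nd.taxon.label)
        tree.reroot_at_edge(target.edge, length1=0.0, length2=0.0)
        tree.is_rooted = True
        return tree

    # ordered edge walk from la to lb: up to the LCA, then down to lb
    walk = [(paths[la][k], _edge_len(paths[la][k])) for k in range(ka)]
    walk += [
        (paths[lb][k], _edge_len(paths[lb][k])) for k in range(kb - 1, -1, -1)
    ]
    half = dmax / 2.0
    acc = 0.0
    for node, ln in walk:
        if acc + ln >= half - 1e-12 and ln > 0:
            into = half - acc  # distance from the la-side end of this edge
            # orientation: edges in the upward part are walked child->parent,
            # downward part parent->child; node is always the edge's child
            upward = node in paths[la][:ka]
            if upward:
                l_child, l_parent = into, ln - into
            else:
                l_child, l_parent = ln - into, into
            tree.reroot_at_edge(
                node.edge, length1=max(0.0, l_parent), length2=max(0.0, l_child)
            )
            tree.is_rooted = True
            return tree
        acc += ln
    raise AssertionError("midpoint not found on path")  # pragma: no cover


# --------------------------------------------------------------------------
# Branch support from replicate trees


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(nd.taxon.label for nd in tree.leaf_node_iter())


def _clade_sets(tree: dendropy.Tree) -> dict[int, frozenset]:
    """Leaf-label set below each node (postorder), keyed by id(node)."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for c in node.child_nodes():
                s |= out[id(c)]
            out[id(node)] = s
    return out


def _canonical_bipartition(side: frozenset, all_leaves: frozenset, anchor: str):
    """Bipartition encoded as the side *not* containing the anchor leaf;
    None when trivial."""
    if anchor in side:
        side = all_leaves - side
    if len(side) < 2 or len(side) > len(all_leaves) - 2:
        return None
    return side


def tree_bipartitions(tree: dendropy.Tree) -> set:
    leaves = leaf_labels(tree)
    anchor = min(leaves)
    clades = _clade_sets(tree)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        bp = _canonical_bipartition(clades[id(node)], leaves, anchor)
        if bp is not None:
            out.add(bp)
    return out


def branch_support(
    reference: dendropy.Tree, replicates: Sequence[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate each internal branch of ``reference`` with the percentage of
    replicate trees containing its (unrooted) bipartition."""
    leaves = leaf_labels(reference)
    anchor = min(leaves)
    for rep in replicates:
        rl = leaf_labels(rep)
        if rl != leaves:
            diff = sorted(leaves.symmetric_difference(rl))
            raise UsageError(f"replicate leaf set differs from reference: {diff}")
    rep_bps = [tree_bipartitions(rep) for rep in replicates]
    clades = _clade_sets(reference)
    nrep = len(replicates)
    for node in reference.preorder_node_iter():
        if node is reference.seed_node or node.is_leaf():
            continue
        bp = _canonical_bipartition(clades[id(node)], leaves, anchor)
        if bp is None:
            # trivial split: contained in every tree by definition
            node.support = 100
        elif nrep == 0:
            node.support = 0
        else:
            count = sum(1 for s in rep_bps if bp in s)
            node.support = round(100.0 * count / nrep)
    return reference


# --------------------------------------------------------------------------
# Monophyly classification (minimum-change reconstruction)

MONOPHYLETIC = "monophyletic"
PARAPHYLETIC = "paraphyletic"
POLYPHYLETIC = "polyphyletic"
TRIVIAL = "trivial"


def _sankoff_updown(tree: dendropy.Tree, members: frozenset):
    """Up/down minimum-change costs for the binary membership character.

    Returns (up, down) dicts mapping id(node) -> [cost state 0, cost state 1].
    """
    up: dict[int, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            m = node.taxon.label in members
            up[id(node)] = [INF if m else 0.0, 0.0 if m else INF]
        else:
            costs = [0.0, 0.0]
            for c in node.child_nodes():
                uc = up[id(c)]
                for s in (0, 1):
                    costs[s] += min(uc[0] + (s != 0), uc[1] + (s != 1))
            up[id(node)] = costs
    down: dict[int, list[float]] = {id(tree.seed_node): [0.0, 0.0]}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        dn = down[id(node)]
        # child transition cost: min over parent state of
        #   down[parent] + sibling subtree costs + change penalty
        for c in children:
            best = [INF, INF]
            for s in (0, 1):
                sib = 0.0
                for o in children:
                    if o is c:
                        continue
                    uo = up[id(o)]
                    sib += min(uo[0] + (s != 0), uo[1] + (s != 1))
                base = dn[s] + sib
                for t in (0, 1):
                    cand = base + (s != t)
                    if cand < best[t]:
                        best[t] = cand
            down[id(c)] = best
    return up, down


def classify_taxon(tree: dendropy.Tree, members: Iterable[str]) -> str:
    """Classify a leaf set as trivial / monophyletic / paraphyletic /
    polyphyletic on a rooted tree.

    Non-clades are paraphyletic when some most-parsimonious reconstruction of
    the binary membership character assigns the member state to the MRCA of
    the set, polyphyletic otherwise.
    """
    members = frozenset(members)
    if not members:
        raise UsageError("empty taxon")
    leaves = leaf_labels(tree)
    unknown = members - leaves
    if unknown:
        raise UsageError(f"unknown leaves: {sorted(unknown)}")
    if len(members) == 1:
        return TRIVIAL
    clades = _clade_sets(tree)
    mrca = None
    for node in tree.postorder_node_iter():
        if members <= clades[id(node)]:
            mrca = node
            break
    if clades[id(mrca)] == members:
        return MONOPHYLETIC
    up, down = _sankoff_updown(tree, members)
    tot = [up[id(mrca)][s] + down[id(mrca)][s] for s in (0, 1)]
    return PARAPHYLETIC if tot[1] <= min(tot) else POLYPHYLETIC


# --------------------------------------------------------------------------
# Taxon support


@dataclass
class TaxonSupportReport:
    rows: list[dict]
    overall: float
    rank: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["taxon", "rank", "n_leaves", "status", "signed_support"]
        )


def _node_support(node: dendropy.Node, is_root: bool) -> int:
    if is_root:
        return 100
    s = getattr(node, "support", None)
    return int(s) if s is not None else 0


def taxon_support(
    tree: dendropy.Tree, taxonomy: pd.DataFrame, rank: str
) -> TaxonSupportReport:
    """Signed support statistic of a rooted support tree against one rank.

    Monophyletic taxa score the support of their subtending branch (the root
    clade scores 100 by convention); non-monophyletic taxa score minus the
    maximum support among clades crossing them.  The overall value is
    sum(signed) / sum(|signed|) over non-trivial taxa, in [-1, 1].
    """
    if rank not in taxonomy.columns:
        raise UsageError(f"taxonomy has no rank column {rank!r}")
    leaves = leaf_labels(tree)
    tax = taxonomy.set_index("genome_id")[rank].to_dict()
    missing = sorted(leaves - set(tax))
    if missing:
        raise UsageError(f"leaves absent from taxonomy: {missing}")
    groups: dict[str, set] = {}
    for leaf in leaves:
        val = tax[leaf]
        if val:
            groups.setdefault(val, set()).add(leaf)

    clades = _clade_sets(tree)
    internal = [
        (node, clades[id(node)])
        for node in tree.preorder_node_iter()
        if not node.is_leaf()
    ]
    rows = []
    pos_sum = abs_sum = 0.0
    for taxon in sorted(groups):
        members = frozenset(groups[taxon])
        status = classify_taxon(tree, members)
        if status == TRIVIAL:
            rows.append(
                dict(taxon=taxon, rank=rank, n_leaves=1, status=status,
                     signed_support=0)
            )
            continue
        if status == MONOPHYLETIC:
            signed = 0
            for node, cl in internal:
                if cl == members:
                    signed = _node_support(node, node is tree.seed_node)
                    break
        else:
            conflict = 0
            for node, cl in internal:
                if (cl & members) and (cl - members) and (members - cl):
                    conflict = max(
                        conflict, _node_support(node, node is tree.seed_node)
                    )
            signed = -conflict
        rows.append(
            dict(taxon=taxon, rank=rank, n_leaves=len(members), status=status,
                 signed_support=signed)
        )
        pos_sum += signed
        abs_sum += abs(signed)
    overall = pos_sum / abs_sum if abs_sum > 0 else 0.0
    return TaxonSupportReport(rows=rows, overall=overall, rank=rank)
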