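"""Phylogeny utilities: pruning, tip substitution, Brownian covariance, PIC.

Trees are carried as :class:`dendropy.Tree` objects.  Under a Brownian
model of residual evolution the expected covariance between two tips is the
shared root-to-ancestor path length, assembled here as the phylogenetic
variance-covariance (VCV) matrix.  Felsenstein's phylogenetically
independent contrasts are implemented directly on the (zero-length-resolved)
tree: each internal node contributes the standardised difference of its two
daughter values, daughters are replaced by their branch-length-weighted
average, and the node's own branch is lengthened by ``v1 v2 / (v1 + v2)``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "leaf_labels",
    "apply_substitutions",
    "prune_to_species",
    "is_ultrametric",
    "vcv_matrix",
    "pic_contrasts",
]


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def apply_substitutions(tree: dendropy.Tree, substitutions: Mapping[str, str]) -> dendropy.Tree:
    """Relabel tree tips so congeners can stand in for missing species.

    ``substitutions`` maps a study species name to the label of the tree tip
    that represents it (a congener); the tip is renamed to the study name.
    Applied in place (and also returned).  Raises if a requested stand-in
    tip is absent from the tree.
    """
    label_to_taxon = {t.label: t for t in tree.taxon_namespace}
    missing = [v for v in substitutions.values() if v not in label_to_taxon]
    if missing:
        raise ValueError(f"substitution stand-in tips not found in tree: {sorted(missing)}")
    for species, stand_in in substitutions.items():
        label_to_taxon[stand_in].label = species
    return tree


def prune_to_species(tree: dendropy.Tree, species: Iterable[str]) -> dendropy.Tree:
    """Prune a copy of ``tree`` down to the listed species.

    Branch lengths stay additive (unary internal nodes created by pruning
    are suppressed, their edge lengths summed).  Raises listing any species
    absent from the tree.
    """
    wanted = list(species)
    have = set(leaf_labels(tree))
    missing = sorted(set(wanted) - have)
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(wanted)
    return pruned


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-8) -> bool:
    depths = _node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    return max(tip_depths) - min(tip_depths) <= tol * max(max(tip_depths), 1.0)


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def vcv_matrix(tree: dendropy.Tree, labels: Sequence[str] | None = None):
    """Brownian expected covariance among tips (shared path to root).

    Returns ``(labels, V)`` where ``V[i, j]`` is the root-to-MRCA distance
    of tips i and j and ``V[i, i]`` the root-to-tip distance.  ``labels``
    fixes the row order (and may repeat species, e.g. for bootstrap
    resamples); by default the tree's own leaf order is used.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    tip_labels = [lf.taxon.label for lf in leaves]
    index = {lab: i for i, lab in enumerate(tip_labels)}
    n = len(leaves)
    base = np.zeros((n, n))
    # Tip pairs split across different children of a node have that node as
    # their MRCA; once merged they stay in one subtree, so each pair is
    # assigned exactly once during the postorder sweep.
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [index[node.taxon.label]]
            continue
        children = [leafsets[c] for c in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                base[np.ix_(ia, ib)] = depths[node]
                base[np.ix_(ib, ia)] = depths[node]
        leafsets[node] = [i for ch in children for i in ch]
    for leaf in leaves:
        i = index[leaf.taxon.label]
        base[i, i] = depths[leaf]

    if labels is None:
        return tip_labels, base
    try:
        ix = [index[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not a tip of the tree") from None
    return list(labels), base[np.ix_(ix, ix)]


def pic_contrasts(tree: dendropy.Tree, values: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's standardised independent contrasts for one trait.

    ``values`` maps tip label to trait value and must cover every tip.
    Polytomies are resolved arbitrarily with zero-length branches, which
    leaves the contrasts' joint distribution exchangeable under Brownian
    motion.  A pair of zero-length sister branches with unequal values has
    no defined contrast and raises.
    """
    work = tree.clone(depth=1)
    work.resolve_polytomies(limit=2, update_bipartitions=False)
    missing = [lab for lab in leaf_labels(work) if lab not in values]
    if missing:
        raise ValueError(f"trait values missing for tips: {sorted(missing)}")

    node_value: dict = {}
    node_length: dict = {}
    contrasts: list[float] = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            node_value[node] = float(values[node.taxon.label])
            node_length[node] = float(node.edge.length or 0.0)
            continue
        c1, c2 = node.child_nodes()
        v1, v2 = node_length[c1], node_length[c2]
        x1, x2 = node_value[c1], node_value[c2]
        vsum = v1 + v2
        if vsum <= 0.0:
            if abs(x1 - x2) > 1e-12 * max(1.0, abs(x1), abs(x2)):
                raise ValueError(
                    "contrast undefined: zero-length sister branches with unequal values"
                )
            node_value[node] = 0.5 * (x1 + x2)
            node_length[node] = float(node.edge.length or 0.0)
            continue
        contrasts.append((x1 - x2) / np.sqrt(vsum))
        # branch-length-weighted average; a zero-length child is known exactly
        node_value[node] = (
            (x1 * v2 + x2 * v1) / vsum if v1 > 0 and v2 > 0 else (x1 if v1 == 0 else x2)
        )
        node_length[node] = float(node.edge.length or 0.0) + v1 * v2 / vsum
    return np.asarray(contrasts)
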