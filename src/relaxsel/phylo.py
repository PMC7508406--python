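"""Ultrametric phylogenies and the Brownian species correlation matrix.

The phylogenetic random effect of the meta-regression needs a
species-by-species correlation matrix.  Under Brownian-motion trait
evolution on an ultrametric tree, the expected correlation between two
species equals the depth of their most recent common ancestor divided by
the total tree height — shared evolutionary history as a fraction of
total history.  Trees are read from newick via dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "is_ultrametric",
    "prune_tree",
    "substitute_congeners",
    "phylo_correlation",
    "PhyloCorrelationMatrix",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class PhyloCorrelationMatrix:
    """Species correlation matrix with its species ordering.

    ``matrix`` is symmetric positive semi-definite with unit diagonal;
    ``species`` gives the row/column ordering.
    """

    species: list[str]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def reorder(self, species: list[str]) -> "PhyloCorrelationMatrix":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelationMatrix(
            species=list(species), matrix=self.matrix[np.ix_(idx, idx)]
        )


def _leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {
        leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()
    }


def read_newick(
    text_or_path: str, validate_ultrametric: bool = True,
    force_height_normalize: bool = False,
) -> dendropy.Tree:
    """Parse a newick tree from a string or a file path.

    Checks that leaf labels are unique and, unless disabled, that the tree
    is ultrametric (all root-to-leaf path lengths equal within relative
    tolerance 1e-6).  ``force_height_normalize`` instead stretches each
    terminal branch so all leaf depths equal the maximum depth.
    """
    text = text_or_path
    if not text.strip():
        raise ValueError("empty newick string")
    if "(" not in text:  # path, not newick
        with open(text_or_path) as fh:
            text = fh.read()
        if not text.strip():
            raise ValueError("empty newick file")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises various parse errors
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    if force_height_normalize:
        depths = _leaf_depths(tree)
        height = max(depths.values())
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + (
                height - depths[leaf.taxon.label]
            )
    elif validate_ultrametric and not is_ultrametric(tree):
        raise ValueError(
            "tree is not ultrametric (root-to-leaf depths differ); "
            "pass force_height_normalize=True to rescale"
        )
    return tree


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    depths = np.array(list(_leaf_depths(tree).values()))
    height = depths.max()
    if height == 0:
        return False
    return bool(np.all(np.abs(depths - height) <= rtol * height))


def prune_tree(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Prune to the given leaf set, preserving all pairwise path lengths.

    Degree-2 internal nodes left by the pruning are collapsed with their
    branch lengths summed (dendropy does this during taxon retention).
    """
    keep = set(keep)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(keep - labels)
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    pruned = tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    pruned.retain_taxa(taxa)
    pruned.purge_taxon_namespace()
    return pruned


def substitute_congeners(
    requested, tree_labels, mapping: dict[str, str] | None = None
) -> tuple[list[str], list[dict]]:
    """Resolve requested species to tree leaves, using congeneric stand-ins.

    Species absent from the tree are replaced via ``mapping``
    (requested -> available leaf); unresolvable species raise.  Returns
    the resolved list (order preserved) and a substitution log.
    """
    mapping = mapping or {}
    tree_labels = set(tree_labels)
    resolved: list[str] = []
    log: list[dict] = []
    unmatched: list[str] = []
    for sp in requested:
        if sp in tree_labels:
            resolved.append(sp)
        elif sp in mapping and mapping[sp] in tree_labels:
            resolved.append(mapping[sp])
            log.append({"requested": sp, "substitute": mapping[sp]})
        else:
            unmatched.append(sp)
    if unmatched:
        raise KeyError(
            f"species missing from tree with no congeneric substitute: {unmatched}"
        )
    return resolved, log


def phylo_correlation(tree: dendropy.Tree) -> PhyloCorrelationMatrix:
    """Brownian-motion correlation matrix from an ultrametric tree.

    Entry (i, j) is the root-to-MRCA depth of leaves i and j divided by the
    tree height; the diagonal is exactly 1.  The result is a Gram matrix,
    hence positive semi-definite.
    """
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    depths = _leaf_depths(tree)
    height = max(depths.values())
    if height <= 0:
        raise ValueError("tree height is zero; correlations undefined")
    n = len(labels)
    mat = np.eye(n)
    taxa = {l.taxon.label: l.taxon for l in leaves}
    for i in range(n):
        for j in range(i + 1, n):
            # MRCA depth = height - (patristic distance)/2 on an ultrametric tree
            dist = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            shared = height - dist / 2.0
            mat[i, j] = mat[j, i] = max(shared, 0.0) / height
    return PhyloCorrelationMatrix(species=labels, matrix=mat)
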