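"""Desk-scale phylogenetics: corrected distances, neighbor joining, clade tests.

Trees are :class:`dendropy.Tree` objects throughout; Newick I/O,
midpoint rooting and bipartition comparison are delegated to dendropy.
Neighbor joining (Saitou–Nei with the Studier–Keppler Q criterion) is
implemented here with fixed tie-breaking so inference is deterministic.
This stands in, at desk scale, for likelihood/Bayesian inference: only
topology-level claims (e.g. monophyly of a planted clade) are made.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

from .align import GAP, MultipleAlignment

logger = logging.getLogger(__name__)

POISSON_P_CAP = 0.95


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise PhyloError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise PhyloError("non-finite distances")
        if np.any(self.values < 0):
            raise PhyloError("negative distances")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise PhyloError("distance matrix not symmetric")
        if np.max(np.abs(np.diag(self.values))) > 0:
            raise PhyloError("nonzero diagonal")

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), frame.values)


def poisson_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Poisson-corrected protein distances, d = -ln(1 - p).

    p is the mismatch fraction over columns where both rows have a
    residue (gapped columns are excluded pairwise).  p is capped at
    0.95 to keep distances finite; the cap is logged when applied.
    """
    if len(msa) < 2:
        raise PhyloError("need >= 2 rows for distances")
    n = len(msa)
    values = np.zeros((n, n))
    rows = msa.rows
    for i in range(n):
        for j in range(i + 1, n):
            both = [
                (a, b)
                for a, b in zip(rows[i], rows[j])
                if a != GAP and b != GAP
            ]
            if not both:
                raise PhyloError(
                    f"no comparable columns between {msa.row_ids[i]!r} and {msa.row_ids[j]!r}"
                )
            p = sum(1 for a, b in both if a != b) / len(both)
            if p > POISSON_P_CAP:
                logger.info(
                    "poisson_distance: capping p=%.3f for (%s, %s)",
                    p,
                    msa.row_ids[i],
                    msa.row_ids[j],
                )
                p = POISSON_P_CAP
            values[i, j] = values[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(list(msa.row_ids), values)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Pair choice uses the Studier–Keppler Q criterion with ties broken by
    the lowest index pair; negative branch lengths are clamped to zero
    and the deficit logged.
    """
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbor joining requires >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(label)) for label in dm.ids]
    D = dm.values.copy()

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.info("neighbor_joining: clamping branch %.6f to 0 (%s)", length, context)
            return 0.0
        return length

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = (math.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li, f"join {i},{j}")
        nodes[j].edge.length = clamp(lj, f"join {i},{j}")
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_d = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = new_d[keep]
        D_new[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = D_new
    # resolve the final three nodes around one internal vertex
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d_ab + d_ac - d_bc) / 2.0,
        (d_ab + d_bc - d_ac) / 2.0,
        (d_ac + d_bc - d_ab) / 2.0,
    ]
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        node.edge.length = clamp(length, "final join")
        center.add_child(node)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The midpoint edge is located explicitly so that a midpoint falling
    exactly on an internal node still yields a bifurcating root (the
    node-adjacent edge on the long-path side is split at length zero).
    """
    work = tree.clone(depth=1)
    pdm = work.phylogenetic_distance_matrix()
    taxa = list(work.taxon_namespace)
    best = (-1.0, None, None)
    for i, tx in enumerate(taxa):
        for ty in taxa[i + 1 :]:
            d = pdm.patristic_distance(tx, ty)
            if d > best[0]:
                best = (d, tx, ty)
    diameter, tx, ty = best
    if diameter <= 0:
        work.is_rooted = True
        return work
    node_x = work.find_node_with_taxon_label(tx.label)
    node_y = work.find_node_with_taxon_label(ty.label)
    ancestors_x = []
    node = node_x
    while node is not None:
        ancestors_x.append(node)
        node = node.parent_node
    node, y_side = node_y, []
    while node not in ancestors_x:
        y_side.append(node)
        node = node.parent_node
    mrca = node
    x_side = ancestors_x[: ancestors_x.index(mrca)]
    # path from x to y: x-side edges upward, then y-side edges downward
    path = [(n, n.edge.length or 0.0) for n in x_side] + [
        (n, n.edge.length or 0.0) for n in reversed(y_side)
    ]
    half = diameter / 2.0
    walked = 0.0
    for node, length in path:
        if walked + length >= half - 1e-12:
            # the midpoint sits on this edge, `walked` in from its x-side end
            offset = half - walked
            if node in x_side:
                length1, length2 = length - offset, offset  # parent side, child side
            else:
                length1, length2 = offset, length - offset
            work.reroot_at_edge(
                node.edge,
                length1=max(length1, 0.0),
                length2=max(length2, 0.0),
                update_bipartitions=True,
            )
            break
        walked += length
    work.is_rooted = True
    return work


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, labels: set[str]) -> bool:
    """True iff some node's leaf descendants are exactly ``labels``.

    The tree must be rooted (monophyly is direction-dependent).
    """
    labels = set(labels)
    all_labels = leaf_labels(tree)
    if not labels or not labels <= all_labels:
        raise PhyloError("labels must be a nonempty subset of the leaf labels")
    if not tree.is_rooted:
        raise PhyloError("monophyly test requires a rooted tree")
    mrca = tree.mrca(taxon_labels=list(labels))
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == labels


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds distance (bipartitions in exactly one tree)."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise PhyloError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; parse failures raise :class:`PhyloError`."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error classes
        raise PhyloError(f"newick parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
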