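"""Trees, alignments, and the three relatedness models.

A phylogenetic-signal test needs the phylogeny expressed as a pairwise
structure over the tips. Three constructions are supported, mirroring the
three standard choices in comparative analysis:

* pairwise genetic distances computed directly from an alignment
  (p-distance, JC69, K2P) with pairwise deletion of gap/ambiguous sites —
  phylogenetically "naive", no tree required;
* Abouheif's matrix of phylogenetic proximities — a topology-only measure
  built from products of inverse node-descendant counts along tip-to-tip
  paths (the "oriAbouheif" form whose rows sum to one);
* the Brownian-motion variance-covariance matrix, where cov(i, j) is the
  shared root-to-MRCA branch length — the explicit evolutionary model
  behind Blomberg's K and PGLS.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .matrices import SquareTaxonMatrix

__all__ = [
    "read_tree",
    "tip_labels",
    "prune_tree",
    "bm_vcv",
    "abouheif_proximity",
    "read_fasta",
    "Alignment",
    "pairwise_distance",
    "distance_to_weights",
    "proximity_to_dissimilarity",
]


class TreeError(ValueError):
    pass


class DistanceError(ValueError):
    pass


def read_tree(
    path: str | Path,
    schema: str = "newick",
    allow_topology_only: bool = False,
) -> dendropy.Tree:
    """Read a rooted tree with branch lengths from Newick/Nexus.

    Unlabeled internal nodes and polytomies are accepted. Missing branch
    lengths are an error unless ``allow_topology_only`` is set, in which
    case unit lengths are substituted (with a warning in ``tree.annotations``
    left implicit; the caller opted in).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific parse errors
        if "uplicate" in str(exc):
            raise TreeError(f"duplicate tip labels: {exc}") from exc
        raise TreeError(f"cannot parse tree {path}: {exc}") from exc
    tree.is_rooted = True
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    missing = [
        e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node and e.length is None
    ]
    if missing:
        if not allow_topology_only:
            raise TreeError(
                f"{len(missing)} branches lack lengths; pass allow_topology_only=True "
                "to substitute unit lengths"
            )
        for e in missing:
            e.length = 1.0
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise TreeError("negative branch length")
    return tree


def tree_from_newick(newick: str, **kw) -> dendropy.Tree:
    """Parse a Newick string (convenience wrapper around :func:`read_tree`)."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    tree.is_rooted = True
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Tree:
    """Tree restricted to `taxa`, re-rooted at their MRCA (no stem edge)."""
    keep = set(taxa)
    have = set(tip_labels(tree))
    missing = keep - have
    if missing:
        raise TreeError(f"taxa absent from tree: {sorted(missing)}")
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    sub.is_rooted = True
    # drop any unifurcating stem above the MRCA of the kept taxa
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        sub.seed_node = child
    return sub


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def bm_vcv(tree: dendropy.Tree, taxa: Sequence[str] | None = None) -> SquareTaxonMatrix:
    """Brownian-motion variance-covariance matrix of a rooted tree.

    ``C[i, i]`` is the root-to-tip path length and ``C[i, j]`` the
    root-to-MRCA path length. With ``taxa`` given, the matrix is that of the
    subtree spanned by those tips rooted at their MRCA (equivalently, the
    submatrix of the full vcv shifted down by the MRCA depth).
    """
    if tree.seed_node is None:
        raise TreeError("tree has no root")
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    idx = {lf: i for i, lf in enumerate(leaves)}
    C = np.zeros((n, n))
    for lf in leaves:
        C[idx[lf], idx[lf]] = depths[lf]
    # cross-subtree pairs at each internal node share that node's depth
    leafsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[nd] = [idx[nd]]
        else:
            kids = [leafsets[ch] for ch in nd.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.array(kids[a])
                    ib = np.array(kids[b])
                    C[np.ix_(ia, ib)] = depths[nd]
                    C[np.ix_(ib, ia)] = depths[nd]
            leafsets[nd] = [i for k in kids for i in k]
    M = SquareTaxonMatrix(labels, C, "covariance")
    if taxa is not None:
        M = M.reorder(list(taxa))
        if M.n >= 2:
            i, j = np.tril_indices(M.n, k=-1)
            shift = M.values[i, j].min()
            M = SquareTaxonMatrix(
                M.taxa, M.values - shift, "covariance", dict(M.meta)
            )
    return M


def _collapse_zero_internal(tree: dendropy.Tree) -> dendropy.Tree:
    """Clone with zero-length internal branches collapsed to polytomies."""
    t = tree.clone(depth=1)
    changed = True
    while changed:
        changed = False
        for nd in list(t.postorder_internal_node_iter()):
            if nd is t.seed_node:
                continue
            if nd.edge.length is not None and nd.edge.length == 0:
                parent = nd.parent_node
                for ch in list(nd.child_nodes()):
                    nd.remove_child(ch)
                    parent.add_child(ch)
                parent.remove_child(nd)
                changed = True
    return t


def abouheif_proximity(tree: dendropy.Tree) -> SquareTaxonMatrix:
    """Abouheif phylogenetic proximities (topology only, "oriAbouheif").

    Off-diagonal ``A[i, j]`` is the product, over the interior nodes on the
    path from tip i to tip j, of one over the node's number of direct
    descendants; the diagonal is set so every row sums to one. Branch
    lengths are ignored; zero-length internal branches are collapsed to
    polytomies first so that soft polytomies are honoured.
    """
    t = _collapse_zero_internal(tree)
    leaves = list(t.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    # ancestors from parent up to root, for each leaf
    anc: list[list] = []
    for lf in leaves:
        chain = []
        nd = lf.parent_node
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        anc.append(chain)
    dd = {nd: len(nd.child_nodes()) for nd in t.preorder_internal_node_iter()}
    A = np.zeros((n, n))
    for i in range(n):
        anc_i = anc[i]
        set_i = {id(x): k for k, x in enumerate(anc_i)}
        for j in range(i + 1, n):
            # walk j's chain up to the first node shared with i's chain (MRCA)
            prod = 1.0
            for nd in anc[j]:
                prod /= dd[nd]
                if id(nd) in set_i:
                    mrca_pos = set_i[id(nd)]
                    break
            for k in range(mrca_pos):
                prod /= dd[anc_i[k]]
            A[i, j] = A[j, i] = prod
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    return SquareTaxonMatrix(labels, A, "proximity")


class Alignment:
    """A simple aligned nucleotide matrix (rows = taxa, upper-cased)."""

    def __init__(self, ids: Sequence[str], seqs: Sequence[str]):
        self.ids = [str(i) for i in ids]
        self.seqs = [s.upper() for s in seqs]
        if len(self.ids) < 2:
            raise ValueError("alignment needs at least two taxa")
        L = len(self.seqs[0])
        for i, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise ValueError(
                    f"ragged alignment: record {i!r} has length {len(s)}, expected {L}"
                )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])

    def to_fasta(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for i, s in zip(self.ids, self.seqs):
                fh.write(f">{i}\n{s}\n")


def read_fasta(path: str | Path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("U")] = 3  # RNA alignments


def _encode(aln: Alignment) -> np.ndarray:
    arr = np.frombuffer(
        "".join(aln.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_taxa, aln.n_sites)
    return _CODE[arr]


def pairwise_distance(aln: Alignment, model: str = "jc69") -> SquareTaxonMatrix:
    """Pairwise nucleotide distances (substitutions/site).

    Sites holding a gap, N, or any ambiguity code in either member of a pair
    are removed for that pair only (pairwise deletion). Models:

    * ``p``    — mismatch fraction;
    * ``jc69`` — d = -(3/4) ln(1 - (4/3) p);
    * ``k2p``  — d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q) with P, Q the
      transition / transversion proportions.
    """
    if model not in ("p", "jc69", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    X = _encode(aln)
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = X[i], X[j]
            ok = (a < 4) & (b < 4)
            L = int(ok.sum())
            if L == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            aa, bb = a[ok], b[ok]
            diff = aa != bb
            p = diff.mean()
            if model == "p":
                d = p
            elif model == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    raise DistanceError(
                        f"JC69 saturated (p={p:.3f}) for pair "
                        f"({aln.ids[i]!r}, {aln.ids[j]!r})"
                    )
                d = -0.75 * math.log(arg)
            else:
                transition = diff & ((aa % 2) == (bb % 2))  # A<->G, C<->T
                P = transition.mean()
                Q = p - P
                a1 = 1.0 - 2.0 * P - Q
                a2 = 1.0 - 2.0 * Q
                if a1 <= 0 or a2 <= 0:
                    raise DistanceError(
                        f"K2P saturated for pair ({aln.ids[i]!r}, {aln.ids[j]!r})"
                    )
                d = -0.5 * math.log(a1) - 0.25 * math.log(a2)
            D[i, j] = D[j, i] = d
    return SquareTaxonMatrix(aln.ids, D, "distance", {"model": model})


def distance_to_weights(
    D: SquareTaxonMatrix, scheme: str = "inverse"
) -> SquareTaxonMatrix:
    """Row-standardized neighbour weights from a distance matrix.

    ``inverse`` (default) sets w_ij = 1/d_ij, ``inverse_squared`` 1/d_ij^2,
    ``rank`` 1/rank(d_ij) within row; rows are then scaled to sum to one.
    Zero distances are replaced by half the smallest positive distance
    before inversion so identical taxa become strong (finite) neighbours.
    """
    if D.kind != "distance":
        raise ValueError("weights require a distance matrix")
    d = D.values.copy()
    off = ~np.eye(D.n, dtype=bool)
    pos = d[off][d[off] > 0]
    if pos.size == 0:
        raise ValueError("degenerate distance matrix: all distances zero")
    d[off & (d == 0)] = pos.min() / 2.0
    np.fill_diagonal(d, 1.0)  # placeholder; masked out below
    if scheme == "inverse":
        w = np.where(off, 1.0 / d, 0.0)
    elif scheme == "inverse_squared":
        w = np.where(off, 1.0 / d**2, 0.0)
    elif scheme == "rank":
        w = np.zeros_like(d)
        for i in range(D.n):
            row = d[i].copy()
            order = np.argsort(row)
            order = order[order != i]
            ranks = np.empty(D.n)
            ranks[order] = np.arange(1, D.n)
            w[i] = np.where(off[i], 1.0 / ranks, 0.0)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    w /= w.sum(axis=1, keepdims=True)
    return SquareTaxonMatrix(D.taxa, w, "weight", {"scheme": scheme})


def proximity_to_weights(A: SquareTaxonMatrix) -> SquareTaxonMatrix:
    """Abouheif proximities as Moran weights: zero diagonal, rows re-scaled."""
    if A.kind != "proximity":
        raise ValueError("expected a proximity matrix")
    w = A.values.copy()
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    return SquareTaxonMatrix(A.taxa, w, "weight", {"scheme": "abouheif"})


def proximity_to_dissimilarity(A: SquareTaxonMatrix) -> SquareTaxonMatrix:
    """Affine flip of a proximity matrix into a dissimilarity.

    d_ij = max_offdiag(A) - A_ij with a zero diagonal. Mantel r is invariant
    to positive affine maps of matrix entries, so correlating a trait
    distance with this is exactly the sign-flip of correlating with A —
    which makes "signal" come out with a positive r in both conventions.
    """
    if A.kind != "proximity":
        raise ValueError("expected a proximity matrix")
    off = ~np.eye(A.n, dtype=bool)
    m = A.values[off].max()
    d = m - A.values
    np.fill_diagonal(d, 0.0)
    return SquareTaxonMatrix(A.taxa, d, "distance", {"derived": "abouheif"})
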