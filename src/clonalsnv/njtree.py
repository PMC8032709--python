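"""Distance phylogenetics on coded genotype sequences.

Biallelic dosages are coded one character per marker — R (homozygous
reference), H (heterozygous), A (homozygous alternative), ? (missing) — and
compared with uncorrected p-distances under pairwise deletion.  Trees are
built by neighbor joining with deterministic tie-breaking, supports by
nonparametric bootstrap over markers, and rooting uses the reference
genotype (all-R) as outgroup.  Characters are matched as distinct states:
R vs A counts as one difference like any other mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .errors import UndefinedDistanceError
from .genotypes import GenotypeMatrix

_CODE = {0.0: "R", 1.0: "H", 2.0: "A"}


@dataclass(frozen=True)
class CodedSequence:
    name: str
    chars: str

    def __post_init__(self) -> None:
        bad = set(self.chars) - set("RHA?")
        if bad:
            raise ValueError(f"invalid character codes {sorted(bad)}")


def code_genotypes(
    m: GenotypeMatrix, outgroup: Optional[str] = "PN40024"
) -> List[CodedSequence]:
    """Code each sample's dosages to an R/H/A/? character string.

    When ``outgroup`` is a name, an all-R sequence under that name is
    appended: the reference genome is homozygous reference at every marker
    by construction, which provides the rooting genotype.
    """
    seqs = []
    for sample in m.samples:
        row = m.data.loc[sample]
        chars = "".join("?" if np.isnan(v) else _CODE[float(v)] for v in row)
        seqs.append(CodedSequence(sample, chars))
    if outgroup is not None:
        seqs.append(CodedSequence(outgroup, "R" * len(m.markers)))
    return seqs


def p_distance(a: CodedSequence, b: CodedSequence) -> float:
    """Proportion of differing characters, missing excluded pairwise."""
    if len(a.chars) != len(b.chars):
        raise ValueError("sequences must have equal length")
    x = np.frombuffer(a.chars.encode(), dtype="S1")
    y = np.frombuffer(b.chars.encode(), dtype="S1")
    comparable = (x != b"?") & (y != b"?")
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError(f"no comparable sites between {a.name} and {b.name}")
    return float(np.sum(x[comparable] != y[comparable]) / n)


@dataclass
class DistanceMatrix:
    names: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match the taxon list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("diagonal must be zero")


def distance_matrix(seqs: Sequence[CodedSequence]) -> DistanceMatrix:
    names = [s.name for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[i], seqs[j])
    return DistanceMatrix(names, d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei, Q-criterion agglomeration).

    Ties in Q are broken by taxon order; negative branch lengths are clamped
    to zero (the computed total edge length stays on the sibling branch).
    The final pair is joined through the root with the remaining distance
    split evenly, which leaves all leaf-to-leaf path lengths unchanged.
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    tns = dendropy.TaxonNamespace(dm.names)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: List[dendropy.Node] = []
    for name in dm.names:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # row-major: first minimal (i, j) in taxon order
        i_loc, j_loc = divmod(int(flat), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k not in (i, j):
                new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    half = max(D[i, j] / 2.0, 0.0)
    nodes[i].edge.length = half
    nodes[j].edge.length = half
    tree.seed_node = root
    tree.is_rooted = False
    return tree


Bipartition = FrozenSet[str]


def bipartitions(tree: dendropy.Tree) -> Set[Bipartition]:
    """Nontrivial unrooted splits, canonicalised as the side not containing
    the alphabetically first leaf."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    out: Set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap_supports(
    seqs: Sequence[CodedSequence], n_reps: int = 200, seed: int = 0
) -> Tuple[dendropy.Tree, Dict[Bipartition, float]]:
    """NJ tree with bootstrap supports on its internal bipartitions.

    Markers are resampled with replacement per replicate; the support of an
    internal split of the full-data tree is the percentage of replicate
    trees containing it.  Supports are written as internal node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    full = nj_tree(distance_matrix(seqs))
    target = bipartitions(full)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_chars = len(seqs[0].chars)
    for _ in range(n_reps):
        cols = rng.integers(0, n_chars, size=n_chars)
        resampled = [
            CodedSequence(s.name, "".join(s.chars[c] for c in cols)) for s in seqs
        ]
        try:
            rep_tree = nj_tree(distance_matrix(resampled))
        except UndefinedDistanceError:
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    _annotate_supports(full, supports)
    return full, supports


def _annotate_supports(tree: dendropy.Tree, supports: Dict[Bipartition, float]) -> None:
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor, all_leaves = leaves[0], frozenset(leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if side in supports:
            node.label = f"{supports[side]:.0f}"


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root the tree on the outgroup's pendant edge (split at its midpoint)."""
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    if tree.is_rooted and node.parent_node is tree.seed_node \
            and len(tree.seed_node.child_nodes()) == 2:
        return tree  # already rooted on this outgroup
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree
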