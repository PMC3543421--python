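"""Pan-genome presence/absence analysis and gene-content trees.

The binary replicons x gene-families matrix drives everything downstream:
gene-content distances (Jaccard by default, a shared-over-smaller log
distance as the alternative), a neighbor-joining tree, single-linkage
subfamily delineation, and per-family conservation classes (core /
semi-conserved / group-specific / singleton).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import squareform

from .homology import GeneFamily


class ConservationClass(str, Enum):
    CORE = "core"
    SEMI_CONSERVED = "semi_conserved"
    GROUP_SPECIFIC = "group_specific"
    SINGLETON = "singleton"


# colour convention for comparative gene maps: core red, semi-conserved
# green, group-specific blue
CLASS_COLORS = {
    ConservationClass.CORE: "red",
    ConservationClass.SEMI_CONSERVED: "green",
    ConservationClass.GROUP_SPECIFIC: "blue",
    ConservationClass.SINGLETON: "grey",
}


def presence_matrix(families: list[GeneFamily],
                    replicon_ids: list[str]) -> pd.DataFrame:
    """Binary replicons x families matrix; paralogs collapse to presence."""
    if not families:
        raise ValueError("no gene families given")
    known = set(replicon_ids)
    data = {}
    for f in families:
        col = pd.Series(0, index=replicon_ids, dtype=int)
        for rep, _pid in f.members:
            if rep not in known:
                raise ValueError(f"family {f.family_id}: unknown replicon {rep!r}")
            col[rep] = 1
        data[f.family_id] = col
    m = pd.DataFrame(data, index=replicon_ids)
    return m.loc[:, (m.sum(axis=0) > 0)]


def paralog_counts(families: list[GeneFamily],
                   replicon_ids: list[str]) -> pd.DataFrame:
    """Sidecar matrix of member counts per replicon (not binarized)."""
    data = {}
    for f in families:
        col = pd.Series(0, index=replicon_ids, dtype=int)
        for rep, _pid in f.members:
            col[rep] += 1
        data[f.family_id] = col
    return pd.DataFrame(data, index=replicon_ids)


def gene_content_distance(m: pd.DataFrame, method: str = "jaccard",
                          zero_overlap_ceiling: float = 5.0) -> pd.DataFrame:
    """Pairwise gene-content distances from a presence/absence matrix.

    jaccard:    d = 1 - |A∩B| / |A∪B|
    shared_min: d = -ln(|A∩B| / min(|A|, |B|)), empty intersections mapped
                to ``zero_overlap_ceiling``
    """
    if m.shape[0] < 2:
        raise ValueError("need at least two replicons")
    sizes = m.sum(axis=1)
    if (sizes == 0).any():
        empty = list(m.index[sizes == 0])
        raise ValueError(f"replicons with zero families: {empty}")
    X = m.to_numpy(dtype=float)
    inter = X @ X.T
    size = X.sum(axis=1)
    if method == "jaccard":
        union = size[:, None] + size[None, :] - inter
        d = 1.0 - inter / union
    elif method == "shared_min":
        mins = np.minimum(size[:, None], size[None, :])
        with np.errstate(divide="ignore"):
            d = -np.log(inter / mins)
        d[~np.isfinite(d)] = zero_overlap_ceiling
    else:
        raise ValueError(f"unknown distance method {method!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.index, columns=m.index)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix is not square")
    if not np.all(np.isfinite(a)):
        raise ValueError("distance matrix has non-finite entries")
    if not np.allclose(a, a.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    return a


# ---------------------------------------------------------------------------
# neighbor joining

class TreeNode:
    """Node of an (un)rooted tree; edge length is toward the parent."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None,
                 children: list["TreeNode"] | None = None,
                 length: float = 0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        if self.length or self.name:
            return f"({inner}){self.name or ''}:{self.length:.6g}"
        return f"({inner})"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions (as leaf-name frozensets, smaller side)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        for c in self.children:
            walk(c)
        return out


@dataclass
class GeneContentTree:
    root: TreeNode  # trifurcating root = unrooted tree

    @property
    def newick(self) -> str:
        return self.root.newick()

    def splits(self) -> set[frozenset]:
        return self.root.splits()

    def leaves(self) -> list[str]:
        return sorted(self.root.leaves())


def nj_tree(d: pd.DataFrame) -> GeneContentTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined each round; among ties the
    lowest (i, j) index pair in the current matrix order wins. Negative
    branch lengths are clamped to 0 with the deficit shifted to the sister
    branch. The result is unrooted (trifurcating root node).
    """
    D = _check_distance(d).copy()
    ids = list(d.index)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        r = np.array([sum(D[i][j] for j in active if j != i) for i in active])
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = D[i][j] / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = D[i][j] - li
        li, lj = _clamp(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        # grow matrix and node list in place
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            D[k][a] = D[a][k] = (D[i][a] + D[j][a] - D[i][j]) / 2
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [k]

    i, j, k = active
    li = (D[i][j] + D[i][k] - D[j][k]) / 2
    lj = (D[i][j] + D[j][k] - D[i][k]) / 2
    lk = (D[i][k] + D[j][k] - D[i][j]) / 2
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return GeneContentTree(TreeNode(children=[nodes[i], nodes[j], nodes[k]]))


def root_with_outgroup(tree: GeneContentTree, outgroup: str) -> TreeNode:
    """Rooted copy of the tree, root placed mid-way on the outgroup's edge."""
    # rebuild as adjacency, then hang from the outgroup pendant edge
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}
    counter = [0]

    def build(node: TreeNode) -> int:
        idx = counter[0]
        counter[0] += 1
        names[idx] = node.name
        adj.setdefault(idx, [])
        for c in node.children:
            ci = build(c)
            adj[idx].append((ci, c.length))
            adj[ci].append((idx, c.length))
        return idx

    build(tree.root)
    leaf_idx = next(i for i, nm in names.items() if nm == outgroup)
    (nbr, length), = adj[leaf_idx]

    def hang(idx: int, parent: int, edge_len: float) -> TreeNode:
        node = TreeNode(name=names[idx], length=edge_len)
        for ci, clen in adj[idx]:
            if ci != parent:
                node.children.append(hang(ci, idx, clen))
        return node

    root = TreeNode()
    root.children = [hang(leaf_idx, nbr, length / 2), hang(nbr, leaf_idx, length / 2)]
    return root


def to_phylip(d: pd.DataFrame) -> str:
    lines = [f" {len(d.index)}"]
    for rid in d.index:
        vals = " ".join(f"{d.loc[rid, c]:.6f}" for c in d.index)
        lines.append(f"{rid[:10]:<10} {vals}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# subfamilies and conservation classes

def delineate_subfamilies(d: pd.DataFrame, k: int = 2,
                          threshold: float | None = None) -> dict[str, int]:
    """Single-linkage agglomerative clustering of replicons.

    Cut to ``k`` clusters (default 2) or at ``threshold`` distance. Labels
    are renumbered 0.. by first appearance in matrix order, so the output
    is deterministic; all-tied matrices therefore split by index order.
    """
    a = _check_distance(d)
    n = len(d.index)
    if threshold is None and not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    Z = linkage(squareform(a, checks=False), method="single")
    if threshold is not None:
        raw = fcluster(Z, t=threshold, criterion="distance")
    else:
        # cut_tree returns exactly k clusters even under tied merge heights
        raw = cut_tree(Z, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = {}
    for rid, c in zip(d.index, raw):
        if c not in relabel:
            relabel[c] = len(relabel)
        labels[rid] = relabel[c]
    return labels


def classify_conservation(m: pd.DataFrame,
                          labels: dict[str, int]) -> dict[str, ConservationClass]:
    """Assign each family a conservation class given subfamily labels.

    core: in all replicons; semi_conserved: in >=1 replicon of each
    subfamily but not all; group_specific: in >=2 replicons of exactly one
    subfamily; singleton: in exactly one replicon.
    """
    missing = set(m.index) - set(labels)
    if missing:
        raise ValueError(f"labels missing for replicons: {sorted(missing)}")
    if len(set(labels.values())) < 2:
        raise ValueError("need at least two subfamilies")
    out: dict[str, ConservationClass] = {}
    for fam in m.columns:
        present = [r for r in m.index if m.loc[r, fam]]
        groups = {labels[r] for r in present}
        if len(present) == len(m.index):
            out[fam] = ConservationClass.CORE
        elif len(present) == 1:
            out[fam] = ConservationClass.SINGLETON
        elif len(groups) >= 2:
            out[fam] = ConservationClass.SEMI_CONSERVED
        else:
            out[fam] = ConservationClass.GROUP_SPECIFIC
    return out
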