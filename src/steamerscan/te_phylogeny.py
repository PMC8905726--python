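"""Distance phylogeny of RT/RNaseH domains and bootstrap-supported family definition.

Distances are p-distances under pairwise deletion (sites where either
sequence has a gap or unknown residue are excluded pair by pair).  Trees are
built with canonical neighbor joining, which is exact on additive matrices;
negative branch lengths are clamped to zero.  Clade support comes from
nonparametric bootstrapping (columns resampled with replacement, distances
and tree recomputed, supports = percent of replicates containing each
original internal bipartition).

Families ("branches") are bipartition sides whose bootstrap support is
strictly greater than the threshold (default 80) and whose members span at
least two species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)

GAP_CHARS = set("-.?X*x")


class MatrixError(ValueError):
    pass


class DistanceError(ValueError):
    pass


class MappingError(KeyError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    compared_sites: np.ndarray | None = None  # pairwise-deletion site counts

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise MatrixError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise MatrixError("matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise MatrixError("diagonal must be zero")
        if np.any(m < 0):
            raise MatrixError("distances must be >= 0")


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass(frozen=True)
class BranchGroup:
    members: frozenset[str]
    species: frozenset[str]
    support: float
    name: str


def pairwise_deletion_pdist(alignment: list[tuple[str, str]]) -> DistanceMatrix:
    """p-distance with pairwise deletion of gap/unknown sites.

    distance(a,b) = mismatches / compared sites, comparing only columns where
    neither row has a gap or unknown character.  A pair with zero comparable
    sites raises a DistanceError naming the pair.
    """
    if len(alignment) < 2:
        raise MatrixError("need at least two rows")
    ids = [i for i, _ in alignment]
    rows = [r.upper() for _, r in alignment]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise MatrixError("alignment is not rectangular")
    mat_chars = np.array([list(r) for r in rows])
    ok = ~np.isin(mat_chars, list(GAP_CHARS))
    n = len(ids)
    dist = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        both = ok[i] & ok[j]
        m = int(both.sum())
        if m == 0:
            raise DistanceError(f"no comparable sites between {ids[i]} and {ids[j]}")
        d = float((mat_chars[i, both] != mat_chars[j, both]).sum()) / m
        dist[i, j] = dist[j, i] = d
        sites[i, j] = sites[j, i] = m
    return DistanceMatrix(ids=ids, matrix=dist, compared_sites=sites)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou & Nei); exact on additive matrices.

    Returns an unrooted tree represented with a trifurcating root.  Negative
    branch lengths are clamped to zero with a log line.
    """
    dist.validate()
    n = len(dist.ids)
    if n < 3:
        raise MatrixError("NJ needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dist.ids]
    D = dist.matrix.astype(float).copy()
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        i_, j_ = (i_, j_) if i_ < j_ else (j_, i_)
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped += 1
        li, lj = max(0.0, li), max(0.0, lj)
        parent = TreeNode()
        nodes[ai].length, nodes[aj].length = li, lj
        parent.children = [nodes[ai], nodes[aj]]
        # distances from the new node
        newd = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = newd
        D[active, -1] = newd
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            clamped += 1
        nodes[idx].length = max(0.0, ln)
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to zero", clamped)
    root = TreeNode()
    root.children = [nodes[a], nodes[b], nodes[c]]
    return root


def tree_bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Non-trivial bipartitions (as the leaf set under each internal edge)."""
    all_leaves = frozenset(lf.name for lf in tree.leaves())
    out: dict[frozenset[str], TreeNode] = {}

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            out[below] = node
        return below

    walk(tree)
    return out


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length distances between leaves (for additivity checks)."""
    leaves = sorted(lf.name for lf in tree.leaves())
    idx = {t: i for i, t in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: node.length}
        below: dict[str, float] = {}
        child_sets = [walk(c) for c in node.children]
        for a, b in combinations(range(len(child_sets)), 2):
            for ta, da in child_sets[a].items():
                for tb, db in child_sets[b].items():
                    D[idx[ta], idx[tb]] = D[idx[tb], idx[ta]] = da + db
        for cs in child_sets:
            for t, d in cs.items():
                below[t] = d + node.length
        return below

    walk(tree)
    return DistanceMatrix(ids=leaves, matrix=D)


def bootstrap_support(
    alignment: list[tuple[str, str]],
    replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with nonparametric bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement, recomputes
    the pairwise-deletion p-distance matrix and the NJ tree; support is the
    percentage of replicates whose tree contains the original bipartition.
    """
    if not alignment or not alignment[0][1]:
        raise MatrixError("alignment must have at least one column")
    tree = nj_tree(pairwise_deletion_pdist(alignment))
    original = tree_bipartitions(tree)
    full = frozenset(i for i, _ in alignment)
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    ids = [i for i, _ in alignment]
    rows = np.array([list(r) for _, r in alignment])
    width = rows.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        resampled = ["".join(r) for r in rows[:, cols]]
        try:
            rep_tree = nj_tree(pairwise_deletion_pdist(list(zip(ids, resampled))))
        except DistanceError:
            continue  # replicate dropped all comparable sites for a pair
        rep_bips = set(tree_bipartitions(rep_tree))
        rep_both = rep_bips | {full - bp for bp in rep_bips}
        for bp in counts:
            if bp in rep_both or (full - bp) in rep_both:
                counts[bp] += 1
    for bp, node in original.items():
        node.support = round(100.0 * counts[bp] / replicates, 1)
    return tree


def define_branches(
    tree: TreeNode,
    species_map: dict[str, str],
    min_support: float = 80.0,
    min_species: int = 2,
    report_nested: bool = False,
    outgroup: set[str] | None = None,
) -> list[BranchGroup]:
    """Families: supported multi-species clades on the (unrooted) tree.

    Every bipartition side is a candidate clade; it qualifies when its
    bootstrap support is strictly greater than min_support and its members
    span at least min_species species.  With an outgroup given, only sides
    excluding the outgroup are considered (implicit rooting); nested
    qualifying clades are dropped in favor of the maximal one unless
    report_nested is true.
    """
    taxa = {lf.name for lf in tree.leaves()}
    unmapped = taxa - set(species_map)
    if unmapped:
        raise MappingError(f"taxa without species mapping: {sorted(unmapped)}")
    full = frozenset(taxa)
    candidates: list[tuple[frozenset[str], float]] = []
    for bp, node in tree_bipartitions(tree).items():
        if node.support is None:
            continue
        for side in (bp, full - bp):
            if len(side) < 2:
                continue
            if outgroup is not None and side & outgroup:
                continue
            candidates.append((side, node.support))
    groups: list[BranchGroup] = []
    for side, support in candidates:
        species = frozenset(species_map[t] for t in side)
        if support > min_support and len(species) >= min_species:
            groups.append(
                BranchGroup(members=side, species=species, support=support, name="")
            )
    if not report_nested:
        groups = [
            g
            for g in groups
            if not any(g is not h and g.members < h.members for h in groups)
        ]
    groups.sort(key=lambda g: (-len(g.members), sorted(g.members)))
    return [
        BranchGroup(g.members, g.species, g.support, name=f"branch{i+1}")
        for i, g in enumerate(groups)
    ]
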