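"""Distance clustering of Ty element alignments: NJ, BIONJ, bootstrap, newick.

Both agglomeration schemes use the classic Q-criterion to pick the pair to
join and the same limb-length formulas; they differ in how distances to the
merged node are formed.  Neighbor joining (Saitou & Nei) averages the two
distances; BIONJ (Gascuel) weights them by a variance model, which is exact
on additive matrices and more robust to heteroscedastic distance noise.
Ties in the Q matrix break deterministically toward the lowest label-index
pair.  Negative branch lengths are retained (and logged), not clamped.

Trees are scikit-bio ``TreeNode`` objects (unrooted, trifurcating root);
bootstrap supports are stored as integer internal-node names, the convention
newick uses for support labels.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import TreeNode

from .divergence import DistanceMatrix, distance_matrix

__all__ = [
    "build_tree",
    "nj_tree",
    "bionj_tree",
    "bootstrap_supports",
    "bipartitions",
    "write_newick",
    "read_newick",
    "same_topology",
]

logger = logging.getLogger(__name__)


def _limb_lengths(d: np.ndarray, i: int, j: int) -> tuple[float, float]:
    n = d.shape[0]
    r = d.sum(axis=1)
    if n > 2:
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
    else:
        li = 0.5 * d[i, j]
    return li, d[i, j] - li


def _q_argmin(d: np.ndarray) -> tuple[int, int]:
    """Lowest-(i,j) pair minimising the NJ Q criterion."""
    n = d.shape[0]
    r = d.sum(axis=1)
    q = (n - 2) * d - r[:, None] - r[None, :]
    np.fill_diagonal(q, np.inf)
    best = None
    best_q = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            # strict < keeps the lowest label-index pair on ties
            if q[i, j] < best_q - 1e-12:
                best_q = q[i, j]
                best = (i, j)
    return best


def _agglomerate(dm: DistanceMatrix, method: str) -> TreeNode:
    n0 = len(dm)
    if n0 < 3:
        raise ValueError("need at least 3 labels to build an unrooted tree")
    if not np.isfinite(dm.d).all():
        raise ValueError("distance matrix contains NA/non-finite entries")
    d = dm.d.astype(float).copy()
    v = d.copy()  # BIONJ variance estimates; initialised to the distances
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]

    while len(nodes) > 3:
        n = d.shape[0]
        i, j = _q_argmin(d)
        li, lj = _limb_lengths(d, i, j)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = float(li), float(lj)
        if li < 0 or lj < 0:
            logger.info("negative branch length at join (%s, %s): %.4g / %.4g",
                        ni.name, nj_.name, li, lj)
        parent = TreeNode(children=[ni, nj_])

        others = [k for k in range(n) if k not in (i, j)]
        if method == "bionj":
            vij = v[i, j]
            if vij > 0:
                lam = 0.5 + (v[j, others] - v[i, others]).sum() / (2 * (n - 2) * vij)
                lam = min(1.0, max(0.0, float(lam)))
            else:
                lam = 0.5
        else:
            lam = 0.5
        new_d = lam * d[i, others] + (1 - lam) * d[j, others] - lam * li - (1 - lam) * lj
        new_v = lam * v[i, others] + (1 - lam) * v[j, others] - lam * (1 - lam) * v[i, j]

        keep = others
        d2 = np.zeros((n - 1, n - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d
        v2 = np.zeros((n - 1, n - 1))
        v2[:-1, :-1] = v[np.ix_(keep, keep)]
        v2[-1, :-1] = v2[:-1, -1] = new_v
        d, v = d2, v2
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form three-point connection at the trifurcating root
    (a, b, c) = nodes
    da_b, da_c, db_c = d[0, 1], d[0, 2], d[1, 2]
    a.length = float(0.5 * (da_b + da_c - db_c))
    b.length = float(0.5 * (da_b + db_c - da_c))
    c.length = float(0.5 * (da_c + db_c - da_b))
    return TreeNode(children=[a, b, c])


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    return _agglomerate(dm, "nj")


def bionj_tree(dm: DistanceMatrix) -> TreeNode:
    return _agglomerate(dm, "bionj")


def build_tree(dm: DistanceMatrix, method: str = "bionj") -> TreeNode:
    """Unrooted distance tree by NJ or BIONJ agglomeration."""
    if method not in ("nj", "bionj"):
        raise ValueError(f"unknown method {method!r}")
    return _agglomerate(dm, method)


# ---------------------------------------------------------------------------
# Topology comparison and bootstrap


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as leaf-name subsets.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest leaf represents the bipartition, making the
    set rotation- and rooting-invariant.
    """
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            parts.add(frozenset(side))
    return parts


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    if {t.name for t in t1.tips()} != {t.name for t in t2.tips()}:
        return False
    return bipartitions(t1) == bipartitions(t2)


def bootstrap_supports(
    msa: dict[str, str],
    method: str = "bionj",
    replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, TreeNode | None, int]:
    """Point-estimate tree with bootstrap supports, plus the majority-rule consensus.

    Alignment columns are resampled with replacement per replicate; the
    support of each internal bipartition of the point tree is the percentage
    of replicate trees containing it, stored as the internal node name.
    Replicates whose resample yields an undefined K2P pair are dropped (the
    number kept is returned).  ``replicates=0`` returns the bare point tree.
    """
    point = build_tree(distance_matrix(msa), method)
    if replicates == 0:
        return point, None, 0
    rng = np.random.default_rng(seed)
    ids = list(msa)
    width = len(next(iter(msa.values())))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point)}
    rep_trees: list[TreeNode] = []
    kept = 0
    for _ in range(replicates):
        cols = rng.integers(0, width, width)
        res = {k: "".join(msa[k][c] for c in cols) for k in ids}
        try:
            t = build_tree(distance_matrix(res), method)
        except ValueError:
            continue  # undefined distances in this resample
        kept += 1
        rep_trees.append(t)
        parts = bipartitions(t)
        for bp in counts:
            if bp in parts:
                counts[bp] += 1

    leaves = {t.name for t in point.tips()}
    anchor = min(leaves)
    for node in point.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = leaves - side
        bp = frozenset(side)
        if bp in counts and kept:
            node.name = str(round(100 * counts[bp] / kept))
    consensus = None
    if rep_trees:
        from skbio.tree import majority_rule

        cons = majority_rule(rep_trees)
        consensus = cons[0] if isinstance(cons, list) else cons
    return point, consensus, kept


# ---------------------------------------------------------------------------
# Newick I/O (scikit-bio behind the surface)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick in {path}: {exc}") from exc


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
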