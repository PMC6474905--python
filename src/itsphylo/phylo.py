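"""Tree building: neighbor-joining, Fitch parsimony with NNI search,
nonparametric bootstrap, and out-group rooting.

Neighbor-joining is the Saitou–Nei agglomeration on a distance matrix;
parsimony trees come from hill-climbing nearest-neighbor-interchange (NNI)
moves scored by the Fitch small-parsimony algorithm, starting from the NJ
tree.  Support values are bootstrap proportions: columns are resampled
with replacement, the tree is rebuilt per replicate, and each internal
edge of the point-estimate tree is annotated with the percentage of
replicates whose tree contains the same leaf bipartition.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .align import Alignment
from .distance import DistanceMatrix, distance_matrix
from .tree import Node, Tree

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# neighbor-joining


def _nj_steps(dm: DistanceMatrix):
    """Run Saitou–Nei NJ; yield join events and return final node layout.

    Returns (joins, nodes, final_active) where ``joins`` is a list of
    (i, j, new_index, length_i, length_j) over internal joins, and
    ``final_active`` holds the 3 (or fewer) remaining indices with their
    distances for the terminal join.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError(
            "distance matrix contains NaN/inf; re-estimate the affected pairs "
            "(e.g. a different deletion policy or shorter-branch data) first")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return dist[(min(i, j), max(i, j))]

    active = list(range(n))
    next_idx = n
    joins = []
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                if best is None or q < best - 1e-12:
                    best, best_pair = q, (i, j)
                # ties: lowest index pair wins; scan order guarantees it
        i, j = best_pair
        li = 0.5 * d(i, j) + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d(i, j) - li
        li, lj = _clamp_pair(li, lj)
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]
        joins.append((i, j, u, li, lj))
    return joins, active, d


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative NJ branch lengths to 0, shifting the deficit to the
    sibling edge (standard practice)."""
    if li < 0:
        log.info("negative NJ branch length %.4g clamped to 0", li)
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0:
        log.info("negative NJ branch length %.4g clamped to 0", lj)
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def nj_join_order(dm: DistanceMatrix) -> list[tuple[int, int, int]]:
    """Join order (i, j, new_index) of NJ agglomeration; guide-tree use."""
    joins, active, d = _nj_steps(dm)
    order = [(i, j, u) for i, j, u, _, _ in joins]
    nxt = (max(o[2] for o in order) + 1) if order else len(dm.taxa)
    rest = list(active)
    while len(rest) > 1:
        i, j = rest[0], rest[1]
        order.append((i, j, nxt))
        rest = [nxt] + rest[2:]
        nxt += 1
    return order


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor-joining tree (unrooted, trifurcating root node)."""
    joins, active, d = _nj_steps(dm)
    nodes: dict[int, Node] = {
        i: Node(name=taxon) for i, taxon in enumerate(dm.taxa)
    }
    for i, j, u, li, lj in joins:
        parent = Node()
        ni, nj = nodes.pop(i), nodes.pop(j)
        parent.add(ni)
        ni.length = li
        parent.add(nj)
        nj.length = lj
        nodes[u] = parent
    if len(active) == 3:
        i, j, k = active
        root = Node()
        lens = {
            i: 0.5 * (d(i, j) + d(i, k) - d(j, k)),
            j: 0.5 * (d(i, j) + d(j, k) - d(i, k)),
            k: 0.5 * (d(i, k) + d(j, k) - d(i, j)),
        }
        for idx in active:
            child = nodes.pop(idx)
            root.add(child)
            if lens[idx] < 0:
                log.info("negative terminal NJ branch %.4g clamped to 0", lens[idx])
            child.length = max(lens[idx], 0.0)
    else:  # exactly 2 active (n was 2? not allowed) — defensive
        i, j = active
        root = Node()
        for idx, ln in ((i, d(i, j) / 2), (j, d(i, j) / 2)):
            child = nodes.pop(idx)
            root.add(child)
            child.length = ln
    return Tree(root, rooted=False)


def path_lengths(tree: Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (sum of branch lengths), for additivity checks."""
    out: dict[tuple[str, str], float] = {}

    def below(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        acc: dict[str, float] = {}
        per_child = []
        for child in node.children:
            sub = {k: v + (child.length or 0.0) for k, v in below(child).items()}
            per_child.append(sub)
            acc.update(sub)
        for a in range(len(per_child)):
            for b in range(a + 1, len(per_child)):
                for la, da in per_child[a].items():
                    for lb, db in per_child[b].items():
                        key = (min(la, lb), max(la, lb))
                        out[key] = da + db
        return acc

    below(tree.root)
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8}


def _column_patterns(aln: Alignment) -> tuple[list[tuple[int, ...]], list[int]]:
    """Collapse alignment columns to unique leaf-state-bitmask patterns with
    multiplicities (gap/ambiguity -> 0, i.e. missing)."""
    from collections import Counter

    ncols = aln.column_count
    masks_per_row = []
    for row in aln.rows:
        masks_per_row.append([_BITS.get(c, 0) for c in row])
    counter: Counter[tuple[int, ...]] = Counter()
    order: list[tuple[int, ...]] = []
    for col in range(ncols):
        pat = tuple(masks[col] for masks in masks_per_row)
        if pat not in counter:
            order.append(pat)
        counter[pat] += 1
    return order, [counter[p] for p in order]


def fitch_score(tree: Tree, aln: Alignment,
                weights: Optional[Sequence[float]] = None) -> float:
    """Total Fitch small-parsimony score of a topology for an alignment.

    Gaps and ambiguity codes are missing data: they contribute no state and
    force no changes.  ``weights`` reweights unique column patterns (used by
    the bootstrap); by default each column counts once.
    """
    tree_leaves = set(tree.leaf_names())
    if tree_leaves != set(aln.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    patterns, counts = _column_patterns(aln)
    if weights is None:
        weights = counts
    elif len(weights) != len(patterns):
        raise ValueError("weights must match unique pattern count")
    leaf_index = {t: k for k, t in enumerate(aln.taxa)}
    post = [n for n in tree.root.postorder()]
    total = 0.0
    for pat, w in zip(patterns, weights):
        if w == 0:
            continue
        changes = 0
        states: dict[int, int] = {}
        for node in post:
            if node.is_leaf:
                states[id(node)] = pat[leaf_index[node.name]]
                continue
            acc = 0  # running Fitch set over non-missing children
            started = False
            for child in node.children:
                cs = states[id(child)]
                if cs == 0:
                    continue
                if not started:
                    acc, started = cs, True
                    continue
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc |= cs
                    changes += 1
            states[id(node)] = acc if started else 0
        total += w * changes
    return total


# ---------------------------------------------------------------------------
# NNI parsimony search


def _postorder_index(tree: Tree) -> list[Node]:
    return list(tree.root.postorder())


def _nni_moves(tree: Tree) -> list[tuple[int, int, int]]:
    """Enumerate NNI moves as (v_index, child_slot, sibling_slot) over the
    postorder node numbering; deterministic scan order."""
    moves = []
    nodes = _postorder_index(tree)
    for vi, v in enumerate(nodes):
        if v.is_leaf or v.parent is None:
            continue
        parent = v.parent
        sib_slots = [k for k, c in enumerate(parent.children) if c is not v]
        if not sib_slots:
            continue
        for child_slot in range(len(v.children)):
            moves.append((vi, child_slot, sib_slots[0]))
    return moves


def _apply_nni(tree: Tree, move: tuple[int, int, int]) -> Tree:
    t2 = tree.copy()
    nodes = _postorder_index(t2)
    vi, child_slot, sib_slot = move
    v = nodes[vi]
    parent = v.parent
    child = v.children[child_slot]
    sib = parent.children[sib_slot]
    v.children[child_slot] = sib
    sib.parent = v
    parent.children[sib_slot] = child
    child.parent = parent
    return t2


def mp_search(aln: Alignment, start: Optional[Tree] = None,
              weights: Optional[Sequence[float]] = None,
              deletion: str = "pairwise") -> tuple[Tree, float]:
    """Maximum-parsimony topology by NNI hill climbing from the NJ tree.

    Strictly improving moves are accepted in a deterministic scan order;
    the search stops at the first local optimum.  Branch lengths are not
    estimated (parsimony trees report topology and support only).
    Returns (tree, parsimony score).
    """
    if len(aln.taxa) < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    if start is None:
        start = neighbor_joining(distance_matrix(aln, deletion=deletion))
    current = start.copy()
    for node in current.root.walk():
        node.length = None
        node.support = None
    score = fitch_score(current, aln, weights)
    improved = True
    while improved:
        improved = False
        for move in _nni_moves(current):
            cand = _apply_nni(current, move)
            cand_score = fitch_score(cand, aln, weights)
            if cand_score < score:
                current, score = cand, cand_score
                improved = True
                break
    return current, score


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap(aln: Alignment, builder: str = "nj", B: int = 1000,
              seed: int = 0, deletion: str = "pairwise") -> Tree:
    """Bootstrap support for the point-estimate tree.

    Columns are resampled with replacement B times; per replicate the tree
    is rebuilt with the same builder ('nj' or 'mp'); each internal edge of
    the point tree gets the percentage of replicates containing its leaf
    bipartition.  Reproducible for a given seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if builder not in ("nj", "mp"):
        raise ValueError(f"unknown builder {builder!r}")
    rng = np.random.default_rng(seed)
    ncols = aln.column_count

    if builder == "nj":
        point = neighbor_joining(distance_matrix(aln, deletion=deletion))
    else:
        point, _ = mp_search(aln, deletion=deletion)

    target = {bp: 0 for bp in point.bipartitions()}
    failures = 0
    for _ in range(B):
        cols = rng.integers(0, ncols, size=ncols)
        res = Alignment(taxa=list(aln.taxa),
                        rows=["".join(r[c] for c in cols) for r in aln.rows])
        try:
            if builder == "nj":
                rep = neighbor_joining(distance_matrix(res, deletion=deletion))
            else:
                rep, _ = mp_search(res, deletion=deletion)
        except ValueError as exc:
            failures += 1
            log.warning("bootstrap replicate failed (%s); skipped", exc)
            continue
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    ok = B - failures
    if ok == 0:
        raise ValueError("all bootstrap replicates failed")
    if failures:
        log.warning("%d of %d bootstrap replicates failed", failures, B)

    out = point.copy()
    all_leaves = frozenset(out.leaf_names())
    anchor = min(all_leaves)
    for node in out.root.walk():
        if node.is_leaf or node is out.root:
            continue
        below = frozenset(node.leaf_names())
        side = below if anchor not in below else all_leaves - below
        if side in target:
            node.support = round(100.0 * target[side] / ok, 1)
    return out


# ---------------------------------------------------------------------------
# rooting


def root_on_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root a tree on the out-group leaf's pendant edge (split in half)."""
    t = tree.copy()
    leaf = t.find_leaf(outgroup)
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot root a single-node tree")
    edge_len = leaf.length if leaf.length is not None else 0.0
    parent.children.remove(leaf)
    leaf.parent = None

    def flip_up(node: Node) -> Node:
        gp = node.parent
        my_len, my_support = node.length, node.support
        node.parent = None
        if gp is not None:
            gp.children.remove(node)
            flipped = flip_up(gp)
            node.add(flipped)
            flipped.length = my_len
            flipped.support = my_support
        return node

    subtree = flip_up(parent)
    # suppress a degree-2 node left where the old (unrooted) root was
    _suppress_unary(subtree)
    new_root = Node()
    new_root.add(leaf)
    leaf.length = edge_len / 2 if leaf.length is not None else None
    new_root.add(subtree)
    subtree.length = edge_len / 2 if edge_len else subtree.length
    return Tree(new_root, rooted=True)


def _suppress_unary(node: Node) -> None:
    for child in list(node.children):
        _suppress_unary(child)
    for child in list(node.children):
        if not child.is_leaf and len(child.children) == 1:
            grand = child.children[0]
            if child.length is not None or grand.length is not None:
                grand.length = (child.length or 0.0) + (grand.length or 0.0)
            node.children[node.children.index(child)] = grand
            grand.parent = node
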