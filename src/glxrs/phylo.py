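"""Distance-based tree building: p/Poisson distances, neighbor joining,
nonparametric bootstrap supports, and outgroup rooting.

Trees are :class:`skbio.TreeNode` objects throughout, so Newick produced by
external maximum-likelihood software can be dropped in anywhere a tree built
here is accepted: the downstream concordance logic is estimator-agnostic.

Numerical conventions: gap handling is pairwise deletion (each pair is
compared over the columns where both rows are non-gap); the Poisson distance
caps p at 0.95 to avoid infinities; NJ breaks Q-matrix ties by the lowest
index pair and clamps negative branch lengths to zero, moving the deficit to
the sister branch; supports below 0.7 are the conventional flagging level.
"""

from __future__ import annotations

import io
import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .domains import AlignedSet

logger = logging.getLogger(__name__)

#: Conventional threshold below which branch supports are flagged as weak.
WEAK_SUPPORT = 0.7

_GAP = ord("-")


def _byte_rows(aln: AlignedSet) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])


def pairwise_distance(aln: AlignedSet, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under pairwise-deletion gap handling.

    ``model='p'`` is the mismatch fraction over shared (both non-gap)
    columns; ``model='poisson'`` is ``-ln(1 - p)`` with p capped at 0.95
    (capped pairs are logged).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(aln.ids) < 2:
        raise ValueError("pairwise_distance requires at least 2 rows")
    mat = _byte_rows(aln)
    nongap = mat != _GAP
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "ungapped columns"
                )
            p = float((mat[i, shared] != mat[j, shared]).sum()) / n_shared
            if model == "poisson":
                if p > 0.95:
                    logger.info(
                        "Poisson distance capped at p=0.95 for pair (%s, %s); "
                        "observed p=%.4f", aln.ids[i], aln.ids[j], p,
                    )
                    p = 0.95
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=list(aln.ids))


def build_nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; trifurcating root node).

    Deterministic for a given input: Q-matrix ties resolve to the lowest
    index pair.  Negative pair branch lengths are clamped to zero with the
    deficit moved to the sister branch.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(len(ids)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = sorted(np.unravel_index(int(np.argmin(q)), q.shape))
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ai, aj = active[i], active[j]
        nodes[ai].length = li
        nodes[aj].length = lj
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        # distances from the new node to every other active node
        new_row = np.full(d.shape[0] + 1, 0.0)
        for k_pos, ak in enumerate(active):
            if k_pos in (i, j):
                continue
            new_row[ak] = 0.5 * (d[ai, ak] + d[aj, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :] = new_row
        d[:, -1] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    nodes[a].length = max(0.0, 0.5 * (dab + dac - dbc))
    nodes[b].length = max(0.0, 0.5 * (dab + dbc - dac))
    nodes[c].length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as its canonical smaller side.

    Canonical side = the side whose sorted label tuple is lexicographically
    smaller (smaller size first), so rooted placement does not matter.
    """
    leaves = frozenset(t.name for t in tree.tips())
    bips: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(leaves) - 1:
            comp = leaves - s
            side = min(s, comp, key=lambda x: (len(x), tuple(sorted(x))))
            bips.add(side)
    return bips


def bootstrap_support(
    aln: AlignedSet, n_reps: int, seed: int, model: str = "p"
) -> TreeNode:
    """NJ tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times;
    support for each internal edge is the fraction of replicate trees
    containing its bipartition.  Rows are canonically sorted by id before
    any random draw, so supports are invariant to leaf input order for a
    fixed seed.  Supports are stored on ``node.support``, which scikit-bio
    serializes as the internal node label in Newick output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    order = sorted(range(len(aln.ids)), key=lambda k: aln.ids[k])
    canon = AlignedSet(
        ids=[aln.ids[k] for k in order], rows=[aln.rows[k] for k in order]
    )
    main = build_nj(pairwise_distance(canon, model=model))

    rng = np.random.default_rng(seed)
    n_cols = canon.n_columns
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = AlignedSet(
            ids=list(canon.ids),
            rows=["".join(row[c] for c in cols) for row in canon.rows],
        )
        try:
            rep_tree = build_nj(pairwise_distance(rep, model=model))
        except ValueError:
            continue  # a replicate may lose all shared columns for a pair
        for bip in bipartitions(rep_tree):
            counts[bip] = counts.get(bip, 0) + 1

    leaves = frozenset(canon.ids)
    for node in main.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(leaves) - 1:
            side = min(s, leaves - s, key=lambda x: (len(x), tuple(sorted(x))))
            frac = counts.get(side, 0) / n_reps
            node.support = frac  # serialized as the internal Newick label
    return main


def root_at(tree: TreeNode, outgroup: Iterable[str]) -> TreeNode:
    """Root the tree on the edge separating the outgroup from the rest.

    If the outgroup does not form a clade in the unrooted tree, the edge
    maximising outgroup purity (Jaccard similarity between an edge side and
    the outgroup) is used instead, with a warning.
    """
    og = set(outgroup)
    leaves = {t.name for t in tree.tips()}
    if not og:
        raise ValueError("outgroup must be non-empty")
    unknown = og - leaves
    if unknown:
        raise ValueError(f"outgroup labels not in tree: {sorted(unknown)}")
    if og == leaves:
        raise ValueError("outgroup cannot contain every leaf")

    best_node, best_score = None, -1.0
    for node in tree.traverse(include_self=False):
        s = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        for side in (s, leaves - s):
            score = len(side & og) / len(side | og)
            if score > best_score:
                best_node, best_score = node, score
    if best_score < 1.0:
        warnings.warn(
            f"outgroup {sorted(og)} is not a clade in the unrooted tree; "
            f"rooting on the edge with maximal outgroup purity "
            f"(Jaccard {best_score:.2f})",
            stacklevel=2,
        )
    rooted = tree.root_at(best_node, above=True, branch_attrs=[])
    if {t.name for t in rooted.tips()} != leaves:
        raise AssertionError("rooting changed the leaf set")  # pragma: no cover
    return rooted


# ---------------------------------------------------------------------------
# Newick interoperability

def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree (supports as internal labels, lengths after colons)."""
    return TreeNode.read(str(path), format="newick")


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
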