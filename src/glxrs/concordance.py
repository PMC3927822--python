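"""Sister-clade placement and dual-phylogeny concordance verdicts.

The central question: did a non-canonical gene copy arise by in-genome
duplication, by full-length horizontal transfer, or by independent
acquisition of its two domains (a chimera)?  The discriminating evidence is
where the query falls in trees built separately from the N-terminal and
C-terminal domains:

* duplication      — the two copies are sister to each other (or their
                     smallest containing clade is pure for the host group);
* full-length HGT  — both domain trees place the query beside the same
                     foreign donor group;
* chimera          — the two domain trees name different donor groups;
* concordant_native— both domain trees place the query within its own group.

"Sister clade" is made precise as the sibling subtree of the query's
attachment edge in the rooted tree; multifurcating siblings are pooled.
Donor groups are majority calls over the sister leaves with a margin
threshold (default 0.6); anything below is ``ambiguous``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from skbio import TreeNode

from .phylo import bipartitions

DEFAULT_MIN_MARGIN = 0.6

VERDICT_DUPLICATION = "duplication"
VERDICT_FULL_HGT = "full_length_hgt"
VERDICT_CHIMERA = "chimera"
VERDICT_NATIVE = "concordant_native"
VERDICT_AMBIGUOUS = "ambiguous"
VERDICT_HGT = "hgt"


@dataclass(frozen=True)
class PlacementReport:
    """Where a query leaf attaches: its sister leaves and their majority group."""

    query: str
    sister_labels: tuple[str, ...]
    donor_group: str | None
    margin: float
    ambiguous: bool = False


@dataclass(frozen=True)
class OriginVerdict:
    query: str
    verdict: str
    n_placement: PlacementReport | None = None
    c_placement: PlacementReport | None = None
    self_group: str | None = None


def sister_group(
    tree: TreeNode, query: str, groups: Mapping[str, str]
) -> PlacementReport:
    """Report the sister clade of ``query`` and its majority (donor) group.

    The sister clade is the pooled leaf set of all sibling subtrees of the
    query's attachment node (pooling covers multifurcations).  The donor
    group is the most common group label among sister leaves; an exact tie
    marks the report ambiguous.
    """
    try:
        node = tree.find(query)
    except Exception as exc:
        raise ValueError(f"query {query!r} not found in tree") from exc
    if not node.is_tip():
        raise ValueError(f"query {query!r} is not a leaf")
    parent = node.parent
    if parent is None:
        raise ValueError(f"query {query!r} is the tree root; no sister exists")
    sisters: list[str] = []
    for child in parent.children:
        if child is node:
            continue
        if child.is_tip():
            sisters.append(child.name)
        else:
            sisters.extend(t.name for t in child.tips())
    missing = [s for s in sisters if s not in groups]
    if missing:
        raise ValueError(f"sister leaves without group labels: {missing}")
    tally = Counter(groups[s] for s in sisters)
    (top_group, top_n), *rest = tally.most_common()
    margin = top_n / len(sisters)
    tied = bool(rest) and rest[0][1] == top_n
    return PlacementReport(
        query=query,
        sister_labels=tuple(sisters),
        donor_group=None if tied else top_group,
        margin=margin,
        ambiguous=tied,
    )


def is_monophyletic(tree: TreeNode, labels: Iterable[str]) -> bool:
    """True iff some clade's leaf set equals ``labels`` exactly."""
    wanted = set(labels)
    if not wanted:
        raise ValueError("label set must be non-empty")
    leaves = {t.name for t in tree.tips()}
    unknown = wanted - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if wanted == leaves or len(wanted) == 1:
        return True
    lca = tree.lca(list(wanted))
    return {t.name for t in lca.tips()} == wanted


def duplication_test(
    tree: TreeNode,
    copy1: str,
    copy2: str,
    groups: Mapping[str, str],
    min_margin: float = DEFAULT_MIN_MARGIN,
) -> str:
    """Did ``copy2`` arise by duplication of ``copy1`` or by transfer?

    ``duplication`` when the copies are mutual sisters (cherry), copy1 lies
    in copy2's sister clade, or the smallest clade containing both copies is
    pure for the host group; ``hgt`` when copy2's sister clade names a
    foreign donor group with sufficient margin; otherwise ``ambiguous``.
    """
    if copy1 == copy2:
        raise ValueError("copy labels must differ")
    report = sister_group(tree, copy2, groups)
    self_group = groups[copy2]
    if copy1 in report.sister_labels:
        return VERDICT_DUPLICATION
    lca = tree.lca([copy1, copy2])
    clade_groups = {groups[t.name] for t in lca.tips()}
    if clade_groups == {self_group}:
        return VERDICT_DUPLICATION
    if (
        not report.ambiguous
        and report.donor_group != self_group
        and report.margin >= min_margin
    ):
        return VERDICT_HGT
    return VERDICT_AMBIGUOUS


def chimera_test(
    n_tree: TreeNode,
    c_tree: TreeNode,
    query: str,
    groups: Mapping[str, str],
    min_margin: float = DEFAULT_MIN_MARGIN,
) -> OriginVerdict:
    """Compare the query's donor groups in the N- and C-domain trees.

    With gN/gC the donor groups and s the query's own group:
    ``concordant_native`` iff gN = gC = s; ``full_length_hgt`` iff
    gN = gC != s; ``chimera`` iff gN != gC; ``ambiguous`` whenever either
    margin falls below ``min_margin`` or a majority is tied.
    """
    rep_n = sister_group(n_tree, query, groups)
    rep_c = sister_group(c_tree, query, groups)
    self_group = groups.get(query)
    if self_group is None:
        raise ValueError(f"query {query!r} has no group label")
    if (
        rep_n.ambiguous
        or rep_c.ambiguous
        or rep_n.margin < min_margin
        or rep_c.margin < min_margin
    ):
        verdict = VERDICT_AMBIGUOUS
    elif rep_n.donor_group == rep_c.donor_group:
        verdict = (
            VERDICT_NATIVE if rep_n.donor_group == self_group else VERDICT_FULL_HGT
        )
    else:
        verdict = VERDICT_CHIMERA
    return OriginVerdict(
        query=query,
        verdict=verdict,
        n_placement=rep_n,
        c_placement=rep_c,
        self_group=self_group,
    )


def shear_to_shared(t1: TreeNode, t2: TreeNode) -> tuple[TreeNode, TreeNode]:
    """Restrict both trees to their shared leaf set (for RF on unequal sets)."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    shared = l1 & l2
    if not shared:
        raise ValueError("trees share no leaves")
    return t1.shear(shared), t2.shear(shared)


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if not (l1 & l2):
        raise ValueError("trees have disjoint leaf sets")
    if l1 != l2:
        raise ValueError(
            "trees have different leaf sets; use shear_to_shared() first"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))
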