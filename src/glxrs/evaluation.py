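"""Recovery experiments and exact combinatorial oracles.

These routines score the pipeline against simulated ground truth (verdict
recovery), against closed-form/combinatorial references (exhaustive
least-squares topology search, bipartition-enumeration Robinson-Foulds), and
against generating probabilities (tRNA signature frequencies).  They are the
quantitative backbone of the test suite and of ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import concordance, phylo, simulate, trna
from .domains import AlignedSet

# ---------------------------------------------------------------------------
# Verdict recovery on simulated gene histories

SCENARIOS = ("chimera", "full_hgt", "duplication", "none")


def scenario_config(scenario: str, seed: int) -> simulate.SimulationConfig:
    """One-event config for a recovery scenario (4 clades x 6 leaves).

    The event hits genome ``A_0``; clade ``C`` donates; clade ``D`` is the
    untouched outgroup used for rooting.
    """
    events: tuple[simulate.SimEvent, ...]
    if scenario == "chimera":
        events = (simulate.SimEvent("hgt_domain_C", "A_0", donor_clade="C"),)
    elif scenario == "full_hgt":
        events = (simulate.SimEvent("hgt_full", "A_0", donor_clade="C"),)
    elif scenario == "duplication":
        events = (simulate.SimEvent("duplication", "A_0"),)
    elif scenario == "none":
        events = ()
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return simulate.SimulationConfig(seed=seed, events=events)


def _aligned(seqs: dict[str, str]) -> AlignedSet:
    ids = sorted(seqs)
    return AlignedSet(ids=ids, rows=[seqs[i] for i in ids])


def run_scenario_replicate(scenario: str, seed: int) -> tuple[str, str]:
    """Simulate one replicate and return (expected, observed) verdicts."""
    ds = simulate.simulate(scenario_config(scenario, seed))
    groups = ds.groups()
    outgroup = [k for k in groups if groups[k] == "D"]

    if scenario == "duplication":
        tree = phylo.root_at(
            phylo.build_nj(phylo.pairwise_distance(_aligned(ds.full_seqs))),
            outgroup,
        )
        observed = concordance.duplication_test(
            tree, "A_0.gltX1", "A_0.gltX2", groups
        )
        expected = ds.truth.expected_verdict("A_0.gltX2")
        return expected, observed

    n_tree = phylo.root_at(
        phylo.build_nj(phylo.pairwise_distance(_aligned(ds.n_seqs))), outgroup
    )
    c_tree = phylo.root_at(
        phylo.build_nj(phylo.pairwise_distance(_aligned(ds.c_seqs))), outgroup
    )
    verdict = concordance.chimera_test(n_tree, c_tree, "A_0.gltX1", groups)
    return ds.truth.expected_verdict("A_0.gltX1"), verdict.verdict


@dataclass(frozen=True)
class RecoveryResult:
    scenario: str
    n_replicates: int
    n_correct: int
    n_false_chimera: int
    observed: tuple[str, ...]

    @property
    def recovery_rate(self) -> float:
        return self.n_correct / self.n_replicates


def verdict_recovery(
    scenario: str, n_replicates: int = 20, base_seed: int = 0
) -> RecoveryResult:
    """Score verdict recovery over seeded replicates of one scenario."""
    observed, correct, false_chimera = [], 0, 0
    for rep in range(n_replicates):
        expected, got = run_scenario_replicate(scenario, base_seed + 1000 * rep)
        observed.append(got)
        correct += got == expected
        false_chimera += (
            expected != concordance.VERDICT_CHIMERA
            and got == concordance.VERDICT_CHIMERA
        )
    return RecoveryResult(
        scenario=scenario,
        n_replicates=n_replicates,
        n_correct=correct,
        n_false_chimera=false_chimera,
        observed=tuple(observed),
    )


# ---------------------------------------------------------------------------
# Random additive matrices and NJ consistency

def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.1,
    max_branch: float = 1.0,
) -> TreeNode:
    """Random unrooted binary topology with positive branch lengths."""
    labels = [f"t{i}" for i in range(n_leaves)]
    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    center = TreeNode()
    center.extend([TreeNode(name=l, length=bl()) for l in labels[:3]])
    tree = center
    for label in labels[3:]:
        edges = [n for n in tree.traverse(include_self=False)]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        parent.remove(target)
        half = (target.length or 0.0) / 2.0
        mid = TreeNode(length=half)
        target.length = half
        mid.extend([target, TreeNode(name=label, length=bl())])
        parent.append(mid)
    return tree


def additive_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (an additive matrix)."""
    ids = sorted(t.name for t in tree.tips())
    return DistanceMatrix(tree.cophenet().filter(ids).data, ids=ids)


def nj_additive_recovery(
    n_matrices: int = 100,
    seed: int = 0,
    leaf_range: tuple[int, int] = (5, 8),
) -> float:
    """Fraction of random additive matrices whose topology NJ recovers."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_matrices):
        n = int(rng.integers(leaf_range[0], leaf_range[1] + 1))
        true = random_binary_tree(n, rng)
        dm = additive_distances(true)
        est = phylo.build_nj(dm)
        hits += concordance.robinson_foulds(true, est) == 0
    return hits / n_matrices


# ---------------------------------------------------------------------------
# Exhaustive topology enumeration (independent of TreeNode machinery)

def enumerate_topologies(labels: list[str]) -> list[list[tuple[object, object]]]:
    """All unrooted binary topologies as edge lists over leaf labels.

    Internal nodes are integers; leaves are their labels.  Counts follow the
    double factorial (2n-5)!!: 3 for n=4, 15 for n=5, 10395 for n=8.
    """
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    first = [[(0, labels[0]), (0, labels[1]), (0, labels[2])]]
    trees = first
    next_internal = 1
    for label in labels[3:]:
        grown = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, w), (w, v), (w, label)]
                grown.append(new_edges)
        trees = grown
        next_internal += 1
    return trees


def _edge_splits(
    edges: list[tuple[object, object]], labels: list[str]
) -> list[frozenset[str]]:
    """Leaf set on one side of every edge, via adjacency traversal."""
    adj: dict[object, list[object]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = []
    for u, v in edges:
        # leaves reachable from v without crossing u
        stack, seen, side = [v], {u, v}, []
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.append(node)
                continue
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        splits.append(frozenset(side))
    return splits


def topology_bipartitions(
    edges: list[tuple[object, object]], labels: list[str]
) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions of an enumerated topology."""
    full = frozenset(labels)
    bips = set()
    for side in _edge_splits(edges, labels):
        if 1 < len(side) < len(full) - 1:
            comp = full - side
            bips.add(min(side, comp, key=lambda x: (len(x), tuple(sorted(x)))))
    return bips


def topology_newick(edges: list[tuple[object, object]]) -> str:
    """Render an enumerated topology as Newick (unit branch lengths)."""
    adj: dict[object, list[object]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def render(node: object, parent: object) -> str:
        if isinstance(node, str):
            return f"{node}:1"
        kids = [render(c, node) for c in adj[node] if c != parent]
        return "(" + ",".join(kids) + "):1"

    root = 0
    kids = [render(c, root) for c in adj[root]]
    return "(" + ",".join(kids) + ");"


def least_squares_best_topology(dm: DistanceMatrix) -> set[frozenset[str]]:
    """Bipartition set of the OLS-best topology by exhaustive search.

    Fits branch lengths to every unrooted binary topology by ordinary least
    squares on the pairwise distances and returns the minimum-residual
    topology's bipartitions.  Feasible up to n=8 (10,395 topologies).
    """
    labels = list(dm.ids)
    n = len(labels)
    pair_idx = list(itertools.combinations(range(n), 2))
    d_vec = np.array([dm[labels[i], labels[j]] for i, j in pair_idx])
    best_res, best_bips = np.inf, None
    for edges in enumerate_topologies(labels):
        splits = _edge_splits(edges, labels)
        member = np.zeros((len(edges), n), dtype=bool)
        for e, side in enumerate(splits):
            for k, lab in enumerate(labels):
                member[e, k] = lab in side
        a = np.zeros((len(pair_idx), len(edges)))
        for r, (i, j) in enumerate(pair_idx):
            a[r] = member[:, i] ^ member[:, j]
        _, res, *_ = np.linalg.lstsq(a, d_vec, rcond=None)
        resid = (
            float(res[0]) if res.size else
            float(((a @ np.linalg.lstsq(a, d_vec, rcond=None)[0] - d_vec) ** 2).sum())
        )
        if resid < best_res - 1e-12:
            best_res = resid
            best_bips = topology_bipartitions(edges, labels)
    return best_bips


def rf_oracle_agreement(max_leaves: int = 5) -> tuple[int, int]:
    """Check robinson_foulds against enumeration on all small topology pairs.

    For every pair of unrooted topologies on 4..``max_leaves`` leaves,
    compares the tree-based RF with the symmetric difference of
    combinatorially enumerated bipartition sets.  Returns (n_pairs_checked,
    n_agreements).
    """
    checked = agreed = 0
    for n in range(4, max_leaves + 1):
        labels = [f"t{i}" for i in range(n)]
        tops = enumerate_topologies(labels)
        trees = [phylo.parse_newick(topology_newick(e)) for e in tops]
        bips = [topology_bipartitions(e, labels) for e in tops]
        for i, j in itertools.combinations_with_replacement(range(len(tops)), 2):
            expected = len(bips[i] ^ bips[j])
            got = concordance.robinson_foulds(trees[i], trees[j])
            checked += 1
            agreed += got == expected
    return checked, agreed


def caterpillar_newick(order: list[str]) -> str:
    """Caterpillar (ladder) tree over the given leaf order."""
    inner = f"({order[0]}:1,{order[1]}:1):1"
    for label in order[2:-1]:
        inner = f"({inner},{label}:1):1"
    return f"({inner},{order[-1]}:1);"


# ---------------------------------------------------------------------------
# tRNA signature frequencies vs generating probabilities

def trna_signature_experiment(
    seed: int = 0,
    n_per_clade: int = 200,
    p_high: float = 0.95,
    p_low: float = 0.05,
    acceptor_prob: float = 1.0,
):
    """Simulate two clades with contrasting signature probabilities.

    Clade ``G`` (gamma-like) gets the U32-U38/A37 signature with probability
    ``p_high``; clade ``X`` with ``p_low``.  Returns the conservation
    summary frames from :func:`glxrs.trna.conservation_summary`.
    """
    rng = np.random.default_rng(seed)
    genomes = [f"G_{i}" for i in range(n_per_clade)] + [
        f"X_{i}" for i in range(n_per_clade)
    ]
    records = simulate.simulate_trna_records(
        genomes, {"G": p_high, "X": p_low}, rng, acceptor_prob=acceptor_prob
    )
    profiles = [trna.extract_profile(r) for r in records]
    grouping = {g: simulate.clade_of(g) for g in genomes}
    return trna.conservation_summary(profiles, grouping)


def binomial_99_interval(p: float, n: int) -> tuple[float, float]:
    """Central 99% interval for a binomial proportion (exact tails)."""
    from scipy import stats

    lo = stats.binom.ppf(0.005, n, p) / n
    hi = stats.binom.ppf(0.995, n, p) / n
    return float(lo), float(hi)
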