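"""Maximum parsimony over linearly ordered multistate (Wagner) characters.

Characters are ordered and reversible: a change from state ``i`` to state
``j`` costs ``|i - j|`` steps.  Tree length is the minimum total cost over
all ancestral-state assignments, computed by linear-cost dynamic
programming (the Sankoff recursion with an O(S) distance-transform for the
``|i - j|`` cost, so scoring is exact for multifurcating trees too).

The module provides exhaustive search (guaranteed optimal for small taxon
sets), greedy stepwise-addition + nearest-neighbor-interchange hill
climbing, and the parsimony ratchet (iterative reweighting of a random
fraction of characters) for larger sets.  Rooting follows the Lundberg
method: a hypothetical ancestor is attached to the edge that minimizes
total length, so no outgroup is required.  Constraint analysis measures
the extra steps ``S`` needed to force a taxon group to be monophyletic —
the ancestrality statistic used for tRNA isoacceptor and anticodon groups.

All tie-breaks are deterministic (lowest index wins) so repeated runs with
the same seed reproduce byte-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .census import CharacterMatrix

_BIG = 1_000_000  # sentinel cost for impossible leaf states

MAX_EXHAUSTIVE_TAXA = 9


class TaxonMismatchError(ValueError):
    """Tree leaves and matrix taxa do not correspond."""


# ---------------------------------------------------------------------------
# Rooted tree container


@dataclass
class TreeNode:
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RootedTree:
    """Rooted tree with unique leaf labels; may be multifurcating."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def clades(self) -> set[frozenset[str]]:
        """Leaf-label sets below each internal node (excluding the root)."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                out.add(below)
            return below

        walk(self.root)
        return out

    def depths(self) -> dict[str, int]:
        """Root-to-leaf path length in edges for every leaf."""
        out: dict[str, int] = {}
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                out[node.label] = d
            else:
                stack.extend((c, d + 1) for c in node.children)
        return out

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            inner = ",".join(fmt(c) for c in node.children)
            tag = ""
            if with_support and node.support is not None:
                tag = f"{node.support:g}"
            elif node.label:
                tag = node.label
            return f"({inner}){tag}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        def conv(dnode) -> TreeNode:
            if dnode.is_leaf():
                return TreeNode(label=dnode.taxon.label if dnode.taxon else dnode.label)
            node = TreeNode(label=dnode.label)
            node.children = [conv(c) for c in dnode.child_nodes()]
            return node

        return cls(root=conv(dtree.seed_node))


@dataclass
class TreeStats:
    """Ensemble homoplasy and signal statistics for a tree + matrix pair."""

    length: int
    ci: float | None
    ri: float | None
    g1: float | None = None


# ---------------------------------------------------------------------------
# Internal unrooted representation: edge lists over node ids.
# Leaves are 0..n_taxa-1 (taxon indices); internal nodes are >= n_taxa.


def _adjacency(edges: list[tuple[int, int]]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _distance_transform(cost: np.ndarray) -> np.ndarray:
    """min-plus convolution with the |i-j| step cost, in O(S) row passes."""
    out = cost.copy()
    for i in range(1, out.shape[0]):
        np.minimum(out[i], out[i - 1] + 1, out=out[i])
    for i in range(out.shape[0] - 2, -1, -1):
        np.minimum(out[i], out[i + 1] + 1, out=out[i])
    return out


def _leaf_cost(states_row: np.ndarray, n_states: int) -> np.ndarray:
    cost = np.full((n_states, states_row.shape[0]), _BIG, dtype=np.int64)
    cost[states_row, np.arange(states_row.shape[0])] = 0
    return cost


def _score_edges(
    edges: list[tuple[int, int]],
    states: np.ndarray,
    n_states: int,
    weights: np.ndarray | None = None,
) -> int:
    """Total Wagner length of an unrooted tree given leaf state rows."""
    adj = _adjacency(edges)
    n_taxa = states.shape[0]
    # root the DP at any internal node (or a leaf for 2-taxon trees)
    root = next((u for u in adj if u >= n_taxa), min(adj))
    # iterative postorder
    order: list[tuple[int, int]] = []  # (node, parent)
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    cost: dict[int, np.ndarray] = {}
    for node, parent in reversed(order):
        if node < n_taxa:
            c = _leaf_cost(states[node], n_states)
        else:
            c = np.zeros((n_states, states.shape[1]), dtype=np.int64)
        for nb in adj[node]:
            if nb != parent:
                c = c + _distance_transform(cost.pop(nb))
        cost[node] = c
    per_char = cost[root].min(axis=0)
    if weights is None:
        return int(per_char.sum())
    return int((per_char * weights).sum())


def _splits(edges: list[tuple[int, int]], n_taxa: int) -> set[frozenset[int]]:
    """Nontrivial bipartitions, each encoded as the side not containing taxon 0."""
    adj = _adjacency(edges)
    out: set[frozenset[int]] = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) is cut
        side: set[int] = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node < n_taxa:
                side.add(node)
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        if 0 in side:
            side = set(range(n_taxa)) - side
        if 1 < len(side) < n_taxa - 1:
            out.add(frozenset(side))
    return out


def _canonical_key(edges: list[tuple[int, int]], n_taxa: int) -> frozenset[frozenset[int]]:
    return frozenset(_splits(edges, n_taxa))


def _insert_on_edge(
    edges: list[tuple[int, int]], edge_idx: int, leaf: int, new_internal: int
) -> list[tuple[int, int]]:
    u, v = edges[edge_idx]
    out = edges[:edge_idx] + edges[edge_idx + 1:]
    out.extend([(u, new_internal), (new_internal, v), (new_internal, leaf)])
    return out


@lru_cache(maxsize=8)
def _all_topologies(n_taxa: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All (2n-5)!! unrooted binary topologies over taxa 0..n_taxa-1."""
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    trees = [[(0, n_taxa), (1, n_taxa), (2, n_taxa)]]
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        trees = [
            _insert_on_edge(t, i, leaf, next_internal)
            for t in trees
            for i in range(len(t))
        ]
        next_internal += 1
    return tuple(tuple(t) for t in trees)


def _stepwise_addition(
    states: np.ndarray,
    n_states: int,
    weights: np.ndarray | None,
    order: list[int],
    constraint: frozenset[int] | None = None,
) -> list[tuple[int, int]]:
    """Greedy build: insert each taxon on the edge giving the shortest tree."""
    n_taxa = states.shape[0]
    first = order[:3]
    edges = [(first[0], n_taxa), (first[1], n_taxa), (first[2], n_taxa)]
    next_internal = n_taxa + 1
    for leaf in order[3:]:
        best = None
        for i in range(len(edges)):
            cand = _insert_on_edge(edges, i, leaf, next_internal)
            if constraint is not None and not _satisfies(cand, n_taxa, constraint):
                continue
            score = _score_edges(cand, states, n_states, weights)
            if best is None or score < best[0]:
                best = (score, cand)
        if best is None:  # no legal placement: put inside the constrained clade
            raise RuntimeError("stepwise addition found no constraint-legal placement")
        edges = best[1]
        next_internal += 1
    return edges


def _satisfies(edges: list[tuple[int, int]], n_taxa: int, group: frozenset[int]) -> bool:
    """True when `group` forms one side of some split (is monophyletic).

    Works on partial trees during stepwise addition: only the leaves
    actually present are considered, so the constraint is judged on the
    group members added so far.
    """
    adj = _adjacency(edges)
    present = frozenset(u for u in adj if u < n_taxa)
    target = group & present
    if len(target) <= 1 or len(present - target) <= 1:
        return True
    for u, v in edges:
        side: set[int] = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node < n_taxa:
                side.add(node)
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        fside = frozenset(side)
        if fside == target or (present - fside) == target:
            return True
    return False


def _nni_neighbors(edges: list[tuple[int, int]]):
    """Yield the two NNI rearrangements of every internal edge."""
    adj = _adjacency(edges)
    edge_set = {tuple(sorted(e)) for e in edges}
    for u, v in sorted(edge_set):
        if len(adj[u]) < 3 or len(adj[v]) < 3:
            continue
        a, b = [x for x in adj[u] if x != v][:2]
        c, d = [x for x in adj[v] if x != u][:2]
        base = [e for e in edges
                if tuple(sorted(e)) not in {tuple(sorted((u, b))), tuple(sorted((v, c))),
                                            tuple(sorted((u, a))), tuple(sorted((v, d)))}]
        # swap b <-> c
        yield base + [(u, a), (u, c), (v, b), (v, d)]
        # swap b <-> d
        yield base + [(u, a), (u, d), (v, c), (v, b)]


def _spr_neighbors(edges: list[tuple[int, int]], n_taxa: int):
    """Yield subtree-prune-regraft rearrangements (small trees only)."""
    adj = _adjacency(edges)
    norm = lambda e: tuple(sorted(e))
    edge_set = sorted({norm(e) for e in edges})
    for u, v in [(a, b) for a, b in edge_set] + [(b, a) for a, b in edge_set]:
        # prune the subtree on v's side of edge (u, v)
        sub_nodes = {v}
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            for nb in adj[node]:
                if nb != parent:
                    sub_nodes.add(nb)
                    stack.append((nb, node))
        rest = [norm(e) for e in edge_set
                if e[0] not in sub_nodes and e[1] not in sub_nodes]
        if not rest:
            continue
        # suppress u (now degree 2) in the remaining tree
        u_nb = [x for x in adj[u] if x != v]
        if len(u_nb) == 2:
            a, b = u_nb
            rest = [e for e in rest if u not in e] + [norm((a, b))]
        elif len(u_nb) != 0:
            continue  # u of odd degree: skip nonstandard cases
        sub_edges = [norm(e) for e in edge_set
                     if e[0] in sub_nodes and e[1] in sub_nodes]
        for target in sorted(set(rest)):
            a, b = target
            w = u  # reuse the suppressed node id as the new attachment point
            cand = [e for e in rest if e != target]
            cand.extend([(a, w), (w, b), (w, v)])
            cand.extend(sub_edges)
            yield cand


def _hillclimb(
    edges: list[tuple[int, int]],
    states: np.ndarray,
    n_states: int,
    weights: np.ndarray | None = None,
    constraint: frozenset[int] | None = None,
    use_spr: bool | None = None,
) -> tuple[list[tuple[int, int]], int]:
    n_taxa = states.shape[0]
    if use_spr is None:
        use_spr = n_taxa <= 12  # SPR neighborhoods grow ~quadratically
    current = edges
    current_score = _score_edges(current, states, n_states, weights)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current):
            if constraint is not None and not _satisfies(cand, n_taxa, constraint):
                continue
            s = _score_edges(cand, states, n_states, weights)
            if s < current_score:
                current, current_score = cand, s
                improved = True
                break
        if improved or not use_spr:
            continue
        for cand in _spr_neighbors(current, n_taxa):
            if constraint is not None and not _satisfies(cand, n_taxa, constraint):
                continue
            s = _score_edges(cand, states, n_states, weights)
            if s < current_score:
                current, current_score = cand, s
                improved = True
                break
    return current, current_score


def _random_topology(n_taxa: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform draw over labeled unrooted binary topologies (random addition)."""
    edges = [(0, n_taxa), (1, n_taxa), (2, n_taxa)]
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        i = int(rng.integers(len(edges)))
        edges = _insert_on_edge(edges, i, leaf, next_internal)
        next_internal += 1
    return edges


# ---------------------------------------------------------------------------
# Conversions between the internal edge lists and RootedTree


def _edges_to_rooted(
    edges: list[tuple[int, int]], taxa: list[str], root_at: int | None = None
) -> RootedTree:
    """Root the unrooted tree at internal node `root_at` (default: adjacent
    to taxon 0) purely for representation; the topology is unchanged."""
    adj = _adjacency(edges)
    n_taxa = len(taxa)
    if root_at is None:
        root_at = adj[0][0] if len(adj) > 1 else 0

    def build(node: int, parent: int) -> TreeNode:
        if node < n_taxa:
            return TreeNode(label=taxa[node])
        out = TreeNode()
        out.children = [build(nb, node) for nb in sorted(adj[node]) if nb != parent]
        return out

    return RootedTree(root=build(root_at, -1))


def _rooted_to_edges(
    tree: RootedTree, taxa: list[str]
) -> list[tuple[int, int]]:
    """Flatten a rooted tree into the internal unrooted edge list.

    The root is suppressed when it has exactly two children (its two edges
    merge into one), matching the usual rooted/unrooted correspondence.
    """
    index = {t: i for i, t in enumerate(taxa)}
    labels = tree.leaf_labels()
    if set(labels) != set(taxa) or len(labels) != len(taxa):
        raise TaxonMismatchError(
            "tree leaves do not match matrix taxa: "
            f"tree has {sorted(labels)[:5]}..., matrix has {sorted(taxa)[:5]}..."
        )
    edges: list[tuple[int, int]] = []
    counter = [len(taxa)]

    def walk(node: TreeNode) -> int:
        if node.is_leaf:
            return index[node.label]
        my_id = counter[0]
        counter[0] += 1
        for c in node.children:
            edges.append((my_id, walk(c)))
        return my_id

    root_id = walk(tree.root)
    root_edges = [e for e in edges if root_id in e]
    if len(root_edges) == 2:
        (a,), (b,) = ([x for x in e if x != root_id] for e in root_edges)
        edges = [e for e in edges if root_id not in e]
        edges.append((a, b))
    return edges


# ---------------------------------------------------------------------------
# Public operations


def _check_matrix(m: CharacterMatrix) -> None:
    if m.states.shape[0] < 2:
        raise ValueError("need at least 2 taxa")


def wagner_length(tree: RootedTree, m: CharacterMatrix) -> int:
    """Minimum number of ordered-character steps for `tree` given `m`.

    The length is invariant to root placement because the |i-j| cost is
    symmetric (reversible characters).
    """
    _check_matrix(m)
    if len(m.taxa) == 2:
        return int(np.abs(m.states[0] - m.states[1]).sum())
    edges = _rooted_to_edges(tree, m.taxa)
    return _score_edges(edges, m.states, m.n_states)


def search_mp(
    m: CharacterMatrix,
    strategy: str = "hillclimb",
    seed: int | None = None,
    n_ratchet: int = 50,
    n_idle: int = 10,
    n_starts: int | None = None,
    reweight_fraction: float = 0.25,
    reweight_factor: int = 2,
) -> tuple[list[RootedTree], int]:
    """Search for most-parsimonious trees.

    Returns all equally best (co-optimal) trees found and their shared
    length.  ``exhaustive`` enumerates every unrooted binary topology and
    is guaranteed optimal for up to 9 taxa; ``hillclimb`` runs
    ``n_starts`` stepwise-addition builds (the first in input order, the
    rest in seeded random orders) each refined by NNI — plus SPR moves on
    small taxon sets — to a local optimum; ``ratchet`` additionally
    alternates hill climbing on reweighted (a random 25% of characters
    upweighted by ``reweight_factor``) and original matrices until
    ``n_idle`` idle iterations.
    """
    _check_matrix(m)
    n_taxa = len(m.taxa)
    if n_taxa < 3:
        raise ValueError("tree search needs >= 3 taxa")
    states, n_states = m.states, m.n_states

    if strategy == "exhaustive":
        if n_taxa > MAX_EXHAUSTIVE_TAXA:
            raise ValueError(
                f"exhaustive search supports at most {MAX_EXHAUSTIVE_TAXA} taxa "
                f"({n_taxa} requested); use 'hillclimb' or 'ratchet'"
            )
        best: list[list[tuple[int, int]]] = []
        best_score = None
        for topo in _all_topologies(n_taxa):
            s = _score_edges(list(topo), states, n_states)
            if best_score is None or s < best_score:
                best, best_score = [list(topo)], s
            elif s == best_score:
                best.append(list(topo))
        trees = best
    elif strategy in ("hillclimb", "ratchet"):
        if n_starts is None:
            # restarts pay off most where the landscape is small and rugged
            n_starts = 5 if n_taxa <= 12 else 1
        rng_starts = np.random.default_rng(0 if seed is None else seed)
        best_score = None
        found: dict[frozenset, list[tuple[int, int]]] = {}
        edges = None
        for start in range(max(1, n_starts)):
            order = list(range(n_taxa))
            if start > 0:
                rng_starts.shuffle(order)
            cand = _stepwise_addition(states, n_states, None, order)
            cand, score = _hillclimb(cand, states, n_states)
            if best_score is None or score < best_score:
                best_score = score
                found = {_canonical_key(cand, n_taxa): cand}
                edges = cand
            elif score == best_score:
                found.setdefault(_canonical_key(cand, n_taxa), cand)
        if strategy == "ratchet":
            rng = np.random.default_rng(seed)
            n_chars = states.shape[1]
            idle = 0
            current = edges
            for _ in range(n_ratchet):
                if idle >= n_idle:
                    break
                weights = np.ones(n_chars, dtype=np.int64)
                k = max(1, int(round(reweight_fraction * n_chars)))
                hot = rng.choice(n_chars, size=k, replace=False)
                weights[hot] = reweight_factor
                perturbed, _ = _hillclimb(current, states, n_states, weights)
                candidate, score = _hillclimb(perturbed, states, n_states)
                if score < best_score:
                    best_score = score
                    found = {_canonical_key(candidate, n_taxa): candidate}
                    current = candidate
                    idle = 0
                elif score == best_score:
                    key = _canonical_key(candidate, n_taxa)
                    if key not in found:
                        found[key] = candidate
                        idle = 0
                    else:
                        idle += 1
                    current = candidate
                else:
                    idle += 1
        trees = list(found.values())
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return [_edges_to_rooted(t, m.taxa) for t in trees], int(best_score)


def lundberg_root(
    tree: RootedTree, m: CharacterMatrix, ancestor: np.ndarray | None = None
) -> RootedTree:
    """Root a tree by attaching a hypothetical ancestor to the best edge.

    The ancestor's character-state vector is scored as an extra leaf on
    every edge in turn; the edge minimizing total Wagner length receives
    the root (lowest-indexed edge on ties).  The ancestor itself is not
    retained in the output tree.
    """
    if ancestor is None:
        ancestor = m.ancestor
    if ancestor is None:
        raise ValueError("no ancestor vector supplied and matrix carries none")
    ancestor = np.asarray(ancestor, dtype=int)
    if ancestor.shape != (m.n_characters,):
        raise ValueError("ancestor length must equal character count")
    edges = _rooted_to_edges(tree, m.taxa)
    n_taxa = len(m.taxa)
    aug_states = np.vstack([m.states, ancestor])
    # renumber: taxa 0..n-1 keep ids, ancestor becomes leaf n_taxa,
    # old internal ids shift up by one
    shifted = [
        (u if u < n_taxa else u + 1, v if v < n_taxa else v + 1) for u, v in edges
    ]
    best = None
    for i, _ in enumerate(shifted):
        cand = _insert_on_edge(shifted, i, n_taxa, 2 * n_taxa)
        score = _score_edges(cand, aug_states, m.n_states)
        if best is None or score < best[0]:
            best = (score, i)
    _, edge_idx = best
    u, v = edges[edge_idx]
    # root at a new node subdividing the chosen edge
    root_id = max(max(e) for e in edges) + 1
    rooted_edges = edges[:edge_idx] + edges[edge_idx + 1:] + [(root_id, u), (root_id, v)]
    return _edges_to_rooted(rooted_edges, m.taxa, root_at=root_id)


def constraint_S(
    m: CharacterMatrix,
    group: set[str] | frozenset[str],
    ancestor: np.ndarray | None = None,
    strategy: str = "auto",
    seed: int | None = None,
) -> int:
    """Extra parsimony steps needed to force `group` monophyletic.

    The hypothetical ancestor is included as an additional terminal so
    monophyly is defined on the rooted tree.  ``S = 0`` means some optimal
    tree already contains the group as a clade — the group's shared
    derived states are congruent with the rest of the data (the signature
    of an ancient, coherent group); larger ``S`` means increasingly strong
    character conflict with monophyly.
    """
    group = frozenset(group)
    if not group:
        raise ValueError("group must be nonempty")
    unknown = group - set(m.taxa)
    if unknown:
        raise TaxonMismatchError(f"group members not in matrix: {sorted(unknown)}")
    if group == set(m.taxa):
        return 0
    if ancestor is None:
        ancestor = m.ancestor
    if ancestor is None:
        raise ValueError("constraint analysis requires an ancestor vector")
    ancestor = np.asarray(ancestor, dtype=int)

    taxa = list(m.taxa) + ["__anc__"]
    states = np.vstack([m.states, ancestor])
    n_taxa = len(taxa)
    group_idx = frozenset(i for i, t in enumerate(m.taxa) if t in group)

    if strategy == "auto":
        strategy = "exhaustive" if n_taxa <= MAX_EXHAUSTIVE_TAXA else "hillclimb"

    if strategy == "exhaustive":
        best_free = best_con = None
        for topo in _all_topologies(n_taxa):
            s = _score_edges(list(topo), states, m.n_states)
            if best_free is None or s < best_free:
                best_free = s
            if _satisfies(list(topo), n_taxa, group_idx):
                if best_con is None or s < best_con:
                    best_con = s
    else:
        order = list(range(n_taxa))
        e_free = _stepwise_addition(states, m.n_states, None, order)
        _, best_free = _hillclimb(e_free, states, m.n_states)
        # constrained build: place group members first so the clade exists
        con_order = sorted(group_idx) + [i for i in order if i not in group_idx]
        e_con = _stepwise_addition(states, m.n_states, None, con_order,
                                   constraint=group_idx)
        _, best_con = _hillclimb(e_con, states, m.n_states, constraint=group_idx)

    return int(best_con - best_free)


def bootstrap_support(
    m: CharacterMatrix,
    replicates: int = 100,
    seed: int | None = None,
    strategy: str = "hillclimb",
    ancestor: np.ndarray | None = None,
) -> RootedTree:
    """Nonparametric bootstrap: resample characters with replacement.

    Resampling size equals the original character count.  The reference
    tree is the best tree on the full matrix (Lundberg-rooted when an
    ancestor is available); each internal node's support is the percentage
    of replicate best trees whose split set contains that node's split.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    trees, _ = search_mp(m, strategy=strategy, seed=seed)
    if ancestor is None:
        ancestor = m.ancestor
    ref = lundberg_root(trees[0], m, ancestor) if ancestor is not None else trees[0]

    n_chars = m.n_characters
    taxa_index = {t: i for i, t in enumerate(m.taxa)}
    counts: dict[frozenset[int], int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, n_chars, size=n_chars)
        boot = CharacterMatrix(
            taxa=list(m.taxa), n_states=m.n_states, states=m.states[:, cols]
        )
        btrees, _ = search_mp(boot, strategy=strategy, seed=int(rng.integers(2**31)))
        bedges = _rooted_to_edges(btrees[0], m.taxa)
        for split in _splits(bedges, len(m.taxa)):
            counts[split] = counts.get(split, 0) + 1

    n_taxa = len(m.taxa)

    def annotate(node: TreeNode) -> frozenset[int]:
        if node.is_leaf:
            return frozenset([taxa_index[node.label]])
        below = frozenset().union(*(annotate(c) for c in node.children))
        side = below if 0 not in below else frozenset(range(n_taxa)) - below
        if 1 < len(side) < n_taxa - 1:
            node.support = 100.0 * counts.get(side, 0) / replicates
        else:
            node.support = 100.0
        return below

    annotate(ref.root)
    return ref


def character_step_bounds(m: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character minimum (state range) and star-tree maximum steps."""
    minima = m.states.max(axis=0) - m.states.min(axis=0)
    medians = np.median(m.states, axis=0)
    maxima = np.abs(m.states - np.floor(medians)).sum(axis=0)
    maxima_ceil = np.abs(m.states - np.ceil(medians)).sum(axis=0)
    return minima.astype(int), np.minimum(maxima, maxima_ceil).astype(int)


def tree_stats(
    trees: list[RootedTree],
    m: CharacterMatrix,
    n_random: int = 1000,
    seed: int | None = None,
    compute_g1: bool = True,
) -> TreeStats:
    """Ensemble consistency index, retention index and g1 signal skewness.

    CI = (sum of per-character minima) / length; RI = (max - length) /
    (max - min) with the star-tree maximum; g1 is the sample skewness of
    the length distribution of `n_random` uniformly drawn topologies —
    strongly negative g1 indicates phylogenetic signal.
    """
    if not trees:
        raise ValueError("need at least one tree")
    length = wagner_length(trees[0], m)
    minima, maxima = character_step_bounds(m)
    min_sum, max_sum = int(minima.sum()), int(maxima.sum())
    if max_sum == min_sum:
        ci = ri = None
    else:
        ci = min_sum / length if length > 0 else None
        ri = (max_sum - length) / (max_sum - min_sum)
    g1 = None
    if compute_g1 and len(m.taxa) >= 4:
        rng = np.random.default_rng(seed)
        lengths = np.empty(n_random)
        for i in range(n_random):
            topo = _random_topology(len(m.taxa), rng)
            lengths[i] = _score_edges(topo, m.states, m.n_states)
        g1 = float(sps.skew(lengths)) if lengths.std() > 0 else 0.0
    return TreeStats(length=length, ci=ci, ri=ri, g1=g1)
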