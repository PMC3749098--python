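import itertools

import numpy as np
import pytest

from codechron.census import CharacterMatrix


@pytest.fixture
def small_matrix() -> CharacterMatrix:
    """Six taxa, clean two-clade signal plus one noisy character."""
    states = np.array([
        [0, 0, 0, 1, 0],
        [0, 0, 1, 0, 0],
        [0, 1, 0, 0, 3],
        [3, 3, 3, 3, 0],
        [3, 3, 3, 2, 3],
        [3, 2, 3, 3, 3],
    ])
    return CharacterMatrix(
        taxa=list("ABCDEF"), n_states=4, states=states,
        ancestor=np.zeros(5, dtype=int),
    )


# ---------------------------------------------------------------------------
# Independent brute-force parsimony oracle (enumeration over ancestral
# states), used to cross-check the dynamic-programming implementation.


def oracle_wagner_length(edges, leaf_states, n_states):
    """Minimum ordered-character length by exhaustive enumeration of
    ancestral state assignments; exponential, tiny trees only."""
    n_taxa = leaf_states.shape[0]
    internal = sorted({u for e in edges for u in e if u >= n_taxa})
    total = 0
    for c in range(leaf_states.shape[1]):
        best = None
        for combo in itertools.product(range(n_states), repeat=len(internal)):
            assign = {node: s for node, s in zip(internal, combo)}
            for t in range(n_taxa):
                assign[t] = int(leaf_states[t, c])
            cost = sum(abs(assign[u] - assign[v]) for u, v in edges)
            if best is None or cost < best:
                best = cost
        total += best
    return total


def all_unrooted_topologies(n_taxa):
    """All (2n-5)!! unrooted binary trees as edge lists (independent of
    the implementation's enumerator: simple recursive edge insertion)."""
    def insert(trees, leaf, next_internal):
        out = []
        for t in trees:
            for i in range(len(t)):
                u, v = t[i]
                nt = t[:i] + t[i + 1:] + [
                    (u, next_internal), (next_internal, v), (next_internal, leaf)
                ]
                out.append(nt)
        return out

    trees = [[(0, n_taxa), (1, n_taxa), (2, n_taxa)]]
    nxt = n_taxa + 1
    for leaf in range(3, n_taxa):
        trees = insert(trees, leaf, nxt)
        nxt += 1
    return trees
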