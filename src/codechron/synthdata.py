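"""Synthetic censuses, sequence sets and tRNA character matrices.

Real inputs to the pipeline are a genomic census of protein-domain
abundances across proteomes and a culled set of single-domain protein
sequences with secondary-structure assignments.  This module generates
stand-ins with the statistical structure the analyses assume, together
with the ground truth needed for recovery tests:

* ``simulate_census`` — domains are born at ranked times on a random
  Yule organismal tree and accumulate abundance proportional to elapsed
  time with multiplicative log-normal noise, so older domains have
  stochastically larger abundances and occur in more proteomes (the
  monotone-accumulation assumption underlying abundance-based
  polarization).
* ``simulate_sequences`` — protein sequences from first-order residue
  chains; families older than the ancient cutoff draw from a chain whose
  transition weights for a planted dipeptide set are multiplied by an
  enrichment factor.  Each record carries a DSSP-like secondary-structure
  string from a helix/strand/turn/coil segment process.
* ``simulate_trna_matrix`` — ordered multistate characters evolved along
  a known tree with a drift toward higher states (increasing
  conformational order), with groups planted as clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .census import AbundanceMatrix, CharacterMatrix
from .dipeptides import AMINO_ACIDS, AA_INDEX, SequenceRecord
from .parsimony import RootedTree, TreeNode
from .timeline import TimelineEntry

#: Default planted enrichment set: 30 dipeptides (mirroring the scale of a
#: 33-dipeptide enriched set) arranged so no residue appears more than
#: twice in either slot — this keeps the enriched pair-probability
#: construction well-conditioned (see :func:`_pair_probabilities`).
_A = AMINO_ACIDS
DEFAULT_PLANTED = [_A[i] + _A[(i + 1) % 20] for i in range(20)] + [
    _A[i] + _A[(i + 5) % 20] for i in range(10)
]


@dataclass
class SimulationConfig:
    """Knobs for all three generators; the seed fixes every downstream draw."""

    n_domains: int = 50
    n_proteomes: int = 20
    n_trna: int = 8
    seq_count: int = 240
    seq_length_range: tuple[int, int] = (80, 200)
    n_states: int = 24
    planted_dipeptides: list[str] = field(default_factory=lambda: list(DEFAULT_PLANTED))
    enrichment_factor: float = 5.0
    noise_sd: float = 0.3
    seed: int = 0
    # census details
    base_rate: float = 100.0
    # tRNA details
    n_trna_characters: int = 40
    gain_rate: float = 2.0
    loss_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_domains", "n_proteomes", "n_trna", "seq_count"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_domains < 3:
            raise ValueError("n_domains must be >= 3")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for dp in self.planted_dipeptides:
            if len(dp) != 2 or any(c not in AMINO_ACIDS for c in dp.upper()):
                raise ValueError(f"invalid planted dipeptide {dp!r}")


@dataclass
class GroundTruth:
    """What the generator knows and the analyses try to recover."""

    birth_order: list[str] | None = None  # domain ids, oldest first
    trna_group_ages: dict[str, int] | None = None  # group -> age rank (0 oldest)
    trna_groups: dict[str, frozenset[str]] | None = None  # group -> taxa
    enriched_set: list[str] | None = None
    tree: RootedTree | None = None


# ---------------------------------------------------------------------------
# Census


def _yule_clades(n_leaves: int, rng: np.random.Generator) -> list[frozenset[int]]:
    """Leaf sets of all nodes of a random Yule topology, preorder.

    Built by uniform random splitting: starting from one lineage holding
    all leaves, a random extant lineage splits until every lineage holds
    one leaf.  Returned clades are ordered root first, so earlier entries
    are (weakly) larger.
    """
    leaves = list(range(n_leaves))
    rng.shuffle(leaves)
    clades: list[frozenset[int]] = [frozenset(leaves)]
    extant: list[list[int]] = [leaves]
    while any(len(c) > 1 for c in extant):
        splittable = [i for i, c in enumerate(extant) if len(c) > 1]
        i = splittable[int(rng.integers(len(splittable)))]
        lineage = extant.pop(i)
        cut = int(rng.integers(1, len(lineage)))
        left, right = lineage[:cut], lineage[cut:]
        for part in (left, right):
            clades.append(frozenset(part))
            extant.append(part)
    return clades


def simulate_census(config: SimulationConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate a domain x proteome abundance census with known birth order.

    Domain ``k`` (birth rank k, oldest = 0) is born at relative time
    ``k / n_domains`` on a random Yule organismal tree and spreads to the
    proteomes of a tree clade whose size tracks the fraction of lineages
    alive at its birth; occupancy is kept non-increasing in birth rank so
    older domains are systematically more widespread.  Abundance in each
    occupied proteome is ``base_rate * (1 - birth_time)`` with
    multiplicative log-normal noise of scale ``noise_sd``.  Row order is
    shuffled; the ground-truth birth order lists domain ids oldest first.
    """
    rng = np.random.default_rng(config.seed)
    nd, npr = config.n_domains, config.n_proteomes
    clades = _yule_clades(npr, rng)

    g = np.zeros((nd, npr), dtype=np.int64)
    prev_occ = npr + 1
    for k in range(nd):
        birth = k / nd
        target = max(1, round(npr * (1.0 - birth)))
        allowed = [c for c in clades if len(c) <= prev_occ]
        best = min(allowed, key=lambda c: (abs(len(c) - target), -len(c)))
        prev_occ = len(best)
        rate = config.base_rate * (1.0 - birth)
        for p in best:
            noise = np.exp(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 1.0
            g[k, p] = max(0, round(rate * noise))

    domain_ids = [f"d{k:03d}" for k in range(nd)]
    order = rng.permutation(nd)
    shuffled_ids = [domain_ids[i] for i in order]
    matrix = AbundanceMatrix(
        domain_ids=shuffled_ids,
        proteome_ids=[f"p{j:02d}" for j in range(npr)],
        g=g[order],
    )
    # birth order over the shuffled ids: domain_ids[k] has birth rank k
    truth = GroundTruth(birth_order=domain_ids)
    return matrix, truth


# ---------------------------------------------------------------------------
# Sequences


_SS_CLASSES = ("helix", "strand", "turn", "coil")
_SS_PROBS = (0.35, 0.25, 0.2, 0.2)
_SS_MEAN_LEN = {"helix": 9, "strand": 5, "turn": 3, "coil": 5}
_SS_LETTERS = {
    "helix": (("H", 0.8), ("G", 0.15), ("I", 0.05)),
    "strand": (("E", 0.9), ("B", 0.1)),
    "turn": (("T", 0.7), ("S", 0.3)),
    "coil": ((" ", 1.0),),
}


def _structure_string(length: int, rng: np.random.Generator) -> str:
    """Secondary structure from a segment process: runs of one class with
    a single DSSP letter drawn per segment."""
    out: list[str] = []
    while len(out) < length:
        cls = _SS_CLASSES[rng.choice(len(_SS_CLASSES), p=_SS_PROBS)]
        run = 1 + rng.geometric(1.0 / _SS_MEAN_LEN[cls])
        letters, probs = zip(*_SS_LETTERS[cls])
        letter = letters[rng.choice(len(letters), p=np.array(probs))]
        out.extend(letter * run)
    return "".join(out[:length])


def _pair_probabilities(planted: list[str], factor: float) -> np.ndarray:
    """Joint dipeptide probabilities with planted pairs at ~factor x 1/400.

    Starting from the uniform joint matrix, each planted pair (a, b) adds
    a rank-one perturbation ``delta * (e_a - u)(e_b - u)^T`` (u = uniform
    vector) which has zero row and column sums, so both residue marginals
    stay uniform.  The boost therefore cannot leak into the single-residue
    composition of the enriched sequences: only the planted pairs — the
    ground truth — are genuinely over-represented, while the remaining
    pairs are uniformly slightly depleted.
    """
    u = np.full(20, 0.05)
    joint = np.full((20, 20), 1.0 / 400.0)
    delta = (factor - 1.0) / 400.0 / (0.95 * 0.95)
    for dp in planted:
        a, b = AA_INDEX[dp[0].upper()], AA_INDEX[dp[1].upper()]
        ea = -u.copy(); ea[a] += 1.0
        eb = -u.copy(); eb[b] += 1.0
        joint += delta * np.outer(ea, eb)
    if joint.min() <= 0:
        raise ValueError(
            "planted set / enrichment factor too aggressive: some pair "
            "probability went nonpositive; use fewer pairs per residue"
        )
    return joint


def _transition_matrix(planted: list[str], factor: float) -> np.ndarray:
    """First-order chain with uniform stationary residue composition."""
    joint = _pair_probabilities(planted, factor)
    return joint / joint.sum(axis=1, keepdims=True)


def _markov_sequence(length: int, trans: np.ndarray, rng: np.random.Generator) -> str:
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.integers(20)
    for i in range(1, length):
        states[i] = rng.choice(20, p=trans[states[i - 1]])
    return "".join(AMINO_ACIDS[s] for s in states)


def default_timeline(n_families: int = 10) -> list[TimelineEntry]:
    """Evenly spaced fold-family ages on the nd scale (F000 oldest)."""
    return [
        TimelineEntry(domain_id=f"F{k:03d}", nd=k / (n_families - 1))
        for k in range(n_families)
    ]


def simulate_sequences(
    config: SimulationConfig,
    timeline: list[TimelineEntry],
    ancient_cutoff: float = 0.2,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate sequences with age-dependent dipeptide composition.

    ``seq_count`` sequences are assigned round-robin to the timeline's
    fold families.  Families with ``nd <= ancient_cutoff`` draw from the
    enriched first-order chain (planted transition weights multiplied by
    ``enrichment_factor``); younger families draw from the uniform
    background chain.  Every record carries a same-length DSSP-like
    structure string.
    """
    if not timeline:
        raise ValueError("timeline must be nonempty")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.seq_length_range
    background = _transition_matrix([], 1.0)
    enriched = _transition_matrix(config.planted_dipeptides, config.enrichment_factor)

    records: list[SequenceRecord] = []
    for i in range(config.seq_count):
        family = timeline[i % len(timeline)]
        length = int(rng.integers(lo, hi + 1))
        trans = enriched if family.nd <= ancient_cutoff else background
        seq = _markov_sequence(length, trans, rng)
        ss = _structure_string(length, rng)
        records.append(SequenceRecord(
            id=f"seq{i:04d}",
            residues=seq,
            ff_id=family.domain_id,
            nd=family.nd,
            structure=ss,
        ))
    truth = GroundTruth(enriched_set=[d.upper() for d in config.planted_dipeptides])
    return records, truth


# ---------------------------------------------------------------------------
# tRNA character matrices


def _random_rooted_tree(labels: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary rooted topology by sequential random joining."""
    nodes = [TreeNode(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def simulate_trna_matrix(
    config: SimulationConfig,
) -> tuple[CharacterMatrix, GroundTruth]:
    """Ordered multistate characters evolved along a known tRNA tree.

    The ancestor sits at state 0 for every character (minimal
    conformational order).  Characters are dealt round-robin to the
    branches of a random rooted binary tree; each branch increments each
    of its dedicated characters by Poisson(``gain_rate``) states — a
    gains-only drift toward higher conformational order in which every
    character changes on a single branch, so internal branches carry
    clean synapomorphies.  ``loss_rate`` > 0 adds Poisson state losses on
    every character of every branch, injecting homoplasy for robustness
    experiments.  Groups (emulating isoacceptor / anticodon-sharing
    sets) are planted as clades of the generating tree; their age ranks
    follow the node depth of each clade's ancestor.
    """
    if config.n_trna < 4:
        raise ValueError("n_trna must be >= 4")
    rng = np.random.default_rng(config.seed)
    labels = [f"t{k:02d}" for k in range(config.n_trna)]
    root = _random_rooted_tree(labels, rng)
    S, C = config.n_states, config.n_trna_characters

    # deal characters to branches (every non-root node owns one branch)
    branch_nodes: list[TreeNode] = []

    def collect_branches(node: TreeNode) -> None:
        for child in node.children:
            branch_nodes.append(child)
            collect_branches(child)

    collect_branches(root)
    chars = rng.permutation(C)
    dedicated: dict[int, list[int]] = {i: [] for i in range(len(branch_nodes))}
    for j, ch in enumerate(chars):
        dedicated[j % len(branch_nodes)].append(int(ch))
    branch_index = {id(node): i for i, node in enumerate(branch_nodes)}

    states: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, state: np.ndarray) -> None:
        if node is not root:
            state = state.copy()
            for ch in dedicated[branch_index[id(node)]]:
                state[ch] += rng.poisson(config.gain_rate)
            if config.loss_rate > 0:
                state = state - rng.poisson(config.loss_rate, size=C)
            state = np.clip(state, 0, S - 1)
        if node.is_leaf:
            states[node.label] = state
            return
        for child in node.children:
            evolve(child, state)

    evolve(root, np.zeros(C, dtype=np.int64))

    matrix = CharacterMatrix(
        taxa=labels,
        n_states=S,
        states=np.array([states[lab] for lab in labels]),
        ancestor=np.zeros(C, dtype=np.int64),
    )

    # plant groups: the two children of the root, split further if large
    groups: dict[str, frozenset[str]] = {}
    ages: dict[str, int] = {}

    def clade_leaves(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        return [lab for c in node.children for lab in clade_leaves(c)]

    candidates: list[tuple[int, frozenset[str]]] = []

    def collect(node: TreeNode, depth: int) -> None:
        if node.is_leaf:
            return
        leaves = frozenset(clade_leaves(node))
        if 2 <= len(leaves) <= config.n_trna - 2 and depth > 0:
            candidates.append((depth, leaves))
        for c in node.children:
            collect(c, depth + 1)

    collect(root, 0)
    candidates.sort(key=lambda dc: (dc[0], sorted(dc[1])))
    chosen: list[tuple[int, frozenset[str]]] = []
    used: set[str] = set()
    for depth, leaves in candidates:
        if leaves & used:
            continue
        chosen.append((depth, leaves))
        used |= leaves
        if len(chosen) >= 3:
            break
    for rank, (depth, leaves) in enumerate(chosen):
        name = f"G{rank + 1}"
        groups[name] = leaves
        ages[name] = rank

    truth = GroundTruth(
        trna_group_ages=ages,
        trna_groups=groups,
        tree=RootedTree(root=root),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# File output


def write_fasta(records: list[SequenceRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord as BioRecord

    bio = [BioRecord(Seq(r.residues), id=r.id, description=r.ff_id or "") for r in records]
    seqio_write(bio, str(path), "fasta")


def write_family_map(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tff_id\tnd\n")
        for r in records:
            fh.write(f"{r.id}\t{r.ff_id}\t{r.nd:.6f}\n")


def write_abundance_tsv(m: AbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\t" + "\t".join(m.proteome_ids) + "\n")
        for i, did in enumerate(m.domain_ids):
            fh.write(did + "\t" + "\t".join(str(v) for v in m.g[i]) + "\n")


def read_abundance_tsv(path) -> AbundanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceMatrix(
        domain_ids=list(df.index.astype(str)),
        proteome_ids=list(df.columns.astype(str)),
        g=df.to_numpy(dtype=np.int64),
    )
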