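"""Dipeptide-composition signatures of fold families.

A dipeptide (peptide-bond type) is an ordered pair of sequential residues;
a protein of length L contains L-1 overlapping dipeptides.  Per fold
family, the 20-dimensional amino-acid and 400-dimensional dipeptide
frequency vectors form compositional signatures that can be tracked along
the evolutionary timeline (nd).  Dipeptides over-represented in the most
ancient families (nd below a cutoff, default 0.2) relative to the whole
set are detected with the upper-tail hypergeometric test, restricted to
items whose ancient-set frequency exceeds the background (k/n > M/N).

The Kyte-Doolittle hydropathy scale summarizes the hydrophobic character
of residue sets and dipeptide collections; its mean over the full
alphabet is -0.49.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as sps

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: The 400 ordered residue pairs, row-major in AMINO_ACIDS order.
DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]
DIPEP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}

AMBIGUOUS = set("XZ")

#: Kyte-Doolittle hydropathy indices (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Residues charged by the ten aaRSs that carry editing functions.
EDITING_RESIDUES = frozenset("SLPKMIVATF")


@dataclass
class SequenceRecord:
    """A single-domain protein sequence with fold-family id and age."""

    id: str
    residues: str
    ff_id: str | None = None
    nd: float | None = None
    structure: str | None = None
    domain_ranges: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.structure is not None and len(self.structure) != len(self.residues):
            raise ValueError(
                f"{self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.residues)}"
            )


@dataclass
class FoldFamilyProfile:
    ff_id: str
    nd: float
    aa_freq: np.ndarray  # (20,)
    dipep_freq: np.ndarray  # (400,)
    aa_count: int
    dipep_count: int


@dataclass
class EnrichmentResult:
    item: str
    M: int  # occurrences in the full set
    k: int  # occurrences in the ancient set
    N: int  # total occurrences of all items, full set
    n: int  # total occurrences of all items, ancient set
    p: float | None
    enriched: bool


# ---------------------------------------------------------------------------
# Culling


def _ungapped_identity(a: str, b: str) -> float:
    """Best identity over all ungapped slidings: matches / overlap length."""
    if len(a) < len(b):
        a, b = b, a
    best = 0.0
    for offset in range(-len(b) + 1, len(a)):
        lo = max(0, offset)
        hi = min(len(a), offset + len(b))
        if hi - lo < 10:  # ignore trivially short overlaps
            continue
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - offset])
        ident = matches / (hi - lo)
        if ident > best:
            best = ident
    return best


def cull_sequences(
    records: list[SequenceRecord],
    max_identity: float = 0.25,
    length_range: tuple[int, int] = (40, 10_000),
    single_domain: bool = True,
    max_unassigned: int = 30,
) -> list[SequenceRecord]:
    """Filter a sequence set to non-redundant single-domain entries.

    Drops sequences outside ``length_range``, those annotated with more
    than one fold family (when ``single_domain``), and those with an
    unassigned stretch longer than ``max_unassigned`` residues.  The
    survivors are processed by descending length and a sequence is
    rejected when its ungapped sliding identity to any retained sequence
    reaches ``max_identity``.
    """
    lo, hi = length_range
    passed = []
    for rec in records:
        L = len(rec.residues)
        if not (lo <= L <= hi):
            continue
        if single_domain and rec.ff_id is not None and "," in rec.ff_id:
            continue  # two or more fold families assigned
        if rec.domain_ranges:
            covered = np.zeros(L, dtype=bool)
            for a, b in rec.domain_ranges:
                covered[a:b] = True
            run, worst = 0, 0
            for c in covered:
                run = 0 if c else run + 1
                worst = max(worst, run)
            if worst > max_unassigned:
                continue
        passed.append(rec)

    passed.sort(key=lambda r: (-len(r.residues), r.id))
    retained: list[SequenceRecord] = []
    for rec in passed:
        if any(_ungapped_identity(rec.residues, kept.residues) >= max_identity
               for kept in retained):
            continue
        retained.append(rec)
    return retained


# ---------------------------------------------------------------------------
# Counting


def dipeptide_counts(seq: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Count overlapping dipeptides and residues in a sequence.

    Returns ``(dipep, aa, n_ambiguous_pairs)`` where ``dipep`` is the
    400-vector over ordered standard-residue pairs, ``aa`` the 20-vector
    of residue counts, and ``n_ambiguous_pairs`` the number of dipeptides
    containing X or Z (tallied separately, excluded from the 400-vector).
    The standard + ambiguous dipeptide tallies always sum to ``len(seq) - 1``.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    aa = np.zeros(20, dtype=np.int64)
    dipep = np.zeros(400, dtype=np.int64)
    ambiguous = 0
    for ch in seq:
        idx = AA_INDEX.get(ch)
        if idx is not None:
            aa[idx] += 1
        elif ch not in AMBIGUOUS:
            raise ValueError(f"unknown residue {ch!r}")
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        j = DIPEP_INDEX.get(pair)
        if j is not None:
            dipep[j] += 1
        else:
            ambiguous += 1
    return dipep, aa, ambiguous


def build_profiles(
    records: list[SequenceRecord],
) -> tuple[list[FoldFamilyProfile], np.ndarray, list[str], np.ndarray, list[str]]:
    """Pool per-family composition vectors and order them for heat maps.

    Returns ``(profiles, aa_matrix, aa_columns, dipep_matrix, dipep_columns)``.
    Rows of both matrices are fold families sorted by nd ascending (oldest
    first); columns are residues / dipeptides sorted by global mean
    frequency descending, the layout used for evolutionary heat maps.
    """
    missing = [r.id for r in records if r.nd is None or r.ff_id is None]
    if missing:
        raise ValueError(f"records without ff_id/nd: {missing[:10]}")
    by_ff: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_ff.setdefault(rec.ff_id, []).append(rec)

    profiles: list[FoldFamilyProfile] = []
    for ff_id, members in by_ff.items():
        aa_total = np.zeros(20, dtype=np.int64)
        dp_total = np.zeros(400, dtype=np.int64)
        for rec in members:
            dp, aa, _ = dipeptide_counts(rec.residues)
            aa_total += aa
            dp_total += dp
        nd = float(np.mean([r.nd for r in members]))
        aa_n, dp_n = int(aa_total.sum()), int(dp_total.sum())
        profiles.append(FoldFamilyProfile(
            ff_id=ff_id,
            nd=nd,
            aa_freq=aa_total / aa_n if aa_n else aa_total.astype(float),
            dipep_freq=dp_total / dp_n if dp_n else dp_total.astype(float),
            aa_count=aa_n,
            dipep_count=dp_n,
        ))
    profiles.sort(key=lambda p: (p.nd, p.ff_id))

    aa_stack = np.array([p.aa_freq for p in profiles])
    dp_stack = np.array([p.dipep_freq for p in profiles])
    aa_order = np.argsort(-aa_stack.mean(axis=0), kind="stable")
    dp_order = np.argsort(-dp_stack.mean(axis=0), kind="stable")
    aa_cols = [AMINO_ACIDS[i] for i in aa_order]
    dp_cols = [DIPEPTIDES[i] for i in dp_order]
    return profiles, aa_stack[:, aa_order], aa_cols, dp_stack[:, dp_order], dp_cols


# ---------------------------------------------------------------------------
# Enrichment


def hypergeom_enrichment(
    ancient: list[SequenceRecord],
    all_records: list[SequenceRecord],
    alpha: float = 0.01,
    items: str = "dipeptides",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of items in the ancient set.

    For each item with ancient frequency strictly above background
    (k/n > M/N), p = P(X >= k) where X ~ Hypergeom(N, M, n): the chance
    of drawing at least k copies of the item when n of the N pooled
    occurrences are sampled without replacement.  Items failing the
    frequency filter are reported without a p-value.
    """
    ancient_ids = {r.id for r in ancient}
    if not ancient_ids <= {r.id for r in all_records}:
        raise ValueError("ancient set must be a subset of the full record set")

    def totals(records):
        dp = np.zeros(400, dtype=np.int64)
        aa = np.zeros(20, dtype=np.int64)
        for rec in records:
            d, a, _ = dipeptide_counts(rec.residues)
            dp += d
            aa += a
        return dp, aa

    dp_all, aa_all = totals(all_records)
    dp_anc, aa_anc = totals(ancient)
    if items == "dipeptides":
        labels, big, small = DIPEPTIDES, dp_all, dp_anc
    elif items == "residues":
        labels, big, small = list(AMINO_ACIDS), aa_all, aa_anc
    else:
        raise ValueError(f"unknown item universe {items!r}")

    N, n = int(big.sum()), int(small.sum())
    results: list[EnrichmentResult] = []
    for label, M, k in zip(labels, big.tolist(), small.tolist()):
        if k > M or n > N:
            raise ValueError(f"{label}: inconsistent counts k={k} M={M} n={n} N={N}")
        if M == 0 or n == 0 or k * N <= M * n:  # k/n must strictly exceed M/N
            results.append(EnrichmentResult(label, M, k, N, n, None, False))
            continue
        p = float(sps.hypergeom.sf(k - 1, N, M, n))
        results.append(EnrichmentResult(label, M, k, N, n, p, p < alpha))
    return results


def benjamini_hochberg(results: list[EnrichmentResult], alpha: float = 0.01
                       ) -> list[EnrichmentResult]:
    """Re-flag enrichment results with a Benjamini-Hochberg FDR cutoff."""
    tested = [r for r in results if r.p is not None]
    if not tested:
        return results
    order = np.argsort([r.p for r in tested])
    m = len(tested)
    passing = set()
    max_rank = 0
    for rank, idx in enumerate(order, start=1):
        if tested[idx].p <= alpha * rank / m:
            max_rank = rank
    for rank, idx in enumerate(order, start=1):
        if rank <= max_rank:
            passing.add(tested[idx].item)
    for r in results:
        r.enriched = r.item in passing
    return results


# ---------------------------------------------------------------------------
# Group-set contrast


def group_set_contrast(
    records: list[SequenceRecord],
    partition: dict[str, frozenset[str]] | None = None,
    n_permutations: int = 100,
    seed: int | None = None,
) -> dict:
    """Chi-square contrast of dipeptide group-pair proportions vs permutation.

    Each dipeptide maps to the cell (group of residue 1, group of residue
    2) of the partition (default the three aaRS age groups, giving 9
    cells).  The expectation comes from free permutation: residues of the
    concatenated sequences are shuffled, dipeptides recounted, and cell
    proportions averaged over permutations.  Returns observed counts,
    expected proportions, the chi-square statistic and p (df = cells - 1).
    """
    from .timeline import GROUP_123

    partition = partition or GROUP_123
    lookup = {aa: name for name, members in partition.items() for aa in members}
    names = sorted(partition)
    cells = [(a, b) for a in names for b in names]
    cell_index = {c: i for i, c in enumerate(cells)}

    def count_cells(seqs: list[str]) -> np.ndarray:
        out = np.zeros(len(cells), dtype=np.int64)
        for s in seqs:
            for i in range(len(s) - 1):
                g1, g2 = lookup.get(s[i]), lookup.get(s[i + 1])
                if g1 is not None and g2 is not None:
                    out[cell_index[(g1, g2)]] += 1
        return out

    seqs = [r.residues.upper() for r in records]
    observed = count_cells(seqs)
    total = int(observed.sum())
    if total == 0:
        raise ValueError("no classifiable dipeptides in input")

    rng = np.random.default_rng(seed)
    pooled = np.array(list("".join(seqs)))
    lengths = [len(s) for s in seqs]
    acc = np.zeros(len(cells), dtype=float)
    for _ in range(n_permutations):
        perm = pooled[rng.permutation(len(pooled))]
        pieces, start = [], 0
        for L in lengths:
            pieces.append("".join(perm[start:start + L]))
            start += L
        acc += count_cells(pieces)
    expected_prop = acc / acc.sum()

    keep = expected_prop > 0
    if not keep.all():
        warnings.warn("cells with zero permutation expectation dropped from the test")
    obs_k = observed[keep]
    exp_k = expected_prop[keep] / expected_prop[keep].sum() * obs_k.sum()
    chi2 = float(((obs_k - exp_k) ** 2 / exp_k).sum())
    df = int(keep.sum()) - 1
    p = float(sps.chi2.sf(chi2, df))
    return {
        "cells": cells,
        "observed": observed,
        "observed_prop": observed / total,
        "expected_prop": expected_prop,
        "chi2": chi2,
        "df": df,
        "p": p,
    }


# ---------------------------------------------------------------------------
# Hydropathy


def kd_mean(items, scale: dict[str, float] | None = None) -> float:
    """Mean Kyte-Doolittle hydropathy of a residue set or dipeptide list.

    Single-letter items are averaged unweighted; two-letter items
    (dipeptides) contribute both residue slots, so the mean is
    occurrence-weighted over all slots.
    """
    scale = scale or KYTE_DOOLITTLE
    values: list[float] = []
    items = list(items)
    if not items:
        raise ValueError("empty item collection")
    for item in items:
        for ch in item:
            if ch not in scale:
                raise ValueError(f"unknown residue {ch!r}")
            values.append(scale[ch])
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Dipeptide network


def dipeptide_network(enriched: list[str]) -> nx.Graph:
    """Build the peptide-bond graph of an enriched-dipeptide set.

    Nodes are residues; an edge's weight counts the dipeptide types
    joining the pair (AL and LA both contribute to edge A-L), self-pairs
    produce self-loops.  Node attribute ``size`` holds the total number of
    dipeptide types the residue participates in.
    """
    if not enriched:
        raise ValueError("enriched dipeptide list is empty")
    g = nx.Graph()
    for dp in enriched:
        if len(dp) != 2:
            raise ValueError(f"not a dipeptide: {dp!r}")
        a, b = dp[0], dp[1]
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    for node in g.nodes:
        g.nodes[node]["size"] = sum(d["weight"] for _, _, d in g.edges(node, data=True))
    return g
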