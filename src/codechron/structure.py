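"""Secondary-structure region analysis of enriched dipeptides.

DSSP assigns each residue one of eight states: H (alpha-helix), G (3-10
helix), I (pi-helix), E (beta-strand), B (beta-bridge), T (turn), S
(bend), or blank (loop/coil).  For region analysis these collapse to four
classes: helix H = {h,g,i}, strand E = {e,b}, turn/bend T = {t,s}, and
loop (omega) for everything else.  A dipeptide occupies the ordered pair
of its residues' classes; mixed pairs are boundary classes and are merged
symmetrically (T-loop == loop-T) for testing.

Region-bias tests compare, across sequences, the per-sequence frequency
of enriched-dipeptide occurrences in each class against the frequency of
all dipeptides in that class (Mann-Whitney, exact for small samples).
Exchange-group analysis asks how the helix/turn/strand residue groups
distribute over secondary-structure states (one-way ANOVA + Tukey HSD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

OMEGA = "O"  # internal symbol for the loop (omega) class

DSSP_LETTERS = set("HGIEBTS ")

_CLASS_OF = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "T", "S": "T",
}

#: Amino-acid exchange groups tied to secondary structure: H enriched in
#: helix formers, T in turn/bend formers, E in strand formers.
EXCHANGE_GROUPS = {
    "H": frozenset("LKFEQ"),
    "T": frozenset("SPTARCGW"),
    "E": frozenset("YMIVNDH"),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _check_exchange_partition() -> None:
    pooled = sorted("".join("".join(g) for g in EXCHANGE_GROUPS.values()))
    if pooled != sorted(AMINO_ACIDS):
        raise AssertionError("exchange groups must partition the 20 residues")


_check_exchange_partition()


# ---------------------------------------------------------------------------
# Parsing


def parse_dssp(path) -> dict[str, str]:
    """Extract per-chain secondary-structure strings from a DSSP file.

    Handles the classic fixed-column DSSP layout (structure letter at
    column 17, blank = loop, ``!`` rows = chain breaks) and the simplified
    two-column tab-separated annotation (``id<TAB>structure string``) used
    for synthetic data.  Returns a mapping id -> structure string.
    """
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t" in first or (first and not first.startswith("==")):
            # try the simplified format first; fall back to classic below
            if "\t" in first:
                return _parse_simple(fh)
        return _parse_classic(fh)


def _parse_simple(fh) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'id<TAB>structure'")
        out[parts[0]] = parts[1]
    return out


def _parse_classic(fh) -> dict[str, str]:
    lines = fh.read().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = i + 1
            break
    if start is None:
        raise ValueError("malformed DSSP file: no '#  RESIDUE AA ...' header found")
    chains: dict[str, list[str]] = {}
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break / discontinuity
            continue
        chain = line[11].strip() or "A"
        ss = line[16]
        chains.setdefault(chain, []).append(ss if ss in DSSP_LETTERS else " ")
    return {c: "".join(v) for c, v in chains.items()}


def write_simple_annotation(structures: dict[str, str], path) -> None:
    """Write the simplified two-column structure annotation."""
    with open(path, "w") as fh:
        for sid, ss in structures.items():
            fh.write(f"{sid}\t{ss}\n")


# ---------------------------------------------------------------------------
# Region classes


def classify_regions(structure: str) -> str:
    """Map a DSSP string to the four-class region string over {H,E,T,O}.

    h/g/i -> H (helix), e/b -> E (strand), t/s -> T (turn/bend),
    everything else (blank = coil) -> O (loop, omega).  Case-insensitive;
    length-preserving.
    """
    out = []
    for pos, ch in enumerate(structure):
        up = ch.upper()
        if up in _CLASS_OF:
            out.append(_CLASS_OF[up])
        elif up == " " or up == "-" or up == "C":
            out.append(OMEGA)
        else:
            raise ValueError(f"unknown DSSP letter {ch!r} at position {pos}")
    return "".join(out)


def dipeptide_class(c1: str, c2: str) -> str:
    """Class of a dipeptide from its residues' region classes.

    Same class -> that class; mixed -> unordered boundary class such as
    ``T-O`` (turn-loop boundary), written with the two classes sorted.
    """
    if c1 == c2:
        return c1
    return "-".join(sorted((c1, c2)))


ALL_DIPEPTIDE_CLASSES = sorted(
    {dipeptide_class(a, b) for a in "HETO" for b in "HETO"}
)


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(
    x, y, alternative: str = "two-sided", exact_max_n: int = 8
) -> tuple[float, float]:
    """Mann-Whitney U with the small-sample exact null distribution.

    Uses the exact distribution when both samples have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie correction.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegionBiasResult:
    dipeptide_class: str
    u: float
    p: float
    direction: str  # '+', '-' or ''
    n_sequences: int


def _class_frequencies(residues: str, structure: str, enriched: set[str]
                       ) -> tuple[dict[str, int], dict[str, int]]:
    regions = classify_regions(structure)
    enriched_counts: dict[str, int] = {}
    all_counts: dict[str, int] = {}
    seq = residues.upper()
    for i in range(len(seq) - 1):
        cls = dipeptide_class(regions[i], regions[i + 1])
        all_counts[cls] = all_counts.get(cls, 0) + 1
        if seq[i:i + 2] in enriched:
            enriched_counts[cls] = enriched_counts.get(cls, 0) + 1
    return enriched_counts, all_counts


def region_bias_test(
    enriched: list[str], records, alpha: float = 0.05
) -> list[RegionBiasResult]:
    """Test whether enriched dipeptides avoid or prefer structural regions.

    For every sequence the frequency of enriched-dipeptide occurrences in
    each dipeptide class is compared with the frequency of all dipeptides
    in that class; the two per-sequence frequency samples are contrasted
    with a two-sided Mann-Whitney test.  Direction is '+' when the
    enriched-set median exceeds the background median, '-' when below.
    Classes with no occurrences anywhere are skipped.
    """
    enriched_set = {d.upper() for d in enriched}
    per_class_enr: dict[str, list[float]] = {c: [] for c in ALL_DIPEPTIDE_CLASSES}
    per_class_all: dict[str, list[float]] = {c: [] for c in ALL_DIPEPTIDE_CLASSES}
    n_seq = 0
    for rec in records:
        if rec.structure is None:
            continue
        n_seq += 1
        enr, alln = _class_frequencies(rec.residues, rec.structure, enriched_set)
        tot_enr = sum(enr.values())
        tot_all = sum(alln.values())
        for cls in ALL_DIPEPTIDE_CLASSES:
            if tot_enr > 0:
                per_class_enr[cls].append(enr.get(cls, 0) / tot_enr)
            if tot_all > 0:
                per_class_all[cls].append(alln.get(cls, 0) / tot_all)
    if n_seq == 0:
        raise ValueError("no records with structure strings")

    results: list[RegionBiasResult] = []
    for cls in ALL_DIPEPTIDE_CLASSES:
        a, b = per_class_enr[cls], per_class_all[cls]
        if not a or not b or (max(a, default=0) == 0 and max(b, default=0) == 0):
            continue
        u, p = mann_whitney(a, b)
        direction = ""
        if p < alpha:
            direction = "+" if np.median(a) > np.median(b) else "-"
        results.append(RegionBiasResult(cls, u, p, direction, n_seq))
    return results


# ---------------------------------------------------------------------------
# T-Omega ratio


@dataclass
class TOmegaRatio:
    r: float | None
    n_boundary: int
    n_other_loop: int
    defined: bool


def t_omega_ratio(record, enriched: list[str]) -> TOmegaRatio:
    """Ratio of turn-loop boundary dipeptides to other loop dipeptides.

    Counts enriched-dipeptide occurrences whose two residues span a T/loop
    boundary (numerator) versus those touching a loop residue in any other
    configuration (denominator).  High r marks proteins whose loops are
    rigidified by turn boundaries — the signature of ancient structures.
    Undefined (flagged) when the denominator is zero.
    """
    if record.structure is None:
        raise ValueError(f"{record.id}: no structure string")
    regions = classify_regions(record.structure)
    enriched_set = {d.upper() for d in enriched}
    seq = record.residues.upper()
    boundary = other_loop = 0
    for i in range(len(seq) - 1):
        if seq[i:i + 2] not in enriched_set:
            continue
        pair = {regions[i], regions[i + 1]}
        if pair == {"T", OMEGA}:
            boundary += 1
        elif OMEGA in pair:
            other_loop += 1
    if other_loop == 0:
        return TOmegaRatio(None, boundary, 0, defined=False)
    return TOmegaRatio(boundary / other_loop, boundary, other_loop, defined=True)


# ---------------------------------------------------------------------------
# Exchange-group ANOVA


@dataclass
class AnovaResult:
    structure_class: str
    f: float
    p: float
    group_means: dict[str, float]
    letters: dict[str, str]


def _compact_letters(names, means, reject) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinct."""
    order = sorted(range(len(names)), key=lambda i: -means[i])
    letters: list[set[int]] = []  # each letter = set of group indices
    for i in order:
        placed = False
        for members in letters:
            if all(not reject.get(frozenset((i, j)), False) for j in members):
                members.add(i)
                placed = True
        if not placed:
            letters.append({i})
    # drop redundant letters fully contained in another
    letters = [s for k, s in enumerate(letters)
               if not any(s < t for t in letters)]
    out = {name: "" for name in names}
    for k, members in enumerate(letters):
        ch = chr(ord("a") + k)
        for i in members:
            out[names[i]] += ch
    return out


def exchange_group_analysis(
    records,
    groups: dict[str, frozenset[str]] | None = None,
    pool_letters: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[AnovaResult]:
    """Compare residue-group frequencies within secondary-structure classes.

    For each structure class, the observation unit is a sequence: the
    fraction of its residues in that class belonging to each exchange
    group.  A one-way ANOVA across groups is followed by Tukey HSD
    pairwise comparisons summarized as a compact letter display (groups
    sharing a letter are not significantly different at ``alpha``).

    ``pool_letters`` maps raw DSSP letters to pooled classes before
    per-sequence averaging (default: the four-region mapping H/E/T/loop).
    """
    groups = groups or EXCHANGE_GROUPS
    if pool_letters is None:
        pool_letters = {**_CLASS_OF, " ": OMEGA}
    names = sorted(groups)
    lookup = {aa: g for g, members in groups.items() for aa in members}

    # per structure class, per group: list of per-sequence frequencies
    freqs: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        if rec.structure is None:
            continue
        seq = rec.residues.upper()
        per_class: dict[str, dict[str, int]] = {}
        totals: dict[str, int] = {}
        for aa, ss in zip(seq, rec.structure.upper()):
            cls = pool_letters.get(ss)
            if cls is None or aa not in lookup:
                continue
            totals[cls] = totals.get(cls, 0) + 1
            per_class.setdefault(cls, {}).setdefault(lookup[aa], 0)
            per_class[cls][lookup[aa]] += 1
        for cls, tot in totals.items():
            bucket = freqs.setdefault(cls, {g: [] for g in names})
            for g in names:
                bucket[g].append(per_class.get(cls, {}).get(g, 0) / tot)

    results: list[AnovaResult] = []
    for cls in sorted(freqs):
        samples = [np.array(freqs[cls][g]) for g in names]
        if any(len(s) < 2 for s in samples):
            raise ValueError(f"class {cls}: fewer than 2 observations per group")
        if all(np.allclose(s, samples[0]) for s in samples):
            results.append(AnovaResult(cls, 0.0, 1.0,
                                       {g: float(np.mean(s)) for g, s in zip(names, samples)},
                                       {g: "a" for g in names}))
            continue
        f, p = sps.f_oneway(*samples)
        tukey = sps.tukey_hsd(*samples)
        reject = {}
        for i, j in combinations(range(len(names)), 2):
            reject[frozenset((i, j))] = tukey.pvalue[i, j] < alpha
        means = [float(np.mean(s)) for s in samples]
        letters = _compact_letters(names, means, reject)
        results.append(AnovaResult(cls, float(f), float(p),
                                   dict(zip(names, means)), letters))
    return results
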