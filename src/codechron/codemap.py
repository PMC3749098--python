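"""Vis-a-vis genetic-code representation and acceptor-stem summaries.

The vis-a-vis layout places each RNA codon opposite its reverse
complement (position 1 pairs with position 3), so the 64 codons form 32
unordered complementary pairs.  Cells carry the groove mode of tRNA
recognition by the cognate synthetase (class II enzymes approach the
acceptor stem from the major groove, class I from the minor groove) and a
code-expansion stage label.  Acceptor-stem summaries tabulate the N73
discriminator base and the base at position 2 of the acceptor stem (the
2:71 pair), whose composition defines the operational RNA code; across a
complementary codon pair the N2 bases are expected to be coordinated
(C2 opposite G2), with rare exceptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Standard genetic code, RNA alphabet ('*' = stop).
STANDARD_CODE = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: Default groove mode by charged amino acid: class II synthetases (major
#: groove) vs class I (minor groove).  Caller-overridable; known behavioral
#: exceptions (e.g. TyrRS, PheRS) are annotations on top of this default.
CLASS_II_RESIDUES = frozenset("GAPSTHDNKF")

STAGES = ("operational-1", "operational-2", "A", "B", "C", "unassigned")


@dataclass
class CodonCell:
    codon: str
    amino_acid: str  # one-letter code or '*' for stop
    complement_codon: str
    groove_mode: str  # 'major' | 'minor' | 'stop'
    stage: str = "unassigned"


@dataclass
class AcceptorRecord:
    """Acceptor-stem identity data for one tRNA."""

    trna_id: str
    amino_acid: str
    n73: str
    pairs: list[tuple[str, str]]  # base pairs 1:72, 2:71, 3:70, 4:69
    codon: str | None = None

    def __post_init__(self) -> None:
        for base in [self.n73] + [b for p in self.pairs for b in p]:
            if base not in RNA_BASES:
                raise ValueError(f"{self.trna_id}: invalid base {base!r}")


def complement_codon(codon: str) -> str:
    """Reverse complement of an RNA codon (position 1 pairs with 3)."""
    codon = codon.upper().replace("T", "U")
    if len(codon) != 3 or any(b not in _COMPLEMENT for b in codon):
        raise ValueError(f"invalid RNA codon {codon!r}")
    return "".join(_COMPLEMENT[b] for b in reversed(codon))


def complement_pairs() -> list[tuple[str, str]]:
    """The 32 unordered complementary codon pairs of the vis-a-vis layout."""
    seen = set()
    out = []
    for codon in ("".join(p) for p in product(RNA_BASES, repeat=3)):
        comp = complement_codon(codon)
        key = frozenset((codon, comp))
        if key not in seen:
            seen.add(key)
            out.append(tuple(sorted((codon, comp))))
    return out


def build_vis_a_vis(
    code: dict[str, str] | None = None,
    groove: dict[str, str] | None = None,
    stages: dict[str, str] | None = None,
) -> list[CodonCell]:
    """Assemble the 64-cell vis-a-vis table.

    ``groove`` optionally maps codons to 'major'/'minor'; by default the
    mode follows the synthetase class of the encoded amino acid.
    ``stages`` maps codons to code-expansion stage labels; unknown codons
    are labeled 'unassigned' with a warning.
    """
    code = code or STANDARD_CODE
    stages = stages or {}
    cells = []
    missing = []
    for codon in ("".join(p) for p in product(RNA_BASES, repeat=3)):
        aa = code.get(codon, "*")
        if groove and codon in groove:
            mode = groove[codon]
        elif aa == "*":
            mode = "stop"
        else:
            mode = "major" if aa in CLASS_II_RESIDUES else "minor"
        stage = stages.get(codon, "unassigned")
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r} for {codon}")
        if codon not in stages and stages:
            missing.append(codon)
        cells.append(CodonCell(codon, aa, complement_codon(codon), mode, stage))
    if missing:
        warnings.warn(f"{len(missing)} codons without stage labels; marked unassigned")
    by_codon = {c.codon: c for c in cells}
    for c in cells:
        assert c.complement_codon in by_codon
    return cells


def n2_composition(
    records: list[AcceptorRecord], by: str = "amino_acid"
) -> dict:
    """Base composition at acceptor-stem position 2 and N73, per group.

    Groups records by ``by`` ('amino_acid' or 'trna_id' prefix), counts
    A/C/G/U at the N2 position (first base of the 2:71 pair) and at N73,
    and — for records carrying codon annotations — tallies complementary
    codon pairs whose N2 bases are coordinated (Watson-Crick
    complementary, e.g. C2 opposite G2) versus exceptions.
    """
    if not records:
        raise ValueError("no acceptor records")
    comp_n2: dict[str, dict[str, int]] = {}
    comp_n73: dict[str, dict[str, int]] = {}
    usable = []
    for rec in records:
        if len(rec.pairs) < 2:
            warnings.warn(f"{rec.trna_id}: missing 2:71 pair; skipped")
            continue
        usable.append(rec)
        key = getattr(rec, by) if by != "all" else "all"
        comp_n2.setdefault(key, {b: 0 for b in RNA_BASES})
        comp_n73.setdefault(key, {b: 0 for b in RNA_BASES})
        comp_n2[key][rec.pairs[1][0]] += 1
        comp_n73[key][rec.n73] += 1

    by_codon: dict[str, list[AcceptorRecord]] = {}
    for rec in usable:
        if rec.codon:
            by_codon.setdefault(rec.codon.upper(), []).append(rec)
    coordinated = exceptions = 0
    checked_pairs = []
    for c1, c2 in complement_pairs():
        if c1 in by_codon and c2 in by_codon:
            n2_a = by_codon[c1][0].pairs[1][0]
            n2_b = by_codon[c2][0].pairs[1][0]
            ok = _COMPLEMENT[n2_a] == n2_b
            coordinated += ok
            exceptions += not ok
            checked_pairs.append((c1, c2, ok))
    return {
        "n2": comp_n2,
        "n73": comp_n73,
        "n_records": len(usable),
        "coordinated": coordinated,
        "exceptions": exceptions,
        "pairs_checked": checked_pairs,
    }
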